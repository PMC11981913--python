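"""Spine detection, head/neck segmentation, synapse spine-part labels."""

import numpy as np
import pytest
import trimesh

from neurodecomp.spines import (detect_spines, filter_spines,
                                label_synapse_spine_part, segment_head_neck,
                                spine_table)
from neurodecomp.synthetic import KIND_SPINE, tube_mesh
from neurodecomp.types import Branch, Spine, SynapseRecord


def shaft_branch(length=20_000.0, radius=450.0, n=11):
    pts = np.column_stack([np.linspace(0, length, n), np.zeros(n), np.zeros(n)])
    return pts, np.full(n, 2 * radius)


def build_branch_mesh(*extras, length=20_000.0, radius=450.0):
    pts, widths = shaft_branch(length, radius)
    shaft = tube_mesh(pts, np.full(len(pts), radius), 16)
    meshes = [shaft] + list(extras)
    verts = np.concatenate([m.vertices for m in meshes])
    offs = np.cumsum([0] + [len(m.vertices) for m in meshes[:-1]])
    faces = np.concatenate([m.faces + o for m, o in zip(meshes, offs)])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    branch = Branch(branch_id=0, points=pts, width_profile=widths,
                    face_ids=np.arange(len(mesh.faces)))
    return mesh, branch


def test_smooth_cylinder_has_no_spines():
    mesh, branch = build_branch_mesh()
    assert detect_spines(mesh, branch) == []


def test_empty_branch_rejected():
    mesh, branch = build_branch_mesh()
    branch.face_ids = np.zeros(0, dtype=int)
    with pytest.raises(ValueError, match="no mesh faces"):
        detect_spines(mesh, branch)


def test_stubby_hemisphere_height():
    r_head, r_shaft = 600.0, 450.0
    head = trimesh.creation.icosphere(subdivisions=2, radius=r_head)
    head.apply_translation([10_000.0, r_shaft, 0.0])  # centre on the surface
    mesh, branch = build_branch_mesh(head, radius=r_shaft)
    spines = detect_spines(mesh, branch)
    assert len(spines) == 1
    assert spines[0].skeletal_length == pytest.approx(r_head, rel=0.2)
    out = segment_head_neck(mesh, spines[0])
    assert not out.has_neck


def test_mushroom_head_neck_split_and_volume():
    r_head, r_neck, neck_len, r_shaft = 400.0, 100.0, 1500.0, 450.0
    base = np.array([10_000.0, r_shaft - 200.0, 0.0])
    tip = np.array([10_000.0, r_shaft + neck_len + 0.2 * r_head, 0.0])
    neck = tube_mesh(np.array([base, tip]), np.array([r_neck, r_neck]), 10)
    head = trimesh.creation.icosphere(subdivisions=3, radius=r_head)
    head.apply_translation([10_000.0, r_shaft + neck_len + 0.7 * r_head, 0.0])
    mesh, branch = build_branch_mesh(neck, head, radius=r_shaft)
    spines = detect_spines(mesh, branch)
    assert len(spines) == 1
    sp = segment_head_neck(mesh, spines[0])
    assert sp.has_neck
    true_vol = 4.0 / 3.0 * np.pi * r_head ** 3
    assert sp.head_volume == pytest.approx(true_vol, rel=0.15)
    assert sp.neck_width == pytest.approx(2 * r_neck, rel=0.5)
    # containment: head+neck never exceed the whole spine's enclosed volume
    from neurodecomp.spines import _closed_patch_volume
    total = _closed_patch_volume(mesh, sp.face_ids, sp.ring_centroid)
    neck_vol = _closed_patch_volume(mesh, sp.neck_face_ids, sp.ring_centroid)
    assert sp.head_volume + neck_vol <= 1.25 * total


def test_generator_spines_matched(neuron_run):
    """Every detection overlaps a distinct ground-truth spine."""
    det = neuron_run.spines
    assert len(det) > 50
    labels = neuron_run.labels
    matched = set()
    good = 0
    for d in det:
        dset = set(d.face_ids.tolist())
        best, best_ov = None, 0
        for s in neuron_run.neuron.spines:
            tset = set(labels.faces_of(KIND_SPINE, s.spine_id).tolist())
            ov = len(dset & tset)
            if ov > best_ov:
                best_ov, best = ov, s.spine_id
        if best is not None and best_ov > 0.5 * len(dset) and best not in matched:
            matched.add(best)
            good += 1
    assert good / len(det) > 0.85


def test_filter_is_strict_and_order_preserving():
    def spine_of(length, sid):
        return Spine(spine_id=sid, branch_id=0, face_ids=np.array([sid]),
                     base_point=np.zeros(3), skeletal_length=length,
                     axis=np.array([0, 0, 1.0]), ring_centroid=np.zeros(3))
    spines = [spine_of(600, 0), spine_of(700, 1), spine_of(800, 2)]
    kept = filter_spines(spines, 700.0)
    assert [s.spine_id for s in kept] == [2]
    assert filter_spines(spines, 0.0) == spines
    assert filter_spines([], 700.0) == []


def test_synapse_spine_part_partition(neuron_run):
    parts = [s.spine_part for s in neuron_run.graph.synapses.values()]
    assert set(parts) <= {"head", "neck", "shaft", "soma"}
    assert len(parts) == len(neuron_run.graph.synapses)
    # generator head synapses mostly recovered as head
    truth_heads = [s for s in neuron_run.neuron.synapses if s.spine_part == "head"]
    got = neuron_run.graph.synapses
    agree = sum(1 for s in truth_heads if got[s.syn_id].spine_part == "head")
    assert agree / len(truth_heads) > 0.8


def test_head_volume_synapse_size_coupling(neuron_run):
    """The generator couples head volume to synapse size; the measured
    table must recover a positive correlation."""
    table = spine_table(neuron_run.spines,
                        list(neuron_run.graph.synapses.values()),
                        neuron_run.mesh)
    sub = table[(table.n_head_synapses > 0) & (table.head_volume_nm3 > 0)]
    assert len(sub) > 30
    r = np.corrcoef(sub.head_volume_nm3, sub.max_head_synapse_size)[0, 1]
    assert r > 0.3
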