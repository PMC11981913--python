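"""Generator contracts: determinism, geometry closed forms, ground truth."""

import numpy as np
import pytest

from neurodecomp.synthetic import (ERROR_TYPES, KIND_SPINE, MorphologyParams,
                                   generate_neuron, inject_merge_error,
                                   make_scene, mesh_from_neuron, preset_scene,
                                   tube_mesh)
from neurodecomp import preprocess


def test_deterministic_for_fixed_seed():
    p = MorphologyParams(n_dendrite_stems=2, branch_depth=1)
    a = generate_neuron(p, 7)
    b = generate_neuron(MorphologyParams(n_dendrite_stems=2, branch_depth=1), 7)
    assert len(a.branches) == len(b.branches)
    for ba, bb in zip(a.branches, b.branches):
        np.testing.assert_array_equal(ba.points, bb.points)
    assert [s.spine_id for s in a.spines] == [s.spine_id for s in b.spines]
    np.testing.assert_array_equal(
        np.array([s.position for s in a.synapses]),
        np.array([s.position for s in b.synapses]))


@pytest.mark.parametrize("field,value", [
    ("spine_density_per_um", -1.0),
    ("soma_radius_nm", float("nan")),
    ("shaft_synapse_density_per_um", -0.1),
])
def test_bad_parameters_rejected_by_name(field, value):
    with pytest.raises(ValueError, match=field):
        generate_neuron(MorphologyParams(**{field: value}), 0)


def test_minimal_tree_single_unbranched_neurite():
    p = MorphologyParams(n_dendrite_stems=1, branch_depth=0,
                         include_axon=False, include_apical=False,
                         spine_density_per_um=0.0)
    n = generate_neuron(p, 1)
    assert len(n.branches) == 1
    assert n.branches[0].parent_id is None
    assert n.spines == []


def test_zero_spine_density_gives_no_spines():
    p = MorphologyParams(n_dendrite_stems=2, branch_depth=1,
                         spine_density_per_um=0.0)
    assert generate_neuron(p, 3).spines == []


def test_synapse_counts_poisson_mean():
    """Density 2/µm on a ~100 µm dendrite: the across-seed mean count must
    sit within 3 standard errors of density x length."""
    p = MorphologyParams(n_dendrite_stems=1, branch_depth=0,
                         include_axon=False, include_apical=False,
                         segment_length_um=(100.0, 100.0),
                         spine_density_per_um=0.0,
                         shaft_synapse_density_per_um=2.0,
                         soma_synapse_count=0)
    n_seeds = 100
    counts = []
    for seed in range(n_seeds):
        n = generate_neuron(p, seed)
        assert abs(n.branches[0].length_um - 100.0) < 1e-6
        counts.append(len([s for s in n.synapses if s.spine_part == "shaft"]))
    mean = np.mean(counts)
    se = np.sqrt(200.0 / n_seeds)
    assert abs(mean - 200.0) <= 3 * se


def test_cylinder_surface_area_closed_form():
    L, r = 10_000.0, 500.0
    tube = tube_mesh(np.array([[0, 0, 0], [L, 0, 0]]), np.array([r, r]), 24)
    expected = 2 * np.pi * r * L + 2 * np.pi * r ** 2
    assert abs(tube.area - expected) / expected < 0.05


def test_soma_only_mesh_volume_closed_form():
    p = MorphologyParams(n_dendrite_stems=0, branch_depth=0,
                         include_axon=False, include_apical=False,
                         spine_density_per_um=0.0, soma_synapse_count=0)
    n = generate_neuron(p, 0)
    mesh, _ = mesh_from_neuron(n, resolution=12)
    expected = 4.0 / 3.0 * np.pi * n.soma_radius ** 3
    assert abs(mesh.volume - expected) / expected < 0.02


def test_face_labels_resolution_independent_and_conserved():
    p = MorphologyParams(n_dendrite_stems=2, branch_depth=1)
    n = generate_neuron(p, 4)
    m6, l6 = mesh_from_neuron(n, resolution=6)
    m24, l24 = mesh_from_neuron(n, resolution=24)
    # same label sets, counts differ
    key6 = set(zip(l6.kind.tolist(), l6.ref_id.tolist()))
    key24 = set(zip(l24.kind.tolist(), l24.ref_id.tolist()))
    assert key6 == key24
    assert len(l6) == len(m6.faces)
    assert len(l24) == len(m24.faces)


def test_mesh_rejects_low_resolution():
    n = generate_neuron(MorphologyParams(n_dendrite_stems=1, branch_depth=0), 0)
    with pytest.raises(ValueError, match="resolution"):
        mesh_from_neuron(n, resolution=5)


def test_unknown_error_type_lists_supported():
    scene = preset_scene("single", 1, resolution=8,
                         n_dendrite_stems=1, branch_depth=0)
    with pytest.raises(ValueError) as err:
        inject_merge_error(scene, "nonsense", 0)
    for et in ERROR_TYPES:
        assert et in str(err.value)


def test_soma_bridge_requires_two_neurons():
    scene = preset_scene("single", 1, resolution=8,
                         n_dendrite_stems=1, branch_depth=0)
    with pytest.raises(ValueError, match="two neurons"):
        inject_merge_error(scene, "soma_bridge", 0)


def test_injected_error_keeps_scene_connected_and_flags_synapses():
    scene = preset_scene("single", 2, resolution=8,
                         n_dendrite_stems=2, branch_depth=0)
    out = inject_merge_error(scene, "axon_on_dendrite", 2)
    assert len(out.error_truth) == 1
    assert len(out.error_truth[0].face_ids) > 0
    # welded interpenetrating parts count as one bridged component
    comps = preprocess.split_components(out.mesh)
    assert len(comps) == 1
    # every invalid synapse sits on/near the foreign geometry
    foreign_faces = out.error_truth[0].face_ids
    cents = out.mesh.triangles_center[foreign_faces]
    for s in out.synapses:
        if not s.valid:
            d = np.linalg.norm(cents - s.position, axis=1).min()
            assert d < 2_000.0


def test_error_truth_faces_partition_against_components():
    scene = preset_scene("orphan-axon", 4, resolution=8,
                         n_dendrite_stems=2, branch_depth=0)
    lab = scene.labels
    assert len(lab) == len(scene.mesh.faces)
    foreign = set(scene.error_truth[0].face_ids.tolist())
    host = set(np.flatnonzero(lab.component == 0).tolist())
    assert foreign.isdisjoint(host)
    assert foreign | host == set(range(len(scene.mesh.faces)))
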