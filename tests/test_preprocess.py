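"""Mesh cleaning, soma detection, skeletonization, correspondence."""

import networkx as nx
import numpy as np
import pytest
import trimesh
from scipy.stats import spearmanr

from neurodecomp.preprocess import (clean_mesh, detect_somas,
                                    flag_non_neuronal, mesh_correspondence,
                                    skeletonize, split_components)
from neurodecomp.synthetic import glia_blob, orphan_axon, tube_mesh


def straight_tube(length=10_000.0, radius=500.0, n=6, res=16):
    pts = np.column_stack([np.linspace(0, length, n), np.zeros(n), np.zeros(n)])
    return tube_mesh(pts, np.full(n, radius), res)


# ---------------------------------------------------------------------------
# clean_mesh
# ---------------------------------------------------------------------------

def test_clean_merges_duplicate_vertices_preserving_topology():
    tube = straight_tube()
    v = np.vstack([tube.vertices, tube.vertices[:3] + 1e-4])
    f = tube.faces.copy()
    # rewire, for each duplicated vertex, one face reference to the dup
    for k in range(3):
        fi, fj = np.argwhere(f == k)[0]
        f[fi, fj] = len(tube.vertices) + k
    dirty = trimesh.Trimesh(vertices=v, faces=f, process=False)
    out = clean_mesh(dirty)
    assert len(out.vertices) == len(tube.vertices)
    assert len(out.faces) == len(tube.faces)


def test_clean_is_idempotent():
    tube = straight_tube()
    once = clean_mesh(tube)
    twice = clean_mesh(once)
    np.testing.assert_array_equal(once.vertices, twice.vertices)
    np.testing.assert_array_equal(once.faces, twice.faces)


def test_clean_drops_degenerate_face():
    tube = straight_tube()
    f = np.vstack([tube.faces, [[0, 0, 1]]])
    dirty = trimesh.Trimesh(vertices=tube.vertices, faces=f, process=False)
    assert len(clean_mesh(dirty).faces) == len(tube.faces)


def test_clean_rejects_empty():
    with pytest.raises(ValueError, match="empty"):
        clean_mesh(trimesh.Trimesh(vertices=np.zeros((0, 3)),
                                   faces=np.zeros((0, 3), dtype=int),
                                   process=False))


# ---------------------------------------------------------------------------
# soma detection and component flags
# ---------------------------------------------------------------------------

def test_detect_soma_on_synthetic_neuron(neuron_run):
    somas = neuron_run.somas
    assert len(somas) == 1
    truth = neuron_run.neuron
    assert np.linalg.norm(somas[0].centroid - truth.soma_center) < 1000.0
    assert abs(somas[0].radius - truth.soma_radius) / truth.soma_radius < 0.1


def test_bare_tube_has_no_soma():
    assert detect_somas(straight_tube()) == []


def test_isolated_sphere_detected():
    sph = trimesh.creation.icosphere(subdivisions=3, radius=5000.0)
    somas = detect_somas(sph)
    assert len(somas) == 1
    assert np.linalg.norm(somas[0].centroid) < 500.0


def test_two_somas_in_bridged_pair(merged_pair_run):
    assert len(merged_pair_run.somas) == 2


def test_component_flags():
    g_mesh, _ = glia_blob(1)
    assert flag_non_neuronal(g_mesh, detect_somas(g_mesh)) == "glia_like"
    o_mesh, _ = orphan_axon(1)
    assert flag_non_neuronal(o_mesh, detect_somas(o_mesh)) == "fragment"


def test_neuron_flagged_as_neuron(neuron_run):
    assert flag_non_neuronal(neuron_run.mesh, neuron_run.somas) == "neuron"


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

def test_cylinder_skeleton_length_and_axis():
    sk = skeletonize(straight_tube(), [])
    assert abs(sk.total_length - 10_000.0) / 10_000.0 < 0.05
    # deviation from the true axis stays below radius/2
    assert np.abs(sk.points[:, 1:]).max() < 250.0


def test_t_shape_has_one_junction():
    pts1 = np.column_stack([np.linspace(0, 30_000, 16), np.zeros(16), np.zeros(16)])
    pts2 = np.column_stack([np.full(16, 15_000.0),
                            np.linspace(0, 20_000, 16), np.zeros(16)])
    t1 = tube_mesh(pts1, np.full(16, 500.0), 12)
    t2 = tube_mesh(pts2, np.full(16, 500.0), 12)
    T = trimesh.util.concatenate([t1, t2])
    T = trimesh.Trimesh(T.vertices, T.faces, process=False)
    sk = skeletonize(T, [])
    g = sk.as_graph()
    assert nx.is_connected(g)
    assert sum(1 for _, d in g.degree() if d >= 3) == 1


def test_sphere_alone_degenerate():
    sph = trimesh.creation.icosphere(subdivisions=3, radius=5000.0)
    sk = skeletonize(sph, detect_somas(sph))
    assert sk.degenerate


def test_skeleton_recovers_generator_length(neuron_run):
    sk = neuron_run.skeleton
    truth = neuron_run.neuron.total_skeletal_length()
    # within 5% once the intra-soma stem sections are discounted
    internal = neuron_run.graph.soma_internal_length
    assert abs((sk.total_length - internal) - truth) / truth < 0.05


def test_skeleton_is_tree_rooted_at_soma(neuron_run):
    g = neuron_run.skeleton.as_graph()
    assert nx.is_tree(g)
    root = neuron_run.skeleton.root
    assert np.linalg.norm(neuron_run.skeleton.points[root]
                          - neuron_run.somas[0].centroid) < 1.0


# ---------------------------------------------------------------------------
# correspondence and width
# ---------------------------------------------------------------------------

def test_cylinder_width_closed_form():
    tube = straight_tube()
    sk = skeletonize(tube, [])
    corr = mesh_correspondence(tube, sk)
    w = corr.widths[corr.widths > 0]
    assert abs(np.median(w) - 1000.0) / 1000.0 < 0.10


def test_cone_width_monotone():
    pts = np.column_stack([np.linspace(0, 40_000, 21), np.zeros(21), np.zeros(21)])
    cone = tube_mesh(pts, np.linspace(800, 200, 21), 14)
    sk = skeletonize(cone, [])
    corr = mesh_correspondence(cone, sk)
    order = np.argsort(sk.points[:, 0])
    w = corr.widths[order]
    keep = w > 0
    rho = spearmanr(sk.points[order][keep][:, 0], w[keep]).statistic
    assert rho < -0.95


def test_every_face_assigned_exactly_once(neuron_run):
    corr = neuron_run.corr
    assert len(corr.face_edge) == len(neuron_run.mesh.faces)
    assert (corr.face_edge >= 0).all()


def test_soma_point_is_widest(neuron_run):
    sk = neuron_run.skeleton
    corr = neuron_run.corr
    assert corr.widths[sk.root] >= corr.widths.max() * 0.95


def test_correspondence_rejects_empty_skeleton():
    from neurodecomp.types import SkeletonTree
    with pytest.raises(ValueError, match="empty"):
        mesh_correspondence(straight_tube(),
                            SkeletonTree(points=np.zeros((0, 3)),
                                         edges=np.zeros((0, 2), dtype=int)))
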