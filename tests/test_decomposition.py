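"""Decomposition tree invariants, conservation laws, SWC, multi-soma split."""

import networkx as nx
import numpy as np
import pytest

from neurodecomp.decomposition import (decompose, export_swc, graph_from_json,
                                       graph_to_json, parse_swc,
                                       split_multi_soma, swc_total_length_nm)
from neurodecomp.preprocess import Correspondence
from neurodecomp.types import ROOT, SkeletonTree, SomaDetection


def toy_soma(center=(0.0, 0.0, 0.0), radius=100.0):
    return SomaDetection(centroid=np.array(center), radius=radius,
                         face_ids=np.zeros(0, dtype=int),
                         surface_area=1.0, volume=1.0)


def chain_skeleton(n=8, step=1000.0, extra_edges=()):
    pts = np.column_stack([np.arange(n) * step, np.zeros(n), np.zeros(n)])
    edges = [(i, i + 1) for i in range(n - 1)] + list(extra_edges)
    sk = SkeletonTree(points=pts, edges=np.array(edges), soma_nodes=[0])
    sk.radius = np.full(n, 400.0)
    return sk


def test_path_skeleton_gives_single_branch():
    g = decompose(chain_skeleton(), None, [toy_soma()], [])
    assert len(g.branches) == 1
    assert list(g.graph.edges) == [(ROOT, 0)]


def test_bifurcation_gives_three_branches():
    pts = np.array([[0, 0, 0], [1000, 0, 0], [2000, 0, 0],
                    [3000, 1000, 0], [4000, 2000, 0],
                    [3000, -1000, 0], [4000, -2000, 0]], dtype=float)
    edges = np.array([(0, 1), (1, 2), (2, 3), (3, 4), (2, 5), (5, 6)])
    sk = SkeletonTree(points=pts, edges=edges, soma_nodes=[0])
    sk.radius = np.full(7, 300.0)
    g = decompose(sk, None, [toy_soma(radius=200.0)], [])
    assert len(g.branches) == 3
    kids = g.children(ROOT)
    assert len(kids) == 1
    grandkids = g.children(kids[0])
    assert len(grandkids) == 2


def test_cycle_broken_once_with_log():
    # a loop back from node 5 to node 2
    sk = chain_skeleton(n=8, extra_edges=[(5, 2)])
    g = decompose(sk, None, [toy_soma()], [])
    assert nx.is_arborescence(g.graph)
    assert g.graph.number_of_edges() == g.graph.number_of_nodes() - 1
    assert sum("cycle_break" in line for line in g.provenance) == 1


def test_skeletal_length_conserved(neuron_run):
    g = neuron_run.graph
    total = g.total_skeletal_length + g.soma_internal_length
    assert abs(total - neuron_run.skeleton.total_length) <= 1.0


def test_tree_invariants(neuron_run):
    g = neuron_run.graph
    assert nx.is_arborescence(g.graph)
    assert g.graph.number_of_edges() == g.graph.number_of_nodes() - 1
    # stems partition the non-root nodes
    seen = set()
    for stem in g.stems():
        assert seen.isdisjoint(stem)
        seen.update(stem)
    assert seen == set(g.branches)


def test_synapse_conservation(neuron_run):
    g = neuron_run.graph
    assert len(g.synapses) == len(neuron_run.neuron.synapses)
    on_branches = sum(len(b.synapse_ids) for b in g.branches.values())
    assert on_branches + len(g.soma_synapse_ids) == len(g.synapses)


def test_face_partition(neuron_run):
    g = neuron_run.graph
    total = sum(len(b.face_ids) for b in g.branches.values())
    total += len(g.soma_face_ids)
    assert total == len(neuron_run.mesh.faces)


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def test_swc_round_trip(neuron_run):
    text = export_swc(neuron_run.graph)
    df = parse_swc(text)
    assert df.iloc[0].parent == -1
    assert df.iloc[0].type == 1
    assert (df.id == np.arange(1, len(df) + 1)).all()
    g = neuron_run.graph
    skeleton_total = g.total_skeletal_length + sum(
        np.linalg.norm(g.branches[s].points[0] - g.soma.centroid)
        for s in g.stem_roots())
    assert abs(swc_total_length_nm(df) - skeleton_total) < 1.0


def test_swc_axon_rows_typed(neuron_run):
    g = neuron_run.graph
    text = export_swc(g)
    df = parse_swc(text)
    axon_branches = [b for b in g.branches.values()
                     if b.compartment in ("axon", "AIS")]
    assert axon_branches
    n_axon_samples = sum(len(b.points) - (1 if b.parent != ROOT else 0)
                         for b in axon_branches)
    assert (df.type == 2).sum() == n_axon_samples


def test_swc_rejects_multi_root(merged_pair_run):
    with pytest.raises(ValueError, match="multi-root"):
        export_swc(merged_pair_run.merged_graph)


def test_graph_json_round_trip(neuron_run):
    g = neuron_run.graph
    g2 = graph_from_json(graph_to_json(g))
    assert set(g2.branches) == set(g.branches)
    assert abs(g2.total_skeletal_length - g.total_skeletal_length) < 1e-6
    assert sorted(g2.graph.edges) == sorted(g.graph.edges)


# ---------------------------------------------------------------------------
# multi-soma splitting
# ---------------------------------------------------------------------------

def test_single_soma_split_is_identity(neuron_run):
    graphs, edits = split_multi_soma(neuron_run.graph)
    assert len(graphs) == 1 and graphs[0] is neuron_run.graph
    assert edits == []


def test_merged_pair_split(merged_pair_run):
    run = merged_pair_run
    assert len(run.graphs) == 2
    assert len(run.edits) == 1
    weld = run.scene.error_truth[0].location
    d = np.linalg.norm(run.edits[0].cut_location - weld)
    assert d < 10_000.0
    # each side keeps a sane share of its own synapses
    for g in run.graphs:
        assert len(g.synapses) > 50


def test_split_hit_rate_across_scenes():
    """Across several seeded merged pairs, nearly every cut lands within
    10 µm of the true weld."""
    from conftest import build_pair_scene
    from neurodecomp import preprocess
    hits = 0
    seeds = (1, 2, 3, 4)
    for seed in seeds:
        scene = build_pair_scene(seed)
        somas = preprocess.detect_somas(scene.mesh)
        sk = preprocess.skeletonize(scene.mesh, somas)
        corr = preprocess.mesh_correspondence(scene.mesh, sk)
        graph = decompose(sk, corr, somas, scene.input_synapses())
        graphs, edits = split_multi_soma(graph)
        if len(graphs) != 2 or not edits:
            continue
        weld = scene.error_truth[0].location
        d = min(np.linalg.norm(e.cut_location - weld) for e in edits)
        hits += d < 10_000.0
    assert hits >= len(seeds) - 1


def test_split_partitions_synapses(merged_pair_run):
    run = merged_pair_run
    ids = [set(g.synapses) for g in run.graphs]
    assert ids[0].isdisjoint(ids[1])
    assert ids[0] | ids[1] == set(run.merged_graph.synapses)
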