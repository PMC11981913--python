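"""Proximity events, conversion rates, skeletal walks, stratification."""

import networkx as nx
import numpy as np
import pytest

from neurodecomp.proximity import (compute_proximities, conversion_rate,
                                   link_synapses, skeletal_walk,
                                   stratify_conversion)
from neurodecomp.types import ROOT, ProximityRecord, SynapseRecord

from _helpers import toy_graph


def axon_graph(points_list, soma_center):
    g = toy_graph([(pts, ROOT if i == 0 else i - 1, 500)
                   for i, pts in enumerate(points_list)],
                  soma_center=soma_center)
    for b in g.branches.values():
        b.compartment = "axon"
    return g


def dendrite_graph(points_list, soma_center):
    g = toy_graph([(pts, ROOT if i == 0 else i - 1, 500)
                   for i, pts in enumerate(points_list)],
                  soma_center=soma_center)
    for b in g.branches.values():
        b.compartment = "basal"
    return g


def test_parallel_pair_single_event():
    pre = axon_graph([[[0, 0, 0], [20_000, 0, 0]]], [-5000, 0, 0])
    post = dendrite_graph([[[0, 3000, 0], [20_000, 3000, 0]]], [-5000, 3000, 0])
    recs = compute_proximities(pre, post, 1, 2)
    assert len(recs) == 1
    assert recs[0].min_dist == pytest.approx(3000.0, abs=100.0)


def test_separation_beyond_radius_no_event():
    pre = axon_graph([[[0, 0, 0], [20_000, 0, 0]]], [-5000, 0, 0])
    post = dendrite_graph([[[0, 6000, 0], [20_000, 6000, 0]]], [-5000, 6000, 0])
    assert compute_proximities(pre, post, 1, 2) == []


def test_u_shaped_axon_two_events():
    u = [[[0, 10_000, 0], [0, 0, 0]],
         [[0, 0, 0], [40_000, 0, 0]],
         [[40_000, 0, 0], [40_000, 10_000, 0]]]
    pre = axon_graph(u, [0, 15_000, 0])
    post = dendrite_graph([[[-5000, 5000, 1000], [45_000, 5000, 1000]]],
                          [-10_000, 5000, 1000])
    recs = compute_proximities(pre, post, 1, 2)
    assert len(recs) == 2


def test_axonless_pre_graph_warns_and_returns_empty():
    pre = dendrite_graph([[[0, 0, 0], [20_000, 0, 0]]], [-5000, 0, 0])
    post = dendrite_graph([[[0, 3000, 0], [20_000, 3000, 0]]], [-5000, 3000, 0])
    with pytest.warns(UserWarning, match="no axon"):
        assert compute_proximities(pre, post, 1, 2) == []


def test_conversion_rate_cases():
    def rec(n_syn):
        r = ProximityRecord(pre_id=1, post_id=2, point_pre=np.zeros(3),
                            point_post=np.zeros(3), min_dist=1000.0,
                            presyn_walk=0.0, postsyn_walk=0.0)
        r.synapse_ids = list(range(n_syn))
        return r
    assert conversion_rate([rec(1), rec(0)]) == 0.5
    assert conversion_rate([rec(1), rec(2)]) == 1.0
    assert conversion_rate([rec(0), rec(0)]) == 0.0
    assert conversion_rate([]) is None


def test_directionality_is_not_symmetric():
    pre = axon_graph([[[0, 0, 0], [20_000, 0, 0]]], [-5000, 0, 0])
    post = dendrite_graph([[[0, 3000, 0], [20_000, 3000, 0]]], [-5000, 3000, 0])
    forward = compute_proximities(pre, post, 1, 2)
    with pytest.warns(UserWarning):
        backward = compute_proximities(post, pre, 2, 1)
    assert len(forward) == 1 and backward == []


# ---------------------------------------------------------------------------
# skeletal walks
# ---------------------------------------------------------------------------

def test_two_branch_walk():
    g = toy_graph([([[0, 0, 0], [10_000, 0, 0]], ROOT, 500),
                   ([[10_000, 0, 0], [10_000, 20_000, 0]], 0, 500)],
                  soma_center=[-3000, 0, 0])
    assert skeletal_walk(g, [10_000, 20_000, 0]) == pytest.approx(30_000, abs=600)
    assert skeletal_walk(g, [-2500, 0, 0]) == 0.0


def test_far_point_rejected():
    g = toy_graph([([[0, 0, 0], [10_000, 0, 0]], ROOT, 500)],
                  soma_center=[-3000, 0, 0])
    with pytest.raises(ValueError, match="from the skeleton"):
        skeletal_walk(g, [5000, 50_000, 0])


def test_walk_matches_brute_force_path_sum(neuron_run):
    g = neuron_run.graph
    rng = np.random.default_rng(3)
    bids = [b for b in g.branch_ids
            if not g.branches[b].is_soma_node and g.branches[b].skeletal_length > 0]
    for bid in rng.choice(bids, size=min(20, len(bids)), replace=False):
        b = g.branches[bid]
        tip = b.points[-1]
        # oracle: sum of ancestor branch lengths plus this branch
        expect = b.skeletal_length
        cur = g.parent_of(bid)
        while cur is not None and cur != ROOT:
            expect += g.branches[cur].skeletal_length
            cur = g.parent_of(cur)
        got = skeletal_walk(g, tip)
        assert got == pytest.approx(expect, abs=600.0)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def make_events(rng, n, p_syn, pre_cls, post_cls):
    out = []
    for i in range(n):
        r = ProximityRecord(pre_id=1 if pre_cls == "excitatory" else 2,
                            post_id=3 if post_cls == "excitatory" else 4,
                            point_pre=np.zeros(3), point_post=np.zeros(3),
                            min_dist=float(rng.uniform(500, 5000)),
                            presyn_walk=float(rng.uniform(0, 3e5)),
                            postsyn_walk=float(rng.uniform(0, 1e5)))
        if rng.uniform() < p_syn:
            r.synapse_ids = [i]
        out.append(r)
    return out


def test_single_stratum_reproduces_conversion_rate():
    rng = np.random.default_rng(0)
    events = make_events(rng, 200, 0.25, "excitatory", "inhibitory")
    table = stratify_conversion(events, ["pre_class"],
                                class_of={1: "excitatory", 2: "inhibitory",
                                          3: "excitatory", 4: "inhibitory"})
    assert len(table) == 1
    assert table.conversion_rate.iloc[0] == pytest.approx(conversion_rate(events))


def test_radius_sweep_monotone():
    rng = np.random.default_rng(1)
    events = make_events(rng, 300, 0.3, "excitatory", "excitatory")
    table = stratify_conversion(events, ["radius_sweep"],
                                radii_nm=[1000, 2000, 3000, 5000])
    counts = table.sort_values("radius_sweep").n_proximities.tolist()
    assert counts == sorted(counts)


def test_unknown_stratum_rejected():
    with pytest.raises(ValueError, match="unknown stratum"):
        stratify_conversion([], ["favourite_colour"])


def test_planted_rates_recovered():
    """E->I events synapse at 0.3, E->E at 0.05 (n=500 each): the
    stratified table must equal the realized fraction exactly and recover
    the planted rate within sampling error (3 sigma)."""
    rng = np.random.default_rng(7)
    ei = make_events(rng, 500, 0.3, "excitatory", "inhibitory")
    ee = make_events(rng, 500, 0.05, "excitatory", "excitatory")
    table = stratify_conversion(ei + ee, ["post_class"],
                                class_of={1: "excitatory", 2: "inhibitory",
                                          3: "excitatory", 4: "inhibitory"})
    rates = dict(zip(table.post_class, table.conversion_rate))
    realized = {"inhibitory": np.mean([e.n_synapses > 0 for e in ei]),
                "excitatory": np.mean([e.n_synapses > 0 for e in ee])}
    for cls, p in [("inhibitory", 0.3), ("excitatory", 0.05)]:
        assert rates[cls] == pytest.approx(realized[cls])
        assert abs(rates[cls] - p) <= 3 * np.sqrt(p * (1 - p) / 500)


def test_every_synapse_lies_within_an_event_when_radius_covers_clearance():
    pre = axon_graph([[[0, 0, 0], [20_000, 0, 0]]], [-5000, 0, 0])
    post = dendrite_graph([[[0, 3000, 0], [20_000, 3000, 0]]], [-5000, 3000, 0])
    recs = compute_proximities(pre, post, 1, 2, radius=5000.0)
    syns = [SynapseRecord(syn_id=k, pre_id=1, post_id=2,
                          position=np.array([x, 1500.0, 0.0]), size=1.0)
            for k, x in enumerate([2000.0, 9000.0, 18_000.0])]
    link_synapses(recs, syns)
    assert sum(r.n_synapses for r in recs) == len(syns)
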