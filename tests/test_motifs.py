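"""Connectivity graph, triad census vs brute force, null models, enrichment."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from neurodecomp.motifs import (TRIAD_CLASSES, TRIAD_EDGE_COUNT, build_graph,
                                enrichment, null_sample, reciprocal_pair_count,
                                triad_census)


def _pattern_class_lookup() -> dict:
    """Map each of the 64 three-node edge patterns to its isomorphism class
    by classifying each tiny pattern graph once."""
    table = {}
    for pattern in range(64):
        g = nx.DiGraph()
        g.add_nodes_from([0, 1, 2])
        bits = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
        for k, (u, v) in enumerate(bits):
            if pattern >> k & 1:
                g.add_edge(u, v)
        raw = nx.triadic_census(g)
        table[pattern] = next(k for k, v in raw.items() if v == 1)
    return table


def brute_force_census(g: nx.DiGraph) -> dict:
    """Independent oracle: enumerate every node triple and classify its
    edge pattern through the 64-entry lookup."""
    lookup = _pattern_class_lookup()
    counts = {c: 0 for c in TRIAD_CLASSES}
    nodes = list(g.nodes)
    A = nx.to_numpy_array(g, nodelist=nodes, dtype=int)
    n = len(nodes)
    for i, j, k in combinations(range(n), 3):
        pattern = (A[i, j] | A[j, i] << 1 | A[i, k] << 2 | A[k, i] << 3
                   | A[j, k] << 4 | A[k, j] << 5)
        counts[lookup[int(pattern)]] += 1
    return counts


def test_build_graph_weights_and_thresholds():
    df = pd.DataFrame({"pre_id": [1, 1, 1, 2, 3],
                       "post_id": [2, 2, 3, 3, 3],
                       "valid": [1, 1, 1, 1, 0]})
    g = build_graph(df)
    assert g.number_of_edges() == 3
    assert g.edges[1, 2]["weight"] == 2
    g4 = build_graph(df, min_synapses=2)
    assert list(g4.edges) == [(1, 2)]


def test_invalid_only_table_gives_empty_graph():
    df = pd.DataFrame({"pre_id": [1], "post_id": [2], "valid": [0]})
    assert build_graph(df).number_of_edges() == 0


def test_autapses_excluded_by_default():
    df = pd.DataFrame({"pre_id": [1, 1], "post_id": [1, 2], "valid": [1, 1]})
    assert list(build_graph(df).edges) == [(1, 2)]
    assert (1, 1) in build_graph(df, allow_autapses=True).edges


def test_small_census_classes():
    cyc = nx.DiGraph([(1, 2), (2, 3), (3, 1)])
    tc = triad_census(cyc)
    assert tc.counts["030C"] == 1
    assert reciprocal_pair_count(cyc) == 0
    full = nx.DiGraph([(a, b) for a in (1, 2, 3) for b in (1, 2, 3) if a != b])
    assert triad_census(full).counts["300"] == 1
    assert triad_census(nx.DiGraph()).total == 0


def test_census_total_is_number_of_triples():
    g = nx.gnp_random_graph(12, 0.3, directed=True, seed=0)
    tc = triad_census(g)
    from math import comb
    assert tc.total == comb(12, 3)
    # coarsening sums match class sums
    assert sum(tc.by_edge_count().values()) == tc.total


@pytest.mark.parametrize("seed", range(10))
def test_census_matches_brute_force(seed):
    g = nx.gnp_random_graph(30, 0.08, directed=True, seed=seed)
    tc = triad_census(g)
    assert tc.counts == brute_force_census(g)


def test_census_isomorphism_invariant():
    g = nx.gnp_random_graph(15, 0.2, directed=True, seed=3)
    base = triad_census(g).counts
    rng = np.random.default_rng(0)
    for _ in range(20):
        perm = rng.permutation(15)
        mapping = {i: int(perm[i]) for i in range(15)}
        assert triad_census(nx.relabel_nodes(g, mapping)).counts == base


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def observed_graph():
    return nx.gnm_random_graph(40, 160, directed=True, seed=2)


def test_degree_preserving_null_preserves_degrees(observed_graph):
    g = observed_graph
    in0 = sorted(d for _, d in g.in_degree())
    out0 = sorted(d for _, d in g.out_degree())
    # sample a few graphs by reusing the machinery and checking invariants
    work = g.copy()
    from neurodecomp.motifs import _double_edge_swap_directed
    rng = np.random.default_rng(0)
    for _ in range(5):
        _double_edge_swap_directed(work, 10 * g.number_of_edges(), rng)
        assert sorted(d for _, d in work.in_degree()) == in0
        assert sorted(d for _, d in work.out_degree()) == out0
        assert work.number_of_edges() == g.number_of_edges()


def test_proximity_constrained_null_subset(observed_graph):
    g = observed_graph
    rng = np.random.default_rng(4)
    prox = set(g.edges)
    nodes = list(g.nodes)
    while len(prox) < 3 * g.number_of_edges():
        u, v = rng.integers(0, len(nodes), size=2)
        if u != v:
            prox.add((nodes[u], nodes[v]))
    prox = sorted(prox)
    samples, mean, sd = null_sample(g, "proximity_constrained", n_samples=10,
                                    seed=1, proximity_edges=prox)
    assert samples.shape == (10, 16)
    # edge count conserved: total triads constant
    assert np.allclose(samples.sum(axis=1), samples.sum(axis=1)[0])


def test_proximity_constrained_validates_input(observed_graph):
    with pytest.raises(ValueError, match="contain every observed"):
        null_sample(observed_graph, "proximity_constrained", n_samples=1,
                    seed=0, proximity_edges=[(0, 1)])


def test_random_shuffle_reciprocal_pairs_match_closed_form():
    """Uniform rewiring: expected reciprocal dyads C(n,2) p^2 with
    p = 1-(1-1/(n(n-1)))^m (independent uniform edge placement)."""
    n, m = 50, 200
    g = nx.gnm_random_graph(n, m, directed=True, seed=1)
    rng = np.random.default_rng([1, 23])
    nodes = list(g.nodes)
    vals = []
    for _ in range(250):
        g2 = nx.DiGraph()
        g2.add_nodes_from(nodes)
        for _ in range(m):
            while True:
                u, v = rng.integers(0, n, size=2)
                if u != v:
                    break
            g2.add_edge(nodes[u], nodes[v])
        vals.append(reciprocal_pair_count(g2))
    p = 1 - (1 - 1 / (n * (n - 1))) ** m
    expect = n * (n - 1) / 2 * p * p
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - expect) <= 3 * se


def test_unknown_null_kind_rejected(observed_graph):
    with pytest.raises(ValueError, match="unknown null kind"):
        null_sample(observed_graph, "bogus", n_samples=1, seed=0)


def test_null_sampling_reproducible(observed_graph):
    a = null_sample(observed_graph, "random_shuffle", n_samples=5, seed=9)[0]
    b = null_sample(observed_graph, "random_shuffle", n_samples=5, seed=9)[0]
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_enrichment_null_observation():
    g = nx.gnp_random_graph(20, 0.2, directed=True, seed=5)
    obs = triad_census(g)
    mean = obs.as_array()
    sd = np.ones(16)
    e = enrichment(obs, mean, sd)
    assert all(abs(z) < 1e-12 for z in e.z.values())
    for code, r in e.ratio.items():
        if mean[TRIAD_CLASSES.index(code)] > 0:
            assert r == pytest.approx(1.0)


def test_zero_variance_classes_reported_separately():
    g = nx.gnp_random_graph(10, 0.2, directed=True, seed=1)
    obs = triad_census(g)
    sd = np.zeros(16)
    e = enrichment(obs, obs.as_array(), sd)
    assert set(e.zero_variance) == set(TRIAD_CLASSES)


def test_planted_triangles_enriched():
    """Adding transitive triangles at well above chance rate must produce
    positive z-scores for edge-dense classes in >=95% of replicates."""
    dense = [c for c in TRIAD_CLASSES if TRIAD_EDGE_COUNT[c] >= 3]
    wins = 0
    reps = 20
    for rep in range(reps):
        rng = np.random.default_rng([rep, 77])
        g = nx.gnm_random_graph(40, 120, directed=True, seed=rep)
        nodes = list(g.nodes)
        for _ in range(25):  # plant feed-forward triangles
            a, b, c = rng.choice(len(nodes), size=3, replace=False)
            g.add_edges_from([(nodes[a], nodes[b]), (nodes[b], nodes[c]),
                              (nodes[a], nodes[c])])
        obs = triad_census(g)
        samples, _, _ = null_sample(g, "random_shuffle", n_samples=100,
                                    seed=rep)
        didx = [TRIAD_CLASSES.index(c) for c in dense]
        obs_dense = obs.as_array()[didx].sum()
        null_dense = samples[:, didx].sum(axis=1)
        z = (obs_dense - null_dense.mean()) / max(null_dense.std(), 1e-9)
        if z > 0:
            wins += 1
    assert wins / reps >= 0.95
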