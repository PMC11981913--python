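"""Neuron-level connectivity graph, triad census and null models.

The connectivity graph has neurons as nodes and a directed edge pre->post
when at least ``min_synapses`` valid synapses connect the pair.  The triad
census counts the 16 directed three-node isomorphism classes
(Holland-Leinhardt codes via networkx) plus a coarsening by the number of
edges among the three nodes.  Three null models reproduce the comparisons
of interest: degree-preserving double-edge swaps, proximity-constrained
edge placement, and uniform rewiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

TRIAD_CLASSES = ("003", "012", "102", "021D", "021U", "021C", "111D", "111U",
                 "030T", "030C", "201", "120D", "120U", "120C", "210", "300")

#: number of directed edges among the 3 nodes for each class code
TRIAD_EDGE_COUNT = {code: 2 * int(code[0]) + int(code[1]) for code in TRIAD_CLASSES}

DEFAULT_NULL_SAMPLES = 250
DEFAULT_SWAPS_PER_EDGE = 10


@dataclass
class TriadCensus:
    counts: dict[str, int]

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in TRIAD_CLASSES], dtype=float)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def by_edge_count(self) -> dict[int, int]:
        """Coarsening: triad counts grouped by #edges among the 3 nodes."""
        out: dict[int, int] = {k: 0 for k in range(7)}
        for code, n in self.counts.items():
            out[TRIAD_EDGE_COUNT[code]] += n
        return out

    @property
    def reciprocal_pairs(self) -> int:
        """Number of mutually connected dyads implied by the graph census is
        not recoverable from triads alone; use :func:`reciprocal_pair_count`
        on the graph instead."""
        raise AttributeError("use reciprocal_pair_count(graph)")


def build_graph(synapse_table: pd.DataFrame, labels: dict[int, str] | None = None,
                min_synapses: int = 1, allow_autapses: bool = False) -> nx.DiGraph:
    """Connectivity graph from a synapse table.

    ``synapse_table`` needs columns pre_id, post_id and (optionally) valid;
    rows with valid == 0 are ignored.  Edge weight = number of synapses.
    """
    df = synapse_table
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    if not allow_autapses:
        df = df[df["pre_id"] != df["post_id"]]
    g = nx.DiGraph()
    if labels:
        for node, cls in labels.items():
            g.add_node(node, cell_class=cls)
    counts = df.groupby(["pre_id", "post_id"]).size()
    for (pre, post), n in counts.items():
        if n >= min_synapses:
            g.add_edge(pre, post, weight=int(n))
    return g


def degree_summary(graph: nx.DiGraph) -> dict:
    n = graph.number_of_nodes()
    if n == 0:
        return {"n_nodes": 0, "n_edges": 0, "mean_in": 0.0, "mean_out": 0.0}
    return {"n_nodes": n, "n_edges": graph.number_of_edges(),
            "mean_in": sum(d for _, d in graph.in_degree()) / n,
            "mean_out": sum(d for _, d in graph.out_degree()) / n}


def reciprocal_pair_count(graph: nx.DiGraph) -> int:
    return sum(1 for u, v in graph.edges if u < v and graph.has_edge(v, u))


def triad_census(graph: nx.DiGraph) -> TriadCensus:
    """Exact counts of the 16 directed triad classes over all node triples.

    Multi-edge weights are ignored (the census is over the simple digraph);
    graphs with fewer than 3 nodes give an all-zero census.
    """
    if graph.number_of_nodes() < 3:
        return TriadCensus(counts={c: 0 for c in TRIAD_CLASSES})
    raw = nx.triadic_census(graph)
    return TriadCensus(counts={c: int(raw[c]) for c in TRIAD_CLASSES})


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def _double_edge_swap_directed(g: nx.DiGraph, nswap: int, rng) -> None:
    """In-place directed double edge swaps preserving in/out degrees."""
    edges = list(g.edges)
    tries = 0
    swaps = 0
    max_tries = nswap * 20
    while swaps < nswap and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if a == d or c == b:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        swaps += 1


def null_sample(graph: nx.DiGraph, kind: str, n_samples: int = DEFAULT_NULL_SAMPLES,
                seed: int = 0, proximity_edges=None,
                swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE):
    """Triad-census distribution under a null model.

    kinds:
      degree_preserving  — directed double-edge swaps (in/out degree
                           sequences preserved); burn-in 10x|E| swaps
                           between samples
      proximity_constrained — |E| edges drawn uniformly without replacement
                           from the proximity edge set (must cover the
                           observed synapse edges and be at least |E| big)
      random_shuffle     — both endpoints rewired uniformly (no self-loops)

    Returns (censuses: n_samples x 16 array, mean, sd) — all reproducible
    from ``seed``.
    """
    rng = np.random.default_rng([int(seed), 23])
    m = graph.number_of_edges()
    nodes = list(graph.nodes)
    out = np.zeros((n_samples, len(TRIAD_CLASSES)))
    if kind == "degree_preserving":
        work = graph.copy()
        for k in range(n_samples):
            _double_edge_swap_directed(work, swaps_per_edge * m, rng)
            out[k] = triad_census(work).as_array()
    elif kind == "proximity_constrained":
        if proximity_edges is None:
            raise ValueError("proximity_constrained requires proximity_edges")
        prox = [tuple(e) for e in proximity_edges]
        observed = set(graph.edges)
        if not observed.issubset(set(prox)):
            raise ValueError("proximity edge set must contain every observed "
                             "synapse edge")
        if len(prox) < m:
            raise ValueError(f"proximity edge set ({len(prox)}) smaller than "
                             f"|E| ({m})")
        for k in range(n_samples):
            take = rng.choice(len(prox), size=m, replace=False)
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(prox[i] for i in take)
            out[k] = triad_census(g).as_array()
    elif kind == "random_shuffle":
        for k in range(n_samples):
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            for _ in range(m):
                while True:
                    u, v = rng.integers(0, len(nodes), size=2)
                    if u != v:
                        break
                g.add_edge(nodes[u], nodes[v])
            out[k] = triad_census(g).as_array()
    else:
        raise ValueError(f"unknown null kind {kind!r}; choose "
                         "degree_preserving|proximity_constrained|random_shuffle")
    return out, out.mean(axis=0), out.std(axis=0, ddof=0)


@dataclass
class Enrichment:
    z: dict[str, float] = field(default_factory=dict)
    ratio: dict[str, float] = field(default_factory=dict)
    zero_variance: list[str] = field(default_factory=list)


def enrichment(observed: TriadCensus, null_mean: np.ndarray,
               null_sd: np.ndarray) -> Enrichment:
    """Per-class z-score and fold ratio of the observed census vs a null.

    Classes with zero null variance are reported separately rather than
    scored.
    """
    obs = observed.as_array()
    out = Enrichment()
    for i, code in enumerate(TRIAD_CLASSES):
        if null_sd[i] > 0:
            out.z[code] = float((obs[i] - null_mean[i]) / null_sd[i])
            out.ratio[code] = float(obs[i] / null_mean[i]) if null_mean[i] > 0 \
                else float("inf") if obs[i] > 0 else 1.0
        else:
            out.zero_variance.append(code)
    return out


def census_table(observed: TriadCensus, nulls: dict[str, tuple] | None = None
                 ) -> pd.DataFrame:
    """Tabular census (+ per-null mean/sd/z when provided)."""
    rows = []
    obs = observed.as_array()
    for i, code in enumerate(TRIAD_CLASSES):
        row = {"triad": code, "n_edges": TRIAD_EDGE_COUNT[code],
               "observed": int(obs[i])}
        if nulls:
            for name, (mean, sd) in nulls.items():
                row[f"{name}_mean"] = mean[i]
                row[f"{name}_sd"] = sd[i]
                row[f"{name}_z"] = ((obs[i] - mean[i]) / sd[i]) if sd[i] > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
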