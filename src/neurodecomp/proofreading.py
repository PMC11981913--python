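"""Heuristic graph filters for merge-error correction, with full audit.

Each rule inspects the decomposition graph and flags nodes whose local
features match a merge-error signature (double-backs toward the soma,
sharp width jumps, high-degree axon crossings, axon-like subtrees hanging
off dendrites).  ``apply_filters`` runs rules in a user-given order; after
each rule the flagged nodes and their entire downstream closures are
stripped, their synapses marked invalid, and an :class:`EditRecord` stored
with the rule name and parameter snapshot.  Stripping only removes data —
nothing is reattached or extended.
"""

from __future__ import annotations

import json
from typing import Callable, Optional

import networkx as nx
import numpy as np

from .features import _window_direction
from .types import NM_PER_UM, ROOT, DecompGraph, EditRecord, PRSummary

DEFAULT_RULES: list[dict] = [
    {"rule": "axon_on_dendrite", "params": {}},
    {"rule": "axon_degree", "params": {}},
    {"rule": "double_back", "params": {"compartment": "axon"}},
    {"rule": "double_back", "params": {"compartment": "dendrite"}},
    {"rule": "width_jump", "params": {"compartment": "dendrite",
                                      "direction": "increase"}},
]


def _is_dendritic(graph: DecompGraph, bid: int) -> bool:
    comp = graph.branches[bid].compartment
    return comp not in ("axon", "AIS") if comp is not None else True


def _is_axonal(graph: DecompGraph, bid: int) -> bool:
    return graph.branches[bid].compartment in ("axon", "AIS")


def _soma_direction(graph: DecompGraph, point: np.ndarray) -> np.ndarray:
    v = point - graph.soma.centroid
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.zeros(3)


# ---------------------------------------------------------------------------
# rules (each returns flagged node ids, deterministic order)
# ---------------------------------------------------------------------------

def rule_double_back(graph: DecompGraph, compartment: Optional[str] = "axon",
                     angle_threshold_deg: float = 120.0,
                     min_length_nm: float = 4000.0) -> list[int]:
    """Flag children that reverse sharply back toward the soma.

    A child is flagged when its contact branching angle with the parent
    exceeds the threshold AND its mean direction points back toward the
    soma (negative dot with the soma->branch-point direction).
    """
    flagged = []
    for p, c in sorted(graph.graph.edges):
        if p == ROOT:
            continue
        child = graph.branches[c]
        if child.is_soma_node or child.skeletal_length < min_length_nm:
            continue
        if compartment == "axon" and not _is_axonal(graph, c):
            continue
        if compartment == "dendrite" and not _is_dendritic(graph, c):
            continue
        dp = _window_direction(graph.branches[p], "end")
        dc = _window_direction(child, "start")
        angle = np.degrees(np.arccos(np.clip(np.dot(dp, dc), -1.0, 1.0)))
        if angle <= angle_threshold_deg:
            continue
        out = _soma_direction(graph, child.points[0])
        if np.dot(child.direction(), out) < 0:
            flagged.append(c)
    return flagged


def _contact_width(b, end: str) -> float:
    """Median width a few samples into a branch, skipping the junction
    sample whose width blends both tubes."""
    w = np.asarray(b.width_profile)
    sel = w[1:4] if end == "start" else w[-4:-1]
    sel = sel[sel > 0]
    if len(sel) == 0:
        sel = w[w > 0]
    return float(np.median(sel)) if len(sel) else 0.0


def rule_width_jump(graph: DecompGraph, jump_threshold_nm: float = 500.0,
                    direction: str = "increase",
                    compartment: Optional[str] = "dendrite") -> list[int]:
    """Flag children whose width jumps discontinuously from the parent.

    Widths are compared a few samples away from the junction (junction
    samples blend both tubes).  In 'increase' mode only positive jumps
    count — the signature of a thin process welded onto a thick foreign
    dendrite.
    """
    flagged = []
    for p, c in sorted(graph.graph.edges):
        if p == ROOT:
            continue
        child = graph.branches[c]
        parent = graph.branches[p]
        if child.is_soma_node or parent.is_soma_node:
            continue
        if compartment == "dendrite" and not (_is_dendritic(graph, c) and _is_dendritic(graph, p)):
            continue
        if compartment == "axon" and not (_is_axonal(graph, c) and _is_axonal(graph, p)):
            continue
        jump = _contact_width(child, "start") - _contact_width(parent, "end")
        if direction == "either":
            jump = abs(jump)
        if jump > jump_threshold_nm:
            flagged.append(c)
    return flagged


def rule_axon_degree(graph: DecompGraph, max_children: int = 3,
                     crossover_angle_deg: float = 35.0) -> list[int]:
    """Flag axon branch points with too many children, and X-crossings.

    High-degree: every child at an axonal branch point with more than
    ``max_children`` children.  Low-degree companion: at a branch point, a
    pair of children forming a straight throughway (one child's direction
    nearly opposite the other's, within ``crossover_angle_deg``) that does
    not continue the parent — the signature of a crossing foreign axon
    welded through the point.
    """
    flagged = []
    for node in sorted(graph.branches):
        # the soma root is excluded: many stems there are legitimate
        if not _is_axonal(graph, node):
            continue
        children = graph.children(node)
        children = [c for c in children if not graph.branches[c].is_soma_node]
        if len(children) > max_children:
            flagged.extend(children)
            continue
        if len(children) < 2:
            continue
        dirs = {c: _window_direction(graph.branches[c], "start") for c in children}
        dpar = _window_direction(graph.branches[node], "end")
        cos_x = np.cos(np.deg2rad(crossover_angle_deg))
        for i, ci in enumerate(children):
            for cj in children[i + 1:]:
                # straight throughway: ci continues into the reverse of cj
                if np.dot(dirs[ci], -dirs[cj]) > cos_x:
                    # skip if either child continues the parent's direction
                    if np.dot(dirs[ci], dpar) > cos_x or np.dot(dirs[cj], dpar) > cos_x:
                        continue
                    for c in (ci, cj):
                        if c not in flagged:
                            flagged.append(c)
    return sorted(flagged)


def rule_axon_on_dendrite(graph: DecompGraph,
                          max_spine_density_per_um: float = 0.2,
                          min_outgoing_fraction: float = 0.75,
                          min_synapses: int = 3) -> list[int]:
    """Flag axon-like subtrees hanging off dendritic nodes.

    A subtree is axon-like when it is spine-poor, its synapses are mostly
    outgoing, and it is thinner than its host dendrite.  Subtrees without
    synapses are never flagged (insufficient evidence).
    """
    flagged = []
    for p, c in sorted(graph.graph.edges):
        if p == ROOT:
            continue
        if not (_is_dendritic(graph, p) and _is_dendritic(graph, c)):
            continue
        child = graph.branches[c]
        if child.is_soma_node:
            continue
        subtree = [c] + sorted(graph.descendants(c))
        subtree = [b for b in subtree if not graph.branches[b].is_soma_node]
        length_um = sum(graph.branches[b].skeletal_length for b in subtree) / NM_PER_UM
        if length_um <= 0:
            continue
        n_spines = sum(len(graph.branches[b].spine_ids) for b in subtree)
        syns = [graph.synapses[s] for b in subtree
                for s in graph.branches[b].synapse_ids
                if graph.synapses[s].valid and graph.synapses[s].direction
                in ("incoming", "outgoing")]
        if len(syns) < min_synapses:
            continue
        out_frac = sum(1 for s in syns if s.direction == "outgoing") / len(syns)
        lengths = np.array([graph.branches[b].skeletal_length for b in subtree])
        widths = np.array([graph.branches[b].width_mean for b in subtree])
        mean_width = float(np.average(widths, weights=np.maximum(lengths, 1.0)))
        host_width = graph.branches[p].width_mean
        if (n_spines / length_um <= max_spine_density_per_um
                and out_frac >= min_outgoing_fraction
                and mean_width < host_width):
            flagged.append(c)
    return flagged


RULES: dict[str, Callable] = {
    "double_back": rule_double_back,
    "width_jump": rule_width_jump,
    "axon_degree": rule_axon_degree,
    "axon_on_dendrite": rule_axon_on_dendrite,
}


# ---------------------------------------------------------------------------
# filter application
# ---------------------------------------------------------------------------

def apply_filters(graph: DecompGraph, rule_configs: list[dict] | None = None
                  ) -> tuple[DecompGraph, list[EditRecord]]:
    """Run rules in order, stripping each flagged node's descendant closure.

    Unknown rule names are rejected before any edit.  The input graph is
    not modified; the edited copy and the edit log are returned.
    """
    if rule_configs is None:
        rule_configs = DEFAULT_RULES
    for cfg in rule_configs:
        if cfg["rule"] not in RULES:
            raise ValueError(f"unknown rule {cfg['rule']!r}; "
                             f"known: {sorted(RULES)}")
    import copy
    g = copy.deepcopy(graph)
    edits: list[EditRecord] = []
    for cfg in rule_configs:
        fn = RULES[cfg["rule"]]
        params = dict(cfg.get("params", {}))
        flagged = fn(g, **params)
        for node in flagged:
            if node not in g.branches:
                continue  # removed by an earlier edit this pass
            removed = [node] + sorted(nx.descendants(g.graph, node))
            removed_syn = []
            removed_len = 0.0
            for b in removed:
                br = g.branches[b]
                removed_len += br.skeletal_length
                for sid in br.synapse_ids:
                    if g.synapses[sid].valid:
                        g.synapses[sid].valid = False
                        removed_syn.append(sid)
            cut_location = g.branches[node].points[0]
            edits.append(EditRecord(
                rule=cfg["rule"], params=params, flagged_node=node,
                cut_location=cut_location, removed_nodes=removed,
                removed_synapse_ids=removed_syn,
                removed_skeletal_length=removed_len))
            for b in removed:
                g.graph.remove_node(b)
                del g.branches[b]
            g.log(f"{cfg['rule']}: stripped {len(removed)} nodes at node {node}")
    return g, edits


def write_edit_log(edits: list[EditRecord], path) -> None:
    """JSON-lines edit log, one EditRecord per line."""
    with open(path, "w") as fh:
        for e in edits:
            fh.write(json.dumps(e.to_json_dict()) + "\n")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_synapse_pr(predicted_valid: set[int], truth_valid: set[int],
                        strata: dict[str, dict[int, str]] | None = None
                        ) -> PRSummary:
    """Synapse-level precision/recall of the retained (predicted-valid) set.

    precision = TP/(TP+FP): true retained over all retained;
    recall = TP/(TP+FN): true retained over all true.
    With an empty predicted set the precision is undefined (None).
    ``strata`` maps stratum-name -> {synapse id -> stratum value} and adds
    per-stratum summaries.
    """
    predicted_valid = set(predicted_valid)
    truth_valid = set(truth_valid)
    tp = len(predicted_valid & truth_valid)
    fp = len(predicted_valid - truth_valid)
    fn = len(truth_valid - predicted_valid)
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    out = PRSummary(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall)
    if strata:
        for name, mapping in strata.items():
            values = sorted({v for v in mapping.values()})
            for v in values:
                ids = {k for k, vv in mapping.items() if vv == v}
                sub = evaluate_synapse_pr(predicted_valid & ids, truth_valid & ids)
                out.strata[(name, v)] = sub
    return out
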