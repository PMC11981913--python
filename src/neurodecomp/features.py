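"""Node / subgraph / graph feature hierarchy on decomposition graphs.

Node features describe one non-branching segment (lengths in nm, densities
per µm); subgraph features describe parent-child relations (branching
angles over 5 µm direction windows); graph features aggregate the whole
neuron by sums and skeletal-length-weighted means.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .types import NM_PER_UM, ROOT, Branch, DecompGraph

DIRECTION_WINDOW_NM = 5000.0


@dataclass
class NodeFeatures:
    branch_id: int
    skeletal_length: float
    width_mean: float
    width_start: float
    width_end: float
    synapse_count: int
    synapse_density: float
    spine_count: int
    spine_density: float
    shaft_synapse_count: int
    tortuosity: float
    direction: np.ndarray


@dataclass
class SubgraphFeatures:
    parent_id: int
    child_id: int
    branching_angle: float
    sibling_angle: Optional[float]
    width_difference: float
    child_degree: int


def _window_direction(branch: Branch, end: str,
                      window: float = DIRECTION_WINDOW_NM) -> np.ndarray:
    """Mean direction over the proximal/distal window of a branch."""
    pts = branch.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if end == "start":
        k = int(np.searchsorted(cum, window))
        v = pts[max(1, min(k, len(pts) - 1))] - pts[0]
    else:
        k = int(np.searchsorted(cum, cum[-1] - window))
        v = pts[-1] - pts[min(max(0, k), len(pts) - 2)]
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.zeros(3)


def node_features(graph: DecompGraph, branch_id: int) -> NodeFeatures:
    """Per-segment morphometrics; rejects degenerate zero-length branches."""
    b = graph.branches[branch_id]
    L = b.skeletal_length
    if L <= 0:
        raise ValueError(f"branch {branch_id} has zero skeletal length")
    L_um = L / NM_PER_UM
    syns = [graph.synapses[s] for s in b.synapse_ids if graph.synapses[s].valid]
    shaft = sum(1 for s in syns if s.spine_part == "shaft")
    chord = float(np.linalg.norm(b.points[-1] - b.points[0]))
    tort = L / chord if chord > 0 else float("inf")
    return NodeFeatures(
        branch_id=branch_id, skeletal_length=L,
        width_mean=b.width_mean, width_start=b.width_start, width_end=b.width_end,
        synapse_count=len(syns), synapse_density=len(syns) / L_um,
        spine_count=len(b.spine_ids), spine_density=len(b.spine_ids) / L_um,
        shaft_synapse_count=shaft, tortuosity=tort, direction=b.direction())


def subgraph_features(graph: DecompGraph, edge: tuple[int, int]) -> SubgraphFeatures:
    """Relations across one parent->child edge (angles in degrees)."""
    p, c = edge
    if not graph.graph.has_edge(p, c):
        raise ValueError(f"edge {p}->{c} not in graph")
    child = graph.branches[c]
    if p == ROOT:
        dp = child.direction()  # stems have no parent direction: angle 0
    else:
        dp = _window_direction(graph.branches[p], "end")
    dc = _window_direction(child, "start")
    angle = float(np.degrees(np.arccos(np.clip(np.dot(dp, dc), -1.0, 1.0))))
    siblings = [s for s in graph.children(p) if s != c]
    sib_angle = None
    if siblings:
        angles = []
        for s in siblings:
            ds = _window_direction(graph.branches[s], "start")
            angles.append(float(np.degrees(np.arccos(np.clip(np.dot(dc, ds), -1.0, 1.0)))))
        sib_angle = min(angles)
    wdiff = child.width_start - (graph.branches[p].width_end if p != ROOT
                                 else graph.soma.radius * 2.0)
    return SubgraphFeatures(parent_id=p, child_id=c, branching_angle=angle,
                            sibling_angle=sib_angle, width_difference=wdiff,
                            child_degree=len(graph.children(p)))


def graph_features(graph: DecompGraph) -> dict:
    """Whole-neuron aggregates; deterministic, stems in root-child order."""
    nf = [node_features(graph, bid) for bid in graph.branch_ids
          if not graph.branches[bid].is_soma_node
          and graph.branches[bid].skeletal_length > 0]
    if not nf:
        raise ValueError("graph has no non-degenerate branches")
    L = np.array([f.skeletal_length for f in nf])
    W = L / L.sum()

    def wmean(vals):
        return float(np.dot(W, vals))

    out = {
        "n_branches": len(nf),
        "total_skeletal_length": float(L.sum()),
        "total_synapses": int(sum(f.synapse_count for f in nf) + len(graph.soma_synapse_ids)),
        "total_spines": int(sum(f.spine_count for f in nf)),
        "width_mean_weighted": wmean([f.width_mean for f in nf]),
        "synapse_density_weighted": wmean([f.synapse_density for f in nf]),
        "spine_density_weighted": wmean([f.spine_density for f in nf]),
        "tortuosity_weighted": wmean([min(f.tortuosity, 1e6) for f in nf]),
        "soma_volume": graph.soma.volume,
        "soma_surface_area": graph.soma.surface_area,
        "soma_synapse_count": len(graph.soma_synapse_ids),
    }
    stems = []
    leaves_total = 0
    for stem_root in graph.stem_roots():
        members = [stem_root] + sorted(graph.descendants(stem_root))
        leaves = [m for m in members if not graph.children(m)]
        depth = 0
        for m in members:
            d = 0
            cur = m
            while cur != stem_root:
                cur = graph.parent_of(cur)
                d += 1
            depth = max(depth, d + 1)
        stems.append({
            "stem_root": stem_root,
            "initial_width": graph.branches[stem_root].width_start,
            "leaf_count": len(leaves),
            "max_depth": depth,
            "skeletal_length": float(sum(graph.branches[m].skeletal_length
                                         for m in members)),
        })
        leaves_total += len(leaves)
    out["stems"] = stems
    out["total_leaves"] = leaves_total
    out["n_branch_points"] = sum(1 for bid in graph.branches
                                 if len(graph.children(bid)) >= 2)
    return out


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

_NODE_UNITS = ("# units: skeletal_length=nm widths=nm densities=per_um "
               "tortuosity=dimensionless direction=unit_vector")


def node_feature_table(graph: DecompGraph) -> pd.DataFrame:
    rows = []
    for bid in graph.branch_ids:
        b = graph.branches[bid]
        if b.is_soma_node or b.skeletal_length <= 0:
            continue
        f = node_features(graph, bid)
        d = asdict(f)
        dx, dy, dz = d.pop("direction")
        d.update(direction_x=dx, direction_y=dy, direction_z=dz,
                 compartment=b.compartment or "")
        rows.append(d)
    return pd.DataFrame(rows)


def write_feature_tables(graph: DecompGraph, outdir) -> None:
    """CSV exports with a `# units:` header line, one file per level."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nt = node_feature_table(graph)
    with open(outdir / "node_features.csv", "w") as fh:
        fh.write(_NODE_UNITS + "\n")
        nt.to_csv(fh, index=False)
    rows = []
    for p, c in sorted(graph.graph.edges):
        f = subgraph_features(graph, (p, c))
        rows.append(asdict(f))
    with open(outdir / "subgraph_features.csv", "w") as fh:
        fh.write("# units: angles=degrees width_difference=nm\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    gf = graph_features(graph)
    stems = gf.pop("stems")
    with open(outdir / "graph_features.csv", "w") as fh:
        fh.write("# units: lengths=nm widths=nm volume=nm3 area=nm2\n")
        pd.DataFrame([gf]).to_csv(fh, index=False)
    with open(outdir / "stem_features.csv", "w") as fh:
        fh.write("# units: initial_width=nm skeletal_length=nm\n")
        pd.DataFrame(stems).to_csv(fh, index=False)
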