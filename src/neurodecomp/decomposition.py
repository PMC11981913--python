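"""Soma-rooted graph decomposition of skeletons into non-branching segments.

The skeleton is cut at every branch point and at the soma surface; each
maximal non-branching run becomes one :class:`Branch` node of a directed
tree whose single root is the soma.  Any residual skeleton cycles are
broken (the cycle edge farthest from the root is removed and logged).
Synapses attach to the branch whose skeleton is nearest.  Multi-soma
skeletons are decomposed around the first soma and split afterwards with
:func:`split_multi_soma`.
"""

from __future__ import annotations

import json
from io import StringIO

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .preprocess import Correspondence
from .types import (ROOT, Branch, DecompGraph, EditRecord, SkeletonTree,
                    SomaDetection, SynapseRecord)

#: SWC type codes by compartment label
SWC_TYPES = {"soma": 1, "axon": 2, "AIS": 2, "basal": 3, "apical": 4,
             "oblique": 4, None: 0}

DEFAULT_SPINE_REACH_NM = 3500.0


# ---------------------------------------------------------------------------
# cycle breaking
# ---------------------------------------------------------------------------

def _break_cycles(g: nx.Graph, root: int, log: list[str]) -> None:
    """Remove, for each independent cycle, the edge farthest from the root."""
    while True:
        basis = nx.cycle_basis(g, root)
        if not basis:
            return
        dist = nx.single_source_dijkstra_path_length(g, root, weight="length")
        cycle = basis[0]
        best = None
        for i in range(len(cycle)):
            u, v = cycle[i], cycle[(i + 1) % len(cycle)]
            score = min(dist.get(u, 0.0), dist.get(v, 0.0))
            key = (score, -min(u, v), -max(u, v))
            if best is None or key > best[0]:
                best = (key, (u, v))
        u, v = best[1]
        g.remove_edge(u, v)
        log.append(f"cycle_break: removed skeleton edge ({u},{v}) "
                   f"at graph distance {best[0][0]:.0f} nm from root")


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def _sphere_exit(points: np.ndarray, center: np.ndarray, radius: float):
    """First crossing of the sphere along the polyline; returns (index, point).

    ``index`` is the last polyline index still inside; the returned point is
    the interpolated surface crossing on segment (index, index+1).
    """
    d = np.linalg.norm(points - center, axis=1)
    outside = np.flatnonzero(d > radius)
    if len(outside) == 0:
        return None
    k = int(outside[0])
    if k == 0:
        return 0, points[0]
    a, b = points[k - 1], points[k]
    da, db = d[k - 1], d[k]
    f = (radius - da) / max(db - da, 1e-9)
    return k - 1, a + f * (b - a)


def _subdivide_path(path: list[int], skeleton: SkeletonTree,
                    kink_angle_deg: float = 100.0,
                    kink_window: int = 2,
                    width_jump_nm: float = 600.0,
                    width_jump_ratio: float = 1.5) -> list[list[int]]:
    """Split a non-branching path at sharp kinks and width discontinuities.

    Merge errors that extend a process collinearly (double-backs, width
    jumps) leave no branch point; cutting at the geometric discontinuity
    makes them visible to node-level proofreading rules.
    """
    if len(path) < 2 * kink_window + 2:
        return [path]
    P = skeleton.points
    W = (skeleton.radius if skeleton.radius is not None else np.zeros(len(P))) * 2
    cut_at = []
    cos_thresh = np.cos(np.deg2rad(kink_angle_deg))
    for i in range(kink_window, len(path) - kink_window):
        v_in = P[path[i]] - P[path[i - kink_window]]
        v_out = P[path[i + kink_window]] - P[path[i]]
        ni, no = np.linalg.norm(v_in), np.linalg.norm(v_out)
        if ni > 0 and no > 0 and np.dot(v_in, v_out) / (ni * no) < cos_thresh:
            cut_at.append(i)
    for i in range(1, len(path) - 1):
        w0, w1 = W[path[i - 1]], W[path[i]]
        lo, hi = min(w0, w1), max(w0, w1)
        if lo > 0 and hi - lo > width_jump_nm and hi / lo > width_jump_ratio:
            cut_at.append(i)
    if not cut_at:
        return [path]
    # keep cuts at least 2 samples apart, interior only
    cuts = []
    for i in sorted(set(cut_at)):
        if 0 < i < len(path) - 1 and (not cuts or i - cuts[-1] >= 2):
            cuts.append(i)
    subs = []
    prev = 0
    for i in cuts:
        subs.append(path[prev:i + 1])
        prev = i
    subs.append(path[prev:])
    return [s for s in subs if len(s) >= 2]


def decompose(skeleton: SkeletonTree, correspondence: Correspondence | None,
              somas: list[SomaDetection], synapses: list[SynapseRecord],
              spine_reach_nm: float = DEFAULT_SPINE_REACH_NM) -> DecompGraph:
    """Build the soma-rooted directed tree of non-branching segments.

    The skeleton is cut at branch points, at the soma surface, and at
    sharp geometric discontinuities (kinks, width jumps) inside otherwise
    non-branching runs.  Widths are taken from ``skeleton.radius`` (filled
    by correspondence); faces attach to branches through the
    correspondence's nearest-point assignment.  Synapses go to the branch
    whose skeleton point is nearest (the soma if nearest to the soma); a
    synapse farther than 2 x local width + spine_reach from the skeleton
    is flagged invalid.
    """
    if not somas:
        raise ValueError("no soma detected; treat this component as a fragment")
    g = skeleton.as_graph()
    if skeleton.radius is None:
        skeleton.radius = np.zeros(skeleton.n_points)
    root = skeleton.root
    provenance: list[str] = []
    _break_cycles(g, root, provenance)

    soma_node_set = set(skeleton.soma_nodes)
    deg = dict(g.degree())
    junctions = {v for v, d in deg.items() if d >= 3} | soma_node_set | {root}

    widths = skeleton.radius * 2.0
    soma0 = somas[0]

    # walk maximal non-branching paths outward from the root (BFS order)
    branches: dict[int, Branch] = {}
    digraph = nx.DiGraph()
    digraph.add_node(ROOT)
    point_branch = np.full(skeleton.n_points, ROOT, dtype=int)
    soma_internal_length = 0.0
    next_id = 0
    # queue entries: (start node, parent branch id, soma detection if the
    # start node is a soma to clip against)
    soma_by_node = {n: somas[i] if i < len(somas) else None
                    for i, n in enumerate(skeleton.soma_nodes)}
    queue = [(root, ROOT)]
    visited = {root}
    while queue:
        start, parent_bid = queue.pop(0)
        for nbr in sorted(g.neighbors(start)):
            if nbr in visited:
                continue
            path = [start, nbr]
            visited.add(nbr)
            while path[-1] not in junctions and deg[path[-1]] == 2:
                nxts = [u for u in g.neighbors(path[-1]) if u != path[-2]]
                if not nxts:
                    break
                nxt = nxts[0]
                if nxt in visited:
                    break
                path.append(nxt)
                visited.add(nxt)
            subpaths = _subdivide_path(path, skeleton)
            bid = None
            for si, sub in enumerate(subpaths):
                pts = skeleton.points[sub].copy()
                wid = widths[sub].copy()
                interior_path = sub[1:-1]
                clip_note = ""
                host_soma = soma_by_node.get(start) if si == 0 else None
                if host_soma is not None:
                    exit_hit = _sphere_exit(pts, host_soma.centroid, host_soma.radius)
                    if exit_hit is None:
                        # entire sub-path inside the soma: absorb into root
                        soma_internal_length += float(
                            np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
                        for p in sub[1:]:
                            point_branch[p] = ROOT
                        bid = parent_bid if bid is None else bid
                        continue
                    k, crossing = exit_hit
                    inside = float(np.linalg.norm(np.diff(pts[:k + 1], axis=0), axis=1).sum())
                    inside += float(np.linalg.norm(crossing - pts[k]))
                    soma_internal_length += inside
                    pts = np.concatenate([crossing[None, :], pts[k + 1:]])
                    wid = np.concatenate([[wid[k]], wid[k + 1:]])
                    interior_path = sub[k + 1:-1]
                    clip_note = f" (clipped {inside:.0f} nm inside soma)"
                if len(pts) < 2:
                    pts = np.vstack([pts[0], pts[0]])
                    wid = np.concatenate([wid, wid[-1:]])
                this_parent = parent_bid if bid is None else bid
                bid = next_id
                next_id += 1
                branch = Branch(branch_id=bid, points=pts, width_profile=wid,
                                parent=this_parent, is_soma_node=False)
                branches[bid] = branch
                digraph.add_edge(this_parent, bid)
                for p in interior_path:
                    point_branch[p] = bid
                sub_end = sub[-1]
                if sub_end not in junctions:
                    point_branch[sub_end] = bid
                if clip_note:
                    provenance.append(f"branch {bid}: starts at soma surface{clip_note}")
                if len(subpaths) > 1 and si < len(subpaths) - 1:
                    provenance.append(
                        f"branch {bid}: cut at geometric discontinuity")
            if bid is None:
                bid = parent_bid
            end = path[-1]
            end_soma = soma_by_node.get(end) if end in soma_node_set and end != root else None
            if end in junctions:
                if end_soma is not None:
                    # embedded extra soma becomes its own (soma) node
                    sid = next_id
                    next_id += 1
                    sbranch = Branch(branch_id=sid,
                                     points=np.vstack([end_soma.centroid] * 2),
                                     width_profile=np.array([2 * end_soma.radius] * 2),
                                     parent=bid, is_soma_node=True, soma=end_soma)
                    branches[sid] = sbranch
                    digraph.add_edge(bid, sid)
                    point_branch[end] = sid
                    queue.append((end, sid))
                else:
                    queue.append((end, bid))

    graph = DecompGraph(soma=soma0, branches=branches, graph=digraph,
                        provenance=provenance)
    graph.log(f"decomposed: {len(branches)} branches, "
              f"{soma_internal_length:.0f} nm soma-internal skeleton")
    graph.soma_internal_length = soma_internal_length

    # faces -> branches through the correspondence
    if correspondence is not None:
        fb = point_branch[correspondence.face_point]
        for bid in branches:
            branches[bid].face_ids = np.flatnonzero(fb == bid)
        graph.soma_face_ids = np.flatnonzero(fb == ROOT)

    _assign_synapses(graph, skeleton, point_branch, synapses, spine_reach_nm)
    return graph


def _assign_synapses(graph: DecompGraph, skeleton: SkeletonTree,
                     point_branch: np.ndarray, synapses: list[SynapseRecord],
                     spine_reach_nm: float) -> None:
    if not synapses:
        return
    kd = cKDTree(skeleton.points)
    widths = (skeleton.radius if skeleton.radius is not None
              else np.zeros(skeleton.n_points)) * 2.0
    pos = np.array([s.position for s in synapses])
    dist, idx = kd.query(pos)
    for s, d, i in zip(synapses, dist, idx):
        rec = s.copy()
        bid = int(point_branch[i])
        near_soma = np.linalg.norm(rec.position - graph.soma.centroid) \
            <= 1.3 * graph.soma.radius
        if bid == ROOT or near_soma:
            rec.branch_id = None
            rec.compartment = "soma"
            rec.spine_part = "soma"
            graph.soma_synapse_ids.append(rec.syn_id)
        else:
            rec.branch_id = bid
            if bid in graph.branches and graph.branches[bid].is_soma_node:
                rec.compartment = "soma"
                rec.spine_part = "soma"
            threshold = 2.0 * widths[i] + spine_reach_nm
            if d > threshold:
                rec.valid = False
                graph.discarded_synapse_ids.append(rec.syn_id)
                graph.log(f"synapse {rec.syn_id}: {d:.0f} nm from skeleton "
                          f"(> {threshold:.0f}), flagged invalid")
            graph.branches[bid].synapse_ids.append(rec.syn_id)
        graph.synapses[rec.syn_id] = rec


# ---------------------------------------------------------------------------
# multi-soma splitting
# ---------------------------------------------------------------------------

def _branch_out_fraction(graph: DecompGraph, bid: int) -> float | None:
    syns = [graph.synapses[s] for s in graph.branches[bid].synapse_ids]
    syns = [s for s in syns if s.direction in ("incoming", "outgoing")]
    if not syns:
        return None
    return sum(1 for s in syns if s.direction == "outgoing") / len(syns)


def split_multi_soma(graph: DecompGraph,
                     weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
                     ) -> tuple[list[DecompGraph], list[EditRecord]]:
    """Split a k-soma decomposition into k single-soma graphs.

    For every extra soma, the unique tree path between it and the root is
    cut at the single most suspicious edge: a weighted sum of the width
    minimum along the edge, the branching angle, and the axon/dendrite
    profile mismatch of the two sides.  Identity (with a warning log) for
    single-soma graphs.
    """
    extra = [bid for bid, b in graph.branches.items() if b.is_soma_node]
    if not extra:
        graph.log("split_multi_soma: single soma, identity")
        return [graph], []

    w_width, w_angle, w_mismatch = weights
    edits: list[EditRecord] = []
    cut_edges = []
    tree = graph.graph

    soma_centers = [graph.soma.centroid] + \
        [b.soma.centroid for b in graph.branches.values()
         if b.is_soma_node and b.soma is not None]
    soma_radii = [graph.soma.radius] + \
        [b.soma.radius for b in graph.branches.values()
         if b.is_soma_node and b.soma is not None]

    def _soma_blended(points: np.ndarray) -> np.ndarray:
        m = np.zeros(len(points), dtype=bool)
        for c, r in zip(soma_centers, soma_radii):
            m |= np.linalg.norm(points - c, axis=1) <= 1.5 * r
        return m

    def contact_width(b: Branch, end: str) -> float:
        # median a few samples into the branch, skipping the junction sample
        # itself (junction widths blend both tubes) and anything inside a
        # soma's influence zone (the approach ramp is not a discontinuity)
        w = b.width_profile
        blended = _soma_blended(b.points)
        ok = (w > 0) & ~blended
        sel = (w[1:4])[ok[1:4]] if end == "start" else (w[-4:-1])[ok[-4:-1]]
        if len(sel) == 0:
            sel = w[ok]
        if len(sel) == 0:
            sel = w[w > 0]
        return float(np.median(sel)) if len(sel) else 0.0

    def contact_dir(b: Branch, end: str, window: float = 5000.0) -> np.ndarray:
        pts = b.points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        if end == "start":
            k = int(np.searchsorted(cum, window))
            v = pts[min(k, len(pts) - 1)] - pts[0]
        else:
            k = int(np.searchsorted(cum, cum[-1] - window))
            v = pts[-1] - pts[max(0, min(k, len(pts) - 2))]
        nv = np.linalg.norm(v)
        return v / nv if nv > 0 else np.zeros(3)

    def windowed_out_fraction(start: int, downstream: bool,
                              window_nm: float = 25_000.0):
        """Outgoing-synapse fraction over ~window of cable from a branch,
        walking away from (downstream) or toward (upstream) the root."""
        seen = []
        length = 0.0
        frontier = [start]
        visited = set()
        while frontier and length < window_nm:
            b = frontier.pop(0)
            if b in visited or b == ROOT or b not in graph.branches:
                if b == ROOT:
                    break
                continue
            visited.add(b)
            br = graph.branches[b]
            if not br.is_soma_node:
                seen.append(b)
                length += br.skeletal_length
            if downstream:
                frontier.extend(graph.children(b))
            else:
                parent = graph.parent_of(b)
                if parent is not None:
                    frontier.append(parent)
        syns = [graph.synapses[s] for b in seen
                for s in graph.branches[b].synapse_ids
                if graph.synapses[s].direction in ("incoming", "outgoing")]
        if len(syns) < 3:
            return None
        return sum(1 for s in syns if s.direction == "outgoing") / len(syns)

    for soma_bid in extra:
        # path of branch nodes root(-1) -> ... -> soma_bid
        path = nx.shortest_path(tree.to_undirected(as_view=True), ROOT, soma_bid)
        best = None
        best_soma_adjacent = None
        for p, c in zip(path[:-1], path[1:]):
            if (p, c) in cut_edges:
                continue
            child = graph.branches[c]
            if child.is_soma_node:
                continue
            if p != ROOT and not graph.branches[p].is_soma_node:
                wp = contact_width(graph.branches[p], "end")
                wc = contact_width(child, "start")
                # a thin foreign bridge meeting a fat host process leaves a
                # sharp relative width discontinuity at the contact
                width_score = abs(wc - wp) / max(wc, wp, 1e-9)
                dp = contact_dir(graph.branches[p], "end")
                dc = contact_dir(child, "start")
                cosang = float(np.clip(np.dot(dp, dc), -1, 1))
                angle_score = np.degrees(np.arccos(cosang)) / 180.0
            else:
                width_score = 0.0
                angle_score = 0.0
            op = windowed_out_fraction(p, downstream=False) if p != ROOT else None
            oc = windowed_out_fraction(c, downstream=True)
            mismatch = abs(op - oc) if (op is not None and oc is not None) else 0.0
            score = w_width * width_score + w_angle * angle_score + w_mismatch * mismatch
            key = (score, -c)
            # edges abutting the far soma carry its width/class ramp, not a
            # weld signature: keep them only as a fallback
            successors = [n for u, n in zip(path[:-1], path[1:]) if u == c]
            adjacent_to_soma = any(graph.branches[s].is_soma_node
                                   for s in successors)
            if adjacent_to_soma:
                if best_soma_adjacent is None or key > best_soma_adjacent[0]:
                    best_soma_adjacent = (key, (p, c))
            elif best is None or key > best[0]:
                best = (key, (p, c))
        if best is None:
            best = best_soma_adjacent
        if best is not None:
            cut_edges.append(best[1])

    # perform cuts on an undirected copy
    und = tree.to_undirected()
    for p, c in cut_edges:
        und.remove_edge(p, c)
        loc = graph.branches[c].points[0]
        edits.append(EditRecord(
            rule="multi_soma_split", params={"weights": list(weights)},
            flagged_node=c, cut_location=loc,
            removed_nodes=[], removed_synapse_ids=[],
            removed_skeletal_length=0.0))
        graph.log(f"multi_soma_split: cut edge {p}->{c} at {np.round(loc, 0)}")

    comps = list(nx.connected_components(und))
    out: list[DecompGraph] = []
    for comp in comps:
        if ROOT in comp:
            out.append(_subgraph_rooted(graph, comp, ROOT, graph.soma))
        else:
            soma_bids = [b for b in comp if graph.branches[b].is_soma_node]
            if not soma_bids:
                continue  # somaless fragment: drop, logged below
            new_root_bid = min(soma_bids)
            out.append(_subgraph_rooted(graph, comp, new_root_bid,
                                        graph.branches[new_root_bid].soma))
    return out, edits


def _subgraph_rooted(graph: DecompGraph, comp: set, root_node,
                     soma: SomaDetection) -> DecompGraph:
    """Re-root the branch subset ``comp`` at ``root_node`` (ROOT or a
    soma-branch id) and rebuild a DecompGraph with flipped orientations
    where needed."""
    und = graph.graph.to_undirected(as_view=False).subgraph(comp).copy()
    order = list(nx.bfs_tree(und, root_node).edges())
    digraph = nx.DiGraph()
    digraph.add_node(ROOT)
    branches: dict[int, Branch] = {}
    id_map = {root_node: ROOT}
    next_id = 0
    for p, c in order:
        new_p = id_map[p]
        old = graph.branches[c] if c != ROOT else None
        if c == ROOT:
            # the old root becomes an ordinary junction: nothing to carry
            id_map[c] = new_p
            continue
        nb = Branch(branch_id=next_id,
                    points=old.points.copy(), width_profile=old.width_profile.copy(),
                    face_ids=old.face_ids.copy(), synapse_ids=list(old.synapse_ids),
                    spine_ids=list(old.spine_ids), compartment=old.compartment,
                    parent=new_p, is_soma_node=old.is_soma_node, soma=old.soma)
        # orientation: in the original graph the branch ran parent->child;
        # if we arrive from the far end, flip the polyline
        orig_parent = graph.parent_of(c)
        if orig_parent != p:
            nb.points = nb.points[::-1].copy()
            nb.width_profile = nb.width_profile[::-1].copy()
        if nb.is_soma_node:
            # embedded soma of another cell inside this side: keep as node
            pass
        id_map[c] = next_id
        branches[next_id] = nb
        digraph.add_edge(new_p, next_id)
        next_id += 1
    sub = DecompGraph(soma=soma, branches=branches, graph=digraph,
                      provenance=[f"split from multi-soma graph; root={root_node}"])
    # carry synapses that live on these branches (or this soma)
    carried = set()
    for bid, b in branches.items():
        for sid in b.synapse_ids:
            rec = graph.synapses[sid].copy()
            rec.branch_id = bid
            sub.synapses[sid] = rec
            carried.add(sid)
    if root_node == ROOT:
        for sid in graph.soma_synapse_ids:
            sub.synapses[sid] = graph.synapses[sid].copy()
            sub.soma_synapse_ids.append(sid)
    else:
        # synapses that were attached to the soma-branch node
        old_root_branch = graph.branches[root_node]
        for sid in old_root_branch.synapse_ids:
            if sid not in carried:
                rec = graph.synapses[sid].copy()
                rec.branch_id = None
                rec.compartment = "soma"
                rec.spine_part = "soma"
                sub.synapses[sid] = rec
                sub.soma_synapse_ids.append(sid)
    return sub


# ---------------------------------------------------------------------------
# SWC export / parse
# ---------------------------------------------------------------------------

def export_swc(graph: DecompGraph, path=None) -> str:
    """Write the decomposition as SWC (µm units, NeuroMorpho dialect).

    One sample per skeleton point; ids contiguous from 1; the soma is the
    single root sample with parent -1.  Rejects multi-root graphs (split
    them first).
    """
    if any(b.is_soma_node for b in graph.branches.values()):
        raise ValueError("multi-root graph: run split_multi_soma before export")
    lines = ["# SWC export (units um; columns id type x y z radius parent)"]
    c = graph.soma.centroid / 1000.0
    lines.append(f"1 1 {c[0]:.4f} {c[1]:.4f} {c[2]:.4f} "
                 f"{graph.soma.radius / 1000.0:.4f} -1")
    next_id = 2
    last_sample: dict[int, int] = {ROOT: 1}
    for bid in nx.bfs_tree(graph.graph, ROOT):
        if bid == ROOT:
            continue
        b = graph.branches[bid]
        t = SWC_TYPES.get(b.compartment, 0)
        parent_sample = last_sample[graph.parent_of(bid)]
        pts = b.points
        wid = b.width_profile
        start = 1 if graph.parent_of(bid) != ROOT else 0
        for i in range(start, len(pts)):
            p = pts[i] / 1000.0
            r = max(wid[i] / 2000.0, 1e-4)
            lines.append(f"{next_id} {t} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f} "
                         f"{r:.4f} {parent_sample}")
            parent_sample = next_id
            next_id += 1
        last_sample[bid] = parent_sample
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def parse_swc(text: str) -> pd.DataFrame:
    """Parse SWC text into a DataFrame (coordinates in µm)."""
    df = pd.read_csv(StringIO(text), sep=r"\s+", comment="#", header=None,
                     names=["id", "type", "x", "y", "z", "radius", "parent"])
    return df


def swc_total_length_nm(df: pd.DataFrame) -> float:
    """Sum of parent-child sample distances, in nm."""
    idx = {int(r.id): np.array([r.x, r.y, r.z]) for r in df.itertuples()}
    total = 0.0
    for r in df.itertuples():
        if r.parent > 0:
            total += np.linalg.norm(idx[int(r.id)] - idx[int(r.parent)])
    return total * 1000.0


# ---------------------------------------------------------------------------
# JSON checkpointing and synapse tables
# ---------------------------------------------------------------------------

def graph_to_json(graph: DecompGraph) -> str:
    doc = {
        "soma": {"centroid": graph.soma.centroid.tolist(),
                 "radius": graph.soma.radius,
                 "surface_area": graph.soma.surface_area,
                 "volume": graph.soma.volume},
        "edges": [[int(a), int(b)] for a, b in graph.graph.edges],
        "branches": {
            str(bid): {
                "points": b.points.tolist(),
                "width_profile": b.width_profile.tolist(),
                "face_ids": b.face_ids.tolist(),
                "synapse_ids": [int(s) for s in b.synapse_ids],
                "spine_ids": [int(s) for s in b.spine_ids],
                "compartment": b.compartment,
                "parent": None if b.parent is None else int(b.parent),
                "is_soma_node": b.is_soma_node,
            } for bid, b in graph.branches.items()},
        "soma_synapse_ids": [int(s) for s in graph.soma_synapse_ids],
        "provenance": graph.provenance,
    }
    return json.dumps(doc)


def graph_from_json(text: str) -> DecompGraph:
    doc = json.loads(text)
    soma = SomaDetection(centroid=np.array(doc["soma"]["centroid"]),
                         radius=doc["soma"]["radius"],
                         face_ids=np.zeros(0, dtype=int),
                         surface_area=doc["soma"]["surface_area"],
                         volume=doc["soma"]["volume"])
    digraph = nx.DiGraph()
    digraph.add_node(ROOT)
    digraph.add_edges_from((a, b) for a, b in doc["edges"])
    branches = {}
    for k, bd in doc["branches"].items():
        bid = int(k)
        branches[bid] = Branch(
            branch_id=bid, points=np.array(bd["points"]),
            width_profile=np.array(bd["width_profile"]),
            face_ids=np.array(bd["face_ids"], dtype=int),
            synapse_ids=list(bd["synapse_ids"]), spine_ids=list(bd["spine_ids"]),
            compartment=bd["compartment"], parent=bd["parent"],
            is_soma_node=bd["is_soma_node"])
    g = DecompGraph(soma=soma, branches=branches, graph=digraph,
                    soma_synapse_ids=list(doc["soma_synapse_ids"]),
                    provenance=list(doc["provenance"]))
    return g
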