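"""Axon-dendrite proximities, conversion rates and skeletal walks.

A proximity is an event where the axon of one neuron passes within a
threshold radius (default 5 µm) of another neuron's dendrite (or soma).
The axon skeleton is resampled at a fixed step; contiguous runs of samples
within the radius merge into one event, and two events on the same pair
are distinct only when separated along the axon by more than ``min_gap``.
The conversion rate is the fraction of proximities containing at least one
synapse.  Skeletal walks are arc lengths along the tree to the soma root.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .types import NM_PER_UM, ROOT, DecompGraph, ProximityRecord, SynapseRecord

DEFAULT_RADIUS_NM = 5000.0
DEFAULT_MIN_GAP_NM = 10_000.0
DEFAULT_RESAMPLE_STEP_NM = 500.0


# ---------------------------------------------------------------------------
# skeleton resampling with walk distances
# ---------------------------------------------------------------------------

def _resample_graph(graph: DecompGraph, compartments, step: float,
                    include_soma: bool = False):
    """Sample points along selected branches at ~step spacing.

    Returns (positions, walk distances to soma, branch ids, along-branch
    order key) — the order key makes samples contiguous along each
    root-to-leaf walk so run-length event merging is well defined.
    """
    pos, walk, bids, order = [], [], [], []
    counter = 0
    for bid in graph.branch_ids:
        b = graph.branches[bid]
        if b.is_soma_node or b.skeletal_length <= 0:
            continue
        if compartments is not None and b.compartment not in compartments:
            continue
        base = _walk_to_root(graph, bid)
        pts = b.points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(2, int(np.ceil(cum[-1] / step)) + 1)
        ts = np.linspace(0.0, cum[-1], n)
        idx = np.searchsorted(cum, ts, side="right") - 1
        idx = np.clip(idx, 0, len(seg) - 1)
        f = (ts - cum[idx]) / np.maximum(seg[idx], 1e-9)
        p = pts[idx] * (1 - f[:, None]) + pts[idx + 1] * f[:, None]
        pos.append(p)
        walk.append(base + ts)
        bids.append(np.full(n, bid))
        order.append(np.arange(counter, counter + n))
        counter += n
    if include_soma:
        pos.append(graph.soma.centroid[None, :])
        walk.append(np.zeros(1))
        bids.append(np.array([ROOT]))
        order.append(np.array([counter]))
        counter += 1
    if not pos:
        return (np.zeros((0, 3)), np.zeros(0), np.zeros(0, dtype=int),
                np.zeros(0, dtype=int))
    return (np.concatenate(pos), np.concatenate(walk),
            np.concatenate(bids), np.concatenate(order))


def _walk_to_root(graph: DecompGraph, bid: int) -> float:
    d = 0.0
    cur = graph.parent_of(bid)
    while cur is not None and cur != ROOT:
        d += graph.branches[cur].skeletal_length
        cur = graph.parent_of(cur)
    return d


# ---------------------------------------------------------------------------
# proximity detection
# ---------------------------------------------------------------------------

def compute_proximities(pre_graph: DecompGraph, post_graph: DecompGraph,
                        pre_id: int, post_id: int,
                        radius: float = DEFAULT_RADIUS_NM,
                        min_gap: float = DEFAULT_MIN_GAP_NM,
                        step: float = DEFAULT_RESAMPLE_STEP_NM,
                        include_soma_target: bool = True
                        ) -> list[ProximityRecord]:
    """Detect events where pre's axon passes within ``radius`` of post's
    dendrites (and soma, by default).

    Returns one record per event with the run's minimum distance, closest
    approach points, presyn/postsyn skeletal walks and the postsynaptic
    compartment at closest approach.  An axonless presynaptic graph yields
    an empty list with a warning.
    """
    apos, awalk, abid, aorder = _resample_graph(
        pre_graph, ("axon", "AIS"), step)
    if len(apos) == 0:
        warnings.warn(f"presynaptic graph {pre_id} has no axon; "
                      "no proximities computed")
        return []
    dcomp = ("basal", "apical", "oblique", None)
    dpos, dwalk, dbid, _ = _resample_graph(post_graph, dcomp, step,
                                           include_soma=include_soma_target)
    if len(dpos) == 0:
        return []
    kd = cKDTree(dpos)
    dist, nearest = kd.query(apos)
    # the soma pseudo-sample sits at the centroid: measure to its surface
    if include_soma_target:
        soma_mask = dbid[nearest] == ROOT
        dist = np.where(soma_mask,
                        np.maximum(dist - post_graph.soma.radius, 0.0), dist)
    within = dist <= radius
    if not within.any():
        return []

    # contiguous runs in axon-sample order; merge runs separated by <= min_gap
    # along the axon walk (same branch chain)
    idxs = np.flatnonzero(within)
    runs = []
    run = [idxs[0]]
    max_order_gap = max(1, int(min_gap / step))
    for i in idxs[1:]:
        prev = run[-1]
        if (aorder[i] - aorder[prev] <= max_order_gap
                and abs(awalk[i] - awalk[prev]) <= min_gap):
            run.append(i)
        else:
            runs.append(run)
            run = [i]
    runs.append(run)

    records = []
    for run in runs:
        run = np.asarray(run)
        k = run[int(np.argmin(dist[run]))]
        j = nearest[k]
        post_comp = "soma" if dbid[j] == ROOT else \
            post_graph.branches[int(dbid[j])].compartment
        records.append(ProximityRecord(
            pre_id=pre_id, post_id=post_id,
            point_pre=apos[k], point_post=dpos[j],
            min_dist=float(dist[k]),
            presyn_walk=float(awalk[k]),
            postsyn_walk=float(dwalk[j]),
            post_compartment=post_comp,
            run_points=apos[run[:: max(1, len(run) // 32)]]))
    return records


def link_synapses(proximities: list[ProximityRecord],
                  synapses: Sequence[SynapseRecord],
                  link_radius: float = DEFAULT_RADIUS_NM) -> None:
    """Attach each synapse to the nearest proximity event of its pair
    (within ``link_radius``), in place."""
    by_pair: dict[tuple, list[ProximityRecord]] = {}
    for p in proximities:
        p.synapse_ids = []
        by_pair.setdefault((p.pre_id, p.post_id), []).append(p)
    def event_distance(s, p):
        d = min(np.linalg.norm(s.position - p.point_pre),
                np.linalg.norm(s.position - p.point_post))
        if p.run_points is not None and len(p.run_points):
            d = min(d, float(np.linalg.norm(
                p.run_points - s.position, axis=1).min()))
        return d

    for s in synapses:
        events = by_pair.get((s.pre_id, s.post_id))
        if not events:
            continue
        d = [event_distance(s, p) for p in events]
        k = int(np.argmin(d))
        if d[k] <= link_radius:
            events[k].synapse_ids.append(s.syn_id)


def conversion_rate(proximities: list[ProximityRecord]) -> Optional[float]:
    """Fraction of proximities with at least one linked synapse.

    None (undefined) when there are no proximities.
    """
    if not proximities:
        return None
    return sum(1 for p in proximities if p.n_synapses > 0) / len(proximities)


# ---------------------------------------------------------------------------
# skeletal walk of an arbitrary point
# ---------------------------------------------------------------------------

def skeletal_walk(graph: DecompGraph, point, max_offaxis_factor: float = 2.0,
                  step: float = DEFAULT_RESAMPLE_STEP_NM) -> float:
    """Arc length along the tree from the projection of ``point`` to the
    soma root.

    The point must lie within ``max_offaxis_factor`` x local width of the
    skeleton (else rejected) — soma-adjacent points return 0.
    """
    point = np.asarray(point, dtype=float).reshape(3)
    if np.linalg.norm(point - graph.soma.centroid) <= graph.soma.radius:
        return 0.0
    pos, walk, bids, _ = _resample_graph(graph, None, step)
    if len(pos) == 0:
        raise ValueError("graph has no skeleton to project onto")
    kd = cKDTree(pos)
    d, i = kd.query(point)
    b = graph.branches[int(bids[i])]
    local_width = max(b.width_mean, 1.0)
    if d > max_offaxis_factor * local_width + 1.0:
        raise ValueError(f"point is {d:.0f} nm from the skeleton "
                         f"(> {max_offaxis_factor} x local width {local_width:.0f})")
    return float(walk[i])


# ---------------------------------------------------------------------------
# stratified conversion rates
# ---------------------------------------------------------------------------

STRATUM_KEYS = ("pre_class", "post_class", "post_compartment",
                "presyn_walk_bin", "postsyn_walk_bin", "radius_sweep")


def stratify_conversion(proximities: list[ProximityRecord],
                        keys: Sequence[str],
                        class_of: dict[int, str] | None = None,
                        walk_bin_um: float = 100.0,
                        radii_nm: Sequence[float] = (),
                        ) -> pd.DataFrame:
    """Grouped conversion-rate table over the requested strata.

    ``radius_sweep`` re-thresholds the stored minimum distances without
    recomputation; walk bins are in µm.  Unknown keys are rejected.
    """
    for k in keys:
        if k not in STRATUM_KEYS:
            raise ValueError(f"unknown stratum key {k!r}; known: {STRATUM_KEYS}")
    class_of = class_of or {}
    rows = []
    radii = list(radii_nm) if "radius_sweep" in keys else [None]
    for radius in radii:
        pool = [p for p in proximities
                if radius is None or p.min_dist <= radius]
        frames = {}
        for p in pool:
            key = []
            for k in keys:
                if k == "pre_class":
                    key.append(class_of.get(p.pre_id, "unknown"))
                elif k == "post_class":
                    key.append(class_of.get(p.post_id, "unknown"))
                elif k == "post_compartment":
                    key.append(p.post_compartment or "unknown")
                elif k == "presyn_walk_bin":
                    key.append(int(p.presyn_walk / (walk_bin_um * NM_PER_UM)))
                elif k == "postsyn_walk_bin":
                    key.append(int(p.postsyn_walk / (walk_bin_um * NM_PER_UM)))
                elif k == "radius_sweep":
                    key.append(radius)
            key = tuple(key)
            n, c = frames.get(key, (0, 0))
            frames[key] = (n + 1, c + (1 if p.n_synapses > 0 else 0))
        for key, (n, c) in sorted(frames.items(), key=lambda t: str(t[0])):
            row = dict(zip(keys, key))
            row.update(n_proximities=n, n_converted=c,
                       conversion_rate=c / n if n else None)
            rows.append(row)
    return pd.DataFrame(rows)


def proximity_table(proximities: list[ProximityRecord]) -> pd.DataFrame:
    rows = []
    for p in proximities:
        rows.append({
            "pre_id": p.pre_id, "post_id": p.post_id,
            "x_nm": p.point_pre[0], "y_nm": p.point_pre[1], "z_nm": p.point_pre[2],
            "min_dist_nm": p.min_dist,
            "presyn_walk_nm": p.presyn_walk, "postsyn_walk_nm": p.postsyn_walk,
            "n_synapses": p.n_synapses,
            "post_compartment": p.post_compartment or ""})
    return pd.DataFrame(rows)
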