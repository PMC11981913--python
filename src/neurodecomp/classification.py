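"""Excitatory/inhibitory classification, axon identification, compartments.

The E/I classifier is a two-feature logistic regression (dendritic spine
density and dendritic shaft-synapse density, both per µm of skeletal
length): spiny, shaft-poor dendrites are excitatory; smooth, shaft-rich
dendrites are inhibitory.  Axon identification scores stems by outgoing-
synapse fraction, spine poverty and thinness.  Compartment labelling marks
the axon initial segment (AIS), apical/oblique/basal dendrites for
excitatory cells, and basal for inhibitory cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.linear_model import LogisticRegression

from .types import NM_PER_UM, ROOT, DecompGraph

EI_FEATURES = ("spine_density_per_um", "shaft_synapse_density_per_um")
DEFAULT_AIS_WINDOW_NM = 50_000.0


@dataclass
class EIModel:
    """Two-feature logistic model; probability is P(inhibitory)."""

    feature_names: tuple[str, str]
    weights: np.ndarray
    intercept: float
    threshold: float = 0.5

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = X @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        return np.where(p >= self.threshold, "inhibitory", "excitatory")

    def to_json(self) -> str:
        return json.dumps({"feature_names": list(self.feature_names),
                           "weights": self.weights.tolist(),
                           "intercept": float(self.intercept),
                           "threshold": self.threshold})

    @staticmethod
    def from_json(text: str) -> "EIModel":
        d = json.loads(text)
        return EIModel(feature_names=tuple(d["feature_names"]),
                       weights=np.asarray(d["weights"], dtype=float),
                       intercept=float(d["intercept"]),
                       threshold=float(d.get("threshold", 0.5)))


def ei_features(graph: DecompGraph) -> np.ndarray:
    """(spine density, shaft-synapse density) over the dendritic arbor."""
    L = 0.0
    spines = 0
    shaft = 0
    for bid in graph.branch_ids:
        b = graph.branches[bid]
        if b.is_soma_node or b.compartment in ("axon", "AIS"):
            continue
        L += b.skeletal_length
        spines += len(b.spine_ids)
        shaft += sum(1 for s in b.synapse_ids
                     if graph.synapses[s].valid
                     and graph.synapses[s].spine_part == "shaft")
    L_um = max(L / NM_PER_UM, 1e-9)
    return np.array([spines / L_um, shaft / L_um])


def fit_ei(X, y) -> EIModel:
    """Maximum-likelihood logistic fit (unpenalized, hence deterministic).

    ``y`` holds class labels 'excitatory'/'inhibitory' (or 0/1 with 1 =
    inhibitory).  Requires both classes present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        yb = (y == "inhibitory").astype(int)
    else:
        yb = y.astype(int)
    if len(np.unique(yb)) < 2:
        raise ValueError("need examples of both classes to fit the E/I model")
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    clf.fit(X, yb)
    return EIModel(feature_names=EI_FEATURES,
                   weights=clf.coef_[0].copy(),
                   intercept=float(clf.intercept_[0]))


def classify_ei(model: EIModel, graph: DecompGraph) -> str:
    return str(model.predict(ei_features(graph)[None, :])[0])


# ---------------------------------------------------------------------------
# axon identification
# ---------------------------------------------------------------------------

def identify_axon(graph: DecompGraph, min_outgoing_fraction: float = 0.5,
                  min_outgoing_synapses: int = 2) -> Optional[int]:
    """Pick the stem that is most axon-like, or None.

    Stems are scored by outgoing-synapse fraction, inverse spine density
    and inverse width; a stem qualifies only above a floor of outgoing
    evidence.  Ties resolve to the lowest stem id.
    """
    best = None
    for stem_root in graph.stem_roots():
        members = [stem_root] + sorted(graph.descendants(stem_root))
        members = [m for m in members if not graph.branches[m].is_soma_node]
        if not members:
            continue
        syns = [graph.synapses[s] for m in members
                for s in graph.branches[m].synapse_ids
                if graph.synapses[s].valid
                and graph.synapses[s].direction in ("incoming", "outgoing")]
        n_out = sum(1 for s in syns if s.direction == "outgoing")
        if not syns or n_out < min_outgoing_synapses:
            continue
        out_frac = n_out / len(syns)
        if out_frac < min_outgoing_fraction:
            continue
        L = np.array([graph.branches[m].skeletal_length for m in members])
        L_um = max(L.sum() / NM_PER_UM, 1e-9)
        spine_density = sum(len(graph.branches[m].spine_ids) for m in members) / L_um
        widths = np.array([graph.branches[m].width_mean for m in members])
        mean_width = float(np.average(widths, weights=np.maximum(L, 1.0)))
        score = (0.5 * out_frac
                 + 0.25 / (1.0 + spine_density / 0.2)
                 + 0.25 / (1.0 + mean_width / 400.0))
        key = (score, -stem_root)
        if best is None or key > best[0]:
            best = (key, stem_root)
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# compartment labelling
# ---------------------------------------------------------------------------

def _walk_start(graph: DecompGraph, bid: int) -> float:
    """Skeletal-walk distance from the soma to the start of a branch."""
    d = 0.0
    cur = graph.parent_of(bid)
    while cur is not None and cur != ROOT:
        d += graph.branches[cur].skeletal_length
        cur = graph.parent_of(cur)
    return d


def label_compartments(graph: DecompGraph, cell_class: str,
                       depth_axis=(0.0, 1.0, 0.0),
                       ais_window_nm: float = DEFAULT_AIS_WINDOW_NM,
                       axon_stem: Optional[int] = None) -> None:
    """Assign axon/AIS/basal/apical/oblique labels in place.

    AIS = axon branches starting within ``ais_window_nm`` of the soma along
    the skeletal walk.  For excitatory cells the widest stem heading toward
    the pia (against the depth axis) is the apical trunk; its side branches
    are oblique; the rest are basal.  Inhibitory dendrites are all basal.
    """
    depth_axis = np.asarray(depth_axis, dtype=float)
    depth_axis = depth_axis / np.linalg.norm(depth_axis)
    if axon_stem is None:
        axon_stem = identify_axon(graph)
    axon_members: set[int] = set()
    if axon_stem is not None:
        axon_members = {axon_stem} | graph.descendants(axon_stem)
    dendritic_stems = [s for s in graph.stem_roots() if s != axon_stem]

    apical_stem = None
    if cell_class == "excitatory" and dendritic_stems:
        cands = []
        for s in dendritic_stems:
            d = graph.branches[s].direction()
            cosang = -float(np.dot(d, depth_axis))  # toward pia
            if cosang > np.cos(np.deg2rad(45.0)):
                cands.append((graph.branches[s].width_start, s))
        if cands:
            apical_stem = max(cands, key=lambda t: (t[0], -t[1]))[1]

    for bid in graph.branch_ids:
        b = graph.branches[bid]
        if b.is_soma_node:
            b.compartment = "soma"
            continue
        if bid in axon_members:
            b.compartment = "AIS" if _walk_start(graph, bid) <= ais_window_nm else "axon"
            continue
        b.compartment = "basal"

    if apical_stem is not None:
        # trunk = follow the straightest continuation; side branches oblique
        members = {apical_stem} | graph.descendants(apical_stem)
        for m in members:
            graph.branches[m].compartment = "oblique"
        cur = apical_stem
        while True:
            graph.branches[cur].compartment = "apical"
            kids = [k for k in graph.children(cur)
                    if not graph.branches[k].is_soma_node]
            if not kids:
                break
            dc = graph.branches[cur].direction()
            cur = max(kids, key=lambda k: (float(np.dot(
                graph.branches[k].direction(), dc)), -k))

    # propagate compartments onto synapses
    for s in graph.synapses.values():
        if s.branch_id is not None and s.branch_id in graph.branches:
            s.compartment = graph.branches[s.branch_id].compartment
        elif s.compartment is None:
            s.compartment = "soma"
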