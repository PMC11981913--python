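"""Core containers shared across the pipeline.

All geometry is in nanometres.  Meshes are ``trimesh.Trimesh`` objects
(constructed with ``process=False`` so vertex/face indexing is stable);
skeletons are polyline trees; decompositions are soma-rooted directed trees
of non-branching segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx
import numpy as np

#: node id used for the soma root in every decomposition graph
ROOT = -1

NM_PER_UM = 1000.0


@dataclass
class SkeletonTree:
    """Polyline skeleton: points (P,3) in nm, edges (E,2) point-index pairs.

    ``radius`` is filled in by mesh correspondence (half of the local width).
    ``soma_nodes`` lists point indices that are collapsed soma centroids;
    the first one is the root used for orientation.  The edge set may contain
    a small number of cycles around junctions; decomposition breaks them.
    """

    points: np.ndarray
    edges: np.ndarray
    radius: Optional[np.ndarray] = None
    soma_nodes: list[int] = field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def root(self) -> int:
        return self.soma_nodes[0] if self.soma_nodes else 0

    def edge_lengths(self) -> np.ndarray:
        if len(self.edges) == 0:
            return np.zeros(0)
        d = self.points[self.edges[:, 0]] - self.points[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths().sum())

    def as_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_points))
        for (a, b), w in zip(self.edges, self.edge_lengths()):
            g.add_edge(int(a), int(b), length=float(w))
        return g


@dataclass
class SomaDetection:
    """One ball-like soma candidate on a mesh."""

    centroid: np.ndarray
    radius: float
    face_ids: np.ndarray
    surface_area: float
    volume: float

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)
        self.face_ids = np.asarray(self.face_ids, dtype=int)


@dataclass
class SynapseRecord:
    """One synapse, with labels accreted as the pipeline runs.

    ``direction`` is relative to the host neuron ('incoming'/'outgoing');
    ``spine_part`` is one of head/neck/shaft/soma/none.
    """

    syn_id: int
    pre_id: int
    post_id: int
    position: np.ndarray
    size: float
    direction: Optional[str] = None
    branch_id: Optional[int] = None
    compartment: Optional[str] = None
    spine_part: str = "none"
    valid: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)

    def copy(self) -> "SynapseRecord":
        return replace(self, position=self.position.copy())


@dataclass
class Branch:
    """A non-branching skeleton segment: one node of the decomposition."""

    branch_id: int
    points: np.ndarray
    width_profile: np.ndarray
    face_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    synapse_ids: list[int] = field(default_factory=list)
    spine_ids: list[int] = field(default_factory=list)
    compartment: Optional[str] = None
    parent: Optional[int] = None
    is_soma_node: bool = False
    soma: Optional[SomaDetection] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.width_profile = np.asarray(self.width_profile, dtype=float).reshape(-1)
        self.face_ids = np.asarray(self.face_ids, dtype=int)

    @property
    def skeletal_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def width_mean(self) -> float:
        return float(np.mean(self.width_profile)) if len(self.width_profile) else 0.0

    @property
    def width_start(self) -> float:
        return float(self.width_profile[0]) if len(self.width_profile) else 0.0

    @property
    def width_end(self) -> float:
        return float(self.width_profile[-1]) if len(self.width_profile) else 0.0

    def direction(self) -> np.ndarray:
        v = self.points[-1] - self.points[0]
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.zeros(3)


@dataclass
class DecompGraph:
    """Soma-rooted directed tree of :class:`Branch` nodes.

    Node ``ROOT`` (=-1) is the soma.  ``graph`` holds the tree topology,
    ``branches`` the payloads, ``synapses`` every synapse record assigned to
    this neuron (including soma synapses and invalidated ones).
    """

    soma: SomaDetection
    branches: dict[int, Branch]
    graph: nx.DiGraph
    synapses: dict[int, SynapseRecord] = field(default_factory=dict)
    soma_synapse_ids: list[int] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    discarded_synapse_ids: list[int] = field(default_factory=list)
    spines: dict[int, object] = field(default_factory=dict)

    def children(self, node: int) -> list[int]:
        return sorted(self.graph.successors(node))

    def parent_of(self, node: int) -> Optional[int]:
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None

    def descendants(self, node: int) -> set[int]:
        return set(nx.descendants(self.graph, node))

    def stems(self) -> list[list[int]]:
        """Root-child subtrees in root-child index order."""
        out = []
        for c in self.children(ROOT):
            out.append([c] + sorted(self.descendants(c)))
        return out

    def stem_roots(self) -> list[int]:
        return self.children(ROOT)

    @property
    def branch_ids(self) -> list[int]:
        return sorted(self.branches)

    @property
    def total_skeletal_length(self) -> float:
        return float(sum(b.skeletal_length for b in self.branches.values()))

    def valid_synapses(self) -> list[SynapseRecord]:
        return [s for s in self.synapses.values() if s.valid]

    def log(self, message: str) -> None:
        self.provenance.append(message)


@dataclass
class Spine:
    """A spine protrusion on a dendritic branch."""

    spine_id: int
    branch_id: int
    face_ids: np.ndarray
    base_point: np.ndarray
    skeletal_length: float
    axis: np.ndarray
    ring_centroid: np.ndarray
    head_face_ids: Optional[np.ndarray] = None
    neck_face_ids: Optional[np.ndarray] = None
    head_volume: float = 0.0
    neck_length: float = 0.0
    neck_width: float = 0.0
    bbox_extents: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.face_ids = np.asarray(self.face_ids, dtype=int)
        self.base_point = np.asarray(self.base_point, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        self.ring_centroid = np.asarray(self.ring_centroid, dtype=float).reshape(3)

    @property
    def has_neck(self) -> bool:
        return self.neck_face_ids is not None and len(self.neck_face_ids) > 0


@dataclass
class EditRecord:
    """One proofreading edit: a flagged node and its stripped closure."""

    rule: str
    params: dict
    flagged_node: int
    cut_location: np.ndarray
    removed_nodes: list[int]
    removed_synapse_ids: list[int]
    removed_skeletal_length: float

    def __post_init__(self) -> None:
        self.cut_location = np.asarray(self.cut_location, dtype=float).reshape(3)

    def to_json_dict(self) -> dict:
        return {
            "rule": self.rule,
            "params": {k: (v if not isinstance(v, float) else float(v)) for k, v in self.params.items()},
            "flagged_node": int(self.flagged_node),
            "cut_location": [float(x) for x in self.cut_location],
            "removed_nodes": [int(n) for n in self.removed_nodes],
            "removed_synapse_ids": [int(s) for s in self.removed_synapse_ids],
            "removed_skeletal_length": float(self.removed_skeletal_length),
        }


@dataclass
class PRSummary:
    """Synapse-level precision/recall against ground truth."""

    tp: int
    fp: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]
    strata: dict = field(default_factory=dict)


@dataclass
class ProximityRecord:
    """One axon-passes-near-dendrite event between a neuron pair."""

    pre_id: int
    post_id: int
    point_pre: np.ndarray
    point_post: np.ndarray
    min_dist: float
    presyn_walk: float
    postsyn_walk: float
    synapse_ids: list[int] = field(default_factory=list)
    post_compartment: Optional[str] = None
    run_points: Optional[np.ndarray] = None  # axon samples spanning the run

    def __post_init__(self) -> None:
        self.point_pre = np.asarray(self.point_pre, dtype=float).reshape(3)
        self.point_post = np.asarray(self.point_post, dtype=float).reshape(3)

    @property
    def n_synapses(self) -> int:
        return len(self.synapse_ids)
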