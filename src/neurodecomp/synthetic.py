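"""Synthetic ground-truth neurons, merged scenes and synapse tables.

The generator emulates the geometry the pipeline assumes: tubular neurites
with tapering radii swept along a branching skeleton, an icosphere soma,
mushroom/stubby spine protrusions, Poisson-scattered synapses with
compartment-dependent densities, and deliberately injected merge errors
(axon-on-axon, axon-on-dendrite, soma bridges, double-back kinks, width
jumps) with per-face and per-synapse ground truth.

Welds are built by interpenetration, never by boolean union: a child tube
starts on its parent's axis so the two solids overlap, and the overlap is
what downstream skeletonization bridges.  This keeps face-level ground
truth exact.

All geometry is in nanometres; user-facing densities are per micrometre and
are converted exactly once, at parameter intake.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import trimesh

from .types import NM_PER_UM, SkeletonTree, SynapseRecord

# face-label kind codes
KIND_SOMA = 0
KIND_BRANCH = 1
KIND_SPINE = 2
KIND_WELD = 3
KIND_NAMES = ("soma", "branch", "spine", "weld")

ERROR_TYPES = ("axon_on_axon", "axon_on_dendrite", "soma_bridge", "double_back", "width_jump")

_EXTERNAL_PARTNER_BASE = 10_000_000


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class MorphologyParams:
    """Morphology and synapse-statistics knobs for one synthetic neuron.

    Lengths in the named units; densities per micrometre of skeletal length.
    """

    n_dendrite_stems: int = 3
    branch_depth: int = 2
    segment_length_um: tuple = (15.0, 30.0)
    step_um: float = 2.0
    taper_rate: float = 0.75
    child_radius_factor: float = 0.9
    dendrite_radius_nm: float = 900.0
    apical_radius_nm: float = 1200.0
    axon_radius_nm: float = 280.0
    soma_radius_nm: float = 5000.0
    wiggle_deg: float = 4.0
    branch_angle_deg: tuple = (25.0, 50.0)
    include_axon: bool = True
    include_apical: bool = True
    axon_depth: int = 1
    axon_segment_length_um: tuple = (25.0, 45.0)
    spine_density_per_um: float = 1.0
    mushroom_fraction: float = 0.6
    spine_synapse_rate: float = 0.9
    shaft_synapse_density_per_um: float = 0.15
    axon_synapse_density_per_um: float = 0.35
    soma_synapse_count: int = 8
    cell_class: str = "excitatory"
    neuron_id: int = 0
    depth_axis: tuple = (0.0, 1.0, 0.0)

    def validate(self) -> None:
        for name in (
            "segment_length_um", "step_um", "taper_rate", "child_radius_factor",
            "dendrite_radius_nm", "apical_radius_nm", "axon_radius_nm",
            "soma_radius_nm", "wiggle_deg", "branch_angle_deg",
            "axon_segment_length_um", "spine_density_per_um", "mushroom_fraction",
            "spine_synapse_rate", "shaft_synapse_density_per_um",
            "axon_synapse_density_per_um", "soma_synapse_count",
            "n_dendrite_stems", "branch_depth", "axon_depth",
        ):
            value = getattr(self, name)
            arr = np.atleast_1d(np.asarray(value, dtype=float))
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
            if np.any(arr < 0):
                raise ValueError(f"parameter {name!r} must be non-negative, got {value!r}")
        if self.cell_class not in ("excitatory", "inhibitory"):
            raise ValueError(f"parameter 'cell_class' must be excitatory|inhibitory, got {self.cell_class!r}")


def inhibitory_params(**overrides) -> MorphologyParams:
    """Smooth, shaft-synapse-rich morphology typical of inhibitory cells."""
    defaults = dict(
        cell_class="inhibitory", include_apical=False,
        spine_density_per_um=0.05, shaft_synapse_density_per_um=0.8,
    )
    defaults.update(overrides)
    return MorphologyParams(**defaults)


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class GTBranch:
    branch_id: int
    parent_id: Optional[int]
    points: np.ndarray       # (k,3) nm; first point = parent's last (or soma exit)
    radii: np.ndarray        # (k,) nm
    compartment: str         # axon | basal | apical | oblique

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def length_um(self) -> float:
        return self.length / NM_PER_UM

    def point_at(self, t: float) -> tuple[np.ndarray, np.ndarray, float]:
        """Interpolate (position, tangent, radius) at arc-length t from start."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        t = float(np.clip(t, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, t, side="right") - 1)
        i = min(i, len(seg) - 1)
        f = (t - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        pos = self.points[i] * (1 - f) + self.points[i + 1] * f
        tan = _unit(self.points[i + 1] - self.points[i])
        rad = self.radii[i] * (1 - f) + self.radii[i + 1] * f
        return pos, tan, float(rad)


@dataclass
class SpineSpec:
    spine_id: int
    branch_id: int
    arc_t: float                # arc length from branch start, nm
    attach_axis: np.ndarray     # point on the branch axis
    outward: np.ndarray         # unit normal from axis to surface
    shaft_radius: float
    kind: str                   # mushroom | stubby
    head_radius: float
    neck_radius: float
    neck_length: float
    truth_length: float         # height above the shaft surface, nm

    @property
    def attach_surface(self) -> np.ndarray:
        return self.attach_axis + self.outward * self.shaft_radius

    def head_center(self) -> np.ndarray:
        if self.kind == "mushroom":
            return self.attach_surface + self.outward * (self.neck_length + 0.7 * self.head_radius)
        return self.attach_surface


@dataclass
class GroundTruthNeuron:
    neuron_id: int
    params: MorphologyParams
    soma_center: np.ndarray
    soma_radius: float
    branches: list[GTBranch]
    spines: list[SpineSpec]
    synapses: list[SynapseRecord]
    cell_class: str
    axon_stem_id: Optional[int]
    apical_stem_id: Optional[int]

    def branch(self, branch_id: int) -> GTBranch:
        return self.branches[branch_id]

    def dendritic_branches(self) -> list[GTBranch]:
        return [b for b in self.branches if b.compartment != "axon"]

    def total_skeletal_length(self, compartments=None) -> float:
        return float(sum(
            b.length for b in self.branches
            if compartments is None or b.compartment in compartments))

    def skeleton_tree(self) -> SkeletonTree:
        """Ground-truth skeleton as a single tree rooted at the soma centre."""
        points = [self.soma_center.copy()]
        edges = []
        end_node = {}  # branch_id -> node index of its last point
        for b in self.branches:
            # a branch's first point duplicates the parent's end (or the soma
            # exit): start a fresh node for stems, reuse the parent's end node
            if b.parent_id is None:
                points.append(b.points[0].copy())
                edges.append((0, len(points) - 1))
                prev = len(points) - 1
            else:
                prev = end_node[b.parent_id]
            for p in b.points[1:]:
                points.append(p.copy())
                edges.append((prev, len(points) - 1))
                prev = len(points) - 1
            end_node[b.branch_id] = prev
        tree = SkeletonTree(np.array(points), np.array(edges, dtype=int), soma_nodes=[0])
        return tree

    def translate(self, offset) -> "GroundTruthNeuron":
        offset = np.asarray(offset, dtype=float)
        branches = [GTBranch(b.branch_id, b.parent_id, b.points + offset, b.radii.copy(), b.compartment)
                    for b in self.branches]
        spines = [SpineSpec(s.spine_id, s.branch_id, s.arc_t, s.attach_axis + offset,
                            s.outward.copy(), s.shaft_radius, s.kind, s.head_radius,
                            s.neck_radius, s.neck_length, s.truth_length)
                  for s in self.spines]
        synapses = []
        for s in self.synapses:
            c = s.copy()
            c.position = c.position + offset
            synapses.append(c)
        return GroundTruthNeuron(self.neuron_id, self.params, self.soma_center + offset,
                                 self.soma_radius, branches, spines, synapses,
                                 self.cell_class, self.axon_stem_id, self.apical_stem_id)


# ---------------------------------------------------------------------------
# small vector helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _perpendicular(v: np.ndarray) -> np.ndarray:
    v = _unit(v)
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    axis = _unit(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _deviate(rng, direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """Tilt `direction` by angle_deg about a random perpendicular axis."""
    perp = _perpendicular(direction)
    perp = _rotate(perp, direction, rng.uniform(0, 2 * np.pi))
    return _unit(_rotate(direction, perp, np.deg2rad(angle_deg)))


# ---------------------------------------------------------------------------
# skeleton growth
# ---------------------------------------------------------------------------

def generate_neuron(params: MorphologyParams, seed: int) -> GroundTruthNeuron:
    """Grow a ground-truth neuron; deterministic for fixed params+seed.

    Sub-streams for geometry, spines and synapses are derived from the one
    seed by fixed offsets, so adding spines never perturbs the skeleton.
    """
    params.validate()
    rng_geo = np.random.default_rng([int(seed), 0])
    rng_spine = np.random.default_rng([int(seed), 1])
    rng_syn = np.random.default_rng([int(seed), 2])

    soma_center = np.zeros(3)
    R = params.soma_radius_nm
    depth_axis = _unit(np.asarray(params.depth_axis, dtype=float))

    branches: list[GTBranch] = []
    next_id = [0]

    def grow(start, direction, radius, compartment, depth, max_depth, seg_len, parent_id):
        bid = next_id[0]
        next_id[0] += 1
        length = rng_geo.uniform(*seg_len) * NM_PER_UM
        step = params.step_um * NM_PER_UM
        n_steps = max(1, int(round(length / step)))
        pts = [np.asarray(start, dtype=float)]
        d = _unit(direction)
        for _ in range(n_steps):
            d = _deviate(rng_geo, d, rng_geo.normal(0.0, params.wiggle_deg))
            pts.append(pts[-1] + d * step)
        pts = np.array(pts)
        radii = np.linspace(radius, radius * params.taper_rate, len(pts))
        branches.append(GTBranch(bid, parent_id, pts, radii, compartment))
        if depth < max_depth:
            a1 = rng_geo.uniform(*params.branch_angle_deg)
            a2 = rng_geo.uniform(*params.branch_angle_deg)
            child_r = radii[-1] * params.child_radius_factor
            child_comp = compartment
            for i, ang in enumerate((a1, -a2)):
                cd = _deviate(rng_geo, d, ang)
                comp = child_comp
                if compartment == "apical":
                    comp = "apical" if i == 0 else "oblique"
                grow(pts[-1], cd, child_r, comp, depth + 1, max_depth, seg_len, bid)
        return bid

    axon_stem_id = None
    apical_stem_id = None
    exit_r = 0.8 * R  # stems start slightly inside the soma so solids overlap

    if params.include_axon:
        d = _deviate(rng_geo, depth_axis, rng_geo.uniform(0, 15))
        axon_stem_id = grow(soma_center + d * exit_r, d, params.axon_radius_nm,
                            "axon", 0, params.axon_depth,
                            params.axon_segment_length_um, None)

    if params.cell_class == "excitatory" and params.include_apical:
        d = _deviate(rng_geo, -depth_axis, rng_geo.uniform(0, 10))
        apical_stem_id = grow(soma_center + d * exit_r, d, params.apical_radius_nm,
                              "apical", 0, params.branch_depth,
                              params.segment_length_um, None)

    for k in range(params.n_dendrite_stems):
        az = 2 * np.pi * k / max(1, params.n_dendrite_stems) + rng_geo.uniform(-0.3, 0.3)
        # basal stems fan out roughly orthogonal to the depth axis
        base = np.cos(az) * _perpendicular(depth_axis) + \
            np.sin(az) * np.cross(depth_axis, _perpendicular(depth_axis))
        d = _unit(base + depth_axis * rng_geo.uniform(-0.4, 0.4))
        grow(soma_center + d * exit_r, d, params.dendrite_radius_nm,
             "basal", 0, params.branch_depth, params.segment_length_um, None)

    spines = _scatter_spines(rng_spine, branches, params)
    synapses = _scatter_synapses(rng_syn, branches, spines, params, soma_center, R)

    return GroundTruthNeuron(
        neuron_id=params.neuron_id, params=params, soma_center=soma_center,
        soma_radius=R, branches=branches, spines=spines, synapses=synapses,
        cell_class=params.cell_class, axon_stem_id=axon_stem_id,
        apical_stem_id=apical_stem_id)


def _frame_at(tangent: np.ndarray, azimuth: float) -> np.ndarray:
    """Unit normal at the given azimuth around a tangent direction."""
    n1 = _perpendicular(tangent)
    n2 = _unit(np.cross(tangent, n1))
    return _unit(np.cos(azimuth) * n1 + np.sin(azimuth) * n2)


def _scatter_spines(rng, branches, params) -> list[SpineSpec]:
    spines = []
    sid = 0
    for b in branches:
        if b.compartment == "axon":
            continue
        n = rng.poisson(params.spine_density_per_um * b.length_um)
        # keep spines off the very ends so the attachment is unambiguous
        ts = np.sort(rng.uniform(0.05, 0.95, size=n)) * b.length
        for t in ts:
            pos, tan, rad = b.point_at(t)
            outward = _frame_at(tan, rng.uniform(0, 2 * np.pi))
            if rng.uniform() < params.mushroom_fraction:
                head_r = rng.uniform(250.0, 500.0)
                neck_r = rng.uniform(80.0, 150.0)
                neck_len = rng.uniform(500.0, 2000.0)
                truth = neck_len + 1.7 * head_r
                spines.append(SpineSpec(sid, b.branch_id, float(t), pos, outward,
                                        rad, "mushroom", head_r, neck_r, neck_len, truth))
            else:
                head_r = rng.uniform(300.0, 600.0)
                spines.append(SpineSpec(sid, b.branch_id, float(t), pos, outward,
                                        rad, "stubby", head_r, 0.0, 0.0, head_r))
            sid += 1
    return spines


def _scatter_synapses(rng, branches, spines, params, soma_center, soma_radius):
    records: list[SynapseRecord] = []
    nid = params.neuron_id
    counter = [0]
    partner = [0]

    def new_record(position, size, direction, branch_id, spine_part):
        pid = _EXTERNAL_PARTNER_BASE + partner[0]
        partner[0] += 1
        pre, post = (nid, pid) if direction == "outgoing" else (pid, nid)
        rec = SynapseRecord(syn_id=counter[0], pre_id=pre, post_id=post,
                            position=position, size=float(size), direction=direction,
                            branch_id=branch_id, spine_part=spine_part, valid=True)
        counter[0] += 1
        records.append(rec)

    for b in branches:
        if b.compartment == "axon":
            density = params.axon_synapse_density_per_um
            n = rng.poisson(density * b.length_um)
            for t in rng.uniform(0, b.length, size=n):
                pos, tan, rad = b.point_at(t)
                surf = pos + _frame_at(tan, rng.uniform(0, 2 * np.pi)) * rad
                new_record(surf, rng.lognormal(np.log(2000), 0.4), "outgoing",
                           b.branch_id, "none")
        else:
            n = rng.poisson(params.shaft_synapse_density_per_um * b.length_um)
            for t in rng.uniform(0, b.length, size=n):
                pos, tan, rad = b.point_at(t)
                surf = pos + _frame_at(tan, rng.uniform(0, 2 * np.pi)) * rad
                new_record(surf, rng.lognormal(np.log(1500), 0.4), "incoming",
                           b.branch_id, "shaft")

    # spine-head synapses: size coupled positively to head volume
    for s in spines:
        if rng.uniform() >= params.spine_synapse_rate:
            continue
        top = s.head_center() + s.outward * s.head_radius * 0.95
        head_vol = 4.0 / 3.0 * np.pi * s.head_radius ** 3
        size = (head_vol / 1e7) * rng.lognormal(0.0, 0.25) * 30.0
        new_record(top, size, "incoming", s.branch_id, "head")

    for _ in range(int(params.soma_synapse_count)):
        d = _unit(rng.normal(size=3))
        new_record(soma_center + d * soma_radius, rng.lognormal(np.log(1800), 0.4),
                   "incoming", None, "soma")
    return records


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

def densify_polyline(points, radii, step: float = 2000.0):
    """Resample a polyline (with per-point radii) at ~step spacing so the
    swept mesh has uniform ring density."""
    points = np.asarray(points, dtype=float)
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if len(radii) == 1:
        radii = np.full(len(points), radii[0])
    out_p, out_r = [points[0]], [radii[0]]
    for i in range(len(points) - 1):
        seg = points[i + 1] - points[i]
        L = np.linalg.norm(seg)
        n = max(1, int(np.ceil(L / step)))
        for k in range(1, n + 1):
            f = k / n
            out_p.append(points[i] + f * seg)
            out_r.append(radii[i] * (1 - f) + radii[i + 1] * f)
    return np.array(out_p), np.array(out_r)


def tube_mesh(points, radii, resolution: int, cap_start=True, cap_end=True) -> trimesh.Trimesh:
    """Closed frustum tube swept along a polyline with per-point radii."""
    points = np.asarray(points, dtype=float)
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if len(radii) == 1:
        radii = np.full(len(points), radii[0])
    P = len(points)
    # parallel-transported frames
    tangents = np.zeros((P, 3))
    segs = np.diff(points, axis=0)
    for i in range(P):
        if i == 0:
            tangents[i] = _unit(segs[0])
        elif i == P - 1:
            tangents[i] = _unit(segs[-1])
        else:
            tangents[i] = _unit(_unit(segs[i - 1]) + _unit(segs[i]))
    n = _perpendicular(tangents[0])
    verts = []
    theta = np.linspace(0, 2 * np.pi, resolution, endpoint=False)
    for i in range(P):
        if i > 0:
            # transport the normal across the tangent rotation
            v = np.cross(tangents[i - 1], tangents[i])
            s = np.linalg.norm(v)
            if s > 1e-9:
                ang = np.arctan2(s, np.dot(tangents[i - 1], tangents[i]))
                n = _rotate(n, v / s, ang)
            n = _unit(n - np.dot(n, tangents[i]) * tangents[i])
        b = _unit(np.cross(tangents[i], n))
        ring = points[i] + radii[i] * (np.outer(np.cos(theta), n) + np.outer(np.sin(theta), b))
        verts.append(ring)
    verts = np.concatenate(verts)
    faces = []
    for i in range(P - 1):
        for j in range(resolution):
            a = i * resolution + j
            bb = i * resolution + (j + 1) % resolution
            c = (i + 1) * resolution + j
            d = (i + 1) * resolution + (j + 1) % resolution
            faces.append([a, bb, d])
            faces.append([a, d, c])
    vlist = [verts]
    nv = len(verts)
    if cap_start:
        vlist.append(points[0][None, :])
        ci = nv
        nv += 1
        for j in range(resolution):
            faces.append([ci, (j + 1) % resolution, j])
    if cap_end:
        vlist.append(points[-1][None, :])
        ci = nv
        nv += 1
        base = (P - 1) * resolution
        for j in range(resolution):
            faces.append([ci, base + j, base + (j + 1) % resolution])
    return trimesh.Trimesh(vertices=np.concatenate(vlist), faces=np.array(faces), process=False)


@dataclass
class FaceLabels:
    """Per-face source labels: kind code, source id, and scene component."""

    kind: np.ndarray       # uint8 codes into KIND_NAMES
    ref_id: np.ndarray     # branch/spine/soma/weld id
    component: np.ndarray  # scene component index; -1 for weld/error collars

    def __len__(self) -> int:
        return len(self.kind)

    @staticmethod
    def concatenate(parts: list["FaceLabels"]) -> "FaceLabels":
        return FaceLabels(
            np.concatenate([p.kind for p in parts]),
            np.concatenate([p.ref_id for p in parts]),
            np.concatenate([p.component for p in parts]))

    def faces_of(self, kind: int, ref_id: Optional[int] = None,
                 component: Optional[int] = None) -> np.ndarray:
        m = self.kind == kind
        if ref_id is not None:
            m &= self.ref_id == ref_id
        if component is not None:
            m &= self.component == component
        return np.flatnonzero(m)

    def to_json_dict(self) -> dict:
        return {"kind": self.kind.tolist(), "ref_id": self.ref_id.tolist(),
                "component": self.component.tolist(), "kind_names": list(KIND_NAMES)}


def _labels_for(mesh, kind, ref_id, component) -> FaceLabels:
    n = len(mesh.faces)
    return FaceLabels(np.full(n, kind, dtype=np.uint8),
                      np.full(n, ref_id, dtype=np.int64),
                      np.full(n, component, dtype=np.int64))


def _assemble(parts: list[tuple[trimesh.Trimesh, FaceLabels]]) -> tuple[trimesh.Trimesh, FaceLabels]:
    meshes = [p[0] for p in parts]
    labels = FaceLabels.concatenate([p[1] for p in parts])
    offsets = np.cumsum([0] + [len(m.vertices) for m in meshes[:-1]])
    verts = np.concatenate([m.vertices for m in meshes])
    faces = np.concatenate([m.faces + o for m, o in zip(meshes, offsets)])
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False), labels


def mesh_from_neuron(neuron: GroundTruthNeuron, resolution: int = 12,
                     component: int = 0) -> tuple[trimesh.Trimesh, FaceLabels]:
    """Mesh a ground-truth neuron; every face carries its source label."""
    if resolution < 6:
        raise ValueError("resolution must be >= 6 segments per ring")
    parts = []
    soma = trimesh.creation.icosphere(subdivisions=3, radius=neuron.soma_radius)
    soma.apply_translation(neuron.soma_center)
    parts.append((soma, _labels_for(soma, KIND_SOMA, 0, component)))

    for b in neuron.branches:
        tube = tube_mesh(b.points, b.radii, resolution)
        parts.append((tube, _labels_for(tube, KIND_BRANCH, b.branch_id, component)))

    for s in neuron.spines:
        sub = []
        if s.kind == "mushroom":
            base = s.attach_surface - s.outward * 0.5 * s.shaft_radius
            tip = s.attach_surface + s.outward * (s.neck_length + 0.2 * s.head_radius)
            neck = tube_mesh(np.array([base, tip]), np.array([s.neck_radius, s.neck_radius]),
                             max(6, resolution // 2))
            head = trimesh.creation.icosphere(subdivisions=2, radius=s.head_radius)
            head.apply_translation(s.head_center())
            sub = [neck, head]
        else:
            head = trimesh.creation.icosphere(subdivisions=2, radius=s.head_radius)
            head.apply_translation(s.attach_surface)
            sub = [head]
        for m in sub:
            parts.append((m, _labels_for(m, KIND_SPINE, s.spine_id, component)))

    return _assemble(parts)


# ---------------------------------------------------------------------------
# scenes and merge errors
# ---------------------------------------------------------------------------

@dataclass
class MergeErrorTruth:
    kind: str
    location: np.ndarray
    face_ids: np.ndarray
    host_branch_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float).reshape(3)
        self.face_ids = np.asarray(self.face_ids, dtype=int)

    def to_json_dict(self) -> dict:
        return {"kind": self.kind, "location": self.location.tolist(),
                "face_ids": self.face_ids.tolist(),
                "host_branch_id": None if self.host_branch_id is None else int(self.host_branch_id)}


@dataclass
class MergeScene:
    mesh: trimesh.Trimesh
    labels: FaceLabels
    components: list
    synapses: list[SynapseRecord]
    error_truth: list[MergeErrorTruth] = field(default_factory=list)

    def neuron(self, idx: int) -> GroundTruthNeuron:
        return self.components[idx]

    def truth_valid_ids(self) -> set[int]:
        return {s.syn_id for s in self.synapses if s.valid}

    def input_synapses(self) -> list[SynapseRecord]:
        """Synapse records as the pipeline receives them: validity reset
        (ground-truth flags are for evaluation only)."""
        out = []
        for s in self.synapses:
            c = s.copy()
            c.valid = True
            c.spine_part = "none"
            c.compartment = None
            c.branch_id = None
            out.append(c)
        return out


def make_scene(neurons: list[GroundTruthNeuron], resolution: int = 12) -> MergeScene:
    """Mesh one or more neurons into a single scene with globally unique ids."""
    parts = []
    synapses = []
    comps = []
    for idx, n in enumerate(neurons):
        m, lab = mesh_from_neuron(n, resolution=resolution, component=idx)
        parts.append((m, lab))
        for s in n.synapses:
            c = s.copy()
            c.syn_id = idx * 1_000_000 + s.syn_id
            synapses.append(c)
        comps.append(n)
    mesh, labels = _assemble(parts)
    return MergeScene(mesh=mesh, labels=labels, components=comps, synapses=synapses)


def _append_geometry(scene: MergeScene, mesh: trimesh.Trimesh, kind_code: int,
                     ref_id: int, component: int) -> tuple[MergeScene, np.ndarray]:
    base_faces = len(scene.mesh.faces)
    combined, labels = _assemble([
        (scene.mesh, scene.labels),
        (mesh, _labels_for(mesh, kind_code, ref_id, component))])
    new_face_ids = np.arange(base_faces, len(combined.faces))
    out = MergeScene(mesh=combined, labels=labels, components=list(scene.components),
                     synapses=[s.copy() for s in scene.synapses],
                     error_truth=list(scene.error_truth))
    return out, new_face_ids


def _foreign_synapses(rng, points, radii, density_per_um, direction, host_id,
                      start_syn_id) -> list[SynapseRecord]:
    length_um = float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum()) / NM_PER_UM
    n = rng.poisson(density_per_um * length_um)
    out = []
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    for i, t in enumerate(rng.uniform(0, cum[-1], size=n)):
        j = min(int(np.searchsorted(cum, t, side="right")) - 1, len(seg) - 1)
        f = (t - cum[j]) / seg[j] if seg[j] > 0 else 0.0
        pos = points[j] * (1 - f) + points[j + 1] * f
        tan = _unit(points[j + 1] - points[j])
        r = radii[j] * (1 - f) + radii[j + 1] * f
        surf = pos + _frame_at(tan, rng.uniform(0, 2 * np.pi)) * r
        pid = _EXTERNAL_PARTNER_BASE + 500_000 + start_syn_id + i
        pre, post = (host_id, pid) if direction == "outgoing" else (pid, host_id)
        out.append(SynapseRecord(syn_id=start_syn_id + i, pre_id=pre, post_id=post,
                                 position=surf, size=float(rng.lognormal(np.log(1800), 0.4)),
                                 direction=direction, spine_part="none", valid=False))
    return out


def _pick_terminal_dendrite(rng, neuron: GroundTruthNeuron) -> GTBranch:
    parents = {b.parent_id for b in neuron.branches if b.parent_id is not None}
    leaves = [b for b in neuron.dendritic_branches() if b.branch_id not in parents]
    return leaves[int(rng.integers(len(leaves)))]


def inject_merge_error(scene: MergeScene, error_type: str, seed: int,
                       resolution: int = 10) -> MergeScene:
    """Weld foreign geometry into the scene and record exact ground truth.

    The foreign sub-mesh interpenetrates the host (no boolean union); its
    faces are recorded in ``error_truth`` and any synapses scattered on it
    are marked invalid.
    """
    if error_type not in ERROR_TYPES:
        raise ValueError(
            f"unknown error type {error_type!r}; supported: {', '.join(ERROR_TYPES)}")
    if not scene.components:
        raise ValueError("scene must contain at least one neuron")
    rng = np.random.default_rng([int(seed), 7])
    host = scene.neuron(0)
    next_syn = 9_000_000 + 10_000 * len(scene.error_truth)

    if error_type == "soma_bridge":
        if len(scene.components) < 2:
            raise ValueError("soma_bridge requires at least two neurons in the scene")
        a, b = scene.neuron(0), scene.neuron(1)
        pts = np.array([a.soma_center, 0.5 * (a.soma_center + b.soma_center), b.soma_center])
        pts, rr = densify_polyline(pts, np.full(3, 1200.0))
        tube = tube_mesh(pts, rr, resolution)
        out, fids = _append_geometry(scene, tube, KIND_WELD, len(scene.error_truth), -1)
        out.error_truth.append(MergeErrorTruth("soma_bridge", pts[1], fids))
        return out

    if error_type == "double_back":
        b = _pick_terminal_dendrite(rng, host)
        tip = b.points[-1]
        d = _unit(b.points[-1] - b.points[-2])
        back = _deviate(rng, -d, 15.0)   # ~165 deg turn, heading back soma-ward
        length = 15_000.0
        pts = np.array([tip - d * 1500.0, tip, tip + back * 0.5 * length, tip + back * length])
        r = float(b.radii[-1])
        pts, rr = densify_polyline(pts, np.full(4, r))
        tube = tube_mesh(pts, rr, resolution)
        out, fids = _append_geometry(scene, tube, KIND_WELD, len(scene.error_truth), -1)
        out.error_truth.append(MergeErrorTruth("double_back", tip, fids, host_branch_id=b.branch_id))
        out.synapses.extend(_foreign_synapses(rng, pts[1:], rr[1:], 0.2,
                                              "incoming", host.neuron_id, next_syn))
        return out

    if error_type == "width_jump":
        b = _pick_terminal_dendrite(rng, host)
        tip = b.points[-1]
        d = _unit(b.points[-1] - b.points[-2])
        thin = float(b.radii[-1])
        fat = max(1200.0, 3.0 * thin)
        length = 18_000.0
        pts = np.array([tip - d * 1500.0, tip + d * 0.4 * length, tip + d * length])
        pts, rr = densify_polyline(pts, np.full(3, fat))
        tube = tube_mesh(pts, rr, resolution)
        out, fids = _append_geometry(scene, tube, KIND_WELD, len(scene.error_truth), -1)
        out.error_truth.append(MergeErrorTruth("width_jump", tip, fids, host_branch_id=b.branch_id))
        out.synapses.extend(_foreign_synapses(rng, pts, rr, 0.2,
                                              "incoming", host.neuron_id, next_syn))
        return out

    if error_type == "axon_on_dendrite":
        dends = [b for b in host.dendritic_branches()]
        b = dends[int(rng.integers(len(dends)))]
        t = rng.uniform(0.3, 0.7) * b.length
        pos, tan, rad = b.point_at(t)
        outward = _frame_at(tan, rng.uniform(0, 2 * np.pi))
        length = 40_000.0
        r = 220.0
        d1 = _deviate(rng, outward, 10.0)
        pts = [pos]
        d = d1
        step = 2000.0
        for _ in range(int(length / step)):
            d = _deviate(rng, d, 4.0)
            pts.append(pts[-1] + d * step)
        pts = np.array(pts)
        tube = tube_mesh(pts, np.full(len(pts), r), resolution)
        out, fids = _append_geometry(scene, tube, KIND_WELD, len(scene.error_truth), -1)
        out.error_truth.append(MergeErrorTruth("axon_on_dendrite", pos, fids, host_branch_id=b.branch_id))
        out.synapses.extend(_foreign_synapses(rng, pts, np.full(len(pts), r), 0.45,
                                              "outgoing", host.neuron_id, next_syn))
        return out

    # axon_on_axon: a straight foreign axon crossing the host axon (X weld)
    axon_branches = [b for b in host.branches if b.compartment == "axon"]
    if not axon_branches:
        raise ValueError("axon_on_axon requires a host axon")
    b = axon_branches[int(rng.integers(len(axon_branches)))]
    t = rng.uniform(0.35, 0.65) * b.length
    pos, tan, rad = b.point_at(t)
    cross = _frame_at(tan, rng.uniform(0, 2 * np.pi))
    half = 22_000.0
    pts = np.array([pos - cross * half, pos - cross * 0.3 * half, pos,
                    pos + cross * 0.3 * half, pos + cross * half])
    r = 220.0
    pts, rr = densify_polyline(pts, np.full(5, r))
    tube = tube_mesh(pts, rr, resolution)
    out, fids = _append_geometry(scene, tube, KIND_WELD, len(scene.error_truth), -1)
    out.error_truth.append(MergeErrorTruth("axon_on_axon", pos, fids, host_branch_id=b.branch_id))
    out.synapses.extend(_foreign_synapses(rng, pts, rr, 0.45,
                                          "outgoing", host.neuron_id, next_syn))
    return out


def weld_pair(scene: MergeScene, seed: int, resolution: int = 10) -> MergeScene:
    """Weld neuron 0's axon tip onto a mid-dendrite point of neuron 1.

    Produces the classic two-soma merge used for multi-soma splitting.
    """
    if len(scene.components) < 2:
        raise ValueError("weld_pair requires two neurons")
    rng = np.random.default_rng([int(seed), 11])
    a, b = scene.neuron(0), scene.neuron(1)
    axons = [br for br in a.branches if br.compartment == "axon"]
    parents = {br.parent_id for br in a.branches if br.parent_id is not None}
    tips = [br for br in axons if br.branch_id not in parents]
    src = tips[int(rng.integers(len(tips)))]
    tip = src.points[-1]
    dends = b.dendritic_branches()
    dst = dends[int(rng.integers(len(dends)))]
    pos, tan, rad = dst.point_at(rng.uniform(0.3, 0.7) * dst.length)
    d = _unit(pos - tip)
    pts = np.array([tip - d * 1500.0, tip, 0.5 * (tip + pos), pos])
    pts, rr = densify_polyline(pts, np.full(4, 260.0))
    tube = tube_mesh(pts, rr, resolution)
    out, fids = _append_geometry(scene, tube, KIND_WELD, len(scene.error_truth), -1)
    out.error_truth.append(MergeErrorTruth("axon_on_dendrite", pos, fids,
                                           host_branch_id=dst.branch_id))
    out.synapses.extend(_foreign_synapses(
        rng, pts[1:], rr[1:], 0.3, "outgoing", a.neuron_id,
        9_500_000 + 10_000 * len(scene.error_truth)))
    return out


# ---------------------------------------------------------------------------
# presets and IO
# ---------------------------------------------------------------------------

def glia_blob(seed: int, radius: float = 7000.0, n_bumps: int = 8) -> tuple[trimesh.Trimesh, FaceLabels]:
    """Large lumpy spine-free blob emulating a glia fragment.

    Bumps are mostly buried in the core so the surface stays fat everywhere
    (no thin tube-like protrusions).
    """
    rng = np.random.default_rng([int(seed), 13])
    core = trimesh.creation.icosphere(subdivisions=3, radius=radius)
    parts = [(core, _labels_for(core, KIND_SOMA, 0, 0))]
    for _ in range(n_bumps):
        d = _unit(rng.normal(size=3))
        bump = trimesh.creation.icosphere(subdivisions=2, radius=rng.uniform(0.5, 0.7) * radius)
        bump.apply_translation(d * radius * 0.8)
        parts.append((bump, _labels_for(bump, KIND_SOMA, 1, 0)))
    return _assemble(parts)


def orphan_axon(seed: int, length_um: float = 50.0, radius: float = 230.0,
                resolution: int = 10) -> tuple[trimesh.Trimesh, FaceLabels]:
    """A soma-less axon tube fragment."""
    rng = np.random.default_rng([int(seed), 17])
    d = _unit(rng.normal(size=3))
    step = 2000.0
    pts = [np.zeros(3)]
    for _ in range(int(length_um * NM_PER_UM / step)):
        d = _deviate(rng, d, 4.0)
        pts.append(pts[-1] + d * step)
    tube = tube_mesh(np.array(pts), np.full(len(pts), radius), resolution)
    return tube, _labels_for(tube, KIND_BRANCH, 0, 0)


def preset_scene(name: str, seed: int, resolution: int = 10, **param_overrides) -> MergeScene:
    """Named study conditions: 'single', 'merged-pair', 'orphan-axon'."""
    if name == "single":
        n = generate_neuron(MorphologyParams(neuron_id=0, **param_overrides), seed)
        return make_scene([n], resolution=resolution)
    if name == "merged-pair":
        a = generate_neuron(MorphologyParams(neuron_id=0, **param_overrides), seed)
        b = generate_neuron(MorphologyParams(neuron_id=1, **param_overrides), seed + 101)
        b = b.translate(np.array([120_000.0, 30_000.0, 0.0]))
        scene = make_scene([a, b], resolution=resolution)
        return weld_pair(scene, seed)
    if name == "orphan-axon":
        n = generate_neuron(MorphologyParams(neuron_id=0, **param_overrides), seed)
        scene = make_scene([n], resolution=resolution)
        return inject_merge_error(scene, "axon_on_dendrite", seed, resolution=resolution)
    raise ValueError(f"unknown preset {name!r}; choose single|merged-pair|orphan-axon")


def synapse_table(synapses: list[SynapseRecord]) -> pd.DataFrame:
    rows = []
    for s in synapses:
        rows.append({
            "synapse_id": s.syn_id, "pre_id": s.pre_id, "post_id": s.post_id,
            "x_nm": s.position[0], "y_nm": s.position[1], "z_nm": s.position[2],
            "size_voxels": s.size, "direction": s.direction or "",
            "branch_id": -1 if s.branch_id is None else s.branch_id,
            "compartment": s.compartment or "", "spine_part": s.spine_part,
            "valid": int(s.valid)})
    return pd.DataFrame(rows)


def write_scene(scene: MergeScene, outdir, binary_ply: bool = True) -> None:
    """Write mesh (OFF + PLY), ground-truth JSON sidecar, and synapse CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene.mesh.export(outdir / "scene.off")
    scene.mesh.export(outdir / "scene.ply", encoding="binary" if binary_ply else "ascii")
    truth = {
        "face_labels": scene.labels.to_json_dict(),
        "error_truth": [e.to_json_dict() for e in scene.error_truth],
        "neurons": [
            {"neuron_id": n.neuron_id, "cell_class": n.cell_class,
             "soma_center": n.soma_center.tolist(), "soma_radius": n.soma_radius,
             "total_skeletal_length_nm": n.total_skeletal_length()}
            for n in scene.components],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth))
    synapse_table(scene.synapses).to_csv(outdir / "synapses.csv", index=False)
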