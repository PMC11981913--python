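"""Spine detection, head/neck segmentation and synapse spine-part labels.

A spine is a connected patch of mesh faces protruding beyond
``shaft_factor`` x the local radius of its host branch.  Its "skeletal
length" is the radial height of the farthest face centroid above the shaft
surface.  Head/neck segmentation looks for a local minimum of the radial
width profile along the spine axis (the neck); heads are closed with a
triangle fan over the cut ring and measured with the divergence theorem.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .types import Branch, DecompGraph, Spine, SynapseRecord

DEFAULT_SHAFT_FACTOR = 1.4
DEFAULT_MIN_FACES = 20
DEFAULT_NECK_RATIO = 0.6
SPINE_LENGTH_FILTER_NM = 700.0


def _branch_samples(points: np.ndarray, widths: np.ndarray, spacing: float = 250.0):
    """Densely sampled (position, local width) along a branch polyline."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    out_p, out_w = [points[:1]], [widths[:1]]
    for i, L in enumerate(seg):
        k = max(1, int(np.ceil(L / spacing)))
        ts = np.linspace(0, 1, k + 1)[1:]
        out_p.append(points[i] * (1 - ts[:, None]) + points[i + 1] * ts[:, None])
        out_w.append(widths[i] * (1 - ts) + widths[i + 1] * ts)
    return np.concatenate(out_p), np.concatenate(out_w)


def detect_spines(mesh: trimesh.Trimesh, branch: Branch,
                  shaft_factor: float = DEFAULT_SHAFT_FACTOR,
                  min_faces: int = DEFAULT_MIN_FACES,
                  spine_id_start: int = 0) -> list[Spine]:
    """Detect spine submeshes on one branch.

    ``branch.face_ids`` select the branch's faces in ``mesh``; face ids in
    the returned spines refer to the full mesh.  An empty branch mesh is
    rejected.
    """
    fids = np.asarray(branch.face_ids, dtype=int)
    if len(fids) == 0:
        raise ValueError(f"branch {branch.branch_id} has no mesh faces")
    centroids = mesh.triangles_center[fids]
    spts, swid = _branch_samples(branch.points, branch.width_profile)
    kd = cKDTree(spts)
    dist, si = kd.query(centroids)
    local_w = swid[si]
    protruding = dist > shaft_factor * local_w / 2.0
    if not protruding.any():
        return []

    # connected components of protruding faces within this branch submesh
    in_branch = np.zeros(len(mesh.faces), dtype=bool)
    in_branch[fids] = True
    prot_global = np.zeros(len(mesh.faces), dtype=bool)
    prot_global[fids[protruding]] = True
    adj = mesh.face_adjacency
    keep = prot_global[adj[:, 0]] & prot_global[adj[:, 1]]
    pairs = adj[keep]
    n = len(mesh.faces)
    g = sparse.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, lab = connected_components(g + g.T, directed=False)
    prot_ids = fids[protruding]
    comps = [prot_ids[lab[prot_ids] == c] for c in np.unique(lab[prot_ids])]
    comps = _merge_aligned_components(mesh, comps, kd, spts)
    spines = []
    sid = spine_id_start
    for comp in comps:
        if len(comp) < min_faces:
            continue
        spine = _measure_spine(mesh, comp, branch, kd, spts, swid, sid)
        if spine is not None:
            spines.append(spine)
            sid += 1
    return spines


def _merge_aligned_components(mesh, comps, kd, spts,
                              contact_tol: float = 450.0,
                              max_angle_deg: float = 15.0):
    """Merge protruding patches that are one protrusion in two pieces.

    A spine head interpenetrating its neck (or a two-part mushroom) shows
    up as nearby patches whose outward rays from the shaft agree; distinct
    neighbouring spines sit at different azimuths and are left alone.
    """
    if len(comps) < 2:
        return comps
    info = []
    for comp in comps:
        cent = mesh.triangles_center[comp]
        mean = cent.mean(axis=0)
        _, si = kd.query(mean[None, :])
        base = spts[int(si[0])]
        ray = mean - base
        nr = np.linalg.norm(ray)
        info.append((mean, base, ray / nr if nr > 0 else np.zeros(3),
                     np.unique(mesh.faces[comp])))
    parent = list(range(len(comps)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def lateral_offset(a, b):
        # distance of b's centroid from a's outward axis
        rel = info[b][0] - info[a][1]
        along = np.dot(rel, info[a][2])
        return float(np.linalg.norm(rel - along * info[a][2]))

    cos_tol = np.cos(np.deg2rad(max_angle_deg))
    V = np.asarray(mesh.vertices)
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            if np.dot(info[i][2], info[j][2]) < cos_tol:
                continue
            # the patches must lie on one outward axis (head over neck),
            # not merely at similar azimuths
            if min(lateral_offset(i, j), lateral_offset(j, i)) > 350.0:
                continue
            vi, vj = V[info[i][3]], V[info[j][3]]
            kdj = cKDTree(vj)
            dmin = kdj.query(vi, k=1)[0].min()
            if dmin < contact_tol:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(len(comps)):
        groups.setdefault(find(i), []).append(i)
    return [np.concatenate([comps[i] for i in members])
            for members in groups.values()]


def _measure_spine(mesh, comp_faces, branch, kd, spts, swid, spine_id):
    centroids = mesh.triangles_center[comp_faces]
    dist, si = kd.query(centroids)
    far = int(np.argmax(dist - swid[si] / 2.0))
    height = float(dist[far] - swid[si[far]] / 2.0)
    if height <= 0:
        return None
    base_idx = int(np.bincount(si).argmax())
    base_point = spts[base_idx]
    # boundary ring: vertices shared with faces outside the component
    comp_set = np.zeros(len(mesh.faces), dtype=bool)
    comp_set[comp_faces] = True
    comp_verts = np.unique(mesh.faces[comp_faces])
    vert_in_comp_only = np.zeros(len(mesh.vertices), dtype=bool)
    vert_in_comp_only[comp_verts] = True
    outside_faces = mesh.faces[~comp_set]
    outside_verts = np.unique(outside_faces)
    ring_verts = np.intersect1d(comp_verts, outside_verts)
    if len(ring_verts):
        ring_centroid = mesh.vertices[ring_verts].mean(axis=0)
    else:
        ring_centroid = centroids[int(np.argmin(dist))]
    axis = centroids[far] - base_point
    nrm = np.linalg.norm(axis)
    axis = axis / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
    ext = centroids.max(axis=0) - centroids.min(axis=0)
    return Spine(spine_id=spine_id, branch_id=branch.branch_id,
                 face_ids=comp_faces, base_point=base_point,
                 skeletal_length=height, axis=axis, ring_centroid=ring_centroid,
                 bbox_extents=ext)


def filter_spines(spines: list[Spine],
                  min_skeletal_length: float = SPINE_LENGTH_FILTER_NM) -> list[Spine]:
    """Keep spines strictly longer than the threshold; order preserved."""
    return [s for s in spines if s.skeletal_length > min_skeletal_length]


def segment_head_neck(mesh: trimesh.Trimesh, spine: Spine,
                      neck_ratio: float = DEFAULT_NECK_RATIO,
                      n_bins: int = 14) -> Spine:
    """Split a spine into head and neck when a neck minimum exists.

    The radial width profile is computed along the spine axis; a local
    minimum below ``neck_ratio`` x the maximum distal width marks the neck.
    With no such minimum the whole spine is head ("no neck" outcome).
    """
    centroids = mesh.triangles_center[spine.face_ids]
    rel = centroids - spine.ring_centroid
    t = rel @ spine.axis
    radial = np.linalg.norm(rel - t[:, None] * spine.axis, axis=1)
    t0, t1 = float(t.min()), float(t.max())
    if t1 - t0 < 1e-6 or len(t) < 8:
        spine.head_face_ids = spine.face_ids.copy()
        spine.neck_face_ids = None
        spine.head_volume = _closed_patch_volume(mesh, spine.face_ids, spine.ring_centroid)
        return spine
    edges = np.linspace(t0, t1, n_bins + 1)
    which = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    prof = np.full(n_bins, np.nan)
    for i in range(n_bins):
        sel = which == i
        if sel.any():
            prof[i] = np.percentile(radial[sel], 80)
    valid = ~np.isnan(prof)
    idxs = np.flatnonzero(valid)
    # neck = last profile bin that is still thin relative to the maximal
    # width distal to it; monotone (stubby) profiles never qualify
    best_cut = None
    for j_pos in range(len(idxs) - 1, 0, -1):
        i = idxs[j_pos]
        distal = prof[idxs[j_pos + 1:]]
        if len(distal) and prof[i] < neck_ratio * np.nanmax(distal):
            best_cut = i
            break
    if best_cut is None:
        spine.head_face_ids = spine.face_ids.copy()
        spine.neck_face_ids = None
        spine.head_volume = _closed_patch_volume(mesh, spine.face_ids, spine.ring_centroid)
        return spine
    t_cut = edges[best_cut + 1]
    head = spine.face_ids[t > t_cut]
    neck = spine.face_ids[t <= t_cut]
    spine.head_face_ids = head
    spine.neck_face_ids = neck
    cut_point = spine.ring_centroid + spine.axis * t_cut
    spine.head_volume = _closed_patch_volume(mesh, head, cut_point)
    spine.neck_length = float(t_cut - t0)
    neck_radial = radial[t <= t_cut]
    spine.neck_width = float(2 * np.median(neck_radial)) if len(neck_radial) else 0.0
    return spine


def _closed_patch_volume(mesh: trimesh.Trimesh, face_ids: np.ndarray,
                         ref_point: np.ndarray) -> float:
    """|volume| of an open patch closed by a fan to ``ref_point``.

    Divergence-theorem sum of signed tetrahedra (patch triangle, ref);
    exact for patches whose boundary ring is star-shaped around the ref.
    """
    if len(face_ids) == 0:
        return 0.0
    tri = mesh.triangles[face_ids] - ref_point
    vol = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    return float(abs(vol))


def label_synapse_spine_part(synapses: list[SynapseRecord], spines: list[Spine],
                             mesh: trimesh.Trimesh) -> None:
    """Propagate head/neck/shaft to synapses in place (soma labels kept)."""
    if not synapses:
        return
    part_of_face = {}
    for sp in spines:
        head = sp.head_face_ids if sp.head_face_ids is not None else sp.face_ids
        for f in head:
            part_of_face[int(f)] = "head"
        if sp.neck_face_ids is not None:
            for f in sp.neck_face_ids:
                part_of_face[int(f)] = "neck"
    kd = cKDTree(mesh.triangles_center)
    pos = np.array([s.position for s in synapses])
    _, fi = kd.query(pos)
    for s, f in zip(synapses, fi):
        if s.spine_part == "soma" or s.compartment == "soma":
            continue
        s.spine_part = part_of_face.get(int(f), "shaft")


def detect_spines_graph(mesh: trimesh.Trimesh, graph: DecompGraph,
                        shaft_factor: float = DEFAULT_SHAFT_FACTOR,
                        min_faces: int = DEFAULT_MIN_FACES,
                        segment_heads: bool = True,
                        include_axon: bool = False) -> list[Spine]:
    """Run spine detection over every dendritic branch of a decomposition.

    Results are attached to the graph (``graph.spines`` and per-branch
    ``spine_ids``) and synapse spine parts are refreshed.
    """
    spines: list[Spine] = []
    for bid in graph.branch_ids:
        b = graph.branches[bid]
        if b.is_soma_node or len(b.face_ids) == 0 or b.skeletal_length <= 0:
            continue
        if not include_axon and b.compartment in ("axon", "AIS"):
            continue
        found = detect_spines(mesh, b, shaft_factor=shaft_factor,
                              min_faces=min_faces, spine_id_start=len(spines))
        if segment_heads:
            found = [segment_head_neck(mesh, s) for s in found]
        b.spine_ids = [s.spine_id for s in found]
        spines.extend(found)
    graph.spines = {s.spine_id: s for s in spines}
    label_synapse_spine_part(list(graph.synapses.values()), spines, mesh)
    return spines


def spine_table(spines: list[Spine], synapses: list[SynapseRecord] | None = None,
                mesh: trimesh.Trimesh | None = None) -> pd.DataFrame:
    """Tabular export of spine morphometrics (one row per spine)."""
    head_syn_count = {}
    head_syn_max = {}
    if synapses and mesh is not None:
        kd = cKDTree(mesh.triangles_center)
        face_spine = {}
        for sp in spines:
            head = sp.head_face_ids if sp.head_face_ids is not None else sp.face_ids
            for f in head:
                face_spine[int(f)] = sp.spine_id
        for s in synapses:
            if s.spine_part not in ("head",):
                continue
            _, f = kd.query(s.position)
            sid = face_spine.get(int(f))
            if sid is not None:
                head_syn_count[sid] = head_syn_count.get(sid, 0) + 1
                head_syn_max[sid] = max(head_syn_max.get(sid, 0.0), s.size)
    rows = []
    for sp in spines:
        rows.append({
            "spine_id": sp.spine_id, "branch_id": sp.branch_id,
            "base_x_nm": sp.base_point[0], "base_y_nm": sp.base_point[1],
            "base_z_nm": sp.base_point[2],
            "skeletal_length_nm": sp.skeletal_length,
            "head_volume_nm3": sp.head_volume,
            "neck_length_nm": sp.neck_length,
            "neck_width_nm": sp.neck_width,
            "has_neck": int(sp.has_neck),
            "n_faces": len(sp.face_ids),
            "n_head_synapses": head_syn_count.get(sp.spine_id, 0),
            "max_head_synapse_size": head_syn_max.get(sp.spine_id, 0.0),
        })
    return pd.DataFrame(rows)
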