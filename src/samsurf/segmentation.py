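"""Organ segmentation on the mesh: curvature-basin attractors plus merge rules.

Every vertex hill-climbs the conditioned curvature field to its basin
attractor (a vertex with no strictly higher neighbour); each attractor's
basin is one domain.  Oversegmentation is then reduced by five merge
rules — depth (eliminate shallow basins), engulfing (domains swallowed
by another), disconnection from the inflorescence, centre distance, and
centre angle at the apex (the latter two fold emerging sepals into their
flower).  The inflorescence domain is the one hit by a vertical ray from
the tissue centre of mass, falling back to the domain with most
neighbours.

All tie-breaks go to the lowest vertex/label index so results are
bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curvature import CurvatureField
from .mesh import SurfaceMesh


@dataclass
class MergeParams:
    """Thresholds for the five merge rules."""

    depth_threshold: float = 0.01  # μm⁻¹
    engulf_fraction: float = 1.0  # 1.0 disables (strict >); a flower fully inside the meristem is legitimate
    disconnect_fraction: float = 0.05
    distance_threshold: float = 10.0  # μm
    angle_threshold: float = 20.0  # degrees

    def __post_init__(self) -> None:
        if not 0 <= self.engulf_fraction <= 1:
            raise ValueError("engulf_fraction must be in [0, 1]")
        if not 0 <= self.disconnect_fraction <= 1:
            raise ValueError("disconnect_fraction must be in [0, 1]")
        if min(self.depth_threshold, self.distance_threshold, self.angle_threshold) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class Segmentation:
    """Per-vertex integer organ labels with attractor bookkeeping."""

    labels: np.ndarray
    attractors: dict = field(default_factory=dict)  # label -> attractor vertex
    inflorescence_label: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()

    def label_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_domains(self) -> int:
        return len(np.unique(self.labels))


def attractor_segmentation(mesh: SurfaceMesh, field: CurvatureField) -> Segmentation:
    """Label every vertex by the curvature attractor its greedy ascent reaches.

    From each vertex, step to the neighbour with the strictly greatest
    field value (ties to the lowest vertex index); a vertex with no
    strictly greater neighbour is an attractor.  Labels are consecutive
    integers from 0 in order of attractor vertex index.
    """
    n = mesh.n_vertices
    if n == 0:
        raise ValueError("empty mesh")
    vals = np.asarray(field.values, dtype=np.float64)
    if len(vals) != n:
        raise ValueError("field length != vertex count")
    adj = mesh.adjacency()
    indptr, indices = adj.indptr, adj.indices

    nxt = np.arange(n, dtype=np.int64)
    for i in range(n):
        nb = indices[indptr[i] : indptr[i + 1]]
        if len(nb) == 0:
            continue
        nv = vals[nb]
        mx = nv.max()
        if mx > vals[i]:
            nxt[i] = nb[np.argmax(nv)]  # CSR indices ascending → lowest index wins

    # pointer-jump to the fixed point
    root = nxt.copy()
    while True:
        nxt2 = root[root]
        if np.array_equal(nxt2, root):
            break
        root = nxt2

    attractor_vertices = np.unique(root)
    label_of_attr = {int(a): lbl for lbl, a in enumerate(attractor_vertices)}
    labels = np.searchsorted(attractor_vertices, root)
    attractors = {lbl: int(a) for a, lbl in label_of_attr.items()}
    return Segmentation(labels, attractors)


# ---------------------------------------------------------------------------
# adjacency helpers


def _label_edges(seg: Segmentation, mesh: SurfaceMesh) -> np.ndarray:
    """Mesh edges whose endpoints carry different labels."""
    e = mesh.edges()
    la, lb = seg.labels[e[:, 0]], seg.labels[e[:, 1]]
    return e[la != lb]


def _border_vertex_map(seg: Segmentation, mesh: SurfaceMesh):
    """For each domain A: {neighbour label B -> set of A's boundary vertices adjacent to B}."""
    cross = _label_edges(seg, mesh)
    out: dict[int, dict[int, set]] = {}
    lab = seg.labels
    for u, v in cross:
        a, b = int(lab[u]), int(lab[v])
        out.setdefault(a, {}).setdefault(b, set()).add(int(u))
        out.setdefault(b, {}).setdefault(a, set()).add(int(v))
    return out


def _boundary_denominators(seg: Segmentation, mesh: SurfaceMesh, border):
    """Total boundary-vertex count per domain.

    A domain's boundary comprises its vertices adjacent to another
    domain plus its vertices on the open mesh rim — a primordium whose
    only labelled neighbour is the meristem is still mostly rim-bounded,
    not engulfed.
    """
    rim_mask = np.zeros(len(seg.labels), dtype=bool)
    rim_mask[mesh.boundary_vertices()] = True
    out = {}
    for a in (int(l) for l in seg.label_ids()):
        verts = set(map(int, np.flatnonzero((seg.labels == a) & rim_mask)))
        for s in border.get(a, {}).values():
            verts |= s
        out[a] = len(verts)
    return out


def _apply_merge(seg: Segmentation, src: int, dst: int) -> Segmentation:
    labels = seg.labels.copy()
    labels[labels == src] = dst
    attractors = {l: v for l, v in seg.attractors.items() if l != src}
    inflo = seg.inflorescence_label
    if inflo == src:
        inflo = dst
    return Segmentation(labels, attractors, inflo)


def domain_centres(seg: Segmentation, mesh: SurfaceMesh) -> dict[int, np.ndarray]:
    """Unweighted vertex centre of mass per domain."""
    return {
        int(l): mesh.vertices[seg.labels == l].mean(axis=0) for l in seg.label_ids()
    }


# ---------------------------------------------------------------------------
# merge rules (each iterated to a fixpoint, one deterministic merge at a time)


def merge_by_depth(
    seg: Segmentation, field: CurvatureField, mesh: SurfaceMesh, params: MergeParams
) -> Segmentation:
    """Merge basins shallower than ``depth_threshold``.

    For an adjacent pair, the candidate A is the domain with the smaller
    field maximum; its depth toward B is max(field over A) − max(field
    over A's vertices bordering B).  Pairs with depth below threshold are
    merged (A absorbed into B), smallest depth first.  An identified
    inflorescence domain is never absorbed (neighbours judged shallow
    merge into it instead).
    """
    vals = field.values
    inflo = seg.inflorescence_label
    while True:
        border = _border_vertex_map(seg, mesh)
        dom_max = {int(l): vals[seg.labels == l].max() for l in seg.label_ids()}
        best = None  # (depth, src, dst)
        for a, nbrs in border.items():
            for b, verts in nbrs.items():
                if a == inflo:
                    continue  # the inflorescence is never absorbed
                if b != inflo and (
                    dom_max[a] > dom_max[b] or (dom_max[a] == dom_max[b] and a < b)
                ):
                    continue  # absorb the smaller-max domain into the larger-max
                depth = dom_max[a] - vals[list(verts)].max()
                if depth < params.depth_threshold:
                    cand = (depth, a, b)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            return seg
        _, src, dst = best
        seg = _apply_merge(seg, src, dst)


def merge_engulfed(
    seg: Segmentation, mesh: SurfaceMesh, params: MergeParams
) -> Segmentation:
    """Merge a domain into a neighbour owning > ``engulf_fraction`` of its boundary.

    The boundary denominator counts both inter-domain border vertices
    and the domain's vertices on the open mesh rim, so only genuinely
    surrounded domains reach high fractions.  The inflorescence is never
    absorbed.
    """
    while True:
        border = _border_vertex_map(seg, mesh)
        denom = _boundary_denominators(seg, mesh, border)
        best = None  # (-fraction, src, dst)
        for a in sorted(border):
            if a == seg.inflorescence_label or denom.get(a, 0) == 0:
                continue
            for b in sorted(border[a]):
                frac = len(border[a][b]) / denom[a]
                if frac > params.engulf_fraction:
                    cand = (-frac, a, b)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            return seg
        _, src, dst = best
        seg = _apply_merge(seg, src, dst)


def merge_disconnected(
    seg: Segmentation, mesh: SurfaceMesh, params: MergeParams
) -> Segmentation:
    """Fold domains barely touching the inflorescence into their biggest neighbour.

    A non-inflorescence domain whose inter-domain border fraction
    adjacent to the inflorescence is below ``disconnect_fraction``
    merges into the neighbour sharing its largest border.  The fraction
    is taken over the domain's border with other domains only — mesh-rim
    vertices say nothing about connectivity to the inflorescence.
    """
    if seg.inflorescence_label is None:
        raise ValueError("inflorescence_label must be set before merge_disconnected")
    while True:
        inflo = seg.inflorescence_label
        border = _border_vertex_map(seg, mesh)
        merged = False
        for a in sorted(border):
            if a == inflo or not border[a]:
                continue
            denom = len(set().union(*border[a].values()))
            frac_inflo = len(border[a].get(inflo, ())) / denom
            if frac_inflo < params.disconnect_fraction:
                dst = min(
                    sorted(border[a]),
                    key=lambda b: (-len(border[a][b]), b),
                )
                seg = _apply_merge(seg, a, dst)
                merged = True
                break
        if not merged:
            return seg


def merge_by_distance(
    seg: Segmentation, mesh: SurfaceMesh, params: MergeParams
) -> Segmentation:
    """Merge non-inflorescence domain pairs with centre distance below threshold."""
    while True:
        centres = domain_centres(seg, mesh)
        labels = [l for l in sorted(centres) if l != seg.inflorescence_label]
        best = None  # (dist, src_hi, dst_lo)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                d = float(np.linalg.norm(centres[a] - centres[b]))
                if d < params.distance_threshold:
                    cand = (d, b, a)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            return seg
        _, src, dst = best
        seg = _apply_merge(seg, src, dst)


def merge_by_angle(
    seg: Segmentation, mesh: SurfaceMesh, apex: np.ndarray, params: MergeParams
) -> Segmentation:
    """Merge non-inflorescence pairs subtending < ``angle_threshold`` at the apex (full 3D angle)."""
    apex = np.asarray(apex, dtype=float)
    while True:
        centres = domain_centres(seg, mesh)
        labels = [l for l in sorted(centres) if l != seg.inflorescence_label]
        vecs = {}
        for l in labels:
            v = centres[l] - apex
            nv = np.linalg.norm(v)
            if nv == 0:
                raise ValueError(f"domain {l} centre coincides with apex")
            vecs[l] = v / nv
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                cosang = float(np.clip(np.dot(vecs[a], vecs[b]), -1.0, 1.0))
                ang = np.degrees(np.arccos(cosang))
                if ang < params.angle_threshold:
                    cand = (ang, b, a)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            return seg
        _, src, dst = best
        seg = _apply_merge(seg, src, dst)


# ---------------------------------------------------------------------------


def identify_inflorescence(seg: Segmentation, mesh: SurfaceMesh) -> int:
    """Label of the domain pierced by a vertical ray from the tissue centre of mass.

    The ray is cast along +z from the unweighted vertex centre of mass,
    then along −z; the first intersected face's majority vertex label is
    returned.  If both rays miss, the domain with the most distinct
    neighbouring domains wins (ties to the lowest label).  Sets and
    returns ``inflorescence_label``.
    """
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    com = mesh.vertices.mean(axis=0)
    zs, faces_hit = mesh.vertical_ray_hits(com[:2])
    face_idx = None
    if len(faces_hit):
        above = zs >= com[2]
        # +z first, then -z; nearest hit along the chosen direction
        if above.any():
            sel = np.flatnonzero(above)
            face_idx = int(faces_hit[sel[np.argmin(zs[sel] - com[2])]])
        else:
            face_idx = int(faces_hit[np.argmin(com[2] - zs)])
    if face_idx is not None:
        face_labels = seg.labels[mesh.faces[face_idx]]
        vals, counts = np.unique(face_labels, return_counts=True)
        label = int(vals[np.argmax(counts)])  # unique() ascending → lowest wins ties
    else:
        border = _border_vertex_map(seg, mesh)
        ids = sorted(int(l) for l in seg.label_ids())
        label = min(ids, key=lambda l: (-len(border.get(l, {})), l))
    seg.inflorescence_label = label
    return label


def segment_mesh(
    mesh: SurfaceMesh,
    field: CurvatureField,
    params: MergeParams | None = None,
    apex: np.ndarray | None = None,
) -> Segmentation:
    """Full segmentation pipeline with the default merge order.

    attractors → identify inflorescence → depth → engulfed →
    disconnected → distance → angle.  The inflorescence is identified
    first so the depth/engulf rules can grow it without ever absorbing
    it into a flower domain.  ``apex`` defaults to the inflorescence
    domain's vertex centre of mass for the angle rule.
    """
    params = params or MergeParams()
    seg = attractor_segmentation(mesh, field)
    identify_inflorescence(seg, mesh)
    seg = merge_by_depth(seg, field, mesh, params)
    seg = merge_engulfed(seg, mesh, params)
    seg = merge_disconnected(seg, mesh, params)
    seg = merge_by_distance(seg, mesh, params)
    if apex is None:
        apex = mesh.vertices[seg.labels == seg.inflorescence_label].mean(axis=0)
    seg = merge_by_angle(seg, mesh, apex, params)
    return seg
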