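"""Triangulated 2.5D surface meshes: extraction, simplification, cleanup, IO.

The tissue surface is extracted from the binary mask with Lewiner
marching cubes (on a lightly smoothed mask so the isosurface is not
terraced at voxel steps), simplified to roughly uniform vertex density
with a centroidal-Voronoi clustering scheme (the ACVD idea: cluster the
dense mesh into k near-equal surface regions, one output vertex per
region), cleaned of degeneracies, and finally opened at the bottom by
clipping the artificial base that the column-fill step created — what
remains is the 2.5D epidermal top surface.

Vertices are stored in (x, y, z) micrometre coordinates, apex up, so the
downstream paraboloid z = f(x, y) is axis-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse import csgraph
from skimage import measure

from .contour import BinaryContour


@dataclass
class SurfaceMesh:
    """Triangle mesh in physical micrometre coordinates with named per-vertex scalars."""

    vertices: np.ndarray  # (n, 3) float, columns (x, y, z)
    faces: np.ndarray  # (m, 3) int
    scalars: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of vertex range")
        for name, arr in self.scalars.items():
            arr = np.asarray(arr)
            if len(arr) != len(self.vertices):
                raise ValueError(f"scalar {name!r} length != vertex count")
            self.scalars[name] = arr
        self._adj = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # -- connectivity ------------------------------------------------------
    def edges(self, unique: bool = True) -> np.ndarray:
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        if unique:
            e = np.unique(np.sort(e, axis=1), axis=0)
        return e

    def adjacency(self) -> csr_matrix:
        """Symmetric vertex adjacency (boolean CSR), cached."""
        if self._adj is None:
            e = self.edges()
            n = self.n_vertices
            data = np.ones(2 * len(e), dtype=bool)
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            self._adj = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
        return self._adj

    def vertex_neighbors(self, i: int) -> np.ndarray:
        a = self.adjacency()
        return a.indices[a.indptr[i] : a.indptr[i + 1]]

    # -- geometry ----------------------------------------------------------
    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        c = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(c, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        c = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        n = np.linalg.norm(c, axis=1)
        n[n == 0] = 1.0
        return c / n[:, None]

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        v = self.vertices
        f = self.faces
        c = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2A * n
        out = np.zeros_like(v)
        for k in range(3):
            np.add.at(out, f[:, k], c)
        n = np.linalg.norm(out, axis=1)
        n[n == 0] = 1.0
        return out / n[:, None]

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (1/3 of incident face area)."""
        fa = self.face_areas() / 3.0
        out = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(out, self.faces[:, k], fa)
        return out

    def boundary_vertices(self) -> np.ndarray:
        """Indices of vertices on boundary edges (edges with one incident face)."""
        e = np.sort(
            np.vstack(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return np.unique(uniq[counts == 1])

    def vertical_ray_hits(self, xy) -> tuple[np.ndarray, np.ndarray]:
        """Intersections of the vertical line through (x, y) with the mesh.

        Returns ``(z_values, face_indices)`` of every face whose XY
        projection contains the point (degenerate-projection faces
        excluded), with z interpolated barycentrically.
        """
        px, py = float(xy[0]), float(xy[1])
        tri = self.vertices[self.faces]  # (m, 3, 3)
        ax, ay = tri[:, 0, 0], tri[:, 0, 1]
        bx, by = tri[:, 1, 0], tri[:, 1, 1]
        cx, cy = tri[:, 2, 0], tri[:, 2, 1]
        den = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
        ok = np.abs(den) > 1e-15
        den = np.where(ok, den, 1.0)
        w1 = ((by - cy) * (px - cx) + (cx - bx) * (py - cy)) / den
        w2 = ((cy - ay) * (px - cx) + (ax - cx) * (py - cy)) / den
        w3 = 1.0 - w1 - w2
        eps = -1e-12
        inside = ok & (w1 >= eps) & (w2 >= eps) & (w3 >= eps)
        idx = np.flatnonzero(inside)
        z = (
            w1[idx] * tri[idx, 0, 2]
            + w2[idx] * tri[idx, 1, 2]
            + w3[idx] * tri[idx, 2, 2]
        )
        return z, idx

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: v.copy() for k, v in self.scalars.items()},
        )


# ---------------------------------------------------------------------------
# extraction


def extract_mesh(
    contour: BinaryContour, smooth_sigma_vox: float = 1.0
) -> SurfaceMesh:
    """Lewiner marching-cubes isosurface of the binary mask at level 0.5.

    The mask is pre-smoothed with a small Gaussian (default 1 voxel) so the
    0.5-isosurface interpolates sub-voxel positions rather than voxel
    terraces.  Output vertices are physical (x, y, z) micrometres; face
    winding gives outward normals.
    """
    mask = contour.mask
    if not mask.any():
        raise ValueError("empty mask has no isosurface")
    if mask.all():
        raise ValueError("full mask has no isosurface")
    field3 = mask.astype(np.float64)
    if smooth_sigma_vox > 0:
        field3 = ndimage.gaussian_filter(field3, smooth_sigma_vox, mode="nearest")
        # smoothing must not destroy the two phases
        if field3.max() <= 0.5 or field3.min() >= 0.5:
            field3 = mask.astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(
        field3, level=0.5, spacing=contour.spacing, method="lewiner",
        gradient_direction="descent",
    )
    # (z, y, x) -> (x, y, z).  The axis swap mirrors the space (winding
    # inverts once); skimage's descent-direction winding then lands
    # outward without a further flip.
    verts = verts[:, ::-1] + np.asarray(contour.origin)[::-1]
    return SurfaceMesh(verts, faces)


# ---------------------------------------------------------------------------
# ACVD-style simplification


def simplify_mesh(
    mesh: SurfaceMesh, fraction: float = 0.1, n_lloyd: int = 8, seed: int = 0
) -> SurfaceMesh:
    """Uniform-density simplification by centroidal Voronoi clustering.

    Vertices are grouped into ``k = round(fraction * n)`` connected
    surface clusters (geodesic Voronoi regions of k seed vertices,
    relaxed by Lloyd iterations toward centroidal regions); each cluster
    becomes one output vertex at its area-weighted centroid, and every
    input face spanning three clusters becomes an output triangle.  The
    result has near-uniform vertex spacing, the ACVD property.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = mesh.n_vertices
    k = max(4, int(round(fraction * n)))
    if k >= n:
        return mesh.copy()

    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    w = np.maximum(w, 1e-12)
    graph = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                  np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    ).tocsr()

    rng = np.random.default_rng(seed)
    seeds = _spread_seeds(mesh.vertices, k, rng)
    varea = mesh.vertex_areas()

    assign = None
    for _ in range(max(1, n_lloyd)):
        _, _, sources = csgraph.dijkstra(
            graph, indices=seeds, min_only=True, return_predecessors=True
        )
        new_assign = np.searchsorted(seeds, sources)
        # unreachable vertices (disconnected fragments): nearest seed in space
        bad = (sources < 0) | (sources >= n)
        if bad.any():
            from scipy.spatial import cKDTree

            _, nn = cKDTree(mesh.vertices[seeds]).query(mesh.vertices[bad])
            new_assign[bad] = nn
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        # move each seed to the member vertex nearest the cluster centroid
        new_seeds = np.empty(k, dtype=np.int64)
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if len(members) == 0:
                new_seeds[c] = seeds[c]
                continue
            wts = varea[members]
            tot = wts.sum()
            centroid = (
                (mesh.vertices[members] * wts[:, None]).sum(0) / tot
                if tot > 0
                else mesh.vertices[members].mean(0)
            )
            d = np.linalg.norm(mesh.vertices[members] - centroid, axis=1)
            new_seeds[c] = members[np.argmin(d)]
        seeds = np.unique(new_seeds)
        if len(seeds) < k:
            k = len(seeds)

    # output vertices: area-weighted cluster centroids
    sums = np.zeros((k, 3))
    wsum = np.zeros(k)
    np.add.at(sums, assign, mesh.vertices * varea[:, None])
    np.add.at(wsum, assign, varea)
    counts = np.bincount(assign, minlength=k)
    wsum[wsum == 0] = 1.0
    new_verts = sums / wsum[:, None]
    # fall back to plain mean for zero-area clusters
    zero = np.flatnonzero((counts > 0) & (np.bincount(assign, weights=varea, minlength=k) == 0))
    for c in zero:
        new_verts[c] = mesh.vertices[assign == c].mean(0)

    fa = assign[mesh.faces]
    spanning = (fa[:, 0] != fa[:, 1]) & (fa[:, 1] != fa[:, 2]) & (fa[:, 0] != fa[:, 2])
    new_faces = fa[spanning]
    # dedupe faces irrespective of rotation, keep first orientation seen
    key = np.sort(new_faces, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    new_faces = new_faces[np.sort(first)]

    out = SurfaceMesh(new_verts, new_faces)
    return _drop_unreferenced(out)


def _spread_seeds(verts: np.ndarray, k: int, rng) -> np.ndarray:
    """k well-spread distinct vertex indices (grid-hash stratified sample)."""
    n = len(verts)
    # sort vertices along a coarse space-filling order, take every n/k-th
    lo = verts.min(0)
    span = np.maximum(verts.max(0) - lo, 1e-9)
    g = np.floor((verts - lo) / span * 63).astype(np.int64)
    order = np.argsort(_interleave_bits(g), kind="stable")
    idx = np.linspace(0, n - 1, k).astype(np.int64)
    return np.unique(order[idx])


def _interleave_bits(g: np.ndarray) -> np.ndarray:
    """Morton code of 6-bit (x, y, z) cells."""
    out = np.zeros(len(g), dtype=np.int64)
    for b in range(6):
        for ax in range(3):
            out |= ((g[:, ax] >> b) & 1) << (3 * b + ax)
    return out


# ---------------------------------------------------------------------------
# cleanup


def clean_mesh(
    mesh: SurfaceMesh, min_component_fraction: float = 0.05, area_tol: float = 1e-12
):
    """Merge duplicate vertices, drop degenerate faces and small components.

    Returns ``(mesh, report)`` where report counts removed entities.
    Raises if cleaning would remove everything.
    """
    report = {"duplicate_vertices": 0, "degenerate_faces": 0,
              "removed_components": 0, "removed_component_faces": 0}
    v, f = mesh.vertices, mesh.faces
    scal = {k: np.asarray(a) for k, a in mesh.scalars.items()}

    uniq, inverse = np.unique(v, axis=0, return_inverse=True)
    if len(uniq) < len(v):
        report["duplicate_vertices"] = len(v) - len(uniq)
        # keep the first occurrence's scalars
        first = np.full(len(uniq), -1, dtype=np.int64)
        seen = np.zeros(len(uniq), dtype=bool)
        order = np.arange(len(v))
        for i in order:
            j = inverse[i]
            if not seen[j]:
                first[j] = i
                seen[j] = True
        v = uniq
        scal = {k: a[first] for k, a in scal.items()}
        f = inverse[f]

    # degenerate: repeated indices or (near) zero area
    repeated = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    zero_area = 0.5 * np.linalg.norm(cross, axis=1) <= area_tol
    bad = repeated | zero_area
    report["degenerate_faces"] = int(bad.sum())
    f = f[~bad]
    # drop exact duplicate faces
    key = np.sort(f, axis=1)
    _, first_f = np.unique(key, axis=0, return_index=True)
    f = f[np.sort(first_f)]

    if len(f) == 0:
        raise ValueError("cleaning removed all faces")

    # connected components by shared vertices; measure size in faces
    tmp = SurfaceMesh(v, f)
    n_comp, vlabel = csgraph.connected_components(tmp.adjacency(), directed=False)
    if n_comp > 1:
        fcomp = vlabel[f[:, 0]]
        sizes = np.bincount(fcomp, minlength=n_comp)
        keep_comp = sizes >= min_component_fraction * len(f)
        if not keep_comp.any():
            keep_comp = sizes == sizes.max()
        report["removed_components"] = int((~keep_comp[: n_comp]).sum())
        keep_f = keep_comp[fcomp]
        report["removed_component_faces"] = int((~keep_f).sum())
        f = f[keep_f]

    out = SurfaceMesh(v, f, scal)
    return _drop_unreferenced(out), report


def clip_base(mesh: SurfaceMesh, z_margin: float) -> SurfaceMesh:
    """Remove faces lying entirely within ``z_margin`` of the minimum z.

    Opens the closed marching-cubes surface at the artificial bottom,
    leaving the 2.5D top surface.
    """
    if z_margin < 0:
        raise ValueError("z_margin must be >= 0")
    if z_margin == 0 or mesh.n_faces == 0:
        return mesh.copy()
    z = mesh.vertices[:, 2]
    zmin = z.min()
    low = z <= zmin + z_margin
    drop = low[mesh.faces].all(axis=1)
    if drop.all():
        raise ValueError("clip_base would remove every face")
    out = SurfaceMesh(mesh.vertices, mesh.faces[~drop], dict(mesh.scalars))
    return _drop_unreferenced(out)


def erode_boundary(mesh: SurfaceMesh, rings: int) -> SurfaceMesh:
    """Remove ``rings`` topological rings of vertices around every open boundary.

    Marching cubes and morphological contouring are unreliable where the
    tissue is cut by the image border (the surface droops over the cut);
    eroding a few rings discards exactly that rim.  Faces touching a
    removed vertex are dropped.
    """
    if rings < 0:
        raise ValueError("rings must be >= 0")
    if rings == 0 or mesh.n_faces == 0:
        return mesh.copy()
    bd = mesh.boundary_vertices()
    if len(bd) == 0:
        return mesh.copy()
    adj = mesh.adjacency()
    remove = np.zeros(mesh.n_vertices, dtype=bool)
    frontier = np.zeros(mesh.n_vertices, dtype=bool)
    frontier[bd] = True
    for _ in range(rings):
        remove |= frontier
        frontier = (adj @ frontier) & ~remove
    keep_face = ~remove[mesh.faces].any(axis=1)
    if not keep_face.any():
        raise ValueError("erode_boundary would remove every face")
    out = SurfaceMesh(mesh.vertices, mesh.faces[keep_face], dict(mesh.scalars))
    return _drop_unreferenced(out)


def _drop_unreferenced(mesh: SurfaceMesh) -> SurfaceMesh:
    used = np.unique(mesh.faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(
        mesh.vertices[used],
        remap[mesh.faces],
        {k: a[used] for k, a in mesh.scalars.items()},
    )


# ---------------------------------------------------------------------------
# IO: ASCII PLY (with scalars), ASCII VTP (with scalars), OBJ (geometry only)


def write_ply(mesh: SurfaceMesh, path) -> None:
    names = list(mesh.scalars)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment samsurf surface mesh\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        for name in names:
            fh.write(f"property double {name}\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        cols = [mesh.vertices] + [
            np.asarray(mesh.scalars[n], dtype=float).reshape(-1, 1) for n in names
        ]
        block = np.hstack(cols)
        for row in block:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_ply(path) -> SurfaceMesh:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vert = n_face = 0
        props: list[str] = []
        element = None
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unexpected EOF in PLY header")
            tok = line.split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "format" and tok[1] != "ascii":
                raise ValueError("only ASCII PLY supported")
            if tok[0] == "element":
                element = tok[1]
                if element == "vertex":
                    n_vert = int(tok[2])
                elif element == "face":
                    n_face = int(tok[2])
            elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
                props.append(tok[2])
            elif tok[0] == "end_header":
                break
        rows = np.array(
            [fh.readline().split() for _ in range(n_vert)], dtype=np.float64
        )
        faces = np.array(
            [fh.readline().split()[1:4] for _ in range(n_face)], dtype=np.int64
        ) if n_face else np.zeros((0, 3), dtype=np.int64)
    idx = {p: i for i, p in enumerate(props)}
    verts = rows[:, [idx["x"], idx["y"], idx["z"]]]
    scalars = {
        p: rows[:, i] for p, i in idx.items() if p not in ("x", "y", "z")
    }
    return SurfaceMesh(verts, faces, scalars)


def write_vtp(mesh: SurfaceMesh, path) -> None:
    """Minimal ASCII XML VTK PolyData writer with per-vertex scalars."""
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n')
        fh.write("<PolyData>\n")
        fh.write(
            f'<Piece NumberOfPoints="{mesh.n_vertices}" NumberOfPolys="{mesh.n_faces}">\n'
        )
        fh.write("<Points>\n")
        fh.write('<DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        np.savetxt(fh, mesh.vertices, fmt="%.10g")
        fh.write("</DataArray>\n</Points>\n")
        if mesh.scalars:
            fh.write("<PointData>\n")
            for name, arr in mesh.scalars.items():
                fh.write(f'<DataArray type="Float64" Name="{name}" format="ascii">\n')
                np.savetxt(fh, np.asarray(arr, dtype=float), fmt="%.10g")
                fh.write("</DataArray>\n")
            fh.write("</PointData>\n")
        fh.write("<Polys>\n")
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        np.savetxt(fh, mesh.faces, fmt="%d")
        fh.write("</DataArray>\n")
        fh.write('<DataArray type="Int64" Name="offsets" format="ascii">\n')
        np.savetxt(fh, 3 * np.arange(1, mesh.n_faces + 1), fmt="%d")
        fh.write("</DataArray>\n</Polys>\n</Piece>\n</PolyData>\n</VTKFile>\n")


def write_obj(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
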