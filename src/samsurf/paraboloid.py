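"""Axis-aligned paraboloid parameterisation of the inflorescence dome.

The dome is summarised by the five-parameter quadric

    z = p1·x² + p2·y² + p3·x + p4·y + p5

fitted to the inflorescence-domain vertices.  The model is linear in the
parameters, so the least-squares optimum is computed in closed form.
Derived quantities: the apex (stationary point), the tissue-level
Gaussian curvature p1·p2 (positive for elliptic caps), and the principal
curvature ratio measuring dome asymmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh

log = logging.getLogger(__name__)


@dataclass
class Paraboloid:
    """z = p1 x² + p2 y² + p3 x + p4 y + p5, with the fit's RMS z-residual."""

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        params = (self.p1, self.p2, self.p3, self.p4, self.p5)
        if not all(np.isfinite(params)):
            raise ValueError(f"non-finite paraboloid parameters {params}")

    @property
    def params(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4, self.p5])

    def __call__(self, x, y):
        return (
            self.p1 * np.asarray(x) ** 2
            + self.p2 * np.asarray(y) ** 2
            + self.p3 * np.asarray(x)
            + self.p4 * np.asarray(y)
            + self.p5
        )


def fit_paraboloid(vertices: np.ndarray) -> Paraboloid:
    """Closed-form least squares of z against [x², y², x, y, 1].

    Requires ≥ 5 points not all collinear in XY (the design matrix must
    have full rank).
    """
    pts = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 5:
        raise ValueError(f"need >= 5 points to fit a paraboloid, got {len(pts)}")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    design = np.column_stack([x * x, y * y, x, y, np.ones_like(x)])
    if np.linalg.matrix_rank(design) < 5:
        raise ValueError("degenerate point configuration (rank-deficient design)")
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    resid = z - design @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    return Paraboloid(*coef, fit_residual=rms)


def apex(p: Paraboloid) -> np.ndarray:
    """Stationary point (x, y, z) of the quadric; requires p1, p2 ≠ 0."""
    if p.p1 == 0 or p.p2 == 0:
        raise ValueError("apex undefined: p1 and p2 must be non-zero")
    x = -p.p3 / (2.0 * p.p1)
    y = -p.p4 / (2.0 * p.p2)
    return np.array([x, y, p(x, y)])


def gaussian_curvature(p: Paraboloid) -> float:
    """Tissue-level Gaussian curvature: the product p1·p2."""
    return p.p1 * p.p2


def curvature_ratio(p: Paraboloid) -> dict:
    """Principal curvature ratio of the fitted dome.

    Returns both the literal ratio max(p1, p2)/min(p1, p2) and the
    normalised asymmetry max(|p1|, |p2|)/min(|p1|, |p2|) ≥ 1 used for
    reporting.
    """
    if min(abs(p.p1), abs(p.p2)) == 0:
        raise ValueError("curvature ratio undefined for a zero coefficient")
    literal = max(p.p1, p.p2) / min(p.p1, p.p2)
    normalised = max(abs(p.p1), abs(p.p2)) / min(abs(p.p1), abs(p.p2))
    return {"literal": float(literal), "normalised": float(normalised)}


def sample_paraboloid_mesh(
    p: Paraboloid, xy_bounds: tuple[float, float, float, float], resolution: float = 1.0
) -> SurfaceMesh:
    """Regular-grid triangulation of the quadric over (xmin, xmax, ymin, ymax)."""
    xmin, xmax, ymin, ymax = xy_bounds
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"empty bounds {xy_bounds}")
    nx = max(2, int(np.floor((xmax - xmin) / resolution)) + 1)
    ny = max(2, int(np.floor((ymax - ymin) / resolution)) + 1)
    xs = xmin + np.arange(nx) * resolution
    ys = ymin + np.arange(ny) * resolution
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    zz = p(xx, yy)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = a + ny
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return SurfaceMesh(verts, np.asarray(faces, dtype=np.int64))


def mesh_to_mesh_distance(source: SurfaceMesh, target: SurfaceMesh):
    """Per-source-vertex Euclidean distance to the closest target vertex.

    Returns ``(distances, mean)``.
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise ValueError("empty mesh")
    d, _ = cKDTree(target.vertices).query(source.vertices)
    return d, float(d.mean())


def fit_distance(
    mesh: SurfaceMesh, p: Paraboloid, resolution: float = 1.0, pad: float = 0.1
):
    """Mean distance from mesh vertices to a densely sampled paraboloid.

    The paraboloid is sampled over the mesh's XY bounding box padded by
    ``pad`` (fraction) at the given resolution, then nearest-vertex
    distances are measured.
    """
    xy = mesh.vertices[:, :2]
    lo, hi = xy.min(0), xy.max(0)
    span = hi - lo
    lo = lo - pad * span
    hi = hi + pad * span
    grid = sample_paraboloid_mesh(p, (lo[0], hi[0], lo[1], hi[1]), resolution)
    return mesh_to_mesh_distance(mesh, grid)


def project_along_axis(
    point: np.ndarray, p: Paraboloid, mesh: SurfaceMesh
) -> np.ndarray:
    """Project a point onto the mesh along the paraboloid's central axis.

    The axis-aligned model has a vertical central axis, so the line
    through ``point`` parallel to z is intersected with the mesh; the
    intersection nearest the point is returned.  If the line misses the
    mesh, the nearest mesh vertex is returned with a warning.
    """
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    pt = np.asarray(point, dtype=float)
    zs, _ = mesh.vertical_ray_hits(pt[:2])
    if len(zs):
        z = zs[np.argmin(np.abs(zs - pt[2]))]
        return np.array([pt[0], pt[1], z])
    log.warning("vertical line through %s misses the mesh; using nearest vertex", pt)
    _, idx = cKDTree(mesh.vertices).query(pt)
    return mesh.vertices[idx].astype(float)
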