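"""Ground-truthed synthetic shoot apices for testing every pipeline stage.

The generator emulates the geometry the pipeline targets: a solid dome
bounded above by an elliptic paraboloid, with Gaussian bumps (flower
primordia) on its flank at chosen azimuths — golden-angle spacing for a
wild-type-like spiral.  Bumps are added to the height field, never as
separate solids, so the surface remains a 2.5D height function by
construction.  The height field can be rendered into a voxel grid with
additive Gaussian noise and exponential attenuation with depth (the two
dominant confocal artefacts the preprocessing stage addresses), or
triangulated directly for isolated tests of curvature, segmentation and
phenotyping.

Default scales mirror an Arabidopsis inflorescence apex: dome principal
curvatures ≈ 0.01 μm⁻¹, primordium bumps of ~10 μm amplitude and 8 μm
width about 40 μm from the axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import SurfaceMesh
from .paraboloid import Paraboloid
from .phenotype import GOLDEN_ANGLE
from .volume import IntensityVolume


@dataclass
class Bump:
    """A primordium bump on the dome flank."""

    azimuth: float  # degrees in [0, 360)
    radial_distance: float  # μm from the dome axis
    amplitude: float = 10.0  # μm
    width: float = 8.0  # μm (Gaussian sigma)

    def __post_init__(self) -> None:
        if not 0 <= self.azimuth < 360:
            raise ValueError("bump azimuth must be in [0, 360)")
        if min(self.radial_distance, self.amplitude, self.width) <= 0:
            raise ValueError("bump distance/amplitude/width must be positive")


@dataclass
class SyntheticApexSpec:
    """Full description of a synthetic apex scene."""

    dome: Paraboloid = field(
        default_factory=lambda: Paraboloid(-0.01, -0.01, 0.0, 0.0, 60.0)
    )
    bumps: list = field(default_factory=list)
    spacing: float = 0.5  # μm, isotropic voxel size
    noise_sigma: float = 0.1  # additive Gaussian, foreground intensity is 1
    depth_falloff: float = 0.0  # per-μm attenuation with depth from stack top
    seed: int = 0
    xy_halfwidth: float | None = None  # scene half-extent; None = auto
    z_margin: float = 2.0  # μm of solid kept below the lowest surface point

    def __post_init__(self) -> None:
        if self.dome.p1 >= 0 or self.dome.p2 >= 0:
            raise ValueError("dome must be apex-up: p1, p2 < 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    # analytic frame -------------------------------------------------------
    def apex_xy(self) -> np.ndarray:
        d = self.dome
        return np.array([-d.p3 / (2 * d.p1), -d.p4 / (2 * d.p2)])

    def halfwidth(self) -> float:
        if self.xy_halfwidth is not None:
            return float(self.xy_halfwidth)
        if not self.bumps:
            return 30.0
        return max(b.radial_distance + 3.0 * b.width for b in self.bumps)

    def bump_centres(self) -> np.ndarray:
        cx, cy = self.apex_xy()
        return np.array(
            [
                [
                    cx + b.radial_distance * np.cos(np.radians(b.azimuth)),
                    cy + b.radial_distance * np.sin(np.radians(b.azimuth)),
                ]
                for b in self.bumps
            ]
        ).reshape(-1, 2)

    def height(self, x, y):
        """Analytic surface height h(x, y) = dome + Σ Gaussian bumps."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        h = self.dome(x, y)
        for (bx, by), b in zip(self.bump_centres(), self.bumps):
            r2 = (x - bx) ** 2 + (y - by) ** 2
            h = h + b.amplitude * np.exp(-r2 / (2.0 * b.width**2))
        return h

    def true_label(self, x, y):
        """Ground-truth generator labels: 0 = dome, i+1 = bump i (nearest within 2σ)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape, dtype=np.int64)
        if self.bumps:
            centres = self.bump_centres()
            d = np.stack(
                [np.hypot(x - bx, y - by) for bx, by in centres], axis=-1
            )
            nearest = np.argmin(d, axis=-1)
            dmin = np.take_along_axis(d, nearest[..., None], axis=-1)[..., 0]
            widths = np.array([b.width for b in self.bumps])
            out = np.where(dmin < 2.0 * widths[nearest], nearest + 1, 0)
        return out


def golden_spiral_spec(
    n_bumps: int,
    radial_distance: float = 40.0,
    radial_step: float = 5.0,
    amplitude: float = 10.0,
    width: float = 8.0,
    direction: str = "counterclockwise",
    **kwargs,
) -> SyntheticApexSpec:
    """Apex spec with ``n_bumps`` primordia on a golden-angle spiral.

    Organ k (k = 0 the youngest) sits at azimuth k·137.5° and radius
    ``radial_distance + k·radial_step`` — older primordia are displaced
    outward by dome growth, so the spiral never closes into a ring and
    the dome stays in contact with every organ, as on a real apex.
    """
    sign = 1.0 if direction == "counterclockwise" else -1.0
    bumps = [
        Bump(
            azimuth=(sign * k * GOLDEN_ANGLE) % 360.0,
            radial_distance=radial_distance + k * radial_step,
            amplitude=amplitude,
            width=width,
        )
        for k in range(n_bumps)
    ]
    return SyntheticApexSpec(bumps=bumps, **kwargs)


def make_apex_volume(spec: SyntheticApexSpec):
    """Render the apex into a voxel grid.

    Returns ``(volume, height_function, truth_label_function)`` — the
    rendered :class:`IntensityVolume` (foreground 1, background 0, plus
    noise and depth falloff), the analytic height field h(x, y) for error
    measurement, and the ground-truth label function for segmentation
    checks.  The volume origin is set so voxel physical coordinates live
    in the same frame as the analytic surface.
    """
    L = spec.halfwidth()
    cx, cy = spec.apex_xy()
    if spec.bumps:
        centres = spec.bump_centres()
        if np.any(np.abs(centres - [cx, cy]).max(axis=1) > L):
            raise ValueError("bump centre outside the scene bounds")
    s = spec.spacing
    x = cx - L + np.arange(int(round(2 * L / s)) + 1) * s
    y = cy - L + np.arange(int(round(2 * L / s)) + 1) * s
    xx, yy = np.meshgrid(x, y)  # (ny, nx)
    h = spec.height(xx, yy)
    z0 = h.min() - spec.z_margin
    z1 = h.max() + spec.z_margin
    z = z0 + np.arange(int(round((z1 - z0) / s)) + 1) * s
    solid = z[:, None, None] <= h[None, :, :]
    data = solid.astype(np.float64)
    if spec.depth_falloff > 0:
        depth = z[-1] - z
        data *= np.exp(-spec.depth_falloff * depth)[:, None, None]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    vol = IntensityVolume(data, (s, s, s), origin=(z[0], y[0], x[0]))
    return vol, spec.height, spec.true_label


def make_apex_mesh(spec: SyntheticApexSpec, resolution: float = 1.0):
    """Direct grid triangulation of the analytic surface (bypasses the image pipeline).

    Returns ``(mesh, true_labels)`` with per-vertex ground-truth labels.
    Face winding gives upward (outward) normals.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    L = spec.halfwidth()
    cx, cy = spec.apex_xy()
    n = int(round(2 * L / resolution)) + 1
    xs = cx - L + np.arange(n) * resolution
    ys = cy - L + np.arange(n) * resolution
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    zz = spec.height(xx, yy)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + n
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    mesh = SurfaceMesh(verts, np.asarray(faces, dtype=np.int64))
    labels = spec.true_label(verts[:, 0], verts[:, 1])
    return mesh, labels
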