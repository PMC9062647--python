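"""Organ- and plant-level phenotypes extracted from the segmented surface.

Per organ: surface area, robust curvature statistics (median and SD
after truncating that organ's values to its own 10–90% quantile range),
mean/max distance to a reference point (inflorescence centre of mass by
default), centre and azimuth.  Per plant: divergence angles between
consecutive organs of the phyllotactic spiral, their spread around the
canonical 137.5° golden angle, the distance of the youngest identified
primordium from the apex, the CLV3-reporter apex, the comparison of the
three apex definitions, and a resolution-sensitivity benchmark.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .curvature import CurvatureField
from .mesh import SurfaceMesh
from .paraboloid import Paraboloid, apex as paraboloid_apex, project_along_axis
from .segmentation import Segmentation
from .volume import IntensityVolume

GOLDEN_ANGLE = 137.5  # degrees; canonical wild-type divergence


@dataclass
class OrganRecord:
    """One segmented organ's geometric phenotype."""

    label: int
    surface_area: float  # μm²
    curv_median: float  # μm⁻¹
    curv_sd: float  # μm⁻¹
    dist_mean: float  # μm, to reference point
    dist_max: float  # μm
    centre: np.ndarray  # (x, y, z) μm
    azimuth: float  # degrees in [0, 360), about the reference
    phyllotactic_index: int | None = None


@dataclass
class OrderingFile:
    """Manual phyllotactic ordering: organ label → index, plus spiral direction."""

    index_of_label: dict  # label -> phyllotactic index (0 = first primordium)
    spiral_direction: str  # "clockwise" | "counterclockwise"

    def __post_init__(self) -> None:
        if self.spiral_direction not in ("clockwise", "counterclockwise"):
            raise ValueError(f"bad spiral direction {self.spiral_direction!r}")
        idx = sorted(self.index_of_label.values())
        if idx != list(range(len(idx))):
            raise ValueError("phyllotactic indices must be unique and contiguous from 0")


@dataclass
class PhyllotaxisResult:
    divergence_angles: list  # degrees, consecutive organ pairs
    sd_around_canonical: float  # degrees
    first_organ_distance: float  # μm


def read_ordering(path) -> dict:
    """Read orderings from CSV columns plant_id,label,phyllotactic_index,spiral_direction."""
    per_plant: dict[str, dict] = {}
    direction: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["plant_id"]
            per_plant.setdefault(pid, {})[int(row["label"])] = int(
                row["phyllotactic_index"]
            )
            direction[pid] = row["spiral_direction"]
    return {
        pid: OrderingFile(mapping, direction[pid]) for pid, mapping in per_plant.items()
    }


def _face_labels(seg: Segmentation, mesh: SurfaceMesh) -> np.ndarray:
    """Majority vote of the three vertex labels per face, ties to the lowest label."""
    fl = seg.labels[mesh.faces]
    out = np.empty(len(fl), dtype=np.int64)
    same01 = fl[:, 0] == fl[:, 1]
    same02 = fl[:, 0] == fl[:, 2]
    same12 = fl[:, 1] == fl[:, 2]
    out[:] = np.min(fl, axis=1)  # all-distinct default: lowest label
    out[same12] = fl[same12, 1]
    out[same02] = fl[same02, 0]
    out[same01] = fl[same01, 0]
    return out


def azimuth_deg(xy: np.ndarray, about_xy: np.ndarray) -> float:
    """Azimuth of a point about a centre in the XY plane, degrees in [0, 360)."""
    d = np.asarray(xy, dtype=float)[:2] - np.asarray(about_xy, dtype=float)[:2]
    if np.linalg.norm(d) == 0:
        raise ValueError("point coincides with centre in XY; azimuth undefined")
    return float(np.degrees(np.arctan2(d[1], d[0])) % 360.0)


def organ_features(
    seg: Segmentation,
    mesh: SurfaceMesh,
    field: CurvatureField,
    reference: np.ndarray,
    ordering: OrderingFile | None = None,
    quantiles: tuple[float, float] = (0.10, 0.90),
) -> list[OrganRecord]:
    """Per-organ phenotype records for every non-inflorescence domain."""
    reference = np.asarray(reference, dtype=float)
    face_lab = _face_labels(seg, mesh)
    areas = mesh.face_areas()
    records = []
    for label in seg.label_ids():
        label = int(label)
        if label == seg.inflorescence_label:
            continue
        vmask = seg.labels == label
        if not vmask.any():
            raise ValueError(f"organ {label} has no vertices")
        verts = mesh.vertices[vmask]
        area = float(areas[face_lab == label].sum())
        cv = field.values[vmask]
        qlo, qhi = np.quantile(cv, quantiles)
        cv_t = np.clip(cv, qlo, qhi)
        d = np.linalg.norm(verts - reference, axis=1)
        centre = verts.mean(axis=0)
        records.append(
            OrganRecord(
                label=label,
                surface_area=area,
                curv_median=float(np.median(cv_t)),
                curv_sd=float(np.std(cv_t)),
                dist_mean=float(d.mean()),
                dist_max=float(d.max()),
                centre=centre,
                azimuth=azimuth_deg(centre, reference),
                phyllotactic_index=(
                    ordering.index_of_label.get(label) if ordering else None
                ),
            )
        )
    return records


def divergence_angles(
    organs: list[OrganRecord], apex: np.ndarray, direction: str
) -> list[float]:
    """Divergence angle between consecutive phyllotactic indices, in [0, 360).

    Azimuths are measured about the apex exclusively in the XY plane and
    differenced along the recorded spiral direction (counterclockwise =
    increasing mathematical azimuth).
    """
    ranked = sorted(
        (o for o in organs if o.phyllotactic_index is not None),
        key=lambda o: o.phyllotactic_index,
    )
    if len(ranked) < 2:
        raise ValueError("need >= 2 ordered organs for divergence angles")
    az = [azimuth_deg(o.centre, apex) for o in ranked]
    sign = 1.0 if direction == "counterclockwise" else -1.0
    return [float((sign * (b - a)) % 360.0) for a, b in zip(az, az[1:])]


def divergence_sd(angles, canonical: float = GOLDEN_ANGLE) -> float:
    """RMS deviation of divergence angles from the canonical golden angle.

    Each deviation is the minimal signed circular difference (wrapped to
    (−180°, 180°]).
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle list")
    dev = (a - canonical + 180.0) % 360.0 - 180.0
    return float(np.sqrt(np.mean(dev**2)))


def first_organ_distance(
    seg: Segmentation, mesh: SurfaceMesh, apex: np.ndarray, ordering: OrderingFile
) -> float:
    """Maximal vertex distance of the first (index 0) primordium from the apex."""
    label0 = [l for l, i in ordering.index_of_label.items() if i == 0]
    if not label0:
        raise ValueError("ordering has no organ with phyllotactic index 0")
    vmask = seg.labels == label0[0]
    if not vmask.any():
        raise ValueError(f"label {label0[0]} absent from segmentation")
    d = np.linalg.norm(mesh.vertices[vmask] - np.asarray(apex, dtype=float), axis=1)
    return float(d.max())


def clv3_apex(
    signal: IntensityVolume, quantile_ladder=(0.9999, 0.9990, 0.9900)
) -> np.ndarray:
    """Apex from a CLV3 reporter channel: centroid of the brightest voxels.

    Voxels strictly above the 99.99% intensity quantile are selected;
    empty sets fall back to 99.90% then 99.00%.  The centroid is
    unweighted and returned as (x, y, z) in micrometres.
    """
    data = np.asarray(signal.data, dtype=np.float64)
    for q in quantile_ladder:
        thr = np.quantile(data, q)
        zyx = np.argwhere(data > thr)
        if len(zyx):
            phys = signal.voxel_to_physical(zyx.astype(float))
            return phys.mean(axis=0)[::-1]  # (z, y, x) -> (x, y, z)
    raise ValueError("no voxels above any ladder quantile (constant volume?)")


def apex_comparison(
    mesh: SurfaceMesh, p: Paraboloid, seg: Segmentation, clv3: np.ndarray
) -> dict:
    """Pairwise distances between the three apex definitions, after projection.

    Candidates — paraboloid apex ("para"), inflorescence centre of mass
    ("com"), CLV3 centroid ("clv3") — are each projected onto the mesh
    along the paraboloid central axis before distances are measured.
    """
    if seg.inflorescence_label is None:
        raise ValueError("inflorescence label required for the COM apex")
    com = mesh.vertices[seg.labels == seg.inflorescence_label].mean(axis=0)
    candidates = {
        "para": paraboloid_apex(p),
        "com": com,
        "clv3": np.asarray(clv3, dtype=float),
    }
    projected = {k: project_along_axis(v, p, mesh) for k, v in candidates.items()}
    names = sorted(projected)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[f"{a}_{b}"] = float(np.linalg.norm(projected[a] - projected[b]))
    out["projected"] = projected
    return out


def resolution_benchmark(
    vol: IntensityVolume, axis: str, factors, reconstruct
) -> dict:
    """Surface error introduced by downsampling the stack.

    For each factor the stated axis (``"z"`` or ``"xy"``, the latter
    scaling x and y together) is downsampled with a cubic spline, the
    surface pipeline ``reconstruct`` (IntensityVolume → SurfaceMesh) is
    rerun, and the mean distance from every high-resolution-mesh vertex
    to the closest downscaled-mesh vertex is recorded.
    """
    from scipy.spatial import cKDTree

    if axis not in ("z", "xy"):
        raise ValueError("axis must be 'z' or 'xy'")
    factors = list(factors)
    if any(f < 1 for f in factors):
        raise ValueError("downsampling factors must be >= 1")
    ref_mesh = reconstruct(vol)
    out = {}
    for f in factors:
        if f == 1:
            low_mesh = reconstruct(vol)
        else:
            zoom = [1.0, 1.0, 1.0]
            spacing = list(vol.spacing)
            ax_ids = [0] if axis == "z" else [1, 2]
            for a in ax_ids:
                zoom[a] = 1.0 / f
                spacing[a] = vol.spacing[a] * f
            data = ndimage.zoom(
                np.asarray(vol.data, dtype=np.float64),
                zoom,
                order=3,
                mode="nearest",
                grid_mode=True,
            )
            low_mesh = reconstruct(IntensityVolume(data, tuple(spacing), vol.origin))
        d, _ = cKDTree(low_mesh.vertices).query(ref_mesh.vertices)
        out[f] = float(d.mean())
    return out
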