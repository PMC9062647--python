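"""End-to-end orchestration: config, per-plant stage running, output bundles.

A :class:`PipelineConfig` holds every tunable of the workflow (resampling
target, CLAHE, smoothing, ACWE, simplification fraction, curvature
band and filter iterations, merge thresholds, paraboloid sampling, CLV3
quantile ladder) and round-trips through a plain YAML file with unknown
keys rejected.  :func:`run_pipeline` processes a batch of stacks (or
precomputed masks) into per-plant meshes, fitted paraboloids and
phenotype tables plus a manifest; a stage failure is recorded per plant
and the batch continues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contour as ct
from . import curvature as cv
from . import mesh as ms
from . import paraboloid as pb
from . import phenotype as ph
from . import segmentation as sg
from . import volume as vl

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All workflow tunables; defaults follow the standard protocol."""

    # preprocessing
    target_spacing: float = 0.5  # μm, isotropic resample target
    resample_order: int = 3
    clahe_enabled: bool = True
    clahe_clip_limit: float = 0.01
    clahe_slicewise: bool = False
    gaussian_sigma: float = 0.5  # μm; 0 disables
    crop_center_xy: tuple | None = None  # μm (x, y); None = no crop
    crop_radii_xy: tuple | None = None
    # contouring
    acwe_iterations: int = 150
    acwe_smoothing: int = 2
    acwe_lambda1: float = 1.0
    acwe_lambda2: float = 1.0
    acwe_init: str = "otsu"
    normalize_orientation: bool = True
    # meshing
    mesh_smooth_sigma_vox: float = 1.0
    simplify_fraction: float = 0.1
    min_component_fraction: float = 0.05
    boundary_erosion_rings: int = 4  # dense-mesh rings dropped at the image-border cut
    clip_margin: float | None = None  # μm; None = 2 * target_spacing
    # curvature
    curv_lo: float = -0.1  # μm⁻¹
    curv_hi: float = 0.1
    minmax_iterations: int = 2
    smoothing_iterations: int = 20
    # segmentation merge thresholds
    depth_threshold: float = 0.01
    engulf_fraction: float = 1.0
    disconnect_fraction: float = 0.05
    distance_threshold: float = 10.0
    angle_threshold: float = 20.0
    # paraboloid / phenotyping
    paraboloid_resolution: float = 1.0  # μm sampling for distance measures
    clv3_quantiles: tuple = (0.9999, 0.9990, 0.9900)
    n_comparisons: int = 1
    # misc
    seed: int = 0
    output_dir: str = "samsurf_out"

    def merge_params(self) -> sg.MergeParams:
        return sg.MergeParams(
            depth_threshold=self.depth_threshold,
            engulf_fraction=self.engulf_fraction,
            disconnect_fraction=self.disconnect_fraction,
            distance_threshold=self.distance_threshold,
            angle_threshold=self.angle_threshold,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("crop_center_xy", "crop_radii_xy", "clv3_quantiles"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage helpers


def preprocess_volume(vol: vl.IntensityVolume, config: PipelineConfig) -> vl.IntensityVolume:
    vol = vl.resample_isotropic(vol, config.target_spacing, config.resample_order)
    if config.clahe_enabled:
        vol = vl.equalize_clahe(
            vol, clip_limit=config.clahe_clip_limit, slicewise=config.clahe_slicewise
        )
    if config.gaussian_sigma > 0:
        vol = vl.smooth_gaussian(vol, config.gaussian_sigma)
    if config.crop_center_xy is not None and config.crop_radii_xy is not None:
        vol = vl.crop_elliptic_cylinder(vol, config.crop_center_xy, config.crop_radii_xy)
    return vol


def orient_apex_up(contour: ct.BinaryContour):
    """Flip the mask along z if the tissue apex faces −z.

    Heuristic: a solid dome with apex up has its foreground centroid in
    the lower half of the foreground z-extent.  Returns
    ``(contour, flipped)``.
    """
    mask = contour.mask
    zs = np.nonzero(mask.any(axis=(1, 2)))[0]
    if len(zs) == 0:
        return contour, False
    centroid_z = np.argwhere(mask)[:, 0].mean()
    mid = (zs[0] + zs[-1]) / 2.0
    if centroid_z > mid:
        return ct.BinaryContour(mask[::-1].copy(), contour.spacing, contour.origin), True
    return contour, False


def mask_to_surface(contour: ct.BinaryContour, config: PipelineConfig) -> ms.SurfaceMesh:
    """Mask → repaired mask → marching cubes → clean → simplify → clip base."""
    contour = ct.fill_xy_holes(contour)
    if config.normalize_orientation:
        contour, flipped = orient_apex_up(contour)
        if flipped:
            log.info("orientation normalised: volume flipped along z")
    contour = ct.extend_to_base(contour)
    mesh = ms.extract_mesh(contour, smooth_sigma_vox=config.mesh_smooth_sigma_vox)
    mesh, _ = ms.clean_mesh(mesh, config.min_component_fraction)
    if config.boundary_erosion_rings > 0:
        mesh = ms.erode_boundary(mesh, config.boundary_erosion_rings)
    mesh = ms.simplify_mesh(mesh, config.simplify_fraction, seed=config.seed)
    mesh, _ = ms.clean_mesh(mesh, config.min_component_fraction)
    margin = config.clip_margin
    if margin is None:
        margin = 2.0 * contour.spacing[0]
    mesh = ms.clip_base(mesh, margin)
    return mesh


def reconstruct_surface(vol: vl.IntensityVolume, config: PipelineConfig) -> ms.SurfaceMesh:
    """Full surface stage from an intensity volume (preprocess → contour → mesh)."""
    vol = preprocess_volume(vol, config)
    contour = ct.contour_with_fallback(
        vol,
        iterations=config.acwe_iterations,
        smoothing=config.acwe_smoothing,
        lambda1=config.acwe_lambda1,
        lambda2=config.acwe_lambda2,
        init=config.acwe_init,
    )
    return mask_to_surface(contour, config)


def analyse_mesh(mesh: ms.SurfaceMesh, config: PipelineConfig, ordering=None) -> dict:
    """Curvature → segmentation → paraboloid → organ/plant phenotypes."""
    field = cv.prepare_curvature(
        mesh,
        lo=config.curv_lo,
        hi=config.curv_hi,
        minmax_iters=config.minmax_iterations,
        smooth_iters=config.smoothing_iterations,
    )
    seg = sg.segment_mesh(mesh, field, config.merge_params())
    inflo_mask = seg.labels == seg.inflorescence_label
    para = pb.fit_paraboloid(mesh.vertices[inflo_mask])
    _, mean_fit_dist = pb.fit_distance(
        ms.SurfaceMesh(mesh.vertices[inflo_mask], np.zeros((0, 3), dtype=int)),
        para,
        resolution=config.paraboloid_resolution,
    )
    com = mesh.vertices[inflo_mask].mean(axis=0)
    organs = ph.organ_features(seg, mesh, field, reference=com, ordering=ordering)
    result = {
        "mesh": mesh,
        "field": field,
        "segmentation": seg,
        "paraboloid": para,
        "inflorescence_com": com,
        "mean_fit_distance": mean_fit_dist,
        "organs": organs,
    }
    if ordering is not None and len(ordering.index_of_label) >= 2:
        angles = ph.divergence_angles(organs, com, ordering.spiral_direction)
        result["phyllotaxis"] = ph.PhyllotaxisResult(
            divergence_angles=angles,
            sd_around_canonical=ph.divergence_sd(angles),
            first_organ_distance=ph.first_organ_distance(seg, mesh, com, ordering),
        )
    return result


# ---------------------------------------------------------------------------
# batch driver


def run_pipeline(config: PipelineConfig, inputs, orderings=None) -> dict:
    """Process a batch of plants into an output bundle per plant plus a manifest.

    ``inputs`` maps plant_id → either a stack path, an
    ``IntensityVolume``, or ``{"mask": path_or_BinaryContour}`` to skip
    contouring.  ``orderings`` maps plant_id → :class:`~samsurf.phenotype.OrderingFile`.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    orderings = orderings or {}
    manifest = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "plants": {},
    }
    results = {}
    for plant_id, source in inputs.items():
        record = {"status": "ok", "stages": []}
        try:
            mesh = _surface_for(source, config, record)
            ordering = orderings.get(plant_id)
            res = analyse_mesh(mesh, config, ordering)
            record["stages"].append("analyse")
            _write_bundle(plant_id, res, outdir, config)
            record["stages"].append("write")
            results[plant_id] = res
        except Exception as exc:  # keep the batch going, record the failure
            log.exception("plant %s failed", plant_id)
            record["status"] = "error"
            record["error"] = f"{type(exc).__name__}: {exc}"
        manifest["plants"][plant_id] = record
    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"manifest": manifest, "results": results}


def _surface_for(source, config: PipelineConfig, record: dict) -> ms.SurfaceMesh:
    if isinstance(source, dict) and "mask" in source:
        m = source["mask"]
        if not isinstance(m, ct.BinaryContour):
            m = ct.load_mask(m, spacing=(config.target_spacing,) * 3)
        record["stages"].append("mask-input (contouring skipped)")
        return mask_to_surface(m, config)
    if isinstance(source, vl.IntensityVolume):
        vol = source
    else:
        vol = vl.load_stack(source)
    record["stages"].append("surface")
    return reconstruct_surface(vol, config)


def _write_bundle(plant_id, res, outdir: Path, config: PipelineConfig) -> None:
    mesh = res["mesh"]
    out = mesh.copy()
    out.scalars["mean_curvature"] = np.asarray(res["field"].values, dtype=float)
    out.scalars["organ_label"] = np.asarray(res["segmentation"].labels, dtype=float)
    ms.write_ply(out, outdir / f"{plant_id}.ply")
    ms.write_vtp(out, outdir / f"{plant_id}.vtp")

    p = res["paraboloid"]
    apex = pb.apex(p)
    ratio = pb.curvature_ratio(p)
    pd.DataFrame(
        [
            {
                "plant_id": plant_id,
                "p1": p.p1, "p2": p.p2, "p3": p.p3, "p4": p.p4, "p5": p.p5,
                "apex_x": apex[0], "apex_y": apex[1], "apex_z": apex[2],
                "gaussian_curvature": pb.gaussian_curvature(p),
                "curvature_ratio": ratio["normalised"],
                "mean_fit_distance_um": res["mean_fit_distance"],
                "fit_residual": p.fit_residual,
            }
        ]
    ).to_csv(outdir / f"{plant_id}_paraboloid.csv", index=False)

    rows = []
    for o in res["organs"]:
        rows.append(
            {
                "plant_id": plant_id,
                "label": o.label,
                "phyllotactic_index": o.phyllotactic_index,
                "surface_area_um2": o.surface_area,
                "curv_median": o.curv_median,
                "curv_sd": o.curv_sd,
                "dist_mean_um": o.dist_mean,
                "dist_max_um": o.dist_max,
                "centre_x": o.centre[0], "centre_y": o.centre[1], "centre_z": o.centre[2],
                "azimuth_deg": o.azimuth,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / f"{plant_id}_organs.csv", index=False)

    if "phyllotaxis" in res:
        phy = res["phyllotaxis"]
        pd.DataFrame(
            [
                {
                    "plant_id": plant_id,
                    "divergence_angles_deg": ";".join(
                        f"{a:.3f}" for a in phy.divergence_angles
                    ),
                    "sd_around_canonical_deg": phy.sd_around_canonical,
                    "first_organ_distance_um": phy.first_organ_distance,
                }
            ]
        ).to_csv(outdir / f"{plant_id}_plant.csv", index=False)
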