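"""Binary tissue contouring: morphological active contours with Otsu fallback.

The tissue mask is produced by the Morphological Chan–Vese level set
(active contours without edges), which needs no sharp boundary — only a
difference in mean intensity between tissue and background.  When ACWE
degenerates (empty or full mask, typical of very poor signal), a plain
Otsu threshold takes over.  Two repair heuristics follow: filling holes
in every XY section, and extending each occupied column down to the
lowest z so that the solid sits on the stack base (the artificial bottom
is clipped off again after meshing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage
from skimage import filters, segmentation

from .volume import IntensityVolume

log = logging.getLogger(__name__)


class DegenerateContourError(RuntimeError):
    """Raised when contouring yields an empty or full mask; fall back to Otsu."""


@dataclass
class BinaryContour:
    """A boolean tissue mask aligned with its parent volume."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)


def acwe_contour(
    vol: IntensityVolume,
    iterations: int = 150,
    smoothing: int = 2,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    init="otsu",
) -> BinaryContour:
    """Morphological Chan–Vese (ACWE) segmentation of the tissue.

    ``init`` may be ``"otsu"`` (threshold mask), ``"checkerboard"``, or a
    boolean array of the volume's shape.  Raises
    :class:`DegenerateContourError` if the result is empty or full, so
    callers can fall back to :func:`otsu_contour`.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    data = np.asarray(vol.data, dtype=np.float64)
    if isinstance(init, str):
        if init == "otsu":
            if np.ptp(data) == 0:
                raise DegenerateContourError("constant volume; no contour possible")
            init_ls = data > filters.threshold_otsu(data)
        elif init == "checkerboard":
            init_ls = segmentation.checkerboard_level_set(data.shape, 5)
        else:
            raise ValueError(f"unknown init {init!r}")
    else:
        init_ls = np.asarray(init, dtype=bool)
        if init_ls.shape != data.shape:
            raise ValueError("init mask shape mismatch")
    mask = segmentation.morphological_chan_vese(
        data,
        num_iter=iterations,
        init_level_set=init_ls,
        smoothing=smoothing,
        lambda1=lambda1,
        lambda2=lambda2,
    ).astype(bool)
    # ACWE labels phases arbitrarily; keep the brighter phase as tissue.
    if mask.any() and (~mask).any():
        if data[mask].mean() < data[~mask].mean():
            mask = ~mask
    n_fg = int(mask.sum())
    if n_fg == 0 or n_fg == mask.size:
        raise DegenerateContourError(
            "ACWE produced a degenerate (empty or full) mask; use otsu_contour"
        )
    return BinaryContour(mask, vol.spacing, vol.origin)


def otsu_contour(vol: IntensityVolume) -> BinaryContour:
    """Threshold mask at the Otsu between-class-variance optimum."""
    data = np.asarray(vol.data, dtype=np.float64)
    if np.ptp(data) == 0:
        raise ValueError("constant volume has no Otsu threshold")
    t = filters.threshold_otsu(data)
    return BinaryContour(data > t, vol.spacing, vol.origin)


def contour_with_fallback(vol: IntensityVolume, **acwe_kwargs) -> BinaryContour:
    """ACWE contouring; on a degenerate result, retry with Otsu and log it."""
    try:
        return acwe_contour(vol, **acwe_kwargs)
    except DegenerateContourError:
        log.warning("ACWE degenerate; falling back to Otsu thresholding")
        return otsu_contour(vol)


def fill_xy_holes(contour: BinaryContour) -> BinaryContour:
    """Fill background holes per XY slice (components not touching the slice border)."""
    mask = contour.mask
    out = np.empty_like(mask)
    for z in range(mask.shape[0]):
        out[z] = ndimage.binary_fill_holes(mask[z])
    return BinaryContour(out, contour.spacing, contour.origin)


def extend_to_base(contour: BinaryContour) -> BinaryContour:
    """Fill every occupied (y, x) column from its topmost foreground voxel down to z = 0."""
    mask = contour.mask
    nz = mask.shape[0]
    any_fg = mask.any(axis=0)
    # topmost foreground index per column (undefined where column empty)
    topmost = nz - 1 - np.argmax(mask[::-1], axis=0)
    zidx = np.arange(nz)[:, None, None]
    out = (zidx <= topmost[None, :, :]) & any_fg[None, :, :]
    return BinaryContour(out, contour.spacing, contour.origin)


def load_mask(path, spacing: tuple[float, float, float]) -> BinaryContour:
    """Read an 8-bit TIFF mask (0 = background, nonzero = foreground)."""
    data = tifffile.imread(str(path))
    return BinaryContour(data > 0, spacing)


def save_mask(contour: BinaryContour, path) -> None:
    """Write the mask as 8-bit TIFF (0 / 255)."""
    tifffile.imwrite(str(path), (contour.mask.astype(np.uint8) * 255))
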