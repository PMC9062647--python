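"""Confocal intensity volumes and the preprocessing stage.

A stack is held as an :class:`IntensityVolume` — a 3D scalar array in
(z, y, x) axis order with physical voxel spacing in micrometres.  The
preprocessing operations mirror the standard sequence for plant confocal
data: resample to an isotropic physical resolution (so one parameter set
works across acquisitions), CLAHE to equalise dye-penetration artefacts,
Gaussian smoothing, and an optional elliptic-cylinder crop that isolates
the central zone when the stack contains too little surrounding tissue
for organ segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage
from skimage import exposure


@dataclass
class IntensityVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array, axes ordered ``(z, y, x)``.
    spacing:
        Physical voxel size along ``(z, y, x)`` in micrometres.
    origin:
        Physical coordinate of voxel ``(0, 0, 0)`` in micrometres.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise ValueError(f"each axis must have length >= 2, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent(self) -> tuple[float, float, float]:
        """Physical size N*s per axis in micrometres."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def voxel_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional (z, y, x) voxel indices to physical coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.array(self.spacing) + np.array(self.origin)


def load_stack(
    path,
    channel: int = 0,
    spacing: tuple[float, float, float] | None = None,
) -> IntensityVolume:
    """Load one channel of a TIFF / OME-TIFF stack.

    Spacing is read from OME or ImageJ metadata; if absent it must be
    supplied via ``spacing`` or a ``ValueError`` is raised.  Channel axis
    handling: 4D arrays are interpreted through the tifffile axes string
    when available, else as (z, c, y, x) for small second axes and
    (c, z, y, x) otherwise.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "ZYX", "ZCYX", "CZYX", "TZCYX"
        meta_spacing = _read_spacing(tf)

    data = _select_channel(data, axes, channel)
    if spacing is None:
        spacing = meta_spacing
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing in metadata; pass spacing=(z, y, x) explicitly"
        )
    return IntensityVolume(np.asarray(data, dtype=np.float64), spacing)


def save_stack(vol: IntensityVolume, path) -> None:
    """Write a volume as ImageJ-style TIFF with spacing metadata."""
    sz, sy, sx = vol.spacing
    data = np.asarray(vol.data, dtype=np.float32)
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


def _read_spacing(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    # OME-XML carries PhysicalSizeZ/Y/X; ImageJ TIFFs carry "spacing" plus
    # the standard resolution tags for XY.
    if tf.ome_metadata:
        import re

        def grab(name):
            m = re.search(rf'{name}="([\d.eE+-]+)"', tf.ome_metadata)
            return float(m.group(1)) if m else None

        sx, sy, sz = grab("PhysicalSizeX"), grab("PhysicalSizeY"), grab("PhysicalSizeZ")
        if sx and sy and sz:
            return (sz, sy, sx)
    ij = tf.imagej_metadata
    if ij is not None and "spacing" in ij:
        page = tf.pages[0]
        try:
            xr = page.tags["XResolution"].value
            yr = page.tags["YResolution"].value
            sx = xr[1] / xr[0]
            sy = yr[1] / yr[0]
        except (KeyError, ZeroDivisionError):
            return None
        return (float(ij["spacing"]), float(sy), float(sx))
    return None


def _select_channel(data: np.ndarray, axes: str, channel: int) -> np.ndarray:
    if data.ndim == 3:
        if channel != 0:
            raise IndexError(f"single-channel stack, channel={channel} invalid")
        return data
    if data.ndim == 4:
        if "C" in axes and len(axes) == 4:
            c_ax = axes.index("C")
        else:
            # heuristic: channel axes are short
            c_ax = 1 if data.shape[1] <= 4 else 0
        if not 0 <= channel < data.shape[c_ax]:
            raise IndexError(f"channel {channel} out of range for axis size {data.shape[c_ax]}")
        return np.take(data, channel, axis=c_ax)
    raise ValueError(f"unsupported stack dimensionality {data.ndim}")


def resample_isotropic(
    vol: IntensityVolume, target: float = 0.5, order: int = 3
) -> IntensityVolume:
    """Resample to an isotropic voxel size of ``target`` micrometres.

    New axis length is ``round(N * s / target)`` (pixel-area convention),
    keeping the physical extent within half a voxel.  Interpolation is a
    spline of the given order (default cubic).
    """
    if target <= 0:
        raise ValueError(f"target spacing must be positive, got {target}")
    if not 0 <= order <= 5:
        raise ValueError(f"spline order must be in 0..5, got {order}")
    shape = vol.data.shape
    new_shape = tuple(
        max(2, int(round(n * s / target))) for n, s in zip(shape, vol.spacing)
    )
    if new_shape == shape and all(abs(s - target) < 1e-12 for s in vol.spacing):
        return replace(vol, data=vol.data.copy(), spacing=(target,) * 3)
    zoom = [n2 / n1 for n1, n2 in zip(shape, new_shape)]
    data = ndimage.zoom(
        np.asarray(vol.data, dtype=np.float64),
        zoom,
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    return IntensityVolume(data, (target, target, target), vol.origin)


def equalize_clahe(
    vol: IntensityVolume,
    kernel_size=None,
    clip_limit: float = 0.01,
    slicewise: bool = False,
) -> IntensityVolume:
    """Contrast-limited adaptive histogram equalisation, rescaled to [0, 1].

    By default CLAHE runs volumetrically (3D tiles); ``slicewise=True``
    applies it per XY section instead.  Default tile size is 1/8 of each
    axis.
    """
    if not 0 < clip_limit <= 1:
        raise ValueError(f"clip_limit must be in (0, 1], got {clip_limit}")
    data = np.asarray(vol.data, dtype=np.float64)
    lo, hi = data.min(), data.max()
    if hi <= lo:
        return replace(vol, data=np.zeros_like(data))
    data = (data - lo) / (hi - lo)
    if kernel_size is not None:
        ks = np.atleast_1d(kernel_size).astype(int)
        if np.any(ks < 2):
            raise ValueError(f"kernel_size must be >= 2 per axis, got {kernel_size}")
        if slicewise:
            ks2 = ks[-2:] if ks.size >= 2 else np.array([ks[0], ks[0]])
            if np.any(ks2 > data.shape[1:]):
                raise ValueError("CLAHE kernel larger than slice")
        elif np.any(np.resize(ks, 3) > data.shape):
            raise ValueError("CLAHE kernel larger than volume")
    else:
        ks = None
    if slicewise:
        out = np.stack(
            [
                exposure.equalize_adapthist(s, kernel_size=ks, clip_limit=clip_limit)
                for s in data
            ]
        )
    else:
        out = exposure.equalize_adapthist(data, kernel_size=ks, clip_limit=clip_limit)
    return replace(vol, data=out)


def smooth_gaussian(vol: IntensityVolume, sigma: float) -> IntensityVolume:
    """Gaussian smoothing with sigma in micrometres (converted per axis)."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return replace(vol, data=vol.data.copy())
    sig_vox = [sigma / s for s in vol.spacing]
    data = ndimage.gaussian_filter(
        np.asarray(vol.data, dtype=np.float64), sig_vox, mode="nearest"
    )
    return replace(vol, data=data)


def crop_elliptic_cylinder(
    vol: IntensityVolume,
    center_xy: tuple[float, float],
    radii_xy: tuple[float, float],
) -> IntensityVolume:
    """Zero out voxels whose (x, y) lies outside a closed ellipse.

    ``center_xy`` and ``radii_xy`` are physical (x, y) micrometre values;
    the crop spans all z (a cylinder).  Points exactly on the boundary are
    kept.
    """
    rx, ry = float(radii_xy[0]), float(radii_xy[1])
    if rx <= 0 or ry <= 0:
        raise ValueError(f"radii must be positive, got {radii_xy}")
    cx, cy = center_xy
    _, sy, sx = vol.spacing
    _, oy, ox = vol.origin
    nz, ny, nx = vol.data.shape
    x = ox + np.arange(nx) * sx
    y = oy + np.arange(ny) * sy
    xx, yy = np.meshgrid(x, y)  # (ny, nx)
    inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0 + 1e-12
    data = vol.data * inside[np.newaxis, :, :]
    return replace(vol, data=data)
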