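import numpy as np
import pytest

from samsurf.volume import (
    IntensityVolume,
    crop_elliptic_cylinder,
    equalize_clahe,
    load_stack,
    resample_isotropic,
    save_stack,
    smooth_gaussian,
)


def make_vol(shape=(10, 12, 14), spacing=(2.0, 1.0, 1.0), seed=0):
    rng = np.random.default_rng(seed)
    return IntensityVolume(rng.random(shape), spacing)


def test_voxel_to_physical_uses_spacing_and_origin():
    vol = IntensityVolume(np.zeros((4, 4, 4)), (2.0, 1.0, 0.5), origin=(1.0, 2.0, 3.0))
    phys = vol.voxel_to_physical(np.array([[1.0, 1.0, 2.0]]))
    assert np.allclose(phys, [[1.0 + 2.0, 2.0 + 1.0, 3.0 + 1.0]])


def test_resample_isotropic_shape_rule():
    vol = make_vol(shape=(10, 20, 20), spacing=(2.0, 0.5, 0.5))
    out = resample_isotropic(vol, target=1.0)
    # N' = round(N * s / target) per axis
    assert out.shape == (20, 10, 10)
    assert out.spacing == (1.0, 1.0, 1.0)


def test_resample_isotropic_noop_copies():
    vol = make_vol(spacing=(1.0, 1.0, 1.0))
    out = resample_isotropic(vol, target=1.0)
    assert out.shape == vol.shape
    assert np.allclose(out.data, vol.data)
    out.data[0, 0, 0] = 99.0
    assert vol.data[0, 0, 0] != 99.0


def test_resample_preserves_smooth_content():
    z, y, x = np.meshgrid(np.arange(16), np.arange(16), np.arange(16), indexing="ij")
    data = np.sin(x / 5.0) + np.cos(y / 7.0) + z / 16.0
    vol = IntensityVolume(data, (1.0, 1.0, 1.0))
    out = resample_isotropic(vol, target=0.5)
    assert out.shape == (32, 32, 32)
    # compare on the common interior via stride-2 sampling
    assert np.abs(out.data[::2, ::2, ::2] - data).mean() < 0.05


def test_clahe_output_in_unit_interval():
    vol = make_vol()
    out = equalize_clahe(vol)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0
    assert out.shape == vol.shape


def test_clahe_slicewise_matches_shape():
    vol = make_vol(shape=(4, 32, 32))
    out = equalize_clahe(vol, slicewise=True)
    assert out.shape == vol.shape
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0


def test_clahe_constant_volume_is_zeroed():
    vol = IntensityVolume(np.full((4, 8, 8), 3.0), (1, 1, 1))
    out = equalize_clahe(vol)
    assert np.all(out.data == 0)


def test_smooth_gaussian_micron_sigma_is_anisotropic_in_voxels():
    data = np.zeros((21, 21, 21))
    data[10, 10, 10] = 1.0
    vol = IntensityVolume(data, (2.0, 1.0, 1.0))
    out = smooth_gaussian(vol, sigma=2.0)
    # sigma is 1 voxel along z but 2 voxels along y/x: decay from the peak
    # must be steeper along z than along y at the same voxel offset
    assert out.data[12, 10, 10] < out.data[10, 12, 10]


def test_smooth_gaussian_zero_sigma_identity():
    vol = make_vol()
    out = smooth_gaussian(vol, 0.0)
    assert np.array_equal(out.data, vol.data)


def test_crop_elliptic_cylinder_keeps_boundary_zeroes_outside():
    vol = IntensityVolume(np.ones((3, 21, 21)), (1.0, 1.0, 1.0))
    out = crop_elliptic_cylinder(vol, center_xy=(10.0, 10.0), radii_xy=(5.0, 5.0))
    assert out.data[1, 10, 15] == 1.0  # exactly on the boundary: kept
    assert out.data[1, 10, 16] == 0.0
    assert out.data[1, 10, 10] == 1.0
    assert out.data[0, 0, 0] == 0.0


def test_save_load_roundtrip_spacing(tmp_path):
    vol = make_vol(shape=(5, 6, 7), spacing=(1.5, 0.5, 0.5))
    path = tmp_path / "stack.tif"
    save_stack(vol, path)
    back = load_stack(path)
    assert back.shape == vol.shape
    assert np.allclose(back.spacing, vol.spacing)
    assert np.allclose(back.data, vol.data, atol=1e-6)


def test_load_stack_requires_spacing(tmp_path):
    import tifffile

    path = tmp_path / "plain.tif"
    tifffile.imwrite(path, np.zeros((3, 4, 5), dtype=np.float32))
    with pytest.raises(ValueError, match="spacing"):
        load_stack(path)
    vol = load_stack(path, spacing=(1.0, 0.5, 0.5))
    assert vol.spacing == (1.0, 0.5, 0.5)


def test_load_stack_channel_selection(tmp_path):
    import tifffile

    data = np.stack(
        [np.zeros((3, 4, 5), dtype=np.float32), np.ones((3, 4, 5), dtype=np.float32)],
        axis=1,
    )  # (z, c, y, x)
    path = tmp_path / "two_channel.tif"
    tifffile.imwrite(path, data, imagej=True, metadata={"spacing": 1.0, "axes": "ZCYX"})
    ch1 = load_stack(path, channel=1, spacing=(1.0, 1.0, 1.0))
    assert ch1.shape == (3, 4, 5)
    assert np.all(ch1.data == 1.0)
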