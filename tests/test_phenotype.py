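import numpy as np
import pytest

from samsurf.curvature import prepare_curvature
from samsurf.paraboloid import Paraboloid, apex, fit_paraboloid
from samsurf.phenotype import (
    GOLDEN_ANGLE,
    OrderingFile,
    apex_comparison,
    azimuth_deg,
    clv3_apex,
    divergence_angles,
    divergence_sd,
    first_organ_distance,
    organ_features,
    read_ordering,
    resolution_benchmark,
)
from samsurf.segmentation import Segmentation
from samsurf.synthetic import SyntheticApexSpec, golden_spiral_spec, make_apex_mesh, make_apex_volume
from samsurf.volume import IntensityVolume


def truth_segmentation(mesh, truth):
    seg = Segmentation(truth.copy())
    seg.inflorescence_label = 0
    return seg


@pytest.fixture(scope="module")
def spiral_scene():
    spec = golden_spiral_spec(5, noise_sigma=0.0)
    mesh, truth = make_apex_mesh(spec, resolution=1.0)
    seg = truth_segmentation(mesh, truth)
    field = prepare_curvature(mesh)
    p = fit_paraboloid(mesh.vertices[truth == 0])
    return spec, mesh, truth, seg, field, p


def test_azimuth_deg_quadrants():
    assert azimuth_deg([1, 0], [0, 0]) == 0.0
    assert azimuth_deg([0, 1], [0, 0]) == 90.0
    assert azimuth_deg([-1, 0], [0, 0]) == 180.0
    assert azimuth_deg([0, -1], [0, 0]) == 270.0
    with pytest.raises(ValueError):
        azimuth_deg([0, 0], [0, 0])


def test_ordering_file_validation():
    OrderingFile({3: 0, 7: 1}, "clockwise")
    with pytest.raises(ValueError):
        OrderingFile({3: 0, 7: 2}, "clockwise")  # indices not contiguous
    with pytest.raises(ValueError):
        OrderingFile({3: 0}, "widdershins")


def test_read_ordering_csv(tmp_path):
    path = tmp_path / "ordering.csv"
    path.write_text(
        "plant_id,label,phyllotactic_index,spiral_direction\n"
        "p1,2,0,clockwise\n"
        "p1,5,1,clockwise\n"
        "p2,1,0,counterclockwise\n"
    )
    orderings = read_ordering(path)
    assert set(orderings) == {"p1", "p2"}
    assert orderings["p1"].index_of_label == {2: 0, 5: 1}
    assert orderings["p2"].spiral_direction == "counterclockwise"


def test_organ_features_on_truth_labels(spiral_scene):
    spec, mesh, truth, seg, field, p = spiral_scene
    ordering = OrderingFile({b + 1: b for b in range(5)}, "counterclockwise")
    com = mesh.vertices[truth == 0].mean(axis=0)
    organs = organ_features(seg, mesh, field, reference=com, ordering=ordering)
    assert len(organs) == 5
    centres = spec.bump_centres()
    for o in organs:
        b = o.phyllotactic_index
        assert o.surface_area > 0
        assert o.dist_max >= o.dist_mean > 0
        # organ centroid sits on its generating bump's azimuth
        true_az = azimuth_deg(centres[b], spec.apex_xy())
        diff = abs((o.azimuth - true_az + 180) % 360 - 180)
        assert diff < 2.0


def test_divergence_angles_recover_golden_angle(spiral_scene):
    spec, mesh, truth, seg, field, p = spiral_scene
    ordering = OrderingFile({b + 1: b for b in range(5)}, "counterclockwise")
    a = apex(p)
    organs = organ_features(seg, mesh, field, reference=a, ordering=ordering)
    angles = divergence_angles(organs, a, ordering.spiral_direction)
    assert len(angles) == 4
    assert max(abs(x - GOLDEN_ANGLE) for x in angles) < 1.0
    assert divergence_sd(angles) < 1.0


def test_divergence_respects_spiral_direction():
    spec = golden_spiral_spec(4, direction="clockwise", noise_sigma=0.0)
    mesh, truth = make_apex_mesh(spec, resolution=1.5)
    seg = truth_segmentation(mesh, truth)
    field = prepare_curvature(mesh)
    ordering = OrderingFile({b + 1: b for b in range(4)}, "clockwise")
    p = fit_paraboloid(mesh.vertices[truth == 0])
    a = apex(p)
    organs = organ_features(seg, mesh, field, reference=a, ordering=ordering)
    angles = divergence_angles(organs, a, "clockwise")
    assert max(abs(x - GOLDEN_ANGLE) for x in angles) < 1.0


def test_divergence_sd_exact_value():
    assert divergence_sd([127.5, 147.5]) == 10.0
    assert divergence_sd([GOLDEN_ANGLE]) == 0.0
    # wrapping: 360 + 137.5 is the same angle
    assert divergence_sd([360.0 + GOLDEN_ANGLE - 360.0]) == 0.0
    assert np.isclose(divergence_sd([317.5]), 180.0)  # maximal wrapped deviation


def test_first_organ_distance(spiral_scene):
    spec, mesh, truth, seg, field, p = spiral_scene
    ordering = OrderingFile({b + 1: b for b in range(5)}, "counterclockwise")
    a = apex(p)
    d = first_organ_distance(seg, mesh, a, ordering)
    # organ 0 sits 40 um out; its farthest vertex lies beyond that
    assert 40.0 < d < 80.0


def test_clv3_apex_quantile_ladder():
    data = np.zeros((20, 20, 20))
    data[5, 10, 12] = 10.0  # one bright voxel: above the 99.99% quantile
    vol = IntensityVolume(data, (1.0, 1.0, 1.0))
    assert np.allclose(clv3_apex(vol), [12.0, 10.0, 5.0])  # (x, y, z)
    with pytest.raises(ValueError):
        clv3_apex(IntensityVolume(np.ones((5, 5, 5)), (1, 1, 1)))


def test_clv3_apex_ladder_fallback():
    # 0.5% bright voxels: the 99.99% and 99.9% quantiles both equal the
    # bright value (nothing strictly above), the 99% rung selects them
    data = np.zeros((10, 10, 10))
    data[3, 4, 4:9] = 1.0
    vol = IntensityVolume(data, (1.0, 1.0, 1.0))
    a = clv3_apex(vol)
    assert np.allclose(a, [6.0, 4.0, 3.0])  # (x, y, z) centroid of the streak


def test_apex_comparison_all_candidates_close_on_symmetric_dome():
    spec = SyntheticApexSpec(dome=Paraboloid(-0.01, -0.01, 0.0, 0.0, 50.0), spacing=1.0,
                             noise_sigma=0.0, xy_halfwidth=25.0)
    mesh, truth = make_apex_mesh(spec, resolution=1.0)
    seg = truth_segmentation(mesh, truth)
    p = fit_paraboloid(mesh.vertices)
    clv3 = np.array([0.5, -0.5, 50.0])
    out = apex_comparison(mesh, p, seg, clv3)
    assert set(out) == {"clv3_com", "clv3_para", "com_para", "projected"}
    for key in ("clv3_com", "clv3_para", "com_para"):
        assert out[key] < 5.0
    # projection preserves the XY position of each candidate
    assert np.allclose(out["projected"]["clv3"][:2], clv3[:2])


def test_resolution_benchmark_monotone_on_dome():
    spec = SyntheticApexSpec(dome=Paraboloid(-0.015, -0.015, 0.0, 0.0, 30.0), spacing=1.0,
                             noise_sigma=0.0, xy_halfwidth=20.0)
    vol, h, _ = make_apex_volume(spec)
    from samsurf.pipeline import PipelineConfig, reconstruct_surface

    cfg = PipelineConfig(target_spacing=1.0, acwe_iterations=30)
    table = resolution_benchmark(vol, "xy", [1, 2], lambda v: reconstruct_surface(v, cfg))
    assert set(table) == {1, 2}
    assert table[1] <= table[2]
    with pytest.raises(ValueError):
        resolution_benchmark(vol, "diagonal", [1], lambda v: None)
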