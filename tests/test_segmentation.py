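import numpy as np
import pytest

from conftest import grid_mesh, random_mesh
from samsurf.curvature import CurvatureField, prepare_curvature
from samsurf.mesh import SurfaceMesh
from samsurf.segmentation import (
    MergeParams,
    Segmentation,
    attractor_segmentation,
    identify_inflorescence,
    merge_by_angle,
    merge_by_depth,
    merge_by_distance,
    merge_disconnected,
    merge_engulfed,
    segment_mesh,
)
from samsurf.synthetic import golden_spiral_spec, make_apex_mesh


def oracle_labels(mesh, vals):
    """Independent per-vertex greedy hill-climb with identical tie-breaking."""
    n = mesh.n_vertices
    roots = np.empty(n, dtype=np.int64)
    for start in range(n):
        i = start
        for _ in range(n + 1):
            nb = sorted(mesh.vertex_neighbors(i))
            best, best_v = i, vals[i]
            for j in nb:  # ascending index: first strict improvement of the max
                if vals[j] > best_v:
                    best, best_v = j, vals[j]
            if best == i:
                break
            i = best
        roots[start] = i
    attractors = np.unique(roots)
    return np.searchsorted(attractors, roots), attractors


def test_attractor_matches_oracle_on_random_meshes(rng):
    for trial in range(40):
        mesh = random_mesh(rng, n_pts=25)
        vals = rng.normal(size=mesh.n_vertices)
        if trial % 3 == 0:  # inject ties
            vals = np.round(vals, 1)
        seg = attractor_segmentation(mesh, CurvatureField(vals))
        labels, attractors = oracle_labels(mesh, vals)
        assert np.array_equal(seg.labels, labels)
        assert sorted(seg.attractors.values()) == list(attractors)


def test_attractor_labels_consecutive_from_zero(rng):
    mesh = random_mesh(rng)
    seg = attractor_segmentation(mesh, CurvatureField(rng.normal(size=mesh.n_vertices)))
    assert np.array_equal(np.unique(seg.labels), np.arange(seg.n_domains))


def two_hill_mesh():
    """15x15 grid with two Gaussian hills of different depth."""
    def h(x, y):
        return (
            3.0 * np.exp(-((x - 4) ** 2 + (y - 7) ** 2) / 4.0)
            + 3.0 * np.exp(-((x - 10) ** 2 + (y - 7) ** 2) / 4.0)
        )

    return grid_mesh(15, height=h)


def test_merge_by_depth_absorbs_shallow_domain():
    mesh = two_hill_mesh()
    vals = np.zeros(mesh.n_vertices)
    # two attractor plateaus separated by a shallow pass
    x = mesh.vertices[:, 0]
    vals[:] = 0.0
    vals[x < 7] = 0.5
    vals[x > 7] = 0.505  # deeper max on the right; pass at 0.5 on the ridge
    vals[np.isclose(x, 7)] = 0.4999
    seg = attractor_segmentation(mesh, CurvatureField(vals))
    seg.inflorescence_label = -1  # no protection in play
    merged = merge_by_depth(seg, CurvatureField(vals), mesh, MergeParams(depth_threshold=0.01))
    assert merged.n_domains < seg.n_domains


def test_merge_disconnected_folds_sepal_cap_into_flower():
    # three stripes: inflorescence | flower | cap; the cap never touches the inflo
    mesh = grid_mesh(12)
    x = mesh.vertices[:, 0]
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    labels[(x >= 4) & (x < 8)] = 1
    labels[x >= 8] = 2
    seg = Segmentation(labels)
    seg.inflorescence_label = 0
    out = merge_disconnected(seg, mesh, MergeParams())
    assert out.n_domains == 2
    assert set(np.unique(out.labels)) == {0, 1}  # cap 2 merged into flower 1


def test_merge_disconnected_keeps_attached_domain():
    mesh = grid_mesh(12)
    x = mesh.vertices[:, 0]
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    labels[x >= 6] = 1  # 100% of its border is on the inflorescence
    seg = Segmentation(labels)
    seg.inflorescence_label = 0
    out = merge_disconnected(seg, mesh, MergeParams())
    assert out.n_domains == 2


def test_merge_disconnected_requires_inflorescence():
    mesh = grid_mesh(5)
    seg = Segmentation(np.zeros(mesh.n_vertices, dtype=np.int64))
    with pytest.raises(ValueError):
        merge_disconnected(seg, mesh, MergeParams())


def test_merge_by_distance_and_angle_merge_close_pairs():
    mesh = grid_mesh(21)
    x, y = mesh.vertices[:, 0], mesh.vertices[:, 1]
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    labels[(x > 12) & (y > 12)] = 1
    labels[(x > 12) & (y <= 12) & (y > 8)] = 2  # adjacent to 1, centres close
    seg = Segmentation(labels)
    seg.inflorescence_label = 0
    out = merge_by_distance(seg, mesh, MergeParams(distance_threshold=10.0))
    assert out.n_domains == 2
    seg2 = Segmentation(labels.copy())
    seg2.inflorescence_label = 0
    apex = np.array([0.0, 0.0, 0.0])
    out2 = merge_by_angle(seg2, mesh, apex, MergeParams(angle_threshold=45.0))
    assert out2.n_domains == 2
    assert out2.inflorescence_label == 0


def test_merges_never_touch_inflorescence_label():
    mesh = grid_mesh(12)
    x = mesh.vertices[:, 0]
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    labels[(x >= 4) & (x < 8)] = 1
    labels[x >= 8] = 2
    seg = Segmentation(labels)
    seg.inflorescence_label = 0
    for op in (
        lambda s: merge_engulfed(s, mesh, MergeParams(engulf_fraction=0.1)),
        lambda s: merge_disconnected(s, mesh, MergeParams(disconnect_fraction=0.9)),
        lambda s: merge_by_distance(s, mesh, MergeParams(distance_threshold=100.0)),
    ):
        out = op(Segmentation(labels.copy(), inflorescence_label=0))
        assert 0 in np.unique(out.labels)
        assert out.inflorescence_label == 0


def test_identify_inflorescence_on_dome_mesh():
    spec = golden_spiral_spec(3, noise_sigma=0.0)
    mesh, truth = make_apex_mesh(spec, resolution=1.5)
    field = prepare_curvature(mesh)
    seg = attractor_segmentation(mesh, field)
    label = identify_inflorescence(seg, mesh)
    apex_idx = np.argmin(
        np.linalg.norm(mesh.vertices[:, :2] - spec.apex_xy(), axis=1)
    )
    assert seg.labels[apex_idx] == label
    assert seg.inflorescence_label == label


def test_segment_mesh_dome_plus_k_bumps_counts():
    # the acceptance criterion runs k in {3, 5, 8}; keep one case here for speed
    k = 3
    spec = golden_spiral_spec(k, noise_sigma=0.0)
    mesh, truth = make_apex_mesh(spec, resolution=1.5)
    field = prepare_curvature(mesh)
    seg = segment_mesh(mesh, field)
    assert seg.n_domains == k + 1
    assert seg.inflorescence_label is not None


def test_merges_only_reduce_labels_and_cover_all_vertices(rng):
    spec = golden_spiral_spec(5, noise_sigma=0.0)
    mesh, _ = make_apex_mesh(spec, resolution=2.0)
    field = prepare_curvature(mesh)
    seg = attractor_segmentation(mesh, field)
    identify_inflorescence(seg, mesh)
    n = seg.n_domains
    params = MergeParams()
    from samsurf.curvature import CurvatureField as CF

    stages = [
        lambda s: merge_by_depth(s, field, mesh, params),
        lambda s: merge_engulfed(s, mesh, params),
        lambda s: merge_disconnected(s, mesh, params),
        lambda s: merge_by_distance(s, mesh, params),
    ]
    for stage in stages:
        seg = stage(seg)
        assert seg.n_domains <= n
        assert len(seg.labels) == mesh.n_vertices
        n = seg.n_domains
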