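import numpy as np
import pytest

from conftest import grid_mesh, icosphere
from samsurf.contour import BinaryContour
from samsurf.mesh import (
    SurfaceMesh,
    clean_mesh,
    clip_base,
    erode_boundary,
    extract_mesh,
    read_ply,
    simplify_mesh,
    write_obj,
    write_ply,
    write_vtp,
)


def sphere_contour(radius=10.0, spacing=1.0, pad=3):
    n = int(2 * (radius + pad) / spacing) + 1
    c = (n - 1) / 2.0 * spacing
    z, y, x = np.meshgrid(*(np.arange(n) * spacing,) * 3, indexing="ij")
    mask = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius**2
    return BinaryContour(mask, (spacing,) * 3), c


def test_extract_mesh_outward_normals_and_volume():
    contour, c = sphere_contour()
    mesh = extract_mesh(contour, smooth_sigma_vox=1.0)
    tm = mesh.to_trimesh()
    assert tm.volume > 0  # positive signed volume = outward winding
    assert abs(tm.volume - 4 / 3 * np.pi * 10**3) / (4 / 3 * np.pi * 10**3) < 0.1
    centre = mesh.vertices - np.array([c, c, c])
    agree = (centre * mesh.vertex_normals()).sum(1)
    assert (agree > 0).mean() > 0.99


def test_extract_mesh_vertices_in_physical_xyz_frame():
    contour, c = sphere_contour()
    mesh = extract_mesh(contour, smooth_sigma_vox=0.0)
    r = np.linalg.norm(mesh.vertices - c, axis=1)
    assert abs(np.median(r) - 10.0) < 0.5


def test_simplify_mesh_vertex_budget_and_area():
    mesh = icosphere(10.0, subdivisions=4)
    simp = simplify_mesh(mesh, 0.1, seed=0)
    assert simp.n_vertices == int(round(0.1 * mesh.n_vertices))
    assert abs(simp.area() - mesh.area()) / mesh.area() < 0.05


def test_simplify_mesh_deterministic():
    mesh = icosphere(10.0)
    a = simplify_mesh(mesh, 0.2, seed=5)
    b = simplify_mesh(mesh, 0.2, seed=5)
    assert np.array_equal(a.vertices, b.vertices)
    assert np.array_equal(a.faces, b.faces)


def test_clean_mesh_removes_duplicates_degenerates_and_islands():
    base = grid_mesh(10)
    # append a duplicate vertex, a degenerate face, and a tiny island
    v = np.vstack([base.vertices, base.vertices[0], [[50, 50, 0], [51, 50, 0], [50, 51, 0]]])
    dup_idx = len(base.vertices)
    isl = dup_idx + 1
    f = np.vstack(
        [
            base.faces,
            [[dup_idx, 1, 10]],  # uses the duplicate of vertex 0
            [[2, 2, 3]],  # degenerate
            [[isl, isl + 1, isl + 2]],  # disconnected island
        ]
    )
    mesh = SurfaceMesh(v, f, {"s": np.arange(len(v), dtype=float)})
    cleaned, report = clean_mesh(mesh, min_component_fraction=0.05)
    assert cleaned.n_vertices == base.n_vertices
    assert report["duplicate_vertices"] >= 1
    assert report["degenerate_faces"] >= 1
    assert report["removed_component_faces"] >= 1
    assert len(cleaned.scalars["s"]) == cleaned.n_vertices


def test_clip_base_opens_bottom():
    contour, c = sphere_contour()
    mesh = extract_mesh(contour, smooth_sigma_vox=1.0)
    clipped = clip_base(mesh, 2.0)
    zmin = mesh.vertices[:, 2].min()
    assert clipped.vertices[:, 2].min() >= zmin  # nothing added
    assert len(clipped.boundary_vertices()) > 0  # now open
    assert clipped.n_faces < mesh.n_faces


def test_erode_boundary_removes_rim_only():
    mesh = grid_mesh(15)
    out = erode_boundary(mesh, 2)
    # a 15x15 grid loses its two outer rings -> an 11x11 grid remains
    assert out.n_vertices == 11 * 11
    inner = mesh.vertices[
        (mesh.vertices[:, 0] >= 2)
        & (mesh.vertices[:, 0] <= 12)
        & (mesh.vertices[:, 1] >= 2)
        & (mesh.vertices[:, 1] <= 12)
    ]
    assert out.n_vertices == len(inner)


def test_erode_boundary_noop_on_closed_mesh():
    mesh = icosphere(5.0, subdivisions=2)
    out = erode_boundary(mesh, 3)
    assert out.n_vertices == mesh.n_vertices


def test_erode_boundary_refuses_total_removal():
    mesh = grid_mesh(4)
    with pytest.raises(ValueError):
        erode_boundary(mesh, 10)


def test_vertical_ray_hits_interpolates_z():
    mesh = grid_mesh(5, height=lambda x, y: x + 2 * y)
    zs, faces = mesh.vertical_ray_hits((1.25, 2.25))
    assert len(zs) == 1
    assert abs(zs[0] - (1.25 + 2 * 2.25)) < 1e-12
    zs2, _ = mesh.vertical_ray_hits((-5.0, -5.0))
    assert len(zs2) == 0


def test_boundary_vertices_of_grid():
    mesh = grid_mesh(6)
    bd = mesh.boundary_vertices()
    assert len(bd) == 4 * 6 - 4


def test_ply_roundtrip_with_scalars(tmp_path):
    mesh = grid_mesh(4, height=lambda x, y: np.sin(x) * y)
    mesh.scalars["mean_curvature"] = np.linspace(-1, 1, mesh.n_vertices)
    mesh.scalars["organ_label"] = np.arange(mesh.n_vertices, dtype=float)
    path = tmp_path / "m.ply"
    write_ply(mesh, path)
    back = read_ply(path)
    assert np.allclose(back.vertices, mesh.vertices)
    assert np.array_equal(back.faces, mesh.faces)
    for k in mesh.scalars:
        assert np.allclose(back.scalars[k], mesh.scalars[k])


def test_vtp_and_obj_outputs_are_wellformed(tmp_path):
    import xml.etree.ElementTree as ET

    mesh = grid_mesh(4)
    mesh.scalars["h"] = mesh.vertices[:, 2].copy()
    vtp = tmp_path / "m.vtp"
    obj = tmp_path / "m.obj"
    write_vtp(mesh, vtp)
    write_obj(mesh, obj)
    root = ET.parse(vtp).getroot()
    assert root.tag == "VTKFile"
    piece = root.find(".//Piece")
    assert int(piece.get("NumberOfPoints")) == mesh.n_vertices
    assert int(piece.get("NumberOfPolys")) == mesh.n_faces
    lines = obj.read_text().splitlines()
    assert sum(1 for l in lines if l.startswith("v ")) == mesh.n_vertices
    assert sum(1 for l in lines if l.startswith("f ")) == mesh.n_faces
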