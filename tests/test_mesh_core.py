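"""Mesh types, geometry kernels, closest-point queries and I/O."""

import numpy as np
import pytest
import trimesh

from craniofit import mesh_core as mc
from craniofit import synthetic_anatomy as sa


def icosphere(subdivisions=3, radius=1.0):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return mc.SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("fmt", ["ply", "obj", "off", "stl"])
def test_surface_round_trip(tmp_path, fmt):
    quad = mc.SurfaceMesh(
        np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]),
        np.array([[0, 1, 2], [0, 2, 3]]),
    )
    path = str(tmp_path / f"quad.{fmt}")
    mc.write_mesh(quad, path)
    back = mc.read_mesh(path)
    assert back.n_vertices == 4 and back.n_triangles == 2
    # vertex order can differ across formats; compare sorted coordinates
    a = np.sort(quad.vertices.round(8), axis=0)
    b = np.sort(back.vertices.round(8), axis=0)
    np.testing.assert_allclose(a, b, atol=1e-6)
    # connectivity preserved: same edge set up to relabeling
    assert {tuple(sorted(t)) for t in back.triangles} == {(0, 1, 2), (0, 2, 3)}


def test_off_out_of_range_index_is_parse_error(tmp_path):
    path = tmp_path / "bad.off"
    path.write_text("OFF\n3 1 0\n0 0 0\n1 0 0\n0 1 0\n3 0 1 7\n")
    with pytest.raises(mc.MeshFormatError):
        mc.read_mesh(str(path))


def test_medit_tet_round_trip(tmp_path):
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]])
    tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    mesh = mc.TetMesh(verts, tets)
    path = str(tmp_path / "t.mesh")
    mc.write_mesh(mesh, path)
    back = mc.read_mesh(path)
    np.testing.assert_allclose(back.vertices, verts, atol=1e-6)
    np.testing.assert_array_equal(back.tets, tets)


def test_tet_requested_from_surface_only_data(tmp_path):
    path = tmp_path / "surf.mesh"
    path.write_text(
        "MeshVersionFormatted 1\nDimension 3\nVertices\n3\n"
        "0 0 0 0\n1 0 0 0\n0 1 0 0\nTriangles\n1\n1 2 3 0\nEnd\n"
    )
    with pytest.raises(mc.MeshFormatError):
        mc.read_mesh(str(path))


def test_tet_hdf5_round_trip(tmp_path):
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    mesh = mc.TetMesh(verts, np.array([[0, 1, 2, 3]]), {"apex": 3})
    path = str(tmp_path / "t.h5")
    mc.write_mesh(mesh, path)
    back = mc.read_mesh(path)
    np.testing.assert_allclose(back.vertices, verts)
    assert back.landmarks == {"apex": 3}


def test_landmark_json_round_trip(tmp_path):
    lm = {"nasion": 12, "probe": np.array([1.0, 2.0, 3.0])}
    path = str(tmp_path / "lm.json")
    mc.write_landmarks(lm, path)
    back = mc.read_landmarks(path)
    assert back["nasion"] == 12
    np.testing.assert_allclose(back["probe"], [1, 2, 3])


def test_volume_nifti_round_trip(tmp_path):
    vol = mc.VoxelVolume(
        np.arange(24, dtype=float).reshape(2, 3, 4), [1.0, 2.0, 3.0], [5.0, 6.0, 7.0]
    )
    path = str(tmp_path / "v.nii.gz")
    mc.write_volume(vol, path)
    back = mc.read_volume(path)
    np.testing.assert_allclose(back.values, vol.values)
    np.testing.assert_allclose(back.spacing, vol.spacing)
    np.testing.assert_allclose(back.origin, vol.origin)


# ---------------------------------------------------------------------------
# iso-surfaces and connectivity
# ---------------------------------------------------------------------------


def test_isosurface_ball_area():
    # voxelized ball radius 10, unit spacing: surface area ~ 4 pi r^2
    n = 25
    ax = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    vals = 10.0 - np.sqrt(X**2 + Y**2 + Z**2)
    vol = mc.VoxelVolume(vals, [1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
    surf = mc.extract_isosurface(vol, 0.0)
    area = mc.triangle_areas(surf.vertices, surf.triangles).sum()
    assert abs(area - 4 * np.pi * 100) / (4 * np.pi * 100) < 0.05


def test_isosurface_constant_volume_empty():
    vol = mc.VoxelVolume(np.zeros((4, 4, 4)), [1, 1, 1], [0, 0, 0])
    assert mc.extract_isosurface(vol, 1.0).n_vertices == 0


def test_isosurface_bone_inside_skin(templates2, basis2):
    sub = sa.make_subject(templates2, basis2, np.zeros(3), seed=1)
    vol = sa.voxelize(sub, spacing=3.0)
    skin = mc.largest_component(mc.extract_isosurface(vol, -200.0))
    bone = mc.largest_component(mc.extract_isosurface(vol, 600.0))
    assert skin.n_vertices and bone.n_vertices
    # every bone vertex lies strictly inside the skin surface: its radius is
    # below the skin's radial hit distance in the same direction
    center = skin.vertices.mean(axis=0)
    rel = bone.vertices - center
    r_bone = np.linalg.norm(rel, axis=1)
    dirs = rel / r_bone[:, None]
    r_skin = sa._radial_hit_radius(skin, center, dirs)
    assert np.all(r_bone < r_skin)


def test_largest_component_picks_bigger_sphere():
    big = icosphere(3)  # 642 vertices
    small = icosphere(2, radius=0.5)  # 162 vertices
    small = mc.SurfaceMesh(small.vertices + 5.0, small.triangles)
    merged = mc.SurfaceMesh(
        np.vstack([big.vertices, small.vertices]),
        np.vstack([big.triangles, small.triangles + big.n_vertices]),
    )
    out = mc.largest_component(merged)
    assert out.n_vertices == 642


def test_largest_component_connected_unchanged():
    m = icosphere(2)
    out = mc.largest_component(m)
    np.testing.assert_allclose(out.vertices, m.vertices)
    np.testing.assert_array_equal(out.triangles, m.triangles)


def test_largest_component_tie_keeps_vertex_zero():
    a = icosphere(2)
    b = mc.SurfaceMesh(a.vertices + 10.0, a.triangles.copy())
    merged = mc.SurfaceMesh(
        np.vstack([a.vertices, b.vertices]),
        np.vstack([a.triangles, b.triangles + a.n_vertices]),
    )
    out = mc.largest_component(merged)
    np.testing.assert_allclose(out.vertices[0], a.vertices[0])
    assert out.n_vertices == a.n_vertices


# ---------------------------------------------------------------------------
# decimation
# ---------------------------------------------------------------------------


def test_decimate_icosphere_hausdorff():
    m = icosphere(4)  # 2562 vertices
    out = mc.decimate(m, 600)
    assert abs(out.n_vertices - 600) <= 0.02 * 600
    diag = m.bounding_box_diagonal()
    # two-sided Hausdorff via dense vertex sampling (brute-force oracle)
    d1 = mc.surface_distances(out, m.vertices).max()
    d2 = mc.surface_distances(m, out.vertices).max()
    assert max(d1, d2) < 0.01 * diag


def test_decimate_target_not_below_returns_input():
    m = icosphere(2)
    with pytest.warns(UserWarning):
        out = mc.decimate(m, m.n_vertices)
    np.testing.assert_allclose(out.vertices, m.vertices)


def test_decimate_cube_preserves_volume():
    box = trimesh.creation.box(extents=(2.0, 2.0, 2.0)).subdivide().subdivide()
    m = mc.SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces)).clean()
    out = mc.decimate(m, 8)
    vol = abs(mc.enclosed_volume(out))
    assert abs(vol - 8.0) / 8.0 < 0.05


# ---------------------------------------------------------------------------
# closest-point queries
# ---------------------------------------------------------------------------


def test_closest_point_at_vertex_is_zero():
    m = icosphere(2)
    _, d, _ = mc.closest_surface_point(m, m.vertices[17])
    assert d < 1e-12


def test_closest_point_center_of_unit_icosphere():
    m = icosphere(3)
    p, d, t = mc.closest_surface_point(m, [0.0, 0.0, 0.0])
    # exhaustive oracle over all triangles
    tri = m.vertices[m.triangles]
    from craniofit.mesh_core import _closest_on_triangles

    q = np.zeros((len(tri), 3))
    cps = _closest_on_triangles(q, tri[:, 0], tri[:, 1], tri[:, 2])
    expected = np.linalg.norm(cps, axis=1).min()
    assert abs(d - expected) < 1e-12
    assert 0.97 < d <= 1.0  # inscribed radius of the faceted sphere


def test_closest_point_foot_of_perpendicular():
    m = mc.SurfaceMesh(
        np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0]]), np.array([[0, 1, 2]])
    )
    p, d, _ = mc.closest_surface_point(m, [1.0, 1.0, 2.0])
    np.testing.assert_allclose(p, [1, 1, 0], atol=1e-12)
    assert abs(d - 2.0) < 1e-12


def test_closest_point_matches_exhaustive_scan():
    # exact agreement with an all-triangle scan on a <= 500-triangle mesh
    m = icosphere(2)  # 320 triangles
    rng = np.random.default_rng(3)
    queries = rng.normal(scale=1.5, size=(50, 3))
    tri = m.vertices[m.triangles]
    from craniofit.mesh_core import _closest_on_triangles

    for q in queries:
        _, d, _ = mc.closest_surface_point(m, q)
        pe = np.broadcast_to(q, (len(tri), 3))
        cps = _closest_on_triangles(pe.copy(), tri[:, 0], tri[:, 1], tri[:, 2])
        expected = np.linalg.norm(cps - q, axis=1).min()
        assert d == pytest.approx(expected, abs=1e-12)


def test_closest_point_empty_mesh_errors():
    empty = mc.SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
    with pytest.raises(mc.MeshError):
        mc.closest_surface_point(empty, [0, 0, 0])


# ---------------------------------------------------------------------------
# geometry kernels
# ---------------------------------------------------------------------------


def test_unit_tet_volume():
    v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    assert mc.tet_volumes(v, np.array([[0, 1, 2, 3]]))[0] == pytest.approx(1 / 6)


def test_tet_volume_scaling_matches_determinant_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        v = rng.normal(size=(4, 3))
        s = rng.uniform(0.5, 3.0)
        vol = mc.tet_volumes(v, np.array([[0, 1, 2, 3]]))[0]
        det = np.linalg.det(np.stack([v[1] - v[0], v[2] - v[0], v[3] - v[0]])) / 6
        assert vol == pytest.approx(det, abs=1e-12)
        vol_s = mc.tet_volumes(v * s, np.array([[0, 1, 2, 3]]))[0]
        assert vol_s == pytest.approx(vol * s**3, rel=1e-12)


def test_sphere_mean_curvature():
    m = icosphere(4, radius=10.0)
    h = mc.mean_curvature(m)
    assert abs(h.mean() - 0.1) / 0.1 < 0.05


def test_plane_mean_curvature_zero():
    xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(25)])
    tris = []
    for i in range(4):
        for j in range(4):
            a = i * 5 + j
            tris += [[a, a + 1, a + 5], [a + 1, a + 6, a + 5]]
    m = mc.SurfaceMesh(verts, np.array(tris))
    h = mc.mean_curvature(m)
    # interior vertices of a flat grid are exactly flat
    interior = [i * 5 + j for i in range(1, 4) for j in range(1, 4)]
    assert np.all(h[interior] < 1e-10)


def test_edge_areas_partition_total_area():
    m = icosphere(2)
    _, ea = mc.edge_areas(m)
    total = mc.triangle_areas(m.vertices, m.triangles).sum()
    assert ea.sum() == pytest.approx(total, rel=1e-12)


def test_tet_volume_sum_matches_divergence_theorem(templates2):
    skull = templates2.skull
    vols = skull.volumes()
    enclosed = mc.enclosed_volume(skull.boundary())
    assert vols.sum() == pytest.approx(enclosed, rel=1e-9)


def test_clean_merges_duplicates_and_drops_degenerates():
    verts = np.array(
        [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1e-9, 0, 0], [2, 2, 2]]
    )
    tris = np.array([[0, 1, 2], [3, 1, 2], [1, 1, 2]])
    m = mc.SurfaceMesh(verts, tris).clean()
    assert m.n_vertices == 3  # duplicate merged, unreferenced dropped
    assert m.n_triangles == 2  # degenerate face dropped
    assert m.triangles.max() < m.n_vertices
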