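"""Alignment, correspondences, regularizers and non-rigid fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import craniofit as cf
from craniofit import mesh_core as mc
from craniofit import registration as rg
from craniofit import synthetic_anatomy as sa


def random_rotation(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


# ---------------------------------------------------------------------------
# similarity transforms
# ---------------------------------------------------------------------------


def test_similarity_identity_for_identical_sets():
    x = np.random.default_rng(0).normal(size=(12, 3))
    tf = rg.similarity_from_correspondences(x, x)
    assert tf.scale == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(tf.translation, 0, atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_similarity_recovers_known_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(10, 3))
    R = random_rotation(seed)
    s = float(rng.uniform(0.5, 2.0))
    t = rng.normal(size=3) * 5
    y = s * x @ R.T + t
    tf = rg.similarity_from_correspondences(x, y)
    assert np.abs(tf.apply(x) - y).max() < 1e-10
    assert tf.scale == pytest.approx(s, abs=1e-10)


def test_similarity_mirrored_target_stays_proper():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(15, 3))
    y = x.copy()
    y[:, 0] *= -1  # reflection
    tf = rg.similarity_from_correspondences(x, y)
    assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-10)
    assert np.abs(tf.apply(x) - y).max() > 0.1  # cannot be matched exactly


def test_similarity_collinear_degenerate():
    x = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(rg.DegenerateCorrespondences):
        rg.similarity_from_correspondences(x, x + 1.0)


# ---------------------------------------------------------------------------
# ICP and coarse alignment
# ---------------------------------------------------------------------------


def test_icp_identity_for_identical_clouds(templates2):
    pts = cf.PointSet(templates2.skull.vertices.copy())
    tf, trace = rg.icp(pts, cf.PointSet(pts.points.copy()), "similarity",
                       return_trace=True)
    assert trace[0] < 1e-20
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)


def test_icp_recovers_small_perturbation(templates2):
    v = templates2.skull.vertices
    R = random_rotation(5)
    # blend toward identity for a ~5 degree rotation
    from scipy.linalg import expm, logm

    R5 = expm(0.12 * np.real(logm(R)))
    moved = v @ R5.T + np.array([5.0, -2.0, 3.0])
    tf, trace = rg.icp(cf.PointSet(v), cf.PointSet(moved), "rigid", return_trace=True)
    assert np.abs(tf.apply(v) - moved).max() / np.abs(moved).max() < 1e-3
    assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))


def test_icp_objective_monotone_from_bad_start(templates2, subject2):
    tf, trace = rg.icp(
        cf.PointSet(templates2.skull.vertices),
        cf.PointSet(subject2.skull_surface.vertices + 8.0),
        "similarity",
        return_trace=True,
    )
    assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))


def _skull_cloud(templates):
    return cf.PointSet(templates.skull.boundary().vertices.copy())


def test_coarse_align_recovers_arbitrary_pose(templates2):
    src = _skull_cloud(templates2)
    R = random_rotation(77)
    dst = cf.PointSet(src.points @ R.T + np.array([40.0, -25.0, 60.0]))
    tf = rg.coarse_align(src, dst, seed=0)
    diag = dst.bounding_box_diagonal()
    rms = np.sqrt(np.mean(np.sum((tf.apply(src.points) - dst.points) ** 2, axis=1)))
    assert rms < 0.02 * diag


def test_coarse_align_near_identity_when_aligned(templates2):
    src = _skull_cloud(templates2)
    tf = rg.coarse_align(src, cf.PointSet(src.points.copy()), seed=0)
    rms = np.sqrt(np.mean(np.sum((tf.apply(src.points) - src.points) ** 2, axis=1)))
    assert rms < 0.02 * src.bounding_box_diagonal()


def test_coarse_align_cropped_target_within_icp_basin(templates2):
    # 25% of the cloud removed: after alignment + ICP the surviving overlap
    # must sit on the target (closest-point RMS inside the ICP basin); the
    # near-spherical synthetic shape leaves the absolute pose only weakly
    # identifiable, so the contract is surface RMS, not pose recovery
    from scipy.spatial import cKDTree

    src = _skull_cloud(templates2)
    R = random_rotation(33)
    moved = src.points @ R.T + np.array([30.0, 15.0, -20.0])
    keep = moved[:, 2] > np.quantile(moved[:, 2], 0.25)
    dst = cf.PointSet(moved[keep])
    tf = rg.coarse_align(src, dst, seed=0)
    tf = rg.icp(cf.PointSet(tf.apply(src.points)), dst, "similarity").compose(tf)
    d, _ = cKDTree(dst.points).query(tf.apply(src.points))
    k = int(0.7 * len(d))
    rms = np.sqrt(np.mean(np.sort(d)[:k] ** 2))
    assert rms <= 0.10 * dst.bounding_box_diagonal()


# ---------------------------------------------------------------------------
# hierarchical ICP and correspondence strategies
# ---------------------------------------------------------------------------


def test_hierarchical_icp_recovers_rigid_motion(templates2):
    surf = templates2.skull.boundary()
    R = random_rotation(9)
    from scipy.linalg import expm, logm

    R1 = expm(0.05 * np.real(logm(R)))
    target = cf.PointSet(surf.vertices @ R1.T + 1.0)
    cset = rg.hierarchical_icp(surf, target, depth=2)
    expected = surf.vertices @ R1.T + 1.0
    idx = cset.rows[:, 0]
    err = np.linalg.norm(cset.targets - expected[idx], axis=1)
    assert np.median(err) < 1e-6


def test_hierarchical_icp_depth_zero_is_global(templates2):
    surf = templates2.skull.boundary()
    target = cf.PointSet(surf.vertices.copy())
    cset = rg.hierarchical_icp(surf, target, depth=0)
    assert len(cset) == surf.n_vertices
    np.testing.assert_allclose(cset.targets, surf.vertices, atol=1e-9)


def test_find_correspondences_identical_meshes(templates2):
    surf = templates2.skull.boundary()
    for strategy in ("curvature_v2v", "two_way_v2s", "closest_point"):
        cset = rg.find_correspondences(surf, surf, strategy, 2.0, 60.0)
        assert len(cset) > 0
        pred = np.einsum("ck,cki->ci", cset.bary, surf.vertices[cset.rows])
        assert np.abs(pred - cset.targets).max() < 1e-9


def test_find_correspondences_flipped_normals_all_pruned(templates2):
    surf = templates2.head
    flipped = mc.SurfaceMesh(surf.vertices.copy(), surf.triangles[:, ::-1].copy())
    cset = rg.find_correspondences(surf, flipped, "closest_point", 2.0, 60.0)
    assert len(cset) == 0


def test_find_correspondences_distance_pruning_at_2mm(templates2):
    surf = templates2.head
    moved = surf.vertices.copy()
    moved[0] += 3.0 * mc.vertex_normals(surf)[0]  # one vertex 3 mm off
    target = mc.SurfaceMesh(moved, surf.triangles.copy())
    cset = rg.find_correspondences(target, surf, "closest_point", 2.0, 60.0)
    assert 0 not in set(cset.rows[:, 0])  # the displaced vertex is pruned
    assert len(cset) > 0.8 * surf.n_vertices


# ---------------------------------------------------------------------------
# regularizers
# ---------------------------------------------------------------------------


@settings(deadline=None, max_examples=10, derandomize=True)
@given(st.integers(0, 10_000))
def test_ereg_volume_zero_under_rigid_motion(templates2, seed):
    skull = templates2.skull
    R = random_rotation(seed)
    t = np.random.default_rng(seed).normal(size=3) * 10
    moved = skull.vertices @ R.T + t
    assert rg.ereg_volume(skull.tets, skull.vertices, moved) < 1e-12


def test_ereg_volume_unit_volume_tet_scaled_by_two():
    # tet with volume exactly 1: unit tet scaled by 6^(1/3)
    v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]) * 6 ** (1 / 3)
    tets = np.array([[0, 1, 2, 3]])
    assert mc.tet_volumes(v, tets)[0] == pytest.approx(1.0, rel=1e-12)
    assert rg.ereg_volume(tets, v, 2 * v) == pytest.approx((8 - 1) ** 2, rel=1e-9)


@settings(deadline=None, max_examples=10, derandomize=True)
@given(st.integers(0, 10_000))
def test_ereg_edge_laplacian_zero_under_rigid_motion(templates2, seed):
    head = templates2.head
    R = random_rotation(seed)
    t = np.random.default_rng(seed).normal(size=3) * 10
    moved = head.vertices @ R.T + t
    assert rg.ereg_edge_laplacian(head, head.vertices, moved) < 1e-10


def test_ereg_edge_laplacian_positive_under_scaling(templates2):
    head = templates2.head
    assert rg.ereg_edge_laplacian(head, head.vertices, 2.0 * head.vertices) > 1e-3
    assert rg.ereg_edge_laplacian(head, head.vertices, head.vertices) <= 1e-20


# ---------------------------------------------------------------------------
# non-rigid fitting
# ---------------------------------------------------------------------------


def test_skull_fit_fixed_point(templates2):
    fitted = rg.nonrigid_fit_skull(
        templates2.skull, templates2.skull.boundary(), rg.FitSchedule()
    )
    assert np.abs(fitted.vertices - templates2.skull.vertices).mean() < 1e-6


def test_skull_fit_energy_non_increasing_within_levels(templates2, subject2):
    _, trace = rg.nonrigid_fit_skull(
        templates2.skull, subject2.skull_surface, rg.FitSchedule(), return_trace=True
    )
    by_level = {}
    for entry in trace:
        by_level.setdefault(entry["level"], []).append(entry["energy"])
    for level, energies in by_level.items():
        assert all(
            b <= a + 1e-9 * max(abs(a), 1) for a, b in zip(energies, energies[1:])
        ), f"energy increased within level {level}"


def test_skull_fit_in_population_accuracy(templates3):
    basis = sa.make_mode_basis(templates3, 3)
    sub = sa.make_subject(templates3, basis, np.array([4.0, -2.5, 1.5]), seed=7)
    fitted = rg.nonrigid_fit_skull(templates3.skull, sub.skull_surface, rg.FitSchedule())
    facial = templates3.skull.vertex_groups["facial_region"]
    d = mc.surface_distances(fitted.boundary(), sub.skull_surface.vertices[facial])
    assert d.mean() <= 0.5


def test_skull_fit_missing_calvaria_completes(templates2, basis2):
    sub = sa.make_subject(templates2, basis2, np.array([3.0, -2.0, 1.0]), seed=19)
    # crop the calvaria off the target skull
    zmax = sub.skull_surface.vertices[:, 2].max()
    plane_z = zmax - 25.0
    # keep everything below the plane (normal points down: the calvaria is
    # on the negative side and gets removed)
    cropped = sa.crop_partial(sub.skull_surface, [0, 0, plane_z], [0, 0, -1])
    fitted = rg.nonrigid_fit_skull(templates2.skull, cropped, rg.FitSchedule())
    # complete output: same connectivity, calvaria present
    assert fitted.n_vertices == templates2.skull.n_vertices
    calv = templates2.skull.vertex_groups["calvaria"]
    # unobserved calvaria stays near the template prior (well under 2x the
    # template-to-subject deviation there)
    prior_dev = np.linalg.norm(
        sub.skull_tet.vertices[calv] - templates2.skull.vertices[calv], axis=1
    ).max()
    fitted_dev = np.linalg.norm(
        fitted.vertices[calv] - templates2.skull.vertices[calv], axis=1
    )
    assert fitted_dev.max() < 2.0 * max(prior_dev, 1.0)


def test_head_fit_fixed_point(templates2):
    target = templates2.head.as_pointset()
    fitted = rg.nonrigid_fit_head(templates2.head, target, schedule=rg.FitSchedule())
    assert rg.rms_error(fitted, target) < 1e-3


def test_head_fit_population_rms(templates2, population2):
    _, pop = population2
    rms = []
    for s in pop[:4]:
        scan = s.skin_surface.as_pointset()
        lm = [
            (i, s.skin_surface.vertices[i])
            for i in templates2.head.landmarks.values()
        ]
        fitted = rg.nonrigid_fit_head(
            templates2.head, scan, landmarks=lm, schedule=rg.FitSchedule()
        )
        rms.append(rg.rms_error(fitted, scan, prune_distance=2.0))
    assert np.mean(rms) <= 0.19


def test_head_fit_landmark_only_interpolates(templates2, basis2):
    sub = sa.make_subject(templates2, basis2, np.array([2.0, 1.0, -0.5]), seed=23)
    lm = [
        (int(i), sub.skin_surface.vertices[int(i)])
        for k, i in templates2.head.landmarks.items()
    ]
    # prune distance zero suppresses every closest-point correspondence,
    # leaving a landmark-only fit
    fitted = rg.nonrigid_fit_head(
        templates2.head,
        sub.skin_surface.as_pointset(),
        landmarks=lm,
        schedule=rg.FitSchedule(prune_distances=0.0),
    )
    idx = np.array([i for i, _ in lm])
    pts = np.array([p for _, p in lm])
    err = np.linalg.norm(fitted.vertices[idx] - pts, axis=1)
    assert err.max() < 0.1


def test_softer_regularization_never_increases_final_efit(templates2, subject2):
    target = subject2.skin_surface.as_pointset()
    efits = []
    for lambdas in [(100.0, 20.0), (100.0, 20.0, 4.0, 0.8)]:
        fitted, trace = rg.nonrigid_fit_head(
            templates2.head, target,
            schedule=rg.FitSchedule(lambdas=lambdas), return_trace=True,
        )
        efits.append(trace[-1]["efit"])
    assert efits[1] <= efits[0] + 1e-9


def test_rms_error_identical_zero(templates2):
    target = templates2.head.as_pointset()
    assert rg.rms_error(templates2.head, target) < 1e-12


def test_rms_error_constant_offset(templates2):
    head = templates2.head
    offset = head.with_vertices(head.vertices + mc.vertex_normals(head) * 1.0)
    rms = rg.rms_error(offset, head.as_pointset(), prune_distance=2.0)
    assert rms == pytest.approx(1.0, abs=0.06)


def test_rms_error_half_offset_hand_computed():
    # flat strip: half the scan points offset 1 mm, half exact -> sqrt(0.5)
    xs = np.arange(10.0)
    verts = np.concatenate(
        [np.column_stack([xs, np.zeros(10), np.zeros(10)]),
         np.column_stack([xs, np.ones(10), np.zeros(10)])]
    )
    tris = []
    for i in range(9):
        tris += [[i, i + 1, i + 10], [i + 1, i + 11, i + 10]]
    strip = mc.SurfaceMesh(verts, np.array(tris))
    scan = verts.copy()
    scan[:10, 2] += 1.0  # half the points 1 mm above the surface
    rms = rg.rms_error(strip, cf.PointSet(scan), prune_distance=2.0,
                       prune_normal_angle=180.0)
    assert rms == pytest.approx(np.sqrt(0.5), abs=1e-6)


def test_fit_schedule_yaml_round_trip(tmp_path):
    import yaml

    sched = rg.FitSchedule(lambdas=(10.0, 2.0, 0.4), inner_iterations=2,
                           prune_distances=(8.0, 4.0, 2.0), landmark_weight=5.0)
    path = tmp_path / "schedule.yaml"
    path.write_text(yaml.safe_dump(sched.to_dict()))
    back = rg.FitSchedule.from_dict(yaml.safe_load(path.read_text()))
    assert back.to_dict() == sched.to_dict()


def test_energy_trace_csv(tmp_path, templates2, subject2):
    _, trace = rg.nonrigid_fit_skull(
        templates2.skull, subject2.skull_surface,
        rg.FitSchedule(lambdas=(50.0, 5.0), inner_iterations=2),
        return_trace=True,
    )
    path = str(tmp_path / "trace.csv")
    rg.write_energy_trace(trace, path)
    import csv

    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    assert len(rows) == len(trace)
    assert float(rows[0]["lambda"]) == 50.0
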