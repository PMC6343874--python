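"""End-to-end reconstruction: skull fitting, sphere model, head fitting."""

import numpy as np
import pytest

import craniofit as cf
from craniofit import mesh_core as mc
from craniofit import reconstruction as rc
from craniofit import synthetic_anatomy as sa


# ---------------------------------------------------------------------------
# outside-weight rule
# ---------------------------------------------------------------------------


def test_outside_weight_zero_distance():
    assert rc.outside_weight([1, 1, 1], [1, 1, 1], [0, 0, 1], 100.0) == 1.0


def test_outside_weight_interior_point():
    # q on the inner side of the surface point (n . (q - h) < 0)
    assert rc.outside_weight([0, 0, 0], [0, 0, -1], [0, 0, 1], 100.0) == 1.0


def test_outside_weight_exterior_formula():
    B = 50.0
    w = rc.outside_weight([0, 0, 0], [0, 0, B], [0, 0, 1], B)
    assert w == pytest.approx(1.0 + 1e8)


def test_outside_weights_vectorized_matches_scalar():
    rng = np.random.default_rng(0)
    feet = rng.normal(size=(20, 3))
    targets = rng.normal(size=(20, 3))
    normals = rng.normal(size=(20, 3))
    normals /= np.linalg.norm(normals, axis=1)[:, None]
    B = 77.0
    vec = rc.outside_weights(feet, targets, normals, B)
    for i in range(20):
        assert vec[i] == pytest.approx(
            rc.outside_weight(feet[i], targets[i], normals[i], B)
        )


# ---------------------------------------------------------------------------
# thickness attachment and landmark projection
# ---------------------------------------------------------------------------


def test_attach_fstt_mean_statistic(templates2, models2, config2):
    stat = models2["statistic"]
    sphere = rc.attach_fstt(templates2.skull, stat, config2)
    active = sphere.active_mask
    np.testing.assert_allclose(sphere.radii[active], stat.mean[active])


def test_attach_fstt_model_zero_weights_equals_mean(templates2, models2, config2):
    model = models2["fstt_model"]
    a = rc.attach_fstt(templates2.skull, model, config2, fstt_weights=np.zeros(model.n_components))
    b = rc.attach_fstt(templates2.skull, model, config2, fstt_weights=None)
    np.testing.assert_allclose(
        a.radii[a.active_mask], b.radii[b.active_mask], atol=1e-12
    )


def test_attach_fstt_explicit_vector(templates2, subject2, config2):
    sphere = rc.attach_fstt(subject2.skull_tet, subject2.true_fstt, config2)
    np.testing.assert_allclose(sphere.radii, subject2.true_fstt)


def test_project_landmarks_zero_radius(templates2, config2):
    radii = np.zeros(templates2.skull.n_vertices)
    radii[:] = 1e-12
    sphere = cf.build_sphere_model(templates2.skull, np.maximum(radii, 1e-12))
    # a vanishing radius projects the landmark onto (essentially) itself
    out = rc.project_landmarks(templates2.skull, sphere)
    for name, idx in config2.reconstruction_landmarks().items():
        np.testing.assert_allclose(
            out[name], templates2.skull.vertices[idx], atol=1e-6
        )


def test_project_landmarks_spherical_constant_fstt():
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=3, radius=40.0)
    # build a thin two-shell tet "skull" from the sphere for landmark support
    tp = sa.make_template_pair(subdivisions=2, outer_radius=40.0, shell_thickness=4.0)
    skull = tp.skull
    r = 6.0
    sphere = cf.build_sphere_model(skull, np.full(skull.n_vertices, r))
    out = rc.project_landmarks(skull, sphere)
    for name, idx in tp.skull.landmarks.items():
        if name.startswith("facial_"):
            continue
        v = skull.vertices[idx]
        p = out[name]
        # moved outward by ~r (up to sphere-sample snap distance)
        assert np.linalg.norm(p - v) == pytest.approx(r, abs=1.0)
        assert np.linalg.norm(p) > np.linalg.norm(v)


def test_project_landmarks_reach_true_skin(templates2, subject2, config2):
    sphere = rc.attach_fstt(subject2.skull_tet, subject2.true_fstt, config2)
    out = rc.project_landmarks(subject2.skull_tet, sphere)
    spacing = subject2.true_fstt.mean() * np.sqrt(4 * np.pi / config2.samples_per_sphere)
    for name, p in out.items():
        d = mc.surface_distances(subject2.skin_surface, p.reshape(1, 3))[0]
        assert d < spacing + 1.0


# ---------------------------------------------------------------------------
# skull fitting to remains
# ---------------------------------------------------------------------------


def test_fit_skull_to_remains_in_model_space(templates2, models2, config2):
    model = models2["skull_model"]
    w_true = 0.8 * model.sigmas
    synth = model.synthesize(w_true).reshape(-1, 3)
    remains = templates2.skull.with_vertices(synth).boundary()
    fitted, weights = rc.fit_skull_to_remains(model, remains, config2)
    d = mc.surface_distances(fitted.boundary(), remains.vertices)
    assert d.mean() <= 0.5
    # leading-component weights recovered
    lead = model.sigmas > 0.2 * model.sigmas[0]
    np.testing.assert_allclose(
        weights[lead], w_true[lead], atol=0.05 * model.sigmas[lead].max()
    )


def test_fit_skull_to_mean_remains_zero_weights(templates2, models2, config2):
    model = models2["skull_model"]
    remains = templates2.skull.with_vertices(model.mean.reshape(-1, 3)).boundary()
    _, weights = rc.fit_skull_to_remains(model, remains, config2)
    assert np.abs(weights / np.maximum(model.sigmas, 1e-9)).max() < 0.2


def test_fit_skull_partial_remains_is_complete(templates2, models2, config2, basis2):
    # partial remains still yield a complete skull on the template
    # connectivity; the paired accuracy comparison runs at study
    # resolution in the acceptance suite
    model = models2["skull_model"]
    sub = sa.make_subject(templates2, basis2, np.array([3.0, -1.5, 1.0]), seed=55)
    full = sub.skull_surface
    zmax = full.vertices[:, 2].max()
    cropped = sa.crop_partial(full, [0, 0, zmax - 18.0], [0, 0, -1])
    fitted_part, _ = rc.fit_skull_to_remains(model, cropped, config2)
    assert fitted_part.n_vertices == templates2.skull.n_vertices
    assert fitted_part.volumes().min() > 0
    # the unobserved calvaria stays near the statistical prior
    calv = templates2.skull.vertex_groups["calvaria"]
    dev = np.linalg.norm(
        fitted_part.vertices[calv] - templates2.skull.vertices[calv], axis=1
    )
    prior = np.linalg.norm(
        sub.skull_tet.vertices[calv] - templates2.skull.vertices[calv], axis=1
    ).max()
    assert dev.max() < 3.0 * max(prior, 1.0)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def held_subject(templates2, basis2):
    return sa.make_subject(templates2, basis2, np.array([-3.0, 2.0, -1.0]), seed=1234)


@pytest.fixture(scope="module")
def light_config(templates2):
    """Reduced sphere sampling and a short head schedule: keeps the many
    end-to-end runs in this module fast while exercising the same code."""
    return cf.ReconstructionConfig(
        skull_template=templates2.skull,
        head_template=templates2.head,
        samples_per_sphere=24,
        head_schedule=cf.FitSchedule(
            n_levels=4, inner_iterations=2,
            prune_distances=1e12, prune_normal_angle=180.0,
        ),
        seed=0,
    )


@pytest.fixture(scope="module")
def recon_true(templates2, models2, light_config, held_subject):
    return rc.reconstruct(
        held_subject.skull_surface, models2["skull_model"], models2["head_model"],
        held_subject.true_fstt, light_config,
    )


def test_reconstruct_with_true_fstt(templates2, recon_true, held_subject):
    res = recon_true
    rmse = rc.head_rmse(res.fitted_head, held_subject.skin_surface)
    # coarse-template smoke bound; the acceptance suite enforces the
    # study-resolution threshold
    assert rmse < 1.5
    assert res.fitted_head.n_vertices == templates2.head.n_vertices
    assert "config" in res.provenance and "skull_energy_trace" in res.provenance


def test_reconstruct_deterministic(models2, light_config, held_subject, recon_true):
    b = rc.reconstruct(
        held_subject.skull_surface, models2["skull_model"], models2["head_model"],
        held_subject.true_fstt, light_config,
    )
    np.testing.assert_array_equal(recon_true.fitted_head.vertices, b.fitted_head.vertices)
    np.testing.assert_array_equal(recon_true.fitted_skull.vertices, b.fitted_skull.vertices)


def test_reconstruct_mean_fstt_worse_than_true(templates2, models2, held_subject):
    # full sphere sampling: the coarse light_config envelope floor would
    # mask the thickness difference this property is about
    config = cf.ReconstructionConfig(
        skull_template=templates2.skull,
        head_template=templates2.head,
        head_schedule=cf.FitSchedule(
            n_levels=4, inner_iterations=2,
            prune_distances=1e12, prune_normal_angle=180.0,
        ),
        seed=0,
    )
    res_true = rc.reconstruct(
        held_subject.skull_surface, models2["skull_model"], models2["head_model"],
        held_subject.true_fstt, config,
    )
    res_mean = rc.reconstruct(
        held_subject.skull_surface, models2["skull_model"], models2["head_model"],
        models2["statistic"], config,
    )
    r_true = rc.head_rmse(res_true.fitted_head, held_subject.skin_surface)
    r_mean = rc.head_rmse(res_mean.fitted_head, held_subject.skin_surface)
    assert r_true < r_mean


def test_generate_variants_grid(models2, light_config, held_subject):
    fitted, _ = rc.fit_skull_to_remains(
        models2["skull_model"], held_subject.skull_surface, light_config
    )
    grid = {0: (-2.0, 0.0, 2.0), 1: (-2.0, 0.0, 2.0)}
    variants = rc.generate_variants(
        fitted, models2["fstt_model"], grid, models2["head_model"], light_config
    )
    assert len(variants) == 9
    # the gamma = 0 grid point equals the mean-thickness reconstruction
    center = next(v for v in variants if all(f == 0 for f in v["factors"].values()))
    sphere_mean = rc.attach_fstt(fitted, models2["fstt_model"], light_config)
    np.testing.assert_allclose(
        center["sphere_model"].radii[center["sphere_model"].active_mask],
        sphere_mean.radii[sphere_mean.active_mask],
        atol=1e-12,
    )
    # determinism: one regenerated grid point matches bit for bit
    again = rc.generate_variants(
        fitted, models2["fstt_model"], {0: (-2.0,), 1: (-2.0,)},
        models2["head_model"], light_config,
    )
    np.testing.assert_array_equal(
        variants[0]["head"].vertices, again[0]["head"].vertices
    )


def test_reconstruct_stage_error_is_labelled(templates2, models2, config2):
    with pytest.raises(cf.MeshError, match="skull-fitting stage"):
        rc.reconstruct(
            cf.PointSet(np.zeros((0, 3))),
            models2["skull_model"],
            models2["head_model"],
            models2["statistic"],
            config2,
        )
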