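"""Automatic craniofacial reconstruction from skull remains.

Pipeline: (1) fit the parametric skull model to the (possibly partial)
remains — coarse alignment, alternating closed-form similarity / Tikhonov
PCA fitting, then non-rigid refinement with the volume-preservation energy;
(2) attach soft-tissue thickness to the fitted skull as a sphere model
(mean statistic, a parametric FSTT model instance, or an explicit
per-vertex vector); (3) project the skull landmarks through the local
thickness onto the sphere model and fit the parametric head model to the
sphere-model samples, weighting points on the outer envelope far more than
interior points, so the fitted surface tracks the envelope (the skin
approximation) while nose/ears/calvaria are filled by the model prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fstt_stats import FSTTStatistic, SphereModel, build_sphere_model
from .mesh_core import MeshError, PointSet, SurfaceMesh, TetMesh, _SurfaceLocator, vertex_normals
from .registration import (
    FitSchedule,
    SimilarityTransform,
    coarse_align,
    icp,
    nonrigid_fit_head,
    nonrigid_fit_skull,
)
from .shape_model import ShapeModel, fit_pca_weights, synthesize

__all__ = [
    "ReconstructionConfig",
    "ReconstructionResult",
    "fit_skull_to_remains",
    "attach_fstt",
    "project_landmarks",
    "outside_weight",
    "outside_weights",
    "fit_head_to_sphere_model",
    "generate_variants",
    "reconstruct",
    "head_rmse",
]


@dataclass
class ReconstructionConfig:
    """Templates, regularization weights and schedules for reconstruction.

    ``skull_template`` / ``head_template`` provide the connectivity and
    landmark indices behind the stacked model vectors.  The Tikhonov
    weights default to 1e-3 for skull-model fitting and 1e-4 for head-model
    fitting; sphere sampling is deterministic (Fibonacci spiral), and all
    remaining randomness (coarse alignment RANSAC) derives from ``seed``.
    """

    skull_template: TetMesh
    head_template: SurfaceMesh
    lambda_tik_skull: float = 1e-3
    lambda_tik_head: float = 1e-4
    skull_schedule: FitSchedule | None = None
    head_schedule: FitSchedule | None = None
    samples_per_sphere: int = 64
    active_min_fraction: float = 0.5
    landmark_weight: float = 10.0
    coarse_align: bool = False
    seed: int = 0

    def resolved_skull_schedule(self) -> FitSchedule:
        return self.skull_schedule or FitSchedule(seed=self.seed)

    def resolved_head_schedule(self) -> FitSchedule:
        # sphere-model targets: no distance/normal pruning (interior points
        # are legitimate, just low-weight); the outside rule does the work
        return self.head_schedule or FitSchedule(
            prune_distances=1e12, prune_normal_angle=180.0, seed=self.seed
        )

    def reconstruction_landmarks(self) -> dict:
        return {
            k: int(v)
            for k, v in self.skull_template.landmarks.items()
            if not k.startswith("facial_")
        }

    def to_manifest(self) -> dict:
        return {
            "lambda_tik_skull": self.lambda_tik_skull,
            "lambda_tik_head": self.lambda_tik_head,
            "skull_schedule": self.resolved_skull_schedule().to_dict(),
            "head_schedule": self.resolved_head_schedule().to_dict(),
            "samples_per_sphere": self.samples_per_sphere,
            "active_min_fraction": self.active_min_fraction,
            "landmark_weight": self.landmark_weight,
            "coarse_align": self.coarse_align,
            "seed": self.seed,
        }


@dataclass
class ReconstructionResult:
    """All artifacts of one reconstruction run.

    ``provenance`` (config manifest, seed, energy traces) suffices to re-run
    the reconstruction bit-identically; all meshes share the world frame of
    the input skull remains.
    """

    fitted_skull: TetMesh
    sphere_model: SphereModel
    fitted_head: SurfaceMesh
    skull_weights: np.ndarray
    head_weights: np.ndarray
    fstt_weights: np.ndarray | None
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage 1: skull fitting
# ---------------------------------------------------------------------------


def fit_skull_to_remains(
    skull_model: ShapeModel,
    remains,
    config: ReconstructionConfig,
    return_trace: bool = False,
):
    """Fit the parametric skull model to skull remains; complete even for
    partial input.

    Alternates closed-form similarity alignment with Tikhonov-regularized
    PCA weight fitting (starting from the mean skull), then refines
    non-rigidly with the volume-preservation energy using the synthesized
    skull as template, so unobserved regions stay on the statistical prior.
    """
    pts = remains.points if isinstance(remains, PointSet) else (
        remains.vertices if hasattr(remains, "vertices") else np.asarray(remains, float)
    )
    if not len(pts):
        raise MeshError("empty remains")
    target_ps = PointSet(pts.copy())

    pre = SimilarityTransform.identity()
    if config.coarse_align:
        mean_skull = PointSet(skull_model.mean.reshape(-1, 3))
        pre = coarse_align(mean_skull, target_ps, seed=config.seed)
        pre = icp(PointSet(pre.apply(mean_skull.points)), target_ps, "similarity").compose(pre)

    # alternate alignment + PCA shape; far matches are pruned and points on
    # a partial scan's cut boundary are excluded so that unobserved regions
    # do not bias alignment or shape
    from .registration import _target_boundary_filter

    bmask = None
    if isinstance(remains, SurfaceMesh):
        fltr = _target_boundary_filter(remains)
        if fltr is not None:
            bmask = fltr(target_ps.points)
    prune = 0.15 * target_ps.bounding_box_diagonal()
    fit = skull_model.fit(
        target_ps, lambda_tik=config.lambda_tik_skull, prune_distance=prune,
        target_point_mask=bmask, direction="target_to_model",
    )
    fit_tf = fit.transform.compose(pre) if config.coarse_align else fit.transform
    # plausibility safeguard: clip weights to +-3 sigma and shrink further if
    # the synthesized instance inverts any tetrahedron (it must serve as the
    # rest state of the volumetric refinement)
    from .mesh_core import tet_volumes

    sig = np.maximum(skull_model.sigmas, 1e-12)
    weights = np.clip(fit.weights, -3.0 * sig, 3.0 * sig)
    for _ in range(8):
        synth = synthesize(skull_model, weights).reshape(-1, 3)
        if tet_volumes(synth, config.skull_template.tets).min() > 0:
            break
        weights = 0.5 * weights
    else:
        synth = skull_model.mean.reshape(-1, 3)
        weights = np.zeros_like(weights)
    start = fit.transform.apply(synth)

    template = config.skull_template.with_vertices(start)
    target = remains if isinstance(remains, (SurfaceMesh, PointSet)) else target_ps
    out = nonrigid_fit_skull(
        template, target, config.resolved_skull_schedule(), return_trace=return_trace
    )
    if return_trace:
        fitted, trace = out
        return fitted, weights, trace
    return out, weights


# ---------------------------------------------------------------------------
# stage 2: thickness attachment
# ---------------------------------------------------------------------------


def attach_fstt(
    fitted_skull: TetMesh,
    fstt_source,
    config: ReconstructionConfig,
    fstt_weights: np.ndarray | None = None,
) -> SphereModel:
    """Build the sphere model for a fitted skull from a thickness source.

    ``fstt_source`` may be an :class:`FSTTStatistic` (its mean is used, on
    the calvaria-excluding active mask), a masked thickness
    :class:`ShapeModel` (evaluated at ``fstt_weights``), or an explicit
    per-vertex vector.
    """
    n = fitted_skull.n_vertices
    if isinstance(fstt_source, FSTTStatistic):
        radii = np.asarray(fstt_source.mean, float).copy()
        mask = fstt_source.active_mask(config.active_min_fraction)
    elif isinstance(fstt_source, ShapeModel):
        values = synthesize(fstt_source, fstt_weights)
        if fstt_source.vertex_mask is not None:
            radii = np.full(n, np.nan)
            radii[np.asarray(fstt_source.vertex_mask, bool)] = values
            mask = np.asarray(fstt_source.vertex_mask, bool).copy()
        else:
            radii = values
            mask = np.ones(n, bool)
    else:
        radii = np.asarray(fstt_source, float).ravel()
        mask = np.isfinite(radii)
    if len(radii) != n:
        raise MeshError("thickness vector length must match skull vertex count")
    return build_sphere_model(fitted_skull, radii, mask, config.samples_per_sphere)


def project_landmarks(
    fitted_skull: TetMesh,
    sphere_model: SphereModel,
    landmark_names: dict | None = None,
) -> dict:
    """Project skull landmarks outward through the local thickness.

    Each landmark vertex moves along its outward surface normal by the
    local sphere radius and snaps to the nearest sphere-model sample, so
    the projected point lies exactly on the sphere model.  Landmarks on
    inactive vertices borrow the nearest active vertex (with a warning).
    """
    lms = landmark_names or {
        k: int(v) for k, v in fitted_skull.landmarks.items() if not k.startswith("facial_")
    }
    boundary = fitted_skull.boundary()
    normals = vertex_normals(boundary)
    samples = sphere_model.samples.points
    out = {}
    active = np.where(sphere_model.active_mask)[0]
    if not len(active):
        raise MeshError("sphere model has no active vertices")
    from scipy.spatial import cKDTree

    sample_tree = cKDTree(samples) if len(samples) else None
    for name, idx in lms.items():
        v = int(idx)
        if not sphere_model.active_mask[v]:
            near = active[
                np.argmin(np.linalg.norm(fitted_skull.vertices[active] - fitted_skull.vertices[v], axis=1))
            ]
            warnings.warn(f"landmark {name!r} on inactive vertex; using nearest active vertex")
            v = int(near)
        r = float(sphere_model.radii[v])
        p = fitted_skull.vertices[v] + normals[v] * r
        if sample_tree is not None and r > 0:
            _, j = sample_tree.query(p)
            p = samples[j]
        out[name] = p
    return out


# ---------------------------------------------------------------------------
# stage 3: head fitting with outside-weighting
# ---------------------------------------------------------------------------


def outside_weight(h, q, n, B: float) -> float:
    """Per-correspondence weight of a sphere-model point.

    If ``q`` lies on the outer side of the template surface point ``h``
    (n . (q - h) >= 0) the weight is 1 + 1e8 * ||h - q|| / B with B the
    bounding-box size of the model; interior points keep weight 1.  Points
    on the outer envelope thereby dominate the fit.
    """
    h = np.asarray(h, float)
    q = np.asarray(q, float)
    n = np.asarray(n, float)
    if float(n @ (q - h)) >= 0.0:
        return 1.0 + 1e8 * float(np.linalg.norm(h - q)) / B
    return 1.0


def outside_weights(feet: np.ndarray, targets: np.ndarray, normals: np.ndarray, B: float) -> np.ndarray:
    """Vectorized outside-weight rule (see :func:`outside_weight`)."""
    d = np.linalg.norm(feet - targets, axis=1)
    outside = np.einsum("ij,ij->i", normals, targets - feet) >= 0.0
    return np.where(outside, 1.0 + 1e8 * d / B, 1.0)


def fit_head_to_sphere_model(
    head_model: ShapeModel,
    sphere_model: SphereModel,
    projected_landmarks: dict,
    config: ReconstructionConfig,
    return_trace: bool = False,
):
    """Fit the parametric head model to an (under-specified) sphere model.

    Landmark pairs initialize similarity alignment and PCA weights; the
    fine non-rigid fit then uses the outside-weight rule (recomputed from
    current template normals each correspondence round) so the outer
    envelope of the spheres — the skin approximation — dominates, while
    regions without sphere support (nose, ears, calvaria) are completed by
    the head-model prior.
    """
    head_template = config.head_template
    lm_idx = []
    lm_pts = []
    for name, p in projected_landmarks.items():
        if name in head_template.landmarks:
            lm_idx.append(int(head_template.landmarks[name]))
            lm_pts.append(np.asarray(p, float))
    if len(lm_idx) < 3:
        raise MeshError("need >= 3 projected landmarks on the head template")
    lm_idx = np.asarray(lm_idx, np.int64)
    lm_pts = np.asarray(lm_pts, float)

    # landmark-only similarity + PCA initialization, alternated
    from .registration import similarity_from_correspondences

    n_v = len(head_model.mean) // 3
    weights = np.zeros(head_model.n_components)
    tf = SimilarityTransform.identity()
    rows = (3 * lm_idx[:, None] + np.arange(3)[None, :]).reshape(-1)
    prev_obj = None
    for _ in range(50):
        shape = synthesize(head_model, weights).reshape(n_v, 3)
        obj = float(np.mean(np.sum((tf.apply(shape[lm_idx]) - lm_pts) ** 2, axis=1)))
        if prev_obj is not None and abs(prev_obj - obj) < 1e-6 * max(prev_obj, 1e-300):
            break
        prev_obj = obj
        tf = similarity_from_correspondences(shape[lm_idx], lm_pts)
        local = tf.inverse().apply(lm_pts)
        weights = fit_pca_weights(
            head_model, rows, local.reshape(-1), lambda_tik=config.lambda_tik_head
        )
        # ten landmarks cannot determine the full weight vector; keep the
        # initialization statistically plausible
        sig = np.maximum(head_model.sigmas, 1e-12)
        weights = np.clip(weights, -2.0 * sig, 2.0 * sig)
    init = tf.apply(synthesize(head_model, weights).reshape(n_v, 3))
    template = head_template.with_vertices(init)

    B = max(sphere_model.samples.bounding_box_diagonal(), 1e-9)
    landmarks = [(int(i), p) for i, p in zip(lm_idx, lm_pts)]
    schedule = config.resolved_head_schedule()
    out = nonrigid_fit_head(
        template,
        PointSet(sphere_model.samples.points.copy()),
        landmarks=landmarks,
        schedule=schedule,
        dynamic_weight=lambda feet, targets, normals: outside_weights(
            feet, targets, normals, B
        ),
        return_trace=return_trace,
    )
    if return_trace:
        fitted, trace = out
        return fitted, weights, trace
    return out, weights


# ---------------------------------------------------------------------------
# variants and the full pipeline
# ---------------------------------------------------------------------------


def generate_variants(
    fitted_skull: TetMesh,
    fstt_model: ShapeModel,
    weight_grid: dict,
    head_model: ShapeModel,
    config: ReconstructionConfig,
) -> list[dict]:
    """Plausible head variants over a grid of FSTT-model weights.

    ``weight_grid`` maps component index -> iterable of sigma multiples
    (e.g. ``{0: (-2, 0, 2), 1: (-2, 0, 2)}``); each grid point evaluates
    the thickness model at gamma_k = c_k * sigma_k, builds the (partial)
    sphere model and fits the head.  Deterministic given the config.
    """
    import itertools

    comps = sorted(weight_grid)
    sig = fstt_model.sigmas
    out = []
    for factors in itertools.product(*(weight_grid[c] for c in comps)):
        gamma = np.zeros(fstt_model.n_components)
        for c, f in zip(comps, factors):
            gamma[c] = f * sig[c]
        sphere = attach_fstt(fitted_skull, fstt_model, config, fstt_weights=gamma)
        lms = project_landmarks(fitted_skull, sphere)
        head, head_w = fit_head_to_sphere_model(head_model, sphere, lms, config)
        out.append(
            {"factors": dict(zip(comps, factors)), "gamma": gamma,
             "sphere_model": sphere, "head": head, "head_weights": head_w}
        )
    return out


def reconstruct(
    remains,
    skull_model: ShapeModel,
    head_model: ShapeModel,
    fstt_source,
    config: ReconstructionConfig,
    fstt_weights: np.ndarray | None = None,
) -> ReconstructionResult:
    """Run the three reconstruction stages on skull remains.

    Returns all intermediates plus a provenance manifest (config, seed,
    energy traces) from which the run can be repeated bit-identically.
    Stage failures propagate with the stage name attached.
    """
    try:
        fitted_skull, skull_w, skull_trace = fit_skull_to_remains(
            skull_model, remains, config, return_trace=True
        )
    except Exception as exc:
        raise MeshError(f"skull-fitting stage failed: {exc}") from exc
    try:
        sphere = attach_fstt(fitted_skull, fstt_source, config, fstt_weights)
        lms = project_landmarks(fitted_skull, sphere)
    except Exception as exc:
        raise MeshError(f"thickness stage failed: {exc}") from exc
    try:
        fitted_head, head_w, head_trace = fit_head_to_sphere_model(
            head_model, sphere, lms, config, return_trace=True
        )
    except Exception as exc:
        raise MeshError(f"head-fitting stage failed: {exc}") from exc
    return ReconstructionResult(
        fitted_skull=fitted_skull,
        sphere_model=sphere,
        fitted_head=fitted_head,
        skull_weights=skull_w,
        head_weights=head_w,
        fstt_weights=None if fstt_weights is None else np.asarray(fstt_weights, float),
        provenance={
            "config": config.to_manifest(),
            "skull_energy_trace": skull_trace,
            "head_energy_trace": head_trace,
            "projected_landmarks": {k: [float(x) for x in v] for k, v in lms.items()},
        },
    )


def head_rmse(fitted_head: SurfaceMesh, true_skin: SurfaceMesh) -> float:
    """RMS distance from fitted-head vertices to the true skin surface."""
    d = _SurfaceLocator(true_skin).query(fitted_head.vertices)[1]
    return float(np.sqrt(np.mean(d**2)))
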