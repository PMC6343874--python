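"""Model-generation workflows: from corresponding scans to parametric models.

These functions chain the registration and statistics layers the way a
model-building study does: fit the skull/head template to every subject,
stack the fitted vertex coordinates, run PCA; measure per-vertex soft-tissue
thickness between corresponding fitted skulls and skin surfaces, mask it by
data support, and aggregate.  The head-model construction supports the
bootstrap used for cropped clinical scans: a preliminary PCA model built
from complete scans constrains the fit to incomplete scans, filling the
missing regions statistically before the final PCA.
"""

from __future__ import annotations

import numpy as np

from .fstt_stats import FSTTStatistic, aggregate, measure_fstt, validity_mask
from .mesh_core import PointSet, SurfaceMesh, TetMesh
from .registration import FitSchedule, nonrigid_fit_head, nonrigid_fit_skull
from .shape_model import ShapeModel, build_pca, synthesize

__all__ = [
    "fit_skull_population",
    "fit_head_population",
    "fit_head_with_model",
    "build_skull_model",
    "build_head_model",
    "build_fstt_statistic",
]


def fit_skull_population(
    template: TetMesh,
    skull_surfaces,
    schedule: FitSchedule | None = None,
) -> list[TetMesh]:
    """Fit the tetrahedral skull template to each extracted skull surface."""
    return [
        nonrigid_fit_skull(template, target, schedule or FitSchedule())
        for target in skull_surfaces
    ]


def _scan_landmark_pairs(template: SurfaceMesh, landmark_points: dict | None):
    if not landmark_points:
        return None
    pairs = []
    for name, p in landmark_points.items():
        if name in template.landmarks:
            pairs.append((int(template.landmarks[name]), np.asarray(p, float)))
    return pairs or None


def fit_head_population(
    template: SurfaceMesh,
    scans,
    landmark_points: list | None = None,
    schedule: FitSchedule | None = None,
) -> list[SurfaceMesh]:
    """Fit the surface head template to each head scan.

    ``landmark_points`` optionally gives one dict (landmark name -> 3D
    point on the scan) per scan; landmarks get elevated weight in the fit.
    """
    fitted = []
    for i, scan in enumerate(scans):
        lp = landmark_points[i] if landmark_points else None
        fitted.append(
            nonrigid_fit_head(
                template,
                scan,
                landmarks=_scan_landmark_pairs(template, lp),
                schedule=schedule or FitSchedule(),
            )
        )
    return fitted


def fit_head_with_model(
    model: ShapeModel,
    template: SurfaceMesh,
    scan,
    landmark_points: dict | None = None,
    schedule: FitSchedule | None = None,
    lambda_tik: float = 1e-4,
    prune_distance: float | None = None,
) -> SurfaceMesh:
    """Model-constrained head fit for incomplete scans.

    The preliminary PCA model is first fitted to the scan (alternating
    similarity and Tikhonov-regularized weights, with distance pruning so
    missing regions exert no pull); the synthesized instance then seeds the
    non-rigid refinement, whose pruning leaves the unobserved regions on
    the statistical prior.
    """
    pts = scan.points if isinstance(scan, PointSet) else (
        scan.vertices if hasattr(scan, "vertices") else np.asarray(scan, float)
    )
    target = PointSet(np.asarray(pts, float).copy())
    if prune_distance is None:
        prune_distance = 0.1 * target.bounding_box_diagonal()
    fit = model.fit(target, lambda_tik=lambda_tik, prune_distance=prune_distance,
                    direction="target_to_model")
    init = fit.transform.apply(synthesize(model, fit.weights).reshape(-1, 3))
    return nonrigid_fit_head(
        template.with_vertices(init),
        target,
        landmarks=_scan_landmark_pairs(template, landmark_points),
        schedule=schedule or FitSchedule(),
    )


def build_skull_model(fitted_skulls, d: int | None = None) -> ShapeModel:
    """PCA over stacked vertex coordinates of fitted skull templates.

    Keeps all p-1 components by default (p = number of training skulls).
    """
    X = [f.vertices.reshape(-1) for f in fitted_skulls]
    model = build_pca(X, d)
    model.metadata["kind"] = "skull"
    model.metadata["n_training"] = len(X)
    return model


def build_head_model(fitted_heads, d: int = 30) -> ShapeModel:
    """PCA over stacked vertex coordinates of fitted head templates.

    ``d`` caps the retained components (30 by default; automatically
    limited to n-1 for small populations).
    """
    X = [f.vertices.reshape(-1) for f in fitted_heads]
    model = build_pca(X, d)
    model.metadata["kind"] = "head"
    model.metadata["n_training"] = len(X)
    return model


def build_fstt_statistic(
    fitted_skulls,
    skins,
    extracted_skulls=None,
    threshold: float = 2.0,
    population_std: bool = True,
):
    """Dense thickness statistic from corresponding fitted skulls and skins.

    Returns ``(statistic, per_subject)`` where ``per_subject`` is the list
    of (distances, validity mask) pairs that also feeds the parametric
    thickness model.  ``extracted_skulls`` (the raw partial skull surfaces)
    drive the 2 mm validity masking; without them every vertex is valid.
    """
    per_subject = []
    for i, (fitted, skin) in enumerate(zip(fitted_skulls, skins)):
        d = measure_fstt(fitted, skin)
        if extracted_skulls is not None:
            m = validity_mask(fitted, extracted_skulls[i], threshold)
        else:
            m = np.ones(len(d), bool)
        per_subject.append((d, m))
    return aggregate(per_subject, population_std=population_std), per_subject
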