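"""Dense facial soft-tissue-thickness (FSTT) statistics and sphere models.

The FSTT at a skull vertex is the *unsigned shortest distance* from that
vertex of the fitted skull template to the subject's skin surface — a
scalar without a measurement direction, which avoids the noise-prone
estimation of skull or skin normals.  Measured per vertex across a
population of corresponding skull/skin pairs, the values are aggregated
into per-vertex mean/standard-deviation/count statistics, masked where the
fitted template is not actually supported by the extracted skull (distance
above a 2 mm validity threshold, e.g. a cropped calvaria).

For reconstruction, thickness is re-attached to a fitted skull as the
*sphere model*: one sphere per active skull vertex with radius equal to
the chosen FSTT value; the outer envelope of the union of spheres
approximates the skin surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import MeshError, PointSet, SurfaceMesh, TetMesh, _SurfaceLocator
from .shape_model import ShapeModel, build_pca

__all__ = [
    "FSTTStatistic",
    "SphereModel",
    "measure_fstt",
    "validity_mask",
    "aggregate",
    "landmark_table",
    "build_fstt_model",
    "project_thickness",
    "build_sphere_model",
]


@dataclass
class FSTTStatistic:
    """Per-template-vertex thickness statistics over a subject population."""

    mean: np.ndarray  # mm; NaN where count == 0
    std: np.ndarray  # mm; NaN where count == 0
    count: np.ndarray  # number of valid subjects per vertex
    valid_mask: np.ndarray  # count > 0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float).ravel()
        self.std = np.asarray(self.std, float).ravel()
        self.count = np.asarray(self.count, np.int64).ravel()
        self.valid_mask = np.asarray(self.valid_mask, bool).ravel()
        if np.any(self.std[self.count > 0] < 0):
            raise MeshError("negative std")
        if np.any(self.valid_mask & (self.count == 0)):
            raise MeshError("valid vertices must have count > 0")

    def active_mask(self, min_fraction: float = 0.5) -> np.ndarray:
        """Vertices supported by at least ``min_fraction`` of the subjects.

        Used to exclude the calvaria region during reconstruction, where
        cropped scans leave few (and mostly invalid, very large) samples.
        """
        n_subj = int(self.count.max(initial=0))
        return self.count >= np.ceil(min_fraction * n_subj)


@dataclass
class SphereModel:
    """Union-of-spheres thickness representation on a fitted skull.

    One sphere per active vertex, centered at the fitted-skull vertex with
    radius equal to its FSTT value; ``samples`` holds quasi-uniform surface
    samples of all spheres, labelled by source vertex.
    """

    centers: np.ndarray
    radii: np.ndarray
    samples: PointSet
    active_mask: np.ndarray

    def __post_init__(self):
        self.centers = np.asarray(self.centers, float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, float).ravel()
        self.active_mask = np.asarray(self.active_mask, bool).ravel()
        # zero radii are allowed: the sphere degenerates to its center and
        # the model degenerates to the skull surface itself
        if np.any(self.radii[self.active_mask] < 0):
            raise MeshError("active sphere radii must be non-negative")


def _skull_vertices(fitted_skull) -> np.ndarray:
    if isinstance(fitted_skull, TetMesh):
        return fitted_skull.vertices
    if isinstance(fitted_skull, SurfaceMesh):
        return fitted_skull.vertices
    return np.asarray(fitted_skull, float).reshape(-1, 3)


def measure_fstt(fitted_skull, skin: SurfaceMesh) -> np.ndarray:
    """Shortest unsigned distance from each skull vertex to the skin surface."""
    if not isinstance(skin, SurfaceMesh) or not skin.n_triangles:
        raise MeshError("skin surface must be a non-empty triangle mesh")
    verts = _skull_vertices(fitted_skull)
    return _SurfaceLocator(skin).query(verts)[1]


def validity_mask(fitted_skull, extracted_skull: SurfaceMesh, threshold: float = 2.0) -> np.ndarray:
    """True where the fitted skull vertex is supported by the extracted skull.

    A vertex farther than ``threshold`` (2 mm by default) from the extracted
    (possibly partial) skull surface got no data support there — e.g. the
    completed calvaria over a cropped scan — and must not contribute to the
    thickness statistic.
    """
    if not isinstance(extracted_skull, SurfaceMesh) or not extracted_skull.n_triangles:
        raise MeshError("extracted skull must be a non-empty triangle mesh")
    verts = _skull_vertices(fitted_skull)
    d = _SurfaceLocator(extracted_skull).query(verts)[1]
    return d <= threshold


def aggregate(per_subject, population_std: bool = True) -> FSTTStatistic:
    """Per-vertex mean/std/count over the valid subjects at each vertex.

    ``per_subject`` is a list of ``(distances, mask)`` pairs.  The standard
    deviation divides by the count (population convention) by default;
    ``population_std=False`` selects the n-1 (sample) convention.
    Permutation-invariant in the subjects; vertices valid in no subject get
    NaN mean/std, count 0, and are excluded from the valid mask.
    """
    if not per_subject:
        raise MeshError("no subjects")
    dists = np.asarray([np.asarray(d, float).ravel() for d, _ in per_subject])
    masks = np.asarray([np.asarray(m, bool).ravel() for _, m in per_subject])
    if dists.shape != masks.shape:
        raise MeshError("distance/mask shape mismatch")
    count = masks.sum(axis=0)
    w = masks.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (dists * w).sum(axis=0) / count
        var = (((dists - mean) ** 2) * w).sum(axis=0)
        denom = count.astype(float) if population_std else np.maximum(count - 1, 1)
        std = np.sqrt(var / denom)
    std = np.where(count > 0, std, np.nan)
    # a single valid sample has zero spread under either convention
    std = np.where(count == 1, 0.0, std)
    mean = np.where(count > 0, mean, np.nan)
    return FSTTStatistic(mean, std, count, count > 0)


def landmark_table(statistic: FSTTStatistic, landmarks: dict) -> list[dict]:
    """Thickness statistics at named landmark vertices.

    One row per landmark with mean/std/count; landmarks whose vertex is
    outside the valid mask are flagged and carry no mean.  Bilateral
    landmarks appear as separate left/right rows (their names carry the
    side suffix).
    """
    rows = []
    for name in sorted(landmarks):
        idx = int(landmarks[name])
        valid = bool(statistic.valid_mask[idx])
        rows.append(
            {
                "landmark": name,
                "vertex": idx,
                "valid": valid,
                "mean_mm": float(statistic.mean[idx]) if valid else None,
                "std_mm": float(statistic.std[idx]) if valid else None,
                "count": int(statistic.count[idx]),
            }
        )
    return rows


def write_landmark_table(rows: list[dict], path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["landmark", "vertex", "valid", "mean_mm", "std_mm", "count"]
        )
        writer.writeheader()
        writer.writerows(rows)


def build_fstt_model(
    per_subject_fstt,
    masks,
    min_count_fraction: float = 1.0,
    d: int | None = None,
) -> ShapeModel:
    """PCA model of per-vertex thickness over the reliably observed vertices.

    Only vertices valid in at least ``min_count_fraction`` of the subjects
    enter the model (default: all of them, avoiding imputation entirely);
    the retained vertex mask is stored on the model.  For subjects missing
    one of the retained vertices, the cross-subject mean at that vertex is
    imputed before the PCA.
    """
    X = np.asarray([np.asarray(v, float).ravel() for v in per_subject_fstt])
    M = np.asarray([np.asarray(m, bool).ravel() for m in masks])
    if X.shape != M.shape:
        raise MeshError("fstt/mask shape mismatch")
    n = len(X)
    frac = M.sum(axis=0) / n
    keep = frac >= min_count_fraction - 1e-12
    if not keep.any():
        raise MeshError("no vertex is valid in enough subjects")
    Xk = X[:, keep]
    Mk = M[:, keep]
    if not Mk.all():
        with np.errstate(invalid="ignore", divide="ignore"):
            col_mean = (Xk * Mk).sum(axis=0) / Mk.sum(axis=0)
        Xk = np.where(Mk, Xk, col_mean[None, :])
    model = build_pca(Xk, d)
    model.vertex_mask = keep
    model.metadata["kind"] = "fstt"
    model.metadata["n_subjects"] = n
    model.metadata["min_count_fraction"] = float(min_count_fraction)
    return model


def project_thickness(
    model: ShapeModel,
    measured: np.ndarray,
    lambda_tik: float = 1e-4,
    var_fraction: float = 0.9,
    clip_sigma: float = 2.0,
) -> np.ndarray:
    """Plausible-thickness projection of a measured FSTT field.

    Returns model weights approximating ``measured`` (given on the model's
    vertex mask) with three plausibility safeguards: only the leading
    components covering ``var_fraction`` of the variance are used (trailing
    sample-PCA components of a small population are noise and make the
    field spatially rough), the fit is Tikhonov-regularized, and weights
    are clipped to ``clip_sigma`` standard deviations — the same sigma
    multiples spanned by the plausible-variant grids.
    """
    from .shape_model import fit_pca_weights

    values = np.asarray(measured, float).ravel()
    if model.vertex_mask is not None and len(values) == len(model.vertex_mask):
        values = values[np.asarray(model.vertex_mask, bool)]
    if len(values) != len(model.mean):
        raise MeshError("measured vector does not match the model rows")
    var = np.maximum(model.variances, 0.0)
    total = var.sum()
    k = int(np.searchsorted(np.cumsum(var), var_fraction * total) + 1) if total > 0 else 1
    k = max(1, min(k, model.n_components))
    sub = model.truncated(k)
    gamma = fit_pca_weights(sub, np.arange(len(values)), values, lambda_tik=lambda_tik)
    gamma = np.clip(gamma, -clip_sigma * sub.sigmas, clip_sigma * sub.sigmas)
    out = np.zeros(model.n_components)
    out[:k] = gamma
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere directions (deterministic spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def build_sphere_model(
    fitted_skull,
    fstt_vector: np.ndarray,
    active_mask: np.ndarray | None = None,
    samples_per_sphere: int = 64,
) -> SphereModel:
    """Sphere model from a fitted skull and a per-vertex thickness vector.

    Each active vertex contributes ``samples_per_sphere`` points on a
    Fibonacci spiral of its sphere; every sample lies exactly at distance
    radius from its center and is labelled with the source vertex index.
    """
    centers = _skull_vertices(fitted_skull)
    radii = np.asarray(fstt_vector, float).ravel()
    if len(radii) != len(centers):
        raise MeshError("one radius per skull vertex required")
    mask = (
        np.ones(len(centers), bool) if active_mask is None
        else np.asarray(active_mask, bool).ravel()
    )
    mask = mask & np.isfinite(radii) & (radii >= 0)
    dirs = _fibonacci_sphere(samples_per_sphere)
    idx = np.where(mask)[0]
    pts = (centers[idx][:, None, :] + radii[idx][:, None, None] * dirs[None, :, :]).reshape(-1, 3)
    labels = np.repeat(idx, samples_per_sphere)
    return SphereModel(centers, radii, PointSet(pts, labels=labels), mask)
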