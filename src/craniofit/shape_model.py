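"""PCA morphable models shared by skull, head, and soft-tissue statistics.

A :class:`ShapeModel` is a mean vector plus orthonormal principal components
with per-component variances, built from stacked training vectors (vertex
coordinates in mm for skull/head models, per-vertex thicknesses in mm for
the soft-tissue model).  Fitting a model to partial observations solves a
Tikhonov-regularized least-squares problem whose penalty (beta_k/sigma_k)^2
keeps the weights statistically plausible; ``ShapeModel.fit`` wraps the
alternating alignment/shape optimization and returns a result object with
the estimates, residual diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import MeshError, PointSet
from .registration import (
    DegenerateCorrespondences,
    SimilarityTransform,
    similarity_from_correspondences,
)

__all__ = [
    "ShapeModel",
    "ShapeFitResult",
    "build_pca",
    "synthesize",
    "fit_pca_weights",
    "align_and_fit",
    "save_model",
    "load_model",
]


@dataclass
class ShapeModel:
    """Linear statistical shape model: x(w) = mean + components @ w.

    ``components`` holds orthonormal principal components in its columns,
    ordered by non-increasing variance; ``variances`` are the per-component
    sigma_k^2 (sample variance along each component).  ``vertex_mask``
    optionally records which template vertices the rows refer to (used by
    the masked soft-tissue model); ``metadata`` carries a creation manifest.
    """

    mean: np.ndarray
    components: np.ndarray
    variances: np.ndarray
    vertex_mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float).ravel()
        self.components = np.asarray(self.components, float).reshape(len(self.mean), -1)
        self.variances = np.asarray(self.variances, float).ravel()
        if self.components.shape[1] != len(self.variances):
            raise MeshError("one variance per component required")
        if np.any(np.diff(self.variances) > 1e-9 * max(self.variances.max(initial=0.0), 1)):
            raise MeshError("variances must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def sigmas(self) -> np.ndarray:
        return np.sqrt(np.maximum(self.variances, 0.0))

    def synthesize(self, weights=None) -> np.ndarray:
        return synthesize(self, weights)

    def project(self, vector: np.ndarray) -> np.ndarray:
        """Orthogonal projection of a stacked vector onto the weight space."""
        return self.components.T @ (np.asarray(vector, float).ravel() - self.mean)

    def truncated(self, d: int) -> "ShapeModel":
        return ShapeModel(
            self.mean.copy(),
            self.components[:, :d].copy(),
            self.variances[:d].copy(),
            None if self.vertex_mask is None else self.vertex_mask.copy(),
            dict(self.metadata),
        )

    def fit(
        self,
        target: PointSet | np.ndarray,
        lambda_tik: float = 1e-4,
        align: bool = True,
        max_rounds: int = 50,
        tol: float = 1e-6,
        prune_distance: float = np.inf,
        target_point_mask: np.ndarray | None = None,
        direction: str = "model_to_target",
    ) -> "ShapeFitResult":
        """Fit the model to a point cloud; see :func:`align_and_fit`."""
        return align_and_fit(
            self, target, lambda_tik, max_rounds=max_rounds, tol=tol,
            align=align, prune_distance=prune_distance,
            target_point_mask=target_point_mask, direction=direction,
        )


@dataclass
class ShapeFitResult:
    """Result of fitting a ShapeModel to data.

    Carries the estimated PCA weights with their prior scale, the recovered
    similarity transform, and residual diagnostics of the final
    correspondence round.
    """

    model: ShapeModel
    weights: np.ndarray
    transform: SimilarityTransform
    residual_rms: float
    n_correspondences: int
    n_rounds: int
    objective_trace: list

    @property
    def fitted_vector(self) -> np.ndarray:
        """Synthesized shape in model coordinates."""
        return self.model.synthesize(self.weights)

    @property
    def fitted_points(self) -> np.ndarray:
        """Synthesized shape mapped into the target frame."""
        return self.transform.apply(self.fitted_vector.reshape(-1, 3))

    def summary(self) -> str:
        sig = self.model.sigmas
        lines = [
            "Shape model fit",
            "=" * 46,
            f"components:          {self.model.n_components}",
            f"correspondences:     {self.n_correspondences}",
            f"rounds:              {self.n_rounds}",
            f"residual RMS [mm]:   {self.residual_rms:.4f}",
            f"scale:               {self.transform.scale:.6f}",
            "",
            " comp      weight       sigma    weight/sigma",
            "-" * 46,
        ]
        for k, w in enumerate(self.weights):
            s = sig[k] if sig[k] > 0 else np.nan
            lines.append(f"{k:5d}  {w:10.4f}  {s:10.4f}  {w / s:13.3f}")
        return "\n".join(lines)


def build_pca(samples, d: int | None = None) -> ShapeModel:
    """Principal-component model of stacked sample vectors.

    The mean is the arithmetic mean; components and variances come from the
    thin SVD of the centered sample matrix with sigma_k^2 =
    singular_value^2 / (n - 1).  With all components retained, every
    training sample is reconstructed exactly (to rounding).
    """
    vecs = [np.asarray(s, float).ravel() for s in samples]
    if len(vecs) < 2 or len({len(v) for v in vecs}) != 1:
        raise MeshError("need >= 2 equal-length sample vectors")
    X = np.asarray(vecs)
    n = len(X)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    max_d = min(n - 1, Xc.shape[1])
    if d is None:
        d = max_d
    d = min(d, max_d)
    return ShapeModel(mean, Vt[:d].T, (S[:d] ** 2) / (n - 1))


def synthesize(model: ShapeModel, weights=None) -> np.ndarray:
    """Evaluate mean + components @ weights (zero weights give the mean).

    ``weights`` may be shorter than the model dimension; missing entries
    are zero.  The display convention for mode grids sets weight_k =
    a_k * sigma_k with a_k in {-2, 0, 2}.
    """
    if weights is None:
        return model.mean.copy()
    w = np.asarray(weights, float).ravel()
    if len(w) > model.n_components:
        raise MeshError("more weights than components")
    if len(w) < model.n_components:
        w = np.pad(w, (0, model.n_components - len(w)))
    return model.mean + model.components @ w


def fit_pca_weights(
    model: ShapeModel,
    row_indices: np.ndarray,
    target_values: np.ndarray,
    weights: np.ndarray | None = None,
    lambda_tik: float = 1e-4,
) -> np.ndarray:
    """Tikhonov-regularized weight estimate from partial observations.

    Solves
        min_b (1/sum w_c) sum_c w_c (mean_c + V_c b - y_c)^2
              + (lambda_tik / d) sum_k (b_k / sigma_k)^2
    in closed form via the normal equations; always solvable since the
    penalty regularizes any rank deficiency.  Rows may index arbitrary
    entries of the stacked model vector (e.g. 3 consecutive rows per
    corresponded vertex, or single rows for scalar thickness values).
    """
    idx = np.asarray(row_indices, np.int64).ravel()
    y = np.asarray(target_values, float).ravel()
    if len(idx) != len(y) or len(idx) == 0:
        raise MeshError("need matching, non-empty rows and targets")
    w = np.ones(len(idx)) if weights is None else np.asarray(weights, float).ravel()
    wsum = w.sum()
    if wsum <= 0:
        raise MeshError("weights sum to zero")
    V = model.components[idx]
    r = y - model.mean[idx]
    d = model.n_components
    A = (V * (w / wsum)[:, None]).T @ V
    sig2 = np.maximum(model.variances, 1e-300)
    A[np.diag_indices(d)] += lambda_tik / d / sig2
    b = (V * (w / wsum)[:, None]).T @ r
    return np.linalg.solve(A, b)


def _expand_vertex_rows(vertex_indices: np.ndarray) -> np.ndarray:
    """Vertex indices -> the 3 consecutive stacked-coordinate rows each."""
    v = np.asarray(vertex_indices, np.int64).ravel()
    return (3 * v[:, None] + np.arange(3)[None, :]).reshape(-1)


def align_and_fit(
    model: ShapeModel,
    target,
    lambda_tik: float = 1e-4,
    max_rounds: int = 50,
    tol: float = 1e-6,
    align: bool = True,
    prune_distance: float = np.inf,
    target_point_mask: np.ndarray | None = None,
    direction: str = "model_to_target",
) -> ShapeFitResult:
    """Alternate closed-form similarity alignment and PCA weight fitting.

    Correspondences are recomputed before each optimization; the loop stops
    when the relative change of the objective falls below ``tol`` (or after
    ``max_rounds``).  The model is assumed to stack 3D vertex coordinates.

    ``direction`` selects the matching direction: ``"model_to_target"``
    (each model vertex to its nearest target point) is right for complete
    targets; ``"target_to_model"`` (each target point to its nearest model
    vertex) leaves unobserved model regions unconstrained and is the robust
    choice for partial scans.
    """
    if direction not in ("model_to_target", "target_to_model"):
        raise MeshError(f"unknown matching direction {direction!r}")
    pts = target.points if isinstance(target, PointSet) else np.asarray(target, float)
    if pts.size == 0:
        raise MeshError("empty target")
    if target_point_mask is not None:
        # e.g. points near a partial scan's open boundary are unreliable
        pts = pts[np.asarray(target_point_mask, bool)]
        if not len(pts):
            raise MeshError("target mask removed every point")
    tree = cKDTree(pts)
    n_v = len(model.mean) // 3
    weights = np.zeros(model.n_components)
    tf = SimilarityTransform.identity()
    trace = []
    prev_obj = None
    rounds = 0
    n_c = 0
    for rounds in range(1, max_rounds + 1):
        shape = model.synthesize(weights).reshape(n_v, 3)
        moved = tf.apply(shape)
        if direction == "model_to_target":
            d, j = tree.query(moved)
            keep = d <= prune_distance
            model_idx = np.where(keep)[0]
            tgt = pts[j[keep]]
        else:
            mtree = cKDTree(moved)
            d, i = mtree.query(pts)
            keep = d <= prune_distance
            model_idx = i[keep]
            tgt = pts[keep]
        if keep.sum() < 3:
            raise DegenerateCorrespondences("too few correspondences survive pruning")
        n_c = int(keep.sum())
        obj = float(np.mean(d[keep] ** 2))
        trace.append(obj)
        if prev_obj is not None and abs(prev_obj - obj) < tol * max(prev_obj, 1e-300):
            break
        prev_obj = obj
        if align:
            tf = similarity_from_correspondences(shape[model_idx], tgt)
        # fit weights in the model frame on back-transformed targets
        local_targets = tf.inverse().apply(tgt)
        rows = _expand_vertex_rows(model_idx)
        weights = fit_pca_weights(
            model, rows, local_targets.reshape(-1), lambda_tik=lambda_tik
        )
    shape = model.synthesize(weights).reshape(n_v, 3)
    if direction == "model_to_target":
        d, _ = tree.query(tf.apply(shape))
    else:
        d, _ = cKDTree(tf.apply(shape)).query(pts)
    keep = d <= prune_distance
    rms = float(np.sqrt(np.mean(d[keep] ** 2))) if keep.any() else float("nan")
    return ShapeFitResult(model, weights, tf, rms, n_c, rounds, trace)


# ---------------------------------------------------------------------------
# persistence (single HDF5 container)
# ---------------------------------------------------------------------------


def save_model(model: ShapeModel, path: str, extra: dict | None = None) -> None:
    """Write a model to HDF5: /mean, /components, /variances, optional
    /vertex_mask, string attributes from metadata, extra arrays under
    /extra/<name>."""
    import h5py
    import json

    with h5py.File(path, "w") as h5:
        h5.create_dataset("mean", data=model.mean)
        h5.create_dataset("components", data=model.components)
        h5.create_dataset("variances", data=model.variances)
        if model.vertex_mask is not None:
            h5.create_dataset("vertex_mask", data=np.asarray(model.vertex_mask, bool))
        h5.attrs["metadata"] = json.dumps(model.metadata, default=str)
        if extra:
            g = h5.create_group("extra")
            for k, v in extra.items():
                g.create_dataset(k, data=np.asarray(v))


def load_model(path: str, with_extra: bool = False):
    import h5py
    import json

    with h5py.File(path, "r") as h5:
        model = ShapeModel(
            h5["mean"][...],
            h5["components"][...],
            h5["variances"][...],
            h5["vertex_mask"][...] if "vertex_mask" in h5 else None,
            json.loads(h5.attrs.get("metadata", "{}")),
        )
        if with_extra:
            extra = {k: h5["extra"][k][...] for k in h5.get("extra", {})}
            return model, extra
    return model
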