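"""Rigid/similarity alignment and non-rigid template fitting.

Two template fitters live here.  The volumetric skull template is fitted by
minimizing a correspondence term plus a tetrahedron volume-preservation
regularizer (Gauss-Newton with step damping, since tet volumes are trilinear
in the vertex positions).  The surface head template is fitted with a
rotation-compensated per-edge Laplacian bending energy in a local/global
alternation: per-edge rotations are re-estimated from the current shape,
then vertex positions solve a sparse linear least-squares problem.

Both fitters run a schedule of decreasing regularization weights
(stiff-to-soft), updating the rest state whenever the weight drops, and
alternate correspondence search with minimization in the spirit of
non-rigid ICP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, identity
from scipy.sparse.linalg import factorized
from scipy.spatial import cKDTree

from .mesh_core import (
    MeshError,
    PointSet,
    SurfaceMesh,
    TetMesh,
    _SurfaceLocator,
    edge_areas,
    edges_with_diamonds,
    high_curvature_mask,
    tet_volumes,
    vertex_normals,
)

__all__ = [
    "SimilarityTransform",
    "write_energy_trace",
    "CorrespondenceSet",
    "FitSchedule",
    "DegenerateCorrespondences",
    "similarity_from_correspondences",
    "coarse_align",
    "icp",
    "hierarchical_icp",
    "find_correspondences",
    "ereg_volume",
    "ereg_edge_laplacian",
    "nonrigid_fit_skull",
    "nonrigid_fit_head",
    "rms_error",
]


class DegenerateCorrespondences(MeshError):
    """Correspondences insufficient to determine a transform."""


# ---------------------------------------------------------------------------
# similarity transforms
# ---------------------------------------------------------------------------


@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation (proper rotation only)."""

    scale: float = 1.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        self.scale = float(self.scale)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return self.scale * p @ self.rotation.T + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return SimilarityTransform(
            self.scale * other.scale,
            self.rotation @ other.rotation,
            self.scale * other.translation @ self.rotation.T + self.translation,
        )

    def inverse(self) -> "SimilarityTransform":
        Rt = self.rotation.T
        return SimilarityTransform(
            1.0 / self.scale, Rt, -Rt @ self.translation / self.scale
        )

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()


def similarity_from_correspondences(
    source: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
    allow_scale: bool = True,
) -> SimilarityTransform:
    """Weighted least-squares similarity (Umeyama's closed form).

    Minimizes sum_c w_c || s R x_c + t - y_c ||^2 over the similarity group
    (rigid group if ``allow_scale`` is false); the rotation is always proper,
    so mirrored targets yield a residual instead of a reflection.
    """
    x = np.asarray(source, float).reshape(-1, 3)
    y = np.asarray(target, float).reshape(-1, 3)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateCorrespondences("need >= 3 point pairs")
    w = np.ones(len(x)) if weights is None else np.asarray(weights, float).ravel()
    if np.any(w < 0) or w.sum() <= 0:
        raise DegenerateCorrespondences("weights must be nonnegative, not all zero")
    w = w / w.sum()
    mx = w @ x
    my = w @ y
    xc = x - mx
    yc = y - my
    cov = (yc * w[:, None]).T @ xc  # 3x3 cross-covariance
    U, D, Vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(np.diag(D), tol=max(D.max(), 1e-300) * 1e-9) < 2:
        raise DegenerateCorrespondences("collinear or coincident point pairs")
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if allow_scale:
        var_x = float(w @ np.einsum("ij,ij->i", xc, xc))
        if var_x <= 0:
            raise DegenerateCorrespondences("source points coincide")
        s = float(np.trace(np.diag(D) @ S)) / var_x
        if s <= 0:
            raise DegenerateCorrespondences("degenerate scale estimate")
    else:
        s = 1.0
    t = my - s * R @ mx
    return SimilarityTransform(s, R, t)


# ---------------------------------------------------------------------------
# coarse global alignment (feature matching + RANSAC, PCA-axes fallback)
# ---------------------------------------------------------------------------


def _estimate_normals(points: np.ndarray, k: int = 12) -> np.ndarray:
    """PCA normals of local neighborhoods, oriented away from the centroid."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=min(k, len(points)))
    nbr = points[idx]  # (n, k, 3)
    cen = nbr.mean(axis=1, keepdims=True)
    d = nbr - cen
    cov = np.einsum("nki,nkj->nij", d, d)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # smallest-eigenvalue direction
    outward = points - points.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    normals[flip] *= -1.0
    lens = np.linalg.norm(normals, axis=1)
    lens[lens == 0] = 1.0
    return normals / lens[:, None]


def _spfh(points, normals, tree, radius, bins=11):
    """Simplified point-feature histograms of Darboux-frame angles."""
    n = len(points)
    hist = np.zeros((n, 3 * bins))
    pairs = tree.query_ball_point(points, radius)
    for i in range(n):
        js = [j for j in pairs[i] if j != i]
        if not js:
            continue
        js = np.asarray(js)
        d = points[js] - points[i]
        dist = np.linalg.norm(d, axis=1)
        dist[dist == 0] = 1e-12
        dhat = d / dist[:, None]
        u = normals[i]
        v = np.cross(dhat, np.broadcast_to(u, dhat.shape))
        vlen = np.linalg.norm(v, axis=1)
        vlen[vlen == 0] = 1e-12
        v = v / vlen[:, None]
        w = np.cross(np.broadcast_to(u, v.shape), v)
        nj = normals[js]
        alpha = np.einsum("ij,ij->i", v, nj)
        phi = dhat @ u
        theta = np.arctan2(np.einsum("ij,ij->i", w, nj), nj @ u)
        for f, lo, hi, off in (
            (alpha, -1.0, 1.0, 0),
            (phi, -1.0, 1.0, bins),
            (theta, -np.pi, np.pi, 2 * bins),
        ):
            b = np.clip(((f - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
            np.add.at(hist[i], off + b, 1.0)
    sums = hist.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return hist / sums


def _fpfh(points, normals, radius, bins=11):
    tree = cKDTree(points)
    spfh = _spfh(points, normals, tree, radius, bins)
    pairs = tree.query_ball_point(points, radius)
    out = spfh.copy()
    for i in range(len(points)):
        js = [j for j in pairs[i] if j != i]
        if not js:
            continue
        js = np.asarray(js)
        wts = 1.0 / np.maximum(np.linalg.norm(points[js] - points[i], axis=1), 1e-12)
        out[i] += (spfh[js] * wts[:, None]).sum(axis=0) / wts.sum()
    sums = out.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return out / sums


def _trimmed_rms(source: np.ndarray, target_tree: cKDTree, fraction: float = 0.7) -> float:
    d, _ = target_tree.query(source)
    d = np.sort(d)
    keep = max(1, int(len(d) * fraction))
    return float(np.sqrt(np.mean(d[:keep] ** 2)))


def _principal_axes_align(src: np.ndarray, dst: np.ndarray, allow_scale: bool):
    """Align principal frames; try the four proper axis-sign combinations."""
    ms, md = src.mean(axis=0), dst.mean(axis=0)
    cs = np.cov((src - ms).T)
    cd = np.cov((dst - md).T)
    _, vs = np.linalg.eigh(cs)
    _, vd = np.linalg.eigh(cd)
    if np.linalg.det(vs) < 0:
        vs[:, 0] *= -1
    if np.linalg.det(vd) < 0:
        vd[:, 0] *= -1
    scale = 1.0
    if allow_scale:
        rs = np.sqrt(np.trace(cs))
        rd = np.sqrt(np.trace(cd))
        if rs > 0:
            scale = float(rd / rs)
    tree = cKDTree(dst)
    best = None
    for signs in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        R = vd @ np.diag(signs) @ vs.T
        t = md - scale * R @ ms
        tf = SimilarityTransform(scale, R, t)
        score = _trimmed_rms(tf.apply(src), tree)
        if best is None or score < best[0]:
            best = (score, tf)
    return best[1], best[0]


def _trimmed_icp_step(sp, tree, dst, tf, trim):
    moved = tf.apply(sp)
    d, j = tree.query(moved)
    k = max(3, int(len(sp) * trim))
    keep = np.argpartition(d, k - 1)[:k]
    try:
        return similarity_from_correspondences(sp[keep], dst[j[keep]]), float(
            np.sqrt(np.mean(d[keep] ** 2))
        )
    except DegenerateCorrespondences:
        return tf, float(np.sqrt(np.mean(d[keep] ** 2)))


def _multistart_rotation_search(sp, dst, trim=0.45, n_iters=10):
    """Global alignment by trimmed ICP from a grid of initial rotations.

    Effective even for shapes whose local geometry is too self-similar for
    feature matching (e.g. near-spherical clouds); the trimmed objective
    tolerates partial overlap.
    """
    import trimesh

    tree = cKDTree(dst)
    dirs = np.asarray(trimesh.creation.icosphere(subdivisions=1).vertices, float)
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    rolls = [0.0, np.pi / 2, np.pi, 3 * np.pi / 2]
    ms, md = sp.mean(axis=0), dst.mean(axis=0)
    best_tf, best_score = None, np.inf
    z = np.array([0.0, 0.0, 1.0])
    for u in dirs:
        # rotation taking z to u
        v = np.cross(z, u)
        c = float(z @ u)
        if np.linalg.norm(v) < 1e-12:
            R_axis = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            R_axis = np.eye(3) + K + K @ K * ((1 - c) / (v @ v))
        for roll in rolls:
            cr, sr = np.cos(roll), np.sin(roll)
            R_roll = np.array([[cr, -sr, 0], [sr, cr, 0], [0, 0, 1.0]])
            R0 = R_axis @ R_roll
            tf = SimilarityTransform(1.0, R0, md - R0 @ ms)
            score = np.inf
            for _ in range(n_iters):
                tf, score = _trimmed_icp_step(sp, tree, dst, tf, trim)
            if score < best_score:
                best_tf, best_score = tf, score
    return best_tf, best_score


def coarse_align(
    source: PointSet,
    target: PointSet,
    n_features: int = 350,
    ransac_iters: int = 800,
    seed: int = 0,
    allow_scale: bool = True,
) -> SimilarityTransform:
    """Global initial alignment of two point sets in arbitrary pose.

    Local Darboux-angle feature histograms are matched between downsampled
    clouds and a similarity transform is robustly estimated by RANSAC over
    3-point samples; if the feature consensus is weak the method falls back
    to principal-axes alignment (best of the four proper sign choices under
    a trimmed-RMS score) with a warning.
    """
    src = np.asarray(source.points, float)
    dst = np.asarray(target.points, float)
    if not len(src) or not len(dst):
        raise MeshError("coarse_align requires non-empty point sets")
    rng = np.random.default_rng(seed)
    diag = max(target.bounding_box_diagonal(), 1e-9)

    def subsample(p, n):
        if len(p) <= n:
            return np.arange(len(p))
        return rng.choice(len(p), size=n, replace=False)

    si = subsample(src, n_features)
    ti = subsample(dst, n_features)
    sp, tp = src[si], dst[ti]
    sn = source.normals[si] if source.normals is not None else _estimate_normals(sp)
    tn = target.normals[ti] if target.normals is not None else _estimate_normals(tp)
    # feature radius: a few multiples of the mean sample spacing
    radius = 4.0 * diag / np.sqrt(len(tp))
    fs = _fpfh(sp, sn, radius)
    ft = _fpfh(tp, tn, radius)
    match = cKDTree(ft).query(fs)[1]
    mt = tp[match]

    tree = cKDTree(dst)
    tol = 0.05 * diag
    # score with a conservative trimmed fraction so that up to ~50% of the
    # source may have no counterpart in a cropped target
    trim = 0.45
    candidates = []  # (inliers, iteration, transform)
    n = len(sp)
    for it in range(ransac_iters):
        pick = rng.choice(n, size=3, replace=False)
        try:
            tf = similarity_from_correspondences(sp[pick], mt[pick], allow_scale=allow_scale)
        except DegenerateCorrespondences:
            continue
        if not 0.5 < tf.scale < 2.0:
            continue
        resid = np.linalg.norm(tf.apply(sp) - mt, axis=1)
        candidates.append((int((resid < tol).sum()), -it, tf))
    candidates.sort(key=lambda c: c[:2], reverse=True)
    best_tf, best_score = None, np.inf
    for inliers, _, tf in candidates[:8]:
        if inliers < 6:
            break
        resid = np.linalg.norm(tf.apply(sp) - mt, axis=1)
        mask = resid < tol
        if mask.sum() >= 3:
            try:
                tf = similarity_from_correspondences(
                    sp[mask], mt[mask], allow_scale=allow_scale
                )
            except DegenerateCorrespondences:
                pass
        # ICP-polish each candidate before scoring so that near-misses of
        # the correct basin are not rejected
        tf = icp(PointSet(tf.apply(src)), PointSet(dst), "similarity",
                 max_iter=15).compose(tf)
        score = _trimmed_rms(tf.apply(src), tree, trim)
        if score < best_score:
            best_tf, best_score = tf, score
    # the feature consensus can lock onto a self-similar impostor pose on
    # weakly featured shapes; always cross-check against a multi-start
    # trimmed-ICP rotation-grid search and keep the better-scoring pose
    grid_tf, _ = _multistart_rotation_search(sp, dst, trim)
    grid_tf = icp(PointSet(grid_tf.apply(src)), PointSet(dst), "similarity",
                  max_iter=20).compose(grid_tf)
    grid_score = _trimmed_rms(grid_tf.apply(src), tree, trim)
    if best_tf is None or grid_score < best_score:
        if best_tf is None:
            warnings.warn("feature matching failed; using rotation-grid alignment")
        best_tf, best_score = grid_tf, grid_score
    return best_tf


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------


def _target_query(target):
    """Return a function points -> (closest points, distances)."""
    if isinstance(target, SurfaceMesh):
        loc = _SurfaceLocator(target)

        def q(p):
            cp, d, _ = loc.query(p)
            return cp, d

        return q
    pts = target.points if isinstance(target, PointSet) else np.asarray(target, float)
    tree = cKDTree(pts)

    def q(p):
        d, i = tree.query(p)
        return pts[i], d

    return q


def icp(
    source,
    target,
    transform_group: str = "similarity",
    max_iter: int = 50,
    tol: float = 1e-8,
    init: SimilarityTransform | None = None,
    return_trace: bool = False,
):
    """Iterative closest point between a point set/mesh and a target.

    The objective (mean squared closest-point distance) is non-increasing
    across iterations; iteration stops when its relative change drops below
    ``tol``.  ``transform_group`` is ``"rigid"`` or ``"similarity"``.
    """
    if transform_group not in ("rigid", "similarity"):
        raise ValueError("transform_group must be 'rigid' or 'similarity'")
    pts = source.points if isinstance(source, PointSet) else (
        source.vertices if hasattr(source, "vertices") else np.asarray(source, float)
    )
    query = _target_query(target)
    tf = init or SimilarityTransform.identity()
    trace = []
    prev_obj = None
    for _ in range(max_iter):
        moved = tf.apply(pts)
        cp, d = query(moved)
        obj = float(np.mean(d**2))
        trace.append(obj)
        if prev_obj is not None and prev_obj - obj < tol * max(prev_obj, 1e-300):
            break
        prev_obj = obj
        try:
            tf = similarity_from_correspondences(
                pts, cp, allow_scale=(transform_group == "similarity")
            )
        except DegenerateCorrespondences:
            break
    if return_trace:
        return tf, trace
    return tf


# ---------------------------------------------------------------------------
# correspondences
# ---------------------------------------------------------------------------


@dataclass
class CorrespondenceSet:
    """Linear point constraints on template vertices.

    Each constraint ties the barycentric combination
    ``sum_k bary[c, k] * vertices[rows[c, k]]`` to ``targets[c]`` with
    weight ``weights[c]``.  Pure vertex correspondences use a single
    nonzero barycentric entry.
    """

    rows: np.ndarray  # (n_c, 3) template vertex indices
    bary: np.ndarray  # (n_c, 3) barycentric weights
    targets: np.ndarray  # (n_c, 3)
    weights: np.ndarray  # (n_c,)

    def __post_init__(self):
        self.rows = np.asarray(self.rows, np.int64).reshape(-1, 3)
        self.bary = np.asarray(self.bary, float).reshape(-1, 3)
        self.targets = np.asarray(self.targets, float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, float).ravel()
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.targets)):
            raise MeshError("invalid correspondence set")

    def __len__(self):
        return len(self.weights)

    @classmethod
    def from_vertices(cls, vertex_indices, targets, weights=None):
        idx = np.asarray(vertex_indices, np.int64).ravel()
        rows = np.stack([idx, idx, idx], axis=1)
        bary = np.tile([1.0, 0.0, 0.0], (len(idx), 1))
        w = np.ones(len(idx)) if weights is None else np.asarray(weights, float)
        return cls(rows, bary, np.asarray(targets, float), w)

    @classmethod
    def empty(cls):
        return cls(
            np.zeros((0, 3), np.int64), np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0)
        )

    def merged(self, other: "CorrespondenceSet") -> "CorrespondenceSet":
        return CorrespondenceSet(
            np.vstack([self.rows, other.rows]),
            np.vstack([self.bary, other.bary]),
            np.vstack([self.targets, other.targets]),
            np.concatenate([self.weights, other.weights]),
        )


def _target_boundary_filter(target, factor: float = 2.0):
    """Predicate rejecting points near a partial target's open boundary.

    Matches onto the cut rim of a cropped scan pull the adjacent unobserved
    template region across the boundary; discarding them is the standard
    defence in partial-scan registration.  Returns None for targets without
    an open boundary (closed meshes, point sets).
    """
    if not isinstance(target, SurfaceMesh) or not target.n_triangles:
        return None
    edges, _, n_opp = edges_with_diamonds(target.triangles, target.n_vertices)
    boundary_edges = edges[n_opp < 2]
    if not len(boundary_edges):
        return None
    bverts = np.unique(boundary_edges)
    v = target.vertices
    edge_len = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    radius = factor * float(np.median(edge_len))
    tree = cKDTree(v[bverts])

    def far_from_boundary(points):
        d, _ = tree.query(np.asarray(points, float).reshape(-1, 3))
        return d > radius

    return far_from_boundary


def _target_points_normals(target):
    if isinstance(target, SurfaceMesh):
        return target.vertices, vertex_normals(target)
    if isinstance(target, PointSet):
        if target.normals is None:
            return target.points, _estimate_normals(target.points)
        return target.points, target.normals
    p = np.asarray(target, float)
    return p, _estimate_normals(p)


def _barycentric_on_triangle(mesh: SurfaceMesh, tri_idx: np.ndarray, points: np.ndarray):
    """Barycentric coordinates of points known to lie on given triangles."""
    t = mesh.triangles[tri_idx]
    a, b, c = mesh.vertices[t[:, 0]], mesh.vertices[t[:, 1]], mesh.vertices[t[:, 2]]
    v0 = b - a
    v1 = c - a
    v2 = points - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) > 1e-300, denom, 1.0)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    bary = np.clip(np.stack([u, v, w], axis=1), 0.0, 1.0)
    bary /= bary.sum(axis=1, keepdims=True)
    return t, bary


def find_correspondences(
    template: SurfaceMesh,
    target,
    strategy: str = "closest_point",
    prune_distance: float = 2.0,
    prune_normal_angle: float = 60.0,
    weights: np.ndarray | None = None,
    curvature_percentile: float = 70.0,
    prune_pull_angle: float = 75.0,
) -> CorrespondenceSet:
    """Template-to-target correspondences for non-rigid fitting.

    Strategies:

    ``curvature_v2v``
        Template vertices in high-curvature regions matched to their nearest
        target vertices, pruned by distance and normal deviation.
    ``two_way_v2s``
        Target vertices are first matched to nearest template vertices
        (pruned by distance and normal deviation); from the matched template
        vertices a second search finds the closest target *surface* point,
        pruned by normal deviation only.  Suppresses tangential drift and
        scan artifacts.
    ``closest_point``
        All template vertices to closest target surface points, pruned by
        distance and normal deviation.

    ``weights`` optionally holds a per-template-vertex fitting weight
    (e.g. reduced weight on the inner skull shell).
    """
    if strategy not in ("curvature_v2v", "two_way_v2s", "closest_point"):
        raise ValueError(f"unknown strategy {strategy!r}")
    tpl_normals = vertex_normals(template)
    tgt_pts, tgt_normals = _target_points_normals(target)
    if not len(tgt_pts):
        return CorrespondenceSet.empty()
    cos_tol = np.cos(np.deg2rad(prune_normal_angle))
    cos_pull = np.cos(np.deg2rad(prune_pull_angle))
    w_all = np.ones(template.n_vertices) if weights is None else np.asarray(weights, float)
    boundary_ok = _target_boundary_filter(target)

    def all_gates(idx, targets_pts):
        ok = pull_ok(idx, targets_pts)
        if boundary_ok is not None:
            ok &= boundary_ok(targets_pts)
        return ok

    def pull_ok(idx, targets_pts):
        """Displacement must point along the template normal, not along the
        surface: tangential pulls come from matches that steal data across a
        partial target's cut boundary."""
        disp = targets_pts - template.vertices[idx]
        d = np.linalg.norm(disp, axis=1)
        small = d <= 1e-9
        cosang = np.abs(np.einsum("ij,ij->i", tpl_normals[idx], disp)) / np.where(
            small, 1.0, d
        )
        return small | (cosang >= cos_pull)

    def vertex_pairs(idx):
        """nearest target vertex for template vertices idx, with pruning"""
        tree = cKDTree(tgt_pts)
        d, j = tree.query(template.vertices[idx])
        ok = d <= prune_distance
        ok &= np.einsum("ij,ij->i", tpl_normals[idx], tgt_normals[j]) >= cos_tol
        return idx[ok], j[ok]

    if strategy == "curvature_v2v":
        mask = high_curvature_mask(template, curvature_percentile)
        idx = np.where(mask)[0]
        ti, tj = vertex_pairs(idx)
        ok = all_gates(ti, tgt_pts[tj])
        ti, tj = ti[ok], tj[ok]
        return CorrespondenceSet.from_vertices(ti, tgt_pts[tj], w_all[ti])

    if strategy == "closest_point":
        if isinstance(target, SurfaceMesh) and target.n_triangles:
            loc = _SurfaceLocator(target)
            cp, d, tri = loc.query(template.vertices)
            fn = vertex_normals(target)
            # normal at the closest point: use the face normal of the hit tri
            from .mesh_core import face_normals as _fn

            nrm = _fn(target.vertices, target.triangles)[tri]
        else:
            tree = cKDTree(tgt_pts)
            d, j = tree.query(template.vertices)
            cp = tgt_pts[j]
            nrm = tgt_normals[j]
        ok = d <= prune_distance
        ok &= np.einsum("ij,ij->i", tpl_normals, nrm) >= cos_tol
        idx = np.where(ok)[0]
        keep = all_gates(idx, cp[ok])
        idx = idx[keep]
        return CorrespondenceSet.from_vertices(idx, cp[ok][keep], w_all[idx])

    # two_way_v2s
    tpl_tree = cKDTree(template.vertices)
    d, i = tpl_tree.query(tgt_pts)
    ok = d <= prune_distance
    ok &= np.einsum("ij,ij->i", tgt_normals, tpl_normals[i]) >= cos_tol
    tpl_idx = np.unique(i[ok])
    if not len(tpl_idx):
        return CorrespondenceSet.empty()
    if isinstance(target, SurfaceMesh) and target.n_triangles:
        loc = _SurfaceLocator(target)
        cp, d2, tri = loc.query(template.vertices[tpl_idx])
        from .mesh_core import face_normals as _fn

        nrm = _fn(target.vertices, target.triangles)[tri]
    else:
        tree = cKDTree(tgt_pts)
        d2, j = tree.query(template.vertices[tpl_idx])
        cp = tgt_pts[j]
        nrm = tgt_normals[j]
    ok2 = np.einsum("ij,ij->i", tpl_normals[tpl_idx], nrm) >= cos_tol
    idx = tpl_idx[ok2]
    keep = all_gates(idx, cp[ok2])
    idx = idx[keep]
    return CorrespondenceSet.from_vertices(idx, cp[ok2][keep], w_all[idx])


def hierarchical_icp(
    template: SurfaceMesh,
    target,
    depth: int = 2,
    min_part_size: int = 10,
    prune_distance: float = np.inf,
) -> CorrespondenceSet:
    """Piecewise similarity ICP on an octree partition of the template.

    The template bounding box is subdivided ``depth`` times; each cell's
    vertices are aligned to the target by their own similarity ICP (cells
    with fewer than ``min_part_size`` vertices are merged into their
    parent).  Correspondences map each template vertex to the closest
    target point of its part-aligned position.  ``depth = 0`` degenerates
    to a single global similarity ICP.
    """
    v = template.vertices
    query = _target_query(target)

    def cell_codes(level):
        if level == 0:
            return np.zeros(len(v), np.int64)
        lo = v.min(axis=0)
        hi = v.max(axis=0)
        span = np.maximum(hi - lo, 1e-9)
        g = np.clip((v - lo) / span * (2**level), 0, 2**level - 1e-9).astype(np.int64)
        return (g[:, 0] * 2**level + g[:, 1]) * 2**level + g[:, 2]

    # assign each vertex the deepest cell that still has enough vertices
    assignment = cell_codes(0)
    for level in range(1, depth + 1):
        codes = cell_codes(level)
        counts = np.bincount(codes)
        big = counts[codes] >= min_part_size
        assignment = np.where(big, codes + (10 ** (2 * level)), assignment)

    targets = np.empty_like(v)
    # the template is coarsely aligned by precondition; a global ICP against
    # a *partial* target would drag the whole template toward the remaining
    # data, so the identity is the reference the parts refine from
    global_tf = SimilarityTransform.identity()
    ext = v.max(axis=0) - v.min(axis=0)
    diag = float(np.linalg.norm(ext))
    # a part is a *local* refinement; if its own ICP carries it far away
    # from where the global alignment puts it (e.g. a part whose data is
    # missing from a cropped target slides onto the wrong surface), fall
    # back to the global transform for that part
    max_part_shift = 0.06 * diag
    for code in np.unique(assignment):
        idx = np.where(assignment == code)[0]
        tf = global_tf
        if len(idx) >= min_part_size:
            cand = icp(PointSet(v[idx]), target, "similarity", init=global_tf)
            centroid = v[idx].mean(axis=0)
            shift = np.linalg.norm(cand.apply(centroid) - global_tf.apply(centroid))
            if shift <= max_part_shift:
                tf = cand
        cp, _ = query(tf.apply(v[idx]))
        targets[idx] = cp
    d = np.linalg.norm(targets - v, axis=1)
    ok = d <= prune_distance if np.isfinite(prune_distance) else np.ones(len(v), bool)
    boundary_ok = _target_boundary_filter(target)
    if boundary_ok is not None:
        ok &= boundary_ok(targets)
    keep = np.where(ok)[0]
    return CorrespondenceSet.from_vertices(keep, targets[keep])


# ---------------------------------------------------------------------------
# regularizers
# ---------------------------------------------------------------------------


def ereg_volume(tets: np.ndarray, prev_positions: np.ndarray, positions: np.ndarray) -> float:
    """Sum over tets of (vol(T(S)) - vol(T(S_prev)))^2.

    Zero iff every tetrahedron preserves its volume; in particular zero for
    any rigid motion.
    """
    vp = tet_volumes(np.asarray(prev_positions, float), tets)
    vc = tet_volumes(np.asarray(positions, float), tets)
    return float(np.sum((vc - vp) ** 2))


def _edge_laplacians(edges, opposites, n_opp, positions):
    """Uniform-weight diamond second difference per edge.

    Interior edge (i, j) with opposite vertices (k, l):
        L_e = x_k + x_l - x_i - x_j
    Boundary edge: L_e = x_k - (x_i + x_j) / 2.
    Translation-invariant and rotation-equivariant.
    """
    x = np.asarray(positions, float)
    i, j = edges[:, 0], edges[:, 1]
    k = opposites[:, 0]
    interior = n_opp == 2
    L = np.where(
        interior[:, None],
        x[k] + x[np.where(interior, opposites[:, 1], 0)] - x[i] - x[j],
        x[k] - 0.5 * (x[i] + x[j]),
    )
    return L


def _diamond_vectors(edges, opposites, n_opp, positions):
    """Centered diamond vertex positions per edge, (E, 4, 3); the slot of a
    missing second opposite vertex is zeroed."""
    x = np.asarray(positions, float)
    i, j, k = edges[:, 0], edges[:, 1], opposites[:, 0]
    l = np.where(n_opp == 2, opposites[:, 1], 0)
    pts = np.stack([x[i], x[j], x[k], x[l]], axis=1)
    valid = np.ones(pts.shape[:2], bool)
    valid[:, 3] = n_opp == 2
    count = valid.sum(axis=1)[:, None]
    cen = (pts * valid[:, :, None]).sum(axis=1) / count
    vec = (pts - cen[:, None, :]) * valid[:, :, None]
    return vec


def _best_fit_edge_rotations(edges, opposites, n_opp, prev_pos, cur_pos):
    """Per-edge proper rotations best mapping rest diamonds to current."""
    a = _diamond_vectors(edges, opposites, n_opp, prev_pos)
    b = _diamond_vectors(edges, opposites, n_opp, cur_pos)
    M = np.einsum("eki,ekj->eij", b, a)  # sum_k b_k a_k^T
    U, _, Vt = np.linalg.svd(M)
    det = np.linalg.det(U @ Vt)
    S = np.repeat(np.eye(3)[None], len(M), axis=0)
    S[:, 2, 2] = det
    return U @ S @ Vt


def ereg_edge_laplacian(
    mesh: SurfaceMesh,
    prev_positions: np.ndarray,
    positions: np.ndarray,
) -> float:
    """Rotation-compensated per-edge Laplacian bending energy.

    (1 / sum_e A_e) * sum_e A_e || L_e(x) - R_e L_e(x_prev) ||^2, with R_e
    the best-fit per-edge rotation between the rest and current diamonds.
    Vanishes (to rounding) under any global rigid motion and is strictly
    positive under pure scaling.
    """
    edges, opposites, n_opp = edges_with_diamonds(mesh.triangles, mesh.n_vertices)
    _, A = edge_areas(mesh.with_vertices(np.asarray(prev_positions, float)))
    if not len(edges) or A.sum() <= 0:
        return 0.0
    R = _best_fit_edge_rotations(edges, opposites, n_opp, prev_positions, positions)
    Lp = _edge_laplacians(edges, opposites, n_opp, prev_positions)
    Lc = _edge_laplacians(edges, opposites, n_opp, positions)
    resid = Lc - np.einsum("eij,ej->ei", R, Lp)
    return float((A * np.einsum("ei,ei->e", resid, resid)).sum() / A.sum())


# ---------------------------------------------------------------------------
# fit schedules
# ---------------------------------------------------------------------------


@dataclass
class FitSchedule:
    """Stiff-to-soft non-rigid fitting schedule.

    ``lambdas`` must be strictly decreasing and positive; ``None`` selects
    a default 6-level geometric decay (factor 0.2) whose starting value is
    10x the initial fitting energy, which makes the first level nearly
    rigid.  ``prune_distances`` may be one value or one per level; the
    final level defaults to the 2 mm threshold used for error evaluation.
    """

    lambdas: tuple | None = None
    inner_iterations: int = 3
    prune_distances: tuple | float = (20.0, 15.0, 10.0, 8.0, 4.0, 2.0)
    prune_normal_angle: float = 60.0
    strategies: tuple | None = None
    landmark_weight: float = 10.0
    inner_shell_weight: float = 0.5
    release_step: bool = True
    release_stride: int = 20
    coarse_align: bool = False
    n_levels: int = 6
    decay: float = 0.2
    lambda0_factor: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.lambdas is not None:
            lam = np.asarray(self.lambdas, float)
            if np.any(lam <= 0) or np.any(np.diff(lam) >= 0):
                raise ValueError("lambdas must be positive and strictly decreasing")
            self.n_levels = len(lam)

    def level_lambdas(self, efit0: float) -> np.ndarray:
        if self.lambdas is not None:
            return np.asarray(self.lambdas, float)
        lam0 = self.lambda0_factor * max(float(efit0), 1.0)
        return lam0 * self.decay ** np.arange(self.n_levels)

    def level_prune_distance(self, level: int) -> float:
        pd = self.prune_distances
        if np.isscalar(pd):
            return float(pd)
        pd = list(pd)
        return float(pd[min(level, len(pd) - 1)])

    def level_strategy(self, level: int, n_levels: int) -> str:
        # default phase plan: hierarchical part alignment, then all-vertex
        # closest-point matching while the template is still far (curvature
        # gating would leave smooth regions unconstrained on low-feature
        # shapes), then the two-way search for the precise final levels
        if self.strategies is not None:
            st = list(self.strategies)
            return st[min(level, len(st) - 1)]
        if level == 0:
            return "hierarchical"
        if level < max(2, n_levels // 2):
            return "closest_point"
        return "two_way_v2s"

    def to_dict(self) -> dict:
        return {
            "lambdas": None if self.lambdas is None else [float(x) for x in self.lambdas],
            "inner_iterations": self.inner_iterations,
            "prune_distances": (
                float(self.prune_distances)
                if np.isscalar(self.prune_distances)
                else [float(x) for x in self.prune_distances]
            ),
            "prune_normal_angle": self.prune_normal_angle,
            "strategies": None if self.strategies is None else list(self.strategies),
            "landmark_weight": self.landmark_weight,
            "inner_shell_weight": self.inner_shell_weight,
            "release_step": self.release_step,
            "release_stride": self.release_stride,
            "coarse_align": self.coarse_align,
            "n_levels": self.n_levels,
            "decay": self.decay,
            "lambda0_factor": self.lambda0_factor,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitSchedule":
        d = dict(d)
        if d.get("lambdas") is not None:
            d["lambdas"] = tuple(d["lambdas"])
        if d.get("prune_distances") is not None and not np.isscalar(d["prune_distances"]):
            d["prune_distances"] = tuple(d["prune_distances"])
        return cls(**d)


# ---------------------------------------------------------------------------
# non-rigid skull fitting (volume-preservation regularizer)
# ---------------------------------------------------------------------------


def _volume_jacobian(tets, positions, rest_vol):
    """Sparse Jacobian of per-tet relative volume change wrt vertex coords."""
    v = positions
    t = tets
    a, b, c, d = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]], v[t[:, 3]]
    g2 = np.cross(c - a, d - a) / 6.0
    g3 = np.cross(d - a, b - a) / 6.0
    g4 = np.cross(b - a, c - a) / 6.0
    g1 = -(g2 + g3 + g4)
    grads = np.stack([g1, g2, g3, g4], axis=1) / rest_vol[:, None, None]
    rows = np.repeat(np.arange(len(t)), 12)
    cols = (3 * t[:, :, None] + np.arange(3)[None, None, :]).reshape(-1)
    vals = grads.reshape(-1)
    return coo_matrix((vals, (rows, cols)), shape=(len(t), 3 * len(v))).tocsr()


def _skull_energies(cset, positions, tets, prev_positions, rest_vol):
    wsum = max(cset.weights.sum(), 1e-300)
    pred = np.einsum(
        "ck,cki->ci", cset.bary, positions[cset.rows]
    )
    efit = float((cset.weights * ((pred - cset.targets) ** 2).sum(axis=1)).sum() / wsum)
    vol_prev = tet_volumes(prev_positions, tets)
    vol_cur = tet_volumes(positions, tets)
    ereg = float(np.mean(((vol_cur - vol_prev) / rest_vol) ** 2))
    return efit, ereg


def _fit_rows_matrix(cset: CorrespondenceSet, n_vertices: int):
    """Sparse (n_c, n_vertices) barycentric constraint matrix."""
    rows = np.repeat(np.arange(len(cset)), 3)
    cols = cset.rows.reshape(-1)
    vals = cset.bary.reshape(-1)
    return coo_matrix((vals, (rows, cols)), shape=(len(cset), n_vertices)).tocsr()


def _skull_inner_solve(cset, cur, prev, tets, rest_vol, lam, n_iters, trace, level):
    """Damped Gauss-Newton inner iterations at one schedule level.

    Minimizes Efit + lam * Ereg with the per-tet relative volume change
    linearized about the current state; step halving guarantees the energy
    never increases within an inner iteration.
    """
    n_vertices = len(cur)
    A_fit = _fit_rows_matrix(cset, n_vertices)
    wsum = max(cset.weights.sum(), 1e-300)
    sw = np.sqrt(cset.weights / wsum)
    Af = A_fit.multiply(sw[:, None]).tocsr()
    N_fit = _interleave_blocks((Af.T @ Af).tocsr())
    for inner in range(n_iters):
        efit, ereg = _skull_energies(cset, cur, tets, prev, rest_vol)
        energy = efit + lam * ereg
        trace.append(
            {"level": level, "iteration": inner, "efit": efit, "ereg": ereg,
             "lambda": float(lam), "energy": energy}
        )
        J_vol = _volume_jacobian(tets, cur, rest_vol) / np.sqrt(len(tets))
        r_vol = (
            (tet_volumes(cur, tets) - tet_volumes(prev, tets)) / rest_vol
        ) / np.sqrt(len(tets))
        fit_res = np.einsum("ck,cki->ci", cset.bary, cur[cset.rows]) - cset.targets
        N = N_fit + (J_vol.T @ J_vol).tocsr() * lam
        rhs = -(Af.T @ (sw[:, None] * fit_res)).reshape(-1) - lam * (J_vol.T @ r_vol)
        N = N + identity(N.shape[0]) * (1e-5 * max(N.diagonal().max(), 1.0))
        delta = factorized(N.tocsc())(rhs).reshape(-1, 3)
        step = 1.0
        for _ in range(12):
            cand = cur + step * delta
            e2f, e2r = _skull_energies(cset, cand, tets, prev, rest_vol)
            if e2f + lam * e2r <= energy + 1e-15:
                cur = cand
                break
            step *= 0.5
        else:
            break
        if energy - (e2f + lam * e2r) < 1e-9 * max(energy, 1e-12):
            break
    return cur


def nonrigid_fit_skull(
    template: TetMesh,
    target,
    schedule: FitSchedule | None = None,
    return_trace: bool = False,
):
    """Fit the tetrahedral skull template to a target skull surface.

    Minimizes the weighted correspondence energy plus a volume-preservation
    regularizer over a stiff-to-soft schedule (Gauss-Newton with step
    halving, so the energy never increases within an inner iteration).
    The rest state follows the schedule; a final release step re-deforms
    the undeformed template toward the fitted state through sparse points
    of interest (removing accumulated tangential distortion) and is
    followed by one soft re-attachment pass from the released rest state.
    Output connectivity is identical to the template's.
    """
    schedule = schedule or FitSchedule()
    tets = template.tets
    rest_vol = tet_volumes(template.vertices, template.tets)
    if np.any(rest_vol <= 0):
        raise MeshError("template rest state has non-positive tet volumes")

    boundary = template.boundary()
    cur = template.vertices.copy()
    if schedule.coarse_align:
        src = PointSet(cur)
        tgt = target if isinstance(target, PointSet) else PointSet(
            target.vertices if hasattr(target, "vertices") else np.asarray(target, float)
        )
        tf = coarse_align(src, tgt, seed=schedule.seed)
        tf = icp(PointSet(tf.apply(cur)), target, "similarity").compose(tf)
        cur = tf.apply(cur)

    # per-vertex fitting weights: outer boundary 1, inner boundary reduced
    vweights = np.full(template.n_vertices, schedule.inner_shell_weight)
    outer = _outer_shell_vertices(template)
    vweights[outer] = 1.0

    trace = []

    def correspondences(level, n_levels, positions):
        surf = boundary.with_vertices(positions)
        strat = schedule.level_strategy(level, n_levels)
        pd = schedule.level_prune_distance(level)
        if strat == "hierarchical":
            cset = hierarchical_icp(surf, target, depth=2, prune_distance=pd)
            cset.weights = vweights[cset.rows[:, 0]].copy()
            return cset
        return find_correspondences(
            surf, target, strat, pd, schedule.prune_normal_angle, weights=vweights
        )

    # probe initial fitting energy for the lambda schedule
    cset0 = correspondences(0, schedule.n_levels, cur)
    if not len(cset0):
        raise MeshError("no correspondences found; is the target aligned?")
    efit0, _ = _skull_energies(cset0, cur, tets, cur, rest_vol)
    lambdas = schedule.level_lambdas(efit0)

    prev = cur.copy()
    for level, lam in enumerate(lambdas):
        cset = cset0 if level == 0 else correspondences(level, len(lambdas), cur)
        if not len(cset):
            continue
        cur = _skull_inner_solve(
            cset, cur, prev, tets, rest_vol, lam, schedule.inner_iterations,
            trace, level,
        )
        prev = cur.copy()  # rest state follows each lambda decrease

    if schedule.release_step:
        cur = _release(template, cur, lambdas[0], schedule)
        # re-attach the released (distortion-free) state to the target with
        # one soft pass; the released state serves as the rest state
        prev = cur.copy()
        cset = correspondences(len(lambdas) - 1, len(lambdas), cur)
        if len(cset):
            cur = _skull_inner_solve(
                cset, cur, prev, tets, rest_vol, lambdas[-1],
                schedule.inner_iterations, trace, len(lambdas),
            )

    fitted = template.with_vertices(cur)
    if return_trace:
        return fitted, trace
    return fitted


def _interleave_blocks(N_coord):
    """Expand an (n, n) coefficient matrix acting identically on x, y, z to
    the (3n, 3n) system over interleaved coordinates."""
    N = N_coord.tocoo()
    rows = 3 * N.row
    cols = 3 * N.col
    data = N.data
    r = np.concatenate([rows, rows + 1, rows + 2])
    c = np.concatenate([cols, cols + 1, cols + 2])
    d = np.concatenate([data, data, data])
    n = N_coord.shape[0]
    return coo_matrix((d, (r, c)), shape=(3 * n, 3 * n)).tocsr()


def _outer_shell_vertices(template: TetMesh) -> np.ndarray:
    """Vertices of the boundary component with the largest mean radius."""
    from .mesh_core import vertex_components

    bnd = template.boundary()
    n_comp, labels = vertex_components(bnd)
    on_boundary = np.zeros(template.n_vertices, bool)
    on_boundary[np.unique(bnd.triangles)] = True
    if n_comp <= 1:
        return np.where(on_boundary)[0]
    center = template.vertices[on_boundary].mean(axis=0)
    best_lbl, best_r = None, -np.inf
    for lbl in np.unique(labels[on_boundary]):
        idx = np.where(on_boundary & (labels == lbl))[0]
        r = np.linalg.norm(template.vertices[idx] - center, axis=1).mean()
        if r > best_r:
            best_lbl, best_r = lbl, r
    return np.where(on_boundary & (labels == best_lbl))[0]


def _release(template: TetMesh, fitted_positions: np.ndarray, lam_stiff: float,
             schedule: FitSchedule) -> np.ndarray:
    """Release step: re-deform the *undeformed* template toward the fitted
    state through sparse points of interest (the named landmarks plus every
    k-th vertex), removing accumulated tangential distortion.

    The best similarity transform through the points of interest is factored
    out first; the residual displacement field is then interpolated by one
    stiff bi-Laplacian solve, so vertices between the points of interest
    follow the deformation smoothly instead of inheriting correspondence
    noise.
    """
    poi = set(int(i) for i in template.landmarks.values())
    poi.update(range(0, template.n_vertices, max(1, schedule.release_stride)))
    poi = np.array(sorted(poi), np.int64)
    try:
        tf = similarity_from_correspondences(
            template.vertices[poi], fitted_positions[poi]
        )
    except DegenerateCorrespondences:
        tf = SimilarityTransform.identity()
    base = tf.apply(template.vertices)
    d_poi = fitted_positions[poi] - base[poi]

    # normalized uniform graph Laplacian of the tet edge graph
    t = template.tets
    pairs = np.concatenate([t[:, [a, b]] for a, b in
                            [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]])
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    n = template.n_vertices
    i, j = pairs[:, 0], pairs[:, 1]
    deg = np.zeros(n)
    np.add.at(deg, i, 1.0)
    np.add.at(deg, j, 1.0)
    deg[deg == 0] = 1.0
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([i, j, j, i])
    data = np.concatenate([np.ones(len(i)), np.ones(len(i)),
                           -np.ones(2 * len(i))])
    Lg = coo_matrix((data / deg[rows], (rows, cols)), shape=(n, n)).tocsr()

    mu = 1e3
    P = coo_matrix(
        (np.ones(len(poi)), (np.arange(len(poi)), poi)), shape=(len(poi), n)
    ).tocsr()
    N = (Lg.T @ Lg) + mu * (P.T @ P)
    rhs = mu * (P.T @ d_poi)
    solve = factorized(N.tocsc())
    delta = np.column_stack([solve(rhs[:, c]) for c in range(3)])
    return base + delta


# ---------------------------------------------------------------------------
# non-rigid head fitting (per-edge Laplacian regularizer)
# ---------------------------------------------------------------------------


def _scan_to_template_correspondences(
    template: SurfaceMesh,
    target,
    prune_distance: float,
    prune_normal_angle: float,
    target_weights: np.ndarray | None = None,
    weight_fn=None,
):
    """Scan-point -> closest template surface point, with pruning.

    Returns a CorrespondenceSet whose rows carry barycentric coordinates of
    the foot point on the template; the constraint pulls that surface point
    toward the scan point.
    """
    tgt_pts, tgt_normals = _target_points_normals(target)
    if not len(tgt_pts) or not template.n_triangles:
        return CorrespondenceSet.empty()
    loc = _SurfaceLocator(template)
    cp, d, tri = loc.query(tgt_pts)
    from .mesh_core import face_normals as _fn

    nrm = _fn(template.vertices, template.triangles)[tri]
    cos_tol = np.cos(np.deg2rad(prune_normal_angle))
    ok = d <= prune_distance
    ok &= np.einsum("ij,ij->i", tgt_normals, nrm) >= cos_tol
    idx = np.where(ok)[0]
    rows, bary = _barycentric_on_triangle(template, tri[idx], cp[idx])
    w = np.ones(len(idx)) if target_weights is None else np.asarray(target_weights, float)[idx]
    if weight_fn is not None:
        # dynamic per-correspondence weights from the current template state
        # (foot points, scan points, template face normals at the feet)
        w = w * weight_fn(cp[idx], tgt_pts[idx], nrm[idx])
    return CorrespondenceSet(rows, bary, tgt_pts[idx], w), idx


def _head_efit(cset: CorrespondenceSet, positions: np.ndarray) -> float:
    if not len(cset):
        return 0.0
    wsum = max(cset.weights.sum(), 1e-300)
    pred = np.einsum("ck,cki->ci", cset.bary, positions[cset.rows])
    return float((cset.weights * ((pred - cset.targets) ** 2).sum(axis=1)).sum() / wsum)


def _laplacian_rows_matrix(edges, opposites, n_opp, n_vertices):
    """Sparse (E, n) matrix applying the diamond second difference."""
    E = len(edges)
    i, j, k = edges[:, 0], edges[:, 1], opposites[:, 0]
    interior = n_opp == 2
    l = np.where(interior, opposites[:, 1], 0)
    rows = np.repeat(np.arange(E), 4)
    cols = np.stack([i, j, k, l], axis=1).reshape(-1)
    coefs = np.where(
        interior[:, None],
        np.array([-1.0, -1.0, 1.0, 1.0]),
        np.array([-0.5, -0.5, 1.0, 0.0]),
    ).reshape(-1)
    return coo_matrix((coefs, (rows, cols)), shape=(E, n_vertices)).tocsr()


def nonrigid_fit_head(
    template: SurfaceMesh,
    target,
    landmarks: list | None = None,
    schedule: FitSchedule | None = None,
    target_weights: np.ndarray | None = None,
    dynamic_weight=None,
    return_trace: bool = False,
):
    """Fit the surface head template to a scan point set.

    Correspondences are scan-point to closest template surface point
    (pruned by distance and normal deviation), optionally extended by
    landmark pairs ``(template vertex index, target point)`` at elevated
    weight.  ``target_weights`` assigns per-scan-point weights (e.g. the
    outside-weighting rule, or down-weighted hair/artifact regions).
    The per-edge Laplacian bending energy regularizes the deformation; the
    fit alternates per-edge rotation estimation with a sparse linear solve.
    """
    schedule = schedule or FitSchedule()
    edges, opposites, n_opp = edges_with_diamonds(template.triangles, template.n_vertices)
    _, A_e = edge_areas(template)
    A_e = A_e / max(A_e.sum(), 1e-300)
    L = _laplacian_rows_matrix(edges, opposites, n_opp, template.n_vertices)
    sqA = np.sqrt(A_e)

    cur = template.vertices.copy()
    if schedule.coarse_align:
        tf = icp(PointSet(cur), target, "similarity")
        cur = tf.apply(cur)

    lm_set = CorrespondenceSet.empty()
    if landmarks:
        lm_idx = np.array([int(i) for i, _ in landmarks], np.int64)
        lm_pts = np.array([p for _, p in landmarks], float)
        lm_set = CorrespondenceSet.from_vertices(
            lm_idx, lm_pts, np.full(len(lm_idx), schedule.landmark_weight)
        )

    def correspondences(level, positions):
        surf = template.with_vertices(positions)
        pd = schedule.level_prune_distance(level)
        cset, _ = _scan_to_template_correspondences(
            surf, target, pd, schedule.prune_normal_angle, target_weights,
            weight_fn=dynamic_weight,
        )
        if len(lm_set):
            cset = cset.merged(lm_set)
        return cset

    cset0 = correspondences(0, cur)
    if not len(cset0):
        raise MeshError("no correspondences found; is the target aligned?")
    efit0 = _head_efit(cset0, cur)
    lambdas = schedule.level_lambdas(efit0)

    trace = []
    prev = cur.copy()
    for level, lam in enumerate(lambdas):
        cset = cset0 if level == 0 else correspondences(level, cur)
        if not len(cset):
            continue
        A_fit = _fit_rows_matrix(cset, template.n_vertices)
        wsum = max(cset.weights.sum(), 1e-300)
        sw = np.sqrt(cset.weights / wsum)
        Af = A_fit.multiply(sw[:, None]).tocsr()
        N_fit = (Af.T @ Af).tocsr()
        N_reg = (L.multiply(sqA[:, None]).T @ L.multiply(sqA[:, None])).tocsr()
        N = (N_fit + lam * N_reg).tocsc()
        N = N + identity(N.shape[0]) * (1e-12 * max(N.diagonal().max(), 1.0))
        solve = factorized(N)
        for inner in range(schedule.inner_iterations):
            # local step: per-edge rotations from the current shape
            R = _best_fit_edge_rotations(edges, opposites, n_opp, prev, cur)
            Lp = _edge_laplacians(edges, opposites, n_opp, prev)
            b_reg = np.einsum("eij,ej->ei", R, Lp)
            efit = _head_efit(cset, cur)
            resid = _edge_laplacians(edges, opposites, n_opp, cur) - b_reg
            ereg = float((A_e * np.einsum("ei,ei->e", resid, resid)).sum())
            trace.append(
                {"level": level, "iteration": inner, "efit": efit, "ereg": ereg,
                 "lambda": float(lam), "energy": efit + lam * ereg}
            )
            # global step: solve for positions, one RHS per coordinate
            rhs = Af.T @ (sw[:, None] * cset.targets) + lam * (
                L.multiply(sqA[:, None]).T @ (sqA[:, None] * b_reg)
            )
            new = np.column_stack([solve(rhs[:, c]) for c in range(3)])
            if np.linalg.norm(new - cur) < 1e-12 * max(np.linalg.norm(cur), 1.0):
                cur = new
                break
            cur = new
        prev = cur.copy()

    fitted = template.with_vertices(cur)
    if return_trace:
        return fitted, trace
    return fitted


def write_energy_trace(trace: list, path: str) -> None:
    """Write a fitter's energy trace as CSV (level, iteration, efit, ereg,
    lambda, energy)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["level", "iteration", "efit", "ereg", "lambda", "energy"]
        )
        writer.writeheader()
        writer.writerows(trace)


def rms_error(
    fitted: SurfaceMesh,
    target,
    target_weights: np.ndarray | None = None,
    prune_distance: float = 2.0,
    prune_normal_angle: float = 60.0,
) -> float:
    """Weighted RMS distance over surviving scan-to-surface correspondences.

    Correspondences farther than ``prune_distance`` (2 mm by default) are
    excluded, mirroring the pruning used during fitting.
    """
    cset, _ = _scan_to_template_correspondences(
        fitted, target, prune_distance, prune_normal_angle, target_weights
    )
    if not len(cset):
        return float("nan")
    return float(np.sqrt(_head_efit(cset, fitted.vertices)))
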