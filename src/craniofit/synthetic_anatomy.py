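"""Synthetic skull/head anatomy with known ground truth.

Real craniofacial model building starts from CT head scans, which cannot be
shipped with a software package.  This module generates a stand-in study
population: a skull-like tetrahedral template (a thick shell between two
deformed icospheres with orbit/jaw indentations), a matching outer head
surface, and subject populations obtained by low-rank smooth radial
deformation modes plus a smooth, strictly positive soft-tissue-thickness
field.  Every generated quantity has a known ground truth (mode weights,
per-vertex thickness), which is what the registration, statistics and
reconstruction tests measure against.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .mesh_core import (
    MeshError,
    PointSet,
    SurfaceMesh,
    TetMesh,
    VoxelVolume,
    _SurfaceLocator,
    face_normals,
    tet_volumes,
    vertex_normals,
)

__all__ = [
    "SyntheticSubject",
    "PopulationSpec",
    "TemplatePair",
    "make_template_pair",
    "make_mode_basis",
    "make_subject",
    "make_population",
    "crop_partial",
    "voxelize",
]

# Face looks along +x, up is +z.  Directions of the named landmarks and of
# the skull-like indentations, all unit vectors.
_LANDMARK_DIRECTIONS = {
    "nasion": (0.97, 0.0, 0.26),
    "menton": (0.88, 0.0, -0.48),
    "mid_supraorbitale_l": (0.84, 0.32, 0.44),
    "mid_supraorbitale_r": (0.84, -0.32, 0.44),
    "porion_l": (0.05, 0.99, -0.10),
    "porion_r": (0.05, -0.99, -0.10),
    "ciliare_lateralis_l": (0.74, 0.60, 0.30),
    "ciliare_lateralis_r": (0.74, -0.60, 0.30),
    "ciliare_medialis_l": (0.92, 0.22, 0.31),
    "ciliare_medialis_r": (0.92, -0.22, 0.31),
}

RECONSTRUCTION_LANDMARKS = tuple(_LANDMARK_DIRECTIONS)

# (direction, depth fraction, angular width in radians) of the three radial
# indentations that give the base shape its orbit- and jaw-like curvature.
_INDENTATIONS = [
    ((0.85, 0.33, 0.41), 0.055, 0.28),
    ((0.85, -0.33, 0.41), 0.055, 0.28),
    ((0.90, 0.0, -0.43), 0.045, 0.35),
]


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _base_radial_profile(directions: np.ndarray) -> np.ndarray:
    """Relative radius (~1) of the skull-like base shape per unit direction."""
    rel = np.ones(len(directions))
    for d, depth, width in _INDENTATIONS:
        ang = np.arccos(np.clip(directions @ _unit(d), -1.0, 1.0))
        rel -= depth * np.exp(-((ang / width) ** 2))
    return rel


@dataclass
class TemplatePair:
    """Skull tet template + head surface template with shared landmarks.

    The skull is a tetrahedralized shell; its first ``n_shell`` vertices are
    the outer shell and coincide direction-wise with the head template's
    vertices, which share the icosphere connectivity.
    """

    skull: TetMesh
    head: SurfaceMesh
    n_shell: int
    directions: np.ndarray  # (n_shell, 3) unit directions of shell vertices
    center: np.ndarray
    outer_radii: np.ndarray  # (n_shell,) base outer-shell radii in mm
    shell_thickness: float
    head_offset: float


@dataclass
class SyntheticSubject:
    """One generated subject: skull + skin with known ground truth."""

    skull_surface: SurfaceMesh
    skin_surface: SurfaceMesh
    true_fstt: np.ndarray  # per skull-template-vertex thickness (mm)
    mode_weights: np.ndarray
    seed: int
    skull_tet: TetMesh | None = None  # ground-truth deformed template


@dataclass
class PopulationSpec:
    """Study-population parameters for :func:`make_population`.

    Defaults emulate a small adult study group: ~75 mm skull radius with a
    few-mm low-rank shape variation and a 5 mm mean soft-tissue layer with
    ~1 mm smooth spatial/individual variation.
    """

    n_subjects: int = 10
    rank: int = 3
    mode_amplitudes: tuple = (4.0, 2.5, 1.5)
    thickness_base: float = 5.0
    thickness_variation: float = 1.0
    thickness_bumps: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.rank >= self.n_subjects:
            raise ValueError("rank must be < n_subjects")
        if np.any(np.asarray(self.mode_amplitudes) < 0):
            raise ValueError("mode amplitudes must be >= 0")
        if len(self.mode_amplitudes) < self.rank:
            raise ValueError("need one amplitude per mode")


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------


def _split_prisms(bottom: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Conforming 3-tet split of triangular prisms (Dompierre's rule).

    ``bottom``/``top`` are (m, 3) global vertex indices with vertical edges
    bottom[i] - top[i].  Each quad face is split by the diagonal through its
    smallest global vertex index, which makes the decomposition agree across
    neighbouring prisms.
    """
    tets = []
    for b, t in zip(bottom, top):
        p = [b[0], b[1], b[2], t[0], t[1], t[2]]
        # bring the smallest global index to local position 0 (bottom)
        if min(p[3:]) < min(p[:3]):
            p = [p[3], p[5], p[4], p[0], p[2], p[1]]
        r = int(np.argmin(p[:3]))
        p = [p[r], p[(r + 1) % 3], p[(r + 2) % 3],
             p[3 + r], p[3 + (r + 1) % 3], p[3 + (r + 2) % 3]]
        if min(p[1], p[5]) < min(p[2], p[4]):
            tets += [(p[0], p[1], p[2], p[5]), (p[0], p[1], p[5], p[4]),
                     (p[0], p[4], p[5], p[3])]
        else:
            tets += [(p[0], p[1], p[2], p[4]), (p[0], p[4], p[2], p[5]),
                     (p[0], p[4], p[5], p[3])]
    return np.asarray(tets, np.int64)


def make_template_pair(
    subdivisions: int = 3,
    shell_thickness: float = 6.0,
    outer_radius: float = 75.0,
    head_offset: float = 5.0,
    n_facial_landmarks: int = 70,
) -> TemplatePair:
    """Build the skull/head template pair.

    The skull template is the tetrahedralized shell between two offset
    copies of the skull-like base surface (icosphere with orbit/jaw
    indentations); the head template is the same surface pushed outward by
    ``head_offset`` (a nominal soft-tissue layer).  Both carry the 10 named
    reconstruction landmarks, ``n_facial_landmarks`` facial landmarks, and
    the ``facial_region`` / ``calvaria`` vertex groups at fixed indices.
    """
    if subdivisions < 1:
        raise ValueError("subdivisions must be >= 1")
    if shell_thickness <= 0:
        raise ValueError("shell_thickness must be positive")
    if not 0 < shell_thickness < outer_radius:
        raise ValueError("shell_thickness must be below the outer radius")

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    directions = np.asarray(ico.vertices, float)
    directions /= np.linalg.norm(directions, axis=1)[:, None]
    faces = np.asarray(ico.faces, np.int64)
    n = len(directions)

    rel = _base_radial_profile(directions)
    outer_r = outer_radius * rel
    inner_r = outer_r - shell_thickness
    outer_v = directions * outer_r[:, None]
    inner_v = directions * inner_r[:, None]
    verts = np.vstack([outer_v, inner_v])

    # prisms between the shells; bottom = inner, top = outer
    tets = _split_prisms(faces + n, faces)
    vols = tet_volumes(verts, tets)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    if np.any(tet_volumes(verts, tets) <= 0):
        raise MeshError("degenerate tetrahedra in template shell")

    landmarks = {
        name: int(np.argmax(directions @ _unit(d)))
        for name, d in _LANDMARK_DIRECTIONS.items()
    }
    facial = np.where(directions[:, 0] > 0.3)[0]
    calvaria = np.where(directions[:, 2] > 0.62)[0]
    step = max(1, len(facial) // n_facial_landmarks)
    facial_lm = facial[::step][:n_facial_landmarks]
    groups = {
        "facial_region": facial,
        "calvaria": calvaria,
        "facial_landmarks": facial_lm,
    }
    lm_all = dict(landmarks)
    for i, idx in enumerate(facial_lm):
        lm_all[f"facial_{i:02d}"] = int(idx)

    skull = TetMesh(verts, tets, lm_all, {k: v.copy() for k, v in groups.items()})
    head = SurfaceMesh(
        directions * (outer_r + head_offset)[:, None],
        faces.copy(),
        dict(lm_all),
        {k: v.copy() for k, v in groups.items()},
    )
    return TemplatePair(
        skull=skull,
        head=head,
        n_shell=n,
        directions=directions,
        center=np.zeros(3),
        outer_radii=outer_r,
        shell_thickness=float(shell_thickness),
        head_offset=float(head_offset),
    )


# ---------------------------------------------------------------------------
# population modes and thickness fields
# ---------------------------------------------------------------------------

# low-order smooth angular profiles; entry k is the k-th deformation mode
_MODE_PROFILES = [
    lambda u: u[:, 0],
    lambda u: u[:, 2],
    lambda u: u[:, 1],
    lambda u: u[:, 0] * u[:, 2] * 2.0,
    lambda u: (u[:, 0] ** 2 - u[:, 1] ** 2),
    lambda u: u[:, 1] * u[:, 2] * 2.0,
]


def mode_profile(directions: np.ndarray, k: int) -> np.ndarray:
    """Scalar radial-displacement profile of mode ``k`` (max amplitude ~1)."""
    if k >= len(_MODE_PROFILES):
        raise ValueError(f"only {len(_MODE_PROFILES)} deformation modes defined")
    return _MODE_PROFILES[k](np.asarray(directions, float))


def make_mode_basis(templates: TemplatePair, rank: int) -> np.ndarray:
    """Stacked displacement basis for the skull template, shape (3m, rank).

    Column k moves every skull vertex radially by ``mode_profile`` evaluated
    at its direction, so a weight of w mm displaces the surface by up to
    ~w mm.  Both shells move together (the shell thickness is preserved).
    """
    m = templates.skull.n_vertices
    n = templates.n_shell
    dirs = templates.directions
    basis = np.zeros((3 * m, rank))
    for k in range(rank):
        g = mode_profile(dirs, k)
        disp = dirs * g[:, None]  # (n, 3)
        full = np.vstack([disp, disp])  # outer and inner shells move together
        basis[:, k] = full.reshape(-1)
    return basis


def _thickness_field(
    directions: np.ndarray,
    base: float,
    variation: float,
    n_bumps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth strictly positive thickness (mm) over unit directions."""
    t = np.full(len(directions), float(base))
    if variation > 0 and n_bumps > 0:
        scale = variation / np.sqrt(n_bumps)
        for _ in range(n_bumps):
            d = _unit(rng.normal(size=3))
            width = rng.uniform(0.5, 0.9)
            amp = rng.normal(0.0, scale) * np.sqrt(n_bumps)
            ang = np.arccos(np.clip(directions @ d, -1.0, 1.0))
            t += amp * np.exp(-((ang / width) ** 2))
    return t


def make_subject(
    templates: TemplatePair,
    mode_basis: np.ndarray,
    mode_weights: np.ndarray,
    thickness_params: dict | None = None,
    seed: int = 0,
    smooth_iterations: int = 1,
) -> SyntheticSubject:
    """Generate one subject from mode weights and a thickness seed.

    The skull is the template displaced by ``mode_basis @ mode_weights``;
    the skin is the deformed outer shell offset outward by the smooth
    thickness field, lightly Laplacian-smoothed.  If the drawn thickness
    field would produce a self-intersecting (non-positive-gap) skin, the
    variation is halved and the field redrawn, with a warning.
    """
    tp = thickness_params or {}
    base = float(tp.get("base", 5.0))
    variation = float(tp.get("variation", 1.0))
    n_bumps = int(tp.get("n_bumps", 4))

    mode_weights = np.zeros(mode_basis.shape[1]) if mode_weights is None else (
        np.asarray(mode_weights, float)
    )
    disp = (mode_basis @ mode_weights).reshape(-1, 3)
    skull_verts = templates.skull.vertices + disp
    skull_tet = templates.skull.with_vertices(skull_verts)

    n = templates.n_shell
    dirs = templates.directions
    rng = np.random.default_rng(seed)
    for attempt in range(8):
        t_outer = _thickness_field(dirs, base, variation * 0.5**attempt, n_bumps, rng)
        if t_outer.min() > 0.25 * base:
            break
        warnings.warn("thickness field nearly self-intersecting; redrawing with reduced variation")
    t_outer = np.maximum(t_outer, 0.25 * base)

    skin_verts = skull_verts[:n] + dirs * t_outer[:, None]
    faces = templates.head.triangles
    skin = SurfaceMesh(skin_verts, faces.copy(), dict(templates.head.landmarks),
                       {k: np.asarray(v).copy() for k, v in templates.head.vertex_groups.items()})
    for _ in range(smooth_iterations):
        skin = _laplacian_smooth(skin, 0.1)

    # ground-truth distance field: exact shortest distance to the final skin
    loc = _SurfaceLocator(skin)
    true_fstt = loc.query(skull_verts)[1]

    # invariant: skin strictly outside skull
    if true_fstt[:n].min() <= 0:
        raise MeshError("generated skin touches the skull; increase base thickness")

    return SyntheticSubject(
        skull_surface=skull_tet.boundary(),
        skin_surface=skin,
        true_fstt=true_fstt,
        mode_weights=mode_weights,
        seed=int(seed),
        skull_tet=skull_tet,
    )


def _laplacian_smooth(mesh: SurfaceMesh, lam: float) -> SurfaceMesh:
    v, t = mesh.vertices, mesh.triangles
    acc = np.zeros_like(v)
    deg = np.zeros(len(v))
    for a, b in [(0, 1), (1, 2), (2, 0)]:
        np.add.at(acc, t[:, a], v[t[:, b]])
        np.add.at(acc, t[:, b], v[t[:, a]])
        np.add.at(deg, t[:, a], 1)
        np.add.at(deg, t[:, b], 1)
    deg[deg == 0] = 1
    return mesh.with_vertices(v + lam * (acc / deg[:, None] - v))


def make_population(spec: PopulationSpec, templates: TemplatePair) -> list[SyntheticSubject]:
    """Draw a population of subjects with the requested per-mode amplitudes.

    Mode weights are centred normal draws scaled by ``mode_amplitudes``;
    the empirical covariance of skull vertices therefore has numerical rank
    equal to ``spec.rank``.
    """
    rng = np.random.default_rng(spec.seed)
    basis = make_mode_basis(templates, spec.rank)
    amps = np.asarray(spec.mode_amplitudes[: spec.rank], float)
    subjects = []
    for i in range(spec.n_subjects):
        w = rng.normal(size=spec.rank) * amps
        sub_seed = int(rng.integers(0, 2**31 - 1))
        subjects.append(
            make_subject(
                templates,
                basis,
                w,
                {"base": spec.thickness_base,
                 "variation": spec.thickness_variation,
                 "n_bumps": spec.thickness_bumps},
                seed=sub_seed,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# cropping and voxelization
# ---------------------------------------------------------------------------


def crop_partial(mesh: SurfaceMesh, plane_point, plane_normal) -> SurfaceMesh:
    """Remove all triangles lying entirely on the negative side of a plane.

    Emulates the cropped fields of view of clinical CT (missing calvaria,
    cropped nose).  The result may have an open boundary; an entirely
    negative mesh comes back empty.
    """
    p0 = np.asarray(plane_point, float).reshape(3)
    nrm = _unit(plane_normal)
    side = (mesh.vertices - p0) @ nrm
    neg = side < 0
    keep = ~neg[mesh.triangles].all(axis=1)
    out = SurfaceMesh(mesh.vertices.copy(), mesh.triangles[keep],
                      dict(mesh.landmarks),
                      {k: np.asarray(v).copy() for k, v in mesh.vertex_groups.items()})
    return out.clean()


def _radial_hit_radius(mesh: SurfaceMesh, center: np.ndarray, dirs_q: np.ndarray) -> np.ndarray:
    """Distance from ``center`` to the mesh along each unit direction.

    Exact ray-triangle intersection; valid because every generated surface is
    star-shaped about the subject centre (each ray hits it exactly once).
    """
    from scipy.spatial import cKDTree

    v = mesh.vertices - center
    tri = mesh.triangles
    cen = v[tri].mean(axis=1)
    cdir = cen / np.linalg.norm(cen, axis=1)[:, None]
    tree = cKDTree(cdir)
    m = len(tri)
    out = np.full(len(dirs_q), np.nan)
    k = min(12, m)
    pending = np.arange(len(dirs_q))
    while len(pending) and k <= m:
        _, idx = tree.query(dirs_q[pending], k=k)
        idx = idx.reshape(len(pending), -1)
        a = v[tri[idx, 0]]
        e1 = v[tri[idx, 1]] - a
        e2 = v[tri[idx, 2]] - a
        u = dirs_q[pending][:, None, :]
        p = np.cross(u, e2)
        det = np.einsum("qkj,qkj->qk", e1, p)
        safe = np.where(np.abs(det) > 1e-14, det, 1.0)
        tvec = -a
        b1 = np.einsum("qkj,qkj->qk", tvec, p) / safe
        qv = np.cross(tvec, e1)
        b2 = np.einsum("qj,qkj->qk", dirs_q[pending], qv) / safe
        t = np.einsum("qkj,qkj->qk", e2, qv) / safe
        eps = 1e-9
        valid = (
            (np.abs(det) > 1e-14)
            & (b1 >= -eps)
            & (b2 >= -eps)
            & (b1 + b2 <= 1 + eps)
            & (t > 0)
        )
        t = np.where(valid, t, np.inf)
        best = t.min(axis=1)
        hit = np.isfinite(best)
        out[pending[hit]] = best[hit]
        pending = pending[~hit]
        if k == m:
            break
        k = min(m, 4 * k)
    if len(pending):
        # numerical corner case (ray grazing an edge): nearest-vertex radius
        vtree = cKDTree(v / np.linalg.norm(v, axis=1)[:, None])
        _, nearest = vtree.query(dirs_q[pending], k=1)
        out[pending] = np.linalg.norm(v[nearest], axis=1)
    return out


def voxelize(subject: SyntheticSubject, spacing: float = 1.5, margin: float = 6.0) -> VoxelVolume:
    """Rasterize a subject into a Hounsfield-like volume.

    Air outside the skin is -1000 HU, soft tissue between skin and outer
    skull surface +40 HU, the bony shell +1000 HU, and the cranial cavity
    +40 HU again — values chosen to straddle the -200 (skin) and 600 (bone)
    extraction iso-levels.
    """
    skin = subject.skin_surface
    skull_bnd = subject.skull_surface
    # split the skull boundary into outer and inner shells by area
    from .mesh_core import largest_component, vertex_components

    n_comp, labels = vertex_components(skull_bnd)
    if n_comp < 2:
        outer = inner = skull_bnd
    else:
        counts = np.bincount(labels)
        comps = []
        for lbl in range(n_comp):
            keep = labels == lbl
            new_index = np.cumsum(keep) - 1
            tri_keep = keep[skull_bnd.triangles].all(axis=1)
            comps.append(
                SurfaceMesh(skull_bnd.vertices[keep], new_index[skull_bnd.triangles[tri_keep]])
            )
        # outer shell = larger mean radius about the common centroid
        center = skull_bnd.vertices.mean(axis=0)
        radii = [np.linalg.norm(c.vertices - center, axis=1).mean() for c in comps]
        order = np.argsort(radii)
        inner, outer = comps[order[0]], comps[order[-1]]

    lo = skin.vertices.min(axis=0) - margin
    hi = skin.vertices.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    center = skin.vertices.mean(axis=0)
    rel = grid - center
    r = np.linalg.norm(rel, axis=1)
    r_safe = np.where(r > 1e-12, r, 1.0)
    dirs_q = rel / r_safe[:, None]
    dirs_q[r <= 1e-12] = (1.0, 0.0, 0.0)

    r_skin = _radial_hit_radius(skin, center, dirs_q)
    vals = np.full(len(grid), -1000.0)
    inside_skin = r <= r_skin
    vals[inside_skin] = 40.0
    # the skull shells only matter for voxels inside the skin
    sub = np.where(inside_skin)[0]
    if len(sub):
        r_outer = _radial_hit_radius(outer, center, dirs_q[sub])
        r_inner = _radial_hit_radius(inner, center, dirs_q[sub])
        bone = (r[sub] <= r_outer) & (r[sub] >= r_inner)
        vals[sub[bone]] = 1000.0
    return VoxelVolume(vals.reshape(shape), np.full(3, float(spacing)), lo)
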