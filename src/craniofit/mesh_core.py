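"""Mesh and point-set data types, geometry kernels, and standard-format I/O.

Coordinates are always in millimetres.  Surface meshes are triangle meshes;
volumetric (skull) templates are tetrahedral meshes whose outer boundary is
exposed as a :class:`SurfaceMesh` view.  Scalar voxel volumes use a
Hounsfield-like intensity scale and carry their voxel spacing and origin so
that extracted iso-surfaces live in world (mm) coordinates; the origin is the
world position of the centre of voxel (0, 0, 0).
"""

from __future__ import annotations

import heapq
import json
import os
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceMesh",
    "TetMesh",
    "PointSet",
    "VoxelVolume",
    "MeshError",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_volume",
    "write_volume",
    "extract_isosurface",
    "largest_component",
    "decimate",
    "closest_surface_point",
    "surface_distances",
    "triangle_areas",
    "vertex_normals",
    "mean_curvature",
    "high_curvature_mask",
    "edge_areas",
    "edges_with_diamonds",
    "tet_volumes",
    "enclosed_volume",
]


class MeshError(ValueError):
    """Invalid mesh data or query (empty mesh, bad indices, ...)."""


class MeshFormatError(MeshError):
    """Malformed file or unsupported format."""


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangle surface mesh with optional named landmarks.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array of vertex indices
    landmarks : dict mapping landmark name -> vertex index
    vertex_groups : dict mapping group name -> int array of vertex indices
        (used e.g. for the facial-region mask of templates)
    """

    vertices: np.ndarray
    triangles: np.ndarray
    landmarks: dict = field(default_factory=dict)
    vertex_groups: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise MeshError("triangle index out of range")

    # -- basic properties ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            dict(self.landmarks),
            {k: np.asarray(v).copy() for k, v in self.vertex_groups.items()},
        )

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        """Same connectivity/landmarks with replaced vertex positions."""
        out = self.copy()
        out.vertices = np.ascontiguousarray(vertices, dtype=np.float64).reshape(-1, 3)
        if len(out.vertices) != self.n_vertices:
            raise MeshError("vertex count mismatch")
        return out

    def bounding_box_diagonal(self) -> float:
        if not len(self.vertices):
            return 0.0
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def clean(self, merge_tol: float = 1e-6) -> "SurfaceMesh":
        """Merge duplicate vertices, drop unreferenced vertices and
        degenerate (zero-area) triangles.  Vertex order is preserved
        (first occurrence wins); landmark indices are remapped."""
        v, t = self.vertices, self.triangles
        if not len(v):
            return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        # merge duplicates within tolerance via rounded-coordinate hashing
        key = np.round(v / max(merge_tol, 1e-12)).astype(np.int64)
        _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
        # remap every vertex to the first occurrence of its bucket
        remap = first[inverse]
        t2 = remap[t] if t.size else t
        # drop degenerate triangles (repeated index or ~zero area)
        if t2.size:
            a, b, c = t2[:, 0], t2[:, 1], t2[:, 2]
            distinct = (a != b) & (b != c) & (a != c)
            t2 = t2[distinct]
            if t2.size:
                areas = triangle_areas(v, t2)
                t2 = t2[areas > merge_tol**2]
        # drop unreferenced vertices, preserving order
        if t2.size:
            used = np.zeros(len(v), bool)
            used[t2.ravel()] = True
        else:
            used = np.zeros(len(v), bool)
            used[np.unique(remap)] = True
        new_index = np.cumsum(used) - 1
        v2 = v[used]
        t3 = new_index[t2] if t2.size else t2.reshape(-1, 3)
        lm = {}
        for name, idx in self.landmarks.items():
            j = remap[int(idx)]
            if used[j]:
                lm[name] = int(new_index[j])
        groups = {}
        for name, idx in self.vertex_groups.items():
            j = np.unique(remap[np.asarray(idx, int)])
            j = j[used[j]]
            groups[name] = new_index[j]
        return SurfaceMesh(v2, t3, lm, groups)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def as_pointset(self) -> "PointSet":
        normals = vertex_normals(self) if self.triangles.size else None
        return PointSet(self.vertices.copy(), normals)


@dataclass
class TetMesh:
    """Tetrahedral mesh (the volumetric skull template).

    All tetrahedra must have strictly positive signed volume in the rest
    state.  ``boundary()`` extracts the outer triangle surface (faces
    belonging to exactly one tet), oriented outward.
    """

    vertices: np.ndarray
    tets: np.ndarray
    landmarks: dict = field(default_factory=dict)
    vertex_groups: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64).reshape(-1, 4)
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.vertices)):
            raise MeshError("tet index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "TetMesh":
        return TetMesh(
            self.vertices.copy(),
            self.tets.copy(),
            dict(self.landmarks),
            {k: np.asarray(v).copy() for k, v in self.vertex_groups.items()},
        )

    def with_vertices(self, vertices: np.ndarray) -> "TetMesh":
        out = self.copy()
        out.vertices = np.ascontiguousarray(vertices, dtype=np.float64).reshape(-1, 3)
        if len(out.vertices) != self.n_vertices:
            raise MeshError("vertex count mismatch")
        return out

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.vertices, self.tets)

    def boundary_faces(self) -> np.ndarray:
        """Outward-oriented boundary triangles (faces on exactly one tet)."""
        # local faces chosen so the outward normal of a positive tet points
        # away from the opposite vertex
        t = self.tets
        faces = np.concatenate(
            [
                t[:, [0, 2, 1]],
                t[:, [0, 1, 3]],
                t[:, [0, 3, 2]],
                t[:, [1, 2, 3]],
            ]
        )
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]

    def boundary(self) -> SurfaceMesh:
        """Boundary surface view; vertex indices are shared with the tet mesh
        (unreferenced interior vertices are retained so indices line up)."""
        return SurfaceMesh(
            self.vertices, self.boundary_faces(), dict(self.landmarks),
            {k: np.asarray(v).copy() for k, v in self.vertex_groups.items()},
        )


@dataclass
class PointSet:
    """Plain point cloud with optional unit normals and integer labels."""

    points: np.ndarray
    normals: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64).reshape(-1, 3)
            norms = np.linalg.norm(self.normals, axis=1)
            if len(norms) and np.any(np.abs(norms - 1.0) > 1e-8):
                raise MeshError("point normals must have unit length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).ravel()

    def __len__(self) -> int:
        return len(self.points)

    def bounding_box_diagonal(self) -> float:
        if not len(self.points):
            return 0.0
        ext = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.linalg.norm(ext))


@dataclass
class VoxelVolume:
    """Scalar voxel grid in Hounsfield-like units.

    ``origin`` is the world (mm) position of the centre of voxel (0, 0, 0);
    world position of voxel index ``(i, j, k)`` is ``origin + spacing * ijk``.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).ravel()
        self.origin = np.asarray(self.origin, dtype=np.float64).ravel()
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise MeshError("volume must be a 3D grid with >= 2 voxels per axis")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise MeshError("spacing must be three positive numbers")
        if self.origin.shape != (3,):
            raise MeshError("origin must be a 3-vector")


# ---------------------------------------------------------------------------
# geometry kernels
# ---------------------------------------------------------------------------


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, float)
    t = np.asarray(triangles, int)
    if not t.size:
        return np.zeros(0)
    e1 = v[t[:, 1]] - v[t[:, 0]]
    e2 = v[t[:, 2]] - v[t[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def face_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, float)
    t = np.asarray(triangles, int)
    n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    lens = np.linalg.norm(n, axis=1)
    lens[lens == 0] = 1.0
    return n / lens[:, None]


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted vertex normals (unit length; zero for isolated verts)."""
    v, t = mesh.vertices, mesh.triangles
    n = np.zeros_like(v)
    if t.size:
        fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])  # 2*area weighted
        for k in range(3):
            np.add.at(n, t[:, k], fn)
    lens = np.linalg.norm(n, axis=1)
    lens[lens == 0] = 1.0
    return n / lens[:, None]


def tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed tetrahedron volumes det([b-a, c-a, d-a]) / 6."""
    v = np.asarray(vertices, float)
    t = np.asarray(tets, int)
    if not t.size:
        return np.zeros(0)
    a = v[t[:, 0]]
    m = np.stack([v[t[:, 1]] - a, v[t[:, 2]] - a, v[t[:, 3]] - a], axis=1)
    return np.linalg.det(m) / 6.0


def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Volume enclosed by a closed, outward-oriented surface
    (divergence theorem over signed origin-tetrahedra)."""
    v, t = mesh.vertices, mesh.triangles
    if not t.size:
        return 0.0
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def _vertex_barycentric_areas(mesh: SurfaceMesh) -> np.ndarray:
    areas = triangle_areas(mesh.vertices, mesh.triangles)
    va = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(va, mesh.triangles[:, k], areas / 3.0)
    return va


def mean_curvature(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex mean-curvature magnitude |H| via the cotangent Laplacian.

    Uses barycentric vertex areas; |H| of a sphere of radius r is ~1/r,
    a flat region gives 0.  Boundary vertices get whatever the open
    stencil yields (they are excluded from curvature gating upstream).
    """
    v, t = mesh.vertices, mesh.triangles
    K = np.zeros_like(v)
    if not t.size:
        return np.zeros(len(v))
    for corner in range(3):
        i = t[:, (corner + 1) % 3]
        j = t[:, (corner + 2) % 3]
        o = t[:, corner]
        e1 = v[i] - v[o]
        e2 = v[j] - v[o]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cross[cross == 0] = 1e-300
        cot = np.einsum("ij,ij->i", e1, e2) / cross
        w = 0.5 * cot[:, None] * (v[j] - v[i])
        np.add.at(K, i, w)
        np.subtract.at(K, j, w)
    area = _vertex_barycentric_areas(mesh)
    area[area == 0] = 1e-300
    # |L x| = 2 H A, so H = |L x| / (2 A)
    return np.linalg.norm(K, axis=1) / (2.0 * area)


def high_curvature_mask(mesh: SurfaceMesh, percentile: float = 70.0) -> np.ndarray:
    """Vertices whose |H| exceeds the given percentile of the mesh."""
    h = mean_curvature(mesh)
    if not len(h):
        return np.zeros(0, bool)
    return h >= np.percentile(h, percentile)


def edges_with_diamonds(triangles: np.ndarray, n_vertices: int):
    """Unique edges with their incident triangles and opposite vertices.

    Returns ``(edges, opposites, n_opposite)`` where ``edges`` is (E, 2),
    ``opposites`` is (E, 2) holding the up-to-two opposite vertex indices
    (-1 where absent) and ``n_opposite`` counts them (1 for boundary edges).
    """
    t = np.asarray(triangles, int)
    if not t.size:
        return np.zeros((0, 2), int), np.zeros((0, 2), int), np.zeros(0, int)
    halfedges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    opp = np.concatenate([t[:, 2], t[:, 0], t[:, 1]])
    key = np.sort(halfedges, axis=1)
    edges, inv = np.unique(key, axis=0, return_inverse=True)
    opposites = -np.ones((len(edges), 2), int)
    count = np.zeros(len(edges), int)
    for he in np.argsort(inv, kind="stable"):
        e = inv[he]
        if count[e] < 2:
            opposites[e, count[e]] = opp[he]
        count[e] += 1
    return edges, opposites, np.minimum(count, 2)


def edge_areas(mesh: SurfaceMesh):
    """Per-edge area A_e := (sum of areas of the up-to-2 incident
    triangles) / 3, which partitions the total surface area (each triangle
    contributes a third to each of its three edges)."""
    t = mesh.triangles
    edges, _, _ = edges_with_diamonds(t, mesh.n_vertices)
    areas = triangle_areas(mesh.vertices, t)
    edge_area = np.zeros(len(edges))
    if t.size:
        halfedges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        key = np.sort(halfedges, axis=1)
        _, inv = np.unique(key, axis=0, return_inverse=True)
        np.add.at(edge_area, inv, np.tile(areas, 3) / 3.0)
    return edges, edge_area


# ---------------------------------------------------------------------------
# closest-point queries
# ---------------------------------------------------------------------------


def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Closest point on triangle (a,b,c) for each paired query p.

    Vectorized version of the classic barycentric-region case analysis.
    All inputs are (k, 3); returns (k, 3) closest points.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(np.abs(d1 - d3) > 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(np.abs(d2 - d6) > 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(np.abs(denom) > 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    safe = np.where(np.abs(denom) > 0, denom, 1.0)
    v = vb / safe
    w = vc / safe
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class _SurfaceLocator:
    """Accelerated exact closest-point structure for one triangle mesh."""

    def __init__(self, mesh: SurfaceMesh):
        if not mesh.n_triangles:
            raise MeshError("closest-point query on empty mesh")
        self.mesh = mesh
        t = mesh.triangles
        v = mesh.vertices
        self.tri_pts = v[t]  # (m, 3, 3)
        self.centroids = self.tri_pts.mean(axis=1)
        self.radius = np.linalg.norm(
            self.tri_pts - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.max_radius = float(self.radius.max())
        self.tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray, _chunk: int = 8192):
        """Exact closest surface points: returns (points, distances, tri ids)."""
        q = np.asarray(points, float).reshape(-1, 3)
        m = len(self.centroids)
        # bound peak memory: process large query batches in chunks
        if len(q) * min(m, 64) > 2_000_000:
            parts = [self.query(q[s : s + _chunk]) for s in range(0, len(q), _chunk)]
            return (
                np.concatenate([p[0] for p in parts]),
                np.concatenate([p[1] for p in parts]),
                np.concatenate([p[2] for p in parts]),
            )
        if m <= 512:
            cand = np.broadcast_to(np.arange(m), (len(q), m))
            return self._exact(q, cand)
        k = min(32, m)
        cdist, idx = self.tree.query(q, k=k)
        cp, d, ti = self._exact(q, idx)
        # exact once no unvisited centroid can hold a closer triangle: every
        # triangle lies within max_radius of its own centroid, so triangles
        # beyond the k-th centroid are at distance >= cdist_k - max_radius
        unresolved = d > cdist[:, -1] - self.max_radius - 1e-12
        while np.any(unresolved) and k < m:
            k = min(m, 4 * k)
            qi = np.where(unresolved)[0]
            cdist2, idx2 = self.tree.query(q[qi], k=k)
            cp2, d2, ti2 = self._exact(q[qi], idx2)
            better = d2 < d[qi]
            d[qi[better]] = d2[better]
            cp[qi[better]] = cp2[better]
            ti[qi[better]] = ti2[better]
            unresolved[qi] = (k < m) & (d[qi] > cdist2[:, -1] - self.max_radius - 1e-12)
        return cp, d, ti

    def _exact(self, q, cand):
        nq, k = cand.shape
        pe = np.repeat(q, k, axis=0)
        tri = self.tri_pts[cand.ravel()]
        cps = _closest_on_triangles(pe, tri[:, 0], tri[:, 1], tri[:, 2])
        ds = np.linalg.norm(cps - pe, axis=1).reshape(nq, k)
        best = np.argmin(ds, axis=1)
        rows = np.arange(nq)
        return (
            cps.reshape(nq, k, 3)[rows, best],
            ds[rows, best],
            np.asarray(cand)[rows, best],
        )


def closest_surface_point(mesh: SurfaceMesh, query, _locator: _SurfaceLocator | None = None):
    """Closest point on ``mesh`` to a single 3D query point.

    Returns ``(point, distance, triangle_index)``.  Exact: equals the
    minimum over all point-to-triangle distances.
    """
    loc = _locator or _SurfaceLocator(mesh)
    cp, d, ti = loc.query(np.asarray(query, float).reshape(1, 3))
    return cp[0], float(d[0]), int(ti[0])


def surface_distances(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Unsigned distances from many points to the mesh surface."""
    return _SurfaceLocator(mesh).query(points)[1]


# ---------------------------------------------------------------------------
# iso-surface extraction and connectivity filtering
# ---------------------------------------------------------------------------


def extract_isosurface(volume: VoxelVolume, iso: float) -> SurfaceMesh:
    """Marching-cubes iso-surface in world (mm) coordinates.

    A constant volume (or an iso level outside the value range) yields an
    empty mesh rather than an error.
    """
    from skimage import measure

    vals = volume.values
    if not (vals.min() < iso < vals.max()):
        return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
    verts, faces, _, _ = measure.marching_cubes(vals, level=iso, spacing=tuple(volume.spacing))
    return SurfaceMesh(verts + volume.origin[None, :], faces).clean()


def vertex_components(mesh: SurfaceMesh):
    """Connected-component label per vertex (edge connectivity)."""
    n = mesh.n_vertices
    t = mesh.triangles
    if not n:
        return 0, np.zeros(0, int)
    if not t.size:
        return n, np.arange(n)
    rows = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
    cols = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    return n_comp, labels


def largest_component(mesh: SurfaceMesh) -> SurfaceMesh:
    """Keep the connected component with the most vertices.

    Ties are broken by the component containing the lowest original vertex
    index.  An empty mesh passes through unchanged.
    """
    if not mesh.n_vertices or not mesh.n_triangles:
        return mesh.copy()
    _, labels = vertex_components(mesh)
    counts = np.bincount(labels)
    best = counts.max()
    # among maximal components pick the one whose minimum vertex index is lowest
    winners = np.where(counts == best)[0]
    if len(winners) > 1:
        min_index = [np.where(labels == w)[0].min() for w in winners]
        label = winners[int(np.argmin(min_index))]
    else:
        label = winners[0]
    keep = labels == label
    new_index = np.cumsum(keep) - 1
    tri_keep = keep[mesh.triangles].all(axis=1)
    lm = {k: int(new_index[i]) for k, i in mesh.landmarks.items() if keep[int(i)]}
    groups = {}
    for name, idx in mesh.vertex_groups.items():
        j = np.asarray(idx, int)
        groups[name] = new_index[j[keep[j]]]
    return SurfaceMesh(mesh.vertices[keep], new_index[mesh.triangles[tri_keep]], lm, groups)


# ---------------------------------------------------------------------------
# decimation (quadric error metric edge collapse)
# ---------------------------------------------------------------------------


def _plane_quadrics(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Per-vertex 4x4 quadrics: sum of area-weighted squared plane distances."""
    n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    area2 = np.linalg.norm(n, axis=1)
    safe = np.where(area2 > 0, area2, 1.0)
    n_unit = n / safe[:, None]
    d = -np.einsum("ij,ij->i", n_unit, v[t[:, 0]])
    plane = np.concatenate([n_unit, d[:, None]], axis=1)  # (m, 4)
    K = plane[:, :, None] * plane[:, None, :] * (area2 / 2.0)[:, None, None]
    Q = np.zeros((len(v), 4, 4))
    for k in range(3):
        np.add.at(Q, t[:, k], K)
    return Q


def _optimal_collapse(Q: np.ndarray, vi: np.ndarray, vj: np.ndarray):
    """Optimal placement for a combined quadric, with endpoint fallback."""
    A = Q[:3, :3]
    b = -Q[:3, 3]
    try:
        if np.linalg.cond(A) < 1e8:
            x = np.linalg.solve(A, b)
        else:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        mid = 0.5 * (vi + vj)
        candidates = [vi, vj, mid]
        costs = [
            float(np.append(c, 1.0) @ Q @ np.append(c, 1.0)) for c in candidates
        ]
        k = int(np.argmin(costs))
        return candidates[k], costs[k]
    cost = float(np.append(x, 1.0) @ Q @ np.append(x, 1.0))
    return x, cost


def decimate(mesh: SurfaceMesh, target_vertex_count: int) -> SurfaceMesh:
    """Quadric-error edge-collapse decimation to a target vertex count.

    If the target is not below the current count, the input is returned
    unchanged (with a warning).  Collapses that would flip an incident
    face normal are skipped while alternatives remain.
    """
    import warnings

    if target_vertex_count >= mesh.n_vertices:
        warnings.warn("decimation target >= current vertex count; returning input")
        return mesh.copy()
    if target_vertex_count < 4:
        raise MeshError("cannot decimate below 4 vertices")

    v = mesh.vertices.copy()
    faces = mesh.triangles.copy()
    Q = _plane_quadrics(v, faces)
    alive = np.ones(len(v), bool)
    face_alive = np.ones(len(faces), bool)
    vert_faces = [set() for _ in range(len(v))]
    for f, tri in enumerate(faces):
        for k in tri:
            vert_faces[k].add(f)
    version = np.zeros(len(v), np.int64)

    def neighbors(i):
        out = set()
        for f in vert_faces[i]:
            if face_alive[f]:
                out.update(faces[f])
        out.discard(i)
        return out

    heap = []

    def push_pair(i, j):
        if i > j:
            i, j = j, i
        pos, cost = _optimal_collapse(Q[i] + Q[j], v[i], v[j])
        heapq.heappush(heap, (cost, version[i], version[j], i, j, tuple(pos)))

    edges, _, _ = edges_with_diamonds(faces, len(v))
    for i, j in edges:
        push_pair(int(i), int(j))

    n_alive = int(alive.sum())
    allow_flips = False
    stalled = 0
    while n_alive > target_vertex_count:
        if not heap:
            if allow_flips:
                break
            # rebuild allowing flips as a last resort
            allow_flips = True
            for i in np.where(alive)[0]:
                for j in neighbors(i):
                    if i < j:
                        push_pair(int(i), int(j))
            if not heap:
                break
        cost, vi_ver, vj_ver, i, j, pos = heapq.heappop(heap)
        if not (alive[i] and alive[j]) or version[i] != vi_ver or version[j] != vj_ver:
            continue
        if j not in neighbors(i):
            continue
        pos = np.asarray(pos)
        # flip check over faces that survive the collapse
        if not allow_flips:
            flip = False
            for f in (vert_faces[i] | vert_faces[j]):
                if not face_alive[f]:
                    continue
                tri = faces[f]
                if i in tri and j in tri:
                    continue  # face collapses away
                pts = v[tri].copy()
                n_old = np.cross(pts[1] - pts[0], pts[2] - pts[0])
                pts[tri == i] = pos
                pts[tri == j] = pos
                n_new = np.cross(pts[1] - pts[0], pts[2] - pts[0])
                if np.dot(n_old, n_new) <= 0:
                    flip = True
                    break
            if flip:
                stalled += 1
                if stalled > 4 * len(v):
                    allow_flips = True
                continue
        # perform collapse j -> i
        v[i] = pos
        Q[i] = Q[i] + Q[j]
        alive[j] = False
        n_alive -= 1
        for f in list(vert_faces[j]):
            if not face_alive[f]:
                continue
            tri = faces[f]
            if i in tri:
                face_alive[f] = False
            else:
                faces[f][tri == j] = i
                vert_faces[i].add(f)
        version[i] += 1
        version[j] += 1
        for nb in neighbors(i):
            push_pair(i, int(nb))

    new_index = np.cumsum(alive) - 1
    out_faces = faces[face_alive]
    ok = (
        (out_faces[:, 0] != out_faces[:, 1])
        & (out_faces[:, 1] != out_faces[:, 2])
        & (out_faces[:, 0] != out_faces[:, 2])
    )
    out_faces = out_faces[ok]
    lm = {k: int(new_index[idx]) for k, idx in mesh.landmarks.items() if alive[int(idx)]}
    return SurfaceMesh(v[alive], new_index[out_faces], lm).clean()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SURFACE_FORMATS = {"ply", "obj", "off", "stl"}


def _format_from_path(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower().lstrip(".")
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    return ext


def read_mesh(path: str, fmt: str | None = None):
    """Read a surface mesh (PLY/OBJ/OFF/STL) or a MEDIT ``.mesh`` tet mesh.

    Surface meshes are cleaned on load (duplicate vertices merged within
    1e-6 mm, unreferenced vertices and degenerate triangles dropped) since
    scan exports are routinely dirty.
    """
    f = _format_from_path(path, fmt)
    if f in _SURFACE_FORMATS:
        try:
            tm = trimesh.load_mesh(path, file_type=f, process=False)
        except Exception as exc:  # noqa: BLE001 - translate parser errors
            raise MeshFormatError(f"failed to parse {path!r} as {f}: {exc}") from exc
        if isinstance(tm, trimesh.Scene):
            geoms = list(tm.geometry.values())
            if not geoms:
                raise MeshFormatError(f"{path!r} contains no geometry")
            tm = trimesh.util.concatenate(geoms)
        verts = np.asarray(tm.vertices, float)
        faces = np.asarray(tm.faces, int)
        if faces.size and faces.max() >= len(verts):
            raise MeshFormatError(f"{path!r}: face index out of range")
        return SurfaceMesh(verts, faces).clean()
    if f in {"mesh", "medit"}:
        return _read_medit(path)
    if f in {"h5", "hdf5"}:
        return _read_tet_h5(path)
    raise MeshFormatError(f"unsupported mesh format {f!r}")


def write_mesh(mesh, path: str, fmt: str | None = None) -> None:
    """Write a SurfaceMesh (PLY/OBJ/OFF/STL) or TetMesh (MEDIT / HDF5)."""
    f = _format_from_path(path, fmt)
    if isinstance(mesh, SurfaceMesh):
        if f not in _SURFACE_FORMATS:
            raise MeshFormatError(f"surface meshes cannot be written as {f!r}")
        mesh.to_trimesh().export(path, file_type=f)
        return
    if isinstance(mesh, TetMesh):
        if f in {"mesh", "medit"}:
            _write_medit(mesh, path)
            return
        if f in {"h5", "hdf5"}:
            _write_tet_h5(mesh, path)
            return
        raise MeshFormatError(f"tet mesh requested in surface-only format {f!r}")
    raise MeshFormatError(f"cannot write object of type {type(mesh).__name__}")


def _read_medit(path: str) -> TetMesh:
    """Minimal ASCII MEDIT .mesh reader (Vertices / Tetrahedra sections)."""
    verts = []
    tets = []
    with open(path) as fh:
        tokens = fh.read().split()
    i = 0
    n_tok = len(tokens)

    def fail(msg):
        raise MeshFormatError(f"{path!r}: {msg} (token offset {i})")

    while i < n_tok:
        tok = tokens[i]
        low = tok.lower()
        if low == "vertices":
            try:
                n = int(tokens[i + 1])
            except (IndexError, ValueError):
                fail("bad Vertices count")
            i += 2
            if i + 4 * n > n_tok:
                fail("truncated Vertices section")
            block = tokens[i : i + 4 * n]
            arr = np.array(block, float).reshape(n, 4)
            verts = arr[:, :3]
            i += 4 * n
        elif low == "tetrahedra":
            try:
                n = int(tokens[i + 1])
            except (IndexError, ValueError):
                fail("bad Tetrahedra count")
            i += 2
            if i + 5 * n > n_tok:
                fail("truncated Tetrahedra section")
            block = tokens[i : i + 5 * n]
            arr = np.array(block, np.int64).reshape(n, 5)
            tets = arr[:, :4] - 1  # MEDIT is 1-based
            i += 5 * n
        elif low == "end":
            break
        else:
            i += 1
    if not len(verts):
        raise MeshFormatError(f"{path!r}: no Vertices section found")
    if not len(tets):
        raise MeshFormatError(f"{path!r}: no Tetrahedra section (surface-only data?)")
    tets = np.asarray(tets)
    if tets.min() < 0 or tets.max() >= len(verts):
        raise MeshFormatError(f"{path!r}: tetrahedron index out of range")
    return TetMesh(np.asarray(verts), tets)


def _write_medit(mesh: TetMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("MeshVersionFormatted 1\nDimension 3\n")
        fh.write(f"Vertices\n{mesh.n_vertices}\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g} 0\n")
        fh.write(f"Tetrahedra\n{len(mesh.tets)}\n")
        for a, b, c, d in mesh.tets + 1:
            fh.write(f"{a} {b} {c} {d} 0\n")
        fh.write("End\n")


def _write_tet_h5(mesh: TetMesh, path: str) -> None:
    """HDF5 tet-mesh layout: /vertices (n,3), /tets (m,4), /landmarks/<name>
    scalar vertex indices, /vertex_groups/<name> index arrays."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("vertices", data=mesh.vertices)
        h5.create_dataset("tets", data=mesh.tets)
        g = h5.create_group("landmarks")
        for k, idx in mesh.landmarks.items():
            g.create_dataset(k, data=int(idx))
        g = h5.create_group("vertex_groups")
        for k, idx in mesh.vertex_groups.items():
            g.create_dataset(k, data=np.asarray(idx, np.int64))


def _read_tet_h5(path: str) -> TetMesh:
    import h5py

    with h5py.File(path, "r") as h5:
        verts = h5["vertices"][...]
        tets = h5["tets"][...]
        lm = {k: int(h5["landmarks"][k][()]) for k in h5.get("landmarks", {})}
        groups = {k: h5["vertex_groups"][k][...] for k in h5.get("vertex_groups", {})}
    return TetMesh(verts, tets, lm, groups)


def read_landmarks(path: str) -> dict:
    """Landmark JSON: {name: vertex_index} or {name: [x, y, z]}."""
    with open(path) as fh:
        data = json.load(fh)
    out = {}
    for name, val in data.items():
        if isinstance(val, (int, np.integer)):
            out[name] = int(val)
        else:
            out[name] = np.asarray(val, float).reshape(3)
    return out


def write_landmarks(landmarks: dict, path: str) -> None:
    serial = {}
    for name, val in landmarks.items():
        if isinstance(val, (int, np.integer)):
            serial[name] = int(val)
        else:
            serial[name] = [float(x) for x in np.asarray(val).ravel()]
    with open(path, "w") as fh:
        json.dump(serial, fh, indent=1, sort_keys=True)


def read_volume(path: str) -> VoxelVolume:
    """Read a NIfTI volume; spacing from the affine, origin at voxel (0,0,0)."""
    import nibabel as nib

    img = nib.load(path)
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    origin = affine[:3, 3]
    return VoxelVolume(np.asarray(img.get_fdata(), float), spacing, origin)


def write_volume(volume: VoxelVolume, path: str) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), path)
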