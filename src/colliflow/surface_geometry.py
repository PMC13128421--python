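"""Nested-surface extraction and signed distance fields.

Surfaces are extracted from segmentation volumes with marching cubes,
refined by discrete curvature flow, and queried for signed Euclidean
distance with the convention used throughout the depth pipeline:
positive for points enclosed by the surface, negative outside.

Distances are exact point-to-triangle (not voxel-to-voxel): the depth
averaging window downstream is 0.5–2 mm at 0.5–1 mm voxels, so
sub-voxel accuracy is required.  Signing uses angle-weighted
pseudonormals, which are exact for closed, consistently oriented
meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "SegmentationVolume",
    "TriangleMesh",
    "extract_isosurface",
    "curvature_flow_smooth",
    "signed_distance",
    "signed_distance_field",
]


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass
class SegmentationVolume:
    """A scalar segmentation (binary or partial-volume fraction) with affine."""

    data: np.ndarray
    affine: np.ndarray
    name: str = ""

    @classmethod
    def from_nifti(cls, path: str | Path, name: str = "") -> "SegmentationVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()), img.affine, name or Path(path).stem)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


class TopologyError(ValueError):
    """Raised when a mesh operation requires a closed oriented surface."""


@dataclass
class TriangleMesh:
    """Closed triangulated surface in mm coordinates.

    ``labels`` maps a label name (e.g. ``"SC_left"``) to an array of
    vertex indices belonging to that region.
    """

    vertices: np.ndarray                 # (V, 3) mm
    faces: np.ndarray                    # (F, 3) int
    labels: dict = field(default_factory=dict)
    _tm: trimesh.Trimesh = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    def as_trimesh(self) -> trimesh.Trimesh:
        if self._tm is None or len(self._tm.vertices) != len(self.vertices):
            self._tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        return self._tm

    @property
    def vertex_normals(self) -> np.ndarray:
        """Outward angle-weighted per-vertex unit normals."""
        return _vertex_pseudonormals(self.vertices, self.faces)

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)

    def vertex_adjacency(self):
        """Sparse symmetric vertex adjacency (csr) from shared edges."""
        from scipy import sparse
        e = self.edges()
        n = len(self.vertices)
        a = sparse.coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
        )
        a = a + a.T
        a.data[:] = 1.0
        return a.tocsr()

    def edges(self) -> np.ndarray:
        """Unique undirected edges, each as a sorted vertex-index pair."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def validate_closed(self) -> None:
        tm = self.as_trimesh()
        if not tm.is_watertight:
            raise TopologyError("mesh is not closed (boundary or non-manifold edges)")
        areas = tm.area_faces
        if np.any(areas <= 0):
            raise TopologyError("mesh contains degenerate (zero-area) triangles")

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            {k: np.array(v) for k, v in self.labels.items()})

    # -- I/O ---------------------------------------------------------------

    def to_gifti(self, path: str | Path) -> None:
        ga = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(self.vertices.astype(np.float32),
                                     intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(self.faces.astype(np.int32),
                                     intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(ga, str(path))

    def to_ply(self, path: str | Path) -> None:
        self.as_trimesh().export(str(path))

    @classmethod
    def from_gifti(cls, path: str | Path) -> "TriangleMesh":
        ga = nib.load(str(path))
        v = ga.darrays[0].data.astype(float)
        f = ga.darrays[1].data.astype(np.int64)
        return cls(v, f)


# --------------------------------------------------------------------------
# Extraction and smoothing
# --------------------------------------------------------------------------

def extract_isosurface(volume: SegmentationVolume, level: float = 0.5) -> TriangleMesh:
    """Marching-cubes iso-surface at ``level``, vertices in mm.

    The mesh is re-oriented so faces wind consistently with outward
    normals (enclosed volume positive).  Raises :class:`TopologyError`
    if the extracted surface is open, and ``ValueError`` if the
    foreground is empty or touches the grid border.
    """
    data = np.asarray(volume.data, dtype=float)
    if not (data.max() > level > data.min()):
        raise ValueError(f"iso-level {level} not bracketed by volume range "
                         f"[{data.min()}, {data.max()}]")
    fg = data > level
    border = np.concatenate([
        fg[0].ravel(), fg[-1].ravel(), fg[:, 0].ravel(),
        fg[:, -1].ravel(), fg[:, :, 0].ravel(), fg[:, :, -1].ravel(),
    ])
    if border.any():
        raise ValueError("foreground touches the grid border; pad the volume")
    verts, faces, _, _ = measure.marching_cubes(data, level)
    verts = verts @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    mesh = TriangleMesh(verts, faces)
    tm = mesh.as_trimesh()
    if not tm.is_watertight:
        raise TopologyError("iso-surface is open; check the segmentation")
    if tm.volume < 0:           # flip winding so normals point outward
        mesh = TriangleMesh(verts, faces[:, ::-1], mesh.labels)
    return mesh


def curvature_flow_smooth(mesh: TriangleMesh, steps: int = 10,
                          dt: float = 0.1) -> TriangleMesh:
    """Discrete mean-curvature (umbrella) flow.

    Each step moves every vertex by ``dt`` times its umbrella Laplacian
    vector (mean of neighbours minus the vertex).  Topology is
    unchanged; ``steps=0`` returns an identical copy.  Raises if the
    flow flips any triangle's orientation (``dt`` too large).
    """
    if steps < 0:
        raise ValueError("steps must be nonnegative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = mesh.copy()
    if steps == 0:
        return out
    adj = mesh.vertex_adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    v = out.vertices
    ref_normals = _face_normals(v, out.faces)
    for _ in range(steps):
        mean_nb = adj @ v / deg[:, None]
        v = v + dt * (mean_nb - v)
        fn = _face_normals(v, out.faces)
        if np.any(np.einsum("ij,ij->i", fn, ref_normals) < 0):
            raise ValueError(f"dt={dt} flipped triangle orientation; reduce dt")
        ref_normals = fn
    out.vertices = v
    out._tm = None
    return out


# --------------------------------------------------------------------------
# Signed distance (exact point-to-triangle, pseudonormal signing)
# --------------------------------------------------------------------------

def _face_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def _vertex_pseudonormals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Angle-weighted average of incident face normals per vertex."""
    fn = _face_normals(vertices, faces)
    out = np.zeros_like(vertices)
    tri = vertices[faces]                       # (F, 3, 3)
    for i in range(3):
        p = tri[:, i]
        u = tri[:, (i + 1) % 3] - p
        w = tri[:, (i + 2) % 3] - p
        cosang = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1))
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(out, faces[:, i], fn * ang[:, None])
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return out / norm


def _edge_pseudonormals(vertices, faces):
    """Map sorted-edge tuple → unit mean of the two adjacent face normals."""
    fn = _face_normals(vertices, faces)
    acc: dict = {}
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (a, b) if a < b else (b, a)
            acc.setdefault(key, np.zeros(3))
            acc[key] = acc[key] + fn[fi]
    keys = np.array(list(acc.keys()), dtype=np.int64)
    vals = np.array(list(acc.values()))
    norm = np.linalg.norm(vals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return keys, vals / norm


def _closest_point_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                             c: np.ndarray):
    """Closest point on each triangle (a, b, c) to each point p.

    All inputs are (N, 3); returns (closest (N, 3), feature code (N,))
    with feature codes 0=face, 1/2/3=vertex a/b/c, 4=edge ab, 5=edge bc,
    6=edge ca (Ericson's region classification).
    """
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    feat = np.zeros(len(p), dtype=np.int8)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)                      # vertex a
    out[m], feat[m], done[m] = a[m], 1, True
    m = ~done & (d3 >= 0) & (d4 <= d3)             # vertex b
    out[m], feat[m], done[m] = b[m], 2, True
    m = ~done & (d6 >= 0) & (d5 <= d6)             # vertex c
    out[m], feat[m], done[m] = c[m], 3, True

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    out[m] = a[m] + t[m, None] * ab[m]
    feat[m], done[m] = 4, True

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ca
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    out[m] = a[m] + t[m, None] * ac[m]
    feat[m], done[m] = 6, True

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    feat[m], done[m] = 5, True

    m = ~done                                       # face interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    feat[m] = 0
    return out, feat


class _SignedDistanceQuery:
    """Reusable exact signed-distance evaluator for one closed mesh."""

    def __init__(self, mesh: TriangleMesh):
        mesh.validate_closed()
        self.mesh = mesh
        v, f = mesh.vertices, mesh.faces
        self.tri = v[f]
        self.centroids = self.tri.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.tri_radius = np.linalg.norm(
            self.tri - self.centroids[:, None, :], axis=2).max(axis=1)
        self.rmax = float(self.tri_radius.max())
        self.face_normals = _face_normals(v, f)
        self.vertex_pn = _vertex_pseudonormals(v, f)
        ekeys, epn = _edge_pseudonormals(v, f)
        self.edge_pn = {tuple(k): n for k, n in zip(ekeys, epn)}

    def _exact_over(self, points, cand):
        """Min distance over candidate triangle lists (equal-length lists)."""
        n, k = cand.shape
        p = np.repeat(points, k, axis=0)
        fidx = cand.ravel()
        cp, feat = _closest_point_triangles(
            p, self.tri[fidx, 0], self.tri[fidx, 1], self.tri[fidx, 2])
        d2 = np.einsum("ij,ij->i", p - cp, p - cp).reshape(n, k)
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        return (np.sqrt(d2[rows, best]),
                cp.reshape(n, k, 3)[rows, best],
                feat.reshape(n, k)[rows, best],
                cand[rows, best])

    def __call__(self, points: np.ndarray, chunk: int = 50000) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty(len(points))
        for lo in range(0, len(points), chunk):
            out[lo:lo + chunk] = self._query(points[lo:lo + chunk])
        return out

    def _query(self, points: np.ndarray) -> np.ndarray:
        k = min(16, len(self.centroids))
        dc, idx = self.tree.query(points, k=k)
        if k == 1:
            dc, idx = dc[:, None], idx[:, None]
        d, cp, feat, fbest = self._exact_over(points, idx)
        # any triangle outside the k candidates has surface distance
        # ≥ (distance to its centroid) - rmax ≥ dc[:, -1] - rmax
        uncertified = d > dc[:, -1] - self.rmax
        if np.any(uncertified) and k < len(self.centroids):
            for i in np.flatnonzero(uncertified):
                cand = self.tree.query_ball_point(points[i], d[i] + self.rmax + 1e-12)
                di, cpi, fi, fb = self._exact_over(points[i:i + 1],
                                                   np.array([cand]))
                d[i], cp[i], feat[i], fbest[i] = di[0], cpi[0], fi[0], fb[0]
        sign = self._sign(points, cp, feat, fbest)
        return sign * d

    def _sign(self, points, cp, feat, fidx) -> np.ndarray:
        n = np.empty_like(points)
        faces = self.mesh.faces
        face_m = feat == 0
        n[face_m] = self.face_normals[fidx[face_m]]
        for code in (1, 2, 3):                      # vertex features
            m = feat == code
            if m.any():
                n[m] = self.vertex_pn[faces[fidx[m], code - 1]]
        edge_corners = {4: (0, 1), 5: (1, 2), 6: (2, 0)}
        for code, (i, j) in edge_corners.items():
            m = feat == code
            for row in np.flatnonzero(m):
                a, b = faces[fidx[row], i], faces[fidx[row], j]
                key = (a, b) if a < b else (b, a)
                n[row] = self.edge_pn[key]
        inside = np.einsum("ij,ij->i", points - cp, n) < 0
        return np.where(inside, 1.0, -1.0)


def signed_distance(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mesh: + inside, − outside."""
    return _SignedDistanceQuery(mesh)(points)


def signed_distance_field(mesh: TriangleMesh, shape: tuple,
                          affine: np.ndarray) -> np.ndarray:
    """Signed distance sampled at every voxel centre of a grid (mm).

    The grid must cover the mesh bounding box; the sign convention is
    positive for voxels enclosed by the surface, negative outside.
    """
    shape = tuple(int(s) for s in shape)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                   axis=-1).reshape(-1, 3)
    pts = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    if np.any(mesh.vertices.min(axis=0) < lo - 1e-9) or \
       np.any(mesh.vertices.max(axis=0) > hi + 1e-9):
        raise ValueError("grid does not cover the mesh bounding box")
    return signed_distance(mesh, pts).reshape(shape)
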