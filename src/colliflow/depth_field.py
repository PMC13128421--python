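"""Normalized depth coordinate, gradient streamlines, and thickness.

Between the outer tectum surface and the inner CA interface the
normalized depth ``w`` solves ``w*S_CA + (1-w)*S_T = 0`` where ``S_T``
and ``S_CA`` are the signed distances (positive inside) from the two
surfaces, i.e. ``w = S_T / (S_T - S_CA)``.  ``w`` is 0 on the tectum
surface and 1 at the CA interface, independent of local thickness, and
swapping the surfaces maps ``w → 1 - w`` (self-reciprocity).

Streamlines ascend ``∇w`` from each tectum-surface vertex toward the
CA interface in fixed ``step_mm`` increments (first step along the
inward surface normal); the terminal cumulative arc length, re-gridded
per vertex, is the physical thickness map.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .surface_geometry import TriangleMesh

__all__ = [
    "DepthField",
    "Streamline",
    "StreamlineSet",
    "TerminationStatus",
    "normalized_depth",
    "gradient_field",
    "trace_streamline",
    "trace_streamlines",
    "thickness_map",
]

W_DENOM_FLOOR_MM = 1e-6


class TerminationStatus(str, Enum):
    REACHED_CA = "reached_CA"
    LEFT_DOMAIN = "left_domain"
    MAX_STEPS = "max_steps"


# --------------------------------------------------------------------------
# Normalized depth
# --------------------------------------------------------------------------

@dataclass
class DepthField:
    """Signed distances, normalized depth and validity mask on one grid."""

    s_tectum: np.ndarray
    s_ca: np.ndarray
    w: np.ndarray
    mask: np.ndarray            # strictly between the surfaces
    affine: np.ndarray

    @property
    def voxel_size_mm(self) -> float:
        return float(np.linalg.norm(self.affine[:3, 0]))

    def write(self, out_dir: str | Path, prefix: str = "") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, vol in [("s_tectum", self.s_tectum), ("s_ca", self.s_ca),
                          ("depth_w", self.w),
                          ("depth_mask", self.mask.astype(np.uint8))]:
            nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), self.affine),
                     out / f"{prefix}{name}.nii.gz")


def normalized_depth(s_tectum: np.ndarray, s_ca: np.ndarray,
                     affine: np.ndarray | None = None) -> DepthField:
    """Solve ``w*S_CA + (1-w)*S_T = 0`` for ``w`` on the whole grid.

    ``w = S_T / (S_T - S_CA)`` wherever the denominator exceeds a small
    floor (1e-6 mm, guarding division exactly on a surface crossing).
    The validity mask flags voxels strictly between the surfaces
    (``S_T > 0`` and ``S_CA < 0``); outside it ``w`` is still stored
    (it extends smoothly) but is not meaningful as a depth.
    """
    s_t = np.asarray(s_tectum, dtype=float)
    s_c = np.asarray(s_ca, dtype=float)
    if s_t.shape != s_c.shape:
        raise ValueError(f"grid mismatch: {s_t.shape} vs {s_c.shape}")
    denom = s_t - s_c
    safe = denom.copy()
    small = np.abs(denom) < W_DENOM_FLOOR_MM
    safe[small] = np.where(denom[small] >= 0, W_DENOM_FLOOR_MM, -W_DENOM_FLOOR_MM)
    w = s_t / safe
    mask = (s_t > 0) & (s_c < 0)
    if affine is None:
        affine = np.eye(4)
    return DepthField(s_tectum=s_t, s_ca=s_c, w=w, mask=mask,
                      affine=np.asarray(affine, dtype=float))


# --------------------------------------------------------------------------
# Gradient
# --------------------------------------------------------------------------

def _axis_derivative(w: np.ndarray, axis: int, h: float) -> np.ndarray:
    """5-point central difference, falling back near the grid boundary."""
    n = w.shape[axis]
    if n < 5:
        raise ValueError(f"need at least 5 voxels along axis {axis}, got {n}")
    # interior: (-1, 8, 0, -8, 1) / 12h — exact for cubic fields
    kern = np.array([-1.0, 8.0, 0.0, -8.0, 1.0])[::-1] / (12.0 * h)
    d = ndimage.convolve1d(w, kern[::-1], axis=axis, mode="nearest")
    # note: convolve1d correlates with the reversed kernel; building the
    # stencil explicitly keeps the sign convention d/dx ≈ (w[i+1]-w[i-1])/2h
    sl = [slice(None)] * w.ndim

    def take(i):
        s = sl.copy()
        s[axis] = i
        return w[tuple(s)]

    def put(i, val):
        s = sl.copy()
        s[axis] = i
        d[tuple(s)] = val

    # second/second-to-last: 3-point central
    put(1, (take(2) - take(0)) / (2 * h))
    put(n - 2, (take(n - 1) - take(n - 3)) / (2 * h))
    # edges: one-sided
    put(0, (take(1) - take(0)) / h)
    put(n - 1, (take(n - 1) - take(n - 2)) / h)
    return d


def gradient_field(w: np.ndarray, voxel_size_mm: float) -> np.ndarray:
    """``∇w`` per axis via 5-point central-difference kernels (1/mm).

    Returns an array of shape ``w.shape + (3,)``.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 3:
        raise ValueError("w must be a 3-D volume")
    return np.stack([_axis_derivative(w, ax, voxel_size_mm) for ax in range(3)],
                    axis=-1)


# --------------------------------------------------------------------------
# Streamlines
# --------------------------------------------------------------------------

@dataclass
class Streamline:
    """One trajectory from a surface vertex toward the CA interface."""

    points: np.ndarray          # (n, 3) mm
    arc_length: np.ndarray      # (n,) cumulative mm, strictly increasing
    vertex: int
    status: TerminationStatus

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


@dataclass
class StreamlineSet:
    """Lock-stepped streamlines for every vertex of the tectum mesh."""

    points: np.ndarray          # (V, max_len, 3), NaN beyond n_points
    n_points: np.ndarray        # (V,) valid points per streamline
    step_mm: float
    status: np.ndarray          # (V,) of TerminationStatus values (object)

    def __len__(self) -> int:
        return len(self.n_points)

    def __getitem__(self, v: int) -> Streamline:
        n = int(self.n_points[v])
        return Streamline(
            points=self.points[v, :n],
            arc_length=np.arange(n) * self.step_mm,
            vertex=v,
            status=TerminationStatus(self.status[v]),
        )

    def terminal_arc_length(self) -> np.ndarray:
        return (self.n_points - 1) * self.step_mm

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in range(len(self)):
            n = int(self.n_points[v])
            rows.append(pd.DataFrame({
                "vertex": v,
                "point": np.arange(n),
                "x_mm": self.points[v, :n, 0],
                "y_mm": self.points[v, :n, 1],
                "z_mm": self.points[v, :n, 2],
                "arc_mm": np.arange(n) * self.step_mm,
                "status": TerminationStatus(self.status[v]).value,
            }))
        return pd.concat(rows, ignore_index=True)

    def save_npz(self, path: str | Path) -> None:
        np.savez_compressed(path, points=self.points, n_points=self.n_points,
                            step_mm=self.step_mm,
                            status=np.array([TerminationStatus(s).value
                                             for s in self.status]))

    @classmethod
    def load_npz(cls, path: str | Path) -> "StreamlineSet":
        z = np.load(path, allow_pickle=False)
        return cls(points=z["points"], n_points=z["n_points"],
                   step_mm=float(z["step_mm"]),
                   status=np.array([TerminationStatus(s) for s in z["status"]],
                                   dtype=object))


def _world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def _trilinear(vol: np.ndarray, vox: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(vol, vox.T, order=1, mode="nearest")


def trace_streamlines(
    start_points: np.ndarray,
    inward_normals: np.ndarray,
    field: np.ndarray,
    depth: DepthField,
    step_mm: float = 0.1,
    max_steps: int = 500,
    eps: float = 0.02,
) -> StreamlineSet:
    """Trace all streamlines in lock-step (vectorized Euler integration).

    First step of ``step_mm`` along each inward normal, then repeated
    steps along the trilinearly interpolated unit ``∇w`` until the
    interpolated ``w ≥ 1 - eps`` (reached the CA interface), the trace
    leaves the validity mask or stalls (zero gradient), or ``max_steps``
    is exhausted.
    """
    start = np.atleast_2d(np.asarray(start_points, dtype=float))
    normals = np.atleast_2d(np.asarray(inward_normals, dtype=float))
    nv = len(start)
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    aff = depth.affine
    wvol = depth.w

    pts = np.full((nv, max_steps + 2, 3), np.nan)
    pts[:, 0] = start
    n_points = np.ones(nv, dtype=int)
    status = np.array([TerminationStatus.MAX_STEPS] * nv, dtype=object)
    active = np.ones(nv, dtype=bool)

    # degenerate start: already at the CA interface
    w0 = _trilinear(wvol, _world_to_voxel(start, aff))
    done0 = w0 >= 1 - eps
    status[done0] = TerminationStatus.REACHED_CA
    active &= ~done0

    cur = start.copy()
    nrm = normals / np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)
    for step in range(max_steps):
        if not active.any():
            break
        if step == 0:
            direction = nrm
        else:
            vox = _world_to_voxel(cur[active], aff)
            g = np.stack([_trilinear(field[..., i], vox) for i in range(3)], axis=1)
            gn = np.linalg.norm(g, axis=1)
            stalled = gn < 1e-12
            direction = np.zeros((nv, 3))
            idx = np.flatnonzero(active)
            direction[idx[~stalled]] = g[~stalled] / gn[~stalled, None]
            if stalled.any():
                status[idx[stalled]] = TerminationStatus.LEFT_DOMAIN
                active[idx[stalled]] = False
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        cur[idx] = cur[idx] + step_mm * direction[idx]
        pts[idx, n_points[idx]] = cur[idx]
        n_points[idx] += 1
        vox = _world_to_voxel(cur[idx], aff)
        wi = _trilinear(wvol, vox)
        inb = np.all((vox >= 0) & (vox <= np.array(wvol.shape) - 1), axis=1)
        reached = wi >= 1 - eps
        # w extends smoothly past the surfaces, so traces are only
        # abandoned when they exit the grid or fall behind the tectum
        left = (~inb) | (wi < -eps)
        status[idx[reached]] = TerminationStatus.REACHED_CA
        status[idx[left & ~reached]] = TerminationStatus.LEFT_DOMAIN
        active[idx[reached | left]] = False
    max_n = int(n_points.max())
    return StreamlineSet(points=pts[:, :max_n], n_points=n_points,
                         step_mm=step_mm, status=status)


def trace_streamline(start_point, inward_normal, field, depth,
                     step_mm: float = 0.1, max_steps: int = 500,
                     eps: float = 0.02) -> Streamline:
    """Trace a single streamline (convenience wrapper)."""
    ss = trace_streamlines(np.atleast_2d(start_point), np.atleast_2d(inward_normal),
                           field, depth, step_mm=step_mm, max_steps=max_steps,
                           eps=eps)
    return ss[0]


def thickness_map(streamlines: StreamlineSet, mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex physical thickness (mm); NaN where the trace failed.

    Thickness is the terminal cumulative arc length of the vertex's
    streamline, defined only for traces that reached the CA interface.
    """
    if len(streamlines) != len(mesh.vertices):
        raise ValueError("need exactly one streamline per mesh vertex")
    th = streamlines.terminal_arc_length().astype(float)
    ok = np.array([s == TerminationStatus.REACHED_CA for s in streamlines.status])
    th[~ok] = np.nan
    return th
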