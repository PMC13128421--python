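"""Synthetic midbrain phantom with a known hemodynamic ground truth.

The phantom emulates a slow event-related BOLD study of the superior
colliculus (SC): a thin shell of responsive tissue between two nested
surfaces — an outer "tectum" (posterior brainstem roof) surface and an
inner cerebral-aqueduct (CA) interface — sampled at TR 1.25 s with
26.25-s task epochs (21 TRs each), 17 epochs per run and 5 runs.

Geometry is a pair of concentric spheres so that every downstream stage
(signed distances, normalized depth, streamlines, thickness, geodesic
band ROIs) has a closed-form oracle: streamlines are radial and the
shell thickness equals ``outer_radius_mm - inner_radius_mm`` everywhere.

One or more SC-like patches are painted on the outer sphere.  Within a
patch the true response amplitude (in percent signal change) is an
affine function of the great-circle ("rostro-caudal") distance from the
patch's rostral pole, running from ``amplitude_rostral`` at the pole to
``amplitude_caudal`` at the patch edge, so the positive-to-negative
transition of the response is known exactly per vertex.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "HRFKernelParams",
    "PhantomConfig",
    "EventDesign",
    "GroundTruth",
    "PhantomDataset",
    "synth_hrf_kernel",
    "make_event_design",
    "make_phantom",
]


# --------------------------------------------------------------------------
# HRF kernel
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFKernelParams:
    """Difference-of-gamma HRF kernel shape.

    ``h(t) ∝ Gamma(peak_shape, 1/peak_rate).pdf(t)
            - under_ratio * Gamma(under_shape, 1/under_rate).pdf(t)``

    Defaults give a hyperoxic peak near 5 s (subcortical responses peak
    earlier than the cortical 6–8 s) followed by a shallow undershoot
    that has essentially returned to baseline by the 26.25-s epoch end.
    """

    peak_shape: float = 6.0
    peak_rate: float = 1.0      # 1/s
    under_shape: float = 16.0
    under_rate: float = 1.0     # 1/s
    under_ratio: float = 1.0 / 6.0

    def validate(self) -> None:
        for name in ("peak_shape", "peak_rate", "under_shape", "under_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"kernel parameter {name}={v!r} must be a positive finite real")
        if not np.isfinite(self.under_ratio) or self.under_ratio < 0:
            raise ValueError(f"under_ratio={self.under_ratio!r} must be a nonnegative finite real")


def _raw_kernel(t: np.ndarray, params: HRFKernelParams) -> np.ndarray:
    g1 = _stats.gamma.pdf(t, a=params.peak_shape, scale=1.0 / params.peak_rate)
    g2 = _stats.gamma.pdf(t, a=params.under_shape, scale=1.0 / params.under_rate)
    return g1 - params.under_ratio * g2


def _kernel_norm(params: HRFKernelParams) -> float:
    # peak height on a dense grid; the kernel is smooth so 1-ms sampling
    # resolves the maximum far below any tolerance used downstream
    tt = np.arange(0.0, 40.0, 0.001)
    return float(np.max(np.abs(_raw_kernel(tt, params))))


def synth_hrf_kernel(
    t: np.ndarray,
    amplitude: float = 1.0,
    params: HRFKernelParams | None = None,
) -> np.ndarray:
    """Evaluate the HRF kernel at times ``t`` (s), scaled to ``amplitude``.

    The kernel is unit-normalized so that ``max|h| == |amplitude|`` (the
    amplitude is the percent-signal-change at the peak); ``h(0) == 0``.
    A negative ``amplitude`` yields the sign-mirrored response.
    """
    params = params or HRFKernelParams()
    params.validate()
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t must be a non-empty 1-D time grid")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t must be nonnegative and strictly increasing")
    if amplitude == 0:
        return np.zeros_like(t)
    return amplitude * _raw_kernel(t, params) / _kernel_norm(params)


# --------------------------------------------------------------------------
# Configuration and design
# --------------------------------------------------------------------------

def _default_poles() -> tuple[tuple[float, float, float], ...]:
    # two SC patches ("left"/"right"), poles in the xy-plane at ±50° from
    # the rostral (+x) axis so the default 8-mm patches do not overlap
    a = np.deg2rad(50.0)
    return (
        (float(np.cos(a)), float(np.sin(a)), 0.0),
        (float(np.cos(a)), float(-np.sin(a)), 0.0),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of the synthetic dataset.

    Temporal design defaults mirror the emulated study: TR 1.25 s,
    26.25-s epochs (exactly 21 TRs), 17 epochs per run, 5 runs, and a
    10-TR (12.5-s) lead-in that is discarded before epoching.  The
    amplitude profile runs linearly from ``amplitude_rostral`` at each
    patch pole to ``amplitude_caudal`` at geodesic distance
    ``sc_patch_extent_mm``, crossing zero inside the patch for the
    default 1.5 → −0.5 %-signal-change profile.
    """

    voxel_size_mm: float = 0.5
    grid_shape: tuple[int, int, int] | None = None
    outer_radius_mm: float = 10.0
    inner_radius_mm: float = 7.0
    tr_s: float = 1.25
    epoch_s: float = 26.25
    n_epochs_per_run: int = 17
    n_runs: int = 5
    lead_in_trs: int = 10
    baseline: float = 100.0
    noise_sd: float = 0.02          # fraction of baseline
    drift_amplitude: float = 0.01   # fraction of baseline
    drift_period_s: float = 300.0
    amplitude_rostral: float = 1.5  # % signal change at the patch pole
    amplitude_caudal: float = -0.5  # % signal change at the patch edge
    sc_patch_extent_mm: float = 8.0
    sc_poles: tuple[tuple[float, float, float], ...] = field(default_factory=_default_poles)
    rostral_axis: int = 0
    kernel: HRFKernelParams = field(default_factory=HRFKernelParams)
    rng_seed: int = 0

    # -- derived quantities ------------------------------------------------

    @property
    def epoch_length_trs(self) -> int:
        n = self.epoch_s / self.tr_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"epoch_s/tr_s = {n} is not an integer; epochs must be TR-aligned"
            )
        return int(round(n))

    @property
    def run_length_trs(self) -> int:
        return self.lead_in_trs + self.n_epochs_per_run * self.epoch_length_trs

    def resolved_grid_shape(self) -> tuple[int, int, int]:
        if self.grid_shape is not None:
            return tuple(int(n) for n in self.grid_shape)
        half = self.outer_radius_mm / self.voxel_size_mm + 2.0  # 2-voxel margin
        n = 2 * int(np.ceil(half)) + 1
        return (n, n, n)

    def affine(self) -> np.ndarray:
        """Voxel-index → mm affine, grid centred on the sphere centre."""
        shape = np.array(self.resolved_grid_shape())
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -(shape - 1) / 2.0 * self.voxel_size_mm
        return aff

    def validate(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if not (0 < self.inner_radius_mm < self.outer_radius_mm):
            raise ValueError("need 0 < inner_radius_mm < outer_radius_mm")
        if self.tr_s <= 0 or self.epoch_s <= 0:
            raise ValueError("tr_s and epoch_s must be positive")
        self.epoch_length_trs  # raises if non-integer
        if self.n_epochs_per_run < 1 or self.n_runs < 1:
            raise ValueError("need at least one epoch and one run")
        if self.lead_in_trs < 0:
            raise ValueError("lead_in_trs must be nonnegative")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be nonnegative")
        if self.drift_period_s <= 0:
            raise ValueError("drift_period_s must be positive")
        if self.sc_patch_extent_mm <= 0:
            raise ValueError("sc_patch_extent_mm must be positive")
        if self.rostral_axis not in (0, 1, 2):
            raise ValueError("rostral_axis must be 0, 1 or 2")
        if len(self.sc_poles) == 0:
            raise ValueError("at least one SC pole is required")
        self.kernel.validate()
        shape = np.array(self.resolved_grid_shape())
        half_extent_mm = (shape - 1) / 2.0 * self.voxel_size_mm
        needed = self.outer_radius_mm + 2 * self.voxel_size_mm
        if np.any(half_extent_mm < needed - 1e-9):
            raise ValueError(
                f"grid {tuple(shape)} at {self.voxel_size_mm} mm does not contain the "
                f"outer sphere plus a 2-voxel margin (needs half-extent ≥ {needed} mm)"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.resolved_grid_shape())
        d["sc_poles"] = [list(p) for p in self.sc_poles]
        return d


@dataclass(frozen=True)
class EventDesign:
    """TR-aligned epoch layout of one run."""

    run_length_trs: int
    epoch_onsets_trs: tuple[int, ...]
    epoch_length_trs: int
    tr_s: float

    def __post_init__(self) -> None:
        on = np.asarray(self.epoch_onsets_trs)
        if on.size == 0:
            raise ValueError("at least one epoch onset required")
        if on.size > 1 and not np.all(np.diff(on) == self.epoch_length_trs):
            raise ValueError("onsets must be spaced exactly epoch_length_trs apart")
        if on[-1] + self.epoch_length_trs > self.run_length_trs:
            raise ValueError("design overruns the run")

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_onsets_trs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self) | {"epoch_onsets_trs": list(self.epoch_onsets_trs)}


def make_event_design(config: PhantomConfig) -> EventDesign:
    """Epoch onsets for one run: lead-in, then back-to-back epochs."""
    config.validate()
    n = config.epoch_length_trs
    onsets = tuple(config.lead_in_trs + k * n for k in range(config.n_epochs_per_run))
    return EventDesign(
        run_length_trs=config.run_length_trs,
        epoch_onsets_trs=onsets,
        epoch_length_trs=n,
        tr_s=config.tr_s,
    )


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Closed-form truth of the phantom's response field.

    The rostro-caudal coordinate of a point is the great-circle distance
    (on the outer sphere) from the nearest patch pole; the true response
    amplitude is affine in that distance inside the patch and zero
    outside.
    """

    outer_radius_mm: float
    inner_radius_mm: float
    sc_poles: tuple[tuple[float, float, float], ...]
    sc_patch_extent_mm: float
    amplitude_rostral: float
    amplitude_caudal: float
    kernel: HRFKernelParams
    rng_seed: int

    def _angles(self, points_mm: np.ndarray) -> np.ndarray:
        """Great-circle angle (rad) from each pole; shape (n_poles, n_points)."""
        p = np.asarray(points_mm, dtype=float)
        r = np.linalg.norm(p, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = p / r[..., None]
        poles = np.asarray(self.sc_poles, dtype=float)
        poles /= np.linalg.norm(poles, axis=1, keepdims=True)
        cosang = np.clip(poles @ u.T, -1.0, 1.0)
        ang = np.arccos(cosang)
        ang[:, ~np.isfinite(r) | (r == 0)] = np.pi
        return ang

    def patch_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Index of the patch containing each point, or -1 outside all patches."""
        ang = self._angles(points_mm)
        dist = ang * self.outer_radius_mm
        best = np.argmin(dist, axis=0)
        out = np.where(np.take_along_axis(dist, best[None, :], 0)[0] <= self.sc_patch_extent_mm,
                       best, -1)
        return out

    def rc_distance(self, points_mm: np.ndarray) -> np.ndarray:
        """Rostro-caudal (geodesic) distance in mm from the nearest pole."""
        return np.min(self._angles(points_mm), axis=0) * self.outer_radius_mm

    def amplitude(self, points_mm: np.ndarray) -> np.ndarray:
        """True peak amplitude (% signal change); zero outside the patches."""
        d = self.rc_distance(points_mm)
        frac = d / self.sc_patch_extent_mm
        amp = self.amplitude_rostral + (self.amplitude_caudal - self.amplitude_rostral) * frac
        return np.where(frac <= 1.0, amp, 0.0)

    def table(self, points_mm: np.ndarray) -> pd.DataFrame:
        pts = np.asarray(points_mm, dtype=float)
        return pd.DataFrame({
            "x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2],
            "patch": self.patch_index(pts),
            "rc_distance_mm": self.rc_distance(pts),
            "amplitude_pct": self.amplitude(pts),
        })


# --------------------------------------------------------------------------
# Dataset
# --------------------------------------------------------------------------

def _partial_volume_ball(r: np.ndarray, radius: float, voxel: float) -> np.ndarray:
    """Partial-volume fraction of a ball: linear ramp one voxel wide."""
    return np.clip((radius - r) / voxel + 0.5, 0.0, 1.0)


@dataclass
class PhantomDataset:
    """Everything downstream stages need, with lazily generated BOLD runs.

    Run volumes are regenerated deterministically on demand from
    per-run child seeds, so holding the dataset costs only the two
    segmentation volumes regardless of the session length.
    """

    config: PhantomConfig
    affine: np.ndarray
    seg_tectum: np.ndarray     # partial-volume fraction of the outer ball
    seg_ca: np.ndarray         # partial-volume fraction of the inner ball
    design: EventDesign
    truth: GroundTruth
    _amp_vol: np.ndarray = dataclasses.field(repr=False, default=None)
    _response_tr: np.ndarray = dataclasses.field(repr=False, default=None)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.seg_tectum.shape)

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-centre world coordinates."""
        shape = self.grid_shape
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def bold_run(self, run: int) -> np.ndarray:
        """Synthesize run ``run`` (0-based) as a float32 (x, y, z, t) array."""
        cfg = self.config
        if not (0 <= run < cfg.n_runs):
            raise IndexError(f"run {run} out of range [0, {cfg.n_runs})")
        t = np.arange(cfg.run_length_trs) * cfg.tr_s
        resp = self._response_tr                                 # (T,)
        amp = self._amp_vol                                      # (x,y,z) percent
        # run-specific noise and drift phase from spawned child seeds
        child = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_runs)[run]
        rng = np.random.default_rng(child)
        phase = rng.uniform(0, 2 * np.pi)
        t_global = t + run * cfg.run_length_trs * cfg.tr_s
        drift = cfg.drift_amplitude * np.cos(2 * np.pi * t_global / cfg.drift_period_s + phase)
        sig = cfg.baseline * (
            1.0
            + amp[..., None] / 100.0 * resp
            + drift
        )
        sig = sig.astype(np.float32)
        if cfg.noise_sd > 0:
            sig += rng.normal(0.0, cfg.baseline * cfg.noise_sd,
                              size=sig.shape).astype(np.float32)
        return sig

    def iter_bold_runs(self):
        for r in range(self.config.n_runs):
            yield self.bold_run(r)

    # -- I/O ---------------------------------------------------------------

    def write(self, out_dir: str | Path) -> None:
        """Write segmentations, BOLD runs, truth table, config and design."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, vol in [("seg_tectum", self.seg_tectum), ("seg_ca", self.seg_ca)]:
            nib.save(nib.Nifti1Image(vol.astype(np.float32), self.affine),
                     out / f"{name}.nii.gz")
        for r in range(self.config.n_runs):
            img = nib.Nifti1Image(self.bold_run(r), self.affine)
            img.header.set_zooms((*[self.config.voxel_size_mm] * 3, self.config.tr_s))
            nib.save(img, out / f"bold_run-{r + 1}.nii.gz")
        centers = self.voxel_centers_mm().reshape(-1, 3)
        shell = (self.seg_tectum.ravel() >= 0.5) & (self.seg_ca.ravel() < 0.5)
        tab = self.truth.table(centers[shell])
        tab.insert(0, "voxel", np.flatnonzero(shell))
        tab.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        (out / "config.json").write_text(json.dumps(self.config.to_dict(), indent=2))
        (out / "event_design.json").write_text(json.dumps(self.design.to_dict(), indent=2))


def make_phantom(config: PhantomConfig | None = None,
                 out_dir: str | Path | None = None) -> PhantomDataset:
    """Build the phantom; optionally write it to ``out_dir``.

    Outputs are a pure function of the config (including ``rng_seed``):
    two calls with equal configs produce bit-identical volumes.
    """
    cfg = config or PhantomConfig()
    cfg.validate()
    shape = cfg.resolved_grid_shape()
    affine = cfg.affine()
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    centers = idx @ affine[:3, :3].T + affine[:3, 3]
    r = np.linalg.norm(centers, axis=-1)
    seg_t = _partial_volume_ball(r, cfg.outer_radius_mm, cfg.voxel_size_mm)
    seg_ca = _partial_volume_ball(r, cfg.inner_radius_mm, cfg.voxel_size_mm)
    truth = GroundTruth(
        outer_radius_mm=cfg.outer_radius_mm,
        inner_radius_mm=cfg.inner_radius_mm,
        sc_poles=cfg.sc_poles,
        sc_patch_extent_mm=cfg.sc_patch_extent_mm,
        amplitude_rostral=cfg.amplitude_rostral,
        amplitude_caudal=cfg.amplitude_caudal,
        kernel=cfg.kernel,
        rng_seed=cfg.rng_seed,
    )
    design = make_event_design(cfg)
    # responsive tissue: shell voxels inside a patch
    shell = (seg_t >= 0.5) & (seg_ca < 0.5)
    amp = np.zeros(shape, dtype=float)
    amp[shell] = truth.amplitude(centers[shell])
    t = np.arange(cfg.run_length_trs) * cfg.tr_s
    resp = np.zeros(cfg.run_length_trs)
    for onset in design.epoch_onsets_trs:
        m = t >= onset * cfg.tr_s
        resp[m] += synth_hrf_kernel(t[m] - onset * cfg.tr_s, 1.0, cfg.kernel)
    ds = PhantomDataset(
        config=cfg, affine=affine, seg_tectum=seg_t, seg_ca=seg_ca,
        design=design, truth=truth, _amp_vol=amp, _response_tr=resp,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds
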