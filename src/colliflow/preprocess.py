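"""Temporal preprocessing of event-related BOLD runs.

Two steps from the emulated protocol are implemented: slice-timing
correction by cubic-spline resampling, and low-frequency baseline
drift removal by subtracting the timeseries smoothed twice with a
rectangular (moving-average) kernel whose duration equals one HRF
epoch.  Head-motion correction and anatomical registration are out of
scope — real data are expected pre-registered (a warning is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .phantom import EventDesign

__all__ = ["BoldRun", "slice_timing_correct", "remove_drift", "epoch_split"]

log = logging.getLogger(__name__)


@dataclass
class BoldRun:
    """One 4-D BOLD run (x, y, z, t) with its temporal metadata."""

    data: np.ndarray
    tr_s: float
    affine: np.ndarray
    slice_axis: int = 2
    slice_offsets_s: np.ndarray | None = None
    units: str = "raw"          # "raw" or "percent_change"

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if self.slice_offsets_s is not None:
            off = np.asarray(self.slice_offsets_s, dtype=float)
            if len(off) != self.data.shape[self.slice_axis]:
                raise ValueError("slice_offsets length must match the slice axis size")
            if np.any(off < 0) or np.any(off >= self.tr_s):
                raise ValueError("slice offsets must lie in [0, tr_s)")
            self.slice_offsets_s = off

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @classmethod
    def from_nifti(cls, path: str | Path, tr_s: float, **kw) -> "BoldRun":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=np.float32), tr_s,
                   img.affine, **kw)

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr_s))
        nib.save(img, str(path))


def slice_timing_correct(run: BoldRun, reference_offset_s: float = 0.0) -> BoldRun:
    """Resample every slice's timeseries onto a common time grid.

    Each voxel's series, acquired at ``k*tr + offset(slice)``, is
    interpolated with a natural cubic spline to the reference grid
    ``k*tr + reference_offset_s``.  Extrapolation is limited to at most
    one TR at the run edges.
    """
    if run.slice_offsets_s is None:
        raise ValueError("slice offsets unknown; set slice_offsets_s first")
    nt = run.n_timepoints
    if nt < 4:
        raise ValueError("need at least 4 timepoints for cubic-spline resampling")
    if abs(reference_offset_s) > run.tr_s:
        raise ValueError("reference offset must be within one TR")
    out = np.empty_like(run.data, dtype=np.float32)
    t_ref = np.arange(nt) * run.tr_s + reference_offset_s
    sl = [slice(None)] * 4
    for k, off in enumerate(run.slice_offsets_s):
        sl[run.slice_axis] = k
        block = run.data[tuple(sl)]                       # (..., t)
        if off == reference_offset_s:
            out[tuple(sl)] = block
            continue
        t_acq = np.arange(nt) * run.tr_s + off
        flat = block.reshape(-1, nt)
        cs = CubicSpline(t_acq, flat, axis=1, bc_type="natural", extrapolate=True)
        out[tuple(sl)] = cs(t_ref).reshape(block.shape).astype(np.float32)
    return replace(run, data=out)


def remove_drift(run: BoldRun, kernel_duration_s: float = 26.25,
                 to_percent: bool = True) -> BoldRun:
    """Subtract a double-RECT-smoothed baseline; optionally convert to %.

    The baseline of each voxel timeseries is the series smoothed twice
    with a moving-average window of ``kernel_duration_s`` (one HRF
    epoch by default), with reflect padding at the run edges.  With
    ``to_percent`` the residual is divided by the voxel's temporal mean
    and multiplied by 100, so downstream HRF amplitudes are in percent
    signal change.
    """
    nt = run.n_timepoints
    win = int(round(kernel_duration_s / run.tr_s))
    if win < 1:
        raise ValueError("kernel shorter than one TR")
    if win > nt:
        raise ValueError(f"kernel ({win} TRs) longer than the run ({nt} TRs)")
    x = np.asarray(run.data, dtype=np.float64)
    baseline = ndimage.uniform_filter1d(x, size=win, axis=-1, mode="reflect")
    baseline = ndimage.uniform_filter1d(baseline, size=win, axis=-1, mode="reflect")
    resid = x - baseline
    if to_percent:
        mean = x.mean(axis=-1, keepdims=True)
        mean = np.where(np.abs(mean) < 1e-12, 1.0, mean)
        resid = 100.0 * resid / mean
        units = "percent_change"
    else:
        units = run.units
    return replace(run, data=resid.astype(np.float32), units=units)


def epoch_split(series: np.ndarray, design: EventDesign) -> np.ndarray:
    """Cut a timeseries into aligned epochs.

    ``series`` has time as its last axis; the result has shape
    ``series.shape[:-1] + (n_epochs, epoch_length_trs)``.  Lead-in
    samples before the first onset (and anything after the last epoch)
    are discarded.
    """
    series = np.asarray(series)
    nt = series.shape[-1]
    last_end = design.epoch_onsets_trs[-1] + design.epoch_length_trs
    if nt < last_end:
        raise ValueError(f"series has {nt} samples but the design needs {last_end}")
    stacks = [series[..., o:o + design.epoch_length_trs]
              for o in design.epoch_onsets_trs]
    return np.stack(stacks, axis=-2)
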