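"""Matplotlib figures: HRF ribbons and the amplitude-vs-distance fit."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .roi_gradient import GradientResult


def band_hrf_ribbons(profile: list, path: str | Path) -> None:
    """Mean ± 68% CI ribbon per ROI, seed first then each 1-mm band."""
    hrfs = [h for h in profile if h is not None]
    if not hrfs:
        return
    fig, axes = plt.subplots(len(hrfs), 1, figsize=(5, 1.6 * len(hrfs)),
                             sharex=True, squeeze=False)
    names = ["seed"] + [f"band {k}" for k in range(len(hrfs) - 1)]
    for ax, hrf, name in zip(axes[:, 0], hrfs, names):
        ax.fill_between(hrf.t, hrf.ci_low, hrf.ci_high, alpha=0.3, lw=0)
        ax.plot(hrf.t, hrf.mean, lw=1.2)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("%")
        ax.set_title(f"{name}: {hrf.label}, peak {hrf.peak_amplitude:.2f}% "
                     f"@ {hrf.peak_time_s:.1f} s", fontsize=8)
    axes[-1, 0].set_xlabel("time since epoch onset (s)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def gradient_scatter(fit: GradientResult, path: str | Path) -> None:
    """Band peak amplitude against normalized rostro-caudal distance."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(fit.distances, fit.amplitudes, zorder=3)
    if fit.fitted:
        xs = np.linspace(0, 1, 50)
        color = "red" if fit.significant else "gray"
        ax.plot(xs, fit.intercept + fit.slope * xs, color=color,
                label=f"R = {fit.pearson_r:.2f}, p = {fit.p_value:.2g}")
        ax.legend(fontsize=8)
    ax.set_xlabel("normalized rostro-caudal distance")
    ax.set_ylabel("peak amplitude (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
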