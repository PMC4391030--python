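"""Diagnostic plots for evaluation reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import DecayFit, decay_curve


def save_cumulative_curve(curve, path: str | Path) -> None:
    """Percentage of frames with detection error <= x, as a step plot."""
    arr = np.asarray(curve, dtype=np.float64)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.step(arr[:, 0], arr[:, 1], where="post")
    ax.set_xlabel("detection error (px)")
    ax.set_ylabel("frames with error ≤ x (%)")
    ax.set_ylim(0, 102)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_error_histogram(errors, fit: DecayFit, path: str | Path,
                         bin_width: float = 1.0) -> None:
    """Normalized error histogram with the fitted decay and hit cut."""
    e = np.asarray(errors, dtype=np.float64)
    nbins = max(int(np.ceil(e.max() / bin_width)), 1)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(e, bins=nbins, range=(0, nbins * bin_width), density=True,
            alpha=0.6, label="errors")
    xs = np.linspace(0, nbins * bin_width, 300)
    ax.plot(xs, decay_curve(xs, fit.p0, fit.ps, fit.pr), label="decay fit")
    ax.axvline(fit.threshold, linestyle="--", color="k",
               label=f"hit cut {fit.threshold:.1f} px")
    ax.set_xlabel("detection error (px)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
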