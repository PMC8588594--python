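"""Three-panel figures for RMSE curves and trajectory confidence bands."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import StudyResult
from .surrogate import OUTPUT_COLUMNS, T_WEEKS, Trajectory
from .uncertainty import ConfidenceBand

__all__ = ["plot_rmse_study", "plot_band"]

_LABELS = {"beta": "BMI", "gamma": "fasting glucose", "tau": "TNF-alpha"}


def plot_rmse_study(study: dict[int, StudyResult], path: str | None = None):
    """One panel per output: E(t) for every sample size of the study."""
    fig, axes = plt.subplots(3, 1, figsize=(7, 9), sharex=True)
    for ax, h in zip(axes, OUTPUT_COLUMNS):
        for k, r in sorted(study.items()):
            ax.plot(r.rmse.values.index, r.rmse.values[h], label=f"n={k}")
        ax.set_ylabel(f"E ({_LABELS[h]})")
        ax.legend(fontsize=8)
    axes[-1].set_xlabel("week")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_band(band: ConfidenceBand, reference: Trajectory | None = None, path: str | None = None):
    """Predicted trajectory with its bootstrap band, one panel per output."""
    weeks = np.arange(1, T_WEEKS + 1)
    fig, axes = plt.subplots(3, 1, figsize=(7, 9), sharex=True)
    for ax, h in zip(axes, OUTPUT_COLUMNS):
        ax.fill_between(
            weeks, band.lower[h], band.upper[h], alpha=0.3, label="bootstrap band"
        )
        ax.plot(weeks, band.center.output(h), label="emulated")
        if reference is not None:
            ax.plot(weeks, reference.output(h), "k--", lw=1, label="simulated")
        ax.set_ylabel(_LABELS[h])
        ax.legend(fontsize=8)
    axes[-1].set_xlabel("week")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
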