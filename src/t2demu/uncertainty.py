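"""Bootstrap-residual confidence bands and coverage probability.

Because the emulator is a regression over a fixed design (the training
table), uncertainty is quantified by *bootstrapping residuals*: the
residuals e(x_i, t) = y(x_i, t) - yhat(x_i, t) are pooled within each
output variable and resampled with replacement to form B pseudo-response
sets

    y*_b(x_i, t) = yhat(x_i, t) + e*_b(x_i, t),    b = 1..B

whose per-week empirical quantiles q_alpha and q_{1-alpha} give a pointwise
confidence band around the predicted trajectory.  Two variants are
provided:

* ``refit=False`` (default): the band is the quantile band of the
  perturbed predictions yhat + e* themselves — the literal bootstrap-sample
  construction, which is calibrated against the training residual
  distribution;
* ``refit=True``: each pseudo-response set is used to refit the full
  emulator over the fixed design and the band is taken over the B refit
  predictions, which measures how much the fitted forest itself moves
  under residual resampling (narrower, model-uncertainty-only bands).

The *coverage probability* of a band against a reference trajectory is the
fraction of the 26 weeks at which the reference lies inside the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emulator import EmulatorResults, INPUT_COLUMNS
from .surrogate import OUTPUT_COLUMNS, T_WEEKS, Trajectory

__all__ = [
    "ConfidenceBand",
    "CoverageReport",
    "compute_residuals",
    "bootstrap_band",
    "bootstrap_replicate_models",
    "coverage_probability",
    "coverage_study",
]


@dataclass(frozen=True)
class ConfidenceBand:
    """Pointwise band per output: lower/upper quantile series and center."""

    lower: pd.DataFrame  # T x 3, columns beta/gamma/tau
    upper: pd.DataFrame
    center: Trajectory
    alpha: float
    B: int

    def __post_init__(self) -> None:
        if not (self.lower.to_numpy() <= self.upper.to_numpy() + 1e-12).all():
            raise ValueError("band lower bound exceeds upper bound")


@dataclass(frozen=True)
class CoverageReport:
    """Coverage per output, optionally averaged over many subjects."""

    per_subject: pd.DataFrame  # one row per subject, columns beta/gamma/tau
    alpha: float
    B: int

    @property
    def mean(self) -> dict[str, float]:
        return {h: float(self.per_subject[h].mean()) for h in OUTPUT_COLUMNS}

    @property
    def overall_mean(self) -> float:
        return float(self.per_subject[OUTPUT_COLUMNS].to_numpy().mean())


def compute_residuals(
    results: EmulatorResults, table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Residuals y - yhat for every row and output, with grouping keys.

    With ``table=None`` the emulator's own training table is used.
    """
    if table is None:
        table = results.model.table
    missing = [c for c in INPUT_COLUMNS + OUTPUT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    preds = results.predict_frame(table)
    out = table[[c for c in ("subject_id", "t") if c in table.columns]].copy()
    for h in OUTPUT_COLUMNS:
        out[h] = table[h].to_numpy(dtype=float) - preds[h].to_numpy()
    return out


def _quantile_band(samples: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise q_alpha / q_{1-alpha} over the replicate axis (axis 0).

    Uses the inclusive linear-interpolation quantile convention.
    """
    lower = np.quantile(samples, alpha, axis=0, method="linear")
    upper = np.quantile(samples, 1.0 - alpha, axis=0, method="linear")
    return lower, upper


def _check_band_args(B: int, alpha: float) -> None:
    if B < 2:
        raise ValueError("at least B=2 bootstrap replicates are required")
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")


def bootstrap_replicate_models(
    results: EmulatorResults, B: int, seed: int
) -> list[EmulatorResults]:
    """Refit the emulator on B residual-bootstrap pseudo-response sets.

    Residuals are pooled per output variable and resampled with
    replacement over the fixed design; replicate b's refit seed derives
    deterministically from ``(seed, b)``.
    """
    _check_band_args(B, 0.05)
    rng = np.random.default_rng(seed)
    refit_seeds = np.random.SeedSequence(seed).generate_state(B)
    yhat = results.fitted_values.to_numpy()
    resid = results.resid.to_numpy()
    n = len(resid)
    models = []
    for b in range(B):
        e_star = np.column_stack(
            [resid[rng.integers(n, size=n), j] for j in range(resid.shape[1])]
        )
        models.append(
            results.refit(yhat + e_star, seed=int(refit_seeds[b] % (2**31)))
        )
    return models


def _replicate_trajectories(
    results: EmulatorResults,
    X_subjects: np.ndarray,
    B: int,
    seed: int,
    refit: bool,
) -> np.ndarray:
    """(B, n_subjects, T, 3) bootstrap trajectories for encoded subjects.

    ``X_subjects`` is an (n_subjects, 10) matrix of encoded features; the
    week column is appended internally.
    """
    n_sub = X_subjects.shape[0]
    weeks = np.arange(1, T_WEEKS + 1)
    X = np.column_stack(
        [
            np.repeat(X_subjects, T_WEEKS, axis=0),
            np.tile(weeks, n_sub)[:, None],
        ]
    )
    center = results.predict_matrix(X).reshape(n_sub, T_WEEKS, 3)
    out = np.empty((B, n_sub, T_WEEKS, 3))
    if refit:
        for b, m in enumerate(bootstrap_replicate_models(results, B, seed)):
            out[b] = m.predict_matrix(X).reshape(n_sub, T_WEEKS, 3)
    else:
        rng = np.random.default_rng(seed)
        resid = results.resid.to_numpy()
        n = len(resid)
        for j in range(3):
            draws = resid[rng.integers(n, size=(B, n_sub, T_WEEKS)), j]
            out[:, :, :, j] = center[None, :, :, j] + draws
    return out


def bootstrap_band(
    results: EmulatorResults,
    x,
    B: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    refit: bool = False,
) -> ConfidenceBand:
    """Pointwise bootstrap-residual confidence band for one subject.

    Parameters follow the study defaults: B = 50 replicates and
    alpha = 0.05, i.e. a band between the 5% and 95% pointwise quantiles.
    Deterministic under ``seed``.
    """
    _check_band_args(B, alpha)
    from .subjects import encode_subject  # local to avoid cycle at import time

    center = results.predict_trajectory(x)
    reps = _replicate_trajectories(
        results, encode_subject(x)[None, :], B, seed, refit
    )[:, 0]  # (B, T, 3)
    lower, upper = _quantile_band(reps, alpha)
    weeks = pd.RangeIndex(1, T_WEEKS + 1, name="t")
    return ConfidenceBand(
        lower=pd.DataFrame(lower, columns=OUTPUT_COLUMNS, index=weeks),
        upper=pd.DataFrame(upper, columns=OUTPUT_COLUMNS, index=weeks),
        center=center,
        alpha=alpha,
        B=B,
    )


def coverage_probability(band: ConfidenceBand, reference: Trajectory) -> CoverageReport:
    """Fraction of the 26 weeks at which the reference lies inside the band."""
    rec = {}
    for h in OUTPUT_COLUMNS:
        y = reference.output(h)
        lo = band.lower[h].to_numpy()
        hi = band.upper[h].to_numpy()
        if len(y) != len(lo):
            raise ValueError("band and reference trajectory lengths differ")
        rec[h] = float(np.mean((lo <= y) & (y <= hi)))
    return CoverageReport(
        per_subject=pd.DataFrame([rec]), alpha=band.alpha, B=band.B
    )


def coverage_study(
    results: EmulatorResults,
    table: pd.DataFrame,
    subject_ids: list[int] | None = None,
    B: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    refit: bool = False,
) -> CoverageReport:
    """Band coverage averaged over many subjects of a trajectory table.

    For every subject in ``table`` (or the subset ``subject_ids``) a
    bootstrap band is built from the fitted emulator's residuals — sharing
    the B refits across subjects in refit mode — and compared against the
    subject's simulated reference trajectory.
    """
    _check_band_args(B, alpha)
    if "subject_id" not in table.columns:
        raise ValueError("table must carry a subject_id column")
    groups = dict(tuple(table.sort_values("t").groupby("subject_id")))
    ids = list(groups) if subject_ids is None else list(subject_ids)
    feats = np.stack(
        [
            groups[i].iloc[0][INPUT_COLUMNS[:-1]].to_numpy(dtype=float)
            for i in ids
        ]
    )
    refs = np.stack(
        [groups[i][OUTPUT_COLUMNS].to_numpy(dtype=float) for i in ids]
    )  # (n_sub, T, 3)
    reps = _replicate_trajectories(results, feats, B, seed, refit)
    lower, upper = _quantile_band(reps, alpha)  # (n_sub, T, 3)
    inside = (lower <= refs) & (refs <= upper)
    cov = inside.mean(axis=1)  # (n_sub, 3)
    frame = pd.DataFrame(cov, columns=OUTPUT_COLUMNS)
    frame.insert(0, "subject_id", ids)
    return CoverageReport(per_subject=frame, alpha=alpha, B=B)
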