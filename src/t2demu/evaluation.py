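"""Unit scaling, per-week RMSE curves, and the sample-size study.

Emulator accuracy is summarised per output variable h and week t by the
root mean square error over the n test subjects,

    E_h(t) = sqrt( (1/n) * sum_i ( y_h(x_i, t) - yhat_h(x_i, t) )^2 )

computed on outputs min-max scaled to the unit interval so the three
curves are directly comparable.  The scaling is fitted on the training
table only and reused for the test set; test values falling outside the
training range scale outside [0, 1] and are flagged, never clipped.

The sample-size study repeats the whole pipeline — stratified design,
70/30 subject-level split, simulation, fit, RMSE and band coverage — for a
ladder of design sizes, to show accuracy improving (and coverage
stabilising) with more training trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emulator import EmulatorResults, fit_emulator
from .subjects import SubjectGrid, lhs_sample, split_train_test
from .surrogate import OUTPUT_COLUMNS, SimulatorConfig, generate_dataset
from .uncertainty import CoverageReport, coverage_study

__all__ = [
    "ScalingSpec",
    "RMSECurve",
    "StudyResult",
    "fit_scaling",
    "rmse_curve",
    "sample_size_study",
    "study_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScalingSpec:
    """Per-output min-max scaling to [0, 1], with provenance."""

    mins: dict[str, float]
    maxs: dict[str, float]
    provenance: str = "training table"

    def transform(self, values, output: str) -> np.ndarray:
        lo, hi = self.mins[output], self.maxs[output]
        return (np.asarray(values, dtype=float) - lo) / (hi - lo)

    def inverse(self, scaled, output: str) -> np.ndarray:
        lo, hi = self.mins[output], self.maxs[output]
        return np.asarray(scaled, dtype=float) * (hi - lo) + lo

    def out_of_range(self, table: pd.DataFrame) -> dict[str, int]:
        """Count of values per output falling outside the fitted range."""
        counts = {}
        for h in OUTPUT_COLUMNS:
            v = table[h].to_numpy(dtype=float)
            counts[h] = int(np.sum((v < self.mins[h]) | (v > self.maxs[h])))
        return counts


@dataclass(frozen=True)
class RMSECurve:
    """E_h(t) for t = 1..26 and h in {beta, gamma, tau}, on the unit scale."""

    values: pd.DataFrame  # index t, columns beta/gamma/tau
    n: int  # number of test trajectories

    @property
    def mean(self) -> dict[str, float]:
        """Mean of E_h(t) over the 26 weeks, per output."""
        return {h: float(self.values[h].mean()) for h in OUTPUT_COLUMNS}

    def edge_to_mid_ratio(self) -> dict[str, float]:
        """Diagnostic: mean of E at the first/last week over the mid-horizon
        mean — values above 1 indicate the boundary weeks are harder."""
        out = {}
        for h in OUTPUT_COLUMNS:
            e = self.values[h].to_numpy()
            edge = 0.5 * (e[0] + e[-1])
            mid = e[1:-1].mean()
            out[h] = float(edge / mid) if mid > 0 else float("nan")
        return out


def fit_scaling(table: pd.DataFrame) -> ScalingSpec:
    """Per-output min/max over a (training) table."""
    if len(table) == 0:
        raise ValueError("cannot fit scaling on an empty table")
    mins, maxs = {}, {}
    for h in OUTPUT_COLUMNS:
        v = table[h].to_numpy(dtype=float)
        mins[h], maxs[h] = float(v.min()), float(v.max())
        if maxs[h] <= mins[h]:
            raise ValueError(f"output {h!r} is constant; min-max scale degenerate")
    return ScalingSpec(mins=mins, maxs=maxs)


def rmse_curve(
    results: EmulatorResults, test: pd.DataFrame, scaling: ScalingSpec
) -> RMSECurve:
    """Per-week, per-output RMSE of the emulator on a test table."""
    if len(test) == 0:
        raise ValueError("test table is empty")
    oor = scaling.out_of_range(test)
    if any(oor.values()):
        logger.warning(
            "test values outside the training scaling range (not clipped): %s", oor
        )
    preds = results.predict_frame(test)
    sq = pd.DataFrame({"t": test["t"].to_numpy()})
    for h in OUTPUT_COLUMNS:
        r = scaling.transform(test[h], h) - scaling.transform(preds[h], h)
        sq[h] = r**2
    curve = sq.groupby("t").mean().pow(0.5).sort_index()
    n = test["subject_id"].nunique() if "subject_id" in test.columns else len(test)
    return RMSECurve(values=curve, n=int(n))


@dataclass(frozen=True)
class StudyResult:
    """One rung of the sample-size ladder."""

    sample_size: int
    rmse: RMSECurve
    coverage: CoverageReport
    oob_error: dict[str, float] = field(default_factory=dict)


def sample_size_study(
    grid: SubjectGrid,
    sizes: list[int],
    config: SimulatorConfig | None = None,
    seed: int = 0,
    n_trees: int = 50,
    train_fraction: float = 0.7,
    B: int = 50,
    alpha: float = 0.05,
    coverage_subjects: int | None = None,
    refit_bands: bool = False,
    coverage_on: str = "train",
) -> dict[int, StudyResult]:
    """Design / simulate / fit / evaluate at each training-set size.

    For each size: a stratified (Latin-hypercube-style) sample of the grid,
    a 70/30 subject-level split, surrogate simulation of both sides, a
    forest fit on the training side, the unit-scaled RMSE curve on the test
    side, and band coverage over up to ``coverage_subjects`` subjects.
    Coverage is measured on training (held-in) trajectories by default —
    the regime where the residual bootstrap has a nominal level, so the
    between-size comparison is not swamped by design-to-design noise;
    ``coverage_on="test"`` switches to held-out trajectories.  All stage
    seeds derive from the master ``seed``.
    """
    if coverage_on not in ("train", "test"):
        raise ValueError("coverage_on must be 'train' or 'test'")
    config = config or SimulatorConfig()
    out: dict[int, StudyResult] = {}
    for i, k in enumerate(sorted(sizes)):
        stage = np.random.SeedSequence([seed, i]).generate_state(4)
        sample = lhs_sample(grid, k, seed=int(stage[0] % (2**31)))
        train_s, test_s = split_train_test(
            sample, train_fraction, seed=int(stage[1] % (2**31))
        )
        sim_seed = int(stage[2] % (2**31))
        train = generate_dataset(train_s, config, seed=sim_seed)
        test = generate_dataset(test_s, config, seed=sim_seed + 1)
        res = fit_emulator(train, n_trees=n_trees, seed=int(stage[3] % (2**31)))
        scaling = fit_scaling(train)
        curve = rmse_curve(res, test, scaling)
        cov_table = train if coverage_on == "train" else test
        ids = sorted(cov_table["subject_id"].unique())
        if coverage_subjects is not None:
            ids = ids[:coverage_subjects]
        cov = coverage_study(
            res,
            cov_table,
            subject_ids=ids,
            B=B,
            alpha=alpha,
            seed=int(stage[3] % (2**31)) + 1,
            refit=refit_bands,
        )
        out[k] = StudyResult(
            sample_size=k, rmse=curve, coverage=cov, oob_error=res.oob_mse()
        )
        logger.info(
            "size %d: mean RMSE %s, mean coverage %s",
            k,
            curve.mean,
            cov.mean,
        )
    return out


def study_to_frame(study: dict[int, StudyResult]) -> pd.DataFrame:
    """Tidy export: one row per (sample_size, output, t) with the E value."""
    rows = []
    for k, r in sorted(study.items()):
        for h in OUTPUT_COLUMNS:
            for t, e in r.rmse.values[h].items():
                rows.append(
                    {"sample_size": k, "output": h, "t": int(t), "E": float(e)}
                )
    return pd.DataFrame(rows)
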