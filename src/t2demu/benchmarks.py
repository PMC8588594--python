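"""Standard benchmark experiments run by tests and the acceptance script.

Each experiment recomputes its quantities from scratch: enumerate the grid,
draw a design, simulate trajectories, fit the emulator, and measure.  All
randomness derives from a single master seed.  The problem sizes follow the
desk-scale study defaults (designs of 500–2000 subjects, 50-tree forests,
B = 50 bootstrap replicates) so each experiment completes in seconds to a
couple of minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emulator import fit_emulator
from .evaluation import StudyResult, fit_scaling, rmse_curve, sample_size_study
from .subjects import SubjectGrid, enumerate_grid, lhs_sample, split_train_test
from .surrogate import OUTPUT_COLUMNS, SimulatorConfig, generate_dataset
from .uncertainty import coverage_study

__all__ = [
    "calibration_benchmark",
    "sample_size_benchmark",
    "baseline_comparison_benchmark",
]


def _stage_seeds(seed: int, label: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence([seed, label]).generate_state(n)]


@dataclass(frozen=True)
class CalibrationResult:
    mean_coverage: dict[str, float]  # per output, averaged over subjects
    grand_mean: float
    n_subjects: int
    tau_inflation: float


def calibration_benchmark(
    seed: int,
    k: int = 500,
    B: int = 50,
    alpha: float = 0.05,
    n_subjects: int = 100,
    tau_inflation: float = 1.0,
    grid: SubjectGrid | None = None,
) -> CalibrationResult:
    """Band coverage of training (held-in) trajectories.

    Fits the emulator on a k-subject design and measures the bootstrap
    band's coverage of the simulated reference trajectories for a random
    subset of the training subjects — the regime where the residual
    bootstrap is expected to attain its nominal 1 - 2*alpha level.
    ``tau_inflation`` scales the generator's TNF noise to probe the
    high-variability output.
    """
    grid = grid or enumerate_grid()
    base = SimulatorConfig()
    config = base.with_noise(
        base.noise_sd_beta, base.noise_sd_gamma, base.noise_sd_tau * tau_inflation
    )
    s_sample, s_sim, s_fit, s_cov, s_pick = _stage_seeds(seed, 1, 5)
    sample = lhs_sample(grid, k, seed=s_sample)
    table = generate_dataset(sample, config, seed=s_sim)
    results = fit_emulator(table, n_trees=50, seed=s_fit)
    ids = np.asarray(sorted(table["subject_id"].unique()))
    pick = np.random.default_rng(s_pick).choice(len(ids), size=n_subjects, replace=False)
    cov = coverage_study(
        results, table, subject_ids=list(ids[np.sort(pick)]), B=B, alpha=alpha, seed=s_cov
    )
    return CalibrationResult(
        mean_coverage=cov.mean,
        grand_mean=cov.overall_mean,
        n_subjects=n_subjects,
        tau_inflation=tau_inflation,
    )


def sample_size_benchmark(
    seed: int,
    sizes: tuple[int, ...] = (500, 1000, 1500, 2000),
    grid: SubjectGrid | None = None,
) -> dict[int, StudyResult]:
    """The desk-scale sample-size ladder (one tenth of the full study)."""
    grid = grid or enumerate_grid()
    return sample_size_study(grid, list(sizes), SimulatorConfig(), seed=seed)


@dataclass(frozen=True)
class BaselineComparison:
    emulator_rmse: pd.DataFrame  # per (t, output), unit scale
    baseline_rmse: pd.DataFrame  # training-mean constant predictor
    n_test: int

    def emulator_wins_everywhere(self) -> bool:
        return bool(
            (self.emulator_rmse.to_numpy() <= self.baseline_rmse.to_numpy()).all()
        )


def baseline_comparison_benchmark(
    seed: int, k: int = 500, grid: SubjectGrid | None = None
) -> BaselineComparison:
    """Held-out RMSE of the emulator versus the training-mean predictor."""
    grid = grid or enumerate_grid()
    s_sample, s_split, s_sim, s_fit = _stage_seeds(seed, 2, 4)
    sample = lhs_sample(grid, k, seed=s_sample)
    train_s, test_s = split_train_test(sample, 0.7, seed=s_split)
    config = SimulatorConfig()
    train = generate_dataset(train_s, config, seed=s_sim)
    test = generate_dataset(test_s, config, seed=s_sim + 1)
    results = fit_emulator(train, n_trees=50, seed=s_fit)
    scaling = fit_scaling(train)
    curve = rmse_curve(results, test, scaling)
    base = {}
    for h in OUTPUT_COLUMNS:
        mean_pred = float(train[h].mean())
        r = scaling.transform(test[h], h) - scaling.transform(mean_pred, h)
        base[h] = (
            pd.DataFrame({"t": test["t"].to_numpy(), "sq": np.asarray(r) ** 2})
            .groupby("t")["sq"]
            .mean()
            .pow(0.5)
        )
    baseline = pd.DataFrame(base).sort_index()
    return BaselineComparison(
        emulator_rmse=curve.values, baseline_rmse=baseline, n_test=len(test_s)
    )
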