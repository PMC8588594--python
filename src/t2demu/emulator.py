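"""Time-as-input random-forest emulator of the trajectory simulator.

The emulator treats the week index as an eleventh regressor next to the ten
subject descriptors, so a single model per output variable covers the whole
26-week trajectory:

    y_h(x, t) = (1/M) * sum_m T_m(x, t) + eps,   h in {beta, gamma, tau}

with T_m the m-th regression tree of an M-tree forest (M = 50 by default)
and eps a residual error whose empirical 3x3 covariance is recorded on the
results object.  One independent forest is fitted per output variable; each
tree is trained on a bootstrap resample of the long-format table, which
makes an out-of-bag (OOB) error estimate available per output.

Usage follows the model/results convention::

    model = TrajectoryEmulator(table, n_trees=50, seed=7)
    res = model.fit()
    res.summary()
    res.predict_trajectory(subject)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .subjects import FEATURE_COLUMNS, VirtualSubject, encode_subject
from .surrogate import OUTPUT_COLUMNS, T_WEEKS, Trajectory

__all__ = [
    "TrajectoryEmulator",
    "EmulatorResults",
    "fit_emulator",
    "OutOfDomainWarning",
    "INPUT_COLUMNS",
]

#: the eleven regressors: ten subject features plus the week index
INPUT_COLUMNS = FEATURE_COLUMNS + ["t"]


class OutOfDomainWarning(UserWarning):
    """Prediction requested outside the training time range."""


class TrajectoryEmulator:
    """Forest emulator specification bound to a long-format training table.

    Parameters
    ----------
    table:
        Long-format training data with the ten feature columns, the week
        index ``t`` and the three output columns.
    n_trees:
        Trees per output forest (M).
    min_samples_leaf, max_features:
        Conventional regression-forest defaults: leaves of at least five
        observations (the regression default of the reference R
        implementation of random forests) and all features considered at
        every split.
    seed:
        Master seed; per-output forest seeds derive from it.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        n_trees: int = 50,
        min_samples_leaf: int = 5,
        max_features: float | str = 1.0,
        seed: int = 0,
    ) -> None:
        missing = [c for c in INPUT_COLUMNS + OUTPUT_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"training table is missing columns: {missing}")
        if len(table) == 0:
            raise ValueError("training table is empty")
        if n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        self.table = table.reset_index(drop=True)
        self.n_trees = n_trees
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.seed = seed
        self.X = self.table[INPUT_COLUMNS].to_numpy(dtype=float)
        self.Y = self.table[OUTPUT_COLUMNS].to_numpy(dtype=float)
        self.t_range = (int(self.table["t"].min()), int(self.table["t"].max()))

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "TrajectoryEmulator":
        return cls(table, **kwargs)

    def _make_forest(self, random_state: int) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            bootstrap=True,
            oob_score=True,
            n_jobs=1,
            random_state=random_state,
        )

    def fit(self, responses: np.ndarray | None = None) -> "EmulatorResults":
        """Fit the three per-output forests; returns an :class:`EmulatorResults`.

        ``responses`` optionally replaces the table's output matrix (same
        row order) — this is how the residual bootstrap refits the emulator
        on pseudo-responses over the fixed design.
        """
        Y = self.Y if responses is None else np.asarray(responses, dtype=float)
        if Y.shape != (len(self.table), len(OUTPUT_COLUMNS)):
            raise ValueError(f"responses must have shape {self.Y.shape}")
        forest_seeds = np.random.SeedSequence(self.seed).generate_state(
            len(OUTPUT_COLUMNS)
        )
        forests: dict[str, RandomForestRegressor] = {}
        with warnings.catch_warnings():
            # small fits can leave some rows with no OOB trees; handled below
            warnings.filterwarnings(
                "ignore", message="Some inputs do not have OOB scores"
            )
            for j, name in enumerate(OUTPUT_COLUMNS):
                f = self._make_forest(int(forest_seeds[j] % (2**31)))
                f.fit(self.X, Y[:, j])
                forests[name] = f
        fitted = np.column_stack([forests[h].predict(self.X) for h in OUTPUT_COLUMNS])
        resid = Y - fitted
        oob = {}
        for j, name in enumerate(OUTPUT_COLUMNS):
            oob_pred = forests[name].oob_prediction_
            ok = np.isfinite(oob_pred)
            oob[name] = float(np.mean((Y[ok, j] - oob_pred[ok]) ** 2))
        residual_cov = pd.DataFrame(
            np.cov(resid, rowvar=False, ddof=1),
            index=OUTPUT_COLUMNS,
            columns=OUTPUT_COLUMNS,
        )
        return EmulatorResults(
            model=self,
            forests=forests,
            fitted_values=pd.DataFrame(fitted, columns=OUTPUT_COLUMNS),
            resid=pd.DataFrame(resid, columns=OUTPUT_COLUMNS),
            oob_error=oob,
            residual_cov=residual_cov,
            n_trees=self.n_trees,
            seed=self.seed,
        )


@dataclass
class EmulatorResults:
    """Fitted emulator: forests, diagnostics, and prediction methods."""

    model: TrajectoryEmulator
    forests: Mapping[str, RandomForestRegressor]
    fitted_values: pd.DataFrame
    resid: pd.DataFrame
    oob_error: dict[str, float]
    residual_cov: pd.DataFrame
    n_trees: int
    seed: int
    _schema: list[str] = field(default_factory=lambda: list(INPUT_COLUMNS))

    def _design_row(self, x: VirtualSubject, t: float) -> np.ndarray:
        lo, hi = self.model.t_range
        if not lo <= t <= hi:
            warnings.warn(
                f"week {t} lies outside the training range [{lo}, {hi}]; "
                "the forests extrapolate by nearest partition",
                OutOfDomainWarning,
                stacklevel=3,
            )
        return np.concatenate([encode_subject(x), [t]])

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predict all outputs for an (n, 11) design matrix."""
        X = np.asarray(X, dtype=float)
        return np.column_stack([self.forests[h].predict(X) for h in OUTPUT_COLUMNS])

    def predict_frame(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Predict all outputs for a frame holding the eleven input columns."""
        missing = [c for c in INPUT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"prediction frame is missing columns: {missing}")
        preds = self.predict_matrix(frame[INPUT_COLUMNS].to_numpy(dtype=float))
        return pd.DataFrame(preds, columns=OUTPUT_COLUMNS, index=frame.index)

    def predict_point(self, x: VirtualSubject, t: float) -> tuple[float, float, float]:
        """Emulated (beta, gamma, tau) at week ``t``: the per-output mean of
        the M tree predictions."""
        row = self._design_row(x, t)[None, :]
        preds = self.predict_matrix(row)[0]
        return tuple(float(v) for v in preds)

    def predict_trajectory(self, x: VirtualSubject) -> Trajectory:
        """Emulated full 26-week trajectory (stack of per-week predictions)."""
        X = np.column_stack(
            [
                np.tile(encode_subject(x), (T_WEEKS, 1)),
                np.arange(1, T_WEEKS + 1)[:, None],
            ]
        )
        preds = self.predict_matrix(X)
        return Trajectory(beta=preds[:, 0], gamma=preds[:, 1], tau=preds[:, 2])

    def oob_mse(self) -> dict[str, float]:
        """Per-output out-of-bag mean squared error on the training table."""
        return dict(self.oob_error)

    def refit(self, responses: np.ndarray, seed: int) -> "EmulatorResults":
        """Refit on pseudo-responses over the same fixed design (bootstrap)."""
        spec = TrajectoryEmulator(
            self.model.table,
            n_trees=self.n_trees,
            min_samples_leaf=self.model.min_samples_leaf,
            max_features=self.model.max_features,
            seed=seed,
        )
        return spec.fit(responses=responses)

    def summary(self) -> str:
        """Plain-text fit summary (per-output diagnostics)."""
        lines = [
            "Trajectory emulator (random forest, time as input)",
            "=" * 52,
            f"training rows:      {len(self.model.table)}",
            f"trees per output:   {self.n_trees}",
            f"min samples / leaf: {self.model.min_samples_leaf}",
            f"seed:               {self.seed}",
            "",
            f"{'output':<8}{'train RMSE':>12}{'OOB MSE':>12}{'resid sd':>12}",
            "-" * 44,
        ]
        for h in OUTPUT_COLUMNS:
            r = self.resid[h].to_numpy()
            lines.append(
                f"{h:<8}{np.sqrt(np.mean(r**2)):>12.4g}"
                f"{self.oob_error[h]:>12.4g}{r.std(ddof=1):>12.4g}"
            )
        return "\n".join(lines)


def fit_emulator(
    table: pd.DataFrame, n_trees: int = 50, seed: int = 0, **kwargs
) -> EmulatorResults:
    """Fit the forest emulator on a long-format training table."""
    return TrajectoryEmulator(table, n_trees=n_trees, seed=seed, **kwargs).fit()
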