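"""End-to-end pipeline driver: enumerate, sample, simulate, fit, evaluate,
bands/coverage, optimize — writing every artifact plus a run manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._version import __version__
from .config import PipelineConfig
from .diet_optimizer import optimize_diet
from .emulator import fit_emulator
from .evaluation import fit_scaling, rmse_curve, sample_size_study, study_to_frame
from .io import save_model, write_training_table
from .subjects import enumerate_grid, lhs_sample, split_train_test, sample_to_frame
from .surrogate import OUTPUT_COLUMNS, generate_dataset
from .uncertainty import bootstrap_band, coverage_study

__all__ = ["RunManifest", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """What a pipeline run produced, and from which configuration."""

    config: dict
    artifacts: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    version: str = __version__

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "config": self.config,
                    "artifacts": self.artifacts,
                    "timings_s": self.timings,
                },
                indent=2,
                default=str,
            )
        )


class _Stage:
    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s ...", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.timings[self.name] = round(time.perf_counter() - self.t0, 3)
        if exc is not None:
            logger.error("stage %s failed: %s", self.name, exc)
        return False


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full emulation pipeline described by ``config``.

    The main pass uses the largest configured sample size; if several sizes
    are configured, the multi-size study (RMSE and coverage per size) runs
    as well.  Every numeric artifact is a CSV or JSON file under
    ``config.outdir``; re-running with the same config reproduces the CSVs
    byte for byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())

    def art(name: str, fname: str) -> Path:
        p = outdir / fname
        manifest.artifacts[name] = str(p)
        return p

    with _Stage(manifest, "grid"):
        grid = enumerate_grid(config.grid)

    k = max(config.sample_sizes)
    with _Stage(manifest, "sample"):
        sample = lhs_sample(grid, k, seed=config.seed)
        train_s, test_s = split_train_test(
            sample, config.train_fraction, seed=config.seed + 1
        )
        sample_to_frame(sample).to_csv(art("sample", "sample.csv"), index=False)

    with _Stage(manifest, "simulate"):
        train = generate_dataset(train_s, config.simulator, seed=config.seed + 2)
        test = generate_dataset(test_s, config.simulator, seed=config.seed + 3)
        write_training_table(train, art("train_table", "train.csv"))
        write_training_table(test, art("test_table", "test.csv"))

    with _Stage(manifest, "fit"):
        results = fit_emulator(train, n_trees=config.n_trees, seed=config.seed + 4)
        save_model(results, art("model", "emulator.joblib"))

    with _Stage(manifest, "evaluate"):
        scaling = fit_scaling(train)
        curve = rmse_curve(results, test, scaling)
        curve.values.to_csv(art("rmse_curve", "rmse_curve.csv"))

    with _Stage(manifest, "bands"):
        ids = sorted(test["subject_id"].unique())[: config.coverage_subjects]
        cov = coverage_study(
            results,
            test,
            subject_ids=ids,
            B=config.B,
            alpha=config.alpha,
            seed=config.seed + 5,
            refit=config.refit_bands,
        )
        cov.per_subject.to_csv(art("coverage", "coverage.csv"), index=False)
        example = grid[ids[0]]
        band = bootstrap_band(
            results,
            example,
            B=config.B,
            alpha=config.alpha,
            seed=config.seed + 6,
            refit=config.refit_bands,
        )
        rows = []
        for h in OUTPUT_COLUMNS:
            for t in band.lower.index:
                rows.append(
                    {
                        "output": h,
                        "t": int(t),
                        "lower": band.lower.loc[t, h],
                        "center": band.center.output(h)[t - 1],
                        "upper": band.upper.loc[t, h],
                    }
                )
        pd.DataFrame(rows).to_csv(art("band_example", "band_example.csv"), index=False)

    if len(config.sample_sizes) > 1:
        with _Stage(manifest, "sample_size_study"):
            study = sample_size_study(
                grid,
                list(config.sample_sizes),
                config.simulator,
                seed=config.seed + 7,
                n_trees=config.n_trees,
                train_fraction=config.train_fraction,
                B=config.B,
                alpha=config.alpha,
                coverage_subjects=config.coverage_subjects,
                refit_bands=config.refit_bands,
            )
            study_to_frame(study).to_csv(
                art("study_rmse", "study_rmse.csv"), index=False
            )
            cov_tbl = pd.DataFrame(
                {kk: r.coverage.mean for kk, r in sorted(study.items())}
            )
            cov_tbl.index.name = "output"
            cov_tbl.to_csv(art("study_coverage", "study_coverage.csv"))

    if config.optimize:
        with _Stage(manifest, "optimize"):
            subject = grid[ids[0]]
            opt = optimize_diet(results, subject, seed=config.seed + 8)
            report = {
                "subject_id": int(ids[0]),
                "baseline_levels": list(subject.diet_levels),
                "best_levels": list(opt.best.levels),
                "best_grams": {
                    "carb": opt.best.carb,
                    "prot": opt.best.prot,
                    "fat": opt.best.fat,
                },
                "objective": opt.objective,
                "baseline_objective": opt.baseline_objective,
                "feasible_count": opt.feasible_count,
                "method": opt.method,
            }
            art("optimization", "optimization.json").write_text(
                json.dumps(report, indent=2)
            )
            base_tau = results.predict_trajectory(subject).tau
            pd.DataFrame(
                {
                    "t": range(1, len(base_tau) + 1),
                    "tau_baseline": base_tau,
                    "tau_optimized": opt.tau_hat,
                }
            ).to_csv(art("optimized_tau", "optimized_tau.csv"), index=False)

    manifest.artifacts["manifest"] = str(outdir / "manifest.json")
    manifest.save(outdir / "manifest.json")
    return manifest
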