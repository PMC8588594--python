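"""Structured pipeline configuration with YAML round-tripping.

One master seed drives every stochastic stage (design sampling, the
train/test split, simulation noise, forest fitting, bootstrap resampling);
per-stage seeds derive from it deterministically, so a config file plus its
seed reproduce every CSV artifact bit for bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .energy import EnergyConstants
from .subjects import GridSpec
from .surrogate import SimulatorConfig

__all__ = ["PipelineConfig"]


def _tupled(cls, data: dict):
    """Rebuild a (frozen) dataclass from a dict, restoring tuple fields."""
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full pipeline run needs, with the study defaults."""

    grid: GridSpec = field(default_factory=GridSpec)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    energy: EnergyConstants = field(default_factory=EnergyConstants)
    #: design sizes of the sample-size ladder (the main run uses the largest)
    sample_sizes: tuple[int, ...] = (500, 1000, 1500, 2000)
    seed: int = 0
    train_fraction: float = 0.7
    n_trees: int = 50
    B: int = 50
    alpha: float = 0.05
    #: refit the emulator per bootstrap replicate instead of perturbing
    #: predictions (slower, model-uncertainty-only bands)
    refit_bands: bool = False
    #: cap on subjects entering each coverage average
    coverage_subjects: int = 100
    #: empirical-quantile interpolation convention for the bands
    quantile_method: str = "linear"
    #: run the diet optimizer for an example subject at the end
    optimize: bool = True
    outdir: str = "t2demu_run"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        if "grid" in data:
            kwargs["grid"] = _tupled(GridSpec, data.pop("grid"))
        if "simulator" in data:
            kwargs["simulator"] = SimulatorConfig(**data.pop("simulator"))
        if "energy" in data:
            kwargs["energy"] = EnergyConstants(**data.pop("energy"))
        if "sample_sizes" in data:
            kwargs["sample_sizes"] = tuple(data.pop("sample_sizes"))
        kwargs.update(data)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
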