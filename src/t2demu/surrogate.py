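"""Synthetic stand-in for the patient-level type-2-diabetes simulator.

The real simulator is a multi-scale agent-based / ODE hybrid that is far too
expensive (and not redistributable) to train an emulator against here.  This
module provides a compact stochastic difference-equation system with the
same input-output structure: a virtual subject (ten descriptors) maps to 26
weekly values of

* ``beta`` — BMI, kg/m^2: slow drift proportional to the relative energy
  imbalance between the diet's calories and the subject's TDEE (an excess of
  7700 kcal adds one kg of body mass);
* ``gamma`` — fasting glucose, mmol/L-like units: a fast (one-to-two week)
  first-order response to current BMI and the carbohydrate level, with a
  transient overshoot at the onset of a hypercaloric diet;
* ``tau`` — TNF-alpha, arbitrary units: systemic inflammation, responding to
  glucose and BMI only after a configurable delay and through a first-order
  smoothing filter (immune "memory"), with markedly larger noise than the
  two metabolic outputs — cytokine lifetimes are short relative to weekly
  sampling, so week-level TNF readings are inherently volatile.

All stochasticity is Gaussian per-week noise; with the noise scales at zero
the system is deterministic and its contracts are exact: an energy-balanced
diet leaves BMI constant, a caloric surplus makes it non-decreasing, and a
glucose peak produces a TNF peak ``tau_lag`` weeks later.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import energy
from .subjects import DesignSample, VirtualSubject, FEATURE_COLUMNS, encode_subject

__all__ = [
    "SimulatorConfig",
    "Trajectory",
    "simulate_subject",
    "generate_dataset",
    "tau_response",
    "T_WEEKS",
    "OUTPUT_COLUMNS",
    "TABLE_COLUMNS",
]

#: weekly horizon of every trajectory
T_WEEKS = 26

OUTPUT_COLUMNS = ["beta", "gamma", "tau"]
#: schema of the long-format training table
TABLE_COLUMNS = ["subject_id"] + FEATURE_COLUMNS + ["t"] + OUTPUT_COLUMNS


@dataclass(frozen=True)
class SimulatorConfig:
    """Parameters of the surrogate dynamics.

    Noise scales are weekly Gaussian standard deviations in output units;
    ``noise_sd_tau`` must dominate the other two (inflammation is the
    high-variability output).  ``tau_lag`` is the delay, in weeks, between a
    metabolic change and the inflammatory response.
    """

    noise_sd_beta: float = 0.05
    noise_sd_gamma: float = 0.10
    #: reference scale of the TNF noise; the realized weekly standard
    #: deviation is this scale times the current inflammatory drive relative
    #: to baseline (multiplicative noise: volatility peaks with the response)
    noise_sd_tau: float = 0.30
    tau_lag: int = 3
    #: first-order smoothing weight of the inflammatory filter, in (0, 1]
    tau_smooth: float = 0.6
    #: per-week adjustment rate of glucose toward its target, in (0, 1]
    gamma_rate: float = 0.7
    gamma_base: float = 5.0
    #: glucose response per BMI unit above the reference BMI of 22
    gamma_beta_gain: float = 0.12
    #: glucose response per unit of carbohydrate multiplier above med
    gamma_carb_gain: float = 1.0
    #: transient glucose overshoot per kcal/day of caloric surplus
    gamma_overshoot: float = 1.0e-3
    #: week of the overshoot peak
    gamma_overshoot_peak: float = 2.0
    tau_base: float = 1.5
    tau_gamma_gain: float = 0.8
    tau_beta_gain: float = 0.15
    #: kcal of imbalance per kg of body-mass change
    kcal_per_kg: float = 7700.0
    #: multiplier on the energy-imbalance BMI drift
    beta_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd_tau > 0 and self.noise_sd_tau <= max(
            self.noise_sd_beta, self.noise_sd_gamma
        ):
            raise ValueError(
                "noise_sd_tau must exceed the beta and gamma noise scales"
            )
        if not 0 < self.tau_smooth <= 1 or not 0 < self.gamma_rate <= 1:
            raise ValueError("tau_smooth and gamma_rate must lie in (0, 1]")
        if self.tau_lag < 0:
            raise ValueError("tau_lag must be non-negative")

    def with_noise(self, beta: float, gamma: float, tau: float) -> "SimulatorConfig":
        return replace(
            self, noise_sd_beta=beta, noise_sd_gamma=gamma, noise_sd_tau=tau
        )


@dataclass(frozen=True)
class Trajectory:
    """26 weekly (beta, gamma, tau) triples for one subject."""

    beta: np.ndarray
    gamma: np.ndarray
    tau: np.ndarray
    subject_id: int | None = None

    def __post_init__(self) -> None:
        for name in OUTPUT_COLUMNS:
            arr = getattr(self, name)
            if arr.shape != (T_WEEKS,):
                raise ValueError(f"{name} must have length {T_WEEKS}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    def output(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _gamma_target(
    beta: float, carb_mult: float, transient: float, config: SimulatorConfig
) -> float:
    return (
        config.gamma_base
        + config.gamma_beta_gain * (beta - 22.0)
        + config.gamma_carb_gain * (carb_mult - 1.0)
        + transient
    )


def _tau_drive(gamma: float, beta: float, config: SimulatorConfig) -> float:
    return (
        config.tau_base
        + config.tau_gamma_gain * (gamma - config.gamma_base)
        + config.tau_beta_gain * (beta - 22.0)
    )


def tau_response(
    gamma: np.ndarray,
    beta: np.ndarray,
    config: SimulatorConfig,
    gamma0: float | None = None,
    beta0: float | None = None,
) -> np.ndarray:
    """Noise-free inflammatory response to given glucose/BMI series.

    Implements the delayed first-order filter used inside
    :func:`simulate_subject`:

        tau[t] = (1 - a) tau[t-1] + a * drive(gamma[t - lag], beta[t - lag])

    with ``a = tau_smooth`` and pre-horizon values held at the initial
    state.  Exposed so the lag between a glucose excursion and the TNF
    response can be checked against the filter's closed form.
    """
    gamma = np.asarray(gamma, dtype=float)
    beta = np.asarray(beta, dtype=float)
    T = len(gamma)
    g0 = gamma[0] if gamma0 is None else gamma0
    b0 = beta[0] if beta0 is None else beta0
    # index by week: g_full[w] is the glucose value at week w (week 0 = initial)
    g_full = np.concatenate([[g0], gamma])
    b_full = np.concatenate([[b0], beta])
    tau = np.empty(T)
    prev = _tau_drive(g0, b0, config)
    a = config.tau_smooth
    for w in range(1, T + 1):
        j = max(w - config.tau_lag, 0)
        prev = (1.0 - a) * prev + a * _tau_drive(g_full[j], b_full[j], config)
        tau[w - 1] = prev
    return tau


def simulate_subject(
    x: VirtualSubject,
    config: SimulatorConfig | None = None,
    seed: int = 0,
    constants: energy.EnergyConstants = energy.DEFAULT_CONSTANTS,
) -> Trajectory:
    """Simulate one subject's 26-week trajectory; deterministic under seed."""
    config = config or SimulatorConfig()
    rng = np.random.default_rng(seed)

    h_m = energy.representative_height_cm(x, constants) / 100.0
    beta0 = constants.bmi_by_class[x.weight_class]
    budget = energy.subject_budget(x, constants)
    diet_kcal = energy.daily_diet_calories(budget, x.diet_levels, constants)
    surplus = diet_kcal - budget.tdee  # kcal/day; 0 at med/med/med
    # weekly BMI drift from the energy imbalance
    dbeta = config.beta_gain * 7.0 * surplus / config.kcal_per_kg / h_m**2
    carb_mult = energy.LEVEL_MULTIPLIERS[x.carb_level]

    beta = np.empty(T_WEEKS)
    gamma = np.empty(T_WEEKS)
    tau = np.empty(T_WEEKS)

    b_prev = beta0
    g_prev = _gamma_target(beta0, carb_mult, 0.0, config)
    t_prev = _tau_drive(g_prev, beta0, config)
    gamma_hist = [g_prev]  # gamma_hist[w] = glucose at week w (0 = initial)
    beta_hist = [b_prev]
    a = config.tau_smooth
    overshoot = config.gamma_overshoot * max(surplus, 0.0)
    p = config.gamma_overshoot_peak
    for w in range(1, T_WEEKS + 1):
        b = b_prev + dbeta + config.noise_sd_beta * rng.standard_normal()
        b = max(b, 10.0)
        transient = overshoot * (w / p) * np.exp(1.0 - w / p)
        g_star = _gamma_target(b, carb_mult, transient, config)
        g = g_prev + config.gamma_rate * (g_star - g_prev)
        g += config.noise_sd_gamma * rng.standard_normal()
        g = max(g, 0.5)
        gamma_hist.append(g)
        beta_hist.append(b)
        j = max(w - config.tau_lag, 0)
        drive = _tau_drive(gamma_hist[j], beta_hist[j], config)
        tv = (1.0 - a) * t_prev + a * drive
        # cytokine fluctuations scale with the inflammation level itself:
        # TNF volatility concentrates where the response peaks
        sd = config.noise_sd_tau * max(drive / config.tau_base, 0.2)
        tv += sd * rng.standard_normal()
        tv = max(tv, 0.05)
        beta[w - 1], gamma[w - 1], tau[w - 1] = b, g, tv
        b_prev, g_prev, t_prev = b, g, tv
    return Trajectory(beta=beta, gamma=gamma, tau=tau)


def generate_dataset(
    sample: DesignSample,
    config: SimulatorConfig | None = None,
    seed: int = 0,
    constants: energy.EnergyConstants = energy.DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Simulate every subject of a design into a long-format training table.

    One row per (subject, week): subject_id, the ten encoded features, the
    week index ``t`` in 1..26, and the three outputs.  Row count is
    ``26 * len(sample)``.  Per-subject noise streams derive from ``seed``,
    so the same seed reproduces the table exactly.
    """
    if len(sample) == 0:
        raise ValueError("design sample is empty")
    config = config or SimulatorConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(len(sample))
    weeks = np.arange(1, T_WEEKS + 1)
    blocks = []
    for s, sub_seed in zip(sample, child_seeds):
        traj = simulate_subject(s, config, seed=int(sub_seed), constants=constants)
        feats = encode_subject(s)
        block = pd.DataFrame(
            np.tile(feats, (T_WEEKS, 1)), columns=FEATURE_COLUMNS
        )
        block.insert(0, "subject_id", sample.grid.index_of(s))
        block["t"] = weeks
        block["beta"] = traj.beta
        block["gamma"] = traj.gamma
        block["tau"] = traj.tau
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)[TABLE_COLUMNS]
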