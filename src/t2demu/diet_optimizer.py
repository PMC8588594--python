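"""Emulator-driven constrained diet optimization against inflammation.

Given a virtual subject, the optimizer chooses the per-meal macronutrient
quantities (C, P, F, grams/meal) minimising the emulated cumulative squared
inflammation

    min  sum_t  tau_hat(x | C, P, F, t)^2
    s.t. l_C <= C <= u_C,   l_P <= P <= u_P,   l_F <= F <= u_F,
         l_T <= C + P + F <= u_T

where the box and total bounds come from the subject's energy budget (the
low/high multiples of the balanced med quantities).  The emulator's diet
inputs are the discrete low/med/high levels, so the default method simply
enumerates all 27 level combinations, keeps the feasible ones, and returns
the exact argmin; a derivative-free continuous search over gram values
(snapped to the nearest level combination) is available for user-supplied
gram-valued bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import energy
from .emulator import EmulatorResults
from .subjects import MACRO_LEVELS, VirtualSubject

__all__ = [
    "DietAssignment",
    "OptimizationResult",
    "InfeasibleDietError",
    "objective_value",
    "feasible",
    "optimize_diet",
]


class InfeasibleDietError(ValueError):
    """No candidate diet satisfies the constraints."""


@dataclass(frozen=True)
class DietAssignment:
    """Per-meal gram quantities together with the levels realizing them."""

    carb: float
    prot: float
    fat: float
    levels: tuple[str, str, str]

    @property
    def total(self) -> float:
        return self.carb + self.prot + self.fat


@dataclass(frozen=True)
class OptimizationResult:
    best: DietAssignment
    objective: float
    baseline_objective: float
    tau_hat: np.ndarray  # emulated 26-week inflammation under the best diet
    feasible_count: int
    method: str


def _assignment_for_levels(
    budget: energy.EnergyBudget,
    levels: tuple[str, str, str],
    constants: energy.EnergyConstants,
) -> DietAssignment:
    m = energy.meal_macros(budget, levels, constants)
    return DietAssignment(carb=m.carb, prot=m.prot, fat=m.fat, levels=levels)


def objective_value(
    results: EmulatorResults, x: VirtualSubject, diet: DietAssignment
) -> float:
    """Cumulative squared emulated inflammation under a candidate diet."""
    traj = results.predict_trajectory(x.with_diet(*diet.levels))
    return float(np.sum(traj.tau**2))


def feasible(diet: DietAssignment, bounds: energy.DietBounds) -> bool:
    """All four constraint pairs: three macronutrient boxes plus the total."""
    return (
        bounds.l_C <= diet.carb <= bounds.u_C
        and bounds.l_P <= diet.prot <= bounds.u_P
        and bounds.l_F <= diet.fat <= bounds.u_F
        and bounds.l_T <= diet.total <= bounds.u_T
    )


def _violations(diet: DietAssignment, bounds: energy.DietBounds) -> list[str]:
    v = []
    for name, val, lo, hi in (
        ("carb", diet.carb, bounds.l_C, bounds.u_C),
        ("prot", diet.prot, bounds.l_P, bounds.u_P),
        ("fat", diet.fat, bounds.l_F, bounds.u_F),
        ("total", diet.total, bounds.l_T, bounds.u_T),
    ):
        if not lo <= val <= hi:
            v.append(f"{name}={val:.1f}g outside [{lo:.1f}, {hi:.1f}]")
    return v


def _sort_key(obj: float, diet: DietAssignment) -> tuple:
    # ties broken by lowest total grams, then lexicographic level order
    return (obj, diet.total, tuple(MACRO_LEVELS.index(l) for l in diet.levels))


def optimize_diet(
    results: EmulatorResults,
    x: VirtualSubject,
    bounds: energy.DietBounds | None = None,
    method: str = "grid",
    seed: int = 0,
    constants: energy.EnergyConstants = energy.DEFAULT_CONSTANTS,
    n_continuous: int = 200,
) -> OptimizationResult:
    """Minimise emulated inflammation over the feasible diets.

    ``method="grid"`` (default) enumerates all 27 level combinations —
    exact on the emulator's discrete diet inputs.  ``method="continuous"``
    runs a seeded derivative-free search over gram triples in the bounds,
    snapping each candidate to its nearest level combination.
    """
    budget = energy.subject_budget(x, constants)
    if bounds is None:
        bounds = energy.diet_bounds(x, constants)

    baseline = _assignment_for_levels(budget, x.diet_levels, constants)
    baseline_obj = objective_value(results, x, baseline)

    candidates: list[tuple[str, str, str]]
    if method == "grid":
        candidates = [
            (c, p, f)
            for c in MACRO_LEVELS
            for p in MACRO_LEVELS
            for f in MACRO_LEVELS
        ]
    elif method == "continuous":
        rng = np.random.default_rng(seed)
        med = _assignment_for_levels(budget, ("med", "med", "med"), constants)
        seen = set()
        for _ in range(n_continuous):
            g = rng.uniform(
                [bounds.l_C, bounds.l_P, bounds.l_F],
                [bounds.u_C, bounds.u_P, bounds.u_F],
            )
            if not bounds.l_T <= g.sum() <= bounds.u_T:
                continue
            lv = tuple(
                min(
                    MACRO_LEVELS,
                    key=lambda l: abs(
                        energy.LEVEL_MULTIPLIERS[l] * m - gi
                    ),
                )
                for gi, m in zip(g, (med.carb, med.prot, med.fat))
            )
            seen.add(lv)
        candidates = sorted(seen) + [x.diet_levels]
    else:
        raise ValueError(f"unknown optimization method {method!r}")

    evaluated: list[tuple[tuple, DietAssignment, float]] = []
    for levels in candidates:
        diet = _assignment_for_levels(budget, levels, constants)
        if not feasible(diet, bounds):
            continue
        obj = objective_value(results, x, diet)
        evaluated.append((_sort_key(obj, diet), diet, obj))

    if not evaluated:
        raise InfeasibleDietError(
            "no candidate diet satisfies the constraints; e.g. med/med/med: "
            + "; ".join(
                _violations(
                    _assignment_for_levels(budget, ("med", "med", "med"), constants),
                    bounds,
                )
            )
        )

    key, best, obj = min(evaluated, key=lambda e: e[0])
    tau_hat = results.predict_trajectory(x.with_diet(*best.levels)).tau
    return OptimizationResult(
        best=best,
        objective=obj,
        baseline_objective=baseline_obj,
        tau_hat=tau_hat,
        feasible_count=len(evaluated),
        method=method,
    )
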