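"""Constrained diet optimization against emulated inflammation."""

import itertools

import numpy as np
import pytest

import t2demu as t
from t2demu import energy
from t2demu.diet_optimizer import (
    DietAssignment,
    InfeasibleDietError,
    feasible,
    objective_value,
    optimize_diet,
)
from t2demu.subjects import MACRO_LEVELS
from t2demu.surrogate import SimulatorConfig, generate_dataset


def brute_force_optimum(results, x, bounds, constants=energy.DEFAULT_CONSTANTS):
    """Independent exhaustive argmin over the 27 level combinations."""
    budget = energy.subject_budget(x, constants)
    best = None
    for levels in itertools.product(MACRO_LEVELS, repeat=3):
        m = energy.meal_macros(budget, levels, constants)
        diet = DietAssignment(m.carb, m.prot, m.fat, levels)
        if not (
            bounds.l_C <= diet.carb <= bounds.u_C
            and bounds.l_P <= diet.prot <= bounds.u_P
            and bounds.l_F <= diet.fat <= bounds.u_F
            and bounds.l_T <= diet.total <= bounds.u_T
        ):
            continue
        traj = results.predict_trajectory(x.with_diet(*levels))
        obj = float(np.sum(traj.tau**2))
        key = (obj, diet.total, tuple(MACRO_LEVELS.index(l) for l in levels))
        if best is None or key < best[0]:
            best = (key, diet, obj)
    return best


class TestObjective:
    def test_constant_tau_closed_form(self, grid):
        sample = t.lhs_sample(grid, 5, seed=0)
        tab = generate_dataset(sample, None, seed=0)
        tab["tau"] = 1.5
        res = t.fit_emulator(tab, n_trees=5, seed=1)
        s = sample.selected[0]
        diet = DietAssignment(10.0, 10.0, 10.0, s.diet_levels)
        assert objective_value(res, s, diet) == pytest.approx(26 * 1.5**2, abs=1e-9)

    def test_equals_hand_summed_loop(self, small_fit, grid):
        s = grid[77]
        diet = DietAssignment(10.0, 10.0, 10.0, ("low", "med", "high"))
        manual = sum(
            small_fit.predict_point(s.with_diet("low", "med", "high"), tt)[2] ** 2
            for tt in range(1, 27)
        )
        assert objective_value(small_fit, s, diet) == pytest.approx(manual, rel=1e-12)


class TestFeasibility:
    def test_med_diet_feasible(self, example_subject):
        b = energy.subject_budget(example_subject)
        m = energy.meal_macros(b, ("med", "med", "med"))
        diet = DietAssignment(m.carb, m.prot, m.fat, ("med", "med", "med"))
        assert feasible(diet, energy.diet_bounds(example_subject))

    def test_box_violation_detected(self, example_subject):
        bd = energy.diet_bounds(example_subject)
        diet = DietAssignment(bd.u_C + 1.0, bd.l_P, bd.l_F, ("high", "low", "low"))
        assert not feasible(diet, bd)

    def test_total_violation_with_tight_cap(self, example_subject):
        bd = energy.diet_bounds(example_subject)
        b = energy.subject_budget(example_subject)
        m = energy.meal_macros(b, ("high", "high", "high"))
        diet = DietAssignment(m.carb, m.prot, m.fat, ("high", "high", "high"))
        tight = energy.DietBounds(
            bd.l_C, bd.u_C, bd.l_P, bd.u_P, bd.l_F, bd.u_F, bd.l_T, diet.total - 1.0
        )
        assert not feasible(diet, tight)  # boxes pass, total fails


class TestOptimizeDiet:
    def test_matches_brute_force_on_random_models(self, grid):
        """Mandatory oracle: exact argmin agreement over random fitted
        models and subjects."""
        rng = np.random.default_rng(2024)
        for trial in range(8):
            sample = t.lhs_sample(grid, 4, seed=300 + trial)
            tab = generate_dataset(sample, SimulatorConfig(), seed=400 + trial)
            # random response perturbation gives each trial a distinct model
            tab["tau"] = tab["tau"] * rng.uniform(0.5, 2.0) + rng.normal(
                0, 0.3, len(tab)
            )
            tab["tau"] = tab["tau"].clip(lower=0.05)
            res = t.fit_emulator(tab, n_trees=10, seed=500 + trial)
            x = sample.selected[int(rng.integers(len(sample)))]
            bounds = energy.diet_bounds(x)
            opt = optimize_diet(res, x, bounds)
            key, diet, obj = brute_force_optimum(res, x, bounds)
            assert opt.best.levels == diet.levels
            assert opt.objective == pytest.approx(obj, rel=1e-12)
            assert feasible(opt.best, bounds)
            assert opt.objective <= opt.baseline_objective + 1e-12

    def test_singleton_feasible_set_returns_baseline(self, small_fit, example_subject):
        b = energy.subject_budget(example_subject)
        base = energy.meal_macros(b, example_subject.diet_levels)
        eps = 1e-9
        bounds = energy.DietBounds(
            base.carb - eps, base.carb + eps,
            base.prot - eps, base.prot + eps,
            base.fat - eps, base.fat + eps,
            base.total - eps, base.total + eps,
        )
        opt = optimize_diet(small_fit, example_subject, bounds)
        assert opt.best.levels == example_subject.diet_levels
        assert opt.feasible_count == 1
        assert opt.objective == pytest.approx(opt.baseline_objective, rel=1e-12)

    def test_infeasible_problem_raises_with_constraint_names(self, small_fit, example_subject):
        bounds = energy.DietBounds(0, 1e-6, 0, 1e-6, 0, 1e-6, 0, 1e-6)
        with pytest.raises(InfeasibleDietError, match="carb"):
            optimize_diet(small_fit, example_subject, bounds)

    def test_calorie_monotone_emulator_selects_minimal_calorie_diet(self, grid):
        """If emulated inflammation increases with total calories, the
        optimizer must pick the lowest-calorie feasible diet (low/low/low)."""
        sample = t.lhs_sample(grid, 6, seed=61)
        tab = generate_dataset(sample, SimulatorConfig(), seed=62)
        # make tau an explicit increasing function of the diet level codes
        tab["tau"] = 1.0 + 0.5 * (
            tab["carb_level"] + tab["prot_level"] + tab["fat_level"]
        )
        res = t.fit_emulator(tab, n_trees=20, seed=63)
        x = sample.selected[0]
        opt = optimize_diet(res, x, energy.diet_bounds(x))
        assert opt.best.levels == ("low", "low", "low")

    def test_continuous_mode_feasible_and_no_worse_than_baseline(
        self, small_fit, example_subject
    ):
        bounds = energy.diet_bounds(example_subject)
        opt = optimize_diet(
            small_fit, example_subject, bounds, method="continuous", seed=5
        )
        assert feasible(opt.best, bounds)
        assert opt.objective <= opt.baseline_objective + 1e-12
        assert opt.method == "continuous"
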