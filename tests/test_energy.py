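"""Energy budget, meal macronutrients and diet bounds."""

import dataclasses
import itertools

import numpy as np
import pytest

from t2demu import energy
from t2demu.subjects import MACRO_LEVELS, VirtualSubject


def subject(**overrides) -> VirtualSubject:
    base = dict(
        sex="male",
        age=48,
        weight_class="normal",
        height_class="average",
        pa_sessions=2,
        pa_duration=60,
        pa_intensity=40,
        carb_level="med",
        prot_level="med",
        fat_level="med",
    )
    base.update(overrides)
    return VirtualSubject(**base)


class TestREE:
    def test_decreases_with_age(self):
        assert energy.compute_ree(subject(age=28)) > energy.compute_ree(subject(age=68))

    def test_increases_with_weight_class(self):
        assert energy.compute_ree(subject(weight_class="overweight")) > energy.compute_ree(
            subject(weight_class="normal")
        ) > energy.compute_ree(subject(weight_class="underweight"))

    def test_matches_published_equation_directly(self):
        # oracle: evaluate Mifflin-St Jeor by hand for the representative
        # 175 cm, BMI-22 male aged 48: 10*67.375 + 6.25*175 - 5*48 + 5
        w = 22.0 * 1.75**2
        assert energy.compute_ree(subject()) == pytest.approx(
            10 * w + 6.25 * 175 - 5 * 48 + 5, abs=1e-12
        )

    def test_sex_offset_is_constant(self):
        # same classes resolve to different representative sizes per sex, so
        # compare at pinned heights/weights via the constants table
        consts = dataclasses.replace(
            energy.DEFAULT_CONSTANTS,
            heights_cm={
                "female": {"short": 170.0, "average": 170.0, "tall": 170.0},
                "male": {"short": 170.0, "average": 170.0, "tall": 170.0},
            },
        )
        m = energy.compute_ree(subject(sex="male"), consts)
        f = energy.compute_ree(subject(sex="female"), consts)
        assert m - f == pytest.approx(166.0, abs=1e-12)


class TestAEE:
    def test_zero_without_exercise(self):
        s = subject(pa_sessions=0, pa_duration=0, pa_intensity=0)
        assert energy.compute_aee(s) == 0.0

    def test_linear_in_sessions(self):
        one = energy.compute_aee(subject(pa_sessions=1))
        two = energy.compute_aee(subject(pa_sessions=2))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_met_formula_hand_value(self):
        # 1 session, 30 min, 60% VO2max -> 6 MET * weight * 0.5 h / 7 days
        s = subject(pa_sessions=1, pa_duration=30, pa_intensity=60)
        w = energy.representative_weight_kg(s)
        assert energy.compute_aee(s) == pytest.approx(6.0 * w * 0.5 / 7.0, rel=1e-12)


class TestTDEE:
    def test_fixed_point_closed_form(self):
        b = energy.compute_tdee(1500.0, 300.0)
        assert b.balanced_intake == pytest.approx(2000.0, abs=1e-9)
        assert b.tef == pytest.approx(200.0, abs=1e-9)
        assert b.tdee == pytest.approx(b.ree + b.aee + b.tef, abs=1e-9)

    def test_intake_equals_tdee_energy_balance(self):
        b = energy.compute_tdee(1700.0, 0.0)
        assert b.tdee == pytest.approx(b.balanced_intake, abs=1e-9)

    def test_tef_is_ten_percent_of_intake(self):
        for ree, aee in [(1200.0, 0.0), (1600.0, 250.0), (2000.0, 700.0)]:
            b = energy.compute_tdee(ree, aee)
            assert b.tef / b.balanced_intake == pytest.approx(0.10, abs=1e-12)

    def test_budget_closure_over_grid_subsample(self, grid):
        for s in grid.subjects[::907]:
            b = energy.subject_budget(s)
            assert b.tdee == pytest.approx(b.ree + b.aee + b.tef, abs=1e-9)
            assert b.tef == pytest.approx(0.10 * b.balanced_intake, abs=1e-9)


class TestMealMacros:
    def test_shares_and_densities_hand_computed(self):
        # balanced intake 1800 -> meal 600 kcal -> 300/120/180 kcal from
        # carbs/proteins/fats -> 75/30/20 grams at 4/4/9 kcal per gram
        b = energy.EnergyBudget(ree=1620.0, aee=0.0, tef=180.0, tdee=1800.0, balanced_intake=1800.0)
        m = energy.meal_macros(b, ("med", "med", "med"))
        assert m.carb == pytest.approx(75.0, abs=1e-12)
        assert m.prot == pytest.approx(30.0, abs=1e-12)
        assert m.fat == pytest.approx(20.0, abs=1e-12)

    @pytest.mark.parametrize("level,mult", [("high", 1.5), ("low", 0.8)])
    def test_level_multipliers_exact(self, level, mult):
        b = energy.subject_budget(subject())
        med = energy.meal_macros(b, ("med", "med", "med"))
        other = energy.meal_macros(b, (level, level, level))
        for a in ("carb", "prot", "fat"):
            assert getattr(other, a) / getattr(med, a) == pytest.approx(mult, abs=1e-12)

    def test_unknown_level_rejected(self):
        b = energy.subject_budget(subject())
        with pytest.raises(ValueError):
            energy.meal_macros(b, ("med", "med", "huge"))


class TestDietBounds:
    def test_bound_ratio_is_multiplier_quotient(self):
        bd = energy.diet_bounds(subject())
        for l, u in [(bd.l_C, bd.u_C), (bd.l_P, bd.u_P), (bd.l_F, bd.u_F), (bd.l_T, bd.u_T)]:
            assert u / l == pytest.approx(1.5 / 0.8, rel=1e-12)

    def test_med_diet_always_feasible(self, grid):
        from t2demu.diet_optimizer import feasible, DietAssignment

        for s in grid.subjects[::1111]:
            b = energy.subject_budget(s)
            m = energy.meal_macros(b, ("med", "med", "med"))
            diet = DietAssignment(m.carb, m.prot, m.fat, ("med", "med", "med"))
            assert feasible(diet, energy.diet_bounds(s))

    def test_box_feasibility_of_all_27_combos_and_total_filter(self):
        from t2demu.diet_optimizer import feasible, DietAssignment

        s = subject()
        b = energy.subject_budget(s)
        bd = energy.diet_bounds(s)
        for levels in itertools.product(MACRO_LEVELS, repeat=3):
            m = energy.meal_macros(b, levels)
            diet = DietAssignment(m.carb, m.prot, m.fat, levels)
            # box constraints hold for every combo by construction
            assert bd.l_C <= diet.carb <= bd.u_C
            assert bd.l_P <= diet.prot <= bd.u_P
            assert bd.l_F <= diet.fat <= bd.u_F
            # feasibility then reduces to the total bound, checked by hand
            assert feasible(diet, bd) == (bd.l_T <= diet.total <= bd.u_T)
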