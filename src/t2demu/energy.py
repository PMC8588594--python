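"""Per-subject energy budget and per-meal macronutrient quantities.

The daily calorie budget is the total daily energy expenditure

    TDEE = REE + AEE + TEF

where REE is the resting energy expenditure (from sex, age, and the
representative weight and height of the subject's classes), AEE the activity
energy expenditure (from the weekly exercise pattern, averaged to a daily
value), and TEF the thermic effect of food, 10% of the calories ingested.
Energy balance means intake = TDEE, so the balanced intake solves the fixed
point ``intake = REE + AEE + 0.10 * intake``, i.e. ``intake = (REE+AEE)/0.9``.

The balanced intake is split into three equal meals; each meal's calories
are split 50/20/30% into carbohydrates, proteins and fats and converted to
grams with the Atwater densities 4/4/9 kcal/g — these gram amounts are the
``med`` diet levels.  ``low`` and ``high`` are fixed multiples 0.8 and 1.5
of ``med``, and the same multipliers bound the optimizer's feasible set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .subjects import VirtualSubject, MACRO_LEVELS

__all__ = [
    "EnergyConstants",
    "EnergyBudget",
    "MealMacros",
    "DietBounds",
    "representative_height_cm",
    "representative_weight_kg",
    "compute_ree",
    "compute_aee",
    "compute_tdee",
    "meal_macros",
    "diet_bounds",
    "daily_diet_calories",
    "LEVEL_MULTIPLIERS",
]

#: gram multipliers realizing the low/med/high levels
LEVEL_MULTIPLIERS = {"low": 0.8, "med": 1.0, "high": 1.5}


@dataclass(frozen=True)
class EnergyConstants:
    """All tunable constants of the energy model (kcal, grams, cm, kg)."""

    #: meal calorie shares for carbohydrates / proteins / fats
    carb_share: float = 0.50
    prot_share: float = 0.20
    fat_share: float = 0.30
    #: thermic effect of food as a fraction of calories ingested
    tef_rate: float = 0.10
    #: Atwater energy densities, kcal per gram
    carb_kcal_per_g: float = 4.0
    prot_kcal_per_g: float = 4.0
    fat_kcal_per_g: float = 9.0
    #: low/high gram multipliers relative to med
    low_multiplier: float = 0.8
    high_multiplier: float = 1.5
    #: meals per day (breakfast, lunch, dinner)
    meals_per_day: int = 3
    #: representative heights (cm) per sex and height class
    heights_cm: dict = field(
        default_factory=lambda: {
            "female": {"short": 155.0, "average": 165.0, "tall": 175.0},
            "male": {"short": 165.0, "average": 175.0, "tall": 185.0},
        }
    )
    #: representative BMI (kg/m^2) per weight class; weight = BMI * height^2
    bmi_by_class: dict = field(
        default_factory=lambda: {"underweight": 18.0, "normal": 22.0, "overweight": 27.5}
    )
    #: total-grams bound multipliers (on the sum of med grams)
    total_low_multiplier: float = 0.8
    total_high_multiplier: float = 1.5


DEFAULT_CONSTANTS = EnergyConstants()


@dataclass(frozen=True)
class EnergyBudget:
    """Daily energy budget of a subject, in kcal/day."""

    ree: float
    aee: float
    tef: float
    tdee: float
    balanced_intake: float


@dataclass(frozen=True)
class MealMacros:
    """Per-meal macronutrient quantities (grams) realizing given levels."""

    carb: float
    prot: float
    fat: float
    level_labels: tuple[str, str, str]

    @property
    def total(self) -> float:
        return self.carb + self.prot + self.fat


@dataclass(frozen=True)
class DietBounds:
    """Feasible set of the diet optimization, grams per meal."""

    l_C: float
    u_C: float
    l_P: float
    u_P: float
    l_F: float
    u_F: float
    l_T: float
    u_T: float


def representative_height_cm(
    subject: VirtualSubject, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> float:
    return constants.heights_cm[subject.sex][subject.height_class]


def representative_weight_kg(
    subject: VirtualSubject, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> float:
    h_m = representative_height_cm(subject, constants) / 100.0
    return constants.bmi_by_class[subject.weight_class] * h_m**2


def compute_ree(
    subject: VirtualSubject, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> float:
    """Resting energy expenditure, kcal/day (Mifflin–St Jeor equation).

    REE = 10 W + 6.25 H - 5 A + 5 for males and - 161 for females, with W
    the representative weight (kg) and H the representative height (cm) of
    the subject's classes.  Increasing in weight and height, decreasing in
    age, with a fixed 166 kcal/day sex offset.
    """
    w = representative_weight_kg(subject, constants)
    h = representative_height_cm(subject, constants)
    offset = 5.0 if subject.sex == "male" else -161.0
    return 10.0 * w + 6.25 * h - 5.0 * subject.age + offset


def compute_aee(
    subject: VirtualSubject, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> float:
    """Activity energy expenditure averaged to kcal/day.

    MET-style formula: the exercise intensity in %VO2max maps to a MET value
    (MET = %VO2max / 10, so 40% -> 4 MET, 60% -> 6 MET) and one session
    spends ``MET * weight_kg * hours`` kcal; the weekly total is averaged
    over 7 days.  Zero when the subject does no exercise; linear in sessions
    and duration.
    """
    if subject.pa_sessions == 0:
        return 0.0
    met = subject.pa_intensity / 10.0
    hours = subject.pa_duration / 60.0
    weekly = subject.pa_sessions * met * representative_weight_kg(subject, constants) * hours
    return weekly / 7.0


def compute_tdee(
    ree: float, aee: float, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> EnergyBudget:
    """Close the budget: intake solving intake = REE + AEE + tef_rate*intake."""
    if ree <= 0:
        raise ValueError("ree must be positive")
    if aee < 0:
        raise ValueError("aee must be non-negative")
    intake = (ree + aee) / (1.0 - constants.tef_rate)
    tef = constants.tef_rate * intake
    return EnergyBudget(ree=ree, aee=aee, tef=tef, tdee=ree + aee + tef, balanced_intake=intake)


def subject_budget(
    subject: VirtualSubject, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> EnergyBudget:
    """Convenience: REE + AEE + TEF closure for one subject."""
    return compute_tdee(
        compute_ree(subject, constants), compute_aee(subject, constants), constants
    )


def _med_grams(budget: EnergyBudget, constants: EnergyConstants) -> tuple[float, float, float]:
    meal_kcal = budget.balanced_intake / constants.meals_per_day
    return (
        constants.carb_share * meal_kcal / constants.carb_kcal_per_g,
        constants.prot_share * meal_kcal / constants.prot_kcal_per_g,
        constants.fat_share * meal_kcal / constants.fat_kcal_per_g,
    )


def _multiplier(level: str, constants: EnergyConstants) -> float:
    if level not in MACRO_LEVELS:
        raise ValueError(f"unknown macronutrient level {level!r}")
    return {
        "low": constants.low_multiplier,
        "med": 1.0,
        "high": constants.high_multiplier,
    }[level]


def meal_macros(
    budget: EnergyBudget,
    levels: tuple[str, str, str],
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> MealMacros:
    """Grams of carbohydrate / protein / fat per meal at the given levels."""
    med_c, med_p, med_f = _med_grams(budget, constants)
    c_lvl, p_lvl, f_lvl = levels
    return MealMacros(
        carb=_multiplier(c_lvl, constants) * med_c,
        prot=_multiplier(p_lvl, constants) * med_p,
        fat=_multiplier(f_lvl, constants) * med_f,
        level_labels=(c_lvl, p_lvl, f_lvl),
    )


def diet_bounds(
    subject: VirtualSubject, constants: EnergyConstants = DEFAULT_CONSTANTS
) -> DietBounds:
    """Optimization bounds: per-macronutrient low/high grams plus total bounds."""
    budget = subject_budget(subject, constants)
    med_c, med_p, med_f = _med_grams(budget, constants)
    lo, hi = constants.low_multiplier, constants.high_multiplier
    tlo, thi = constants.total_low_multiplier, constants.total_high_multiplier
    return DietBounds(
        l_C=lo * med_c,
        u_C=hi * med_c,
        l_P=lo * med_p,
        u_P=hi * med_p,
        l_F=lo * med_f,
        u_F=hi * med_f,
        # summed per-macronutrient so the all-low / all-high diets sit exactly
        # on the default total bounds (no rounding slack)
        l_T=tlo * med_c + tlo * med_p + tlo * med_f,
        u_T=thi * med_c + thi * med_p + thi * med_f,
    )


def daily_diet_calories(
    budget: EnergyBudget,
    levels: tuple[str, str, str],
    constants: EnergyConstants = DEFAULT_CONSTANTS,
) -> float:
    """kcal/day actually ingested under the given diet levels.

    At med/med/med this equals the balanced intake (= TDEE); low or high
    levels scale each macronutrient's calorie share by its multiplier.
    """
    macros = meal_macros(budget, levels, constants)
    per_meal = (
        macros.carb * constants.carb_kcal_per_g
        + macros.prot * constants.prot_kcal_per_g
        + macros.fat * constants.fat_kcal_per_g
    )
    return constants.meals_per_day * per_meal
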