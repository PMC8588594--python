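# Methods

This note records the modelling choices behind `t2demu`, the package's own
rationale for each, and what its synthetic experiments do and do not show.

## 1. The input space

A virtual subject is a point on a discrete factorial grid of ten factors:
sex {female, male}; age {28, 38, 48, 58, 68} years; weight class
{underweight, normal, overweight}; height class {short, average, tall};
exercise sessions/week {0, 1, 2, 3}; session duration {30, 60, 90} min;
intensity {40, 60} %VO2max; and per-meal carbohydrate/protein/fat levels
{low, med, high}. When sessions = 0 the duration and intensity are
undefined; the grid collapses that branch to a single sentinel (0, 0)
combination, making the physical-activity block a 19-level composite factor
(1 + 3·3·2) and the full grid 2·5·3·3 · 19 · 27 = 46170 subjects. Without
the collapse the grid would double-count physically identical no-exercise
subjects.

Encoding is ordinal, not one-hot: quantitative factors keep their numeric
values (age, sessions, minutes, %VO2max), ordered categories get codes
0/1/2, sex is 0/1. Tree ensembles split ordinal features natively, and
every ordered factor's levels are genuinely ordered, so this is both the
most compact and the most tree-friendly representation. The mapping is
bijective on the grid.

**Designs.** The literature's Latin-hypercube sampling presumes continuous
factors; on a finite categorical grid the space-filling intent is realized
as per-factor stratification: each factor's levels appear with frequencies
within one unit of proportional (floor counts plus a seeded random
remainder assignment), columns are matched by independent seeded
permutations, and duplicate rows are repaired by swapping single factor
values between rows — an operation that leaves every marginal count intact.
Sampling the whole grid returns the grid itself. Train/test splits are at
the subject level (all 26 weeks of a subject on one side) because the
evaluation must measure generalization to *new subjects*, not to new weeks
of already-seen subjects.

## 2. The energy budget

The optimizer's constraint scale and the surrogate's drift both derive from
the subject's total daily energy expenditure,

TDEE = REE + AEE + TEF.

* **REE** uses the Mifflin–St Jeor equation (10·W + 6.25·H − 5·A + 5 for
  males, −161 for females; W kg, H cm, A years): a standard, documented
  linear form with the monotonicities any REE equation must have
  (increasing in size, decreasing in age, fixed sex offset). The pipeline
  is insensitive to the specific published equation chosen.
* Weight/height **classes** resolve to representative numbers via a
  per-sex lookup: heights 155/165/175 cm (women) and 165/175/185 cm (men);
  weight = BMI_rep · height², with BMI_rep = 18 / 22 / 27.5 kg/m² for
  underweight / normal / overweight. These sit near the centers of the
  conventional BMI bands.
* **AEE** is MET-based: MET = %VO2max / 10 (40% → 4 MET, 60% → 6 MET), one
  session spends MET · weight · hours kcal, and the weekly total is
  averaged over 7 days. Zero sessions give exactly zero; the formula is
  linear in sessions and duration by construction.
* **TEF** is 10% *of intake*, so energy balance is the fixed point
  intake = (REE + AEE)/0.9, not "10% of the expenditure without TEF".
  At balance, intake = TDEE exactly.

The balanced intake splits into three equal meals (equal thirds assumed);
each meal's calories split 50/20/30% into carbohydrates/proteins/fats and
convert to grams with the Atwater densities 4/4/9 kcal/g — these are the
`med` levels. `low` and `high` are 0.8× and 1.5× `med`. The optimizer's
box bounds are exactly those low/high grams; the total-grams bounds default
to the same multipliers applied to the med total (summed per macronutrient
so the all-low and all-high diets sit exactly on the bounds, with no
floating-point slack). The total bounds are not dictated by theory; they
keep the total constraint active but never infeasible, and are overridable
in the config.

## 3. The synthetic surrogate

The real simulator is a multi-scale agent-based/ODE hybrid; re-implementing
it is out of scope and unnecessary for studying the emulation methodology.
The surrogate is the smallest stochastic system with the qualitative
structure the emulator must face, at weekly resolution (T = 26):

* **β (BMI)**: β_{t} = β_{t−1} + 7·Δ/(7700·h²) + σ_β ε, where Δ is the
  daily calorie surplus of the diet over TDEE and 7700 kcal ≈ 1 kg of body
  mass. Balanced diets leave β exactly constant at zero noise; the sign of
  the 26-week change equals the sign of Δ.
* **γ (glucose)**: first-order relaxation (rate 0.7/week — a one-to-two
  week response) toward a target linear in current BMI and the
  carbohydrate multiplier, plus a transient overshoot at the onset of a
  hypercaloric diet (peak near week 2), plus σ_γ ε.
* **τ (TNF-α)**: a *delayed* (`tau_lag` = 3 weeks) and *smoothed*
  (first-order filter, weight 0.6) response to past glucose and BMI — the
  immune system's inertia — with the largest noise. The noise is
  state-dependent: its standard deviation is `noise_sd_tau` times the
  current inflammatory drive relative to baseline (floored at 0.2×).
  Cytokine levels fluctuate in proportion to the response itself —
  volatility concentrates at the peaks — which is also what makes
  inflammation the hardest output to band: a pooled residual band is
  narrower than the local spread exactly where τ peaks.

Default noise scales are σ_β = 0.05 kg/m², σ_γ = 0.10, `noise_sd_tau` =
0.30 per week: a fraction of a percent of the BMI range week-to-week,
glucose noise of a couple of percent of its range, and TNF weekly
variability several times larger than either — the stated variability
ordering is enforced at construction. All noise is Gaussian with per-subject
streams derived from one seed; outputs are floored at small positive values.

What the surrogate does **not** emulate: 10-second internal dynamics,
immune-cell populations, hormone/fuel ODEs, weight-change feedback onto
REE within the horizon, or any protein-specific anti-inflammatory pathway
(all three macronutrients act only through calories, so the optimizer's
minimum is the lowest-calorie feasible diet rather than a protein-rich
one). Passing tests therefore demonstrate that the emulation machinery —
design, fitting, banding, evaluation, optimization — works as specified on
a generator with the right structure; they say nothing about predictive
accuracy on the real simulator's trajectories.

## 4. The emulator

Three independent random forests (one per output), each taking the ten
encoded features plus the week index. Independent forests are the simplest
faithful reading of a per-output tree-average; the residual cross-output
covariance is recorded on the results object (it is reported, not used).
M = 50 trees; leaves of at least 5 observations (the regression default of
the reference R implementation of random forests) and all features
considered at each split — conventional regression-forest defaults, all
exposed as arguments. Bagging is on, so a per-output out-of-bag MSE is
available. Predictions outside weeks 1–26 are flagged with a warning but
returned (trees extrapolate by nearest partition).

## 5. Uncertainty: bootstrapping residuals

Residuals e(x_i, t) = y − ŷ are pooled *within each output* (the standard
fixed-design residual bootstrap; stratifying 50 replicates by week would
leave 50 draws per stratum of a 26-fold smaller pool) and resampled with
replacement into B = 50 pseudo-response sets y*_b = ŷ + e*_b. The band is
the pointwise q_α / q_{1−α} (α = 0.05, inclusive linear-interpolation
quantiles) of the B bootstrap trajectories.

Two variants are implemented. The default takes the quantiles of the
perturbed predictions y*_b themselves; `refit=True` instead refits the full
emulator on each pseudo-response set and takes quantiles of the refit
predictions. The default was chosen on calibration grounds: the refit band
measures only how much the fitted forest moves under residual resampling,
which is a fraction of the residual spread — measured held-in coverage at
the study conditions is ≈ 0.39 against a nominal 0.90, versus ≈ 0.87 for
the default. The default band is calibrated against the training residual
distribution by construction; its ≈ 0.87 (slightly under 0.90) reflects
the inward bias of interpolated quantiles at B = 50.

Coverage probability is the fraction of the 26 weeks at which a reference
trajectory lies inside the band, averaged over subjects. Calibration is
measured on *held-in* (training) subjects, the regime where the residual
bootstrap has its nominal level; held-out coverage is lower (the band does
not include the test subject's fresh noise and model error) and is what the
sample-size study's `coverage_on="test"` switch exposes. The study's
default coverage metric averages over **all** training subjects of each
rung so that between-size comparisons are not swamped by the ±0.02–0.03
Monte-Carlo noise of a 100-subject average.

A structural note, established while validating the band machinery: with
per-output pooling, the band quantiles are quantiles of the same empirical
mixture the held-in deviations are drawn from, so each output's
subject-averaged held-in coverage is pool-calibrated *independently of that
output's noise scale* — inflating one output's noise inflates its band by
the same factor. A γ-vs-τ coverage gap therefore cannot be produced by a
noise-scale knob; in real emulation problems it arises when the emulator
misses structure (e.g. sharp peaks) relative to its residual pool.

## 6. Evaluation

Outputs are min–max scaled to [0, 1] using the *training* table only
(avoiding leakage); test values outside the training range scale outside
[0, 1] and are logged, never clipped (clipping would bias E downward). The
per-week RMSE E_h(t) is computed over test subjects; it equals the per-week
root mean square of the residual set, which the tests cross-check. The
edge-vs-mid-horizon ratio E(1), E(26) versus the interior mean is reported
as a diagnostic but not asserted — whether boundaries are harder depends on
the generator.

The sample-size study runs the whole pipeline at design sizes
500/1000/1500/2000 — one tenth of the full-scale 5000–20000 design, the
same ladder shape at desk scale; each rung is an independent seeded design,
simulation, fit and evaluation. The full-scale sizes remain available
through the configuration.

## 7. Diet optimization

The emulator's diet inputs are the discrete low/med/high levels, so the
default optimizer enumerates all 27 level combinations, keeps those whose
gram realizations satisfy all four constraint pairs, and returns the exact
argmin of Σ_t τ̂(t)²; ties break by lowest total grams, then lexicographic
levels (determinism). A seeded derivative-free continuous mode samples gram
triples inside the bounds and snaps them to the nearest level combination,
for user-supplied gram-valued bounds. Infeasible problems raise an error
naming the violated constraints. Because the surrogate's inflammation is
calorie-driven, the optimum under default bounds is the all-low diet; the
baseline-versus-optimized comparison (objective ratio ≈ 0.65 for the
showcase overweight subject) is the meaningful output, not the specific
levels.

## 8. Reproducibility and problem sizes

Every stochastic stage (design, split, simulation, fitting, bootstrap)
takes a seed derived deterministically from one master seed; identical
configs reproduce identical CSV artifacts byte for byte. The shipped
experiment sizes — 500-subject designs for calibration, the 500–2000
ladder, 50-tree forests, B = 50 — keep the full test suite under a minute
on one CPU while leaving every estimate's Monte-Carlo error well inside
the tolerances asserted; they are the package's desk-scale defaults, with
the full-scale design available via configuration.

## 9. Known limitations

* The surrogate is a caricature: conclusions about emulator accuracy on
  the real simulator require the real trajectory library.
* The residual bootstrap pools per output; heteroscedasticity across the
  design (which the surrogate's TNF noise deliberately has) makes bands
  locally mis-sized even when globally calibrated.
* Coverage at B = 50 sits ≈ 0.03 below nominal due to quantile
  interpolation; larger B narrows the gap but was fixed at 50 as the study
  default.
* The optimizer treats the emulator as truth; emulation error is not
  propagated into the optimization (no band on the objective).
* Physical-activity variables are not optimized, only diet.
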