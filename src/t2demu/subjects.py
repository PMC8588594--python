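"""Virtual-subject input space: factorial grid, encoding, designs, splits.

A virtual subject is a point in a discrete factorial space of ten factors:
four anthropometric (sex, age, weight class, height class), three describing
weekly physical activity (sessions per week, minutes per session, intensity
as a percentage of VO2max), and three per-meal macronutrient levels
(carbohydrates, proteins, fats, each low/med/high).  When the subject does
no exercise (0 sessions/week) the duration and intensity are undefined; the
grid collapses that branch to a single sentinel combination so the
physical-activity block contributes ``1 + sessions>0 combinations`` cells.
With the default levels this yields 90 x 19 x 27 = 46170 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VirtualSubject",
    "GridSpec",
    "SubjectGrid",
    "DesignSample",
    "enumerate_grid",
    "encode_subject",
    "decode_subject",
    "lhs_sample",
    "split_train_test",
    "sample_to_frame",
    "FEATURE_COLUMNS",
    "PA_SENTINEL",
]

SEXES = ("female", "male")
WEIGHT_CLASSES = ("underweight", "normal", "overweight")
HEIGHT_CLASSES = ("short", "average", "tall")
MACRO_LEVELS = ("low", "med", "high")

#: sentinel (duration, intensity) used when pa_sessions == 0
PA_SENTINEL = (0, 0)

#: column order of the encoded feature vector (matches field order below)
FEATURE_COLUMNS = [
    "sex",
    "age",
    "weight_class",
    "height_class",
    "pa_sessions",
    "pa_duration",
    "pa_intensity",
    "carb_level",
    "prot_level",
    "fat_level",
]


@dataclass(frozen=True, order=True)
class VirtualSubject:
    """One point of the input grid: who is simulated / emulated."""

    sex: str
    age: int
    weight_class: str
    height_class: str
    pa_sessions: int
    pa_duration: int
    pa_intensity: int
    carb_level: str
    prot_level: str
    fat_level: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.weight_class not in WEIGHT_CLASSES:
            raise ValueError(f"unknown weight_class {self.weight_class!r}")
        if self.height_class not in HEIGHT_CLASSES:
            raise ValueError(f"unknown height_class {self.height_class!r}")
        for lvl in (self.carb_level, self.prot_level, self.fat_level):
            if lvl not in MACRO_LEVELS:
                raise ValueError(f"unknown macronutrient level {lvl!r}")
        if self.pa_sessions == 0 and (self.pa_duration, self.pa_intensity) != PA_SENTINEL:
            raise ValueError(
                "pa_duration/pa_intensity must be the sentinel "
                f"{PA_SENTINEL} when pa_sessions is 0"
            )

    @property
    def diet_levels(self) -> tuple[str, str, str]:
        return (self.carb_level, self.prot_level, self.fat_level)

    def with_diet(self, carb: str, prot: str, fat: str) -> "VirtualSubject":
        """Same subject with the per-meal macronutrient levels replaced."""
        return replace(self, carb_level=carb, prot_level=prot, fat_level=fat)


@dataclass(frozen=True)
class GridSpec:
    """Levels of each factor; defaults give the 46170-point grid."""

    sexes: tuple[str, ...] = SEXES
    ages: tuple[int, ...] = (28, 38, 48, 58, 68)
    weight_classes: tuple[str, ...] = WEIGHT_CLASSES
    height_classes: tuple[str, ...] = HEIGHT_CLASSES
    pa_sessions: tuple[int, ...] = (0, 1, 2, 3)
    pa_durations: tuple[int, ...] = (30, 60, 90)
    pa_intensities: tuple[int, ...] = (40, 60)
    macro_levels: tuple[str, ...] = MACRO_LEVELS

    def __post_init__(self) -> None:
        for name in (
            "sexes",
            "ages",
            "weight_classes",
            "height_classes",
            "pa_sessions",
            "pa_durations",
            "pa_intensities",
            "macro_levels",
        ):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid specification has no levels for {name}")

    def pa_combinations(self) -> list[tuple[int, int, int]]:
        """(sessions, duration, intensity) triples; the 0-session branch
        collapses to a single sentinel combination."""
        combos: list[tuple[int, int, int]] = []
        for n in self.pa_sessions:
            if n == 0:
                combos.append((0, *PA_SENTINEL))
            else:
                for d in self.pa_durations:
                    for i in self.pa_intensities:
                        combos.append((n, d, i))
        return combos


@dataclass(frozen=True)
class SubjectGrid:
    """The full factorial grid, lexicographically ordered, with provenance."""

    subjects: tuple[VirtualSubject, ...]
    spec: GridSpec = field(default_factory=GridSpec)

    def __len__(self) -> int:
        return len(self.subjects)

    def __getitem__(self, i: int) -> VirtualSubject:
        return self.subjects[i]

    def __iter__(self):
        return iter(self.subjects)

    def index_of(self, subject: VirtualSubject) -> int:
        """Stable id of a subject: its position in lexicographic grid order."""
        try:
            return self._index[subject]
        except AttributeError:
            object.__setattr__(
                self, "_index", {s: i for i, s in enumerate(self.subjects)}
            )
            return self._index[subject]


@dataclass(frozen=True)
class DesignSample:
    """A subset of a grid selected by a (seeded) design scheme."""

    selected: tuple[VirtualSubject, ...]
    grid: SubjectGrid
    seed: int
    scheme: str  # {"lhs", "random", "full"}

    def __len__(self) -> int:
        return len(self.selected)

    def __iter__(self):
        return iter(self.selected)


def enumerate_grid(spec: GridSpec | None = None) -> SubjectGrid:
    """Enumerate the full factorial subject grid in lexicographic order.

    Order is the field order of :class:`VirtualSubject` with each factor's
    levels in their listed order; deterministic across runs.
    """
    spec = spec or GridSpec()
    subjects = tuple(
        VirtualSubject(sex, age, w, h, n, d, i, c, p, f)
        for sex in spec.sexes
        for age in spec.ages
        for w in spec.weight_classes
        for h in spec.height_classes
        for (n, d, i) in spec.pa_combinations()
        for c in spec.macro_levels
        for p in spec.macro_levels
        for f in spec.macro_levels
    )
    return SubjectGrid(subjects=subjects, spec=spec)


def encode_subject(x: VirtualSubject) -> np.ndarray:
    """Map a subject to its length-10 numeric feature vector.

    Ordinal factors keep their numeric values (age, sessions, minutes,
    %VO2max); ordered categories become ordered codes (weight/height class
    and macronutrient levels 0/1/2); sex is 0 (female) / 1 (male).  The
    mapping is invertible, see :func:`decode_subject`.
    """
    return np.array(
        [
            SEXES.index(x.sex),
            x.age,
            WEIGHT_CLASSES.index(x.weight_class),
            HEIGHT_CLASSES.index(x.height_class),
            x.pa_sessions,
            x.pa_duration,
            x.pa_intensity,
            MACRO_LEVELS.index(x.carb_level),
            MACRO_LEVELS.index(x.prot_level),
            MACRO_LEVELS.index(x.fat_level),
        ],
        dtype=float,
    )


def decode_subject(v: Sequence[float]) -> VirtualSubject:
    """Inverse of :func:`encode_subject`."""
    v = np.asarray(v, dtype=float)
    if v.shape != (10,):
        raise ValueError(f"expected a length-10 vector, got shape {v.shape}")
    return VirtualSubject(
        sex=SEXES[int(v[0])],
        age=int(v[1]),
        weight_class=WEIGHT_CLASSES[int(v[2])],
        height_class=HEIGHT_CLASSES[int(v[3])],
        pa_sessions=int(v[4]),
        pa_duration=int(v[5]),
        pa_intensity=int(v[6]),
        carb_level=MACRO_LEVELS[int(v[7])],
        prot_level=MACRO_LEVELS[int(v[8])],
        fat_level=MACRO_LEVELS[int(v[9])],
    )


def _grid_factor_levels(spec: GridSpec) -> list[list]:
    """The eight stratification factors (physical activity is composite)."""
    return [
        list(spec.sexes),
        list(spec.ages),
        list(spec.weight_classes),
        list(spec.height_classes),
        spec.pa_combinations(),
        list(spec.macro_levels),
        list(spec.macro_levels),
        list(spec.macro_levels),
    ]


def _subject_from_factor_row(row: tuple) -> VirtualSubject:
    sex, age, w, h, (n, d, i), c, p, f = row
    return VirtualSubject(sex, age, w, h, n, d, i, c, p, f)


def lhs_sample(grid: SubjectGrid, k: int, seed: int) -> DesignSample:
    """Latin-hypercube-style stratified sample of ``k`` distinct subjects.

    On this categorical grid a continuous maximin Latin hypercube is
    inapplicable, so the space-filling intent is realized as per-factor
    stratification: each factor's levels appear with frequencies within one
    unit of proportional, columns are matched by independent seeded
    permutations, and duplicate rows are resolved by marginal-preserving
    column swaps.  Deterministic under ``seed``.
    """
    if not 1 <= k <= len(grid):
        raise ValueError(f"sample size {k} not in [1, {len(grid)}]")
    if k == len(grid):
        return DesignSample(selected=grid.subjects, grid=grid, seed=seed, scheme="full")

    rng = np.random.default_rng(seed)
    factors = _grid_factor_levels(grid.spec)

    # stratified column per factor: counts are floor(k/L) with the remainder
    # spread over a seeded random subset of levels, then a seeded permutation
    columns: list[list] = []
    for levels in factors:
        L = len(levels)
        counts = np.full(L, k // L, dtype=int)
        counts[rng.choice(L, size=k % L, replace=False)] += 1
        col = [lev for lev, c in zip(levels, counts) for _ in range(c)]
        columns.append([col[j] for j in rng.permutation(k)])

    rows = [tuple(columns[f][i] for f in range(len(factors))) for i in range(k)]

    # duplicate resolution: swap one factor value between a duplicate row and
    # a random partner -- marginal counts are invariant under such swaps
    for _ in range(1000):
        seen: dict[tuple, int] = {}
        dups = []
        for i, r in enumerate(rows):
            if r in seen:
                dups.append(i)
            else:
                seen[r] = i
        if not dups:
            break
        for i in dups:
            f = int(rng.integers(len(factors)))
            j = int(rng.integers(k))
            ri, rj = list(rows[i]), list(rows[j])
            ri[f], rj[f] = rj[f], ri[f]
            rows[i], rows[j] = tuple(ri), tuple(rj)
    else:  # pragma: no cover - dense designs only
        raise RuntimeError(
            "could not resolve duplicate design rows; "
            "sample size too close to grid size for stratified sampling"
        )

    selected = tuple(_subject_from_factor_row(r) for r in rows)
    return DesignSample(selected=selected, grid=grid, seed=seed, scheme="lhs")


def random_sample(grid: SubjectGrid, k: int, seed: int) -> DesignSample:
    """Simple random sample without replacement (baseline design scheme)."""
    if not 1 <= k <= len(grid):
        raise ValueError(f"sample size {k} not in [1, {len(grid)}]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(grid), size=k, replace=False)
    return DesignSample(
        selected=tuple(grid.subjects[i] for i in idx),
        grid=grid,
        seed=seed,
        scheme="random",
    )


def split_train_test(
    sample: DesignSample, train_fraction: float, seed: int
) -> tuple[DesignSample, DesignSample]:
    """Partition a design at the subject level into train / test.

    All 26 weeks of a subject end up on the same side.  The training side
    has ``floor(train_fraction * k)`` subjects; the split is a seeded
    permutation, hence reproducible.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be strictly between 0 and 1")
    k = len(sample)
    n_train = int(np.floor(train_fraction * k))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(k)
    train = tuple(sample.selected[i] for i in sorted(perm[:n_train]))
    test = tuple(sample.selected[i] for i in sorted(perm[n_train:]))
    mk = lambda sel: DesignSample(
        selected=sel, grid=sample.grid, seed=seed, scheme=sample.scheme
    )
    return mk(train), mk(test)


def sample_to_frame(sample: DesignSample) -> pd.DataFrame:
    """Serialize a design to a DataFrame: subject_id + the ten factors."""
    records = []
    for s in sample:
        rec = {"subject_id": sample.grid.index_of(s)}
        rec.update({c: getattr(s, c) for c in FEATURE_COLUMNS})
        records.append(rec)
    return pd.DataFrame.from_records(records)
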