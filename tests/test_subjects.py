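"""Subject grid, encoding, stratified designs and subject-level splits."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import t2demu as t
from t2demu.subjects import (
    GridSpec,
    PA_SENTINEL,
    MACRO_LEVELS,
    encode_subject,
    decode_subject,
)


def brute_force_count(spec: GridSpec) -> int:
    """Independent nested-loop enumeration of the grid size."""
    n = 0
    for _sex in spec.sexes:
        for _age in spec.ages:
            for _w in spec.weight_classes:
                for _h in spec.height_classes:
                    for s in spec.pa_sessions:
                        pa = 1 if s == 0 else len(spec.pa_durations) * len(spec.pa_intensities)
                        n += pa * len(spec.macro_levels) ** 3
    return n


class TestEnumerateGrid:
    def test_default_grid_has_46170_subjects(self, grid):
        assert len(grid) == 46170
        assert len(grid) == brute_force_count(GridSpec())
        assert len(grid) == 90 * 19 * 27

    def test_no_exercise_branch_counts_2430(self):
        g = t.enumerate_grid(GridSpec(pa_sessions=(0,)))
        assert len(g) == 2430  # 2*5*3*3 anthropometric x 1 PA x 27 diets
        assert all(
            (s.pa_duration, s.pa_intensity) == PA_SENTINEL for s in g
        )

    def test_degenerate_one_level_grid(self):
        g = t.enumerate_grid(
            GridSpec(
                sexes=("female",),
                ages=(28,),
                weight_classes=("normal",),
                height_classes=("short",),
                pa_sessions=(1,),
                pa_durations=(30,),
                pa_intensities=(40,),
                macro_levels=("med",),
            )
        )
        assert len(g) == 1

    def test_empty_level_list_rejected(self):
        with pytest.raises(ValueError, match="no levels"):
            GridSpec(ages=())

    def test_subjects_distinct_and_lexicographically_ordered(self, grid):
        subs = grid.subjects
        assert len(set(subs)) == len(subs)
        # deterministic order: re-enumeration reproduces it exactly
        assert t.enumerate_grid().subjects[:100] == subs[:100]


class TestEncoding:
    def test_showcase_subject_round_trips(self, example_subject):
        v = encode_subject(example_subject)
        assert v.shape == (10,)
        np.testing.assert_array_equal(
            v, [1, 38, 2, 1, 1, 30, 60, 1, 2, 2]
        )
        assert decode_subject(v) == example_subject

    def test_bijection_on_grid_subsample(self, grid):
        for s in grid.subjects[::501]:
            assert decode_subject(encode_subject(s)) == s

    def test_single_factor_difference_is_single_coordinate(self, example_subject):
        other = example_subject.with_diet(
            example_subject.carb_level, example_subject.prot_level, "low"
        )
        diff = encode_subject(example_subject) != encode_subject(other)
        assert diff.sum() == 1

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="obese"):
            t.VirtualSubject(
                "male", 38, "obese", "tall", 0, 0, 0, "low", "low", "low"
            )

    @given(st.integers(min_value=0, max_value=46169))
    @settings(max_examples=50, deadline=None)
    def test_encode_decode_identity_property(self, grid, idx):
        s = grid[idx]
        assert decode_subject(encode_subject(s)) == s


class TestLHSSample:
    def test_reproducible_distinct_subjects(self, grid):
        a = t.lhs_sample(grid, 500, seed=7)
        b = t.lhs_sample(grid, 500, seed=7)
        assert a.selected == b.selected
        assert len(set(a.selected)) == 500
        assert t.lhs_sample(grid, 500, seed=8).selected != a.selected

    def test_marginals_within_one_of_proportional(self, grid):
        k = 777
        sample = t.lhs_sample(grid, k, seed=3)
        factors = {
            "sex": lambda s: s.sex,
            "age": lambda s: s.age,
            "weight": lambda s: s.weight_class,
            "height": lambda s: s.height_class,
            "pa": lambda s: (s.pa_sessions, s.pa_duration, s.pa_intensity),
            "carb": lambda s: s.carb_level,
            "prot": lambda s: s.prot_level,
            "fat": lambda s: s.fat_level,
        }
        n_levels = {"sex": 2, "age": 5, "weight": 3, "height": 3, "pa": 19,
                    "carb": 3, "prot": 3, "fat": 3}
        for name, key in factors.items():
            counts = Counter(key(s) for s in sample)
            target = k / n_levels[name]
            assert len(counts) == n_levels[name]
            for c in counts.values():
                assert abs(c - target) <= 1.0

    def test_k_19_covers_each_pa_combination_once(self, grid):
        sample = t.lhs_sample(grid, 19, seed=5)
        pa = Counter(
            (s.pa_sessions, s.pa_duration, s.pa_intensity) for s in sample
        )
        assert len(pa) == 19 and set(pa.values()) == {1}

    def test_full_sample_is_the_grid(self):
        g = t.enumerate_grid(
            GridSpec(sexes=("female",), ages=(28, 38), pa_sessions=(0,))
        )
        sample = t.lhs_sample(g, len(g), seed=0)
        assert sample.scheme == "full"
        assert set(sample.selected) == set(g.subjects)

    def test_oversized_sample_rejected(self, grid):
        with pytest.raises(ValueError, match="sample size"):
            t.lhs_sample(grid, len(grid) + 1, seed=0)


class TestSplit:
    def test_split_sizes_and_partition(self, grid):
        sample = t.lhs_sample(grid, 5000, seed=1)
        train, test = t.split_train_test(sample, 0.7, seed=2)
        assert (len(train), len(test)) == (3500, 1500)
        assert set(train.selected) | set(test.selected) == set(sample.selected)
        assert set(train.selected) & set(test.selected) == set()

    def test_split_reproducible(self, grid):
        sample = t.lhs_sample(grid, 100, seed=1)
        a = t.split_train_test(sample, 0.7, seed=9)
        b = t.split_train_test(sample, 0.7, seed=9)
        assert a[0].selected == b[0].selected and a[1].selected == b[1].selected

    def test_bad_fraction_rejected(self, grid):
        sample = t.lhs_sample(grid, 10, seed=1)
        with pytest.raises(ValueError):
            t.split_train_test(sample, 1.0, seed=0)
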