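"""Association screen: exact permutation p, effect sizes, power, calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ptsdlang.stats import (
    anova_assoc,
    association_table,
    chi2_assoc,
    cohens_d,
    mann_whitney_assoc,
)


def enumeration_p(x, y):
    """Independent oracle: full enumeration of label assignments, ranking
    computed from scratch (no shared helpers with the implementation)."""
    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)

    def u_of(indices):
        u = 0.0
        group1 = [pooled[i] for i in indices]
        group2 = [pooled[i] for i in range(n) if i not in set(indices)]
        for a in group1:
            for b in group2:
                u += (a > b) + 0.5 * (a == b)
        return u

    obs = u_of(tuple(range(n1)))
    us = [u_of(c) for c in itertools.combinations(range(n), n1)]
    lo = sum(u <= obs + 1e-9 for u in us) / len(us)
    hi = sum(u >= obs - 1e-9 for u in us) / len(us)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_small_sample_exact_p(self):
        r = mann_whitney_assoc([1, 2, 3, 4], [0, 0, 1, 1],
                               group_order=[0, 1], power_reps=0)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 6)

    def test_identical_groups_zero_effect(self):
        r = mann_whitney_assoc([5, 5, 5, 5, 5, 5], [0, 0, 0, 1, 1, 1],
                               power_reps=0)
        assert r.effect_size == 0.0

    def test_sign_convention_symptomatic_higher_is_negative(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(0, 1, 200)
        sympt = rng.normal(1, 1, 200)
        d = cohens_d(ref, sympt)
        assert d == pytest.approx(-1.0, abs=0.15)

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mann_whitney_assoc([1, 2, 3], [0, 0, 1], power_reps=0)

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_exact_p_matches_enumeration_oracle(self, data):
        n1 = data.draw(st.integers(2, 5))
        n2 = data.draw(st.integers(2, 10 - n1))
        vals = data.draw(st.lists(st.integers(0, 6), min_size=n1 + n2,
                                  max_size=n1 + n2))
        labels = [0] * n1 + [1] * n2
        r = mann_whitney_assoc(vals, labels, group_order=[0, 1], power_reps=0)
        assert r.p_value == pytest.approx(
            enumeration_p(vals[:n1], vals[n1:]))

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(500):
            v = rng.normal(size=40)
            labels = np.repeat([0, 1], 20)
            ps.append(mann_whitney_assoc(v, labels, power_reps=0).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_power_monotone_in_effect_and_n(self):
        powers_d = [mann_whitney_assoc(
            np.r_[np.zeros(20), np.full(20, d)], np.repeat([0, 1], 20),
            power_reps=800, seed=5).power for d in (0.2, 0.8, 1.6)]
        assert powers_d == sorted(powers_d)
        powers_n = []
        for n in (10, 40, 160):
            rng = np.random.default_rng(7)
            v = np.r_[rng.normal(0, 1, n), rng.normal(0.8, 1, n)]
            powers_n.append(mann_whitney_assoc(
                v, np.repeat([0, 1], n), power_reps=800, seed=5).power)
        assert powers_n == sorted(powers_n)


class TestAnova:
    def test_identical_groups_f_zero(self):
        v = np.r_[[1, 2, 3]] * 1.0
        r = anova_assoc(np.r_[v, v, v], np.repeat([0, 1, 2], 3), power_reps=0)
        assert r.statistic == pytest.approx(0.0)
        assert r.effect_size == pytest.approx(0.0)

    def test_strong_separation_tiny_p(self):
        rng = np.random.default_rng(11)
        v = np.r_[rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                  rng.normal(3, 1, 30)]
        r = anova_assoc(v, np.repeat([0, 1, 2], 30), power_reps=0)
        assert r.p_value < 1e-6

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="3 groups"):
            anova_assoc([1, 2, 3, 4], [0, 0, 1, 1], power_reps=0)


class TestChi2:
    def test_independent_table(self):
        r = chi2_assoc([[10, 10], [10, 10]], power_reps=0)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_sex_by_exposure_cohort_table(self):
        # 2×2 reconstructed from cohort percentages: 61/110 vs 26/38 female
        r = chi2_assoc([[61, 49], [26, 12]], power_reps=0)
        assert r.p_value == pytest.approx(0.22, abs=0.01)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            chi2_assoc([[3, 4]], power_reps=0)
        with pytest.raises(ValueError, match="marginal"):
            chi2_assoc([[0, 0], [1, 2]], power_reps=0)


class TestAssociationTable:
    def test_planted_feature_flagged(self, small_table):
        rng = np.random.default_rng(2)
        n = len(small_table)
        labels = {d: int(i >= n // 2)
                  for i, d in enumerate(small_table.doc_ids)}
        values = small_table.values.copy()
        j = small_table.names.index("model_death")
        lab = np.array([labels[d] for d in small_table.doc_ids])
        col = rng.normal(0, 1, n) + 1.5 * lab
        values[:, j] = col
        from ptsdlang.registry import FeatureTable

        table = FeatureTable(small_table.doc_ids, values,
                             small_table.registry)
        results = association_table(table, labels, group_order=[0, 1],
                                    power_reps=0)
        planted = next(r for r in results if r.feature == "model_death")
        assert planted.significant
        assert planted.p_value < 0.01

    def test_label_mismatch_rejected(self, small_table):
        with pytest.raises(ValueError, match="missing"):
            association_table(small_table, {"nope": 1}, power_reps=0)

    def test_results_cover_every_feature_once(self, small_table):
        n = len(small_table)
        labels = {d: i % 2 for i, d in enumerate(small_table.doc_ids)}
        results = association_table(small_table, labels, power_reps=0)
        assert sorted(r.feature for r in results) == sorted(small_table.names)
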