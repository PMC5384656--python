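"""Burden counting, rank-sum test (with brute-force oracle), regression,
residualization, extreme-load subset, timing context and GA stratification."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dnmburden.burden import (
    age_burden_correlation,
    compare_groups,
    count_burden,
    extreme_load_subset,
    fit_preterm_logistic,
    rank_sum_test,
    residualize_burden,
    stratified_burden,
    timing_context,
)
from dnmburden.types import ReplicationTimingTrack, TrioRecord


def brute_force_two_sided_p(x, y):
    """Independent oracle: enumerate all label assignments of the pooled data
    and count those whose rank-sum deviates at least as much as observed."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    m, N = len(x), len(pooled)
    mu = m * (N + 1) / 2
    obs = abs(ranks[:m].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(N), m):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestCountBurden:
    def test_x_chromosome_excluded(self, tiny_trios, mutation_factory):
        muts = [
            mutation_factory(chrom="1"),
            mutation_factory(chrom="22"),
            mutation_factory(chrom="X"),
        ]
        counts = count_burden(muts, tiny_trios)
        assert counts["F1"] == 2

    def test_zero_for_subjects_without_mutations(self, tiny_trios):
        counts = count_burden([], tiny_trios)
        assert set(counts.index) == {t.family_id for t in tiny_trios}
        assert (counts == 0).all()

    def test_orphan_subject_raises(self, tiny_trios, mutation_factory):
        with pytest.raises(ValueError, match="F99"):
            count_burden([mutation_factory(subject="F99")], tiny_trios)


class TestRankSum:
    def test_complete_separation_u_zero(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0  # U counts pairs with x > y

    def test_all_tied_p_one(self):
        res = rank_sum_test([5, 5, 5], [5, 5, 5], method="normal")
        assert res.p_value == 1.0

    def test_tiny_exact_example(self):
        res = rank_sum_test([1, 2], [3, 4], method="exact")
        assert res.p_value == pytest.approx(2 / 6)

    @pytest.mark.parametrize("m,n", [(2, 3), (3, 3), (4, 5), (5, 5), (6, 4)])
    def test_exact_matches_brute_force_with_ties(self, m, n, rng):
        x = rng.integers(0, 4, size=m).astype(float)
        y = rng.integers(0, 4, size=n).astype(float)
        res = rank_sum_test(x, y, method="exact")
        assert res.p_value == pytest.approx(brute_force_two_sided_p(x, y))

    def test_normal_matches_scipy_untied(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(0.5, size=25)
        res = rank_sum_test(x, y, method="normal")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_exact_close_to_normal_for_moderate_untied(self, rng):
        # the exact and the continuity-corrected normal p agree within 0.02
        # on untied groups of 10 (without the correction the normal tail
        # overshoots the discrete tail by up to ~0.035 at this size)
        for _ in range(3):
            x = rng.normal(size=10)
            y = rng.normal(0.3, size=10)
            pe = rank_sum_test(x, y, method="exact").p_value
            pn = rank_sum_test(x, y, method="normal", continuity=True).p_value
            assert abs(pe - pn) < 0.02

    @given(
        x=st.lists(st.integers(0, 9), min_size=1, max_size=6),
        y=st.lists(st.integers(0, 9), min_size=1, max_size=6),
    )
    def test_label_symmetry(self, x, y):
        p_xy = rank_sum_test(x, y).p_value
        p_yx = rank_sum_test(y, x).p_value
        assert p_xy == pytest.approx(p_yx)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2])


class TestCompareGroups:
    def test_boolean_labels_order(self):
        values = {"a": 1.0, "b": 2.0, "c": 10.0, "d": 11.0}
        labels = {"a": False, "b": False, "c": True, "d": True}
        res = compare_groups(values, labels)
        assert res.n_group1 == res.n_group2 == 2
        assert res.p_value == pytest.approx(2 / 6)

    def test_three_groups_raises(self):
        with pytest.raises(ValueError, match="two groups"):
            compare_groups([1, 2, 3], ["a", "b", "c"])


class TestResidualize:
    def test_perfect_linear_fit_gives_zero_residuals(self):
        ages = np.array([30.0, 35, 40, 45])
        counts = 2 * ages + 5
        assert residualize_burden(counts, ages) == pytest.approx(np.zeros(4), abs=1e-9)

    def test_hand_computed_ols(self):
        # ages (30,35,40), counts (40,45,47): slope 35/50 = 0.7,
        # intercept 19.5, fitted (40.5, 44, 47.5)
        resid = residualize_burden([40, 45, 47], [30, 35, 40])
        assert resid == pytest.approx([-0.5, 1.0, -0.5])
        assert resid.sum() == pytest.approx(0.0, abs=1e-9)

    def test_rank_preserving_when_slope_zero(self, rng):
        # counts constructed exactly orthogonal to age: the fit has slope 0,
        # so residuals are counts - mean and the rank-sum p is unchanged
        ages = rng.normal(33, 5, size=40)
        raw = rng.poisson(40, size=40).astype(float)
        counts = residualize_burden(raw, ages) + 40.0
        labels = rng.random(40) < 0.4
        resid = residualize_burden(counts, ages)
        assert resid == pytest.approx(counts - counts.mean())
        p_raw = compare_groups(counts, labels).p_value
        p_res = compare_groups(resid, labels).p_value
        assert p_res == pytest.approx(p_raw)

    def test_invariant_to_added_age_trend(self, rng):
        # adding c*age to every count is absorbed by the fit
        ages = rng.normal(33, 5, size=60)
        counts = rng.poisson(44, size=60).astype(float)
        labels = rng.random(60) < 0.35
        p1 = compare_groups(residualize_burden(counts, ages), labels).p_value
        p2 = compare_groups(residualize_burden(counts + 3.7 * ages, ages), labels).p_value
        assert p1 == pytest.approx(p2)

    def test_zero_age_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            residualize_burden([1, 2, 3], [30, 30, 30])


class TestExtremeLoad:
    def test_distinct_counts_exact_five_percent(self):
        burden = {f"s{i}": float(i) for i in range(100)}
        assert extreme_load_subset(burden, 0.05) == {f"s{i}" for i in range(95, 100)}

    def test_total_tie_returns_everyone(self):
        burden = {f"s{i}": 7.0 for i in range(20)}
        assert extreme_load_subset(burden, 0.05) == set(burden)

    def test_study_sized_quantile(self):
        # counts 1..816 at fraction 0.05: threshold 776, 41 subjects
        burden = {f"s{i}": float(i) for i in range(1, 817)}
        top = extreme_load_subset(burden, 0.05)
        assert len(top) == 41
        assert min(int(s[1:]) for s in top) == 776


class TestLogistic:
    def _simulate(self, rng, n, beta_burden):
        burden = rng.poisson(44, size=n).astype(float)
        z = (burden - burden.mean()) / burden.std()
        p = 1 / (1 + np.exp(-(-0.6 + beta_burden * z)))
        preterm = rng.random(n) < p
        trios = [
            TrioRecord(
                f"F{i}",
                float(max(rng.normal(33.5, 5.8), 18.0)),
                float(max(rng.normal(31.4, 4.9), 16.0)),
                33.0 if preterm[i] else 39.0,
            )
            for i in range(n)
        ]
        return trios, {t.family_id: burden[i] for i, t in enumerate(trios)}

    def test_null_burden_coefficient_near_zero(self, rng):
        trios, burden = self._simulate(rng, 10_000, 0.0)
        fit = fit_preterm_logistic(trios, burden)
        assert abs(fit.coef["burden"]) < 0.05

    def test_recovers_planted_log_odds(self, rng):
        trios, burden = self._simulate(rng, 10_000, 0.3)
        fit = fit_preterm_logistic(trios, burden)
        assert fit.coef["burden"] == pytest.approx(0.30, abs=0.05)
        assert fit.p_values["burden"] < 1e-6

    def test_duplicated_dataset_same_coefficients(self, rng):
        trios, burden = self._simulate(rng, 400, 0.3)
        fit1 = fit_preterm_logistic(trios, burden)
        doubled = trios + [
            TrioRecord(t.family_id + "b", t.paternal_age, t.maternal_age, t.gestational_age)
            for t in trios
        ]
        burden2 = dict(burden) | {t.family_id + "b": burden[t.family_id] for t in trios}
        fit2 = fit_preterm_logistic(doubled, burden2)
        for k in fit1.coef:
            assert fit1.coef[k] == pytest.approx(fit2.coef[k], abs=1e-6)

    def test_too_few_cases_raises(self, tiny_trios):
        with pytest.raises(ValueError, match=">= 10"):
            fit_preterm_logistic(tiny_trios, {t.family_id: 40.0 for t in tiny_trios})


class TestTimingContext:
    def test_uniform_track(self, mutation_factory):
        track = ReplicationTimingTrack([("1", 0, 10_000, 0.7)])
        out = timing_context([mutation_factory(pos=5000)], track)
        assert out[0] == pytest.approx(0.7)

    def test_split_window_symmetric(self, mutation_factory):
        track = ReplicationTimingTrack([("1", 0, 5000, 0.2), ("1", 5000, 10_000, 0.8)])
        # pos 5001 -> 0-based 5000; window [4500, 5500): half on each value
        out = timing_context([mutation_factory(pos=5001)], track)
        assert out[0] == pytest.approx(0.5)

    def test_base_weighted_mean(self, mutation_factory):
        # 600 bp at 1.0 and 400 bp at 0.0 inside the 1 kb window
        track = ReplicationTimingTrack([("1", 0, 5100, 1.0), ("1", 5100, 10_000, 0.0)])
        out = timing_context([mutation_factory(pos=5001)], track)
        assert out[0] == pytest.approx(0.6)

    def test_uncovered_window_is_nan(self, mutation_factory):
        track = ReplicationTimingTrack([("2", 0, 10_000, 0.7)])
        out = timing_context([mutation_factory(pos=5000, chrom="1")], track)
        assert math.isnan(out[0])


class TestStratified:
    def _trios(self, gas):
        return [TrioRecord(f"F{i}", 33.0, 31.0, ga) for i, ga in enumerate(gas)]

    def test_bins_shift_same_direction(self, rng):
        gas = np.concatenate([
            rng.uniform(32, 36.9, 40), rng.uniform(25, 31.9, 40), rng.uniform(37, 42, 80)
        ])
        trios = self._trios(gas)
        burden = {
            t.family_id: float(rng.poisson(46 if t.preterm else 43))
            for t in trios
        }
        strata = stratified_burden(trios, burden, [(32, 37), (20, 32)])
        term_median = np.median(
            [burden[t.family_id] for t in trios if t.gestational_age >= 37]
        )
        for s in strata:
            vals = [
                burden[t.family_id]
                for t in trios
                if s.bin[0] <= t.gestational_age < s.bin[1]
            ]
            assert np.median(vals) > term_median

    def test_empty_bin_flagged_without_p(self):
        trios = self._trios([33.0, 34.0, 38.0, 39.0, 40.0, 41.0, 42.0])
        burden = {t.family_id: 44.0 for t in trios}
        strata = stratified_burden(trios, burden, [(32, 37), (20, 28)])
        empty = [s for s in strata if s.bin == (20, 28)][0]
        assert empty.n_bin == 0 and empty.result is None and empty.underpowered

    def test_bin_overlapping_term_range_raises(self, tiny_trios):
        with pytest.raises(ValueError, match="term"):
            stratified_burden(tiny_trios, {t.family_id: 1.0 for t in tiny_trios}, [(35, 38)])


def test_age_burden_correlation_raw_scale(rng):
    trios = [
        TrioRecord(f"F{i}", float(a), 31.0, 39.0)
        for i, a in enumerate(rng.normal(33.5, 5.8, 200).clip(18))
    ]
    burden = {t.family_id: 40 + 0.9 * t.paternal_age + rng.normal(0, 3) for t in trios}
    r, r2 = age_burden_correlation(trios, burden)
    assert r > 0.5
    assert r2 == pytest.approx(r * r)
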