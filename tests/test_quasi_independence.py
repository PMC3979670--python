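import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ethoseq as es
from ethoseq.quasi_independence import (
    CohortSet,
    classify_hi_involvement,
    fit_quasi_independence,
    freeman_tukey_deviates,
    g_statistic,
    significance_criterion,
)
from ethoseq.transitions import TransitionCounts

ABC = ["A", "B", "C"]
ABCD = ["A", "B", "C", "D"]


def tc_from(labels, n):
    return TransitionCounts(labels=list(labels), n=np.asarray(n, dtype=np.int64))


def brute_force_ipf(n, iters=200_000, tol=1e-12):
    """Naive alternating row/column scaling, independent of the package path."""
    n = np.asarray(n, dtype=float)
    r, c = n.sum(1), n.sum(0)
    m = np.ones_like(n)
    np.fill_diagonal(m, 0.0)
    for _ in range(iters):
        m *= (r / m.sum(1))[:, None]
        m *= (c / m.sum(0))[None, :]
        if max(abs(m.sum(1) - r).max(), abs(m.sum(0) - c).max()) < tol:
            break
    return m


class TestIPF:
    def test_uniform_matrix_is_fixed_point(self):
        tc = tc_from(ABC, [[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        m = fit_quasi_independence(tc)
        off = ~np.eye(3, dtype=bool)
        assert m[off] == pytest.approx(5.0, abs=1e-8)

    def test_three_by_three_against_frozen_oracle(self):
        tc = tc_from(ABC, [[0, 2, 8], [4, 0, 6], [3, 7, 0]])
        m = fit_quasi_independence(tc, tol=1e-12)
        expected = np.array(
            [[0.0, 3.296646, 6.703354],
             [2.703354, 0.0, 7.296646],
             [4.296646, 5.703354, 0.0]]
        )
        assert m == pytest.approx(expected, abs=1e-5)

    def test_margins_conserved_on_day3(self, day3_matrix, day3_fit):
        m = day3_fit.expected
        assert np.abs(m.sum(1) - day3_matrix.row_sums).max() < 1e-9
        assert np.abs(m.sum(0) - day3_matrix.col_sums).max() < 1e-9
        u = day3_matrix.index("U")
        sta = day3_matrix.index("Sta")
        assert m.sum(1)[u] == pytest.approx(408)
        assert m.sum(0)[sta] == pytest.approx(1013)

    def test_random_4x4_matches_bruteforce(self):
        rng = np.random.default_rng(1234)
        for _ in range(20):
            n = rng.integers(1, 50, size=(4, 4))
            np.fill_diagonal(n, 0)
            tc = tc_from(ABCD, n)
            m = fit_quasi_independence(tc, tol=1e-12)
            assert np.abs(m - brute_force_ipf(n)).max() < 1e-9

    def test_zero_margin_warns_and_fits_zero(self):
        n = [[0, 2, 8], [0, 0, 0], [3, 7, 0]]  # behavior B never initiates
        tc = tc_from(ABC, n)
        with pytest.warns(UserWarning, match="trivially"):
            m = fit_quasi_independence(tc, tol=1e-9)
        assert m[1].sum() == 0


class TestGStatistic:
    def test_zero_when_observed_equals_expected(self):
        tc = tc_from(ABC, [[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        m = fit_quasi_independence(tc)
        G, df, p = g_statistic(tc, m)
        assert G == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("k,df", [(3, 1), (6, 19), (16, 209)])
    def test_df_formula(self, k, df):
        labels = [f"b{i}" for i in range(k)]
        n = np.ones((k, k), dtype=int) * 4
        np.fill_diagonal(n, 0)
        tc = tc_from(labels, n)
        m = fit_quasi_independence(tc)
        assert g_statistic(tc, m)[1] == df

    def test_day3_model_strongly_rejected(self, day3_fit):
        assert day3_fit.df == 209
        assert day3_fit.pvalue < 0.0001

    def test_bootstrap_type_one_error_calibrated(self):
        """Parametric bootstrap from the fitted model: rejection near alpha."""
        rng = np.random.default_rng(2024)
        k = 6
        labels = [f"b{i}" for i in range(k)]
        base = rng.integers(20, 60, size=(k, k))
        np.fill_diagonal(base, 0)
        m0 = fit_quasi_independence(tc_from(labels, base))
        probs = (m0 / m0.sum()).ravel()
        N = int(base.sum())
        crit = stats.chi2.ppf(0.95, k * k - 3 * k + 1)
        rejections = 0
        reps = 500
        for _ in range(reps):
            sample = rng.multinomial(N, probs).reshape(k, k)
            np.fill_diagonal(sample, 0)
            tc = tc_from(labels, sample)
            m = fit_quasi_independence(tc, tol=1e-8)
            G, _, _ = g_statistic(tc, m)
            rejections += G > crit
        assert 0.03 <= rejections / reps <= 0.07


class TestFreemanTukeyDeviates:
    def test_closed_forms(self):
        tc = tc_from(ABC, [[0, 0, 0], [0, 0, 0], [0, 0, 0]])
        m = np.array([[0, 0.0, 2.0], [0.0, 0, 0.0], [0.0, 0.0, 0]])
        z = freeman_tukey_deviates(tc, m)
        assert z[0, 1] == pytest.approx(0.0)  # n=0, m=0
        assert z[0, 2] == pytest.approx(-2.0)  # n=0, m=2: 1 - 3
        assert np.isnan(z[0, 0])

    def test_negative_expected_rejected(self):
        tc = tc_from(ABC, np.zeros((3, 3), dtype=int))
        m = np.full((3, 3), -1.0)
        with pytest.raises(ValueError):
            freeman_tukey_deviates(tc, m)

    @given(
        n=st.integers(min_value=0, max_value=500),
        m=st.floats(min_value=0.01, max_value=500.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_observed_and_expected(self, n, m):
        tc = tc_from(["A", "B"], [[0, 0], [0, 0]])

        def z(nn, mm):
            return np.sqrt(nn) + np.sqrt(nn + 1) - np.sqrt(4 * mm + 1)

        assert z(n + 1, m) > z(n, m)
        assert z(n, m + 0.5) < z(n, m)

    def test_day3_bobbing_to_standing_band(self, day3_fit):
        # a transition the study renders as an intermediate-strength arrow
        assert 5.0 < day3_fit.deviate("B", "Sta") < 10.0


class TestSignificanceCriterion:
    def test_default_analysis_value(self):
        assert significance_criterion(0.05, 209, 240) == pytest.approx(1.008, abs=5e-4)

    def test_monotone_decreasing_toward_zero_as_alpha_grows(self):
        values = [significance_criterion(a, 209, 240) for a in (0.001, 0.05, 0.5, 0.99, 0.9999)]
        assert all(x > y for x, y in zip(values, values[1:]))
        assert values[-1] < 0.8

    def test_median_chi_square_near_one(self):
        # chi2 median ~ df for large df, so c ~ 1 at alpha = 0.5, df = n_cells
        assert significance_criterion(0.5, 240, 240) == pytest.approx(0.9986, abs=1e-3)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            significance_criterion(1.5, 209, 240)


class TestSignificantTransitions:
    def test_day3_set_and_members(self, day3_fit):
        sig = day3_fit.significant_transitions()
        assert len(sig) == 55
        assert ("L", "Wr") in sig and ("L", "H") in sig
        assert ("W", "Ap") in sig and ("G", "Sta") in sig

    def test_no_transitions_when_model_fits(self):
        tc = tc_from(ABC, [[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        res = es.QuasiIndependence(tc).fit()
        assert res.significant_transitions() == set()

    def test_only_positive_deviates_qualify(self, day3_fit):
        for a, b in day3_fit.significant_transitions():
            assert day3_fit.deviate(a, b) > day3_fit.criterion > 0

    def test_summary_lists_all_significant(self, day3_fit):
        text = day3_fit.summary()
        assert "Significant transitions: 55" in text
        assert text.count("\n") > 55


class TestHighIntensityClassification:
    def test_day3_involvement(self, day3_fit):
        s = day3_fit.classify_hi_involvement()
        assert s.involving_hi == 18
        assert s.hi_to_hi == 6
        assert s.to_behavior["L"] == 5
        assert s.to_behavior["Wr"] == 5
        assert s.distinct_non_hi_precursors == 6

    def test_empty_set(self):
        s = classify_hi_involvement(set())
        assert (s.involving_hi, s.hi_to_hi, s.distinct_non_hi_precursors) == (0, 0, 0)

    def test_counts_consistent(self, day3_fit):
        s = day3_fit.classify_hi_involvement()
        assert s.involving_hi == s.to_hi + s.from_hi - s.hi_to_hi


class TestCohortComparisons:
    def _small_cohorts(self, shift=0):
        rng = np.random.default_rng(7)
        base = rng.integers(10, 40, size=(4, 4))
        np.fill_diagonal(base, 0)
        out = {}
        for i, age in enumerate([1, 2, 3]):
            n = base.copy()
            if shift:
                n[0, 1] += shift * i
            out[age] = tc_from(ABCD, n)
        return CohortSet(matrices=out)

    def test_marginal_df(self, cohort_fits):
        cs = CohortSet(matrices={a: f.counts for a, f in cohort_fits.items()})
        G, df, p = es.marginal_by_age_test(cs, axis="first")
        assert df == 60
        G2, df2, p2 = es.marginal_by_age_test(cs, axis="second")
        assert df2 == 60
        assert p < 1e-4 and p2 < 1e-4

    def test_identical_cohorts_homogeneous(self):
        cs = self._small_cohorts(shift=0)
        Gm, _, _ = es.marginal_by_age_test(cs)
        Gh, _, _ = es.homogeneity_across_ages(cs)
        assert Gm == pytest.approx(0.0, abs=1e-9)
        assert Gh == pytest.approx(0.0, abs=1e-9)

    def test_homogeneity_df(self):
        cs = self._small_cohorts()
        _, df, _ = es.homogeneity_across_ages(cs)
        assert df == (3 - 1) * 4 * (4 - 2)

    def test_heterogeneity_detected(self):
        cs = self._small_cohorts(shift=60)
        _, _, p = es.homogeneity_across_ages(cs)
        assert p < 0.001

    def test_homogeneity_calibrated_on_common_chain(self):
        """Cohorts simulated from one chain: rejection rate near alpha."""
        rng = np.random.default_rng(99)
        k, a, steps, reps = 6, 5, 2000, 500
        P = rng.uniform(0.5, 1.5, size=(k, k))
        np.fill_diagonal(P, 0.0)
        P /= P.sum(1, keepdims=True)
        cum = P.cumsum(axis=1)
        labels = [f"b{i}" for i in range(k)]
        # all (replicate, cohort) chains stepped in parallel
        n_chains = reps * a
        counts = np.zeros((n_chains, k, k), dtype=np.int64)
        state = rng.integers(k, size=n_chains)
        chain_idx = np.arange(n_chains)
        for _ in range(steps):
            u = rng.random(n_chains)
            nxt = (cum[state] > u[:, None]).argmax(axis=1)
            np.add.at(counts, (chain_idx, state, nxt), 1)
            state = nxt
        rejections = 0
        for r in range(reps):
            mats = {c: tc_from(labels, counts[r * a + c]) for c in range(a)}
            _, _, p = es.homogeneity_across_ages(CohortSet(matrices=mats))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestPersistenceClasses:
    def test_fixture_cohorts(self, cohort_fits):
        classes = es.cohort_persistence_classes(cohort_fits)
        assert len(classes.common_all) == 20
        assert {d: len(s) for d, s in classes.appears_from_day.items()} == {2: 8, 3: 5, 4: 4, 6: 3}
        assert classes.disappears_after_day[3] == {("Av", "W"), ("Wr", "W")}
        assert classes.disappears_after_day[4] == {("R", "U")}
        # named transitions the cohorts share at every age
        assert {("W", "Ap"), ("Ap", "Av"), ("G", "Sta")} <= classes.common_all

    def test_single_cohort_rejected(self, cohort_fits):
        with pytest.raises(ValueError):
            es.cohort_persistence_classes({3: cohort_fits[3]})

    def test_identical_fits_all_common(self, day3_fit):
        classes = es.cohort_persistence_classes({1: day3_fit, 2: day3_fit, 3: day3_fit})
        assert len(classes.common_all) == 55
        assert not classes.other
        assert all(not s for s in classes.appears_from_day.values())
        assert all(not s for s in classes.disappears_after_day.values())
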