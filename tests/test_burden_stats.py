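"""Pooled count test, CADD aggregation, logistic burden test, Bonferroni."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from comphet.burden_stats import (
    aggregate_cadd,
    bonferroni_threshold,
    is_significant,
    logistic_burden_test,
    pooled_count_test,
)
from comphet.compound_het import detect_events_cohort
from comphet.models import Genotype, VariantCall


class TestPooledCountTest:
    @pytest.mark.parametrize(
        "a,b,chi2,p",
        [
            (68, 41, 6.69, 0.0097),
            (21, 8, 5.83, 0.0158),
            (20, 8, 5.14, 0.0233),
            (61, 34, 7.67, 0.0056),
        ],
    )
    def test_reproduces_published_statistics(self, a, b, chi2, p):
        res = pooled_count_test(a, b)
        assert res.chi_square == pytest.approx(chi2, abs=0.005)
        assert res.p_value == pytest.approx(p, abs=0.0005)
        assert res.df == 1

    def test_equal_counts_give_zero_statistic(self):
        res = pooled_count_test(7, 7)
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_closed_form(self):
        # X^2 = (a-b)^2 / (a+b) for the equal-split 1-df test
        res = pooled_count_test(13, 5)
        assert res.chi_square == pytest.approx((13 - 5) ** 2 / 18)

    @given(
        a=st.integers(min_value=0, max_value=200),
        b=st.integers(min_value=0, max_value=200),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, a, b):
        if a + b == 0:
            with pytest.raises(ValueError):
                pooled_count_test(a, b)
            return
        r1, r2 = pooled_count_test(a, b), pooled_count_test(b, a)
        assert r1.chi_square == pytest.approx(r2.chi_square)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_strictly_increasing_in_imbalance_at_fixed_total(self):
        total = 60
        stats = [pooled_count_test(a, total - a).chi_square for a in range(30, 61)]
        assert all(x < y for x, y in zip(stats, stats[1:]))

    def test_type_one_error_near_nominal(self):
        """Under a fair binomial split the 5%-level rejection rate is ~5%."""
        rng = np.random.default_rng(1234)
        totals = rng.integers(80, 140, size=2000)
        a = rng.binomial(totals, 0.5)
        rejected = 0
        for total, ai in zip(totals, a):
            if pooled_count_test(int(ai), int(total - ai)).p_value < 0.05:
                rejected += 1
        assert abs(rejected / 2000 - 0.05) < 0.02


class TestAggregateCadd:
    def _event(self, cohort, idx=0):
        return detect_events_cohort(
            cohort.pedigrees, cohort.cnv_calls, cohort.genes, cohort.variant_calls
        )

    def test_simple_sum(self):
        from tests_support import make_event

        ev1 = make_event(cadd=10.0)
        ev2 = make_event(cadd=20.0, pos=ev1.variant.pos + 1)
        sums = aggregate_cadd([ev1, ev2])
        assert sums[(ev1.variant.sample_id, "proband")] == pytest.approx(30.0)

    def test_full_sample_mode_zero_fills(self):
        from tests_support import make_event

        ev = make_event(cadd=5.0)
        sums = aggregate_cadd(
            [ev],
            all_individuals=[(ev.variant.sample_id, "proband"), ("X1", "parent")],
        )
        assert sums[("X1", "parent")] == 0.0

    def test_missing_score_errors_under_strict_policy(self):
        from tests_support import make_event

        ev = make_event(cadd=None)
        with pytest.raises(ValueError, match="no scaled CADD"):
            aggregate_cadd([ev])
        with pytest.warns(UserWarning):
            assert aggregate_cadd([ev], missing_score_policy="skip") == {}

    def test_matches_brute_force_from_truth_record(self, default_cohort):
        events = detect_events_cohort(
            default_cohort.pedigrees,
            default_cohort.cnv_calls,
            default_cohort.genes,
            default_cohort.variant_calls,
        )
        sums = aggregate_cadd(events, default_cohort.cadd_table)
        expected = {}
        for t in default_cohort.truth:
            if t.scenario != 1:
                continue
            key = (t.sample_id, t.carrier)
            expected[key] = expected.get(key, 0.0) + t.scaled_cadd
        assert set(sums) == set(expected)
        for key in expected:
            assert sums[key] == pytest.approx(expected[key])


def _oracle_logistic(scores, y):
    """Independent ML fit: direct minimisation of the negative log-likelihood."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, float)

    def nll(theta):
        eta = theta[0] + theta[1] * scores
        return np.sum(np.logaddexp(0.0, eta)) - np.sum(y * eta)

    res = minimize(nll, x0=[0.0, 0.0], method="BFGS")
    return res.x[1]


class TestLogisticBurdenTest:
    def _simulate(self, rng, n=400, beta=0.15, intercept=-1.0):
        scores = rng.exponential(10.0 / math.log(10), size=n)
        p = 1.0 / (1.0 + np.exp(-(intercept + beta * scores)))
        y = rng.random(n) < p
        labels = ["proband" if yi else "parent" for yi in y]
        return scores, labels

    def test_null_gives_small_beta(self):
        rng = np.random.default_rng(0)
        scores = rng.exponential(5.0, size=2000)
        labels = ["proband" if rng.random() < 0.5 else "parent" for _ in scores]
        res = logistic_burden_test(scores, labels)
        assert res.converged
        assert abs(res.beta) < 3 * res.standard_error

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(60):
            scores = rng.exponential(5.0, size=300)
            labels = ["proband" if v < 0.5 else "parent" for v in rng.random(300)]
            res = logistic_burden_test(scores, labels)
            pvals.append(res.p_value)
        assert 0.01 < np.mean(pvals) < 0.99
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_complete_separation_flagged_not_estimated(self):
        scores = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        labels = ["parent"] * 3 + ["proband"] * 3
        res = logistic_burden_test(scores, labels)
        assert not res.converged
        assert res.beta is None and res.message

    def test_recovers_planted_beta_against_oracle(self):
        rng = np.random.default_rng(11)
        betas, oracle_betas = [], []
        for _ in range(40):
            scores, labels = self._simulate(rng)
            res = logistic_burden_test(scores, labels)
            assert res.converged
            betas.append(res.beta)
            oracle_betas.append(
                _oracle_logistic(scores, [l == "proband" for l in labels])
            )
        # the package fit and the independent optimiser agree fit-by-fit
        assert np.allclose(betas, oracle_betas, atol=1e-4)
        # and the replicate mean recovers the generating coefficient
        mc_err = np.std(betas, ddof=1) / math.sqrt(len(betas))
        assert abs(np.mean(betas) - 0.15) < 4 * mc_err + 0.005

    def test_coverage_of_wald_interval(self):
        rng = np.random.default_rng(21)
        covered = 0
        n_rep = 100
        for _ in range(n_rep):
            scores, labels = self._simulate(rng)
            res = logistic_burden_test(scores, labels)
            if not res.converged:
                continue
            if abs(res.beta - 0.15) <= 2 * res.standard_error:
                covered += 1
        assert covered / n_rep >= 0.93

    def test_input_validation(self):
        with pytest.raises(ValueError):
            logistic_burden_test([1.0], ["proband"])
        with pytest.raises(ValueError):
            logistic_burden_test([1.0, 2.0], ["proband", "proband"])
        with pytest.raises(ValueError):
            logistic_burden_test([1.0, float("inf")], ["proband", "parent"])
        with pytest.raises(ValueError):
            logistic_burden_test([1.0, 2.0], ["proband", "case"])


class TestBonferroni:
    def test_threshold_for_three_tests(self):
        assert bonferroni_threshold(0.05, 3) == pytest.approx(0.05 / 3)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_main_result_passes_its_own_correction(self):
        res = pooled_count_test(68, 41)
        assert is_significant(res.p_value, 0.05, 3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)
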