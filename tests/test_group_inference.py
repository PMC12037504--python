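"""Covariate residualization, t-tests, BH-FDR, symptom correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avhnet.connectivity import SparsityGrid, correlation_matrix, sparsity_sweep
from avhnet.errors import (CollinearityError, DegenerateVarianceError,
                           InsufficientDataError)
from avhnet.graph_metrics import compute_metrics
from avhnet.group_inference import (correlate_with_symptoms, fdr_bh,
                                    paired_test, residualize, two_sample_test)
from avhnet.null_models import MetricCurve, auc
from avhnet.synthetic_data import CohortSpec, simulate_cohort


def bh_bruteforce(p):
    """Step-up rule written out directly: cummin of sorted p*m/rank."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestResidualize:
    def test_values_linear_in_covariate_leave_no_residual(self, rng):
        age = rng.uniform(18, 45, 30)
        values = 2.0 * age + 5.0
        res = residualize(values, age[:, None])
        np.testing.assert_allclose(res, 0.0, atol=1e-9)

    def test_orthogonal_covariates_leave_centered_values(self, rng):
        values = rng.standard_normal(40)
        values -= values.mean()
        cov = rng.standard_normal((40, 2))
        cov -= cov.mean(0)
        # force exact orthogonality to the values
        cov -= np.outer(values, values @ cov) / (values @ values)
        res = residualize(values, cov)
        np.testing.assert_allclose(res, values, atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        values = rng.standard_normal(40)
        cov = rng.standard_normal((40, 3))
        design = np.column_stack([np.ones(40), cov])
        beta = np.linalg.inv(design.T @ design) @ design.T @ values
        np.testing.assert_allclose(residualize(values, cov),
                                   values - design @ beta, atol=1e-9)

    def test_collinear_design_names_offender(self, rng):
        age = rng.uniform(18, 45, 20)
        with pytest.raises(CollinearityError, match="column"):
            residualize(rng.standard_normal(20),
                        np.column_stack([age, 2 * age]))

    def test_residuals_sum_to_zero(self, rng):
        res = residualize(rng.standard_normal(25),
                          rng.standard_normal((25, 3)))
        assert abs(res.sum()) < 1e-8


class TestTTests:
    def test_identical_groups_null_result(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = two_sample_test(a, a.copy())
        assert r.statistic == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        a = rng.standard_normal(10) + 0.5
        b = rng.standard_normal(10)
        r = two_sample_test(a, b)
        sp2 = (9 * a.var(ddof=1) + 9 * b.var(ddof=1)) / 18
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 10))
        assert r.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert r.df == 18

    def test_paired_operates_on_differences(self, rng):
        pre = rng.standard_normal(12)
        post = pre + 0.3 + 0.1 * rng.standard_normal(12)
        r = paired_test(pre, post)
        d = post - pre
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        assert r.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert r.direction == 1

    def test_constant_paired_difference_degenerate(self):
        pre = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateVarianceError):
            paired_test(pre, pre + 2.0)

    def test_residualize_then_test_equals_plain_test_when_orthogonal(self, rng):
        # covariate-free synthetic data: noise covariates, orthogonalized
        a = rng.standard_normal(20) + 1.0
        b = rng.standard_normal(20)
        pooled = np.concatenate([a, b])
        cov = rng.standard_normal((40, 3))
        # project out the group-relevant structure so covariates carry none
        design = np.column_stack([np.ones(40), pooled])
        cov -= design @ np.linalg.lstsq(design, cov, rcond=None)[0]
        res = residualize(pooled, cov)
        t_resid = two_sample_test(res[:20], res[20:]).statistic
        # orthogonal covariates: residualization reduces to centering,
        # which leaves the two-sample t unchanged
        t_expected = two_sample_test(a, b).statistic
        assert t_resid == pytest.approx(t_expected, abs=1e-9)


class TestFdr:
    def test_stepup_hand_example(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_unchanged(self):
        np.testing.assert_array_equal(fdr_bh([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_single_p_unchanged(self):
        np.testing.assert_array_equal(fdr_bh([0.2]), [0.2])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 9))
    def test_matches_bruteforce_stepup_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 30))
        np.testing.assert_allclose(fdr_bh(p), bh_bruteforce(p), atol=1e-12)


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r = correlate_with_symptoms(x, 2 * x + 1)
        assert r.r == pytest.approx(1.0)

    def test_independent_inputs_within_permutation_bound(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        res = correlate_with_symptoms(x, y)
        perm = np.array([np.corrcoef(
            x, np.random.default_rng(k).permutation(y))[0, 1]
            for k in range(2000)])
        assert abs(res.r) < np.quantile(np.abs(perm), 0.99)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            correlate_with_symptoms([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlate_with_symptoms([1.0, 2.0], [3.0, 4.0])


class TestNullCalibration:
    def test_type_one_error_rate_on_null_cohorts(self):
        """With no group effect planted, ~5% of metric comparisons reject."""
        grid = SparsityGrid(0.1, 0.4, 0.1)
        rejections = 0
        total = 0
        for rep in range(250):
            spec = CohortSpec(n_hc=16, n_sz=0, t_len=120, rng_seed=50000 + rep)
            cohort = simulate_cohort(spec)
            aucs = {m: [] for m in ("cp", "lp", "eloc", "eglob")}
            for rec in cohort.records:
                cm = correlation_matrix(rec.timeseries)
                graphs = sparsity_sweep(cm, grid)
                vals = {m: [] for m in aucs}
                for g in graphs:
                    met = compute_metrics(g)
                    for m in vals:
                        vals[m].append(getattr(met, m))
                for m in vals:
                    aucs[m].append(auc(MetricCurve(m, grid.levels,
                                                   vals[m])).auc)
            for m in aucs:  # arbitrary half-split: both halves HC
                r = two_sample_test(np.array(aucs[m][:8]),
                                    np.array(aucs[m][8:]))
                rejections += r.p_raw < 0.05
                total += 1
        assert total == 1000
        assert 0.03 <= rejections / total <= 0.07
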