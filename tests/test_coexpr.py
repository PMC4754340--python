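"""Genotype classes, correlation tests, the coexpression LRT and eQTL regression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tagfun.coexpr import (
    ExpressionMatrix,
    additive_expression_assoc,
    coexpr_f_test,
    coexpr_lrt,
    correlation_difference_meta,
    correlation_test,
    expression_presence_filter,
    genotype_class,
)
from tagfun.errors import DegenerateInputError, SizeError
from tagfun.synthdata import sim_expression


class TestGenotypeClass:
    def test_hard_calls(self):
        out = genotype_class(np.array([0.0, 1.0, 2.0, 0.0]))
        assert out.tolist() == [0.0, 1.0, 1.0, 0.0]

    def test_imputed_dosage_threshold(self):
        assert genotype_class(np.array([0.4]))[0] == 0.0
        assert genotype_class(np.array([0.5]))[0] == 1.0

    def test_missing_preserved(self):
        out = genotype_class(np.array([np.nan, np.nan]))
        assert np.isnan(out).all()


class TestCorrelationTest:
    def test_perfect_fit(self):
        x = np.arange(10, dtype=float)
        res = correlation_test(x, x)
        assert res.r == 1.0
        assert res.perfect_fit
        assert res.p < 1e-15

    def test_antisymmetry(self):
        x = np.arange(10, dtype=float)
        assert correlation_test(x, -x).r == -1.0

    def test_asymptotic_p_within_permutation_oracle_ci(self):
        rng = np.random.default_rng(61)
        x = rng.standard_normal(20)
        y = 0.6 * x + rng.standard_normal(20)
        res = correlation_test(x, y)
        # oracle: 10^5 random permutations of y, two-sided on |r|
        B = 100_000
        perm = np.array([y[rng.permutation(20)] for _ in range(B)])
        xc = x - x.mean()
        pc = perm - perm.mean(axis=1, keepdims=True)
        r_perm = (pc @ xc) / np.sqrt((pc**2).sum(axis=1) * (xc**2).sum())
        p_perm = np.mean(np.abs(r_perm) >= abs(res.r))
        half = 2.576 * math.sqrt(p_perm * (1 - p_perm) / B)
        assert p_perm - half - 0.005 <= res.p <= p_perm + half + 0.005

    def test_spearman_matches_scipy(self):
        rng = np.random.default_rng(62)
        x = rng.standard_normal(50)
        y = x**3 + rng.standard_normal(50)
        res = correlation_test(x, y, method="spearman")
        ref = stats.spearmanr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)

    def test_bootstrap_p_reported(self):
        rng = np.random.default_rng(63)
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        res = correlation_test(x, y, bootstrap_b=2000, seed=64)
        assert res.p_bootstrap is not None
        assert 0 <= res.p_bootstrap <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlation_test(np.ones(10), np.arange(10.0))


def _classed_data(n0, n1, r0, r1, seed):
    cls = np.concatenate([np.zeros(n0), np.ones(n1)])
    tf, target = sim_expression(cls, r0, r1, seed=seed)
    return target, tf, cls


class TestCoexprLrt:
    def test_statistic_matches_loglikelihood_oracle(self):
        """n*ln(RSS_r/RSS_f) equals twice the Gaussian log-likelihood gap (statsmodels)."""
        sm = pytest.importorskip("statsmodels.api")
        target, tf, cls = _classed_data(25, 15, 0.5, 0.1, seed=1)
        res = coexpr_lrt(target, tf, cls)
        t_std = (target - target.mean()) / target.std(ddof=1)
        f_std = (tf - tf.mean()) / tf.std(ddof=1)
        X_red = np.column_stack([np.ones(40), f_std, cls])
        X_full = np.column_stack([X_red, f_std * cls])
        llf_red = sm.OLS(t_std, X_red).fit().llf
        llf_full = sm.OLS(t_std, X_full).fit().llf
        assert res.lrt_stat == pytest.approx(2 * (llf_full - llf_red), abs=1e-8)

    def test_null_type_one_error_calibrated(self):
        rejections = 0
        B = 400
        for s in range(B):
            target, tf, cls = _classed_data(250, 250, 0.3, 0.3, seed=1000 + s)
            rejections += coexpr_lrt(target, tf, cls).p_two_sided < 0.05
        rate = rejections / B
        half = 1.96 * math.sqrt(0.05 * 0.95 / B)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_delta_estimates_correlation_difference(self):
        target, tf, cls = _classed_data(10000, 10000, 0.24, 0.15, seed=65)
        res = coexpr_lrt(target, tf, cls)
        assert abs(res.delta_hat - (res.r_class1 - res.r_class0)) < 0.01

    def test_affine_invariance(self):
        target, tf, cls = _classed_data(100, 60, 0.4, 0.1, seed=66)
        base = coexpr_lrt(target, tf, cls)
        scaled = coexpr_lrt(3.7 * target - 11.0, -0.2 * tf + 5.0, cls)
        assert scaled.lrt_stat == pytest.approx(base.lrt_stat, abs=1e-8)

    def test_small_class_rejected(self):
        target, tf, cls = _classed_data(30, 2, 0.3, 0.3, seed=67)
        with pytest.raises(SizeError):
            coexpr_lrt(target, tf, cls)

    def test_one_sided_convention(self):
        target, tf, cls = _classed_data(300, 60, 0.6, 0.0, seed=68)
        res = coexpr_lrt(target, tf, cls)
        assert res.delta_hat < 0  # attenuation in the risk class
        assert res.p_one_sided == pytest.approx(res.p_two_sided / 2)

    def test_f_variant_agrees_at_large_n(self):
        target, tf, cls = _classed_data(2000, 2000, 0.4, 0.2, seed=69)
        lrt = coexpr_lrt(target, tf, cls)
        _, p_f = coexpr_f_test(target, tf, cls)
        assert p_f == pytest.approx(lrt.p_two_sided, rel=0.1)

    def test_power_regression_guard(self):
        # delta = 0.3 at n = 450/450 should reject more than half the time
        rej = 0
        B = 200
        for s in range(B):
            target, tf, cls = _classed_data(450, 450, 0.45, 0.15, seed=3000 + s)
            rej += coexpr_lrt(target, tf, cls).p_one_sided < 0.05
        assert rej / B > 0.5


class TestCorrelationDifferenceMeta:
    def _res(self, delta, se, seed):
        target, tf, cls = _classed_data(50, 50, 0.3, 0.3, seed=seed)
        r = coexpr_lrt(target, tf, cls)
        r.delta_hat, r.delta_se = delta, se
        return r

    def test_single_result_passthrough(self):
        r = self._res(-0.09, 0.05, 70)
        rec = correlation_difference_meta([r])
        assert rec.beta_comb == pytest.approx(-0.09)
        assert rec.se_comb == pytest.approx(0.05)

    def test_two_equal_results_halve_variance(self):
        r = self._res(-0.09, 0.05, 71)
        rec = correlation_difference_meta([r, r])
        assert rec.beta_comb == pytest.approx(-0.09)
        assert rec.se_comb == pytest.approx(0.05 / math.sqrt(2))

    def test_matches_wls_oracle(self):
        rs = [self._res(d, s, 72 + i) for i, (d, s) in enumerate([(-0.1, 0.04), (0.02, 0.08), (-0.05, 0.06)])]
        rec = correlation_difference_meta(rs)
        w = np.array([1 / r.delta_se**2 for r in rs])
        d = np.array([r.delta_hat for r in rs])
        assert rec.beta_comb == pytest.approx(float((w * d).sum() / w.sum()), abs=1e-12)


class TestAdditiveExpressionAssoc:
    def test_hand_ols(self):
        dose = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        expr = np.array([1.0, 0.8, 0.6, 1.1, 0.9, 0.7])
        beta, se, p = additive_expression_assoc(expr, dose)
        assert beta == pytest.approx(-0.2, abs=1e-12)
        # hand fit: intercept 1.05, residuals +-0.05 -> RSS = 0.015
        resid = expr - (1.05 + beta * dose)
        assert float(resid @ resid) == pytest.approx(0.015, abs=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(73)
        pvals = []
        for _ in range(400):
            dose = rng.binomial(2, 0.3, 80).astype(float)
            expr = rng.standard_normal(80)
            pvals.append(additive_expression_assoc(expr, dose)[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_log2_transform_matches_manual(self):
        rng = np.random.default_rng(74)
        dose = rng.binomial(2, 0.4, 60).astype(float)
        expr = np.exp(rng.standard_normal(60))
        b1, _, _ = additive_expression_assoc(expr, dose, log2_transform=True)
        b2, _, _ = additive_expression_assoc(np.log2(expr), dose)
        assert b1 == pytest.approx(b2, abs=1e-12)

    def test_constant_dose_rejected(self):
        with pytest.raises(DegenerateInputError):
            additive_expression_assoc(np.arange(10.0), np.ones(10))


class TestPresenceFilter:
    def _mat(self, values):
        return ExpressionMatrix(pd.DataFrame(values))

    def test_expressed_gene_retained(self):
        vals = pd.DataFrame({"g1": [0.02] * 80 + [0.0] * 20})
        assert expression_presence_filter(ExpressionMatrix(vals)) == ["g1"]

    def test_boundary_is_strict(self):
        vals = pd.DataFrame({"g1": [0.02] * 75 + [0.0] * 25})
        assert expression_presence_filter(ExpressionMatrix(vals)) == []

    def test_empty_matrix(self):
        assert expression_presence_filter(ExpressionMatrix(pd.DataFrame())) == []
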