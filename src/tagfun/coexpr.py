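"""Expression analytics around a regulatory SNP.

The central test asks whether the correlation between a transcription
factor's expression and a target gene's expression differs by genotype
class at the SNP (0 risk alleles versus 1 or more).  Two nested linear
models are compared: the reduced model regresses target on TF expression
and genotype class; the full model adds the TF x class interaction.
Because both expression columns are standardized to mean 0 / variance 1,
the interaction coefficient is interpretable as a difference in
correlation between classes, and per-population estimates can be pooled
by inverse-variance weighting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ParameterError, SizeError
from .meta import MetaRecord, StudyEffect, fixed_effects_meta

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with a transform tag."""

    values: pd.DataFrame  # index = sample ids, columns = gene ids
    transform_tag: str = "raw"  # raw | log2 | rank-normal | standardized
    units: str = ""

    def standardized(self) -> "ExpressionMatrix":
        v = self.values
        out = (v - v.mean()) / v.std(ddof=1)
        return ExpressionMatrix(out, "standardized", self.units)


@dataclass
class CoexprResult:
    """Genotype-dependent coexpression LRT result.

    ``delta_hat`` is the interaction coefficient of the full model; on
    standardized data it estimates r_class1 - r_class0.
    """

    r_class0: float
    r_class1: float
    delta_hat: float
    delta_se: float
    lrt_stat: float
    p_two_sided: float
    p_one_sided: float
    n_class0: int
    n_class1: int


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str
    p_bootstrap: float | None = None
    perfect_fit: bool = False


def genotype_class(dose: np.ndarray) -> np.ndarray:
    """Collapse dosages to the 0-risk-alleles (0) vs risk-allele-carrier (1) classes.

    Imputed-dosage convention: class 1 iff dose >= 0.5.  Missing stays missing.
    """
    dose = np.asarray(dose, dtype=float)
    out = np.where(dose >= 0.5, 1.0, 0.0)
    return np.where(np.isnan(dose), np.nan, out)


def correlation_test(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "pearson",
    bootstrap_b: int = 0,
    seed: int = 0,
) -> CorrelationResult:
    """Correlation coefficient with the asymptotic t significance test.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 df, two-sided.  Spearman uses
    average ranks for ties with the same t approximation.  When
    ``bootstrap_b`` > 0 a percentile-bootstrap P (sign test on the
    resampled r distribution) is reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise SizeError("need at least 4 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("constant input")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ParameterError("method must be 'pearson' or 'spearman'")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1 - 1e-14:
        return CorrelationResult(float(np.sign(r)), 1e-300, n, method, perfect_fit=True)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    p_boot = None
    if bootstrap_b > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(bootstrap_b, n))
        xs, ys = x[idx], y[idx]
        xs = xs - xs.mean(axis=1, keepdims=True)
        ys = ys - ys.mean(axis=1, keepdims=True)
        num = (xs * ys).sum(axis=1)
        den = np.sqrt((xs**2).sum(axis=1) * (ys**2).sum(axis=1))
        rb = np.where(den > 0, num / den, 0.0)
        lo = float(np.mean(rb <= 0))
        hi = float(np.mean(rb >= 0))
        p_boot = min(1.0, 2 * min(lo, hi))
    return CorrelationResult(r, p, n, method, p_boot)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant expression column")
    return (v - v.mean()) / sd


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares fit returning (coef, cov, rss)."""
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    n, k = X.shape
    sigma2 = rss / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef, cov, rss


def coexpr_lrt(
    target: np.ndarray,
    tf: np.ndarray,
    class01: np.ndarray,
    one_sided_direction: int = -1,
) -> CoexprResult:
    """Likelihood-ratio test for genotype-dependent coexpression.

    Reduced model: target ~ tf + class.  Full model adds tf x class.
    LRT = n * ln(RSS_reduced / RSS_full), chi-square 1 df.  Expression
    columns are standardized internally (mean 0, variance 1) so the
    interaction coefficient reads as a correlation difference.  The
    one-sided P assumes attenuation in the risk class (interaction sign
    ``one_sided_direction``, default negative): it is half the two-sided
    P when the sign matches, else 1 minus the half.
    """
    target = np.asarray(target, dtype=float)
    tf = np.asarray(tf, dtype=float)
    cls = np.asarray(class01, dtype=float)
    ok = ~np.isnan(target) & ~np.isnan(tf) & ~np.isnan(cls)
    if (~ok).sum():
        log.info("coexpr_lrt: dropped %d incomplete samples", int((~ok).sum()))
    target, tf, cls = target[ok], tf[ok], cls[ok]
    n0 = int((cls == 0).sum())
    n1 = int((cls == 1).sum())
    if n0 < 3 or n1 < 3:
        raise SizeError("each genotype class needs at least 3 samples")
    target = _standardize(target)
    tf = _standardize(tf)
    n = len(target)

    ones = np.ones(n)
    X_red = np.column_stack([ones, tf, cls])
    X_full = np.column_stack([ones, tf, cls, tf * cls])
    _, _, rss_red = _ols_rss(X_red, target)
    coef_f, cov_f, rss_full = _ols_rss(X_full, target)
    lrt = n * math.log(rss_red / rss_full) if rss_full > 0 else float("inf")
    lrt = max(lrt, 0.0)
    p2 = float(stats.chi2.sf(lrt, df=1))
    delta = float(coef_f[3])
    delta_se = float(math.sqrt(cov_f[3, 3]))
    if math.copysign(1, delta) == one_sided_direction:
        p1 = p2 / 2
    else:
        p1 = 1 - p2 / 2
    r0 = float(np.corrcoef(tf[cls == 0], target[cls == 0])[0, 1])
    r1 = float(np.corrcoef(tf[cls == 1], target[cls == 1])[0, 1])
    return CoexprResult(r0, r1, delta, delta_se, lrt, p2, p1, n0, n1)


def coexpr_f_test(target: np.ndarray, tf: np.ndarray, class01: np.ndarray) -> tuple[float, float]:
    """F-test variant of the nested-model comparison (1 and n-4 df)."""
    target = np.asarray(target, dtype=float)
    tf = _standardize(np.asarray(tf, dtype=float))
    cls = np.asarray(class01, dtype=float)
    target = _standardize(target)
    n = len(target)
    ones = np.ones(n)
    _, _, rss_red = _ols_rss(np.column_stack([ones, tf, cls]), target)
    _, _, rss_full = _ols_rss(np.column_stack([ones, tf, cls, tf * cls]), target)
    f = (rss_red - rss_full) / (rss_full / (n - 4))
    return float(f), float(stats.f.sf(f, 1, n - 4))


def correlation_difference_meta(results: list[CoexprResult]) -> MetaRecord:
    """Inverse-variance pooling of per-population correlation differences."""
    effects = [
        StudyEffect(f"pop{i}", r.delta_hat, r.delta_se) for i, r in enumerate(results)
    ]
    return fixed_effects_meta(effects)


def additive_expression_assoc(
    expr: np.ndarray,
    dose: np.ndarray,
    covariates: np.ndarray | None = None,
    log2_transform: bool = False,
) -> tuple[float, float, float]:
    """OLS of (optionally log2) expression on allele dose, t-test on the dose term.

    Serves both the cis-eQTL dosage regression and the exon-usage
    regression.  Returns (beta, se, p_two_sided).
    """
    expr = np.asarray(expr, dtype=float)
    dose = np.asarray(dose, dtype=float)
    cov = np.asarray(covariates, dtype=float) if covariates is not None else None
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    ok = ~np.isnan(expr) & ~np.isnan(dose)
    if cov is not None:
        ok &= ~np.isnan(cov).any(axis=1)
    expr, dose = expr[ok], dose[ok]
    cov = cov[ok] if cov is not None else None
    if np.std(dose) == 0:
        raise DegenerateInputError("constant dose vector")
    if log2_transform:
        if (expr <= 0).any():
            raise ParameterError("log2 transform requires positive expression values")
        expr = np.log2(expr)
    n = len(expr)
    X = np.column_stack([np.ones(n), dose] + ([cov] if cov is not None else []))
    if n <= X.shape[1] + 1:
        raise SizeError("too few samples for the number of parameters")
    coef, covm, rss = _ols_rss(X, expr)
    beta = float(coef[1])
    if rss <= 1e-300:
        log.warning("additive_expression_assoc: perfect fit; p set to 0")
        return beta, 0.0, 0.0
    se = float(math.sqrt(covm[1, 1]))
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), df=n - X.shape[1]))
    return beta, se, p


def expression_presence_filter(
    expr: ExpressionMatrix, min_value: float = 0.01, min_fraction: float = 0.75
) -> list[str]:
    """Genes expressed above ``min_value`` in strictly more than ``min_fraction`` of samples."""
    v = expr.values
    if v.shape[1] == 0 or v.shape[0] == 0:
        return []
    frac = (v > min_value).mean(axis=0)
    return list(v.columns[frac > min_fraction])
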