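"""Genotype/sample QC filters and additive allele-dosage association tests.

The association model throughout is the additive allele-dosage logistic
regression: logit P(case) = alpha + beta * dose + covariates, where ``dose``
counts copies of the effect allele (fractional doses allowed for imputed
posterior means).  Conditional tests enter other SNPs' dosages as covariates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ParameterError, SizeError

log = logging.getLogger(__name__)

Z95 = 1.959964  # two-sided 95% normal quantile, meta-analysis software convention
MIN_SNPS_FOR_INBREEDING = 50  # per-sample F needs a genome-scale SNP count


# ---------------------------------------------------------------------------
# containers


@dataclass
class VariantInfo:
    id: str
    chrom: str = "9"
    pos: int = 0
    effect_allele: str = "A"
    other_allele: str = "G"


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix.

    ``dosages`` holds reals in [0, 2] with NaN for missing.  Rows are
    samples, columns are variants, aligned with ``samples`` / ``variants``.
    """

    dosages: np.ndarray
    variants: list[VariantInfo]
    samples: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ParameterError("dosages must be a 2-D samples x variants matrix")
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ParameterError("dosage shape does not match sample/variant metadata")
        if len(set(self.samples)) != len(self.samples):
            raise ParameterError("sample ids must be unique")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ParameterError("variant ids must be unique")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ParameterError("dosages must lie in [0, 2] or be missing")

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def dose(self, snp_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"variant {snp_id!r} not in matrix") from None
        return self.dosages[:, j]

    def subset_variants(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_ids.index(s) for s in keep]
        return GenotypeMatrix(self.dosages[:, idx], [self.variants[i] for i in idx], list(self.samples))


@dataclass
class PhenotypeTable:
    """Case/control status (1 = case) plus named covariate vectors."""

    status: np.ndarray
    covariates: pd.DataFrame | None = None
    samples: list[str] | None = None

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=float)
        bad = ~np.isin(self.status[~np.isnan(self.status)], [0.0, 1.0])
        if bad.any():
            raise ParameterError("status must be 0 (control) / 1 (case)")
        if self.covariates is not None and len(self.covariates) != len(self.status):
            raise ParameterError("covariate table length does not match status")

    @property
    def n_case(self) -> int:
        return int(np.nansum(self.status == 1))

    @property
    def n_control(self) -> int:
        return int(np.nansum(self.status == 0))

    def covariate_matrix(self, names: list[str] | None) -> np.ndarray:
        if not names:
            return np.empty((len(self.status), 0))
        if self.covariates is None:
            raise ParameterError("no covariates available")
        return self.covariates[list(names)].to_numpy(dtype=float)


@dataclass
class QcThresholds:
    """SNP/sample exclusion thresholds of a standard pre-imputation GWAS QC."""

    maf_min: float = 0.01
    snp_missing_max: float = 0.05
    sample_missing_max: float = 0.02
    hwe_p_min: float = 1e-4
    diff_missing_p_min: float = 0.05
    inbreeding_f_max: float = 0.05


@dataclass
class QcReport:
    """Exclusion counts per rule, attributed to the first triggering rule."""

    samples_call_rate: int = 0
    samples_inbreeding: int = 0
    snps_missingness: int = 0
    snps_maf: int = 0
    snps_hwe: int = 0
    snps_diff_missing: int = 0
    dropped_samples: list[str] = field(default_factory=list)
    dropped_snps: dict[str, str] = field(default_factory=dict)

    @property
    def n_snps_removed(self) -> int:
        return len(self.dropped_snps)


@dataclass
class AssocRecord:
    """Per-SNP additive-dose association result (log-OR scale)."""

    snp_id: str
    effect_allele: str
    beta: float
    se: float
    p_two_sided: float
    p_one_sided: float
    n_case: int
    n_control: int
    conditioned_on: list[str] = field(default_factory=list)
    converged: bool = True

    @property
    def or_point(self) -> float:
        return math.exp(self.beta)

    @property
    def ci95(self) -> tuple[float, float]:
        return (math.exp(self.beta - Z95 * self.se), math.exp(self.beta + Z95 * self.se))


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> tuple[float, float, bool]:
    """1-df chi-square test of Hardy-Weinberg proportions.

    Compares observed genotype counts with the p^2 / 2pq / q^2 expectations
    at the sample allele frequency.  Returns ``(chi2, p, degenerate)``;
    a monomorphic SNP returns ``(0.0, 1.0, True)``.
    """
    counts = np.array([n_hom_effect, n_het, n_hom_other], dtype=float)
    if (counts < 0).any():
        raise ParameterError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise SizeError("need at least one genotyped sample")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 0.0, 1.0, True
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1)), False


def _hard_calls(dose: np.ndarray) -> np.ndarray:
    """Round dosages to 0/1/2 hard calls, preserving NaN."""
    calls = np.round(dose)
    return np.clip(calls, 0, 2)


def _genotype_counts(dose: np.ndarray) -> tuple[int, int, int]:
    calls = _hard_calls(dose[~np.isnan(dose)])
    return (int((calls == 2).sum()), int((calls == 1).sum()), int((calls == 0).sum()))


# ---------------------------------------------------------------------------
# QC pipeline


def inbreeding_coefficients(geno: GenotypeMatrix, maf_min: float = 0.01) -> np.ndarray:
    """Per-sample inbreeding F = 1 - observed het / expected het.

    Expected heterozygosity is summed over polymorphic SNPs (MAF above
    ``maf_min``) at their sample allele frequencies.
    """
    d = geno.dosages
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    use = maf >= maf_min
    if not use.any():
        return np.zeros(d.shape[0])
    calls = _hard_calls(d[:, use])
    het_obs = np.nansum(calls == 1, axis=1).astype(float)
    p = freq[use]
    exp_h = 2 * p * (1 - p)
    obs_mask = ~np.isnan(calls)
    het_exp = obs_mask @ exp_h
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1.0 - het_obs / het_exp
    return np.where(het_exp > 0, f, 0.0)


def apply_qc(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, PhenotypeTable, QcReport]:
    """Apply sample then SNP QC filters in fixed order.

    Order: sample call rate, sample |F| (inbreeding), SNP missingness,
    MAF, HWE, case/control differential missingness.  Each removed SNP is
    attributed to the first rule that triggers.
    """
    thr = thresholds or QcThresholds()
    if geno.dosages.shape[0] != len(pheno.status):
        raise ParameterError("genotype and phenotype tables are not sample-aligned")
    report = QcReport()
    d = geno.dosages

    # -- sample filters
    miss_rate = np.isnan(d).mean(axis=1)
    keep_s = miss_rate <= thr.sample_missing_max
    report.samples_call_rate = int((~keep_s).sum())
    # per-sample F is only meaningful with many informative SNPs; on narrow
    # locus panels the estimator is pure noise, so the rule is not applied
    if d.shape[1] >= MIN_SNPS_FOR_INBREEDING and np.isfinite(thr.inbreeding_f_max):
        f = inbreeding_coefficients(geno, thr.maf_min)
        bad_f = (np.abs(f) > thr.inbreeding_f_max) & keep_s
    else:
        if np.isfinite(thr.inbreeding_f_max):
            log.info("apply_qc: < %d SNPs, inbreeding filter skipped", MIN_SNPS_FOR_INBREEDING)
        bad_f = np.zeros(len(keep_s), dtype=bool)
    report.samples_inbreeding = int(bad_f.sum())
    keep_s &= ~bad_f
    report.dropped_samples = [s for s, k in zip(geno.samples, keep_s) if not k]
    d = d[keep_s]
    status = pheno.status[keep_s]
    covs = pheno.covariates.loc[keep_s].reset_index(drop=True) if pheno.covariates is not None else None
    samples = [s for s, k in zip(geno.samples, keep_s) if k]

    # -- SNP filters, first-triggering-rule attribution
    keep_v = np.ones(d.shape[1], dtype=bool)
    miss_v = np.isnan(d).mean(axis=0)
    for j, v in enumerate(geno.variants):
        if miss_v[j] > thr.snp_missing_max:
            report.dropped_snps[v.id] = "missingness"
            keep_v[j] = False
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    for j, v in enumerate(geno.variants):
        if keep_v[j] and (np.isnan(maf[j]) or maf[j] < thr.maf_min):
            report.dropped_snps[v.id] = "maf"
            keep_v[j] = False
    for j, v in enumerate(geno.variants):
        if not keep_v[j]:
            continue
        _, p_hwe, degen = hwe_test(*_genotype_counts(d[:, j]))
        if not degen and p_hwe < thr.hwe_p_min:
            report.dropped_snps[v.id] = "hwe"
            keep_v[j] = False
    is_case = status == 1
    for j, v in enumerate(geno.variants):
        if not keep_v[j]:
            continue
        p_dm = _diff_missingness_p(np.isnan(d[:, j]), is_case)
        if p_dm is not None and p_dm < thr.diff_missing_p_min:
            report.dropped_snps[v.id] = "diff_missingness"
            keep_v[j] = False

    report.snps_missingness = sum(r == "missingness" for r in report.dropped_snps.values())
    report.snps_maf = sum(r == "maf" for r in report.dropped_snps.values())
    report.snps_hwe = sum(r == "hwe" for r in report.dropped_snps.values())
    report.snps_diff_missing = sum(r == "diff_missingness" for r in report.dropped_snps.values())

    if not keep_v.any():
        log.warning("QC removed every SNP")
    out_geno = GenotypeMatrix(d[:, keep_v], [v for v, k in zip(geno.variants, keep_v) if k], samples)
    out_pheno = PhenotypeTable(status, covs, samples)
    return out_geno, out_pheno, report


def _diff_missingness_p(missing: np.ndarray, is_case: np.ndarray) -> float | None:
    """Chi-square p for case/control differential missingness; None if no missingness."""
    if not missing.any() or missing.all():
        return None
    table = np.array(
        [
            [(missing & is_case).sum(), (~missing & is_case).sum()],
            [(missing & ~is_case).sum(), (~missing & ~is_case).sum()],
        ],
        dtype=float,
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return None
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


# ---------------------------------------------------------------------------
# logistic association


def _irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 25):
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Returns (beta, cov, converged).  Convergence is on the change in
    log-likelihood; non-convergence (including quasi-complete separation,
    where coefficients diverge) is reported, not raised.
    """
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.max(w) < 1e-12:
            break
        XtW = X.T * w
        H = XtW @ X
        try:
            step = np.linalg.solve(H, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    # quasi-complete separation: absurd coefficients or exploding SEs
    if converged and (np.any(np.abs(beta) > 25) or np.any(np.diag(cov) > 1e6)):
        converged = False
    return beta, cov, converged


def logistic_assoc(
    dose: np.ndarray,
    pheno: PhenotypeTable,
    covariates: list[str] | None = None,
    condition_on: dict[str, np.ndarray] | None = None,
    snp_id: str = "snp",
    effect_allele: str = "A",
    one_sided_direction: int = +1,
) -> AssocRecord:
    """Additive allele-dosage logistic regression with Wald inference.

    Conditioning SNPs are entered as additional covariates.  The one-sided
    P halves the two-sided P when the fitted beta matches the prespecified
    direction (+1 = risk), and is 1 - half otherwise.  Samples with missing
    dose, status or covariates are dropped complete-case.
    """
    dose = np.asarray(dose, dtype=float)
    cov_mat = pheno.covariate_matrix(covariates)
    cond = condition_on or {}
    cond_names = list(cond.keys())
    cond_mat = (
        np.column_stack([np.asarray(cond[c], dtype=float) for c in cond_names])
        if cond_names
        else np.empty((len(dose), 0))
    )
    X_extra = np.column_stack([cov_mat, cond_mat]) if (cov_mat.size or cond_mat.size) else np.empty((len(dose), 0))
    y = pheno.status

    ok = ~np.isnan(dose) & ~np.isnan(y)
    if X_extra.size:
        ok &= ~np.isnan(X_extra).any(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("logistic_assoc: dropped %d incomplete samples", n_drop)
    dose, y = dose[ok], y[ok]
    X_extra = X_extra[ok]

    n_case, n_control = int((y == 1).sum()), int((y == 0).sum())
    if n_case < 1 or n_control < 1:
        raise SizeError("need at least one case and one control")
    if np.nanstd(dose) == 0:
        raise DegenerateInputError("dose vector is constant among analyzed samples")

    X = np.column_stack([np.ones(len(dose)), dose, X_extra])
    beta_vec, cov, converged = _irls_logistic(X, y)
    if not converged:
        log.warning("logistic_assoc: model for %s did not converge; P=NA", snp_id)
        return AssocRecord(snp_id, effect_allele, float("nan"), float("nan"), float("nan"),
                           float("nan"), n_case, n_control, cond_names, converged=False)
    beta = float(beta_vec[1])
    se = float(math.sqrt(cov[1, 1]))
    z = beta / se
    p2 = float(2 * stats.norm.sf(abs(z)))
    p2 = min(max(p2, np.nextafter(0, 1)), 1.0)
    if math.copysign(1, beta) == one_sided_direction:
        p1 = p2 / 2
    else:
        p1 = 1 - p2 / 2
    return AssocRecord(snp_id, effect_allele, beta, se, p2, p1, n_case, n_control, cond_names)


def score_assoc(
    dose: np.ndarray,
    pheno: PhenotypeTable,
    covariates: list[str] | None = None,
) -> tuple[float, float]:
    """Expected-dosage score test of the dose term (chi2, p), 1 df.

    Efficient score statistic at the null fit (covariates only); agrees
    asymptotically with the Wald test of ``logistic_assoc``.
    """
    dose = np.asarray(dose, dtype=float)
    y = pheno.status
    cov_mat = pheno.covariate_matrix(covariates)
    ok = ~np.isnan(dose) & ~np.isnan(y)
    if cov_mat.size:
        ok &= ~np.isnan(cov_mat).any(axis=1)
    dose, y = dose[ok], y[ok]
    cov_mat = cov_mat[ok] if cov_mat.size else np.empty((len(dose), 0))
    if np.nanstd(dose) == 0:
        raise DegenerateInputError("dose vector is constant among analyzed samples")
    X0 = np.column_stack([np.ones(len(dose)), cov_mat])
    beta0, _, _ = _irls_logistic(X0, y)
    mu = 1.0 / (1.0 + np.exp(-np.clip(X0 @ beta0, -30, 30)))
    w = mu * (1 - mu)
    u = float(dose @ (y - mu))
    # variance of the score with the null nuisance fit projected out
    xw = X0.T @ (w * dose)
    v = float((w * dose) @ dose - xw @ np.linalg.solve((X0.T * w) @ X0, xw))
    chi2 = u * u / v
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# homogeneity chi-square and analytic power


def chisq_homogeneity(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square test of homogeneity on a 2 x k count table.

    (k-1) degrees of freedom, no continuity correction.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ParameterError("expected a 2 x k table with k >= 2")
    if (table < 0).any():
        raise ParameterError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise DegenerateInputError("table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def allelic_power(
    odds_ratio: float,
    maf: float,
    n_case: int,
    n_control: int,
    alpha: float = 0.05,
    sided: str = "one",
) -> float:
    """Analytic power of the allelic 2x2 case/control comparison.

    Normal approximation on the log odds ratio: the control effect-allele
    frequency is ``maf``; the case frequency follows from the allelic OR;
    Var(log OR) uses expected allele counts under the alternative
    (2N chromosomes per group).
    """
    if odds_ratio <= 0 or not (0 < maf < 1) or not (0 < alpha < 1):
        raise ParameterError("odds_ratio > 0, 0 < maf < 1 and 0 < alpha < 1 required")
    if n_case < 1 or n_control < 1:
        raise SizeError("need positive case and control counts")
    if sided not in ("one", "two"):
        raise ParameterError("sided must be 'one' or 'two'")
    p0 = maf
    odds1 = odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    var = (
        1 / (2 * n_case * p1)
        + 1 / (2 * n_case * (1 - p1))
        + 1 / (2 * n_control * p0)
        + 1 / (2 * n_control * (1 - p0))
    )
    ncp = abs(math.log(odds_ratio)) / math.sqrt(var)
    if sided == "one":
        return float(stats.norm.sf(stats.norm.isf(alpha) - ncp))
    zc = stats.norm.isf(alpha / 2)
    return float(stats.norm.sf(zc - ncp) + stats.norm.cdf(-zc - ncp))
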