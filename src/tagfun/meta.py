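"""Fixed-effects inverse-variance meta-analysis with heterogeneity statistics.

Per-study effects are log odds ratios with standard errors; printed
"OR (95% CI)" cells are converted back to that scale with ``se_from_ci``.
Heterogeneity is summarized by Cochran's Q and I^2; genomic inflation by
the median-based lambda.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError, SizeError

Z95 = 1.959964
CHI2_1DF_MEDIAN = 0.45494  # median of the 1-df chi-square distribution


@dataclass
class StudyEffect:
    label: str
    beta: float
    se: float

    def __post_init__(self):
        if not self.se > 0:
            raise ParameterError(f"study {self.label!r}: se must be positive")


@dataclass
class MetaRecord:
    beta_comb: float
    se_comb: float
    p_two_sided: float
    q: float
    q_p: float
    i2: float
    k: int
    snp_id: str = ""

    @property
    def or_comb(self) -> float:
        return math.exp(self.beta_comb)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.beta_comb - Z95 * self.se_comb),
            math.exp(self.beta_comb + Z95 * self.se_comb),
        )


class AsymmetricCIWarning(UserWarning):
    """The printed CI is not symmetric on the log scale beyond rounding tolerance."""


def se_from_ci(or_point: float, ci_lo: float, ci_hi: float, level: float = 0.95) -> float:
    """Recover the log-scale SE implicit in a printed OR (CI_lo - CI_hi) cell.

    se = (ln hi - ln lo) / (2 z).  Warns when the point estimate is not the
    geometric midpoint of the interval beyond what 2-decimal printing can
    explain (|ln(or^2 / (lo*hi))| > 0.02).
    """
    if not (0 < ci_lo <= ci_hi):
        raise ParameterError("require 0 < ci_lo <= ci_hi")
    if not (ci_lo <= or_point <= ci_hi):
        raise ParameterError("point estimate lies outside its CI")
    if ci_lo == ci_hi:
        warnings.warn("degenerate CI (lo == hi): se = 0", AsymmetricCIWarning)
        return 0.0
    z = stats.norm.isf((1 - level) / 2)
    se = (math.log(ci_hi) - math.log(ci_lo)) / (2 * z)
    asym = abs(math.log(or_point**2 / (ci_lo * ci_hi)))
    if asym > 0.02:
        warnings.warn(
            f"CI asymmetric on log scale (|ln(or^2/(lo*hi))| = {asym:.3f} > 0.02); "
            "the printed interval may not be Wald-normal",
            AsymmetricCIWarning,
        )
    return se


def fixed_effects_meta(effects: list[StudyEffect], snp_id: str = "") -> MetaRecord:
    """Inverse-variance weighted fixed-effects combination.

    beta = sum(w_i b_i) / sum(w_i), w_i = 1/se_i^2; Cochran's Q on k-1 df;
    I^2 = max(0, (Q - (k-1))/Q) * 100.
    """
    if len(effects) == 0:
        raise SizeError("need at least one study")
    b = np.array([e.beta for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    p = max(p, 5e-324)
    q = float(np.sum(w * (b - beta) ** 2))
    k = len(effects)
    if k > 1:
        q_p = float(stats.chi2.sf(q, df=k - 1))
        i2 = max(0.0, (q - (k - 1)) / q) * 100 if q > 0 else 0.0
    else:
        q_p, i2 = 1.0, 0.0
    return MetaRecord(beta, se, p, q, q_p, i2, k, snp_id)


def lambda_gc(chi2_or_p: np.ndarray, input_type: str = "chi2") -> float:
    """Genomic-control inflation factor: median chi-square over its null median.

    ``input_type='p'`` converts two-sided P values to 1-df chi-square
    quantiles first.
    """
    x = np.asarray(chi2_or_p, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise SizeError("empty statistic vector")
    if input_type == "p":
        x = stats.chi2.isf(x, df=1)
    elif input_type != "chi2":
        raise ParameterError("input_type must be 'chi2' or 'p'")
    return float(np.median(x) / CHI2_1DF_MEDIAN)


def heterogeneity_filter(
    records: list[MetaRecord], i2_max: float = 50.0
) -> tuple[list[MetaRecord], int]:
    """Drop records with I^2 above ``i2_max`` percent; returns (kept, n_excluded)."""
    kept = [r for r in records if r.i2 <= i2_max]
    return kept, len(records) - len(kept)
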