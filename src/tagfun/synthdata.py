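"""Synthetic inputs for every pipeline stage.

Generates (a) phased two-locus haplotype panels with specified allele
frequencies and r^2, (b) case/control genotypes under an additive log-odds
disease model, (c) expression pairs whose correlation differs by genotype
class, and (d) null 1-df chi-square sets for genomic-control calibration.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FeasibilityError, ParameterError, SizeError
from .qc_assoc import GenotypeMatrix, PhenotypeTable, VariantInfo

DEFAULT_PREVALENCE = 0.10  # baseline disease prevalence of the logistic sampler


@dataclass
class HaplotypePanel:
    """Phased 0/1 alleles, haplotypes x variants (1 = effect/risk allele)."""

    alleles: np.ndarray
    variants: list[VariantInfo]

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ParameterError("alleles must be a 2-D haplotypes x variants matrix")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ParameterError("panel alleles must be 0/1")
        if self.alleles.shape[1] != len(self.variants):
            raise ParameterError("allele columns do not match variant metadata")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ParameterError("variant ids must be unique")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def column(self, snp_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"variant {snp_id!r} not in panel") from None
        return self.alleles[:, j]


@dataclass
class SimConfig:
    """Two-locus case/control study design."""

    freq_causal: float = 0.25
    freq_tag: float = 0.25
    r2_target: float = 0.6
    odds_ratio: float = 1.5
    n_case: int = 203
    n_control: int = 1363
    seed: int = 0
    prevalence: float = DEFAULT_PREVALENCE
    negative_d: bool = False

    def __post_init__(self):
        for f in (self.freq_causal, self.freq_tag):
            if not (0 < f < 1):
                raise ParameterError("allele frequencies must lie in (0, 1)")
        if not (0 <= self.r2_target <= 1):
            raise ParameterError("r2_target must lie in [0, 1]")
        if self.odds_ratio <= 0:
            raise ParameterError("odds_ratio must be positive")
        if self.n_case < 0 or self.n_control < 0 or self.n_case + self.n_control == 0:
            raise SizeError("need n_case + n_control > 0")


def max_r2(freq_a: float, freq_b: float, negative_d: bool = False) -> float:
    """Maximum attainable two-locus r^2 for given marginal frequencies."""
    pa, pb = freq_a, freq_b
    qa, qb = 1 - pa, 1 - pb
    if negative_d:
        d_max = min(pa * pb, qa * qb)
    else:
        d_max = min(pa * qb, qa * pb)
    return d_max**2 / (pa * qa * pb * qb)


def haplotype_frequencies(
    freq_a: float, freq_b: float, r2_target: float, negative_d: bool = False
) -> np.ndarray:
    """Population frequencies of the AB / Ab / aB / ab haplotypes.

    Solves p_AB = p_A p_B + D with D = sign * sqrt(r2 * p_A q_A p_B q_B);
    risk alleles are positively coupled unless ``negative_d``.
    """
    pa, pb = freq_a, freq_b
    qa, qb = 1 - pa, 1 - pb
    attainable = max_r2(pa, pb, negative_d)
    if r2_target > attainable + 1e-12:
        raise FeasibilityError(
            f"r2_target={r2_target:.4g} infeasible for frequencies "
            f"({pa:.4g}, {pb:.4g}); maximum attainable r2 = {attainable:.4g}",
            attainable=attainable,
        )
    d = math.sqrt(r2_target * pa * qa * pb * qb)
    if negative_d:
        d = -d
    freqs = np.array([pa * pb + d, pa * qb - d, qa * pb - d, qa * qb + d])
    return np.clip(freqs, 0.0, 1.0) / np.clip(freqs, 0.0, 1.0).sum()


def sim_haplotype_panel(
    freq_a: float,
    freq_b: float,
    r2_target: float,
    n_hap: int,
    seed: int,
    negative_d: bool = False,
    ids: tuple[str, str] = ("causal", "tag"),
) -> HaplotypePanel:
    """Multinomial draw of a phased two-variant panel at the target LD."""
    for f in (freq_a, freq_b):
        if not (0 < f < 1):
            raise ParameterError("allele frequencies must lie in (0, 1)")
    if not (0 <= r2_target <= 1):
        raise ParameterError("r2_target must lie in [0, 1]")
    if n_hap < 4:
        raise SizeError("need at least 4 haplotypes")
    freqs = haplotype_frequencies(freq_a, freq_b, r2_target, negative_d)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_hap, freqs)
    blocks = [
        np.tile([1, 1], (counts[0], 1)),
        np.tile([1, 0], (counts[1], 1)),
        np.tile([0, 1], (counts[2], 1)),
        np.tile([0, 0], (counts[3], 1)),
    ]
    alleles = np.vstack(blocks).astype(np.int8)
    rng.shuffle(alleles, axis=0)
    variants = [
        VariantInfo(ids[0], "9", 22030438, "A", "G"),
        VariantInfo(ids[1], "9", 22057530, "C", "A"),
    ]
    return HaplotypePanel(alleles, variants)


def sim_case_control(
    panel_or_config,
    odds_ratio: float | None = None,
    n_case: int | None = None,
    n_control: int | None = None,
    seed: int | None = None,
    causal: str | None = None,
    prevalence: float = DEFAULT_PREVALENCE,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Retrospective case/control sample from an additive log-odds model.

    Individuals are formed from two random panel haplotypes; disease status
    follows logit P = alpha + ln(OR) * dose(causal), alpha = logit of the
    baseline prevalence; rejection sampling fills the requested case and
    control counts.  Accepts either (panel, odds_ratio, n_case, n_control,
    seed) or a :class:`SimConfig` (a panel is then simulated internally).
    """
    if isinstance(panel_or_config, SimConfig):
        cfg = panel_or_config
        panel = sim_haplotype_panel(
            cfg.freq_causal, cfg.freq_tag, cfg.r2_target, 20000, cfg.seed, cfg.negative_d
        )
        odds_ratio, n_case, n_control = cfg.odds_ratio, cfg.n_case, cfg.n_control
        seed, prevalence = cfg.seed + 1, cfg.prevalence
    else:
        panel = panel_or_config
    if odds_ratio is None or odds_ratio <= 0:
        raise ParameterError("odds_ratio must be positive")
    if n_case is None or n_control is None or (n_case == 0 and n_control == 0):
        raise SizeError("need n_case + n_control > 0")
    if panel.alleles.shape[1] < 1:
        raise ParameterError("panel must carry at least one variant")
    causal = causal or panel.variant_ids[0]
    j_causal = panel.variant_ids.index(causal)

    rng = np.random.default_rng(seed)
    alpha = math.log(prevalence / (1 - prevalence))
    log_or = math.log(odds_ratio)
    need_case, need_control = n_case, n_control
    case_rows, control_rows = [], []
    batch = max(1024, 4 * (n_case + n_control))
    while need_case > 0 or need_control > 0:
        h1 = rng.integers(0, panel.n_hap, size=batch)
        h2 = rng.integers(0, panel.n_hap, size=batch)
        geno = panel.alleles[h1].astype(np.int16) + panel.alleles[h2]
        p = 1.0 / (1.0 + np.exp(-(alpha + log_or * geno[:, j_causal])))
        is_case = rng.random(batch) < p
        if need_case > 0:
            take = geno[is_case][:need_case]
            case_rows.append(take)
            need_case -= take.shape[0]
        if need_control > 0:
            take = geno[~is_case][:need_control]
            control_rows.append(take)
            need_control -= take.shape[0]
    geno_all = np.vstack(
        [np.vstack(case_rows) if case_rows else np.empty((0, len(panel.variants)))]
        + ([np.vstack(control_rows)] if control_rows else [])
    ).astype(float)
    status = np.concatenate([np.ones(n_case), np.zeros(n_control)])
    samples = [f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_control)]
    gm = GenotypeMatrix(geno_all, list(panel.variants), samples)
    return gm, PhenotypeTable(status, None, samples)


def sim_expression(
    genotype_class: np.ndarray,
    r_class0: float,
    r_class1: float,
    n: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class bivariate normal expression pairs with unit marginal variances.

    Within genotype class c the (tf, target) pair has Pearson correlation
    r_class{c}.  Returns (tf_expr, target_expr) aligned with
    ``genotype_class``.
    """
    genotype_class = np.asarray(genotype_class)
    if n is not None and n != len(genotype_class):
        raise ParameterError("n does not match genotype_class length")
    for r in (r_class0, r_class1):
        if abs(r) > 1:
            raise ParameterError("class correlations must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    m = len(genotype_class)
    tf = rng.standard_normal(m)
    noise = rng.standard_normal(m)
    r = np.where(genotype_class == 1, r_class1, r_class0).astype(float)
    target = r * tf + np.sqrt(1 - r**2) * noise
    return tf, target


def sim_null_chisq(n_snps: int, seed: int = 0) -> np.ndarray:
    """I.i.d. 1-df chi-square statistics, the null of a well-calibrated GWAS."""
    if n_snps < 1:
        raise SizeError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.chisquare(df=1, size=n_snps)
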