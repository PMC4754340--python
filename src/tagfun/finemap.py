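"""Trans-ethnic fine-mapping utilities.

LD statistics from phased panels, the constrained haplotype-resampling null
that asks how often a tag SNP's association would look weaker than observed
given the causal SNP's genotype counts, and the cross-ancestry
prioritization filter (one-sided P below alpha in every population with a
concordant risk allele).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, FeasibilityError, ParameterError, SizeError
from .qc_assoc import AssocRecord
from .synthdata import HaplotypePanel


@dataclass
class LdStats:
    r2: float
    d_prime: float
    haplotype_counts: np.ndarray  # 2x2: rows allele at A (1/0), cols allele at B


@dataclass
class SimReport:
    """Summary of the constrained-resampling null for tag-SNP consistency."""

    b: int
    observed_tag_p: float
    frac_less_significant: float
    replicate_p: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# LD


def ld_counts(hap_a: np.ndarray, hap_b: np.ndarray) -> np.ndarray:
    """2x2 haplotype count table [[n11, n10], [n01, n00]] from phased 0/1 vectors."""
    hap_a = np.asarray(hap_a, dtype=int)
    hap_b = np.asarray(hap_b, dtype=int)
    return np.array(
        [
            [int(((hap_a == 1) & (hap_b == 1)).sum()), int(((hap_a == 1) & (hap_b == 0)).sum())],
            [int(((hap_a == 0) & (hap_b == 1)).sum()), int(((hap_a == 0) & (hap_b == 0)).sum())],
        ]
    )


def ld_from_counts(counts: np.ndarray) -> LdStats:
    """r^2 and D' from a 2x2 haplotype count table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise SizeError("empty haplotype table")
    p11 = counts[0, 0] / n
    pa = counts[0].sum() / n
    pb = counts[:, 0].sum() / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise DegenerateInputError("monomorphic SNP: LD undefined")
    d = p11 - pa * pb
    qa, qb = 1 - pa, 1 - pb
    r2 = d * d / (pa * qa * pb * qb)
    if d > 0:
        d_max = min(pa * qb, qa * pb)
    elif d < 0:
        d_max = min(pa * pb, qa * qb)
    else:
        d_max = 1.0
    d_prime = d / d_max if d_max > 0 else 0.0
    return LdStats(float(r2), float(d_prime), counts.astype(int))


def ld_r2(panel: HaplotypePanel, snp_a: str, snp_b: str) -> LdStats:
    """Two-locus LD from a phased panel's haplotype counts."""
    return ld_from_counts(ld_counts(panel.column(snp_a), panel.column(snp_b)))


def select_tagged(panel: HaplotypePanel, index_snp: str, r2_min: float = 0.6) -> list[str]:
    """SNPs in LD with the index above ``r2_min`` (strict), index included first."""
    idx_col = panel.column(index_snp)
    if idx_col.min() == idx_col.max():
        raise DegenerateInputError(f"index SNP {index_snp} is monomorphic in the panel")
    out = [index_snp]
    for v in panel.variants:
        if v.id == index_snp:
            continue
        col = panel.column(v.id)
        if col.min() == col.max():
            continue  # monomorphic partner: r2 undefined, skipped
        if ld_from_counts(ld_counts(idx_col, col)).r2 > r2_min:
            out.append(v.id)
    return out


# ---------------------------------------------------------------------------
# constrained haplotype resampling


def _stratum_pools(panel: HaplotypePanel, causal: str, tag: str) -> tuple[np.ndarray, np.ndarray]:
    """Tag alleles of panel haplotypes carrying causal allele 0 and 1."""
    c = panel.column(causal)
    t = panel.column(tag)
    pool0 = t[c == 0]
    pool1 = t[c == 1]
    return pool0.astype(np.int8), pool1.astype(np.int8)


def _chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorized Pearson chi-square for 2x2 tables [[a, b], [c, d]] (1 df)."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    return chi2


def constrained_resample_sim(
    panel: HaplotypePanel,
    causal: str,
    tag: str,
    case_genotype_counts: tuple[int, int, int],
    control_genotype_counts: tuple[int, int, int],
    observed_tag_p: float,
    b: int,
    seed: int,
    table: str = "allele",
    without_replacement: bool = False,
) -> SimReport:
    """Resampling null for tag-SNP association under fixed causal genotype counts.

    Each replicate assembles cases and controls whose causal-SNP genotype
    counts equal the inputs exactly: every individual's two haplotypes are
    drawn from the panel conditional on the causal alleles implied by that
    individual's assigned causal genotype, and the tag SNP's alleles ride
    along.  The replicate tag P comes from a chi-square test of homogeneity
    on the tag allele 2x2 table (``table='genotype'`` uses the 2x3 genotype
    table).  ``frac_less_significant`` is the fraction of replicates whose
    tag P is strictly greater than ``observed_tag_p``.

    Haplotypes are drawn with replacement within causal-allele stratum by
    default; ``without_replacement`` restricts each replicate to distinct
    panel haplotypes (only feasible when the panel is large enough).
    """
    if b < 1:
        raise SizeError("need at least one replicate")
    if table not in ("allele", "genotype"):
        raise ParameterError("table must be 'allele' or 'genotype'")
    counts = {}
    for grp, g in (("case", case_genotype_counts), ("control", control_genotype_counts)):
        g = tuple(int(x) for x in g)
        if len(g) != 3 or any(x < 0 for x in g):
            raise ParameterError(f"{grp} genotype counts must be three non-negative integers")
        counts[grp] = g
    pool0, pool1 = _stratum_pools(panel, causal, tag)
    need1 = {grp: g[1] + 2 * g[2] for grp, g in counts.items()}  # causal-allele-1 haplotypes
    need0 = {grp: 2 * g[0] + g[1] for grp, g in counts.items()}
    total1 = sum(need1.values())
    total0 = sum(need0.values())
    if total1 > 0 and pool1.size == 0:
        raise FeasibilityError("panel has no haplotypes carrying the causal allele")
    if total0 > 0 and pool0.size == 0:
        raise FeasibilityError("panel has no haplotypes carrying the non-causal allele")
    if without_replacement and (total1 > pool1.size or total0 > pool0.size):
        raise FeasibilityError(
            f"without-replacement sampling needs {total1}/{total0} haplotypes per causal "
            f"stratum but the panel holds {pool1.size}/{pool0.size}"
        )

    rng = np.random.default_rng(seed)
    # one panel draw per replicate, shared by cases and controls, stratified
    # by causal allele so the causal genotype counts are matched exactly
    if without_replacement:
        draws1_all = np.empty((b, total1), dtype=np.int8)
        draws0_all = np.empty((b, total0), dtype=np.int8)
        for i in range(b):
            draws1_all[i] = pool1[rng.permutation(pool1.size)[:total1]]
            draws0_all[i] = pool0[rng.permutation(pool0.size)[:total0]]
    else:
        draws1_all = (
            pool1[rng.integers(0, pool1.size, size=(b, total1))] if total1 else np.zeros((b, 0), np.int8)
        )
        draws0_all = (
            pool0[rng.integers(0, pool0.size, size=(b, total0))] if total0 else np.zeros((b, 0), np.int8)
        )

    tag_tables = {}
    off1 = off0 = 0
    for grp in ("case", "control"):
        n0, n1, n2 = counts[grp]
        m1, m0 = need1[grp], need0[grp]
        draws1 = draws1_all[:, off1 : off1 + m1]
        draws0 = draws0_all[:, off0 : off0 + m0]
        off1 += m1
        off0 += m0

        # assemble individuals: n2 with two stratum-1 haplotypes, n1 with one of
        # each, n0 with two stratum-0 haplotypes; causal dose is fixed by design
        hom1 = draws1[:, : 2 * n2].reshape(b, n2, 2).sum(axis=2) if n2 else np.zeros((b, 0), int)
        het_1 = draws1[:, 2 * n2 :]
        het_0 = draws0[:, :n1]
        hom0 = draws0[:, n1:].reshape(b, n0, 2).sum(axis=2) if n0 else np.zeros((b, 0), int)
        causal_dose = np.concatenate([np.full(n2, 2), np.full(n1, 1), np.full(n0, 0)])
        tag_geno = np.concatenate([hom1, (het_1 + het_0).astype(int), hom0], axis=1)
        # hard constraint: causal genotype counts match the input in every replicate
        assert tag_geno.shape[1] == n0 + n1 + n2
        assert (np.bincount(causal_dose, minlength=3) == np.array([n0, n1, n2])).all()
        tag_tables[grp] = tag_geno

    if table == "allele":
        a1 = tag_tables["case"].sum(axis=1).astype(float)
        a0 = 2 * sum(counts["case"]) - a1
        c1 = tag_tables["control"].sum(axis=1).astype(float)
        c0 = 2 * sum(counts["control"]) - c1
        chi2 = _chi2_2x2(a1, a0, c1, c0)
        rep_p = stats.chi2.sf(chi2, df=1)
        degenerate = ((a1 + c1) == 0) | ((a0 + c0) == 0)
        rep_p = np.where(degenerate, 1.0, rep_p)
    else:
        pvals = np.ones(b)
        for i in range(b):
            tab = np.array(
                [
                    np.bincount(tag_tables["case"][i], minlength=3),
                    np.bincount(tag_tables["control"][i], minlength=3),
                ],
                dtype=float,
            )
            keep = tab.sum(axis=0) > 0
            tab = tab[:, keep]
            if tab.shape[1] < 2 or (tab.sum(axis=1) == 0).any():
                pvals[i] = 1.0
            else:
                pvals[i] = stats.chi2_contingency(tab, correction=False)[1]
        rep_p = pvals

    frac = float(np.mean(rep_p > observed_tag_p))
    return SimReport(b, observed_tag_p, frac, rep_p, seed)


# ---------------------------------------------------------------------------
# cross-ancestry prioritization


def prioritize_crossancestry(
    assoc_tables: dict[str, list[AssocRecord]],
    alpha: float = 0.05,
    require_same_risk_allele: bool = True,
    discovery: list[AssocRecord] | None = None,
) -> list[str]:
    """SNPs with one-sided P < alpha in every population.

    With ``require_same_risk_allele`` the SNP must carry the same effect
    allele with the same effect direction in every population (and in
    ``discovery`` when given) to count as validated.
    """
    if not assoc_tables:
        raise SizeError("need at least one population")
    pops = list(assoc_tables)
    by_pop = {p: {r.snp_id: r for r in assoc_tables[p]} for p in pops}
    disc = {r.snp_id: r for r in discovery} if discovery else None
    shared = set(by_pop[pops[0]])
    for p in pops[1:]:
        shared &= set(by_pop[p])
    out = []
    for snp in shared:
        recs = [by_pop[p][snp] for p in pops]
        if any(np.isnan(r.p_one_sided) or r.p_one_sided >= alpha for r in recs):
            continue
        if require_same_risk_allele:
            ref = disc[snp] if disc and snp in disc else recs[0]
            concordant = all(
                r.effect_allele == ref.effect_allele and np.sign(r.beta) == np.sign(ref.beta)
                for r in recs
            )
            if not concordant:
                continue
        out.append(snp)
    # stable, position-free ordering
    return sorted(out)
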