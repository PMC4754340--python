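"""File I/O: VCF/TSV genotype readers and writers, expression and phenotype
tables, JASPAR/TRANSFAC PWM readers, summary-statistic tables, and the
packaged locus fixtures.

Conventions: coordinates are 1-based (VCF); TSVs are tab-separated with a
mandatory header and '.' for missing; dosages count the effect allele.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError
from .meta import StudyEffect, se_from_ci
from .motif import PWM
from .qc_assoc import AssocRecord, GenotypeMatrix, PhenotypeTable, VariantInfo
from .synthdata import HaplotypePanel

MISSING = "."


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    effect_allele_policy: str = "alt",
) -> tuple[GenotypeMatrix, HaplotypePanel | None]:
    """Read genotypes as effect-allele dosages.

    VCF: the DS field is preferred over GT when both are present; fully
    phased GT records ('|' separator) additionally yield a HaplotypePanel.
    ``effect_allele_policy`` 'alt' (default) counts ALT copies, 'ref'
    counts REF copies.  Dosage TSV: first column sample id, remaining
    columns one variant each, values in [0, 2] or '.'.
    """
    if effect_allele_policy not in ("alt", "ref"):
        raise ParameterError("effect_allele_policy must be 'alt' or 'ref'")
    if format == "vcf":
        return _read_vcf(Path(path), effect_allele_policy)
    if format == "dosage_tsv":
        return _read_dosage_tsv(Path(path)), None
    raise ParameterError("format must be 'vcf' or 'dosage_tsv'")


def _read_vcf(path: Path, policy: str) -> tuple[GenotypeMatrix, HaplotypePanel | None]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as e:  # cyvcf2 raises bare exceptions on malformed input
        raise ParseError(f"cannot open VCF {path}: {e}") from e
    samples = list(vcf.samples)
    doses, variants, hap_cols = [], [], []
    all_phased = True
    for i, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise ParseError(f"multi-allelic record {rec.ID or rec.POS} unsupported", line=i)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        ea, oa = (rec.ALT[0], rec.REF) if policy == "alt" else (rec.REF, rec.ALT[0])
        variants.append(VariantInfo(vid, rec.CHROM, rec.POS, ea, oa))
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        gts = rec.genotype.array()  # columns: allele1, allele2, phased flag
        ploidy = gts.shape[1] - 1
        if ploidy != 2:
            raise ParseError(f"non-diploid record at {rec.CHROM}:{rec.POS}", line=i)
        a = gts[:, 0].astype(float)
        b = gts[:, 1].astype(float)
        missing = (a < 0) | (b < 0)
        gt_dose = np.where(missing, np.nan, a + b)
        if ds is not None:
            dose = ds.astype(float).reshape(-1)
            dose = np.where(np.isnan(gt_dose) & np.isnan(dose), np.nan, dose)
        else:
            dose = gt_dose
        if policy == "ref":
            dose = 2.0 - dose
        doses.append(dose)
        phased = gts[:, 2].astype(bool) & ~missing
        if phased.all() and not missing.any():
            hap_cols.append(np.concatenate([gts[:, 0], gts[:, 1]]) if policy == "alt"
                            else np.concatenate([1 - gts[:, 0], 1 - gts[:, 1]]))
        else:
            all_phased = False
    if not variants:
        raise ParseError(f"no variant records in {path}")
    geno = GenotypeMatrix(np.column_stack(doses), variants, samples)
    panel = None
    if all_phased and hap_cols:
        # haplotype rows: all first alleles then all second alleles, per sample order
        alleles = np.column_stack(hap_cols).astype(np.int8)
        panel = HaplotypePanel(alleles, list(variants))
    return geno, panel


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype={0: str})
    except Exception as e:
        raise ParseError(f"cannot parse dosage TSV {path}: {e}") from e
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a sample column plus at least one variant column")
    samples = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    try:
        dosages = body.to_numpy(dtype=float)
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric dosage value: {e}") from e
    variants = [VariantInfo(c) for c in body.columns]
    return GenotypeMatrix(dosages, variants, samples)


def write_vcf(path: str | Path, geno: GenotypeMatrix, phased_from: HaplotypePanel | None = None) -> None:
    """Write a minimal VCF (CHROM, POS, ID, REF, ALT, GT).

    Integer dosages become hard GT calls; if ``phased_from`` is given its
    haplotypes are written as phased GT instead.  REF is the other allele,
    ALT the effect allele, so ALT dose equals effect-allele dose.
    """
    path = Path(path)
    n = len(geno.samples)
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom in dict.fromkeys(v.chrom for v in geno.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.samples))
    for j, v in enumerate(geno.variants):
        if phased_from is not None:
            col = phased_from.column(v.id)
            h1, h2 = col[:n], col[n:]
            gts = [f"{a}|{b}" for a, b in zip(h1, h2)]
        else:
            gts = []
            for d in geno.dosages[:, j]:
                if np.isnan(d):
                    gts.append("./.")
                else:
                    k = int(round(d))
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[min(max(k, 0), 2)])
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.other_allele}\t{v.effect_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


def write_dosage_tsv(path: str | Path, geno: GenotypeMatrix) -> None:
    df = pd.DataFrame(geno.dosages, columns=geno.variant_ids)
    df.insert(0, "sample", geno.samples)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# phenotypes / expression


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Phenotype/covariate TSV: columns 'sample', 'status' (case/control or 1/0), covariates."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    for col in ("sample", "status"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    status = df["status"]
    if status.dtype == object:
        mapping = {"case": 1.0, "control": 0.0}
        try:
            status = status.map(mapping)
        except KeyError:
            raise ParseError(f"{path}: status must be case/control or 1/0") from None
    covs = df.drop(columns=["sample", "status"])
    return PhenotypeTable(
        status.to_numpy(dtype=float),
        covs if covs.shape[1] else None,
        df["sample"].astype(str).tolist(),
    )


def write_phenotypes(path: str | Path, pheno: PhenotypeTable) -> None:
    df = pd.DataFrame({"sample": pheno.samples, "status": pheno.status.astype(int)})
    if pheno.covariates is not None:
        df = pd.concat([df, pheno.covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column 'sample', remaining columns gene ids."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    if df.columns[0] != "sample":
        raise ParseError(f"{path}: first column must be 'sample'")
    return df.set_index("sample")


def write_expression(path: str | Path, values: pd.DataFrame) -> None:
    values.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# PWMs


def read_pwm(path: str | Path, dialect: str = "jaspar", pseudocount: float = 0.25) -> PWM:
    """Read a count-matrix PWM.

    JASPAR: a '>name' header then four rows 'A [ 4 19 0 ... ]'.  TRANSFAC:
    'ID'/'P0' header with one row per position.  Counts are converted to
    probabilities with an additive pseudocount per cell.
    """
    text = Path(path).read_text()
    if dialect == "jaspar":
        name, counts = _parse_jaspar(text, str(path))
    elif dialect == "transfac":
        name, counts = _parse_transfac(text, str(path))
    else:
        raise ParameterError("dialect must be 'jaspar' or 'transfac'")
    return PWM.from_counts(name, counts, pseudocount)


def _parse_jaspar(text: str, source: str) -> tuple[str, np.ndarray]:
    name = "pwm"
    rows: dict[str, list[float]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] if line[1:].split() else "pwm"
            continue
        parts = line.replace("[", " ").replace("]", " ").split()
        if not parts or parts[0].upper() not in "ACGT":
            raise ParseError(f"{source}: unrecognized JASPAR row", line=lineno)
        base = parts[0].upper()
        try:
            rows[base] = [float(x) for x in parts[1:]]
        except ValueError:
            raise ParseError(f"{source}: non-numeric count", line=lineno) from None
    missing = set("ACGT") - set(rows)
    if missing:
        raise ParseError(f"{source}: missing rows for {sorted(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ParseError(f"{source}: unequal row lengths {sorted(lengths)}")
    counts = np.array([rows["A"], rows["C"], rows["G"], rows["T"]]).T
    return name, counts


def _parse_transfac(text: str, source: str) -> tuple[str, np.ndarray]:
    name = "pwm"
    counts = []
    order = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        tag = parts[0]
        if tag in ("ID", "NA", "AC") and len(parts) > 1:
            name = parts[1]
        elif tag in ("P0", "PO"):
            order = [b.upper() for b in parts[1:5]]
            if sorted(order) != ["A", "C", "G", "T"]:
                raise ParseError(f"{source}: P0 row must name A C G T", line=lineno)
        elif tag[0].isdigit():
            if order is None:
                raise ParseError(f"{source}: matrix row before P0 header", line=lineno)
            try:
                vals = [float(x) for x in parts[1:5]]
            except ValueError:
                raise ParseError(f"{source}: non-numeric count", line=lineno) from None
            if len(vals) != 4:
                raise ParseError(f"{source}: matrix row needs 4 counts", line=lineno)
            row = dict(zip(order, vals))
            counts.append([row["A"], row["C"], row["G"], row["T"]])
    if not counts:
        raise ParseError(f"{source}: no matrix rows found")
    return name, np.array(counts)


def write_pwm_jaspar(path: str | Path, pwm: PWM, counts: np.ndarray | None = None) -> None:
    """Write JASPAR format; probabilities are written when counts are not supplied."""
    mat = np.asarray(counts if counts is not None else pwm.probs, dtype=float).T
    lines = [f">{pwm.name}"]
    for base, row in zip("ACGT", mat):
        lines.append(f"{base} [ " + " ".join(f"{x:.12g}" for x in row) + " ]")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# summary statistics and fixtures


def read_study_effects(path: str | Path) -> list[StudyEffect]:
    """Per-study summary TSV with columns snp/label and either (beta, se) or (or, ci_lo, ci_hi)."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    label_col = "snp" if "snp" in df.columns else "label"
    out = []
    for _, row in df.iterrows():
        if "beta" in df.columns and "se" in df.columns and not pd.isna(row.get("beta")):
            out.append(StudyEffect(str(row[label_col]), float(row["beta"]), float(row["se"])))
        else:
            se = se_from_ci(float(row["or"]), float(row["ci_lo"]), float(row["ci_hi"]))
            out.append(StudyEffect(str(row[label_col]), math.log(float(row["or"])), se))
    return out


def write_assoc_tsv(path: str | Path, records: list[AssocRecord]) -> None:
    rows = []
    for r in records:
        lo, hi = r.ci95 if r.converged else (float("nan"), float("nan"))
        rows.append(
            {
                "snp": r.snp_id,
                "effect_allele": r.effect_allele,
                "beta": r.beta,
                "se": r.se,
                "or": r.or_point if r.converged else float("nan"),
                "ci_lo": lo,
                "ci_hi": hi,
                "p": r.p_two_sided,
                "p_onesided": r.p_one_sided,
                "n_case": r.n_case,
                "n_control": r.n_control,
                "conditioned_on": ",".join(r.conditioned_on) or MISSING,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=MISSING)


def _fixture(name: str) -> Path:
    return Path(str(resources.files("tagfun").joinpath("data", name)))


def load_table1() -> pd.DataFrame:
    """Packaged European-ancestry locus table: per-study and combined OR (95% CI) and P."""
    return pd.read_csv(_fixture("table1.tsv"), sep="\t", na_values=[MISSING])


def load_table2() -> pd.DataFrame:
    """Packaged Hispanic-American / African-American locus association table."""
    return pd.read_csv(_fixture("table2.tsv"), sep="\t", na_values=[MISSING])


def table2_assoc_records() -> dict[str, list[AssocRecord]]:
    """Table-2 fixture as per-population association records for prioritization.

    Printed P values are the one-sided validation P of the admixed-population
    analyses; risk alleles are shared with the European table.
    """
    import warnings

    from .meta import AsymmetricCIWarning

    t2 = load_table2()
    t1 = load_table1().set_index("snp")
    out: dict[str, list[AssocRecord]] = {"HA": [], "AA": []}
    for _, row in t2.iterrows():
        snp = row["snp"]
        allele = t1.loc[snp, "risk_allele"] if snp in t1.index else "?"
        for pop, prefix in (("HA", "ha"), ("AA", "aa")):
            or_point = float(row[f"{prefix}_or"])
            with warnings.catch_warnings():
                # printed CIs are rounded to 2 decimals; asymmetry is expected
                warnings.simplefilter("ignore", AsymmetricCIWarning)
                se = se_from_ci(or_point, float(row[f"{prefix}_lo"]), float(row[f"{prefix}_hi"]))
            p1 = float(row[f"{prefix}_p"])
            out[pop].append(
                AssocRecord(
                    snp_id=snp,
                    effect_allele=allele,
                    beta=math.log(or_point),
                    se=se,
                    p_two_sided=min(1.0, 2 * p1),
                    p_one_sided=p1,
                    n_case=391 if pop == "HA" else 203,
                    n_control=1008 if pop == "HA" else 1363,
                )
            )
    return out
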