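"""Configuration-driven pipeline tying the analysis stages together.

A YAML config declares an ordered list of stages (simulate, qc, assoc,
meta, finemap-sim, coexpr) with per-stage parameter blocks.  Every output
file gets a JSON provenance record (inputs, parameters, seed, version) and
deterministic stages are bit-identical on rerun.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, coexpr, finemap, io, meta, qc_assoc, synthdata
from .errors import ConfigError, TagfunError

log = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "qc", "assoc", "meta", "finemap-sim", "coexpr")
STOCHASTIC_STAGES = ("simulate", "finemap-sim", "coexpr")


@dataclass
class PipelineConfig:
    outdir: Path
    stages: list[dict]
    log_level: str = "INFO"
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "stages" not in raw:
            raise ConfigError(f"{path}: config must be a mapping with a 'stages' list")
        cfg = cls(
            outdir=Path(raw.get("outdir", "tagfun_out")),
            stages=list(raw["stages"]),
            log_level=raw.get("log_level", "INFO"),
            inputs=dict(raw.get("inputs", {})),
        )
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        for st in self.stages:
            name = st.get("stage")
            if name not in KNOWN_STAGES:
                raise ConfigError(f"unknown stage {name!r}; known: {KNOWN_STAGES}")
            params = st.get("params", {}) or {}
            if name in STOCHASTIC_STAGES and "seed" not in params:
                raise ConfigError(f"stochastic stage {name!r} must carry an explicit seed")
        for key, p in self.inputs.items():
            p = Path(p)
            if base is not None and not p.is_absolute():
                p = base / p
            if not p.exists():
                raise ConfigError(f"input file {key}={p} does not exist")


class StageError(TagfunError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _provenance(outdir: Path, stage: str, params: dict, inputs: list[str], outputs: list[str]) -> Path:
    rec = {
        "stage": stage,
        "params": params,
        "inputs": inputs,
        "outputs": outputs,
        "seed": params.get("seed"),
        "version": __version__,
    }
    p = outdir / f"{stage}.provenance.json"
    p.write_text(json.dumps(rec, indent=2, sort_keys=True, default=str) + "\n")
    return p


def run_pipeline(config: PipelineConfig) -> dict[str, list[str]]:
    """Execute stages in declared order; returns a manifest stage -> output paths."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    state: dict = {}
    for st in config.stages:
        name = st["stage"]
        params = dict(st.get("params", {}) or {})
        log.info("[%s] starting", name)
        try:
            outputs = _STAGE_FUNCS[name](outdir, params, state, config)
        except TagfunError as e:
            raise StageError(name, e) from e
        prov = _provenance(outdir, name, params, list(map(str, config.inputs.values())), outputs)
        manifest[name] = outputs + [str(prov)]
        log.info("[%s] wrote %s", name, ", ".join(outputs))
    return manifest


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(outdir: Path, params: dict, state: dict, config: PipelineConfig) -> list[str]:
    cfg = synthdata.SimConfig(
        freq_causal=params.get("freq_causal", 0.25),
        freq_tag=params.get("freq_tag", 0.25),
        r2_target=params.get("r2_target", 0.6),
        odds_ratio=params.get("odds_ratio", 1.5),
        n_case=params.get("n_case", 200),
        n_control=params.get("n_control", 800),
        seed=params["seed"],
        prevalence=params.get("prevalence", synthdata.DEFAULT_PREVALENCE),
    )
    panel = synthdata.sim_haplotype_panel(
        cfg.freq_causal, cfg.freq_tag, cfg.r2_target, params.get("n_hap", 20000), cfg.seed
    )
    geno, pheno = synthdata.sim_case_control(
        panel, cfg.odds_ratio, cfg.n_case, cfg.n_control, cfg.seed + 1, prevalence=cfg.prevalence
    )
    state.update(panel=panel, geno=geno, pheno=pheno, sim_cfg=cfg)
    vcf = outdir / "simulated.vcf"
    dose = outdir / "simulated.dosage.tsv"
    phen = outdir / "simulated.pheno.tsv"
    io.write_vcf(vcf, geno)
    io.write_dosage_tsv(dose, geno)
    io.write_phenotypes(phen, pheno)
    return [str(vcf), str(dose), str(phen)]


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise ConfigError(f"stage {stage!r} needs the output of an earlier stage providing {key!r}")
    return state[key]


def _stage_qc(outdir: Path, params: dict, state: dict, config: PipelineConfig) -> list[str]:
    geno = _require(state, "geno", "qc")
    pheno = _require(state, "pheno", "qc")
    thr = qc_assoc.QcThresholds(**params) if params else qc_assoc.QcThresholds()
    fgeno, fpheno, report = qc_assoc.apply_qc(geno, pheno, thr)
    state.update(geno=fgeno, pheno=fpheno)
    out = outdir / "qc_report.json"
    out.write_text(
        json.dumps(
            {
                "samples_call_rate": report.samples_call_rate,
                "samples_inbreeding": report.samples_inbreeding,
                "snps_missingness": report.snps_missingness,
                "snps_maf": report.snps_maf,
                "snps_hwe": report.snps_hwe,
                "snps_diff_missing": report.snps_diff_missing,
                "dropped_snps": report.dropped_snps,
            },
            indent=2,
        )
        + "\n"
    )
    return [str(out)]


def _stage_assoc(outdir: Path, params: dict, state: dict, config: PipelineConfig) -> list[str]:
    geno = _require(state, "geno", "assoc")
    pheno = _require(state, "pheno", "assoc")
    records = []
    for v in geno.variants:
        rec = qc_assoc.logistic_assoc(
            geno.dose(v.id), pheno, snp_id=v.id, effect_allele=v.effect_allele
        )
        records.append(rec)
    state["assoc"] = records
    out = outdir / "assoc.tsv"
    io.write_assoc_tsv(out, records)
    return [str(out)]


def _stage_meta(outdir: Path, params: dict, state: dict, config: PipelineConfig) -> list[str]:
    """Combine per-study summary tables (config inputs 'studies': list of TSVs).

    Without study inputs, the packaged locus table's discovery and
    replication cells are combined SNP by SNP.
    """
    import pandas as pd

    rows = []
    study_paths = params.get("studies") or config.inputs.get("studies")
    if study_paths:
        tables = [{e.label: e for e in io.read_study_effects(p)} for p in study_paths]
        shared = set(tables[0])
        for t in tables[1:]:
            shared &= set(t)
        for snp in sorted(shared):
            rec = meta.fixed_effects_meta([t[snp] for t in tables], snp_id=snp)
            rows.append(rec)
    else:
        t1 = io.load_table1()
        import warnings

        for _, row in t1.iterrows():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", meta.AsymmetricCIWarning)
                effects = [
                    meta.StudyEffect(
                        "discovery",
                        np.log(row["disc_or"]),
                        meta.se_from_ci(row["disc_or"], row["disc_lo"], row["disc_hi"]),
                    ),
                    meta.StudyEffect(
                        "replication",
                        np.log(row["rep_or"]),
                        meta.se_from_ci(row["rep_or"], row["rep_lo"], row["rep_hi"]),
                    ),
                ]
            rows.append(meta.fixed_effects_meta(effects, snp_id=row["snp"]))
    kept, n_excluded = meta.heterogeneity_filter(rows, params.get("i2_max", 50.0))
    df = pd.DataFrame(
        {
            "snp": [r.snp_id for r in kept],
            "or": [r.or_comb for r in kept],
            "ci_lo": [r.ci95[0] for r in kept],
            "ci_hi": [r.ci95[1] for r in kept],
            "p": [float(f"{r.p_two_sided:.3g}") for r in kept],
            "q": [r.q for r in kept],
            "q_p": [r.q_p for r in kept],
            "i2": [r.i2 for r in kept],
            "k": [r.k for r in kept],
        }
    )
    out = outdir / "meta.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.6g")
    log.info("[meta] %d SNPs combined, %d removed for heterogeneity", len(kept), n_excluded)
    state["meta"] = kept
    return [str(out)]


def _stage_finemap_sim(outdir: Path, params: dict, state: dict, config: PipelineConfig) -> list[str]:
    import pandas as pd

    panel = _require(state, "panel", "finemap-sim")
    geno = _require(state, "geno", "finemap-sim")
    pheno = _require(state, "pheno", "finemap-sim")
    causal = params.get("causal", panel.variant_ids[0])
    tag = params.get("tag", panel.variant_ids[-1])
    is_case = pheno.status == 1

    def gcounts(mask) -> tuple[int, int, int]:
        d = np.round(geno.dose(causal)[mask]).astype(int)
        c = np.bincount(np.clip(d, 0, 2), minlength=3)
        return int(c[0]), int(c[1]), int(c[2])

    tag_dose = np.round(geno.dose(tag)).astype(int)
    a_case = int(tag_dose[is_case].sum())
    a_ctrl = int(tag_dose[~is_case].sum())
    table = np.array(
        [[a_case, 2 * int(is_case.sum()) - a_case], [a_ctrl, 2 * int((~is_case).sum()) - a_ctrl]]
    )
    _, observed_p = qc_assoc.chisq_homogeneity(table)
    report = finemap.constrained_resample_sim(
        panel,
        causal,
        tag,
        gcounts(is_case),
        gcounts(~is_case),
        observed_p,
        b=params.get("b", 1000),
        seed=params["seed"],
    )
    out_json = outdir / "finemap_sim.json"
    out_tsv = outdir / "finemap_sim_replicates.tsv"
    out_json.write_text(
        json.dumps(
            {
                "b": report.b,
                "observed_tag_p": report.observed_tag_p,
                "frac_less_significant": report.frac_less_significant,
                "seed": report.seed,
            },
            indent=2,
        )
        + "\n"
    )
    pd.DataFrame({"replicate_p": report.replicate_p}).to_csv(out_tsv, sep="\t", index=False)
    state["finemap_sim"] = report
    return [str(out_json), str(out_tsv)]


def _stage_coexpr(outdir: Path, params: dict, state: dict, config: PipelineConfig) -> list[str]:
    geno = _require(state, "geno", "coexpr")
    snp = params.get("snp", geno.variant_ids[0])
    cls = coexpr.genotype_class(geno.dose(snp))
    tf, target = synthdata.sim_expression(
        cls, params.get("r_class0", 0.24), params.get("r_class1", 0.15), seed=params["seed"]
    )
    res = coexpr.coexpr_lrt(target, tf, cls)
    out = outdir / "coexpr.json"
    out.write_text(
        json.dumps(
            {
                "r_class0": res.r_class0,
                "r_class1": res.r_class1,
                "delta_hat": res.delta_hat,
                "delta_se": res.delta_se,
                "lrt_stat": res.lrt_stat,
                "p_two_sided": res.p_two_sided,
                "p_one_sided": res.p_one_sided,
                "n_class0": res.n_class0,
                "n_class1": res.n_class1,
            },
            indent=2,
        )
        + "\n"
    )
    state["coexpr"] = res
    return [str(out)]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "assoc": _stage_assoc,
    "meta": _stage_meta,
    "finemap-sim": _stage_finemap_sim,
    "coexpr": _stage_coexpr,
}
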