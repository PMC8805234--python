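"""Configured end-to-end workflow: simulate a cohort to disk, then run
haplotype resolution → scoring → MV models → MR → meta-analysis →
difference tests → diagnostics, producing one tidy results table and a
human-readable report.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import haplotypes, inference, io, prs
from .estimators import DEFAULT_MODELS, EstimateRecord, mv_regress, tsls
from .simdata import SimConfig, config_to_dict, simulate_cohort

__all__ = ["RunConfig", "cmd_simulate", "cmd_estimate", "record_row", "results_frame"]

log = logging.getLogger("ntmr")


@dataclass
class RunConfig:
    """One pipeline run: either a simulation config or input file paths."""

    out_dir: str = "ntmr_out"
    sim: SimConfig | None = None
    vcf: str | None = None
    phenotypes: str | None = None
    weights: str | None = None
    outcomes: list[str] = field(default_factory=list)
    exposure: str = "maternal_bmi"
    models: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_MODELS.items()})
    mr_covariates: list[str] = field(default_factory=lambda: ["pc1", "pc2", "pc3", "pc4"])
    strata_column: str | None = None
    use_fathers: bool = False
    ambiguity_policy: str = "expected"
    clump: dict | None = None  # p_max, r2_max, window_kb
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "allele_freq_range" in sim:
                sim["allele_freq_range"] = tuple(sim["allele_freq_range"])
            raw["sim"] = SimConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def cmd_simulate(cfg: RunConfig) -> dict[str, Path]:
    """Simulate a cohort and write it to disk (VCF + TSVs + manifest)."""
    if cfg.sim is None:
        raise ValueError("cmd_simulate requires a 'sim' section in the config")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, pheno = simulate_cohort(cfg.sim)
    paths = {
        "vcf": out / "cohort.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.tsv",
        "weights": out / "weights.tsv",
        "manifest": out / "manifest.json",
    }
    io.write_trio_vcf(cohort, paths["vcf"])
    pheno.to_csv(paths["phenotypes"], sep="\t", index_label="family_id", float_format="%.10g")
    cohort.truth.to_csv(paths["truth"], sep="\t", index_label="family_id", float_format="%.10g")
    wtab = cohort.snp_meta.rename(columns={"chrom": "chrom"})[
        ["id", "chrom", "pos", "ea", "oa", "weight"]
    ]
    prs.write_weight_table(wtab, paths["weights"])
    io.write_manifest(paths["manifest"], seed=cfg.sim.seed, sim=config_to_dict(cfg.sim),
                      n_trios=cfg.sim.n_trios, n_snps=cfg.sim.n_snps)
    log.info("simulated cohort: %d trios x %d SNPs -> %s",
             cfg.sim.n_trios, cfg.sim.n_snps, out)
    return paths


def record_row(rec: EstimateRecord) -> dict:
    lo, hi = rec.ci
    return dict(
        method=rec.method, outcome=rec.outcome, stratum=rec.stratum,
        beta=rec.beta, se=rec.se, ci_low=lo, ci_high=hi, n=rec.n, p=rec.p,
        first_stage_r2=rec.first_stage_r2, first_stage_f=rec.first_stage_f,
    )


def results_frame(records: list[EstimateRecord]) -> pd.DataFrame:
    return pd.DataFrame([record_row(r) for r in records])


def _estimate_one_sample(pheno: pd.DataFrame, outcome: str, instrument: pd.Series,
                         cfg: RunConfig, stratum: str,
                         report: list[str]) -> list[EstimateRecord]:
    recs = []
    for model in ("one", "two", "three"):
        rec = mv_regress(pheno, outcome, model=model, exposure=cfg.exposure,
                         models=cfg.models, stratum=stratum)
        recs.append(rec)
    mr_covs = [c for c in cfg.mr_covariates if c in pheno.columns]
    rec_mr = tsls(pheno, outcome, instrument, covariates=mr_covs,
                  exposure=cfg.exposure, stratum=stratum)
    recs.append(rec_mr)
    report.append(
        f"  [{stratum}] {outcome}: MV complete-case N={recs[0].n}, MR N={rec_mr.n}, "
        f"first-stage R2={rec_mr.first_stage_r2:.4f}, F={rec_mr.first_stage_f:.1f}"
    )
    return recs


def cmd_estimate(cfg: RunConfig) -> dict:
    """Run the full estimation workflow on files produced by
    :func:`cmd_simulate` (or equivalently formatted real data)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcf_path = cfg.vcf or out / "cohort.vcf"
    pheno_path = cfg.phenotypes or out / "phenotypes.tsv"
    weights_path = cfg.weights or out / "weights.tsv"
    for p in (vcf_path, pheno_path, weights_path):
        if not Path(p).exists():
            raise ValueError(f"input file not found: {p}")

    snp_meta, mat, pat, child, fam = io.read_trio_vcf(vcf_path)
    pheno = pd.read_csv(pheno_path, sep="\t", index_col="family_id")
    if not pheno.index.isin(fam).all() or not fam.isin(pheno.index).all():
        raise ValueError("family ids in phenotype table do not match the VCF")
    pheno = pheno.loc[fam]
    weights = prs.read_weight_table(weights_path)

    report: list[str] = [f"cohort: {len(fam)} families, {len(snp_meta)} SNPs"]

    # 1. haplotype resolution
    mother_g = mat.sum(axis=1)
    res = haplotypes.resolve_cohort(
        mother_g, child, pat.sum(axis=1) if cfg.use_fathers else None,
        policy=cfg.ambiguity_policy,
    )
    counts = res.status_counts()
    report.append(f"duo resolution: {counts}; excluded SNPs: {len(res.excluded_snps)}")

    nt = pd.DataFrame(res.nontransmitted, index=fam, columns=snp_meta["id"])
    full = pd.DataFrame(mother_g, index=fam, columns=snp_meta["id"])
    pat_dos = pd.DataFrame(pat.sum(axis=1), index=fam, columns=snp_meta["id"])

    # 2. instrument construction
    harm = prs.harmonize(weights, snp_meta)
    report.append(
        f"harmonisation: {len(harm)} SNPs kept, {len(harm.attrs['dropped'])} dropped"
    )
    if cfg.clump:
        ref = pd.DataFrame(mother_g, index=fam, columns=snp_meta["id"])
        kept = prs.clump_and_threshold(harm.rename(columns={"p_value": "p"}), ref,
                                       **cfg.clump)
        harm = harm[harm["id"].isin(kept)]
        report.append(f"clumping+thresholding: {len(harm)} SNPs selected")
    nt_score = prs.score(nt, harm)
    full_score = prs.score(full, harm)
    pat_score = prs.score(pat_dos, harm)
    report.append(f"NT instrument: {nt_score.n_snps_used} SNPs, "
                  f"{nt_score.n_imputed} dosages mean-imputed")

    outcomes = cfg.outcomes or [c for c in pheno.columns if c.startswith("y_")]
    if not outcomes:
        raise ValueError("no outcome columns found or declared")

    records: list[EstimateRecord] = []
    meta_rows = []
    diff_rows = []
    strata = (
        {str(s): pheno[pheno[cfg.strata_column] == s] for s in
         pheno[cfg.strata_column].unique()}
        if cfg.strata_column else {"all": pheno}
    )
    for outcome in outcomes:
        per_stratum: dict[str, list[EstimateRecord]] = {}
        for name, sub in strata.items():
            per_stratum[name] = _estimate_one_sample(
                sub, outcome, nt_score.score, cfg, name, report
            )
        records += [r for recs in per_stratum.values() for r in recs]
        if len(strata) > 1:
            for method in ("mv1", "mv2", "mv3", "tsls"):
                members = [r for recs in per_stratum.values() for r in recs
                           if r.method == method]
                mr = inference.meta_fixed(members)
                records.append(EstimateRecord(
                    method=f"{method}_meta", outcome=outcome, stratum="pooled",
                    beta=mr.pooled_beta, se=mr.pooled_se,
                    n=sum(m.n for m in members),
                    extra=dict(q=mr.q, df=mr.df, p_q=mr.p_q, i2=mr.i2),
                ))
                meta_rows.append(dict(method=method, outcome=outcome, q=mr.q,
                                      df=mr.df, p_q=mr.p_q, i2=mr.i2))
        # MV-vs-MR difference test on the full sample
        mr_covs = [c for c in cfg.mr_covariates if c in pheno.columns]
        diff = inference.mv_mr_difference_test(
            pheno, outcome, nt_score.score, mr_covariates=mr_covs,
            exposure=cfg.exposure, models=cfg.models,
            n_boot=cfg.n_boot, seed=cfg.seed,
        )
        diff_rows.append(dict(outcome=outcome, beta_mv=diff.beta_mv,
                              beta_mr=diff.beta_mr, z=diff.z, p=diff.p,
                              cov_boot=diff.cov_boot, n_boot=diff.n_boot))
        report.append(f"  MV-vs-MR difference for {outcome}: z={diff.z:.2f} p={diff.p:.3g}")

    # 3. diagnostics
    risk_cols = [c for c in ("conf1", "conf2", "paternal_bmi", "maternal_age")
                 if c in pheno.columns]
    screen = inference.instrument_validity_screen(nt_score.score, pheno[risk_cols])
    parental = inference.parental_prs_correlation(
        nt_score.score, full_score.score, pat_score.score
    )
    report.append("parental PRS correlation (NT vs paternal): "
                  f"r={parental.loc[0, 'r']:.3f} "
                  f"[{parental.loc[0, 'ci_low']:.3f}, {parental.loc[0, 'ci_high']:.3f}]")

    results = results_frame(records)
    results.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.6g")
    screen.to_csv(out / "instrument_screen.tsv", sep="\t", index=False, float_format="%.6g")
    parental.to_csv(out / "parental_correlation.tsv", sep="\t", index=False,
                    float_format="%.6g")
    pd.DataFrame(diff_rows).to_csv(out / "difference_tests.tsv", sep="\t", index=False,
                                   float_format="%.6g")
    (out / "report.txt").write_text("\n".join(report) + "\n")
    io.write_manifest(out / "estimate_manifest.json", seed=cfg.seed, n_boot=cfg.n_boot,
                      outcomes=list(outcomes), n_families=len(fam))
    return dict(results=results, screen=screen, parental=parental,
                difference_tests=pd.DataFrame(diff_rows),
                meta=pd.DataFrame(meta_rows), report="\n".join(report))
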