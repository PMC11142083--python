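"""End-to-end linkage-guided sequence analysis.

Orchestrates: sample/variant QC -> change-trait derivation (adjust + Blom)
-> polygenic heritability -> LOD scan over the provided IBD loci -> per-family
LOD decomposition and linkage-enriched family selection -> 1-LOD support
interval -> mixed-model association of interval variants -> percent of
linkage accounted for by the top variant -> simpleM gene-level verdict.
Every stage logs its sample sizes and parameters; the final JSON report
embeds the resolved configuration and a hash of it, and contains no
timestamps, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, delta, io, linkage, qc
from .pedigree import kinship_matrix, read_pedigree

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "conditional_rescan"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage, self.code = stage, code


@dataclass
class RunConfig:
    pedigree: str
    phenotypes: str
    genotypes: str
    ibd_dir: str
    out_dir: str
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "center"])
    delta_mode: str = "annualized_slope"
    lod_significant: float = 3.0
    lod_suggestive: float = 1.9
    gwas_significant: float = 5e-8
    gwas_suggestive: float = 1e-5
    pedlod_threshold: float = 0.1
    pedlod_per_n_threshold: float = 0.01
    cumulative_lod: float = 9.0
    support_drop: float = 1.0
    alpha: float = 0.05
    simplem_fraction: float = 0.995
    apply_t2d_exclusions: bool = True
    genome_wide_assoc: bool = False
    reestimate_per_variant: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_and_align(cfg: RunConfig):
    """Read all inputs and restrict to the common analysis set."""
    stage = "load"
    try:
        ped = read_pedigree(cfg.pedigree)
        pheno = io.read_phenotypes(cfg.phenotypes)
        geno = io.read_genotypes(cfg.genotypes)
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, "read_error", str(exc)) from exc
    kin = kinship_matrix(ped)

    retained = set(pheno["id"])
    exclusion_log = None
    if cfg.apply_t2d_exclusions and {
        "t2d_diagnosis",
        "t2d_treatment",
        "fasting_glucose",
        "hba1c",
    } <= set(pheno.columns):
        visit1 = pheno.loc[pheno["visit"] == 1]
        keep_ids, exclusion_log = qc.apply_t2d_exclusions(visit1)
        retained = set(keep_ids)
        logger.info("qc: %d of %d subjects retained after T2D exclusions",
                    len(retained), len(visit1))

    geno_f, qc_report = qc.apply_variant_qc(geno)
    logger.info("qc: %d of %d variants pass QC", geno_f.n_variants, geno.n_variants)

    ids = [
        i
        for i in kin.ids
        if i in retained and i in set(geno_f.ids) and i in set(pheno["id"])
    ]
    if not ids:
        raise PipelineError(stage, "no_overlap", "no individuals shared by all inputs")
    return ped, kin, pheno, geno_f, qc_report, exclusion_log, ids


def _design(pheno_v1: pd.DataFrame, ids: list[str], covariates: list[str]) -> np.ndarray:
    cov = pheno_v1.set_index("id").reindex(ids)[covariates]
    X, _ = delta._design_matrix(cov)
    return X


def run_pipeline(cfg: RunConfig, extra_covariate: str | None = None) -> dict:
    """Run the full analysis; returns the report dict (also written to
    out_dir/run_report.json together with per-stage TSVs)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }

    ped, kin, pheno, geno, qc_report, excl_log, ids = _load_and_align(cfg)
    qc_report.to_csv(out / "variant_qc.tsv", sep="\t", index=False)
    if excl_log is not None:
        excl_log.to_csv(out / "sample_exclusions.tsv", sep="\t", index=False)
    report["stages"]["qc"] = {
        "n_subjects": len(ids),
        "n_variants": geno.n_variants,
    }

    # trait derivation on the analysis set only
    covariates = list(cfg.covariates)
    if extra_covariate is not None:
        covariates = covariates + [extra_covariate]
        present = pheno.loc[pheno["visit"] == 1].set_index("id").reindex(ids)[extra_covariate]
        frac = float(present.notna().mean())
        if frac < 0.9:
            raise PipelineError(
                "rescan", "covariate_coverage",
                f"extra covariate present for only {frac:.0%} of subjects",
            )
    sub = pheno[pheno["id"].isin(ids)]
    try:
        trait = delta.derive_adjusted_trait(sub, covariates, mode=cfg.delta_mode)
    except ValueError as exc:
        raise PipelineError("derive", "trait_error", str(exc)) from exc
    trait.table.to_csv(out / "trait.csv")
    with open(out / "trait_meta.json", "w") as fh:
        json.dump(trait.metadata(), fh, indent=2, sort_keys=True)
    ids = [i for i in ids if i in trait.table.index]
    report["stages"]["derive"] = trait.metadata()

    kin_sub = kin.subset(ids)
    y = trait.table["transformed"].reindex(ids).to_numpy()
    X = np.ones((len(ids), 1))  # covariates already regressed out of the trait

    poly = linkage.fit_polygenic(y, X, kin_sub)
    report["stages"]["polygenic"] = {
        "h2": poly.h2,
        "h2_se": poly.h2_se,
        "h2_p": poly.h2_p,
        "loglik": poly.loglik,
        "n": poly.n,
    }

    ibd = io.read_ibd_dir(cfg.ibd_dir, kin_sub)
    scan = linkage.lod_scan(y, X, kin_sub, ibd)
    scan_df = pd.DataFrame(
        [
            {"chrom": l.chrom, "pos": l.pos, "lod": l.lod, "loglik_h1": l.loglik_h1}
            for l in scan.loci
        ]
    )
    scan_df.to_csv(out / "lod_scan.tsv", sep="\t", index=False)
    peak = scan.peak
    report["stages"]["scan"] = {
        "peak": {"chrom": peak.chrom, "pos": peak.pos, "lod": peak.lod},
        "n_loci": len(scan.loci),
        "significant": peak.lod > cfg.lod_significant,
        "suggestive": peak.lod > cfg.lod_suggestive,
    }

    if peak.lod <= cfg.lod_significant:
        logger.info(
            "scan: peak LOD %.2f does not exceed %.1f; interval stages skipped",
            peak.lod, cfg.lod_significant,
        )
        report["stages"]["interval"] = {
            "skipped": True,
            "reason": f"peak LOD {peak.lod:.3f} <= {cfg.lod_significant}",
        }
        _write_report(out, report)
        return report

    ibd_peak = next(m for m in ibd if (m.chrom, m.pos) == (peak.chrom, peak.pos))
    fams = linkage.family_lods(y, X, kin_sub, ibd_peak, scan)
    selection = linkage.select_linked_families(
        fams,
        pedlod_threshold=cfg.pedlod_threshold,
        pedlod_per_n_threshold=cfg.pedlod_per_n_threshold,
        cumulative_lod=cfg.cumulative_lod,
    )
    fam_df = pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "pedlod": f.pedlod,
                "n_members": f.n_members,
                "potentially_linked": f.family_id in selection["potentially_linked"],
                "top_linked": f.family_id in selection["top_linked"],
            }
            for f in fams
        ]
    ).sort_values("pedlod", ascending=False)
    fam_df.to_csv(out / "family_lods.tsv", sep="\t", index=False)
    report["stages"]["families"] = {
        "n_potentially_linked": len(selection["potentially_linked"]),
        "n_top_linked": len(selection["top_linked"]),
        "top_linked": sorted(selection["top_linked"]),
    }

    interval = linkage.support_interval(scan, drop=cfg.support_drop)
    report["stages"]["interval"] = {
        "chrom": interval[0][0],
        "start": interval[0][1],
        "end": interval[1][1],
        "drop": cfg.support_drop,
    }

    # association restricted to the support interval (genome-wide on request)
    geno_sub = geno.subset_individuals(ids)
    if cfg.genome_wide_assoc:
        mask = np.ones(geno_sub.n_variants, dtype=bool)
    else:
        v = geno_sub.variants
        mask = (
            (v["chrom"].astype(str) == str(interval[0][0]))
            & (v["pos"] >= interval[0][1])
            & (v["pos"] <= interval[1][1])
        ).to_numpy()
    results: list[association.AssocResult] = []
    null_ratio = poly.a
    for j in np.flatnonzero(mask):
        gvec = geno_sub.dosages[:, j]
        ok = ~np.isnan(gvec)
        if np.ptp(gvec[ok]) == 0:
            continue
        # analysis set restricted to observed dosages for this variant
        sub_ids = [ids[k] for k in np.flatnonzero(ok)]
        try:
            res = association.mg_assoc(
                y[ok],
                gvec[ok],
                X[ok],
                kin_sub.subset(sub_ids),
                variant_id=str(geno_sub.variants["variant_id"].iloc[j]),
                reestimate=cfg.reestimate_per_variant,
                null_ratio=null_ratio,
            )
        except association.MonomorphicError:
            continue
        results.append(res)
    association.classify_hits(
        results, significant=cfg.gwas_significant, suggestive=cfg.gwas_suggestive
    )
    assoc_df = pd.DataFrame([asdict(r) for r in results]).sort_values("p") if results else pd.DataFrame()
    assoc_df.to_csv(out / "association.tsv", sep="\t", index=False)
    report["stages"]["assoc"] = {
        "n_tested": len(results),
        "top_variant": assoc_df.iloc[0].to_dict() if len(assoc_df) else None,
    }

    if results:
        top_id = assoc_df.iloc[0]["variant_id"]
        gtop = geno_sub.dosage_of(top_id)
        ok = ~np.isnan(gtop)
        sub_ids = [ids[k] for k in np.flatnonzero(ok)]
        acct = linkage.linkage_accounted(
            y[ok], X[ok], kin_sub.subset(sub_ids),
            _subset_ibd(ibd_peak, sub_ids), gtop[ok],
        )
        report["stages"]["linkage_accounted"] = acct

        Gmat = geno_sub.dosages[:, mask]
        eff = association.simpleM_neff(
            Gmat, variance_fraction=cfg.simplem_fraction, alpha=cfg.alpha
        )
        min_p = float(assoc_df["p"].min())
        report["stages"]["simplem"] = {
            "n_markers": eff.n_markers,
            "n_eff": eff.n_eff,
            "threshold": eff.threshold,
            "min_p": min_p,
            "replicated": association.gene_level_replicated(min_p, eff),
        }

    _write_report(out, report)
    return report


def _subset_ibd(mat: linkage.IBDMatrix, ids: list[str]) -> linkage.IBDMatrix:
    return linkage.IBDMatrix(
        chrom=mat.chrom, pos=mat.pos, ids=list(ids), values=mat.reindex(ids)
    )


def _write_report(out: Path, report: dict) -> None:
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def conditional_rescan(cfg: RunConfig, extra_covariate: str) -> dict:
    """Re-derive the trait with one extra covariate and re-run the scan.

    Writes a side-by-side LOD comparison (lod_rescan.tsv) and returns a dict
    with both scans' peak LODs.  The extra covariate must be present for at
    least 90% of subjects; a constant covariate is an error.
    """
    base_out = Path(cfg.out_dir)
    pheno = io.read_phenotypes(cfg.phenotypes)
    col = pheno.loc[pheno["visit"] == 1, extra_covariate].dropna()
    if col.nunique() <= 1:
        raise PipelineError("rescan", "constant_covariate",
                            f"{extra_covariate!r} is constant")
    cfg_base = RunConfig(**{**asdict(cfg), "out_dir": str(base_out / "rescan_base")})
    cfg_cond = RunConfig(**{**asdict(cfg), "out_dir": str(base_out / "rescan_cond")})
    rep0 = run_pipeline(cfg_base)
    rep1 = run_pipeline(cfg_cond, extra_covariate=extra_covariate)
    s0 = pd.read_csv(Path(cfg_base.out_dir) / "lod_scan.tsv", sep="\t")
    s1 = pd.read_csv(Path(cfg_cond.out_dir) / "lod_scan.tsv", sep="\t")
    merged = s0.merge(s1, on=["chrom", "pos"], suffixes=("_base", "_conditioned"))
    base_out.mkdir(parents=True, exist_ok=True)
    merged.to_csv(base_out / "lod_rescan.tsv", sep="\t", index=False)
    return {
        "extra_covariate": extra_covariate,
        "peak_lod_base": rep0["stages"]["scan"]["peak"]["lod"],
        "peak_lod_conditioned": rep1["stages"]["scan"]["peak"]["lod"],
        "comparison_table": str(base_out / "lod_rescan.tsv"),
    }
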