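"""End-to-end pipeline: simulate -> QC -> REML -> wssGWAS -> windows.

Drives the library from a single RunConfig (YAML-loadable), writes every
stage artifact (QC report, variance components, GEBVs, per-iteration
marker effects, window tables, summary JSON) and a manifest sufficient to
reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinship import Pedigree, a_inverse
from .mme import ModelSpec, RepeatabilityModel, VarianceComponents, ai_reml
from .gwas import WssGwas
from .qc import QcConfig, apply_qc, impute_missing
from .simulate import SimConfig, simulate_dataset
from . import plink, windows as _windows

logger = logging.getLogger("wssgwas")

__all__ = ["RunConfig", "run_pipeline", "summarize"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the published analysis
    (0.9/0.1 blend, 3 iterations, 0.4 Mb windows, 1% selection)."""

    out_dir: str = "wssgwas_run"
    # either simulate...
    simulate: dict | None = None
    # ...or load from files
    ped_prefix: str | None = None
    pedigree_csv: str | None = None
    phenotype_csv: str | None = None

    trait: str = "trait"
    transform: str | None = None
    qc: dict = field(default_factory=dict)
    impute_mode: str = "sample"
    g_share: float = 0.9
    n_iterations: int = 3
    window_bp: int = 400_000
    threshold_pct: float = 1.0
    k_top: int = 3
    solver: str = "auto"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def manifest(self) -> dict:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return {"config": d, "config_sha256": hashlib.sha256(blob).hexdigest(),
                "package_version": __version__, "seed": self.seed}


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = SimConfig(**{**config.simulate, "seed": config.seed})
        pedigree, genotypes, phen, truth = simulate_dataset(sim)
        return pedigree, genotypes, phen, truth
    if not (config.ped_prefix and config.pedigree_csv
            and config.phenotype_csv):
        raise ValueError("provide either `simulate` settings or all of "
                         "ped_prefix / pedigree_csv / phenotype_csv")
    pedigree = plink.read_pedigree_csv(config.pedigree_csv)
    genotypes = plink.read_ped_map(config.ped_prefix)
    phen = plink.read_phenotypes_csv(config.phenotype_csv)
    id_pos = {str(v): i for i, v in enumerate(pedigree.ids)}
    mask = np.zeros(pedigree.n, dtype=bool)
    keep = []
    for i, gid in enumerate(genotypes.ids):
        if str(gid) in id_pos:
            mask[id_pos[str(gid)]] = True
            keep.append(i)
        else:
            raise ValueError(f"genotyped animal {gid!r} not in pedigree")
    order = np.argsort([id_pos[str(genotypes.ids[i])] for i in keep])
    genotypes = genotypes.subset(ind_mask=np.asarray(keep)[order])
    pedigree.genotyped = mask
    return pedigree, genotypes, phen, None


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the artifact dictionary also written to
    disk under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        pedigree, genotypes, phen, truth = _load_inputs(config)
        spec = ModelSpec(trait=config.trait, transform=config.transform)

        stage = "qc"
        from .qc import QcReport
        if genotypes.n_ind > 0:
            qc_cfg = QcConfig(**config.qc)
            geno_qc, report = apply_qc(genotypes, qc_cfg)
            # keep the pedigree mask in sync with QC-dropped individuals
            kept = set(map(str, geno_qc.ids))
            pedigree.genotyped = np.array(
                [pedigree.genotyped[i] and str(pedigree.ids[i]) in kept
                 for i in range(pedigree.n)])
            geno_qc = impute_missing(geno_qc, seed=config.seed,
                                     mode=config.impute_mode)
        else:
            geno_qc, report = genotypes, QcReport()
        pd.DataFrame([report.as_dict()]).T.to_csv(
            out / "qc_report.tsv", sep="\t", header=False)
        logger.info("QC: %d -> %d SNPs, %d -> %d individuals",
                    report.n_snps_in, report.n_snps_out, report.n_ind_in,
                    report.n_ind_out)

        stage = "reml"
        varcomp = ai_reml(phen, spec, a_inverse(pedigree), pedigree.ids)
        (out / "variance_components.json").write_text(
            json.dumps(varcomp.as_dict(), indent=1))
        logger.info("REML: var_a=%.5f var_pe=%.5f var_e=%.5f h2=%.4f",
                    varcomp.var_a, varcomp.var_pe, varcomp.var_e, varcomp.h2)

        n_genotyped = int(pedigree.genotyped.sum())
        if n_genotyped == 0:
            warnings.warn("no genotyped animals: degrading to pedigree "
                          "BLUP; window scan skipped")
            stage = "pedigree-blup"
            model = RepeatabilityModel(phen, pedigree, spec=spec)
            res = model.fit(var=varcomp, solver=config.solver)
            res.gebv.rename("gebv").to_csv(out / "gebv.tsv", sep="\t")
            artifacts = {"qc_report": report.as_dict(),
                         "varcomp": varcomp.as_dict(),
                         "gebv": res.gebv, "windows": None,
                         "truth": truth, "manifest": config.manifest()}
        else:
            stage = "wssgwas"
            gw = WssGwas(phen, pedigree, geno_qc, spec=spec)
            fitted = gw.fit(var=varcomp, n_iter=config.n_iterations,
                            g_share=config.g_share, solver=config.solver)
            for rec in fitted.trace.records:
                df = pd.DataFrame({
                    "snp": geno_qc.snp_ids, "chrom": geno_qc.chrom,
                    "bp": geno_qc.pos, "effect": rec.marker_effects,
                    "weight": rec.weights})
                df.to_csv(out / f"marker_effects_iter{rec.iteration}.tsv",
                          sep="\t", index=False)
            fitted.gebv.rename("gebv").to_csv(out / "gebv.tsv", sep="\t")

            stage = "windows"
            res = fitted.window_scan(size_bp=config.window_bp)
            res.drop(columns="snp_indices").to_csv(
                out / "windows.tsv", sep="\t", index=False)
            selected = _windows.select_windows(res, config.threshold_pct)
            merged = _windows.merge_windows(selected)
            top = _windows.top_regions(res, k=config.k_top)
            merged.to_csv(out / "regions_merged.tsv", sep="\t", index=False)
            top.drop(columns="snp_indices").to_csv(
                out / "regions_top.tsv", sep="\t", index=False)
            _windows.write_bed(selected, out / "regions_selected.bed")
            artifacts = {"qc_report": report.as_dict(),
                         "varcomp": varcomp.as_dict(), "gebv": fitted.gebv,
                         "windows": res, "selected": selected,
                         "merged": merged, "top": top, "trace": fitted.trace,
                         "truth": truth, "manifest": config.manifest()}
        (out / "manifest.json").write_text(
            json.dumps(config.manifest(), indent=1))
        summary = summarize(artifacts)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        artifacts["summary"] = summary
        return artifacts
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") \
            from exc


def summarize(artifacts: dict) -> dict:
    """One-page JSON report: h2, top-region shares, total selected share."""
    if "varcomp" not in artifacts:
        raise ValueError("missing variance components in artifacts")
    vc = artifacts["varcomp"]
    summary = {
        "h2": vc["h2"],
        "repeatability": vc["repeatability"],
        "var_a": vc["var_a"], "var_pe": vc["var_pe"], "var_e": vc["var_e"],
        "qc": artifacts.get("qc_report"),
    }
    if artifacts.get("windows") is not None:
        sel = artifacts["selected"]
        top = artifacts["top"]
        summary.update({
            "n_windows": int(len(artifacts["windows"])),
            "n_selected": int(len(sel)),
            "pct_var_selected_total": float(sel["pct_var"].sum()),
            "pct_var_top": [float(v) for v in top["pct_var"]],
            "top_regions": [
                {"chrom": str(r["chrom"]),
                 "start": int(r["region_start"]),
                 "end": int(r["region_end"]),
                 "pct_var": float(r["pct_var"])}
                for _, r in top.iterrows()],
        })
    return summary
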