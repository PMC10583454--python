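"""End-to-end pipeline: simulate/load -> GWAS -> SLDP -> predict -> evaluate.

A single config (YAML file or dict) drives five stages:

1. genotypes — simulate a diploid panel or load one from disk, then QC;
2. trait — simulate an additive trait (or load phenotypes);
3. split — disjoint discovery / training / validation populations;
4. gwas — MLM scan on the discovery population;
5. selection & prediction — grid-search SLDP parameters by k-fold CV in
   the training population, build the chosen panel, predict validation
   GEBV and report accuracy and bias.

Every random stage takes its own named seed, so a fixed config yields a
byte-identical run manifest (JSON, sorted keys, no timestamps).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayesr import BayesRConfig, bayesr_fit, bayesr_predict
from .evaluate import accuracy, bias, default_p_grid, default_r2_grid, grid_search, split_populations
from .gblup import build_grm, gblup_predict, reml_fit
from .genotype import GenotypeMatrix, PhenotypeTable, qc_filter, read_genotypes, read_phenotypes
from .gwas import mlma_scan
from .ld import PruneConfig, mark_important, sldp_prune
from .simulate import GenoSimConfig, simulate_genotypes, simulate_trait

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    outdir: str
    genotypes: dict = field(default_factory=dict)   # sim params or {"path": ...}
    trait: dict = field(default_factory=dict)       # sim params or {"path": ...}
    split: dict = field(default_factory=dict)       # counts+seed or explicit ids
    model: str = "gblup"
    p_grid: list = field(default_factory=lambda: list(default_p_grid()))
    r2_grid: list = field(default_factory=lambda: list(default_r2_grid()))
    prune_window: int = 500
    prune_step: int = 200
    link_window_bp: int = 1_000_000
    cv_k: int = 5
    cv_seed: int = 0
    qc: dict = field(default_factory=lambda: dict(maf_min=0.05, snp_call_min=0.95,
                                                  ind_call_min=0.90))
    bayesr: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if self.model not in ("gblup", "bayesr"):
            raise ValueError(f"unknown model {self.model!r}")
        if not self.p_grid or not self.r2_grid:
            raise ValueError("empty parameter grid")
        explicit = {k: v for k, v in self.split.items()
                    if k in ("discovery", "training", "validation") and v}
        if explicit:
            if set(explicit) != {"discovery", "training", "validation"}:
                raise ValueError("explicit split needs all three populations")
            seen: set[str] = set()
            for name, ids in explicit.items():
                overlap = seen & set(ids)
                if overlap:
                    raise ValueError(f"populations overlap: {sorted(overlap)[:5]}")
                seen |= set(ids)
        else:
            for key in ("n_discovery", "n_validation", "seed"):
                if key not in self.split:
                    raise ValueError(f"split requires {key!r} (or explicit id lists)")


def _stage_genotypes(cfg: PipelineConfig) -> GenotypeMatrix:
    if "path" in cfg.genotypes:
        gm = read_genotypes(cfg.genotypes["path"], cfg.genotypes.get("format"))
    else:
        gm = simulate_genotypes(GenoSimConfig(**cfg.genotypes))
    return qc_filter(gm, **cfg.qc)


def _stage_trait(cfg: PipelineConfig, gm: GenotypeMatrix):
    if "path" in cfg.trait:
        pheno = read_phenotypes(cfg.trait["path"])
        pheno = pheno.reindex(list(gm.samples))
        return pheno, None
    pheno, truth = simulate_trait(gm, n_qtn=int(cfg.trait["n_qtn"]),
                                  h2=float(cfg.trait["h2"]),
                                  seed=int(cfg.trait["seed"]))
    return pheno, truth


def run_pipeline(cfg: PipelineConfig | dict | str) -> dict:
    """Execute the staged pipeline; returns (and writes) the run manifest."""
    if isinstance(cfg, str):
        cfg = PipelineConfig.from_yaml(cfg)
    elif isinstance(cfg, dict):
        cfg = PipelineConfig(**cfg)
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {"version": __version__, "model": cfg.model,
                      "stages": {}, "outputs": {}, "metrics": {}}
    failure_marker = os.path.join(cfg.outdir, "FAILED")
    stage = "genotypes"
    try:
        gm = _stage_genotypes(cfg)
        manifest["stages"]["genotypes"] = dict(n_samples=gm.n_samples,
                                               n_snps=gm.n_snps)

        stage = "trait"
        pheno, truth = _stage_trait(cfg, gm)
        pheno_path = os.path.join(cfg.outdir, "phenotypes.tsv")
        pd.DataFrame({"id": pheno.samples, "y": pheno.y}).to_csv(
            pheno_path, sep="\t", index=False, float_format="%.10g")
        manifest["outputs"]["phenotypes"] = "phenotypes.tsv"
        manifest["stages"]["trait"] = dict(
            n_qtn=int(len(truth.qtn_indices)) if truth else None,
            h2_realized=round(truth.h2_realized, 10) if truth else None)

        stage = "split"
        if "n_discovery" in cfg.split:
            pops = split_populations(list(gm.samples),
                                     int(cfg.split["n_discovery"]),
                                     int(cfg.split["n_validation"]),
                                     int(cfg.split["seed"]))
        else:
            pops = {k: list(cfg.split[k]) for k in ("discovery", "training",
                                                    "validation")}
        manifest["stages"]["split"] = {k: len(v) for k, v in pops.items()}

        stage = "gwas"
        disc_idx = gm.sample_index(pops["discovery"])
        gm_disc = gm.subset(samples=disc_idx)
        pheno_disc = pheno.reindex(pops["discovery"])
        gwas = mlma_scan(gm_disc, pheno_disc, build_grm(gm_disc))
        assoc_path = os.path.join(cfg.outdir, "assoc.tsv")
        gwas.write(assoc_path)
        manifest["outputs"]["assoc"] = "assoc.tsv"
        manifest["stages"]["gwas"] = dict(
            n_tested=int(gwas.tested.sum()),
            h2_null=round(gwas.variance.h2, 10))

        stage = "selection"
        trn_idx = gm.sample_index(pops["training"])
        gm_trn = gm.subset(samples=trn_idx)
        pheno_trn = pheno.reindex(pops["training"])
        target_trn = truth.tbv[trn_idx] if truth is not None else None
        # GWAS scores must come from the discovery scan, aligned by variant
        grid = grid_search(gm_trn, pheno_trn, gwas, p_grid=cfg.p_grid,
                           r2_grid=cfg.r2_grid, model=cfg.model, k=cfg.cv_k,
                           seed=cfg.cv_seed, target=target_trn,
                           cfg_template=PruneConfig(1.0, cfg.prune_window,
                                                    cfg.prune_step),
                           link_window_bp=cfg.link_window_bp)
        grid_path = os.path.join(cfg.outdir, "grid.tsv")
        grid.write(grid_path)
        manifest["outputs"]["grid"] = "grid.tsv"
        if not grid.best:
            raise RuntimeError("every grid cell failed (empty panels)")
        manifest["stages"]["selection"] = dict(best=grid.best,
                                               n_cells=int(len(grid.cells)))

        stage = "prediction"
        important = mark_important(gwas, grid.best["p"], gm,
                                   link_window_bp=cfg.link_window_bp)
        panel = sldp_prune(gm, important,
                           PruneConfig(grid.best["r2"], cfg.prune_window,
                                       cfg.prune_step))
        panel_path = os.path.join(cfg.outdir, "panel.txt")
        panel.write(panel_path)
        manifest["outputs"]["panel"] = "panel.txt"

        gm_panel = gm.subset(snps=panel.kept)
        val_ids = pops["validation"]
        trn_val_ids = pops["training"] + val_ids
        if cfg.model == "gblup":
            sub = gm_panel.subset(samples=gm_panel.sample_index(trn_val_ids))
            grm = build_grm(sub)
            pred = gblup_predict(pheno.reindex(pops["training"]), grm, val_ids,
                                 panel_label="SLDP")
        else:
            br_cfg = BayesRConfig(seed=int(cfg.bayesr.get("seed", cfg.cv_seed)),
                                  iterations=int(cfg.bayesr.get("iterations", 3000)),
                                  burnin=int(cfg.bayesr.get("burnin", 1000)),
                                  thinning=int(cfg.bayesr.get("thinning", 5)))
            post = bayesr_fit(gm_panel.subset(samples=gm_panel.sample_index(
                pops["training"])), pheno.reindex(pops["training"]), br_cfg)
            pred = bayesr_predict(post, gm_panel.subset(
                samples=gm_panel.sample_index(val_ids)), panel_label="SLDP")

        val_idx = gm.sample_index(val_ids)
        target_val = truth.tbv[val_idx] if truth is not None else pheno.y[val_idx]
        pred_path = os.path.join(cfg.outdir, "predictions.tsv")
        pd.DataFrame({"id": val_ids, "gebv": pred.gebv,
                      "target": target_val}).to_csv(
            pred_path, sep="\t", index=False, float_format="%.12g")
        manifest["outputs"]["predictions"] = "predictions.tsv"
        manifest["metrics"]["accuracy"] = round(accuracy(pred.gebv, target_val), 12)
        manifest["metrics"]["bias"] = round(bias(pred.gebv, target_val), 12)
        manifest["metrics"]["panel_size"] = int(len(panel))
        manifest["stages"]["prediction"] = dict(n_validation=len(val_ids))
    except Exception as exc:
        with open(failure_marker, "w") as fh:
            fh.write(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    if os.path.exists(failure_marker):
        os.remove(failure_marker)
    manifest_path = os.path.join(cfg.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return manifest
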