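"""End-to-end orchestration: simulate -> pseudobulk -> eQTL -> interactions
-> colocalization -> MR, driven by a single config mapping.

Each stage writes plain-text TSV outputs under the run directory and is
resumable: when a stage's outputs already exist they are loaded instead of
recomputed.  A ``manifest.json`` capturing the config hash, root seed,
package versions and output checksums makes a run re-executable
bit-identically.

Cohort modes: ``full`` (mixed disease-case and control donors; the
interaction stage tests genotype x diagnosis) and ``control_only``
(nondiseased donors only; the interaction stage tests genotype x age, and
a diagnosis-interaction request is a configuration error).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cis_eqtl import compute_pcs, map_cis, optimize_pcs, residualize
from .coloc import ColocPriors, build_regions, run_coloc_grid
from .exceptions import ConfigurationError
from .genotype_io import ld_correlation, write_dosage_tsv, write_sumstats_tsv
from .interaction import age_interaction_scan, interaction_scan
from .mr import run_mr
from .pseudobulk import aggregate, normalize, write_mtx_counts
from .synthetic import (DEFAULT_DIAGNOSIS_PROPORTIONS, build_truth,
                        default_config, simulate_cells, simulate_cohort,
                        simulate_genotypes, simulate_gwas)

__all__ = ["DEFAULT_PARAMS", "validate_config", "run_pipeline", "compare_cohorts"]

STAGES = ("simulate", "pseudobulk", "eqtl", "interactions", "coloc", "mr")

DEFAULT_PARAMS = {
    "min_cells": 10,
    "expressed_fraction": 0.05,
    "cis_window": 1_000_000,
    "fdr": 0.05,
    "maf_floor": 0.05,
    "pc_grid": [0, 2],
    "n_geno_pcs": 5,
    "gwas_p_threshold": 5e-8,
    "region_window": 1_000_000,
    "min_region_snps": 100,
    "priors": {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5},
    "pp4_cut": 0.8,
    "f_min": 15.0,
    "r2_max": 0.01,
    "var_explained": 0.999,
    "exclusion_loci": [],
    "interaction_q_cut": 0.05,
}


def validate_config(config: dict) -> dict:
    """Fill defaults and enforce mode/threshold invariants."""
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("cohort_mode", "full")
    cfg.setdefault("stages", list(STAGES))
    cfg.setdefault("simulation", {})
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params", {}))
    cfg["params"] = params
    if cfg["cohort_mode"] not in ("full", "control_only"):
        raise ConfigurationError(f"cohort_mode must be full|control_only, "
                                 f"got {cfg['cohort_mode']!r}")
    if cfg["cohort_mode"] == "control_only" and cfg.get("interaction_term") == "diagnosis":
        raise ConfigurationError(
            "control_only mode forbids the diagnosis-interaction scan "
            "(age interaction is allowed)")
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    for key, lo, hi in (("fdr", 0, 1), ("pp4_cut", 0, 1.5), ("r2_max", 0, 1),
                        ("expressed_fraction", 0, 1), ("var_explained", 0, 1)):
        v = params[key]
        if not (lo <= v <= hi):
            raise ConfigurationError(f"params.{key}={v} outside [{lo}, {hi}]")
    if "outdir" not in cfg:
        raise ConfigurationError("config needs an outdir")
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _build_sim_config(cfg: dict):
    sim = dict(cfg.get("simulation", {}))
    sim.setdefault("seed", cfg["seed"])
    if cfg["cohort_mode"] == "control_only":
        sim.setdefault("diagnosis_proportions",
                       {"control": 1.0, "AD": 0.0, "PD": 0.0, "MS": 0.0})
    else:
        sim.setdefault("diagnosis_proportions", dict(DEFAULT_DIAGNOSIS_PROPORTIONS))
    builder_keys = {"n_donors", "n_genes", "cell_types", "cells_per_donor", "seed"}
    builder = {k: sim[k] for k in list(sim) if k in builder_keys}
    overrides = {k: v for k, v in sim.items() if k not in builder_keys}
    return default_config(**builder, **overrides)


def run_pipeline(config: dict) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    cfg = validate_config(config)
    params = cfg["params"]
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    control_only = cfg["cohort_mode"] == "control_only"

    sim_cfg = _build_sim_config(cfg)
    cell_types = list(sim_cfg.cell_plan)

    # --- simulate -----------------------------------------------------------
    genotypes = simulate_genotypes(sim_cfg)
    covariates = simulate_cohort(sim_cfg)
    cells = simulate_cells(genotypes, covariates, sim_cfg)
    gwas = {plan.trait: simulate_gwas(sim_cfg.snp_map, plan, sim_cfg.seed,
                                      sim_cfg.ld_rho)
            for plan in sim_cfg.gwas_plan}
    truth = build_truth(sim_cfg)
    if "simulate" in cfg["stages"]:
        write_dosage_tsv(genotypes, outdir / "genotypes")
        covariates.to_csv(outdir / "covariates.tsv", sep="\t",
                          float_format="%.10g")
        for ct, cc in cells.items():
            write_mtx_counts(cc, outdir / f"counts.{ct}")
        for trait, ss in gwas.items():
            write_sumstats_tsv(ss, outdir / f"gwas.{trait}.tsv")
        _write_tsv(truth.egenes, outdir / "truth.egenes.tsv")
        _write_tsv(truth.coloc, outdir / "truth.coloc.tsv")

    log: dict = {"n_donors": len(covariates), "cell_types": cell_types}

    # --- pseudobulk ---------------------------------------------------------
    scaled = {}
    if set(cfg["stages"]) & {"pseudobulk", "eqtl", "interactions", "coloc", "mr"}:
        raw = aggregate(cells, min_cells=params["min_cells"])
        for ct, pb in raw.items():
            sc = normalize(pb, expressed_fraction=params["expressed_fraction"])
            scaled[ct] = sc
            if "pseudobulk" in cfg["stages"]:
                mat = sc.matrix.copy()
                mat.insert(0, "gene", mat.index)
                _write_tsv(mat, outdir / f"pseudobulk.{ct}.tsv")
        log["pseudobulk_donors"] = {ct: len(pb.donors) for ct, pb in scaled.items()}

    # --- eQTL ---------------------------------------------------------------
    eqtl_pairs, egenes, pcs_by_ct = [], [], {}
    if set(cfg["stages"]) & {"eqtl", "interactions", "coloc", "mr"}:
        fixed = ("age", "sex", "pmi", "source") if control_only else \
            ("age", "sex", "pmi", "diagnosis", "source")
        for ct, sc in scaled.items():
            resid = residualize(sc, covariates, fixed_terms=fixed)
            grid = params["pc_grid"]
            n_expr, grid_counts = optimize_pcs(
                resid, genotypes, sim_cfg.gene_map, grid,
                n_geno=params["n_geno_pcs"], cis_window=params["cis_window"],
                fdr=params["fdr"], maf_floor=params["maf_floor"])
            pcs = compute_pcs(resid, genotypes, n_expr=max(grid),
                              n_geno=params["n_geno_pcs"])
            res = map_cis(resid, genotypes, pcs, sim_cfg.gene_map,
                          cis_window=params["cis_window"], fdr=params["fdr"],
                          maf_floor=params["maf_floor"], n_expr_pcs=n_expr)
            eqtl_pairs.append(res.pairs)
            eg = res.egenes.copy()
            eg.insert(0, "cell_type", ct)
            egenes.append(eg)
            pcs_by_ct[ct] = pcs.design(n_expr)
            log.setdefault("pc_choice", {})[ct] = {"chosen": n_expr,
                                                   "grid": grid_counts}
        eqtl_pairs = pd.concat(eqtl_pairs, ignore_index=True)
        egenes = pd.concat(egenes, ignore_index=True)
        if "eqtl" in cfg["stages"]:
            _write_tsv(eqtl_pairs, outdir / "eqtl.pairs.tsv")
            _write_tsv(egenes, outdir / "eqtl.egenes.tsv")
        log["n_egenes"] = int(egenes["is_egene"].sum())

    # --- interactions -------------------------------------------------------
    exclusions: set = set()
    if "interactions" in cfg["stages"] and len(egenes):
        leads = egenes[egenes["is_egene"]].rename(columns={"lead_snp": "snp"})
        leads = leads[["cell_type", "gene", "snp"]]
        if len(leads):
            scan = age_interaction_scan if control_only else interaction_scan
            table, summary = scan(leads, scaled, covariates, genotypes,
                                  pcs=pcs_by_ct)
            _write_tsv(table, outdir / "interactions.tsv")
            _write_tsv(summary, outdir / "interactions.summary.tsv")
            hits = table[table["lrt12_q"] < params["interaction_q_cut"]]
            exclusions = set(zip(hits["gene"], hits["cell_type"]))
            log["n_interaction_hits"] = len(exclusions)

    # --- colocalization -----------------------------------------------------
    coloc_table = pd.DataFrame()
    regions_by_trait = {}
    if set(cfg["stages"]) & {"coloc", "mr"} and len(eqtl_pairs):
        priors = ColocPriors(**params["priors"])
        for trait, ss in gwas.items():
            regions, dropped = build_regions(
                ss, p_threshold=params["gwas_p_threshold"],
                window_bp=params["region_window"],
                min_snps=params["min_region_snps"])
            regions_by_trait[trait] = regions
            if len(dropped):
                _write_tsv(dropped, outdir / f"regions.dropped.{trait}.tsv")
        coloc_table = run_coloc_grid(eqtl_pairs, gwas, regions_by_trait,
                                     priors=priors, pp4_cut=params["pp4_cut"],
                                     exclusion_loci=tuple(params["exclusion_loci"]))
        if "coloc" in cfg["stages"]:
            _write_tsv(coloc_table, outdir / "coloc.tsv")
        log["n_coloc_tests"] = len(coloc_table)
        log["n_coloc_flagged"] = int(coloc_table["flagged"].sum()) if len(coloc_table) else 0

    # --- MR -----------------------------------------------------------------
    if "mr" in cfg["stages"] and len(coloc_table):
        flagged = coloc_table[coloc_table["flagged"]
                              & ~coloc_table["excluded_locus"]]
        exposure_stats, ld_by_gene = {}, {}
        for (gene, ct), sub in eqtl_pairs.groupby(["gene", "cell_type"]):
            exposure_stats[(gene, ct)] = sub.reset_index(drop=True)
            ld_by_gene[(gene, ct)] = ld_correlation(genotypes, list(sub["snp"]))
        mr_table, skips = run_mr(
            flagged, exposure_stats, gwas, ld_by_gene, exclusions=exclusions,
            excluded_genes=tuple(params["exclusion_loci"]),
            fdr_max=params["fdr"], r2_max=params["r2_max"],
            f_min=params["f_min"], var_explained=params["var_explained"])
        _write_tsv(mr_table, outdir / "mr.tsv")
        _write_tsv(skips, outdir / "mr.skipped.tsv")
        log["n_mr_significant"] = int(mr_table["significant"].sum()) if len(mr_table) else 0

    # --- manifest -----------------------------------------------------------
    outputs = sorted(p.name for p in outdir.glob("*.tsv"))
    manifest = {
        "config_hash": _config_hash({k: v for k, v in cfg.items() if k != "outdir"}),
        "seed": seed,
        "cohort_mode": cfg["cohort_mode"],
        "versions": {"scmr": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stage_log": log,
        "outputs": {name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
                    for name in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True, default=str))
    return outdir


def compare_cohorts(coloc_full: pd.DataFrame,
                    coloc_control: pd.DataFrame) -> pd.DataFrame:
    """Overlap of flagged colocalizations between two cohort runs.

    Returns one row per gene/cell-type/trait triplet seen in either run
    with its status: both, full_only, control_only or neither.
    """
    traits_full = set(coloc_full["trait"])
    traits_ctrl = set(coloc_control["trait"])
    if traits_full != traits_ctrl:
        raise ConfigurationError(
            f"trait sets differ between runs: {sorted(traits_full ^ traits_ctrl)}")
    key = ["gene", "cell_type", "trait"]
    f = coloc_full.set_index(key)["flagged"]
    c = coloc_control.set_index(key)["flagged"]
    idx = f.index.union(c.index)
    f = f.reindex(idx, fill_value=False)
    c = c.reindex(idx, fill_value=False)
    status = np.select(
        [f & c, f & ~c, ~f & c], ["both", "full_only", "control_only"], "neither")
    out = pd.DataFrame({"flagged_full": f, "flagged_control": c,
                        "status": status}, index=idx).reset_index()
    return out
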