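"""Seeded synthetic cohorts with known ground truth.

This module generates every input the pipeline consumes — genotypes with
block LD, donor covariates, cell-level counts, and GWAS/pQTL summary
statistics — from a single :class:`SimulationConfig`, so each downstream
stage can be tested against a :class:`TruthTable` without restricted-access
data.

Generative model
----------------
* Genotypes: per haplotype, a latent AR(1) Gaussian within each LD block
  (adjacent correlation ``ld_rho``) thresholded at the allele-frequency
  quantile; the two haplotypes are independent, so HWE holds marginally and
  dosages are hard calls in {0, 1, 2}.
* Cell counts: each donor's per-gene log-mean is
  ``baseline + covariate effects + beta_main*G + sum_d beta_d*G*1[diag=d]
  + beta_age*G*(age - mean age) + source random intercept
  + source-by-diagnosis random deviation + donor noise``,
  i.e. exactly the family fitted by the interaction mixed models; counts
  are negative binomial around ``exp(log-mean)`` (Poisson as the
  dispersion goes to 0).
* GWAS: summary statistics come from single-SNP regressions on a freshly
  simulated individual-level cohort whose phenotype is
  ``gamma * (SD-scaled dosage of the causal SNP) + noise`` (quantitative)
  or a liability-thresholded binary outcome (case-control), so the LD
  structure of the region is respected.

All randomness flows from ``config.seed`` through named sub-streams
(see :mod:`scmr._rng`), making every artifact bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from ._rng import rng_for
from .exceptions import ConfigurationError
from .genotype_io import GenotypeMatrix, GwasSumstats
from .pseudobulk import CellCounts

__all__ = [
    "CELL_TYPES",
    "DIAGNOSES",
    "SimulationConfig",
    "GwasPlan",
    "TruthTable",
    "make_snp_map",
    "make_gene_map",
    "default_config",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_cells",
    "simulate_gwas",
    "build_truth",
]

#: the eight brain cell types profiled by the study design this emulates
CELL_TYPES = (
    "excitatory_neurons",
    "inhibitory_neurons",
    "astrocytes",
    "microglia",
    "oligodendrocytes",
    "opcs",
    "endothelial",
    "pericytes",
)

DIAGNOSES = ("control", "AD", "PD", "MS")

#: cohort composition: 183 controls and 208 disease cases out of 391 donors;
#: the case split across AD/PD/MS is not pinned by the study design and is
#: configurable (near-even split by default).
DEFAULT_DIAGNOSIS_PROPORTIONS = {
    "control": 183 / 391,
    "AD": 70 / 391,
    "PD": 70 / 391,
    "MS": 68 / 391,
}


@dataclass
class GwasPlan:
    """Specification of one simulated outcome trait."""

    trait: str
    trait_type: str = "quant"  # quant | cc
    n: int = 50_000
    causal_snp: str | None = None
    gamma: float = 0.0  # outcome effect per SD of the genetic exposure
    case_fraction: float = 0.5  # cc only

    def validate(self, snp_map: pd.DataFrame) -> None:
        if self.n < 100:
            raise ConfigurationError(f"GWAS {self.trait}: N must be >= 100")
        if self.trait_type not in ("quant", "cc"):
            raise ConfigurationError(f"GWAS {self.trait}: bad trait_type {self.trait_type!r}")
        if self.trait_type == "cc" and not (0 < self.case_fraction < 1):
            raise ConfigurationError(f"GWAS {self.trait}: case fraction outside (0,1)")
        if self.causal_snp is not None and self.causal_snp not in snp_map.index:
            raise ConfigurationError(f"GWAS {self.trait}: causal SNP not in snp_map")
        if not np.isfinite(self.gamma):
            raise ConfigurationError(f"GWAS {self.trait}: gamma not finite")


@dataclass
class SimulationConfig:
    """All generative quantities of the synthetic study.

    ``snp_map`` needs columns chrom, pos (1-based bp), maf in [0, 0.5] and
    block (LD block id); ``gene_map`` columns gene (index), chrom, start,
    end, baseline (log-mean); ``effect_table`` one row per (gene,
    cell_type) genetic effect with columns gene, cell_type, snp, beta_main,
    beta_AD, beta_PD, beta_MS, beta_age.
    """

    n_donors: int = 391
    diagnosis_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_PROPORTIONS))
    n_sources: int = 4
    snp_map: pd.DataFrame = None
    ld_rho: float = 0.8
    gene_map: pd.DataFrame = None
    cell_plan: dict = field(default_factory=dict)  # cell_type -> mean cells/donor
    effect_table: pd.DataFrame = None
    gwas_plan: list = field(default_factory=list)
    source_re_sd: tuple = (0.1, 0.1)  # (intercept SD, per-diagnosis deviation SD)
    donor_noise_sd: float = 0.15
    nb_dispersion: float = 0.5
    age_mean: float = 75.0
    age_sd: float = 15.0
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.002, "sex": 0.05, "pmi": 0.002})
    seed: int = 0

    def validate(self) -> None:
        props = self.diagnosis_proportions
        if abs(sum(props.values()) - 1.0) > 1e-8:
            raise ConfigurationError("diagnosis proportions must sum to 1")
        if any(p < 0 for p in props.values()):
            raise ConfigurationError("negative diagnosis proportion")
        if self.n_sources < 1:
            raise ConfigurationError("n_sources must be >= 1")
        if not 0 <= self.ld_rho < 1:
            raise ConfigurationError("ld_rho must be in [0, 1)")
        maf = np.asarray(self.snp_map["maf"], float)
        if (~np.isfinite(maf)).any() or (maf < 0).any() or (maf > 0.5).any():
            raise ConfigurationError("MAF must be finite and in [0, 0.5]")
        if any(m < 0 for m in self.cell_plan.values()):
            raise ConfigurationError("negative cell counts in cell_plan")
        if self.effect_table is not None and len(self.effect_table):
            bad = set(self.effect_table["snp"]) - set(self.snp_map.index)
            if bad:
                raise ConfigurationError(f"effect_table causal SNPs not in snp_map: {bad}")
            bad = set(self.effect_table["gene"]) - set(self.gene_map.index)
            if bad:
                raise ConfigurationError(f"effect_table genes not in gene_map: {bad}")
        for plan in self.gwas_plan:
            plan.validate(self.snp_map)


@dataclass
class TruthTable:
    """Ground truth of the simulated study.

    ``egenes``: one row per (gene, cell_type) with the true causal SNP and
    effect sizes (genes without a row have no genetic effect).
    ``coloc``: one row per (gene, cell_type, trait) with the true
    colocalization flag and causal outcome effect gamma.
    """

    egenes: pd.DataFrame
    coloc: pd.DataFrame


# ---------------------------------------------------------------------------
# config builders


def make_snp_map(n_blocks: int = 4, block_size: int = 30, chrom: int = 1,
                 start: int = 1_000_000, spacing: int = 5_000,
                 maf_low: float = 0.1, maf_high: float = 0.5,
                 seed: int = 0, prefix: str = "rs") -> pd.DataFrame:
    rng = rng_for(seed, "snp_map")
    m = n_blocks * block_size
    pos = start + spacing * np.arange(m)
    maf = rng.uniform(maf_low, maf_high, size=m)
    ids = [f"{prefix}{chrom}_{p}" for p in pos]
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "maf": maf,
         "block": np.repeat(np.arange(n_blocks), block_size),
         "a1": "A", "a2": "G"},
        index=pd.Index(ids, name="snp"),
    )


def make_gene_map(n_genes: int, chrom: int = 1, start: int = 1_000_000,
                  spacing: int = 50_000, length: int = 20_000,
                  baseline: float = -0.7) -> pd.DataFrame:
    starts = start + spacing * np.arange(n_genes)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + length,
         "baseline": baseline},
        index=pd.Index([f"GENE{i}" for i in range(n_genes)], name="gene"),
    )


def default_config(seed: int = 0, n_donors: int = 391, n_genes: int = 12,
                   cell_types=CELL_TYPES[:2], cells_per_donor: float = 120.0,
                   **overrides) -> SimulationConfig:
    """A compact but fully featured configuration for demos and tests."""
    snp_map = make_snp_map(seed=seed)
    gene_map = make_gene_map(n_genes)
    rows = []
    block_lead = snp_map.groupby("block").head(1).index
    for ct in cell_types:
        for i, gene in enumerate(gene_map.index[: len(block_lead)]):
            rows.append({"gene": gene, "cell_type": ct,
                         "snp": block_lead[i % len(block_lead)],
                         "beta_main": 0.4 if i % 2 == 0 else 0.0,
                         "beta_AD": 0.3 if i % 3 == 0 else 0.0,
                         "beta_PD": 0.0, "beta_MS": 0.0, "beta_age": 0.0})
    effect_table = pd.DataFrame(rows)
    cfg = SimulationConfig(
        n_donors=n_donors,
        snp_map=snp_map,
        gene_map=gene_map,
        cell_plan={ct: cells_per_donor for ct in cell_types},
        effect_table=effect_table,
        gwas_plan=[GwasPlan("trait1", "quant", 20_000,
                            causal_snp=str(block_lead[0]), gamma=0.25)],
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generators


def _block_haplotypes(rng, n_hap: int, maf: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) latent Gaussian per haplotype, thresholded at Phi^-1(maf)."""
    m = len(maf)
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        eps = rng.standard_normal((n_hap, m - 1))
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j - 1]
    thresh = stats.norm.ppf(maf)  # maf=0 -> -inf -> monomorphic
    return (z < thresh[None, :]).astype(float)


def _draw_dosages(rng, n: int, snp_map: pd.DataFrame, ld_rho: float) -> np.ndarray:
    dosage = np.empty((n, len(snp_map)))
    blocks = snp_map["block"].to_numpy()
    maf = snp_map["maf"].to_numpy(float)
    for b in pd.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        h1 = _block_haplotypes(rng, n, maf[cols], ld_rho)
        h2 = _block_haplotypes(rng, n, maf[cols], ld_rho)
        dosage[:, cols] = h1 + h2
    return dosage


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw donor hard-call dosages with within-block AR(1) LD.

    The returned SNP map carries the empirical (recomputed) MAF.
    """
    config.validate()
    rng = rng_for(config.seed, "genotypes")
    dosage = _draw_dosages(rng, config.n_donors, config.snp_map, config.ld_rho)
    donors = pd.Index([f"D{i:04d}" for i in range(config.n_donors)])
    smap = config.snp_map.copy()
    freq = dosage.mean(axis=0) / 2.0
    smap["maf"] = np.minimum(freq, 1 - freq)
    if "a1" not in smap.columns:
        smap["a1"], smap["a2"] = "A", "G"
    return GenotypeMatrix(donors, config.snp_map.index, dosage, smap)


def _largest_remainder_counts(props: dict, n: int) -> dict:
    levels = list(props)
    raw = np.array([props[k] * n for k in levels])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="mergesort")
    for i in order[:rem]:
        counts[i] += 1
    return dict(zip(levels, counts))


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Donor covariates: age, sex, PMI, diagnosis, sample source.

    Diagnosis counts match the configured proportions up to rounding
    (largest-remainder apportionment).
    """
    config.validate()
    rng = rng_for(config.seed, "cohort")
    n = config.n_donors
    counts = _largest_remainder_counts(config.diagnosis_proportions, n)
    diagnosis = np.concatenate([[lvl] * c for lvl, c in counts.items()])
    rng.shuffle(diagnosis)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 35, 105)
    sex = rng.integers(0, 2, n)
    pmi = rng.gamma(shape=4.0, scale=6.0, size=n)  # hours, mean 24
    source = rng.integers(0, config.n_sources, n)
    return pd.DataFrame(
        {"age": age, "sex": sex, "pmi": pmi, "diagnosis": diagnosis,
         "source": [f"S{s}" for s in source]},
        index=pd.Index([f"D{i:04d}" for i in range(n)], name="donor"),
    )


def donor_log_means(genotypes: GenotypeMatrix, covariates: pd.DataFrame,
                    config: SimulationConfig, cell_type: str,
                    rng=None) -> pd.DataFrame:
    """Per-donor per-gene log-means for one cell type (the generative law).

    With ``rng=None`` the stochastic terms (source random effects and donor
    noise) are omitted, leaving the deterministic part only.
    """
    genes = config.gene_map.index
    donors = covariates.index
    eta = np.tile(config.gene_map["baseline"].to_numpy(float)[:, None], (1, len(donors)))
    ce = config.covariate_effects
    age_c = covariates["age"].to_numpy(float) - config.age_mean
    eta += ce.get("age", 0.0) * age_c[None, :]
    eta += ce.get("sex", 0.0) * covariates["sex"].to_numpy(float)[None, :]
    eta += ce.get("pmi", 0.0) * (covariates["pmi"].to_numpy(float) - 24.0)[None, :]

    diag = covariates["diagnosis"].to_numpy()
    eff = config.effect_table
    eff = eff[eff["cell_type"] == cell_type] if eff is not None else pd.DataFrame()
    for _, row in eff.iterrows():
        gi = genes.get_loc(row["gene"])
        g = genotypes.dosage[:, genotypes.snps.get_loc(row["snp"])]
        g = g[genotypes.donors.get_indexer(donors)]
        eta[gi] += row.get("beta_main", 0.0) * g
        for d in ("AD", "PD", "MS"):
            eta[gi] += row.get(f"beta_{d}", 0.0) * g * (diag == d)
        eta[gi] += row.get("beta_age", 0.0) * g * age_c

    if rng is not None:
        sd0, sd1 = config.source_re_sd
        sources = pd.unique(covariates["source"])
        src_idx = pd.Index(sources).get_indexer(covariates["source"])
        if sd0 > 0:
            u0 = rng.normal(0.0, sd0, size=(len(genes), len(sources)))
            eta += u0[:, src_idx]
        if sd1 > 0:
            levels = list(dict.fromkeys(diag))
            diag_idx = pd.Index(levels).get_indexer(diag)
            u1 = rng.normal(0.0, sd1, size=(len(genes), len(sources), len(levels)))
            eta += u1[:, src_idx, diag_idx]
        if config.donor_noise_sd > 0:
            eta += rng.normal(0.0, config.donor_noise_sd, size=eta.shape)
    return pd.DataFrame(eta, index=genes, columns=donors)


def simulate_cells(genotypes: GenotypeMatrix, covariates: pd.DataFrame,
                   config: SimulationConfig) -> dict:
    """Cell-level counts per cell type; negative binomial around exp(log-mean)."""
    config.validate()
    out = {}
    for cell_type, mean_cells in config.cell_plan.items():
        rng = rng_for(config.seed, "cells", cell_type)
        eta = donor_log_means(genotypes, covariates, config, cell_type, rng=rng)
        n_cells = rng.poisson(mean_cells, size=len(covariates))
        cell_donor_idx = np.repeat(np.arange(len(covariates)), n_cells)
        mu = np.exp(eta.to_numpy())[:, cell_donor_idx]
        if config.nb_dispersion <= 1e-12:
            counts = rng.poisson(mu)
        else:
            r = 1.0 / config.nb_dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        donors = covariates.index.to_numpy()[cell_donor_idx]
        out[cell_type] = CellCounts(cell_type, config.gene_map.index,
                                    sparse.csr_matrix(counts), donors)
    return out


def _marginal_stats(G: np.ndarray, y: np.ndarray):
    """Vectorized per-column simple regression of y on each dosage column."""
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    sxy = gc.T @ yc
    syy = (yc**2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = syy - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(np.where(sxx > 0, sigma2 / np.where(sxx > 0, sxx, 1.0), np.inf))
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return beta, se, p


def simulate_gwas(snp_map: pd.DataFrame, plan: GwasPlan, seed: int,
                  ld_rho: float = 0.8) -> GwasSumstats:
    """Marginal GWAS summary statistics from an individual-level simulation.

    A fresh cohort of ``plan.n`` individuals is drawn over ``snp_map`` with
    the same block-LD law as the eQTL cohort; the phenotype is
    ``gamma * x + noise`` where x is the SD-scaled dosage of the causal SNP
    (quantitative) or a liability-thresholded binary outcome whose effects
    are reported on an approximate log-odds scale (case-control).
    """
    plan.validate(snp_map)
    rng = rng_for(seed, "gwas", plan.trait)
    G = _draw_dosages(rng, plan.n, snp_map, ld_rho)
    if plan.causal_snp is not None:
        j = snp_map.index.get_loc(plan.causal_snp)
        g = G[:, j]
        sd = g.std()
        x = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
    else:
        x = np.zeros(plan.n)
    noise = rng.standard_normal(plan.n)

    if plan.trait_type == "quant":
        y = plan.gamma * x + noise
        beta, se, p = _marginal_stats(G, y)
        case_fraction = None
    else:
        liability = plan.gamma * x + noise
        thresh = stats.norm.ppf(1 - plan.case_fraction) * np.sqrt(1 + plan.gamma**2)
        y = (liability > thresh).astype(float)
        beta, se, p = _marginal_stats(G, y)
        mu = y.mean()
        # linear-probability to log-odds conversion (logistic approximation)
        beta = beta / (mu * (1 - mu))
        se = se / (mu * (1 - mu))
        case_fraction = float(mu)

    freq = G.mean(axis=0) / 2.0
    table = pd.DataFrame({
        "snp": snp_map.index,
        "chrom": snp_map["chrom"].to_numpy(),
        "pos": snp_map["pos"].to_numpy(),
        "a1": snp_map.get("a1", pd.Series("A", index=snp_map.index)).to_numpy(),
        "a2": snp_map.get("a2", pd.Series("G", index=snp_map.index)).to_numpy(),
        "beta": beta, "se": se, "p": np.clip(p, np.finfo(float).tiny, 1.0),
        "n": plan.n, "maf": np.minimum(freq, 1 - freq),
    }).reset_index(drop=True)
    table = table[table["se"].apply(np.isfinite)].reset_index(drop=True)
    return GwasSumstats(table, trait_type=plan.trait_type, case_fraction=case_fraction)


def build_truth(config: SimulationConfig) -> TruthTable:
    """Assemble the ground-truth table implied by the configuration."""
    eff = config.effect_table if config.effect_table is not None else pd.DataFrame(
        columns=["gene", "cell_type", "snp", "beta_main"])
    egenes = eff.copy()
    egenes["is_egene"] = (egenes.get("beta_main", 0) != 0)
    rows = []
    for plan in config.gwas_plan:
        for _, r in eff.iterrows():
            shared = (plan.causal_snp is not None and r["snp"] == plan.causal_snp
                      and r.get("beta_main", 0.0) != 0.0)
            rows.append({"gene": r["gene"], "cell_type": r["cell_type"],
                         "trait": plan.trait, "colocalizes": bool(shared),
                         "gamma": plan.gamma if shared else 0.0})
    coloc = pd.DataFrame(rows, columns=["gene", "cell_type", "trait",
                                        "colocalizes", "gamma"])
    return TruthTable(egenes, coloc)
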