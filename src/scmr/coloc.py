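"""Wakefield approximate-Bayes-factor colocalization.

For each region (a 1 Mb window around a genome-wide-significant GWAS lead)
and each gene/cell-type eQTL signal overlapping it, the five single-
causal-variant hypotheses are weighed:

* H0 no association with either trait,
* H1/H2 association with one trait only,
* H3 two distinct causal variants,
* H4 one shared causal variant.

Each SNP's evidence is its Wakefield approximate Bayes factor
``log ABF = 0.5 * (log(1 - r) + r * z^2)`` with ``z = beta/se``,
``r = W/(W + se^2)`` and prior effect variance ``W``: (0.15 * sdY)^2 for a
quantitative trait (sdY = 1 for standardized expression, otherwise
estimated from MAF and N) or 0.2^2 on the log-odds scale for case-control
traits.  Hypothesis sums are accumulated in log space (log-sum-exp), and
the per-SNP H4 posterior identifies the lead colocalized SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import ConfigurationError
from .genotype_io import GwasSumstats, window_clump

__all__ = ["ColocPriors", "Region", "ColocRecord", "log_abf", "estimate_sdy",
           "trait_log_abf", "coloc_abf", "build_regions", "run_coloc_grid",
           "align_alleles"]


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities and prior effect scales.

    p1/p2: a SNP is causal for trait 1/2 only; p12: for both.  The pQTL
    replication stage overrides p12 = 0.01.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    c_quant: float = 0.15  # prior effect SD per sdY unit (quantitative)
    c_cc: float = 0.2  # prior effect SD, log-odds scale (case-control)

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ConfigurationError("coloc priors must be positive")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ConfigurationError("p1 + p2 + p12 must be < 1")


@dataclass
class Region:
    """A colocalization test region: lead GWAS SNP +/- half the window."""

    region_id: str
    chrom: int
    start: int
    end: int
    lead_snp: str
    snps: pd.DataFrame  # GWAS rows inside the region


@dataclass
class ColocRecord:
    region_id: str
    gene: str
    cell_type: str
    trait: str
    n_snps: int
    pp: np.ndarray  # PP.H0..PP.H4
    lead_snp: str  # max per-SNP H4 posterior
    flagged: bool = False
    excluded_locus: bool = False


def log_abf(beta, se, prior_sd: float) -> np.ndarray:
    """Per-SNP Wakefield log approximate Bayes factor."""
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    z = beta / se
    V = se**2
    r = prior_sd**2 / (prior_sd**2 + V)
    return 0.5 * (np.log1p(-r) + r * z**2)


def estimate_sdy(beta_var, maf, n) -> float:
    """Trait SD from summary statistics: sdY^2 is the through-origin
    regression slope of 2*N*MAF*(1-MAF) on 1/var(beta) across SNPs."""
    beta_var = np.asarray(beta_var, float)
    maf = np.asarray(maf, float)
    n = np.asarray(n, float)
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("MAF must be in (0, 0.5] to estimate sdY")
    oneover = 1.0 / beta_var
    nvx = 2.0 * n * maf * (1.0 - maf)
    slope = float((nvx * oneover).sum() / (oneover**2).sum())
    if slope <= 0:
        raise ValueError("negative sdY^2 slope: inconsistent summary statistics")
    return float(np.sqrt(slope))


def trait_log_abf(stats_df: pd.DataFrame, trait_type: str, priors: ColocPriors,
                  sdY: float | None = None) -> np.ndarray:
    """Per-SNP log ABF for one trait's aligned summary statistics.

    For quantitative traits ``sdY=None`` triggers estimation from the maf/n
    columns; standardized-expression eQTL datasets should pass ``sdY=1``.
    """
    if trait_type == "cc":
        prior_sd = priors.c_cc
    else:
        if sdY is None:
            sdY = estimate_sdy(stats_df["se"].to_numpy() ** 2,
                               stats_df["maf"].to_numpy(), stats_df["n"].to_numpy())
        prior_sd = priors.c_quant * sdY
    return log_abf(stats_df["beta"].to_numpy(), stats_df["se"].to_numpy(), prior_sd)


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(labf1: np.ndarray, labf2: np.ndarray,
              priors: ColocPriors = ColocPriors()):
    """Posterior probabilities of H0..H4 from per-SNP log ABFs.

    Returns (pp, per_snp_h4) where pp is the length-5 posterior vector and
    per_snp_h4 the normalized per-SNP posterior under H4.
    """
    labf1 = np.asarray(labf1, float)
    labf2 = np.asarray(labf2, float)
    if labf1.shape != labf2.shape or labf1.size < 2:
        raise ValueError("coloc_abf needs >= 2 shared SNPs with aligned ABFs")
    lS1 = logsumexp(labf1)
    lS2 = logsumexp(labf2)
    lS12 = logsumexp(labf1 + labf2)
    lcross = _logdiffexp(lS1 + lS2, lS12)  # sum over i != j
    lw = np.array([
        0.0,
        np.log(priors.p1) + lS1,
        np.log(priors.p2) + lS2,
        np.log(priors.p1) + np.log(priors.p2) + lcross,
        np.log(priors.p12) + lS12,
    ])
    pp = np.exp(lw - logsumexp(lw))
    per_snp_h4 = np.exp(labf1 + labf2 - lS12)
    return pp, per_snp_h4


def build_regions(gwas: GwasSumstats, p_threshold: float = 5e-8,
                  window_bp: int = 1_000_000, min_snps: int = 100):
    """Lead-SNP windows repopulated with every GWAS SNP inside.

    Leads come from greedy distance clumping; each region is lead +/-
    ``window_bp``/2.  Regions with fewer than ``min_snps`` SNPs are dropped
    (reported).  Returns (regions, dropped report DataFrame).
    """
    table = gwas.table
    leads = window_clump(table, p_threshold=p_threshold, window_bp=window_bp)
    half = window_bp // 2
    regions, dropped = [], []
    for _, lead in leads.iterrows():
        start = int(lead["pos"]) - half
        end = int(lead["pos"]) + half
        inside = table[(table["chrom"] == lead["chrom"]) & (table["pos"] >= start)
                       & (table["pos"] <= end)]
        rid = f"chr{lead['chrom']}:{start}-{end}"
        if len(inside) < min_snps:
            dropped.append({"region_id": rid, "lead_snp": lead["snp"],
                            "n_snps": len(inside), "reason": "min_snps"})
            continue
        regions.append(Region(rid, int(lead["chrom"]), start, end,
                              str(lead["snp"]), inside.reset_index(drop=True)))
    return regions, pd.DataFrame(dropped, columns=["region_id", "lead_snp",
                                                   "n_snps", "reason"])


def align_alleles(eqtl: pd.DataFrame, gwas: pd.DataFrame) -> pd.DataFrame:
    """Inner-join eQTL and GWAS stats on SNP id and align effect alleles.

    A GWAS row with swapped A1/A2 has its beta sign flipped; unresolvable
    allele pairs are dropped (counted in the ``n_dropped`` attribute).
    Palindromic (strand-ambiguous) SNPs are retained and flagged.
    """
    merged = eqtl.merge(gwas, on="snp", suffixes=("_e", "_g"))
    a1e = merged["a1_e"].str.upper()
    a2e = merged["a2_e"].str.upper()
    a1g = merged["a1_g"].str.upper()
    a2g = merged["a2_g"].str.upper()
    match = (a1e == a1g) & (a2e == a2g)
    swap = (a1e == a2g) & (a2e == a1g)
    merged.loc[swap, "beta_g"] *= -1.0
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    merged["palindromic"] = a1e.map(comp).fillna("?") == a2e
    out = merged[match | swap].reset_index(drop=True)
    out.attrs["n_dropped"] = int((~(match | swap)).sum())
    return out


def run_coloc_grid(eqtl_pairs: pd.DataFrame, gwas_by_trait: dict,
                   regions_by_trait: dict, priors: ColocPriors = ColocPriors(),
                   pp4_cut: float = 0.8, min_shared_snps: int = 2,
                   exclusion_loci: tuple = ()) -> pd.DataFrame:
    """One colocalization test per (gene, cell type, region, trait).

    ``eqtl_pairs`` is the per-pair scan table (columns cell_type, gene, snp,
    chrom, pos, a1, a2, beta, se); a gene/cell-type is tested in a region
    when it has eQTL statistics for at least ``min_shared_snps`` of the
    region's SNPs.  eQTL prior SD uses sdY = 1 (standardized expression);
    the GWAS side uses its trait type.  Genes named in ``exclusion_loci``
    (e.g. MAPT/HLA members) are flagged, not silently merged.
    """
    records = []
    for trait, regions in regions_by_trait.items():
        gwas = gwas_by_trait[trait]
        gtab = gwas.table
        gwas_sdY = None
        if gwas.trait_type == "quant" and {"maf", "n"} <= set(gtab.columns):
            gwas_sdY = estimate_sdy(gtab["se"].to_numpy() ** 2,
                                    gtab["maf"].clip(1e-6, 0.5).to_numpy(),
                                    gtab["n"].to_numpy())
        for region in regions:
            rsnps = set(region.snps["snp"])
            epairs = eqtl_pairs[eqtl_pairs["snp"].isin(rsnps)]
            for (ct, gene), sub in epairs.groupby(["cell_type", "gene"], sort=True):
                aligned = align_alleles(
                    sub.rename(columns={"beta": "beta", "se": "se"}),
                    region.snps)
                if len(aligned) < min_shared_snps:
                    continue
                labf_e = trait_log_abf(
                    aligned.rename(columns={"beta_e": "beta", "se_e": "se"})
                    [["beta", "se"]], "quant", priors, sdY=1.0)
                gstats = aligned.rename(columns={"beta_g": "beta", "se_g": "se"})
                if gwas.trait_type == "cc":
                    labf_g = trait_log_abf(gstats[["beta", "se"]], "cc", priors)
                else:
                    labf_g = trait_log_abf(gstats[["beta", "se"]], "quant",
                                           priors, sdY=gwas_sdY)
                pp, per_snp = coloc_abf(labf_e, labf_g, priors)
                lead = aligned["snp"].iloc[int(np.argmax(per_snp))]
                records.append({
                    "trait": trait, "region_id": region.region_id, "gene": gene,
                    "cell_type": ct, "n_snps": len(aligned),
                    "pp_h0": pp[0], "pp_h1": pp[1], "pp_h2": pp[2],
                    "pp_h3": pp[3], "pp_h4": pp[4], "lead_snp": lead,
                    "lead_snp_h4": float(per_snp.max()),
                    "flagged": bool(pp[4] > pp4_cut),
                    "excluded_locus": gene in exclusion_loci,
                })
    cols = ["trait", "region_id", "gene", "cell_type", "n_snps", "pp_h0",
            "pp_h1", "pp_h2", "pp_h3", "pp_h4", "lead_snp", "lead_snp_h4",
            "flagged", "excluded_locus"]
    return pd.DataFrame(records, columns=cols)
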