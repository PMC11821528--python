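"""Colocalization-anchored two-sample Mendelian randomization.

Instruments for a (gene, cell type) exposure are selected inside the
colocalized region: cis-eQTL associations below 5% FDR, r^2-pruned
(threshold 0.01) with the colocalization lead SNP as the anchor, then
filtered on instrument strength F = (beta_x / se_x)^2 > 15.  Estimators:

* Wald ratio (single instrument): beta = by/bx, se = se_y/|bx|;
* fixed-effects IVW, which reduces to the Wald ratio for one instrument;
* PCA-IVW: the weighted matrix Psi_kl = (bx_k/se_y,k)(bx_l/se_y,l) rho_kl
  is eigendecomposed, the top components covering ``var_explained`` of its
  trace replace the correlated instruments, and a generalized
  (correlation-aware) IVW is run on the projected effects.

Exposures with a significant disease- or age-interaction (context-dependent
allelic effects) are excluded up front, as are configured MAPT/HLA loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import LdMatrix, r2_prune

__all__ = ["IvSet", "harmonize", "f_statistic", "select_ivs", "wald_ratio",
           "ivw_fixed", "pca_ivw", "run_mr"]


@dataclass
class IvSet:
    """Harmonized instruments for one exposure (gene, cell type)."""

    gene: str
    cell_type: str
    trait: str
    snps: list
    bx: np.ndarray
    se_x: np.ndarray
    by: np.ndarray
    se_y: np.ndarray
    f_stats: np.ndarray
    anchor: str | None = None
    ld: LdMatrix | None = None

    def __len__(self) -> int:
        return len(self.snps)


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele (A1).

    Exact A1/A2 match keeps the row; swapped alleles flip the outcome beta;
    anything else is dropped with reason "allele_mismatch".  Palindromic
    SNPs are flagged (retained by default; drop them for strict mode).
    Returns the merged frame with columns bx, se_x, by, se_y.
    """
    for df, side in ((exposure, "exposure"), (outcome, "outcome")):
        if not {"a1", "a2"} <= set(df.columns):
            raise ValueError(f"{side} table lacks allele columns a1/a2")
    m = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))
    a1x, a2x = m["a1_x"].str.upper(), m["a2_x"].str.upper()
    a1y, a2y = m["a1_y"].str.upper(), m["a2_y"].str.upper()
    match = (a1x == a1y) & (a2x == a2y)
    swap = (a1x == a2y) & (a2x == a1y)
    m.loc[swap, "beta_y"] *= -1.0
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    m["palindromic"] = a1x.map(comp).fillna("?") == a2x
    m["drop_reason"] = np.where(match | swap, "", "allele_mismatch")
    out = m[match | swap].reset_index(drop=True)
    out = out.rename(columns={"beta_x": "bx", "se_x": "se_x",
                              "beta_y": "by", "se_y": "se_y"})
    out.attrs["n_dropped"] = int((~(match | swap)).sum())
    return out


def f_statistic(bx, se_x) -> np.ndarray:
    """Per-SNP instrument strength: the squared exposure t statistic."""
    bx = np.asarray(bx, float)
    se_x = np.asarray(se_x, float)
    if (se_x <= 0).any():
        raise ValueError("exposure standard errors must be positive")
    return (bx / se_x) ** 2


def select_ivs(region_stats: pd.DataFrame, coloc_lead: str, ld: LdMatrix,
               gene: str, cell_type: str, trait: str, fdr_max: float = 0.05,
               r2_max: float = 0.01, f_min: float = 15.0):
    """Instrument selection anchored on the colocalization lead SNP.

    ``region_stats``: harmonized per-SNP frame with columns snp, p, fdr,
    bx, se_x, by, se_y.  Candidates are associations at FDR < ``fdr_max``;
    the anchor (if eligible) survives pruning by construction; SNPs with
    F <= ``f_min`` are dropped after pruning.  Returns (IvSet | None,
    skip_reason).
    """
    cand = region_stats[region_stats["fdr"] < fdr_max].copy()
    if coloc_lead not in set(region_stats["snp"]):
        raise KeyError(f"anchor SNP {coloc_lead!r} absent from exposure statistics")
    if cand.empty:
        return None, "no_candidates_below_fdr"
    anchor = coloc_lead if coloc_lead in set(cand["snp"]) else None
    kept = r2_prune(cand[["snp", "p"]], ld, r2_threshold=r2_max, anchor=anchor)
    sub = cand.set_index("snp").loc[kept].reset_index()
    F = f_statistic(sub["bx"], sub["se_x"])
    strong = F > f_min
    if not strong.any():
        return None, "no_instrument_above_F"
    sub = sub[strong]
    F = F[strong]
    ivs = IvSet(gene, cell_type, trait, list(sub["snp"]),
                sub["bx"].to_numpy(float), sub["se_x"].to_numpy(float),
                sub["by"].to_numpy(float), sub["se_y"].to_numpy(float),
                np.asarray(F, float),
                anchor=anchor if anchor in set(sub["snp"]) else None,
                ld=ld.submatrix(sub["snp"]))
    return ivs, ""


def wald_ratio(bx: float, se_x: float, by: float, se_y: float):
    """Single-instrument estimate: beta = by/bx, se = se_y/|bx| (first order)."""
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    beta = by / bx
    se = se_y / abs(bx)
    p = 2 * stats.norm.sf(abs(beta / se))
    return float(beta), float(se), float(p)


def ivw_fixed(ivs: IvSet):
    """Fixed-effects inverse-variance-weighted estimate.

    beta = sum(bx*by/se_y^2) / sum(bx^2/se_y^2); for a single instrument
    this is identical to the Wald ratio.
    """
    if len(ivs) == 0:
        raise ValueError("empty instrument set")
    w = ivs.bx**2 / ivs.se_y**2
    beta = float((ivs.bx * ivs.by / ivs.se_y**2).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def pca_ivw(bx, se_y, by, ld: LdMatrix | np.ndarray, var_explained: float = 0.999,
            ridge: float = 1e-8):
    """Generalized IVW on principal components of the weighted instruments.

    Psi_kl = (bx_k/se_y,k)(bx_l/se_y,l) rho_kl is eigendecomposed; the
    smallest k with cumulative eigenvalue fraction >= ``var_explained``
    defines the projection W; the estimate is GLS with outcome covariance
    Sigma_kl = se_y,k se_y,l rho_kl projected onto W.
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    se_y = np.asarray(se_y, float)
    rho = ld.rho if isinstance(ld, LdMatrix) else np.asarray(ld, float)
    if len(bx) < 2:
        raise ValueError("PCA-IVW needs >= 2 SNPs")
    psi_vec = bx / se_y
    Psi = np.outer(psi_vec, psi_vec) * rho
    evals, evecs = np.linalg.eigh(Psi)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    total = evals.sum()
    frac = np.cumsum(evals) / total if total > 0 else np.ones_like(evals)
    k = int(np.searchsorted(frac, var_explained - 1e-12) + 1)
    k = min(k, len(evals))
    W = evecs[:, :k]
    bxp = W.T @ bx
    byp = W.T @ by
    Sigma = np.outer(se_y, se_y) * rho
    Sp = W.T @ Sigma @ W
    try:
        Si = np.linalg.inv(Sp)
    except np.linalg.LinAlgError:
        warnings.warn("projected outcome covariance singular; adding ridge")
        Sp = Sp + ridge * np.eye(k)
        Si = np.linalg.inv(Sp)
    denom = float(bxp @ Si @ bxp)
    beta = float(bxp @ Si @ byp) / denom
    se = float(np.sqrt(1.0 / denom))
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return beta, se, p, k


def run_mr(coloc_flagged: pd.DataFrame, exposure_stats: dict, gwas_by_trait: dict,
           ld_by_gene: dict, exclusions: set = frozenset(),
           excluded_genes: tuple = (), fdr_max: float = 0.05,
           r2_max: float = 0.01, f_min: float = 15.0,
           var_explained: float = 0.999):
    """MR over colocalization-flagged exposures; Wald/IVW primary, PCA-IVW
    cross-validation.

    Parameters
    ----------
    coloc_flagged : ColocRecord table rows with pp_h4 above the cut
        (columns trait, gene, cell_type, lead_snp).
    exposure_stats : (gene, cell_type) -> per-SNP frame with columns snp,
        a1, a2, beta, se, p, fdr over the region.
    gwas_by_trait : trait -> GwasSumstats (outcome).
    ld_by_gene : (gene, cell_type) -> LdMatrix over the exposure SNPs.
    exclusions : set of (gene, cell_type) with disease/age interaction
        evidence (excluded, logged).
    excluded_genes : genes in excluded loci (MAPT/HLA), dropped entirely.

    Returns (MrRecord table, skip log).
    """
    records, skips = [], []
    for _, row in coloc_flagged.iterrows():
        gene, ct, trait = row["gene"], row["cell_type"], row["trait"]
        key = (gene, ct)
        if gene in excluded_genes:
            skips.append({"gene": gene, "cell_type": ct, "trait": trait,
                          "reason": "excluded_locus"})
            continue
        if key in exclusions:
            skips.append({"gene": gene, "cell_type": ct, "trait": trait,
                          "reason": "interaction_exclusion"})
            continue
        exp = exposure_stats[key].rename(columns={"beta": "bx", "se": "se_x"})
        out = gwas_by_trait[trait].table.rename(
            columns={"beta": "beta_y", "se": "se_y"})
        merged = exp.merge(out[["snp", "a1", "a2", "beta_y", "se_y"]], on="snp",
                           suffixes=("", "_y"))
        merged = merged.rename(columns={"a1": "a1_x", "a2": "a2_x",
                                        "a1_y": "a1_y", "a2_y": "a2_y"})
        a1x, a2x = merged["a1_x"].str.upper(), merged["a2_x"].str.upper()
        a1y, a2y = merged["a1_y"].str.upper(), merged["a2_y"].str.upper()
        match = (a1x == a1y) & (a2x == a2y)
        swap = (a1x == a2y) & (a2x == a1y)
        merged.loc[swap, "beta_y"] *= -1.0
        merged = merged[match | swap].rename(columns={"beta_y": "by"})
        if merged.empty:
            skips.append({"gene": gene, "cell_type": ct, "trait": trait,
                          "reason": "no_harmonizable_snps"})
            continue
        try:
            ivs, reason = select_ivs(merged, row["lead_snp"], ld_by_gene[key],
                                     gene, ct, trait, fdr_max=fdr_max,
                                     r2_max=r2_max, f_min=f_min)
        except KeyError:
            skips.append({"gene": gene, "cell_type": ct, "trait": trait,
                          "reason": "anchor_missing"})
            continue
        if ivs is None:
            skips.append({"gene": gene, "cell_type": ct, "trait": trait,
                          "reason": reason})
            continue
        beta, se, p = ivw_fixed(ivs)
        method = "wald" if len(ivs) == 1 else "ivw_fe"
        rec = {"gene": gene, "cell_type": ct, "trait": trait, "n_iv": len(ivs),
               "method": method, "beta": beta, "se": se, "p": p,
               "significant": p < 0.05, "pca_beta": np.nan, "pca_se": np.nan,
               "pca_p": np.nan, "direction_agree": np.nan}
        # PCA-IVW cross-validation over the full FDR-passing region set
        full = merged[merged["fdr"] < fdr_max]
        if len(full) >= 2:
            ld_full = ld_by_gene[key].submatrix(full["snp"])
            pb, ps, pp_, _ = pca_ivw(full["bx"].to_numpy(), full["se_y"].to_numpy(),
                                     full["by"].to_numpy(), ld_full,
                                     var_explained=var_explained)
        else:
            pb, ps, pp_ = beta, se, p
        rec.update(pca_beta=pb, pca_se=ps, pca_p=pp_,
                   direction_agree=bool(np.sign(pb) == np.sign(beta)))
        records.append(rec)
    cols = ["gene", "cell_type", "trait", "n_iv", "method", "beta", "se", "p",
            "significant", "pca_beta", "pca_se", "pca_p", "direction_agree"]
    return (pd.DataFrame(records, columns=cols),
            pd.DataFrame(skips, columns=["gene", "cell_type", "trait", "reason"]))
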