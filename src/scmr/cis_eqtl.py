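"""Covariate residualization, PC optimization and the windowed cis-eQTL scan.

The scan model per (SNP, gene) pair is

    E ~ G + expression PCs(1..n) + genotype PCs(1..5)

where E is scaled expression residualized on clinical/technical covariates
(age, sex, PMI, diagnosis, sample source) and G the effect-allele dosage.
SNPs are tested against a gene when the distance from the SNP to the
nearest gene-body boundary is at most the cis window (1 Mb by default,
0 inside the gene).  P-values come from the exact OLS t distribution and
are BH-adjusted across all tested pairs within a cell type; an eGene is a
gene whose minimum FDR is below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import RankDeficiencyError
from .genotype_io import GenotypeMatrix
from .pseudobulk import Pseudobulk

__all__ = ["PcSet", "EqtlResult", "bh_fdr", "residualize", "compute_pcs",
           "optimize_pcs", "map_cis", "build_covariate_design"]


@dataclass
class PcSet:
    """Orthonormal donor-score PCs used as scan covariates."""

    expr_pcs: pd.DataFrame  # donors x n_expr
    geno_pcs: pd.DataFrame  # donors x n_geno

    def design(self, n_expr: int | None = None) -> pd.DataFrame:
        e = self.expr_pcs if n_expr is None else self.expr_pcs.iloc[:, :n_expr]
        return pd.concat([e, self.geno_pcs], axis=1)


@dataclass
class EqtlResult:
    """Per-pair scan statistics and the derived eGene table."""

    pairs: pd.DataFrame  # cell_type gene snp chrom pos a1 beta se t p fdr
    egenes: pd.DataFrame  # gene lead_snp min_p min_fdr is_egene
    n_imputed_dosages: int = 0

    def egene_count(self, fdr: float = 0.05) -> int:
        return int((self.egenes["min_fdr"] < fdr).sum())


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values passed to bh_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def build_covariate_design(covariates: pd.DataFrame,
                           fixed_terms=("age", "sex", "pmi", "diagnosis", "source"),
                           ) -> pd.DataFrame:
    """Intercept + numeric terms + one-hot categoricals (reference dropped).

    Constant categorical terms (e.g. diagnosis in a control-only run)
    contribute no columns.
    """
    cols = {"intercept": np.ones(len(covariates))}
    for term in fixed_terms:
        v = covariates[term]
        if v.dtype.kind in "if" and term not in ("diagnosis", "source"):
            arr = v.to_numpy(float)
            if np.ptp(arr) > 0:  # constant terms are absorbed by the intercept
                cols[term] = arr
        else:
            levels = list(pd.unique(v))
            for lvl in levels[1:]:
                cols[f"{term}[{lvl}]"] = (v == lvl).to_numpy(float)
    X = pd.DataFrame(cols, index=covariates.index)
    _check_full_rank(X)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(float)
    r = np.linalg.qr(A, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(A.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [X.columns[i] for i in np.flatnonzero(diag <= tol)]
    if bad:
        raise RankDeficiencyError(f"collinear design columns: {bad}")


def residualize(expr: Pseudobulk, covariates: pd.DataFrame,
                fixed_terms=("age", "sex", "pmi", "diagnosis", "source"),
                ) -> Pseudobulk:
    """Per-gene least-squares residuals of expression on the covariates."""
    if expr.stage != "scaled":
        raise ValueError(f"residualize expects scaled expression, got {expr.stage!r}")
    cov = covariates.loc[expr.donors]
    X = build_covariate_design(cov, fixed_terms).to_numpy(float)
    Y = expr.matrix.to_numpy(float).T  # donors x genes
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    out = pd.DataFrame(resid.T, index=expr.genes, columns=expr.donors)
    return Pseudobulk(expr.cell_type, out, "residual", expr.cells_per_donor)


def _svd_scores(A: np.ndarray, n: int) -> np.ndarray:
    """Left singular vectors with a fixed sign convention.

    The sign of each component is chosen so that the largest-magnitude
    loading (right singular vector entry) is positive, making results
    reproducible across runs and LAPACK builds.
    """
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int((s > s[0] * max(A.shape) * np.finfo(float).eps).sum()) if s.size else 0
    if n > rank:
        raise ValueError(f"requested {n} PCs but matrix rank is {rank}")
    for k in range(n):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            U[:, k] *= -1
            Vt[k] *= -1
    return U[:, :n]


def compute_pcs(residuals: Pseudobulk, genotypes: GenotypeMatrix,
                n_expr: int, n_geno: int = 5) -> PcSet:
    """Expression PCs from the donor x gene residual matrix and genotype PCs
    from centred dosages (population structure), both as orthonormal donor
    scores."""
    donors = residuals.donors
    A = residuals.matrix.to_numpy(float).T
    A = A - A.mean(axis=0)
    expr_u = _svd_scores(A, n_expr) if n_expr > 0 else np.empty((len(donors), 0))
    G = genotypes.subset_donors(donors).dosage
    G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
    G = G - G.mean(axis=0)
    n_geno = min(n_geno, min(G.shape) - 1) if min(G.shape) > 1 else 0
    geno_u = _svd_scores(G, n_geno) if n_geno > 0 else np.empty((len(donors), 0))
    return PcSet(
        pd.DataFrame(expr_u, index=donors,
                     columns=[f"ePC{i+1}" for i in range(expr_u.shape[1])]),
        pd.DataFrame(geno_u, index=donors,
                     columns=[f"gPC{i+1}" for i in range(geno_u.shape[1])]),
    )


def _cis_distance(pos: np.ndarray, start: int, end: int) -> np.ndarray:
    d = np.maximum.reduce([start - pos, pos - end, np.zeros_like(pos)])
    return d


def map_cis(residuals: Pseudobulk, genotypes: GenotypeMatrix, pcs: PcSet | None,
            gene_map: pd.DataFrame, cis_window: float = 1e6, fdr: float = 0.05,
            maf_floor: float = 0.05, n_expr_pcs: int | None = None) -> EqtlResult:
    """Windowed cis-eQTL linear scan with BH FDR across all tested pairs.

    Missing dosages are mean-imputed per SNP for the scan only (count
    reported).  Returns per-pair statistics plus the eGene table (lead SNP
    = minimum p per gene).
    """
    donors = residuals.donors
    gm = genotypes.subset_donors(donors)
    n = len(donors)

    if pcs is not None:
        W = np.column_stack([np.ones(n), pcs.design(n_expr_pcs).loc[donors].to_numpy(float)])
    else:
        W = np.ones((n, 1))
    Qw, _ = np.linalg.qr(W)
    p_cov = W.shape[1]
    df = n - p_cov - 1

    D = gm.dosage.copy()
    nan_mask = np.isnan(D)
    n_imputed = int(nan_mask.sum())
    if n_imputed:
        col_means = np.nanmean(D, axis=0)
        D[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
    maf = np.minimum(D.mean(axis=0) / 2.0, 1 - D.mean(axis=0) / 2.0)
    snp_ok = maf >= maf_floor

    Dres = D - Qw @ (Qw.T @ D)
    Y = residuals.matrix.to_numpy(float).T
    Yres = Y - Qw @ (Qw.T @ Y)

    sxx = (Dres**2).sum(axis=0)
    pos = gm.snp_map["pos"].to_numpy()
    chrom = gm.snp_map["chrom"].to_numpy()

    frames = []
    for gi, gene in enumerate(residuals.genes):
        if gene not in gene_map.index:
            continue
        grow = gene_map.loc[gene]
        same_chr = chrom == grow["chrom"]
        dist = _cis_distance(pos, int(grow["start"]), int(grow["end"]))
        sel = np.flatnonzero(same_chr & (dist <= cis_window) & snp_ok & (sxx > 0))
        if sel.size == 0:
            continue
        y = Yres[:, gi]
        sxy = Dres[:, sel].T @ y
        syy = float(y @ y)
        beta = sxy / sxx[sel]
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / sxx[sel])
        with np.errstate(divide="ignore"):
            t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
        pv = 2 * stats.t.sf(np.abs(t), df=df)
        pv = np.clip(pv, np.finfo(float).tiny, 1.0)
        frames.append(pd.DataFrame({
            "cell_type": residuals.cell_type, "gene": gene,
            "snp": gm.snps[sel], "chrom": chrom[sel], "pos": pos[sel],
            "a1": gm.snp_map["a1"].to_numpy()[sel],
            "a2": gm.snp_map["a2"].to_numpy()[sel],
            "distance": dist[sel], "beta": beta, "se": se, "t": t, "p": pv,
        }))
    if not frames:
        pairs = pd.DataFrame(columns=["cell_type", "gene", "snp", "chrom", "pos",
                                      "a1", "a2", "distance", "beta", "se", "t",
                                      "p", "fdr"])
        egenes = pd.DataFrame(columns=["gene", "lead_snp", "min_p", "min_fdr",
                                       "is_egene"])
        return EqtlResult(pairs, egenes, n_imputed)
    pairs = pd.concat(frames, ignore_index=True)
    pairs["fdr"] = bh_fdr(pairs["p"].to_numpy())

    lead_idx = pairs.groupby("gene")["p"].idxmin()
    egenes = pd.DataFrame({
        "gene": lead_idx.index,
        "lead_snp": pairs.loc[lead_idx, "snp"].to_numpy(),
        "min_p": pairs.loc[lead_idx, "p"].to_numpy(),
        "min_fdr": pairs.groupby("gene")["fdr"].min().to_numpy(),
    })
    egenes["is_egene"] = egenes["min_fdr"] < fdr
    return EqtlResult(pairs, egenes.reset_index(drop=True), n_imputed)


def optimize_pcs(residuals: Pseudobulk, genotypes: GenotypeMatrix,
                 gene_map: pd.DataFrame, pc_grid, n_geno: int = 5,
                 cis_window: float = 1e6, fdr: float = 0.05,
                 maf_floor: float = 0.05):
    """Choose the expression-PC count maximizing the eGene count.

    Runs the scan at each grid value; ties break to the smallest n.
    Returns (chosen_n, {n: egene_count}).
    """
    pc_grid = sorted(set(int(g) for g in pc_grid))
    if not pc_grid:
        raise ValueError("pc_grid is empty")
    pcs_full = compute_pcs(residuals, genotypes, n_expr=max(pc_grid), n_geno=n_geno)
    counts = {}
    for n in pc_grid:
        res = map_cis(residuals, genotypes, pcs_full, gene_map,
                      cis_window=cis_window, fdr=fdr, maf_floor=maf_floor,
                      n_expr_pcs=n)
        counts[n] = res.egene_count(fdr)
    best = max(counts.values())
    chosen = min(n for n, c in counts.items() if c == best)
    return chosen, counts
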