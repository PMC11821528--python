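"""Nested linear mixed models for genotype x context interactions.

For each top eSNP-gene pair the scan fits three nested models by maximum
likelihood and compares them with likelihood-ratio tests:

* M0 (null): expression ~ diagnosis + age + PMI + sex + PCs
* M1 (eQTL): M0 + G
* M2 (interaction): M1 + G x diagnosis

all with a nested random structure — a random intercept per sample source
plus a per-(source, diagnosis) deviation — to absorb brain-bank and
diagnostic-practice effects that a fixed source term cannot capture.
M0 vs M1 (df 1) validates the discovery eQTL; when it passes (p < 0.05),
M1 vs M2 (df = number of non-reference diagnosis levels) tests for a
disease-dependent allelic effect, with Storey q-values across genes per
cell type.  The age variant (control-only cohorts) compares G + age
against G x age with a source random intercept only.

The likelihood is maximized by direct optimization over the variance
components with the fixed effects and residual variance profiled out
(Woodbury/determinant-lemma identities keep each evaluation at the cost of
a small q x q Cholesky, q = number of random-effect columns).  With all
random-effect variances at 0 the log-likelihood equals the OLS Gaussian
log-likelihood, which is always evaluated as a candidate, so degenerate
fits reduce exactly to OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import RankDeficiencyError

__all__ = ["LmeFit", "fit_lme", "lrt", "qvalues", "build_interaction_design",
           "interaction_scan", "age_interaction_scan"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LmeFit:
    """A fitted Gaussian (mixed) linear model (ML)."""

    params: pd.Series
    bse: pd.Series
    loglik: float
    sigma2: float
    varcomps: dict
    converged: bool
    n: int
    columns: tuple
    method: str = "ML"

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Wald p-values (normal approximation on ML standard errors)."""
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(float)
    r = np.linalg.qr(A, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(A.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [str(X.columns[i]) for i in np.flatnonzero(diag <= tol)]
    if bad:
        raise RankDeficiencyError(f"collinear design columns: {bad}")


def _indicator(codes: np.ndarray) -> np.ndarray:
    levels, idx = np.unique(codes, return_inverse=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), idx] = 1.0
    return Z


class _Profile:
    """Profiled ML deviance over variance ratios theta (one per component)."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Z_blocks: list[np.ndarray]):
        self.n, self.k = X.shape
        self.Z = np.hstack(Z_blocks) if Z_blocks else np.empty((self.n, 0))
        self.block_sizes = [Zb.shape[1] for Zb in Z_blocks]
        self.col_comp = np.repeat(np.arange(len(Z_blocks)),
                                  self.block_sizes) if Z_blocks else np.empty(0, int)
        C = np.column_stack([X, y])
        self.CtC = C.T @ C
        self.CtZ = C.T @ self.Z
        self.ZtZ = self.Z.T @ self.Z

    def _solve(self, theta: np.ndarray):
        q = self.Z.shape[1]
        if q and theta.size:
            s = np.sqrt(theta[self.col_comp])
            M = np.eye(q) + (s[:, None] * self.ZtZ) * s[None, :]
            L = np.linalg.cholesky(M)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            B = self.CtZ * s[None, :]
            W = np.linalg.solve(L, B.T)
            CVC = self.CtC - W.T @ W
        else:
            logdet = 0.0
            CVC = self.CtC
        XtVX = CVC[: self.k, : self.k]
        XtVy = CVC[: self.k, self.k]
        ytVy = CVC[self.k, self.k]
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(float(ytVy - beta @ XtVy), 1e-300)
        sigma2 = rss / self.n
        ll = -0.5 * (self.n * (_LOG2PI + np.log(sigma2) + 1.0) + logdet)
        return ll, beta, sigma2, XtVX

    def neg_ll(self, zeta: np.ndarray) -> float:
        return -self._solve(np.exp(zeta))[0]


def fit_lme(y, X: pd.DataFrame, source=None, diagnosis=None,
            random: str = "nested", extra_starts: int = 2) -> LmeFit:
    """Fit a Gaussian LME by ML with profiled fixed effects.

    Parameters
    ----------
    y : response vector (length n).
    X : fixed-effects design (full rank required; collinearity raises
        :class:`RankDeficiencyError` naming the offending columns).
    source : sample-source labels (grouping factor), or None for pure OLS.
    diagnosis : diagnosis labels; with ``random="nested"`` adds the
        per-(source, diagnosis) deviation component.
    random : "nested" (source intercept + source x diagnosis deviation),
        "intercept" (source intercept only) or "none".

    Grouping factors with fewer than two levels are dropped, so a
    single-source cohort reduces exactly to OLS.
    """
    _check_rank(X)
    y = np.asarray(y, float)
    Xv = X.to_numpy(float)
    n = len(y)

    comp_names: list[str] = []
    Z_blocks: list[np.ndarray] = []
    if source is not None and random != "none":
        src = np.asarray(source)
        if len(np.unique(src)) >= 2:
            Z_blocks.append(_indicator(src))
            comp_names.append("source")
            if random == "nested" and diagnosis is not None:
                combo = np.char.add(np.char.add(src.astype(str), ":"),
                                    np.asarray(diagnosis).astype(str))
                if len(np.unique(combo)) > len(np.unique(src)):
                    Z_blocks.append(_indicator(combo))
                    comp_names.append("source:diagnosis")

    prob = _Profile(y, Xv, Z_blocks)
    c = len(Z_blocks)

    if c == 0:
        ll, beta, sigma2, XtVX = prob._solve(np.empty(0))
        cov = sigma2 * np.linalg.inv(XtVX)
        return LmeFit(pd.Series(beta, index=X.columns),
                      pd.Series(np.sqrt(np.diag(cov)), index=X.columns),
                      ll, sigma2, {}, True, n, tuple(X.columns))

    starts = [np.full(c, np.log(0.1)), np.full(c, np.log(1.0))]
    for j in range(extra_starts):
        starts.append(np.full(c, np.log(0.1)) + (j + 1) * np.array(
            [(-1.0) ** (i + j) * 1.5 for i in range(c)]))

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(prob.neg_ll, x0, method="L-BFGS-B",
                                bounds=[(-16.0, 8.0)] * c,
                                options={"ftol": 1e-12, "gtol": 1e-8})
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    theta = np.exp(best.x)
    ll, beta, sigma2, XtVX = prob._solve(theta)

    # boundary candidate: all variance components at zero (OLS)
    ll0, beta0, sigma20, XtVX0 = prob._solve(np.zeros(c))
    if ll0 >= ll - 1e-10:
        theta = np.zeros(c)
        ll, beta, sigma2, XtVX = ll0, beta0, sigma20, XtVX0

    cov = sigma2 * np.linalg.inv(XtVX)
    varcomps = {name: float(sigma2 * t) for name, t in zip(comp_names, theta)}
    return LmeFit(pd.Series(beta, index=X.columns),
                  pd.Series(np.sqrt(np.diag(cov)), index=X.columns),
                  float(ll), float(sigma2), varcomps, any_success, n,
                  tuple(X.columns))


def lrt(fit_simple: LmeFit, fit_complex: LmeFit):
    """ML likelihood-ratio test between nested fixed-effects models.

    Returns (stat, df, p) with the statistic clamped at 0 and p from a
    central chi-square with df = fixed-parameter difference.
    """
    if fit_simple.method != "ML" or fit_complex.method != "ML":
        raise ValueError("LRT requires ML fits")
    if fit_simple.n != fit_complex.n:
        raise ValueError("LRT fits use different response vectors")
    if not set(fit_simple.columns) <= set(fit_complex.columns):
        raise ValueError("models are not nested in their fixed effects")
    df = len(fit_complex.columns) - len(fit_simple.columns)
    if df == 0:
        return 0.0, 0, 1.0
    stat = max(0.0, 2.0 * (fit_complex.loglik - fit_simple.loglik))
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# q-values


def qvalues(pvalues, lambdas=None, min_m_for_pi0: int = 100) -> np.ndarray:
    """Storey q-values with smoother pi0 estimation.

    pi0 is estimated on the grid lambda = 0.05..0.90 (step 0.05) with a
    cubic-polynomial smoother evaluated at the largest lambda, capped into
    (0, 1]; with fewer than ``min_m_for_pi0`` tests (or an unstable fit)
    pi0 falls back to 1, which reduces q exactly to BH-adjusted p.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("qvalues needs at least one p-value")
    if np.isnan(p).any():
        raise ValueError("NaN p-values passed to qvalues")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.9001, 0.05)
    pi0 = 1.0
    if m >= min_m_for_pi0:
        pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
        if np.all(np.isfinite(pi0_l)) and pi0_l.max() > 0:
            coef = np.polyfit(lambdas, pi0_l, deg=3)
            cand = float(np.polyval(coef, lambdas.max()))
            if np.isfinite(cand) and cand > 0:
                pi0 = min(cand, 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# scans


def build_interaction_design(dosage: np.ndarray, covariates: pd.DataFrame,
                             pcs: pd.DataFrame | None, model: str,
                             interaction: str = "diagnosis",
                             diag_levels=("AD", "PD", "MS")) -> pd.DataFrame:
    """Fixed-effects design for M0 / M1 / M2 (or the age variant).

    ``model`` is one of "M0", "M1", "M2"; for ``interaction="age"`` M1 is
    G + age and M2 adds G x age (diagnosis terms are omitted: control-only).
    """
    n = len(covariates)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    diag = covariates["diagnosis"].to_numpy() if "diagnosis" in covariates else None
    G = np.asarray(dosage, float)
    age = covariates["age"].to_numpy(float)
    if model in ("M1", "M2"):
        cols["G"] = G
    if interaction == "diagnosis":
        for lvl in diag_levels:
            if diag is not None and (diag == lvl).any():
                cols[f"diagnosis[{lvl}]"] = (diag == lvl).astype(float)
    for name, arr in (("age", age),
                      ("pmi", covariates["pmi"].to_numpy(float)),
                      ("sex", covariates["sex"].to_numpy(float))):
        if np.ptp(arr) > 0:  # constant covariates are absorbed by the intercept
            cols[name] = arr
    if pcs is not None:
        for c in pcs.columns:
            cols[str(c)] = pcs[c].to_numpy(float)
    if model == "M2":
        if interaction == "diagnosis":
            for lvl in diag_levels:
                key = f"diagnosis[{lvl}]"
                if key in cols:
                    cols[f"G:{key}"] = G * cols[key]
        else:
            cols["G:age"] = G * age
    return pd.DataFrame(cols, index=covariates.index)


def _scan_one(y, g, cov, pcs, interaction: str):
    rand = "nested" if interaction == "diagnosis" else "intercept"
    src = cov["source"].to_numpy()
    diag = cov["diagnosis"].to_numpy() if interaction == "diagnosis" else None
    X0 = build_interaction_design(g, cov, pcs, "M0", interaction)
    X1 = build_interaction_design(g, cov, pcs, "M1", interaction)
    f0 = fit_lme(y, X0, src, diag, random=rand)
    f1 = fit_lme(y, X1, src, diag, random=rand)
    stat01, df01, p01 = lrt(f0, f1)
    rec = {"ll_m0": f0.loglik, "ll_m1": f1.loglik, "ll_m2": np.nan,
           "lrt01_stat": stat01, "lrt01_p": p01, "pass": p01 < 0.05,
           "lrt12_stat": np.nan, "lrt12_p": np.nan,
           "converged": f0.converged and f1.converged}
    if rec["pass"]:
        X2 = build_interaction_design(g, cov, pcs, "M2", interaction)
        try:
            f2 = fit_lme(y, X2, src, diag, random=rand)
            stat12, df12, p12 = lrt(f1, f2)
        except RankDeficiencyError:
            # degenerate interaction (e.g. constant age): M2 reduces to M1
            f2, stat12, df12, p12 = f1, 0.0, 0, 1.0
        rec.update(ll_m2=f2.loglik, lrt12_stat=stat12, lrt12_p=p12,
                   lrt12_df=df12, converged=rec["converged"] and f2.converged)
        if interaction == "diagnosis":
            rec["beta_G_control"] = f2.params.get("G", np.nan)
            rec["p_control"] = f2.pvalues.get("G", np.nan)
            for lvl in ("AD", "PD", "MS"):
                key = f"G:diagnosis[{lvl}]"
                rec[f"beta_Gx{lvl}"] = f2.params.get(key, np.nan)
                rec[f"p_{lvl}"] = f2.pvalues.get(key, np.nan)
        else:
            rec["beta_GxAge"] = f2.params.get("G:age", np.nan)
            rec["p_age"] = f2.pvalues.get("G:age", np.nan)
    return rec


def _run_scan(lead_pairs, expr, covariates, genotypes, pcs, interaction):
    records = []
    for _, pair in lead_pairs.iterrows():
        ct, gene, snp = pair["cell_type"], pair["gene"], pair["snp"]
        pb = expr[ct]
        if gene not in pb.genes:
            raise KeyError(f"gene {gene!r} missing from {ct} expression matrix")
        if snp not in genotypes.snps:
            raise KeyError(f"SNP {snp!r} missing from genotype matrix")
        donors = pb.donors
        y = pb.matrix.loc[gene].to_numpy(float)
        g = genotypes.subset_donors(donors).dosage[:, genotypes.snps.get_loc(snp)]
        g = np.where(np.isnan(g), np.nanmean(g), g)
        cov = covariates.loc[donors]
        pc = pcs[ct].loc[donors] if pcs is not None else None
        rec = {"cell_type": ct, "gene": gene, "snp": snp}
        rec.update(_scan_one(y, g, cov, pc, interaction))
        records.append(rec)
    table = pd.DataFrame(records)
    # q-values per cell type over converged, passing records
    table["lrt12_q"] = np.nan
    for ct, sub in table.groupby("cell_type"):
        ok = sub["converged"] & sub["lrt12_p"].notna()
        if ok.any():
            table.loc[sub.index[ok], "lrt12_q"] = qvalues(sub.loc[ok, "lrt12_p"].to_numpy())
    summary = (
        table.assign(hit=table["lrt12_q"] < 0.05)
        .groupby("cell_type")
        .agg(n_pairs=("gene", "size"), n_pass=("pass", "sum"), n_hits=("hit", "sum"))
        .reset_index()
    )
    summary["interaction_fraction"] = summary["n_hits"] / summary["n_pairs"]
    return table, summary


def interaction_scan(lead_pairs: pd.DataFrame, expr: dict, covariates: pd.DataFrame,
                     genotypes, pcs: dict | None = None):
    """Disease-interaction scan over top eSNP-gene pairs.

    ``lead_pairs`` needs columns cell_type, gene, snp; ``expr`` maps cell
    type to its scaled :class:`~scmr.pseudobulk.Pseudobulk`; ``pcs``
    (optional) maps cell type to a donor-indexed PC design.  Returns
    (records, per-cell-type summary with the interaction fraction).
    """
    return _run_scan(lead_pairs, expr, covariates, genotypes, pcs, "diagnosis")


def age_interaction_scan(lead_pairs: pd.DataFrame, expr: dict,
                         covariates: pd.DataFrame, genotypes,
                         pcs: dict | None = None):
    """Age-interaction scan (G + age vs G x age, df 1) for control-only data."""
    if "diagnosis" in covariates and (covariates["diagnosis"] != "control").any():
        raise ValueError("age_interaction_scan expects a control-only cohort")
    return _run_scan(lead_pairs, expr, covariates, genotypes, pcs, "age")
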