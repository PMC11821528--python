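"""Residualization, PCs, the cis scan and BH FDR against naive oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmr.cis_eqtl import (bh_fdr, compute_pcs, map_cis, optimize_pcs,
                           residualize)
from scmr.exceptions import RankDeficiencyError
from scmr.genotype_io import GenotypeMatrix
from scmr.pseudobulk import Pseudobulk


def _pb(matrix: np.ndarray, donors, stage="scaled", genes=None):
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    df = pd.DataFrame(matrix, index=pd.Index(genes), columns=pd.Index(donors))
    return Pseudobulk("ct", df, stage, pd.Series(50, index=df.columns))


def _cov(n, rng, control_only=False):
    return pd.DataFrame({
        "age": rng.normal(70, 10, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "pmi": rng.gamma(4, 6, n),
        "diagnosis": np.full(n, "control") if control_only
        else rng.choice(["control", "AD"], n),
        "source": rng.choice(["S0", "S1"], n),
    }, index=pd.Index([f"d{i}" for i in range(n)]))


# ---------------------------------------------------------------------------
# residualize


def test_residuals_with_constant_covariates_are_centered():
    rng = np.random.default_rng(0)
    n = 40
    Y = rng.normal(size=(3, n))
    Y = (Y - Y.mean(axis=1, keepdims=True)) / Y.std(axis=1, ddof=1, keepdims=True)
    cov = _cov(n, rng, control_only=True)
    cov["age"] = 70.0
    cov["sex"] = 1.0
    cov["pmi"] = 20.0
    cov["source"] = "S0"
    resid = residualize(_pb(Y, cov.index), cov)
    centered = Y - Y.mean(axis=1, keepdims=True)
    assert np.allclose(resid.matrix.to_numpy(), centered, atol=1e-10)


def test_residuals_orthogonal_to_design():
    rng = np.random.default_rng(1)
    n = 60
    cov = _cov(n, rng)
    Y = rng.normal(size=(5, n))
    resid = residualize(_pb(Y, cov.index), cov)
    from scmr.cis_eqtl import build_covariate_design

    X = build_covariate_design(cov).to_numpy()
    inner = resid.matrix.to_numpy() @ X
    assert np.abs(inner).max() < 1e-8


def test_residualize_matches_per_gene_regression_oracle():
    rng = np.random.default_rng(2)
    n = 80
    cov = _cov(n, rng)
    Y = rng.normal(size=(6, n))
    resid = residualize(_pb(Y, cov.index), cov).matrix.to_numpy()
    from scmr.cis_eqtl import build_covariate_design

    X = build_covariate_design(cov).to_numpy()
    for g in range(Y.shape[0]):
        beta, *_ = np.linalg.lstsq(X, Y[g], rcond=None)
        assert np.abs(resid[g] - (Y[g] - X @ beta)).max() < 1e-10


def test_residualize_names_collinear_columns():
    rng = np.random.default_rng(3)
    n = 30
    cov = _cov(n, rng)
    cov["pmi"] = cov["age"] * 2.0  # exact collinearity
    with pytest.raises(RankDeficiencyError, match="pmi|age"):
        residualize(_pb(rng.normal(size=(2, n)), cov.index), cov)


# ---------------------------------------------------------------------------
# PCs


def test_rank_one_matrix_has_single_dominant_pc(small_genotypes):
    rng = np.random.default_rng(4)
    donors = small_genotypes.donors
    u = rng.normal(size=len(donors))
    v = rng.normal(size=8)
    Y = np.outer(v, u) + 1e-8 * rng.normal(size=(8, len(donors)))
    resid = _pb(Y, donors, stage="residual")
    pcs = compute_pcs(resid, small_genotypes, n_expr=1)
    score = pcs.expr_pcs.to_numpy()[:, 0]
    uc = u - u.mean()
    corr = np.abs(np.corrcoef(score, uc)[0, 1])
    assert corr > 0.999


def test_pcs_orthonormal_and_sign_deterministic(small_genotypes):
    rng = np.random.default_rng(5)
    donors = small_genotypes.donors
    Y = rng.normal(size=(10, len(donors)))
    resid = _pb(Y, donors, stage="residual")
    a = compute_pcs(resid, small_genotypes, n_expr=4)
    b = compute_pcs(resid, small_genotypes, n_expr=4)
    E = a.expr_pcs.to_numpy()
    assert np.abs(E.T @ E - np.eye(4)).max() < 1e-10
    pd.testing.assert_frame_equal(a.expr_pcs, b.expr_pcs)
    pd.testing.assert_frame_equal(a.geno_pcs, b.geno_pcs)


def test_pc_request_beyond_rank_errors(small_genotypes):
    donors = small_genotypes.donors
    Y = np.outer(np.ones(2), np.arange(len(donors), dtype=float))
    resid = _pb(Y, donors, stage="residual")
    with pytest.raises(ValueError, match="rank"):
        compute_pcs(resid, small_genotypes, n_expr=2)


# ---------------------------------------------------------------------------
# BH


def test_bh_step_up_hand_example():
    out = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, 0.04)
    assert bh_fdr([0.37])[0] == pytest.approx(0.37)


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        bh_fdr([0.1, np.nan])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                min_size=1, max_size=40))
def test_bh_matches_definitional_oracle(pvals):
    p = np.asarray(pvals)
    out = bh_fdr(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    # definitional step-up: adj_(i) = min_{j >= i} p_(j) * m / j
    for rank_i, idx in enumerate(order, start=1):
        expected = min(min(p[order[j - 1]] * m / j for j in range(rank_i, m + 1)), 1.0)
        assert out[idx] == pytest.approx(expected, abs=1e-12)
    # cross-check against statsmodels
    from statsmodels.stats.multitest import multipletests

    _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(out, sm_adj)


# ---------------------------------------------------------------------------
# the scan


def _scan_instance(seed=6, n=100, n_genes=4, n_snps=30):
    rng = np.random.default_rng(seed)
    donors = pd.Index([f"d{i}" for i in range(n)])
    snps = pd.Index([f"s{j}" for j in range(n_snps)])
    dosage = rng.binomial(2, 0.3, size=(n, n_snps)).astype(float)
    pos = 1_000_000 + 10_000 * np.arange(n_snps)
    smap = pd.DataFrame({"chrom": 1, "pos": pos, "a1": "A", "a2": "G",
                         "maf": 0.3}, index=snps)
    gm = GenotypeMatrix(donors, snps, dosage, smap)
    gene_map = pd.DataFrame({
        "chrom": 1,
        "start": 1_000_000 + 50_000 * np.arange(n_genes),
        "end": 1_020_000 + 50_000 * np.arange(n_genes)},
        index=pd.Index([f"g{i}" for i in range(n_genes)]))
    Y = rng.normal(size=(n_genes, n))
    Y[0] += 0.6 * dosage[:, 0]
    resid = _pb(Y, donors, stage="residual",
                genes=list(gene_map.index))
    return resid, gm, gene_map


def test_cis_window_boundary_is_respected():
    resid, gm, gene_map = _scan_instance()
    gene_map = gene_map.iloc[[0]]
    # place one SNP exactly 1,000,001 bp beyond the gene end
    gm.snp_map.loc["s29", "pos"] = int(gene_map.iloc[0]["end"]) + 1_000_001
    gm.snp_map.loc["s28", "pos"] = int(gene_map.iloc[0]["end"]) + 1_000_000
    res = map_cis(resid, gm, None, gene_map, cis_window=1e6)
    tested = set(res.pairs["snp"])
    assert "s28" in tested and "s29" not in tested


def test_noiseless_linear_expression_recovers_slope_exactly():
    resid, gm, gene_map = _scan_instance()
    Y = resid.matrix.to_numpy().copy()
    Y[1] = 0.37 * gm.dosage[:, 5]
    resid = _pb(Y, resid.donors, stage="residual", genes=list(gene_map.index))
    res = map_cis(resid, gm, None, gene_map, cis_window=1e9)
    row = res.pairs[(res.pairs["gene"] == "g1") & (res.pairs["snp"] == "s5")].iloc[0]
    assert row["beta"] == pytest.approx(0.37, abs=1e-8)
    assert row["p"] <= np.finfo(float).tiny * 10


def test_scan_matches_naive_per_pair_regression_oracle():
    import scipy.stats as sps

    resid, gm, gene_map = _scan_instance()
    res = map_cis(resid, gm, None, gene_map, cis_window=1e9)
    Y = resid.matrix.to_numpy()
    n = Y.shape[1]
    for _, row in res.pairs.sample(40, random_state=0).iterrows():
        y = Y[gene_map.index.get_loc(row["gene"])]
        g = gm.dosage[:, gm.snps.get_loc(row["snp"])]
        X = np.column_stack([np.ones(n), g])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        s2 = (r @ r) / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        p = 2 * sps.t.sf(abs(t), n - 2)
        assert row["beta"] == pytest.approx(beta[1], abs=1e-8)
        assert row["t"] == pytest.approx(t, abs=1e-8)
        assert row["p"] == pytest.approx(p, abs=1e-8, rel=1e-6)


def test_dosage_rescaling_rescales_beta_keeps_t_and_p():
    # halving the dosage coding doubles beta and leaves t and p unchanged
    resid, gm, gene_map = _scan_instance()
    res1 = map_cis(resid, gm, None, gene_map, cis_window=1e9, maf_floor=0.0)
    half = GenotypeMatrix(gm.donors, gm.snps, gm.dosage / 2.0, gm.snp_map)
    res2 = map_cis(resid, half, None, gene_map, cis_window=1e9, maf_floor=0.0)
    merged = res1.pairs.merge(res2.pairs, on=["gene", "snp"], suffixes=("_1", "_2"))
    assert np.allclose(2 * merged["beta_1"], merged["beta_2"])
    assert np.allclose(merged["t_1"], merged["t_2"])
    assert np.allclose(merged["p_1"], merged["p_2"])


def test_egene_count_monotone_in_cis_window():
    resid, gm, gene_map = _scan_instance()
    counts = [map_cis(resid, gm, None, gene_map, cis_window=w).egene_count()
              for w in (1e4, 1e5, 1e9)]
    assert counts == sorted(counts)


def test_missing_dosages_are_mean_imputed():
    resid, gm, gene_map = _scan_instance()
    d = gm.dosage.copy()
    d[:5, 3] = np.nan
    gm2 = GenotypeMatrix(gm.donors, gm.snps, d, gm.snp_map)
    res = map_cis(resid, gm2, None, gene_map, cis_window=1e9)
    assert res.n_imputed_dosages == 5
    assert res.pairs["p"].notna().all()


# ---------------------------------------------------------------------------
# PC optimization


def test_optimize_pcs_singleton_grid():
    resid, gm, gene_map = _scan_instance()
    chosen, counts = optimize_pcs(resid, gm, gene_map, [0])
    assert chosen == 0 and list(counts) == [0]


def test_optimize_pcs_tie_breaks_to_smaller():
    resid, gm, gene_map = _scan_instance()
    chosen, counts = optimize_pcs(resid, gm, gene_map, [0, 1, 2])
    best = max(counts.values())
    assert chosen == min(n for n, c in counts.items() if c == best)


def test_optimize_pcs_recovers_confounded_signal():
    """With a strong shared confounder, removing one expression PC should
    recover at least as many eGenes as removing none."""
    rng = np.random.default_rng(8)
    n, n_genes = 150, 12
    donors = pd.Index([f"d{i}" for i in range(n)])
    snps = pd.Index([f"s{j}" for j in range(20)])
    dosage = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
    smap = pd.DataFrame({"chrom": 1, "pos": 1_000_000 + 1000 * np.arange(20),
                         "a1": "A", "a2": "G", "maf": 0.3}, index=snps)
    gm = GenotypeMatrix(donors, snps, dosage, smap)
    gene_map = pd.DataFrame({"chrom": 1, "start": 1_000_000, "end": 1_020_000},
                            index=pd.Index([f"g{i}" for i in range(n_genes)]))
    confounder = rng.normal(size=n) * 3.0
    Y = rng.normal(size=(n_genes, n)) + confounder[None, :]
    for i in range(n_genes):
        Y[i] += 0.4 * dosage[:, i % 20]
    resid = _pb(Y, donors, stage="residual", genes=list(gene_map.index))
    _, counts = optimize_pcs(resid, gm, gene_map, [0, 1])
    assert counts[1] >= counts[0]
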