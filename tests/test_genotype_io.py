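"""QC filters, sumstats munging, LD, clumping and pruning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scmr.exceptions import EmptyCohortError, FormatError
from scmr.genotype_io import (GenotypeMatrix, LdMatrix, hwe_chi2_p,
                              ld_correlation, munge_sumstats, qc_filter,
                              r2_prune, read_dosage_tsv, read_vcf,
                              window_clump, write_dosage_tsv, write_vcf)
from scmr.synthetic import default_config, simulate_genotypes


# ---------------------------------------------------------------------------
# QC


def test_qc_removes_low_imputation_score(toy_genotypes):
    toy_genotypes.snp_map.loc["s1", "info"] = 0.39
    out, report = qc_filter(toy_genotypes)
    assert "s1" not in out.snps
    row = report[report["item"] == "s1"].iloc[0]
    assert row["rule"] == "imputation_score"


def test_qc_keeps_exact_hwe_proportions():
    # (AA, Aa, aa) = (25, 50, 25) has chi-square statistic exactly 0
    assert hwe_chi2_p(np.array([25]), np.array([50]), np.array([25]))[0] == 1.0
    n = 100
    dosage = np.concatenate([np.full(25, 2.0), np.full(50, 1.0), np.full(25, 0.0)])
    gm = GenotypeMatrix(
        pd.Index([f"d{i}" for i in range(n)]), pd.Index(["s"]),
        dosage[:, None],
        pd.DataFrame({"chrom": [1], "pos": [10], "a1": ["A"], "a2": ["G"],
                      "maf": [0.5]}, index=["s"]))
    out, _ = qc_filter(gm)
    assert "s" in out.snps


def test_qc_removes_hwe_violators():
    # all heterozygotes: maximal HWE departure
    n = 200
    gm = GenotypeMatrix(
        pd.Index([f"d{i}" for i in range(n)]), pd.Index(["s"]),
        np.ones((n, 1)),
        pd.DataFrame({"chrom": [1], "pos": [10], "a1": ["A"], "a2": ["G"],
                      "maf": [0.5]}, index=["s"]))
    out, report = qc_filter(gm)
    assert len(out.snps) == 0
    assert (report["rule"] == "hwe").any()


def test_qc_removes_high_missingness_donor():
    rng = np.random.default_rng(0)
    dosage = rng.integers(0, 3, size=(20, 100)).astype(float)
    dosage[0, :3] = np.nan  # donor 0: 3% missing
    gm = GenotypeMatrix(
        pd.Index([f"d{i}" for i in range(20)]),
        pd.Index([f"s{j}" for j in range(100)]), dosage,
        pd.DataFrame({"chrom": 1, "pos": np.arange(100) + 1, "a1": "A",
                      "a2": "G", "maf": 0.3},
                     index=[f"s{j}" for j in range(100)]))
    out, report = qc_filter(gm, kinship=None)
    assert "d0" not in out.donors
    assert set(report.loc[report["kind"] == "donor", "rule"]) == {"missingness"}


def test_qc_non_autosomal_and_kinship(toy_genotypes):
    toy_genotypes.snp_map["chrom"] = toy_genotypes.snp_map["chrom"].astype(object)
    toy_genotypes.snp_map.loc["s3", "chrom"] = "X"
    kin = pd.DataFrame({"donor1": ["d0"], "donor2": ["d1"], "kinship": [0.5]})
    out, report = qc_filter(toy_genotypes, kinship=kin)
    assert "s3" not in out.snps
    assert "d1" not in out.donors


def test_qc_is_idempotent(small_genotypes):
    once, rep1 = qc_filter(small_genotypes)
    twice, rep2 = qc_filter(once)
    assert len(rep2) == 0
    assert np.array_equal(once.dosage, twice.dosage)


def test_qc_empty_cohort_error():
    # every donor misses 3% of SNPs (circulant pattern), so each SNP passes
    # its 5% missingness filter but every donor trips the 2% donor filter
    rng = np.random.default_rng(1)
    n = 100
    dosage = rng.binomial(2, 0.3, size=(n, n)).astype(float)
    for i in range(n):
        dosage[i, [(3 * i + k) % n for k in range(3)]] = np.nan
    gm = GenotypeMatrix(
        pd.Index([f"d{i}" for i in range(n)]),
        pd.Index([f"s{j}" for j in range(n)]), dosage,
        pd.DataFrame({"chrom": 1, "pos": np.arange(n) + 1, "a1": "A",
                      "a2": "G", "maf": 0.3}, index=[f"s{j}" for j in range(n)]))
    with pytest.raises(EmptyCohortError):
        qc_filter(gm)


# ---------------------------------------------------------------------------
# munging


def test_munge_imputes_se_from_beta_and_p():
    t = pd.DataFrame({"SNP": ["a"], "A1": ["a"], "A2": ["g"],
                      "BETA": [0.196], "P": [0.05]})
    ss = munge_sumstats(t)
    assert ss.table.loc[0, "se"] == pytest.approx(0.196 / stats.norm.ppf(0.975),
                                                  abs=5e-5)
    assert round(ss.table.loc[0, "se"], 4) == 0.1000
    assert ss.table.loc[0, "a1"] == "A"  # upper-cased


def test_munge_imputes_beta_from_z_times_se():
    t = pd.DataFrame({"SNP": ["a"], "A1": ["A"], "A2": ["G"],
                      "Z": [2.0], "SE": [0.05]})
    ss = munge_sumstats(t)
    assert ss.table.loc[0, "beta"] == pytest.approx(0.1)


def test_munge_drops_unresolvable_rows():
    t = pd.DataFrame({"SNP": ["a", "b"], "A1": ["A", "A"], "A2": ["G", "G"],
                      "BETA": [0.0, 0.1], "P": [1.0, 0.01]})
    ss = munge_sumstats(t)  # p=1 -> quantile 0 -> se undefined -> dropped
    assert ss.n_dropped == 1
    assert list(ss.table["snp"]) == ["b"]


def test_munge_requires_effect_columns():
    t = pd.DataFrame({"SNP": ["a"], "A1": ["A"], "A2": ["G"], "P": [0.5]})
    with pytest.raises(FormatError, match="effect"):
        munge_sumstats(t)


def test_munge_write_read_fixed_point(tmp_path):
    from scmr.genotype_io import read_sumstats_tsv, write_sumstats_tsv

    t = pd.DataFrame({"SNP": ["a", "b"], "CHR": [1, 1], "BP": [10, 20],
                      "A1": ["A", "C"], "A2": ["G", "T"],
                      "BETA": [0.1, -0.2], "SE": [0.05, 0.04],
                      "P": [0.045, 1e-6], "N": [1000, 1000],
                      "FRQ": [0.3, 0.2]})
    ss = munge_sumstats(t)
    write_sumstats_tsv(ss, tmp_path / "ss.tsv")
    again = read_sumstats_tsv(tmp_path / "ss.tsv")
    pd.testing.assert_frame_equal(ss.table, again.table, check_dtype=False)


# ---------------------------------------------------------------------------
# LD


def test_ld_duplicated_column_is_perfectly_correlated(toy_genotypes):
    ld = ld_correlation(toy_genotypes, ["s1", "s2"])
    assert ld.rho[0, 1] == pytest.approx(1.0)
    assert np.all(np.diag(ld.rho) == 1.0)


def test_ld_matches_two_pass_covariance_oracle(small_genotypes):
    snps = list(small_genotypes.snps[:12])
    ld = ld_correlation(small_genotypes, snps)
    X = small_genotypes.subset_snps(snps).dosage
    n = X.shape[0]
    oracle = np.eye(len(snps))
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            xi, xj = X[:, i], X[:, j]
            cov = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (n - 1)
            r = cov / (xi.std(ddof=1) * xj.std(ddof=1))
            oracle[i, j] = oracle[j, i] = r
    assert np.abs(ld.rho - oracle).max() < 1e-12


def test_ld_null_correlation_bound():
    from scmr.synthetic import make_snp_map

    snp_map = make_snp_map(n_blocks=20, block_size=1, seed=9)
    cfg = default_config(seed=9, n_donors=10_000, snp_map=snp_map,
                         effect_table=pd.DataFrame(), gwas_plan=[], ld_rho=0.0)
    g = simulate_genotypes(cfg)
    ld = ld_correlation(g)
    off = np.abs(ld.rho[np.triu_indices(20, 1)])
    assert (off < 0.05).mean() >= 0.99


def test_ld_zero_variance_flagged(toy_genotypes):
    with pytest.warns(UserWarning, match="zero-variance"):
        ld = ld_correlation(toy_genotypes, ["s1", "s4"])
    assert ld.rho[0, 1] == 0.0
    assert ld.rho[1, 1] == 1.0
    assert "s4" in ld.zero_variance


# ---------------------------------------------------------------------------
# clumping / pruning


def _ss(pos, p, chrom=1):
    return pd.DataFrame({"snp": [f"s{i}" for i in range(len(pos))],
                         "chrom": chrom, "pos": pos, "p": p})


def test_window_clump_merges_nearby_hits():
    ss = _ss([1_000_000, 1_300_000], [1e-9, 1e-10])
    leads = window_clump(ss, 5e-8, 1_000_000)
    assert len(leads) == 1
    assert leads.iloc[0]["p"] == 1e-10


def test_window_clump_empty_without_hits():
    assert len(window_clump(_ss([1, 2], [0.5, 1e-7]), 5e-8, 1_000_000)) == 0


def test_window_clump_chromosomes_do_not_conflict():
    ss = pd.concat([_ss([1_000_000], [1e-9], 1), _ss([1_000_000], [1e-9], 2)])
    assert len(window_clump(ss.reset_index(drop=True), 5e-8, 1_000_000)) == 2


def _toy_ld(r2_mat, snps):
    return LdMatrix(pd.Index(snps), np.sqrt(np.asarray(r2_mat)))


def test_r2_prune_greedy_enumeration():
    # r2(1,2)=0.5, snp3 independent: greedy keeps best of {1,2} plus 3
    ld = _toy_ld([[1, 0.5, 0], [0.5, 1, 0], [0, 0, 1]], ["a", "b", "c"])
    stats_df = pd.DataFrame({"snp": ["a", "b", "c"], "p": [0.01, 0.001, 0.5]})
    assert set(r2_prune(stats_df, ld, 0.01)) == {"b", "c"}


def test_r2_prune_vacuous_threshold_keeps_all():
    ld = _toy_ld([[1, 0.99], [0.99, 1]], ["a", "b"])
    stats_df = pd.DataFrame({"snp": ["a", "b"], "p": [0.1, 0.2]})
    assert set(r2_prune(stats_df, ld, 1.0)) == {"a", "b"}


def test_r2_prune_anchor_precedence():
    ld = _toy_ld([[1, 0.5], [0.5, 1]], ["a", "b"])
    stats_df = pd.DataFrame({"snp": ["a", "b"], "p": [0.001, 0.5]})
    kept = r2_prune(stats_df, ld, 0.01, anchor="b")
    assert kept == ["b"]


def test_r2_prune_missing_snp_is_hard_error():
    ld = _toy_ld([[1.0]], ["a"])
    stats_df = pd.DataFrame({"snp": ["a", "zzz"], "p": [0.1, 0.2]})
    with pytest.raises(KeyError):
        r2_prune(stats_df, ld, 0.01)


def test_r2_prune_output_is_maximal(small_genotypes):
    snps = list(small_genotypes.snps[:20])
    ld = ld_correlation(small_genotypes, snps)
    stats_df = pd.DataFrame({"snp": snps,
                             "p": np.linspace(1e-6, 0.05, len(snps))})
    kept = r2_prune(stats_df, ld, 0.1)
    pos = {s: i for i, s in enumerate(ld.snps)}
    for s in set(snps) - set(kept):
        # every removed SNP violates the threshold against some kept SNP
        assert any(ld.r2[pos[s], pos[k]] > 0.1 for k in kept)


# ---------------------------------------------------------------------------
# file round trips


def test_dosage_tsv_roundtrip(tmp_path, toy_genotypes):
    write_dosage_tsv(toy_genotypes, tmp_path / "g")
    back = read_dosage_tsv(tmp_path / "g")
    assert np.allclose(back.dosage, toy_genotypes.dosage)
    assert list(back.snps) == list(toy_genotypes.snps)


def test_vcf_roundtrip_hard_calls(tmp_path, small_genotypes):
    path = tmp_path / "g.vcf"
    write_vcf(small_genotypes, path)
    back, n_multi = read_vcf(path)
    assert n_multi == 0
    back = back.subset_snps(small_genotypes.snps)
    assert np.array_equal(back.dosage, small_genotypes.hard_calls())
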