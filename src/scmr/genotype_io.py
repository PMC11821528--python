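"""Genotype and GWAS summary-statistics I/O, QC, LD and pruning primitives.

The container here is :class:`GenotypeMatrix`: a donor x SNP matrix of
effect-allele (A1) dosages in [0, 2] together with a SNP map (chromosome,
1-based position, alleles, MAF, imputation score, missingness).  QC applies
the standard post-imputation filters (imputation score, missingness, HWE,
autosomes, per-donor missingness, optional kinship) and reports every
exclusion with the rule that triggered it.

GWAS summary statistics are harmonized into a fixed schema by
:func:`munge_sumstats`, which can impute a missing standard error from
(beta, p) or a missing beta from (z, se).

:func:`window_clump` and :func:`r2_prune` are the shared clumping/pruning
primitives used by region construction (colocalization) and instrument
selection (MR).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, EmptyCohortError, FormatError

__all__ = [
    "GenotypeMatrix",
    "GwasSumstats",
    "LdMatrix",
    "QcThresholds",
    "qc_filter",
    "munge_sumstats",
    "ld_correlation",
    "window_clump",
    "r2_prune",
    "hwe_chi2_p",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "read_sumstats_tsv",
    "write_sumstats_tsv",
]

SNP_MAP_COLUMNS = ["chrom", "pos", "a1", "a2", "maf"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Donor x SNP effect-allele dosage matrix with a SNP map.

    Parameters
    ----------
    donors : ordered donor identifiers (length n).
    snps : ordered SNP identifiers (length m), unique.
    dosage : (n, m) float array of A1 dosages in [0, 2]; NaN marks missing.
    snp_map : DataFrame indexed by SNP id with columns ``chrom`` (int),
        ``pos`` (1-based bp), ``a1``, ``a2``, ``maf`` and optionally
        ``info`` (imputation score) and ``block``.
    """

    donors: pd.Index
    snps: pd.Index
    dosage: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.donors = pd.Index(self.donors)
        self.snps = pd.Index(self.snps)
        if not self.snps.is_unique:
            raise ConfigurationError("duplicate SNP ids in genotype matrix")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.donors), len(self.snps)):
            raise ConfigurationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.donors)} donors x {len(self.snps)} SNPs"
            )
        self.snp_map = self.snp_map.loc[self.snps]
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if bad.any():
            raise ConfigurationError("dosages outside [0, 2]")

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def hard_calls(self) -> np.ndarray:
        """Dosages rounded to {0, 1, 2}; NaN preserved."""
        return np.round(self.dosage)

    def empirical_maf(self) -> np.ndarray:
        """Folded allele frequency of A1 computed from the data."""
        freq = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=0)

    def subset_snps(self, snps) -> "GenotypeMatrix":
        idx = self.snps.get_indexer(snps)
        if (idx < 0).any():
            missing = [s for s, i in zip(snps, idx) if i < 0]
            raise KeyError(f"SNPs absent from genotype matrix: {missing[:5]}")
        return GenotypeMatrix(
            self.donors, pd.Index(snps), self.dosage[:, idx], self.snp_map.iloc[idx]
        )

    def subset_donors(self, donors) -> "GenotypeMatrix":
        idx = self.donors.get_indexer(donors)
        if (idx < 0).any():
            raise KeyError("donors absent from genotype matrix")
        return GenotypeMatrix(pd.Index(donors), self.snps, self.dosage[idx], self.snp_map)


@dataclass
class GwasSumstats:
    """Harmonized per-SNP marginal association statistics for one trait.

    ``table`` columns: snp, chrom, pos, a1, a2, beta, se, p, n, maf.
    ``trait_type`` is ``"quant"`` or ``"cc"``; case-control traits carry the
    case fraction (cases / N).
    """

    table: pd.DataFrame
    trait_type: str = "quant"
    case_fraction: float | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quant", "cc"):
            raise ConfigurationError(f"trait_type must be quant|cc, got {self.trait_type!r}")
        if self.trait_type == "cc":
            if self.case_fraction is None or not (0 < self.case_fraction < 1):
                raise ConfigurationError("case-control trait needs case_fraction in (0,1)")
        t = self.table
        if "se" in t and (t["se"].dropna() <= 0).any():
            raise FormatError("non-positive standard errors in summary statistics")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LdMatrix:
    """Signed, allele-aligned dosage correlation matrix over a SNP set."""

    snps: pd.Index
    rho: np.ndarray
    zero_variance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.snps = pd.Index(self.snps)
        self.rho = np.asarray(self.rho, dtype=float)

    @property
    def r2(self) -> np.ndarray:
        return self.rho**2

    def submatrix(self, snps) -> "LdMatrix":
        idx = self.snps.get_indexer(snps)
        if (idx < 0).any():
            missing = [s for s, i in zip(snps, idx) if i < 0]
            raise KeyError(f"SNPs absent from LD matrix: {missing[:5]}")
        return LdMatrix(pd.Index(snps), self.rho[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# QC


@dataclass(frozen=True)
class QcThresholds:
    """Variant/donor QC thresholds (defaults are the standard ones)."""

    info_min: float = 0.4
    snp_missing_max: float = 0.05
    hwe_p_min: float = 1e-6
    donor_missing_max: float = 0.02
    kinship_max: float = 0.2
    autosomes_only: bool = True


def hwe_chi2_p(n_aa: np.ndarray, n_ab: np.ndarray, n_bb: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg chi-square (1 df) p-value from genotype counts.

    Monomorphic SNPs (allele frequency 0 or 1) are returned as p = 1.
    """
    n_aa = np.asarray(n_aa, float)
    n_ab = np.asarray(n_ab, float)
    n_bb = np.asarray(n_bb, float)
    n = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = (2 * n_aa + n_ab) / (2 * n)
        exp = np.stack([n * p_a**2, 2 * n * p_a * (1 - p_a), n * (1 - p_a) ** 2])
        obs = np.stack([n_aa, n_ab, n_bb])
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(axis=0)
    pval = stats.chi2.sf(chi2, df=1)
    mono = (p_a <= 0) | (p_a >= 1) | (n == 0)
    return np.where(mono, 1.0, pval)


def qc_filter(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
    kinship: pd.DataFrame | None = None,
):
    """Apply variant and donor QC filters.

    Filters, in order: imputation score < ``info_min``; SNP missingness >
    ``snp_missing_max``; HWE exact-proportion chi-square p < ``hwe_p_min``
    (on hard calls); non-autosomal chromosomes; donors with missingness >
    ``donor_missing_max``; one donor of each pair with kinship >
    ``kinship_max`` (``kinship`` is a precomputed table with columns
    donor1, donor2, kinship).

    Returns the filtered :class:`GenotypeMatrix` and an exclusion report
    (DataFrame with columns item, kind, rule, value).
    """
    gm = genotypes
    removals: list[tuple[str, str, str, float]] = []

    snp_keep = np.ones(gm.n_snps, dtype=bool)
    smap = gm.snp_map

    if "info" in smap.columns:
        info = smap["info"].to_numpy(float)
        bad = info < thresholds.info_min
        for s, v in zip(gm.snps[bad], info[bad]):
            removals.append((s, "snp", "imputation_score", float(v)))
        snp_keep &= ~bad

    miss = gm.missingness()
    bad = snp_keep & (miss > thresholds.snp_missing_max)
    for s, v in zip(gm.snps[bad], miss[bad]):
        removals.append((s, "snp", "missingness", float(v)))
    snp_keep &= ~bad

    hard = gm.hard_calls()
    n_bb = np.nansum(hard == 0, axis=0)
    n_ab = np.nansum(hard == 1, axis=0)
    n_aa = np.nansum(hard == 2, axis=0)
    hwe_p = hwe_chi2_p(n_aa, n_ab, n_bb)
    bad = snp_keep & (hwe_p < thresholds.hwe_p_min)
    for s, v in zip(gm.snps[bad], hwe_p[bad]):
        removals.append((s, "snp", "hwe", float(v)))
    snp_keep &= ~bad

    if thresholds.autosomes_only:
        chrom = smap["chrom"].to_numpy()
        auto = np.array([str(c).lstrip("chr").isdigit() and 1 <= int(str(c).lstrip("chr")) <= 22
                         for c in chrom])
        bad = snp_keep & ~auto
        for s in gm.snps[bad]:
            removals.append((s, "snp", "non_autosomal", np.nan))
        snp_keep &= ~bad

    dosage = gm.dosage[:, snp_keep]
    snps = gm.snps[snp_keep]
    smap = gm.snp_map.loc[snps]

    donor_keep = np.ones(gm.n_donors, dtype=bool)
    if dosage.shape[1]:
        dmiss = np.mean(np.isnan(dosage), axis=1)
        bad = dmiss > thresholds.donor_missing_max
        for d, v in zip(gm.donors[bad], dmiss[bad]):
            removals.append((d, "donor", "missingness", float(v)))
        donor_keep &= ~bad

    if kinship is not None and len(kinship):
        related = kinship[kinship["kinship"] > thresholds.kinship_max]
        for _, row in related.iterrows():
            # drop the second member of each related pair if still present
            d = row["donor2"]
            pos = gm.donors.get_indexer([d])
            if pos[0] >= 0 and donor_keep[pos[0]]:
                removals.append((d, "donor", "kinship", float(row["kinship"])))
                donor_keep[pos[0]] = False

    if not donor_keep.any():
        raise EmptyCohortError("QC removed every donor")

    dosage = dosage[donor_keep]
    smap = smap.copy()
    if dosage.shape[0]:
        freq = np.nanmean(dosage, axis=0) / 2.0
        smap["maf"] = np.minimum(freq, 1 - freq)
    out = GenotypeMatrix(gm.donors[donor_keep], snps, dosage, smap)
    report = pd.DataFrame(removals, columns=["item", "kind", "rule", "value"])
    return out, report


# ---------------------------------------------------------------------------
# summary-statistics munging

_CANONICAL = {
    "snp": {"snp", "rsid", "id", "markername", "variant_id"},
    "chrom": {"chr", "chrom", "chromosome"},
    "pos": {"bp", "pos", "position", "base_pair_location"},
    "a1": {"a1", "effect_allele", "alt", "ea"},
    "a2": {"a2", "other_allele", "ref", "nea", "oa"},
    "beta": {"beta", "b", "effect", "effect_size"},
    "se": {"se", "standard_error", "stderr"},
    "p": {"p", "pval", "pvalue", "p_value"},
    "z": {"z", "zscore", "z_score", "stat"},
    "n": {"n", "ntotal", "sample_size"},
    "maf": {"frq", "maf", "freq", "eaf", "af"},
}


def _resolve_columns(table: pd.DataFrame, column_map: dict | None) -> dict[str, str]:
    column_map = {k.lower(): v for k, v in (column_map or {}).items()}
    resolved: dict[str, str] = {}
    lower = {c.lower(): c for c in table.columns}
    for canon, aliases in _CANONICAL.items():
        if canon in column_map:
            resolved[canon] = column_map[canon]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    return resolved


def munge_sumstats(
    table: pd.DataFrame,
    column_map: dict | None = None,
    trait_type: str = "quant",
    case_fraction: float | None = None,
    n: float | None = None,
) -> GwasSumstats:
    """Harmonize a raw summary-statistics table into the standard schema.

    Column names are matched case-insensitively against common aliases,
    overridable via ``column_map`` (canonical name -> input column).  A
    missing standard error is imputed as ``|beta| / |Phi^-1(p/2)|``; a
    missing beta as ``z * se``.  Rows whose effect/se cannot be resolved are
    dropped and counted in ``n_dropped``.  Alleles are upper-cased.
    """
    cols = _resolve_columns(table, column_map)
    for required in ("a1", "a2"):
        if required not in cols:
            raise FormatError(f"summary statistics missing required column {required!r}")
    if "snp" not in cols and not ("chrom" in cols and "pos" in cols):
        raise FormatError("summary statistics need an SNP id or chrom+pos")
    have = set(cols) & {"beta", "se", "p", "z"}
    if not ({"beta", "se"} <= have or {"beta", "p"} <= have or {"z", "se"} <= have):
        raise FormatError(
            "no resolvable effect columns: need (beta,se), (beta,p) or (z,se); "
            f"found {sorted(have)}"
        )

    out = pd.DataFrame(index=table.index)
    if "snp" in cols:
        out["snp"] = table[cols["snp"]].astype(str)
    if "chrom" in cols:
        out["chrom"] = table[cols["chrom"]]
    if "pos" in cols:
        out["pos"] = table[cols["pos"]].astype(int)
    if "snp" not in cols:
        out["snp"] = out["chrom"].astype(str) + ":" + out["pos"].astype(str)
    out["a1"] = table[cols["a1"]].astype(str).str.upper()
    out["a2"] = table[cols["a2"]].astype(str).str.upper()
    for c in ("beta", "se", "p", "z", "n", "maf"):
        if c in cols:
            out[c] = pd.to_numeric(table[cols[c]], errors="coerce")
        elif c in ("beta", "se", "p"):
            out[c] = np.nan
    if "n" not in out.columns and n is not None:
        out["n"] = float(n)

    # impute beta from z*se, then se from |beta|/|Phi^-1(p/2)|
    if "z" in out.columns:
        need = out["beta"].isna() & out["z"].notna() & out["se"].notna()
        out.loc[need, "beta"] = out.loc[need, "z"] * out.loc[need, "se"]
    need_se = out["se"].isna() & out["beta"].notna() & out["p"].notna()
    with np.errstate(divide="ignore", invalid="ignore"):
        q = -stats.norm.ppf(out.loc[need_se, "p"] / 2.0)
        imputed = np.abs(out.loc[need_se, "beta"]) / np.abs(q)
    imputed[~np.isfinite(imputed) | (imputed <= 0)] = np.nan
    out.loc[need_se, "se"] = imputed
    if out["p"].isna().any():
        need_p = out["p"].isna() & out["beta"].notna() & out["se"].notna()
        zz = out.loc[need_p, "beta"] / out.loc[need_p, "se"]
        out.loc[need_p, "p"] = 2 * stats.norm.sf(np.abs(zz))

    resolvable = out["beta"].notna() & out["se"].notna() & (out["se"] > 0)
    n_dropped = int((~resolvable).sum())
    out = out[resolvable].drop(columns=[c for c in ("z",) if c in out.columns])
    out = out.reset_index(drop=True)
    return GwasSumstats(out, trait_type=trait_type, case_fraction=case_fraction,
                        n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# LD, clumping, pruning


def ld_correlation(genotypes: GenotypeMatrix, snp_subset=None) -> LdMatrix:
    """Pearson correlation of dosage columns (pairwise deletion of missing).

    Zero-variance SNPs get 0 off-diagonal (flagged in ``zero_variance``);
    the diagonal is exactly 1.
    """
    gm = genotypes if snp_subset is None else genotypes.subset_snps(snp_subset)
    X = gm.dosage
    if np.isnan(X).any():
        rho = pd.DataFrame(X).corr(min_periods=2).to_numpy()
    else:
        sd = X.std(axis=0)
        zero = sd == 0
        Xc = X - X.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.where(zero, 1.0, sd) * np.sqrt(X.shape[0])
            Z = Xc / denom
            rho = Z.T @ Z
        rho[zero, :] = 0.0
        rho[:, zero] = 0.0
    zero_var = list(gm.snps[np.nanstd(X, axis=0) == 0])
    if zero_var:
        warnings.warn(f"zero-variance SNPs in LD computation: {zero_var[:5]}")
        idx = gm.snps.get_indexer(zero_var)
        rho[idx, :] = 0.0
        rho[:, idx] = 0.0
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return LdMatrix(gm.snps, rho, zero_variance=zero_var)


def window_clump(sumstats: pd.DataFrame, p_threshold: float = 5e-8,
                 window_bp: int = 1_000_000) -> pd.DataFrame:
    """Greedy distance-based clumping: retain the top variant per window.

    Candidates are rows with p < ``p_threshold``; scanning by ascending p, a
    candidate becomes a lead unless a previously accepted lead on the same
    chromosome lies within ``window_bp``.  Returns the lead rows.
    """
    cand = sumstats[sumstats["p"] < p_threshold].sort_values("p", kind="mergesort")
    leads: list[int] = []
    accepted: dict = {}
    for idx, row in cand.iterrows():
        chrom, pos = row["chrom"], row["pos"]
        taken = accepted.get(chrom, [])
        if all(abs(pos - q) > window_bp for q in taken):
            leads.append(idx)
            accepted.setdefault(chrom, []).append(pos)
    return sumstats.loc[leads]


def r2_prune(snp_stats: pd.DataFrame, ld: LdMatrix, r2_threshold: float = 0.01,
             anchor: str | None = None) -> list[str]:
    """Greedy r^2 pruning by ascending p; the anchor SNP (if given) is first.

    A SNP is kept iff its r^2 with every already-kept SNP is <= threshold.
    Every candidate must be present in ``ld`` (silent drops are forbidden).
    """
    snps = list(snp_stats["snp"])
    missing = [s for s in snps if s not in ld.snps]
    if missing:
        raise KeyError(f"SNPs absent from LD matrix: {missing[:5]}")
    order = snp_stats.sort_values("p", kind="mergesort")["snp"].tolist()
    if anchor is not None:
        if anchor not in order:
            raise KeyError(f"anchor SNP {anchor!r} not among candidates")
        order = [anchor] + [s for s in order if s != anchor]
    r2 = ld.r2
    pos = {s: i for i, s in enumerate(ld.snps)}
    kept: list[str] = []
    for s in order:
        if all(r2[pos[s], pos[k]] <= r2_threshold for k in kept):
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# file I/O


def write_dosage_tsv(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.dosage.tsv`` (SNPs x donors) and ``<prefix>.snps.tsv``."""
    prefix = Path(prefix)
    dm = pd.DataFrame(gm.dosage.T, index=gm.snps, columns=gm.donors)
    dm.to_csv(prefix.with_suffix(".dosage.tsv"), sep="\t", index_label="snp",
              float_format="%.6g")
    gm.snp_map.to_csv(prefix.with_suffix(".snps.tsv"), sep="\t", index_label="snp",
                      float_format="%.10g")


def read_dosage_tsv(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    dm = pd.read_csv(prefix.with_suffix(".dosage.tsv"), sep="\t", index_col="snp")
    smap = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t", index_col="snp")
    return GenotypeMatrix(pd.Index(dm.columns), dm.index, dm.to_numpy().T, smap)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call GT records as a minimal VCFv4.2 text file."""
    hard = gm.hard_calls()
    order = np.argsort(
        gm.snp_map["chrom"].astype(int).to_numpy() * 10**10 + gm.snp_map["pos"].to_numpy()
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.donors)) + "\n")
        for j in order:
            row = gm.snp_map.iloc[j]
            calls = []
            for d in hard[:, j]:
                if np.isnan(d):
                    calls.append("./.")
                else:  # dosage counts A1 = ALT copies
                    calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{gm.snps[j]}\t{row['a2']}\t"
                     f"{row['a1']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path: str | Path):
    """Read GT (or DS) dosages from a VCF; A1 is the ALT allele.

    Multi-allelic records are rejected at read time (dropped and counted).
    Returns (GenotypeMatrix, n_multiallelic_dropped).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = pd.Index(vcf.samples)
    snp_ids, rows, meta = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, float).reshape(-1)
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            dose = np.where((gts < 0).any(axis=1), np.nan, gts.clip(min=0).sum(axis=1))
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(dose.astype(float))
        meta.append((str(var.CHROM).lstrip("chr"), var.POS, var.ALT[0], var.REF))
    smap = pd.DataFrame(meta, columns=["chrom", "pos", "a1", "a2"],
                        index=pd.Index(snp_ids, name="snp"))
    dosage = np.array(rows, float).T if rows else np.empty((len(donors), 0))
    freq = np.nanmean(dosage, axis=0) / 2.0 if rows else np.array([])
    smap["maf"] = np.minimum(freq, 1 - freq)
    smap["chrom"] = pd.to_numeric(smap["chrom"], errors="coerce").fillna(-1).astype(int)
    return GenotypeMatrix(donors, pd.Index(snp_ids), dosage, smap), n_multi


def write_sumstats_tsv(ss: GwasSumstats, path: str | Path) -> None:
    ss.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sumstats_tsv(path: str | Path, trait_type: str = "quant",
                      case_fraction: float | None = None) -> GwasSumstats:
    table = pd.read_csv(path, sep="\t")
    return munge_sumstats(table, trait_type=trait_type, case_fraction=case_fraction)
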