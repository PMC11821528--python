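"""Pseudobulk aggregation, normalization and scaling of single-cell counts.

Cells are aggregated per donor within a cell type (or across all cell types
in ``all_cells`` "bulk" mode) by summing raw counts.  Donors contributing
fewer than ``min_cells`` cells to a cell type are excluded from that cell
type only.  Normalization is log2 CPM with a prior count, followed by a
per-gene expressed-fraction filter and per-gene standardization, so a unit
of the final matrix is one standard deviation of expression.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .exceptions import ConfigurationError, FormatError

__all__ = ["CellCounts", "Pseudobulk", "aggregate", "normalize",
           "read_mtx_counts", "write_mtx_counts"]


@dataclass
class CellCounts:
    """Cell-level integer counts for one cell type.

    ``counts`` is genes x cells (sparse or dense); ``cell_donors`` maps each
    cell (column) to a donor id.
    """

    cell_type: str
    genes: pd.Index
    counts: sparse.spmatrix | np.ndarray
    cell_donors: np.ndarray

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.cell_donors = np.asarray(self.cell_donors)
        if self.counts.shape != (len(self.genes), len(self.cell_donors)):
            raise ConfigurationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cell_donors)} cells"
            )
        data = self.counts.data if sparse.issparse(self.counts) else self.counts
        if (np.asarray(data) < 0).any():
            raise ConfigurationError("negative cell counts")

    @property
    def n_cells(self) -> int:
        return len(self.cell_donors)


@dataclass
class Pseudobulk:
    """Gene x donor pseudobulk matrix with a processing-stage tag.

    ``stage`` is one of ``raw_sum``, ``logcpm``, ``scaled`` (or
    ``residual`` downstream); ``cells_per_donor`` records how many cells
    each retained donor contributed.
    """

    cell_type: str
    matrix: pd.DataFrame
    stage: str
    cells_per_donor: pd.Series
    dropped_genes: list = field(default_factory=list)

    @property
    def donors(self) -> pd.Index:
        return self.matrix.columns

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index


def aggregate(cells, min_cells: int = 10, mode: str = "per_cell_type"):
    """Sum cell counts to donor pseudobulk.

    Parameters
    ----------
    cells : a single :class:`CellCounts`, or a mapping cell_type ->
        :class:`CellCounts`.
    min_cells : donors with fewer cells than this in a cell type are
        excluded from that cell type (default 10).
    mode : ``per_cell_type`` returns a dict cell_type -> :class:`Pseudobulk`;
        ``all_cells`` pools every cell into one "bulk" matrix.

    Returns a :class:`Pseudobulk` (single input or ``all_cells``) or a dict.
    """
    if min_cells < 1:
        raise ConfigurationError("min_cells must be >= 1")
    if isinstance(cells, CellCounts):
        return _aggregate_one(cells, min_cells)
    if mode == "per_cell_type":
        return {ct: _aggregate_one(cc, min_cells) for ct, cc in cells.items()}
    if mode == "all_cells":
        items = list(cells.values())
        genes = items[0].genes
        for cc in items[1:]:
            if not cc.genes.equals(genes):
                raise ConfigurationError("all_cells mode requires a shared gene index")
        counts = sparse.hstack([sparse.csr_matrix(cc.counts) for cc in items])
        donors = np.concatenate([cc.cell_donors for cc in items])
        pooled = CellCounts("all_cells", genes, counts, donors)
        return _aggregate_one(pooled, min_cells)
    raise ConfigurationError(f"unknown aggregation mode {mode!r}")


def _aggregate_one(cc: CellCounts, min_cells: int) -> Pseudobulk:
    donors = pd.Index(pd.unique(cc.cell_donors))
    codes = donors.get_indexer(cc.cell_donors)
    ind = sparse.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), len(donors)),
    )
    sums = np.asarray((sparse.csr_matrix(cc.counts) @ ind).todense())
    n_cells = pd.Series(np.bincount(codes, minlength=len(donors)), index=donors)
    keep = n_cells >= min_cells
    mat = pd.DataFrame(sums, index=cc.genes, columns=donors).loc[:, keep[keep].index]
    # stable donor order for reproducible output
    mat = mat.reindex(sorted(mat.columns, key=str), axis=1)
    return Pseudobulk(cc.cell_type, mat, "raw_sum", n_cells[keep].reindex(mat.columns))


def normalize(raw: Pseudobulk, expressed_fraction: float = 0.05,
              prior_count: float = 2.0) -> Pseudobulk:
    """log2-CPM transform, expressed-gene filter and per-gene scaling.

    ``logCPM = log2(count / library_size * 1e6 + prior_count)``.  Genes with
    a nonzero raw count in fewer than ``expressed_fraction`` of donors are
    removed before scaling; remaining genes are centred and scaled to unit
    SD, so one unit of the output is one SD of expression.
    """
    if raw.stage != "raw_sum":
        raise ConfigurationError(
            f"normalize expects stage raw_sum, got {raw.stage!r} (double scaling?)"
        )
    counts = raw.matrix
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        bad = list(libsize.index[libsize == 0])
        raise ConfigurationError(f"zero library size for donors {bad[:5]}")
    cpm = counts / libsize * 1e6
    logcpm = np.log2(cpm + prior_count)

    frac = (counts > 0).mean(axis=1)
    keep = frac >= expressed_fraction
    logcpm = logcpm.loc[keep]
    dropped = list(counts.index[~keep])

    sd = logcpm.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"dropping {int(zero_var.sum())} zero-variance genes before scaling")
        dropped += list(logcpm.index[zero_var])
        logcpm = logcpm.loc[~zero_var]
        sd = sd[~zero_var]
    scaled = logcpm.sub(logcpm.mean(axis=1), axis=0).div(sd, axis=0)
    return Pseudobulk(raw.cell_type, scaled, "scaled", raw.cells_per_donor, dropped)


# ---------------------------------------------------------------------------
# I/O


def write_mtx_counts(cc: CellCounts, prefix: str | Path) -> None:
    """Write counts as MTX plus features/barcodes TSVs (plain text)."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix) + ".mtx", sparse.coo_matrix(cc.counts))
    pd.Series(cc.genes).to_csv(str(prefix) + ".features.tsv", sep="\t",
                               index=False, header=False)
    pd.DataFrame({"cell": np.arange(len(cc.cell_donors)),
                  "donor": cc.cell_donors}).to_csv(
        str(prefix) + ".barcodes.tsv", sep="\t", index=False)


def read_mtx_counts(prefix: str | Path, cell_type: str) -> CellCounts:
    prefix = Path(prefix)
    counts = sparse.csr_matrix(spio.mmread(str(prefix) + ".mtx"))
    genes = pd.read_csv(str(prefix) + ".features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(str(prefix) + ".barcodes.tsv", sep="\t")
    if "donor" not in barcodes.columns:
        raise FormatError("barcodes file lacks a 'donor' column")
    return CellCounts(cell_type, pd.Index(genes), counts, barcodes["donor"].to_numpy())


def write_pseudobulk(pb: Pseudobulk, prefix: str | Path) -> None:
    prefix = Path(prefix)
    pb.matrix.to_csv(str(prefix) + ".tsv", sep="\t", index_label="gene",
                     float_format="%.10g")
    sidecar = {"cell_type": pb.cell_type, "stage": pb.stage,
               "cells_per_donor": {str(k): int(v) for k, v in pb.cells_per_donor.items()}}
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_pseudobulk(prefix: str | Path) -> Pseudobulk:
    prefix = Path(prefix)
    mat = pd.read_csv(str(prefix) + ".tsv", sep="\t", index_col="gene")
    sidecar = json.loads(Path(str(prefix) + ".json").read_text())
    cells = pd.Series(sidecar["cells_per_donor"]).reindex(mat.columns)
    return Pseudobulk(sidecar["cell_type"], mat, sidecar["stage"], cells)
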