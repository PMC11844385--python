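"""Cell-level QC, normalization, and pseudobulk aggregation for CROP-seq.

Cells are filtered on total counts, detected genes, and ribosomal /
mitochondrial content fractions before clustering; expression is then
scaled to a fixed per-cell target sum and log1p-transformed. For
differential expression, raw counts are summed into pseudobulk profiles
grouped by (knockdown target, GEM library) and handed to an external
count-model engine — the aggregation here deliberately uses raw integer
counts, not the normalized matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellQcThresholds:
    """QC gates applied per cell.

    ``min_total`` and ``min_genes`` are inclusive ("minimum of" reads as
    >=). The ribosomal-content bounds are an open interval and the
    mitochondrial bound is strict, so cells sitting exactly on a content
    boundary are removed. Fractions are percentages of total counts;
    mito/ribo genes are identified by symbol prefix.
    """

    min_total: int = 2000
    min_genes: int = 100
    ribo_bounds: tuple[float, float] = (3.0, 8.0)
    max_mito: float = 6.5
    mito_prefixes: tuple[str, ...] = ("MT-",)
    ribo_prefixes: tuple[str, ...] = ("RPS", "RPL")

    def __post_init__(self) -> None:
        lo, hi = self.ribo_bounds
        if not (0 <= lo <= hi <= 100):
            raise ValueError(f"ribo bounds {self.ribo_bounds} not ordered in [0, 100]")
        if not (0 <= self.max_mito <= 100):
            raise ValueError(f"max_mito {self.max_mito} outside [0, 100]")


@dataclass
class PseudobulkTable:
    """Per-group summed counts (genes x groups) plus group cell counts."""

    counts: pd.DataFrame
    n_cells: pd.Series = field(repr=False)


def _row_sums(X) -> np.ndarray:
    return np.asarray(X.sum(axis=1)).ravel()


def _prefix_mask(var_names: pd.Index, prefixes: tuple[str, ...]) -> np.ndarray:
    upper = var_names.str.upper()
    mask = np.zeros(len(var_names), dtype=bool)
    for p in prefixes:
        mask |= np.asarray(upper.str.startswith(p.upper()))
    return mask


def qc_filter_cells(
    adata: ad.AnnData, thresholds: CellQcThresholds = CellQcThresholds()
) -> tuple[ad.AnnData, dict[str, int]]:
    """Apply the per-cell QC gates; return the filtered matrix and a report.

    A cell is kept iff total >= min_total, detected genes >= min_genes,
    ribo% strictly inside ``ribo_bounds`` and mito% strictly below
    ``max_mito``. The report lists how many cells fail each criterion
    (a cell can fail several) and the total removed; filtering is
    idempotent.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty expression matrix")
    t = thresholds
    X = adata.X
    totals = _row_sums(X)
    if sparse.issparse(X):
        genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        genes_detected = (np.asarray(X) > 0).sum(axis=1)
    mito_mask = _prefix_mask(adata.var_names, t.mito_prefixes)
    ribo_mask = _prefix_mask(adata.var_names, t.ribo_prefixes)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = 100 * np.where(totals > 0, _row_sums(X[:, mito_mask]) / totals, 0.0)
        ribo_pct = 100 * np.where(totals > 0, _row_sums(X[:, ribo_mask]) / totals, 0.0)

    pass_total = totals >= t.min_total
    pass_genes = genes_detected >= t.min_genes
    lo, hi = t.ribo_bounds
    pass_ribo = (ribo_pct > lo) & (ribo_pct < hi)
    pass_mito = mito_pct < t.max_mito
    keep = pass_total & pass_genes & pass_ribo & pass_mito
    report = {
        "n_cells": int(adata.n_obs),
        "fail_min_total": int((~pass_total).sum()),
        "fail_min_genes": int((~pass_genes).sum()),
        "fail_ribo_bounds": int((~pass_ribo).sum()),
        "fail_max_mito": int((~pass_mito).sum()),
        "n_removed": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    logger.info("QC kept %d / %d cells", report["n_kept"], report["n_cells"])
    return adata[keep].copy(), report


def normalize_log(adata: ad.AnnData, target_sum: float = 1000.0) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Delegates to scanpy's normalize_total/log1p (the standard tooling for
    this transform). All-zero cells are rejected — QC upstream guarantees
    none survive.
    """
    import scanpy as sc  # deferred: scanpy import is heavy

    totals = _row_sums(adata.X)
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0].tolist()
        raise ValueError(f"all-zero cell(s): {bad[:5]}{'...' if len(bad) > 5 else ''}")
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    return out


def pseudobulk_aggregate(
    adata: ad.AnnData,
    knockdown_key: str = "knockdown",
    gem_key: str = "gem",
) -> PseudobulkTable:
    """Sum raw counts per (knockdown, GEM library) group.

    Group columns are named ``<knockdown>|<gem>`` in sorted group order.
    Cells with missing metadata abort with the offending barcode named;
    the grand total of the output equals the grand total of the input.
    """
    for key in (knockdown_key, gem_key):
        if key not in adata.obs.columns:
            raise ValueError(f"cell metadata lacks column {key!r}")
        vals = adata.obs[key]
        missing = vals.isna() | (vals.astype(str).str.len() == 0)
        if missing.any():
            bad = adata.obs_names[missing][0]
            raise ValueError(f"cell {bad!r} is missing {key!r} metadata")
    labels = (
        adata.obs[knockdown_key].astype(str) + "|" + adata.obs[gem_key].astype(str)
    )
    groups = sorted(labels.unique())
    codes = pd.Categorical(labels, categories=groups).codes
    # indicator (groups x cells) @ X gives per-group per-gene sums
    indicator = sparse.csr_matrix(
        (np.ones(adata.n_obs), (codes, np.arange(adata.n_obs))),
        shape=(len(groups), adata.n_obs),
    )
    X = adata.X if sparse.issparse(adata.X) else np.asarray(adata.X)
    summed = indicator @ X
    if sparse.issparse(summed):
        summed = np.asarray(summed.todense())
    counts = pd.DataFrame(
        np.asarray(summed, dtype=np.int64).T,
        index=adata.var_names,
        columns=groups,
    )
    n_cells = pd.Series(np.bincount(codes, minlength=len(groups)), index=groups)
    return PseudobulkTable(counts=counts, n_cells=n_cells)


# ---------------------------------------------------------------------------
# MTX triplet I/O for expression matrices
# ---------------------------------------------------------------------------

def read_expression_mtx(
    mtx_path: str | Path,
    barcodes_path: str | Path | None = None,
    features_path: str | Path | None = None,
    obs: pd.DataFrame | None = None,
) -> ad.AnnData:
    """Read a features x barcodes MTX triplet into an AnnData (cells x genes)."""
    mtx_path = Path(mtx_path)
    folder = mtx_path.parent
    barcodes_path = Path(barcodes_path) if barcodes_path else folder / "barcodes.tsv"
    features_path = Path(features_path) if features_path else folder / "features.tsv"
    mat = sparse.csr_matrix(spio.mmread(mtx_path)).T  # cells x genes
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=barcodes.tolist()),
        var=pd.DataFrame(index=features.tolist()),
    )
    if obs is not None:
        adata.obs = adata.obs.join(obs)
    return adata


def write_expression_mtx(adata: ad.AnnData, folder: str | Path) -> None:
    """Write an AnnData (cells x genes) as a features x barcodes MTX triplet."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(np.asarray(adata.X))
    spio.mmwrite(folder / "matrix.mtx", X.T)
    pd.Series(adata.obs_names).to_csv(
        folder / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.var_names).to_csv(
        folder / "features.tsv", sep="\t", header=False, index=False
    )
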