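"""CROP-seq guide assignment from cell x guide UMI counts.

Each cell's guide-enrichment UMIs are a mixture of its true guide(s) and
ambient molecules. A cell is assigned to its majority guide when three
conditions hold simultaneously: the hypergeometric upper-tail p of the top
guide's count (BH-adjusted across cells) is below ``p_thresh``, the log2
odds ratio between the top and second counts exceeds ``lor_thresh``, and
the cell's total UMI count exceeds ``min_umi``. Cells passing all three
carry exactly one confidently detected guide — the MOI-1 population used
downstream.

The hypergeometric test asks whether the top guide's share of the cell's
UMIs is surprising given that guide's share of the whole experiment:
population = grand-total UMIs, successes = the guide's column total,
draws = the cell's total.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Evaluated through the survival function's log form for stability in
    deep tails. k = 0 returns exactly 1 (the whole support).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid margins K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); exponentiating logsf keeps tiny tails accurate
    return float(np.exp(sps.hypergeom.logsf(k - 1, N, K, n)))


def assign_guides(
    counts: pd.DataFrame,
    p_thresh: float = 0.05,
    lor_thresh: float = 1.0,
    min_umi: int = 5,
) -> pd.DataFrame:
    """Per-cell guide assignment from a cells x guides UMI count table.

    Returns one row per cell: barcode, top_guide, second_guide, c1, c2, n,
    p_raw, p_adj, log2_odds, assigned. Ties for the top guide are never
    assigned; a cell with a single observed guide has infinite log-odds.
    ``assigned`` requires p_adj < p_thresh, log2_odds > lor_thresh and
    n > min_umi (strict, so min_umi=5 means at least 6 UMIs).
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty cell x guide matrix")
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise ValueError("duplicate barcodes or guide ids")
    mat = counts.to_numpy(dtype=np.int64)
    if (mat < 0).any():
        raise ValueError("UMI counts must be nonnegative integers")
    guide_totals = mat.sum(axis=0)
    grand_total = int(mat.sum())
    cell_totals = mat.sum(axis=1)

    order = np.argsort(mat, axis=1, kind="stable")
    top_idx = order[:, -1]
    second_idx = order[:, -2] if mat.shape[1] > 1 else None
    c1 = mat[np.arange(len(mat)), top_idx]
    c2 = (
        mat[np.arange(len(mat)), second_idx]
        if second_idx is not None
        else np.zeros(len(mat), dtype=np.int64)
    )
    # a tie means >=2 guides share the maximal count (and it is nonzero)
    tied = (c1 == c2) & (c1 > 0) if second_idx is not None else np.zeros(len(mat), bool)

    guides = counts.columns.to_numpy()
    p_raw = np.ones(len(mat))
    for i in range(len(mat)):
        if c1[i] > 0:
            p_raw[i] = hypergeom_tail(
                int(c1[i]), int(guide_totals[top_idx[i]]),
                int(cell_totals[i]), grand_total,
            )
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    with np.errstate(divide="ignore"):
        log2_odds = np.where(
            c1 > 0,
            np.log2(c1) - np.where(c2 > 0, np.log2(c2), -np.inf),
            0.0,
        )
    log2_odds = np.where(tied, 0.0, log2_odds)
    assigned = (
        ~tied
        & (c1 > 0)
        & (p_adj < p_thresh)
        & (log2_odds > lor_thresh)
        & (cell_totals > min_umi)
    )
    top_guide = np.where(c1 > 0, guides[top_idx], None)
    top_guide = np.where(tied, None, top_guide)
    second_guide = (
        np.where(c2 > 0, guides[second_idx], None)
        if second_idx is not None
        else np.full(len(mat), None)
    )
    out = pd.DataFrame(
        {
            "barcode": counts.index,
            "top_guide": top_guide,
            "second_guide": second_guide,
            "c1": c1,
            "c2": c2,
            "n": cell_totals,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "log2_odds": log2_odds,
            "assigned": assigned,
        }
    )
    logger.info(
        "assigned %d / %d cells (%.1f%%)",
        int(assigned.sum()), len(out), 100 * assigned.mean(),
    )
    return out


def moi1_filter(assignments: pd.DataFrame) -> tuple[dict[str, str], dict[str, int]]:
    """Keep only confidently assigned (MOI-1) cells.

    Returns (barcode -> guide map, report). The report partitions the
    input: retained + dropped == total cells.
    """
    kept = assignments[assignments["assigned"]]
    mapping = dict(zip(kept["barcode"], kept["top_guide"]))
    report = {
        "n_cells": len(assignments),
        "n_retained": len(mapping),
        "n_dropped": len(assignments) - len(mapping),
    }
    return mapping, report


# ---------------------------------------------------------------------------
# matrix-market I/O (10x-style triplet: matrix.mtx + barcodes/features TSVs)
# ---------------------------------------------------------------------------

def read_cell_guide_mtx(
    mtx_path: str | Path,
    barcodes_path: str | Path | None = None,
    features_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a features x barcodes MTX triplet into a cells x guides table.

    Follows the 10x convention of features as rows and barcodes as
    columns; sidecar paths default to ``barcodes.tsv`` / ``features.tsv``
    next to the matrix.
    """
    mtx_path = Path(mtx_path)
    folder = mtx_path.parent
    barcodes_path = Path(barcodes_path) if barcodes_path else folder / "barcodes.tsv"
    features_path = Path(features_path) if features_path else folder / "features.tsv"
    mat = sparse.csr_matrix(spio.mmread(mtx_path))
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
    features = pd.read_csv(features_path, sep="\t", header=None)[0].tolist()
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    dense = np.asarray(mat.todense(), dtype=np.int64)
    return pd.DataFrame(dense.T, index=barcodes, columns=features)


def write_cell_guide_mtx(counts: pd.DataFrame, folder: str | Path) -> None:
    """Write a cells x guides table as a features x barcodes MTX triplet."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(counts.to_numpy(dtype=np.int64).T)
    spio.mmwrite(folder / "matrix.mtx", mat)
    pd.Series(counts.index).to_csv(
        folder / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(counts.columns).to_csv(
        folder / "features.tsv", sep="\t", header=False, index=False
    )
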