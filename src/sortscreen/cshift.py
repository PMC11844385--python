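"""Cluster-occupancy-shift statistics for perturbation single-cell data.

Given cluster labels and a guide group per cell, each knockdown group is
tested for over- or under-representation in each cluster: a 2x2 Pearson
chi-square (in-cluster vs out-of-cluster) is computed against every
non-targeting-control (NTC) group separately, the per-NTC p-values are
aggregated by geometric mean, and the aggregated p-values are BH-adjusted
across all (knockdown, cluster) pairs. Effect size is the percent change
in occupancy relative to the pooled NTC cells.

The geometric-mean aggregation is a heuristic combination rule, not a
calibrated one; its empirical null behavior is verified by simulation in
the test-suite rather than guaranteed analytically.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("barcode", "cluster", "group", "is_ntc")


def _validate(labels: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(labels.columns)
    if missing:
        raise ValueError(f"label table missing columns {sorted(missing)}")
    if len(labels) == 0:
        raise ValueError("empty label table")


def cluster_occupancy(labels: pd.DataFrame, group: str) -> pd.Series:
    """Fraction of the group's cells in each cluster (all clusters reported).

    Clusters absent from the group get 0; fractions sum to 1.
    """
    _validate(labels)
    sub = labels[labels["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"unknown or empty group {group!r}")
    clusters = pd.Index(sorted(labels["cluster"].unique()), name="cluster")
    counts = sub["cluster"].value_counts().reindex(clusters, fill_value=0)
    return counts / counts.sum()


def chi2_2x2(a: int, b: int, c: int, d: int, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], 1 df.

    No continuity correction by default. A zero row or column margin
    carries no information; by convention that returns (0, 1).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if table.sum() == 0:
        raise ValueError("empty 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.debug("degenerate 2x2 margin; returning p = 1")
        return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def cshift_table(
    labels: pd.DataFrame, q_thresh: float = 0.05, correction: bool = False
) -> pd.DataFrame:
    """Occupancy-shift statistics for every (knockdown, cluster) pair.

    For each knockdown group and cluster, a 2x2 chi-square is run against
    each NTC group; the per-NTC p-values are combined by geometric mean,
    BH-adjusted across all pairs, and flagged significant at
    ``q < q_thresh``. ``percent_change`` compares the knockdown's
    occupancy with the pooled (size-weighted) NTC occupancy.
    """
    _validate(labels)
    ntc_groups = sorted(labels.loc[labels["is_ntc"], "group"].unique())
    kd_groups = sorted(labels.loc[~labels["is_ntc"], "group"].unique())
    if not ntc_groups:
        raise ValueError("no NTC groups in label table")
    if not kd_groups:
        raise ValueError("no knockdown groups in label table")
    clusters = sorted(labels["cluster"].unique())

    # per-group per-cluster tallies
    tally = (
        labels.groupby(["group", "cluster"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=clusters, fill_value=0)
    )
    group_sizes = tally.sum(axis=1)
    ntc_pool = tally.loc[ntc_groups].sum(axis=0)
    ntc_pool_frac = ntc_pool / ntc_pool.sum()

    rows = []
    for kd in kd_groups:
        kd_counts = tally.loc[kd]
        kd_total = int(group_sizes[kd])
        for cl in clusters:
            a = int(kd_counts[cl])
            b = kd_total - a
            ps = []
            for ntc in ntc_groups:
                c = int(tally.loc[ntc, cl])
                d = int(group_sizes[ntc]) - c
                _, p = chi2_2x2(a, b, c, d, correction=correction)
                ps.append(p)
            agg_p = float(np.exp(np.mean(np.log(ps))))
            kd_frac = a / kd_total
            ntc_frac = float(ntc_pool_frac[cl])
            pct = 100 * (kd_frac - ntc_frac) / ntc_frac if ntc_frac > 0 else np.nan
            rows.append(
                {
                    "group": kd,
                    "cluster": cl,
                    "kd_fraction": kd_frac,
                    "ntc_fraction": ntc_frac,
                    "percent_change": pct,
                    "p_aggregated": agg_p,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p_aggregated"], method="fdr_bh")[1]
    out["significant"] = out["q"] < q_thresh
    return out


def percent_change_matrix(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot a cshift_table into (knockdown x cluster percent change, mask)."""
    pct = results.pivot(index="group", columns="cluster", values="percent_change")
    sig = results.pivot(index="group", columns="cluster", values="significant")
    return pct, sig
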