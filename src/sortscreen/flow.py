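"""Per-event CaMPARI red/green ratios and well-level summaries.

CaMPARI photoconverts green to red in proportion to integrated calcium
activity, so the per-event red/green (R/G) intensity ratio is the activity
readout. Wells are summarized by the arithmetic mean event ratio and
normalized so the pooled mean over designated reference wells (no sgRNA
transduction) equals one; a marker-channel gate (e.g. BFP in the sgRNA
vector) splits events within a well into transduced and untransduced
subsets for paired comparisons.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("well", "green", "red")


def _validate(events: pd.DataFrame) -> None:
    if len(events) == 0:
        raise ValueError("empty event table")
    missing = set(REQUIRED_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")


def event_ratios(events: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Red/green ratio per event; non-ratioable events excluded.

    Events with nonpositive or nonfinite green intensity cannot be
    ratioed; they are dropped (not pseudocounted) and tallied in the
    returned report. The ratio series keeps the original event index.
    """
    _validate(events)
    green = events["green"].to_numpy(dtype=float)
    red = events["red"].to_numpy(dtype=float)
    ok = np.isfinite(green) & np.isfinite(red) & (green > 0)
    ratios = pd.Series(red[ok] / green[ok], index=events.index[ok], name="rg_ratio")
    report = {"n_events": len(events), "n_excluded": int((~ok).sum())}
    if report["n_excluded"]:
        logger.info("excluded %d non-ratioable events", report["n_excluded"])
    return ratios, report


def well_summary(events: pd.DataFrame, ratios: pd.Series | None = None) -> pd.DataFrame:
    """Mean R/G per well over ratioable events.

    Wells with zero ratioable events are absent from the output (logged).
    Columns: well, n_events, mean_rg.
    """
    _validate(events)
    if ratios is None:
        ratios, _ = event_ratios(events)
    wells = events.loc[ratios.index, "well"]
    grouped = ratios.groupby(wells)
    out = pd.DataFrame(
        {"n_events": grouped.size(), "mean_rg": grouped.mean()}
    ).reset_index().rename(columns={"well": "well"})
    dropped = set(events["well"]) - set(out["well"])
    if dropped:
        logger.info("wells with no ratioable events dropped: %s", sorted(dropped))
    return out


def normalize_to_reference(
    summaries: pd.DataFrame, reference_well_ids: list[str]
) -> pd.DataFrame:
    """Scale well means so the pooled reference-well mean equals one.

    The reference value is the event-count-weighted mean over reference
    wells, i.e. the plain mean over all reference events, so the pooled
    reference normalized mean is exactly 1 regardless of how events are
    distributed across reference wells.
    """
    ref = summaries[summaries["well"].isin(reference_well_ids)]
    if len(ref) == 0:
        raise ValueError(
            f"no reference wells found among {sorted(set(summaries['well']))}"
        )
    pooled = (ref["mean_rg"] * ref["n_events"]).sum() / ref["n_events"].sum()
    out = summaries.copy()
    out["normalized_rg"] = out["mean_rg"] / pooled
    return out


def split_by_marker(
    events: pd.DataFrame, threshold: float, marker_column: str = "marker"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition events at a fixed marker-intensity gate (>= is positive).

    Both subsets retain well ids (and all other columns) so positive and
    negative populations in the same well can be compared pairwise.
    """
    if marker_column not in events.columns:
        raise ValueError(f"event table has no {marker_column!r} column")
    positive = events[events[marker_column] >= threshold]
    negative = events[events[marker_column] < threshold]
    return positive, negative
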