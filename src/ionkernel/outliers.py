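"""Analytical outlier removal by median absolute deviation within groups.

Single-kernel ICP-MS data contain occasional analytical outliers —
contamination, spurious interferences, poor sample uptake — that are not
biology. Within each group (a field plot for replicated designs, or a line
otherwise) and separately for each element, a value is removed when it lies
more than ``k`` median absolute deviations from the group median. The
default ``k`` = 15 counts raw MADs (no 1.4826 consistency scaling): the rule
is deliberately conservative so genuine biological extremes survive.

The filter makes exactly one pass — medians and MADs are not recomputed
after removals — and a group whose MAD is zero removes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import OutlierConfig

logger = logging.getLogger("ionkernel.outliers")

MAD_CONSISTENCY = 1.4826


@dataclass
class FilterResult:
    """Filtered table plus a record of what was removed and why.

    ``kept`` preserves the input's rows and order with removed readings set
    to NaN (removal is per element, so a seed may keep some elements and
    lose others). ``removed`` lists one row per removed reading with the
    group statistics that triggered it.
    """

    kept: pd.DataFrame
    removed: pd.DataFrame
    notes: list[str]

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def mad(values: np.ndarray) -> float:
    """Median absolute deviation from the median (unscaled)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan
    med = np.median(v)
    return float(np.median(np.abs(v - med)))


_REMOVED_COLS = ["row", "sample_id", "group", "element", "value",
                 "group_median", "group_mad", "reason"]


def remove_outliers(
    table: pd.DataFrame,
    elements: list[str],
    config: OutlierConfig | None = None,
) -> FilterResult:
    """Remove per-element values beyond k MADs of their group median.

    ``table`` is seed-level with the grouping columns named in
    ``config.group_by`` and one numeric column per element. Groups smaller
    than ``config.min_group_size`` pass through untouched with a note, as do
    zero-MAD groups. Input row order is preserved.
    """
    config = config or OutlierConfig()
    group_cols = [c for c in config.group_by if c in table.columns]
    if not group_cols:
        raise ValueError(
            f"none of the grouping columns {config.group_by} are present")
    scale = MAD_CONSISTENCY if config.scale_mad else 1.0
    reason = f"|x - median| > {config.threshold} x MAD"

    kept = table.reset_index(drop=True).copy()
    grouped = kept.groupby(group_cols, sort=False, observed=True)
    group_label = grouped.ngroup().to_numpy()
    size = grouped[group_cols[0]].transform("size").to_numpy()
    key_strings = kept[group_cols].astype(str).agg("|".join, axis=1)

    notes: list[str] = []
    small = size < config.min_group_size
    if small.any():
        for key in key_strings[small].unique():
            notes.append(f"group {key}: below minimum size, passed through")

    removed_frames: list[pd.DataFrame] = []
    for el in elements:
        med = grouped[el].transform("median").to_numpy()
        vals = kept[el].to_numpy(dtype=float)
        absdev = pd.Series(np.abs(vals - med), index=kept.index)
        spread = (absdev.groupby(group_label).transform("median")
                  .to_numpy()) * scale
        zero_mad = np.isfinite(spread) & (spread == 0.0)
        if zero_mad.any():
            for key in key_strings[zero_mad].unique():
                notes.append(f"group {key} element {el}: zero MAD, "
                             "nothing removed")
        over = (~small & np.isfinite(vals) & np.isfinite(spread)
                & (spread > 0.0)
                & (np.abs(vals - med) > config.threshold * spread))
        if over.any():
            rows = np.flatnonzero(over)
            removed_frames.append(pd.DataFrame({
                "row": rows,
                "sample_id": (kept["sample_id"].to_numpy()[rows]
                              if "sample_id" in kept.columns else rows),
                "group": key_strings.to_numpy()[rows],
                "element": el,
                "value": vals[rows],
                "group_median": med[rows],
                "group_mad": spread[rows],
                "reason": reason,
            }))
            kept.loc[rows, el] = np.nan

    removed = (pd.concat(removed_frames, ignore_index=True)
               if removed_frames else pd.DataFrame(columns=_REMOVED_COLS))
    if len(removed):
        logger.info("removed %d readings across %d groups", len(removed),
                    removed["group"].nunique())
    return FilterResult(kept=kept, removed=removed, notes=notes)
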