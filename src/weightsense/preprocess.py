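"""Preprocessing of raw magnitude estimates.

Three stages, applied in order:

1. ``to_grams`` — convert arbitrary response units to grams via the reference
   anchoring (the 375 g reference cube is labelled "50", so 7.5 g per unit).
2. ``normalise`` — remove idiosyncratic use of the response scale: each
   participant's estimates are rescaled multiplicatively so every participant's
   grand mean equals the pooled grand mean; the pooled grand mean is unchanged
   and the operation is idempotent.
3. ``remove_outliers`` — iterative censoring: within each condition cell
   (unordered pair × judged cube), estimates more than 5, then 4, then 3.5
   sample SDs (n−1 denominator) from the cell mean across observers are
   removed, with re-normalisation of the survivors after every pass.

Removed records stay in the frame, flagged by the pass that removed them
(``outlier_pass``), and are excluded from every later statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import GRAMS_PER_UNIT

__all__ = [
    "DEFAULT_THRESHOLDS",
    "RemovalReport",
    "to_grams",
    "normalise",
    "remove_outliers",
    "preprocess",
    "retained",
]

DEFAULT_THRESHOLDS = (5.0, 4.0, 3.5)
MIN_CELL_OBSERVERS = 3


def retained(records: pd.DataFrame) -> pd.DataFrame:
    """Records not flagged as outliers."""
    if "outlier_pass" not in records.columns:
        return records
    return records[records["outlier_pass"].isna()]


def to_grams(
    records: pd.DataFrame, grams_per_unit: float = GRAMS_PER_UNIT
) -> pd.DataFrame:
    """Populate the ``grams`` column from ``raw_units``; order preserved."""
    if not grams_per_unit > 0:
        raise ValueError("grams_per_unit must be positive")
    raw = records["raw_units"].to_numpy(dtype=float)
    bad = ~np.isfinite(raw)
    if bad.any():
        raise ValueError(
            f"non-finite raw estimates at rows {list(records.index[bad])[:10]}"
        )
    out = records.copy()
    out["grams"] = raw * grams_per_unit
    if "outlier_pass" not in out.columns:
        out["outlier_pass"] = pd.array([pd.NA] * len(out), dtype="Int64")
    return out


def normalise(records: pd.DataFrame) -> pd.DataFrame:
    """Equalise participants' grand means at the pooled grand mean.

    Each participant's retained estimates are multiplied by
    pooled_mean / participant_mean, computed over retained records only but
    applied to all of that participant's rows.
    """
    out = records.copy()
    if "outlier_pass" not in out.columns:
        out["outlier_pass"] = pd.array([pd.NA] * len(out), dtype="Int64")
    keep = out["outlier_pass"].isna()
    src_col = "normalised" if "normalised" in out.columns else "grams"
    counts = out.loc[keep].groupby("participant_id").size()
    empty = set(out["participant_id"].unique()) - set(counts.index)
    if empty:
        raise ValueError(f"participants with zero retained records: {sorted(empty)}")
    pooled = float(out.loc[keep, src_col].mean())
    per_participant = out.loc[keep].groupby("participant_id")[src_col].mean()
    factors = pooled / per_participant
    out["normalised"] = out[src_col].to_numpy(dtype=float) * out[
        "participant_id"
    ].map(factors).to_numpy(dtype=float)
    return out


@dataclass
class RemovalReport:
    """Counts of records removed per censoring pass."""

    thresholds: tuple
    removed_per_pass: list = field(default_factory=list)
    skipped_cells: list = field(default_factory=list)
    n_records: int = 0

    @property
    def total_removed(self) -> int:
        return int(sum(self.removed_per_pass))

    @property
    def fraction_removed(self) -> float:
        return self.total_removed / self.n_records if self.n_records else 0.0

    def to_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "removed_per_pass": [int(x) for x in self.removed_per_pass],
            "total_removed": self.total_removed,
            "fraction_removed": self.fraction_removed,
            "n_records": int(self.n_records),
        }


def remove_outliers(
    records: pd.DataFrame, thresholds=DEFAULT_THRESHOLDS
) -> tuple[pd.DataFrame, RemovalReport]:
    """Iterative per-cell outlier censoring with re-normalisation.

    One pass per threshold, in the given order.  A cell is the unordered pair
    crossed with the judged cube; the mean and SD pool all retained estimates
    across observers, positions and repeats.  Cells with fewer than 3
    surviving observers are skipped for that pass (with a warning).
    """
    out = normalise(records)
    report = RemovalReport(thresholds=tuple(thresholds), n_records=len(out))
    for pass_no, thr in enumerate(thresholds, start=1):
        keep = out["outlier_pass"].isna()
        values = out.loc[keep, "normalised"]
        groups = out.loc[keep].groupby(["pair_id", "cube_id"], sort=False)
        n_obs = groups["participant_id"].nunique()
        mean = groups["normalised"].transform("mean")
        sd = groups["normalised"].transform(lambda v: v.std(ddof=1))
        cell_ok = out.loc[keep, ["pair_id", "cube_id"]].apply(tuple, axis=1).map(
            n_obs >= MIN_CELL_OBSERVERS
        )
        skipped = sorted(n_obs.index[n_obs < MIN_CELL_OBSERVERS])
        if skipped:
            warnings.warn(
                f"pass {pass_no}: skipping {len(skipped)} cells with fewer than "
                f"{MIN_CELL_OBSERVERS} observers",
                stacklevel=2,
            )
            report.skipped_cells.append((pass_no, skipped))
        flag = cell_ok & (np.abs(values - mean) > thr * sd) & (sd > 0)
        idx = values.index[flag.fillna(False)]
        out.loc[idx, "outlier_pass"] = pass_no
        report.removed_per_pass.append(len(idx))
        out = normalise(out)
    return out, report


def preprocess(
    records: pd.DataFrame,
    grams_per_unit: float = GRAMS_PER_UNIT,
    thresholds=DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, RemovalReport]:
    """Full pipeline: grams transform, normalisation, iterative censoring.

    Returns the augmented frame (all rows, removed ones flagged) and the
    removal report.  Use :func:`retained` to obtain analysis-ready records.
    """
    out = to_grams(records, grams_per_unit)
    out, report = remove_outliers(out, thresholds)
    return out, report
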