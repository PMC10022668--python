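"""Preprocessing of continuous rating streams.

Ratings are captured at roughly the screen refresh (about every 20 ms),
downsampled to 250-ms bins, and joined to the stimulus schedule so every
retained sample carries the current epoch's physical value of the rated
dimension, the concurrent value of the other dimension, and the preceding
epoch's value of the rated dimension — the three level-1 predictors of the
rating-accuracy models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import DuoscaleError, SchemaError
from .task_design import TaskSchedule, coded_value

log = logging.getLogger(__name__)

ALIGNED_COLUMNS = [
    "participant",
    "t_ms",
    "rating_dim",
    "rating",
    "current_value",
    "other_value",
    "previous_value",
    "scale_type",
    "set_id",
    "age_group",
]


def downsample(
    series: pd.DataFrame, bin_ms: int = 250, duration_ms: float | None = None
) -> pd.DataFrame:
    """Average a rating stream into contiguous fixed-width time bins.

    Every column except ``t_ms`` is averaged per bin; the output timestamp is
    the bin center.  The stream duration defaults to ``t_last - t_first + dt``
    with ``dt`` the median sampling interval (each sample covers one
    acquisition frame); the number of bins is ``floor(duration / bin_ms)``
    and any trailing partial bin is dropped.  Bins left empty by acquisition
    gaps carry the previous bin's value forward, with a logged count.
    """
    if "t_ms" not in series.columns:
        raise SchemaError("rating stream needs a t_ms column")
    t = series["t_ms"].to_numpy(dtype=float)
    if len(t) == 0:
        raise DuoscaleError("empty rating stream")
    if np.any(np.diff(t) < 0):
        raise DuoscaleError("rating stream must be sorted by t_ms")
    if duration_ms is None:
        if len(t) < 2:
            raise DuoscaleError("cannot infer duration from a single sample")
        dt = float(np.median(np.diff(t)))
        duration_ms = t[-1] - t[0] + dt
    n_bins = int(np.floor(duration_ms / bin_ms))
    if n_bins < 1:
        raise DuoscaleError("stream shorter than one bin")
    t0 = t[0]
    idx = ((t - t0) // bin_ms).astype(int)
    keep = idx < n_bins
    value_cols = [c for c in series.columns if c != "t_ms"]
    binned = (
        series.loc[keep, value_cols]
        .groupby(idx[keep])
        .mean()
        .reindex(range(n_bins))
    )
    n_empty = int(binned[value_cols[0]].isna().sum())
    if n_empty:
        log.warning("%d empty bins carried forward from previous value", n_empty)
        binned = binned.ffill()
    binned.insert(0, "t_ms", t0 + (np.arange(n_bins) + 0.5) * bin_ms)
    return binned.reset_index(drop=True)


def align(
    series: pd.DataFrame,
    schedule: TaskSchedule,
    rating_dim: str,
    metadata: dict | None = None,
    assignment: dict[str, str] | None = None,
    lag_ms: float = 0.0,
    exclude_transition_ms: float = 0.0,
) -> pd.DataFrame:
    """Join downsampled rating samples to their stimulus epochs.

    Epochs are half-open intervals ``[onset, onset + duration)``, so a sample
    exactly at a transition belongs to the later epoch.  ``previous_value``
    is the preceding epoch's value of the rated dimension and is NaN
    throughout the first epoch (models using it drop those rows).  Samples at
    or beyond the schedule end are dropped with a logged count, as are
    samples closer than ``exclude_transition_ms`` to an epoch transition
    (useful to discard bins that straddle a stimulus change; default keeps
    everything).  ``lag_ms`` shifts sample times backwards before the join to
    compensate a fixed response latency (default 0).

    For a 2D stream (columns x and y) ``assignment`` maps dimension names to
    axis columns; a 1D stream uses its single value column.
    """
    dims = schedule.dims
    if rating_dim not in dims:
        raise DuoscaleError(f"rating_dim {rating_dim!r} not in task dims {dims}")
    j = dims.index(rating_dim)
    other = 1 - j
    if "y" in series.columns:
        if assignment is None:
            raise DuoscaleError("2D rating stream requires an axis assignment")
        col = assignment[rating_dim]
    else:
        value_cols = [c for c in series.columns if c != "t_ms"]
        col = value_cols[0]

    t = series["t_ms"].to_numpy(dtype=float) - lag_ms
    onsets = schedule.onsets
    in_range = (t >= 0) & (t < schedule.total_duration)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        log.warning("%d samples outside the schedule were dropped", n_dropped)
    if exclude_transition_ms > 0 and len(onsets) > 1:
        dist = np.min(
            np.abs(t[:, None] - onsets[None, 1:]), axis=1
        )
        near = dist < exclude_transition_ms
        log.debug("%d samples within %.0f ms of a transition excluded",
                  int(near.sum()), exclude_transition_ms)
        in_range &= ~near

    t_kept = t[in_range]
    epoch_idx = np.searchsorted(onsets, t_kept, side="right") - 1
    raw1 = np.array([e.dim1_value for e in schedule.epochs])
    raw2 = np.array([e.dim2_value for e in schedule.epochs])
    coded = (
        np.asarray(coded_value(schedule.task, 0, raw1)),
        np.asarray(coded_value(schedule.task, 1, raw2)),
    )
    current = coded[j][epoch_idx]
    other_v = coded[other][epoch_idx]
    prev_all = np.concatenate([[np.nan], coded[j][:-1]])
    previous = prev_all[epoch_idx]

    meta = metadata or {}
    out = pd.DataFrame(
        {
            "participant": meta.get("participant", 0),
            "t_ms": series["t_ms"].to_numpy(dtype=float)[in_range],
            "rating_dim": rating_dim,
            "rating": series[col].to_numpy(dtype=float)[in_range],
            "current_value": current,
            "other_value": other_v,
            "previous_value": previous,
            "scale_type": meta.get("scale_type", "2D"),
            "set_id": meta.get("set_id", schedule.set_id),
            "age_group": meta.get("age_group", "younger"),
        }
    )
    return out[ALIGNED_COLUMNS]


def write_ratings_tsv(series: pd.DataFrame, path) -> None:
    series.to_csv(path, sep="\t", index=False)


def read_ratings_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "t_ms" not in df.columns:
        raise SchemaError("rating TSV needs a t_ms column")
    return df


def write_aligned_tsv(records: pd.DataFrame, path) -> None:
    records[ALIGNED_COLUMNS].to_csv(path, sep="\t", index=False)


def read_aligned_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in ALIGNED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"aligned TSV missing columns: {missing}")
    return df
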