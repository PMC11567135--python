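"""Accelerometer count processing.

Triaxial activity counts recorded in short (default 10 s) epochs are
cropped to the measurement window, re-integrated to one-minute epochs,
screened for non-wear, and classified by per-minute vector magnitude
(VM = sqrt(a1^2 + a2^2 + a3^2)) into sedentary+nonwear (< 200
counts/min), light ([200, 2690)) and moderate-to-vigorous physical
activity (MVPA, >= 2690).  Daily totals and participant means follow.

A stream is a DataFrame with a monotone, equally spaced DatetimeIndex
and columns ``axis1, axis2, axis3, steps``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import DEFAULT_CUTPOINTS, DEFAULT_WEAR, CutPoints, WearParams

__all__ = [
    "STREAM_COLUMNS",
    "epoch_seconds",
    "crop_to_window",
    "reintegrate",
    "vector_magnitude",
    "mark_wear",
    "classify_minutes",
    "summarize_days",
    "participant_means",
]

STREAM_COLUMNS = ["axis1", "axis2", "axis3", "steps"]

CLASSES = ("sedentary_nonwear", "light", "mvpa")


def epoch_seconds(stream: pd.DataFrame) -> float:
    """Epoch length inferred from the (equally spaced) index."""
    if len(stream) < 2:
        raise ValueError("need at least two epochs to infer the epoch length")
    diffs = np.diff(stream.index.view("int64")) / 1e9
    if not np.allclose(diffs, diffs[0]):
        raise ValueError("stream epochs are not equally spaced")
    if diffs[0] <= 0:
        raise ValueError("stream timestamps must be strictly increasing")
    return float(diffs[0])


def crop_to_window(stream: pd.DataFrame, start, end) -> pd.DataFrame:
    """Retain epochs with start <= t < end (half-open window)."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if not start < end:
        raise ValueError(f"start must precede end, got {start} .. {end}")
    out = stream[(stream.index >= start) & (stream.index < end)]
    if out.empty:
        warnings.warn("cropping window contains no epochs", stacklevel=2)
    return out


def reintegrate(stream: pd.DataFrame, target_epoch_s: int = 60) -> pd.DataFrame:
    """Sum counts and steps into non-overlapping *target_epoch_s* windows.

    The target must be an integer multiple of the source epoch; windows
    are aligned to clock boundaries (floor of the target period), so
    reintegrating 10 s epochs to 60 s yields calendar minutes.
    """
    src = epoch_seconds(stream)
    ratio = target_epoch_s / src
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"target epoch ({target_epoch_s} s) must be an integer multiple "
            f"of the source epoch ({src:g} s)"
        )
    return stream[STREAM_COLUMNS].resample(f"{int(target_epoch_s)}s").sum()


def vector_magnitude(stream: pd.DataFrame) -> pd.Series:
    """Euclidean norm of the three axes, per epoch."""
    a = stream[["axis1", "axis2", "axis3"]].to_numpy(dtype=float)
    return pd.Series(np.sqrt((a**2).sum(axis=1)), index=stream.index, name="vm")


def _runs(mask: np.ndarray):
    """Yield (start, stop, value) runs of a boolean array."""
    if len(mask) == 0:
        return
    edges = np.flatnonzero(np.diff(mask)) + 1
    bounds = np.concatenate([[0], edges, [len(mask)]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        yield int(lo), int(hi), bool(mask[lo])


def mark_wear(minute_stream: pd.DataFrame, params: WearParams = DEFAULT_WEAR) -> pd.Series:
    """Boolean wear flag per minute (True = worn).

    Zero-VM runs are candidate non-wear; interruptions of at most
    ``spike_tolerance_min`` consecutive active minutes bridge adjacent
    zero runs.  A bridged block spanning at least ``window_min``
    minutes is flagged non-wear, spike minutes included.
    """
    if round(epoch_seconds(minute_stream)) != 60:
        raise ValueError("mark_wear expects 60 s epochs; reintegrate first")
    vm = vector_magnitude(minute_stream).to_numpy()
    zero = vm == 0
    n = len(zero)
    # absorb short active spikes between zero runs
    bridged = zero.copy()
    for lo, hi, val in _runs(zero):
        if not val and hi - lo <= params.spike_tolerance_min and lo > 0 and hi < n:
            bridged[lo:hi] = True
    nonwear = np.zeros(n, dtype=bool)
    for lo, hi, val in _runs(bridged):
        if val and hi - lo >= params.window_min:
            nonwear[lo:hi] = True
    return pd.Series(~nonwear, index=minute_stream.index, name="wear")


def classify_minutes(
    minute_stream: pd.DataFrame, cut: CutPoints = DEFAULT_CUTPOINTS
) -> pd.Series:
    """Intensity class per minute from vector magnitude.

    The classes tile every VM value: [0, 200) sedentary+nonwear,
    [200, 2690) light, [2690, inf) MVPA.
    """
    if round(epoch_seconds(minute_stream)) != 60:
        raise ValueError("classify_minutes expects 60 s epochs; reintegrate first")
    vm = vector_magnitude(minute_stream)
    cls = np.where(
        vm >= cut.mvpa_lo, "mvpa", np.where(vm >= cut.light_lo, "light", "sedentary_nonwear")
    )
    return pd.Series(pd.Categorical(cls, categories=list(CLASSES)),
                     index=minute_stream.index, name="activity_class")


def summarize_days(
    minute_stream: pd.DataFrame,
    cut: CutPoints = DEFAULT_CUTPOINTS,
    wear: WearParams = DEFAULT_WEAR,
) -> pd.DataFrame:
    """Per-calendar-day steps, class minutes and worn minutes.

    Non-wear necessarily falls in the sedentary+nonwear class (VM = 0);
    wear flags are reported alongside and do not null activity classes.
    """
    cls = classify_minutes(minute_stream, cut)
    worn = mark_wear(minute_stream, wear)
    df = pd.DataFrame(
        {
            "steps": minute_stream["steps"],
            "sed_nonwear": (cls == "sedentary_nonwear").astype(int),
            "light": (cls == "light").astype(int),
            "mvpa": (cls == "mvpa").astype(int),
            "worn": worn.astype(int),
        }
    )
    day = df.groupby(df.index.date).sum()
    day.index = pd.Index(day.index, name="date")
    day = day.rename(
        columns={
            "sed_nonwear": "sed_nonwear_min",
            "light": "light_min",
            "mvpa": "mvpa_min",
            "worn": "worn_min",
        }
    )
    if (day["worn_min"] == 0).all():
        warnings.warn("no wear time detected on any day", stacklevel=2)
        return day.iloc[0:0]
    return day


def participant_means(day_summary: pd.DataFrame) -> pd.Series:
    """Mean daily values over days with any wear."""
    worn = day_summary[day_summary["worn_min"] > 0]
    if worn.empty:
        warnings.warn("no days with wear; empty participant summary", stacklevel=2)
        return pd.Series(dtype=float)
    return worn.mean()
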