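"""Beat-series containers and pre-conditioning of NN-interval data.

The raw object of HRV analysis is the sequence of normal-to-normal
intervals (NNIs): the times between consecutive normal heartbeats, in
milliseconds. This module holds the two carriers used throughout the
package — :class:`BeatSeries` (beat timestamps plus the intervals they
imply) and :class:`UniformTachogram` (the NNI signal resampled onto a
uniform grid so that filtering and spectral estimation are well
defined) — together with the pre-conditioning steps: sharp-peak removal
and cubic-spline resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "BeatSeries",
    "UniformTachogram",
    "intervals_from_beats",
    "beats_from_intervals",
    "remove_sharp_peaks",
    "resample_uniform",
]

#: Upper edge of the HF band; the resampling Nyquist must exceed it.
_HF_UPPER_HZ = 0.4
#: Lower edge of the LF band; sets the minimum useful recording span.
_LF_LOWER_HZ = 0.04


@dataclass(frozen=True)
class BeatSeries:
    """Beat timestamps (s) and the NN intervals (ms) between them.

    Invariants: ``beat_times`` strictly increasing, ``intervals[k] ==
    (beat_times[k+1] - beat_times[k]) * 1000`` and every interval
    positive. Construct through :func:`intervals_from_beats` or
    :func:`beats_from_intervals` rather than directly.
    """

    beat_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", iv)
        if bt.ndim != 1 or iv.ndim != 1 or len(iv) != len(bt) - 1:
            raise ValueError("need len(intervals) == len(beat_times) - 1")
        if np.any(np.diff(bt) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(iv <= 0):
            raise ValueError("all NN intervals must be positive")
        if not np.allclose(iv, np.diff(bt) * 1000.0, atol=1e-6):
            raise ValueError("intervals inconsistent with beat times")

    @property
    def midpoints(self) -> np.ndarray:
        """Time coordinate of each interval: midpoint of its two beats."""
        return 0.5 * (self.beat_times[:-1] + self.beat_times[1:])

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])

    def __len__(self) -> int:
        return len(self.beat_times)


def intervals_from_beats(beat_times: np.ndarray) -> BeatSeries:
    """Derive NN intervals from ≥ 2 strictly increasing beat timestamps."""
    bt = np.asarray(beat_times, dtype=float)
    if bt.ndim != 1 or len(bt) < 2:
        raise ValueError("need at least 2 beat timestamps")
    if np.any(np.diff(bt) <= 0):
        raise ValueError("beat times must be strictly increasing")
    return BeatSeries(beat_times=bt, intervals=np.diff(bt) * 1000.0)


def beats_from_intervals(intervals_ms: np.ndarray, t0: float = 0.0) -> BeatSeries:
    """Accumulate beat times from intervals, first beat at ``t0`` seconds."""
    iv = np.asarray(intervals_ms, dtype=float)
    if iv.ndim != 1 or len(iv) == 0:
        raise ValueError("need at least one interval")
    if np.any(iv <= 0):
        raise ValueError("all NN intervals must be positive")
    bt = t0 + np.concatenate(([0.0], np.cumsum(iv) / 1000.0))
    return BeatSeries(beat_times=bt, intervals=iv)


@dataclass(frozen=True)
class UniformTachogram:
    """NNI signal on a uniform time grid: ``values[k]`` at ``t0 + k/fs``."""

    fs: float
    t0: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 2 * _HF_UPPER_HZ:
            raise ValueError("fs must exceed twice the 0.4 Hz HF edge")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tachogram values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) / self.fs

    def slice(self, t_start: float, t_end: float) -> np.ndarray:
        """Values in the half-open window [t_start, t_end)."""
        eps = 1e-9
        k0 = int(np.ceil((t_start - self.t0) * self.fs - eps))
        k1 = int(np.ceil((t_end - self.t0) * self.fs - eps))
        return self.values[max(k0, 0) : max(k1, 0)]

    def __len__(self) -> int:
        return len(self.values)


def remove_sharp_peaks(
    series: BeatSeries,
    rel_threshold: float = 0.3,
    context: int = 11,
) -> tuple[BeatSeries, int]:
    """Replace sharp NNI peaks by interpolation between their neighbors.

    An interval counts as a sharp peak when it deviates from the running
    median of its ``context``-interval neighborhood by more than
    ``rel_threshold`` times that median. Flagged intervals are replaced
    by linear interpolation between the nearest surviving intervals and
    the beat times are re-accumulated from the first beat, which keeps
    the time axis needed by the sliding windows.

    Returns the cleaned series and the number of replaced intervals.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must lie in (0, 1)")
    if context < 3 or context % 2 == 0:
        raise ValueError("context must be odd and >= 3")
    iv = series.intervals
    med = (
        pd.Series(iv)
        .rolling(context, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    flagged = np.abs(iv - med) > rel_threshold * med
    n_replaced = int(flagged.sum())
    if n_replaced == 0:
        return series, 0
    if flagged.all():
        raise ValueError("every interval flagged as a peak; nothing to interpolate from")
    idx = np.arange(len(iv), dtype=float)
    cleaned = iv.copy()
    cleaned[flagged] = np.interp(idx[flagged], idx[~flagged], iv[~flagged])
    return beats_from_intervals(cleaned, t0=series.beat_times[0]), n_replaced


def resample_uniform(series: BeatSeries, fs: float = 4.0) -> UniformTachogram:
    """Resample NN intervals onto a uniform grid by cubic spline.

    The intervals are interpolated against their midpoint times and
    evaluated on a grid at ``fs`` covering [first midpoint, last
    midpoint]. 4 Hz puts the Nyquist frequency at 2 Hz, comfortably
    above the 0.4 Hz upper edge of the HF band.
    """
    if len(series.beat_times) < 4:
        raise ValueError("need at least 4 beats to resample")
    t_mid = series.midpoints
    span = t_mid[-1] - t_mid[0]
    if span < 2.0 / _LF_LOWER_HZ:
        warnings.warn(
            f"recording spans only {span:.0f} s; LF content below "
            f"{_LF_LOWER_HZ} Hz is poorly determined",
            stacklevel=2,
        )
    spline = CubicSpline(t_mid, series.intervals)
    n = int(np.floor(span * fs + 1e-9)) + 1
    grid = t_mid[0] + np.arange(n) / fs
    return UniformTachogram(fs=fs, t0=float(t_mid[0]), values=spline(grid))
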