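"""Windowed LF/HF band powers, normalization, and the 1-D metric family.

HRV frequency-domain analysis splits the spectrum of the NNI signal
into the low-frequency band LF = [0.04, 0.15) Hz (conventionally linked
to sympathetic activity) and the high-frequency band HF = [0.15, 0.4]
Hz (parasympathetic, respiratory). This module computes the band powers
LFp and HFp over sliding windows, the normalized powers LFn = LFp / (LFp
+ HFp) and HFn = 1 - LFn, the classical LF/HF ratio, and the wider
family of one-dimensional "stress metrics"

    P1 = LFp / HFp
    P2 = b1 * LFp**2 / HFp + b2
    P3 = c1 * LFp - c2 * HFp + c3
    P4 = d1 * LFp**2 - d2 * HFp + d3
    P5 = e1 * LFp / HFp**2 + e2

which all increase with LFp and decrease with HFp yet disagree with one
another along any fixed-ratio locus — the ambiguity that motivates
analyzing LF and HF jointly in a 2-D scatter rather than through any
single such number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .preprocess import UniformTachogram

__all__ = [
    "FrequencyBand",
    "LF_BAND",
    "HF_BAND",
    "MetricConstants",
    "WindowGrid",
    "sliding_windows",
    "validate_window_length",
    "band_power",
    "normalize_powers",
    "metric_family",
    "window_features",
    "FEATURE_COLUMNS",
]


@dataclass(frozen=True)
class FrequencyBand:
    """Half-open frequency band [lo, hi) in Hz."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError("need 0 < lo < hi")


LF_BAND = FrequencyBand(0.04, 0.15, "LF")
HF_BAND = FrequencyBand(0.15, 0.4, "HF")


@dataclass(frozen=True)
class MetricConstants:
    """User-defined constants of the metric family P2–P5.

    Multiplicative constants must be positive so every metric increases
    in LFp and decreases in HFp; additive offsets default to zero.
    """

    b1: float = 1.0
    b2: float = 0.0
    c1: float = 1.0
    c2: float = 1.0
    c3: float = 0.0
    d1: float = 1.0
    d2: float = 1.0
    d3: float = 0.0
    e1: float = 1.0
    e2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("b1", "c1", "c2", "d1", "d2", "e1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class WindowGrid:
    """Sliding half-open windows [start, end) in seconds."""

    window_length: float
    step: float
    windows: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def centers(self) -> np.ndarray:
        return np.array([0.5 * (a + b) for a, b in self.windows])


def sliding_windows(
    t_start: float,
    t_end: float,
    length: float = 300.0,
    step: float = 10.0,
) -> WindowGrid:
    """Sliding windows [t_start + k*step, ... + length) with end <= t_end."""
    if step <= 0 or length <= 0:
        raise ValueError("length and step must be positive")
    if t_end - t_start < length:
        raise ValueError(
            f"span {t_end - t_start:.1f} s shorter than window length {length:.1f} s"
        )
    n = int(np.floor((t_end - t_start - length) / step + 1e-9)) + 1
    windows = tuple(
        (t_start + k * step, t_start + k * step + length) for k in range(n)
    )
    return WindowGrid(window_length=length, step=step, windows=windows)


def validate_window_length(
    length: float, f_lo: float, heart_rate: float
) -> tuple[int, float, float]:
    """Window-validity arithmetic for spectral HRV estimates.

    Returns ``(cycles, min_period, nyquist)``: the number of full cycles
    of the lowest analyzed frequency inside the window, the longest
    reliably estimable oscillation period under the ten-cycle rule of
    thumb (``length / 10`` seconds), and the effective Nyquist frequency
    set by the beat rate (half the heart rate, in Hz).
    """
    if min(length, f_lo, heart_rate) <= 0:
        raise ValueError("all inputs must be positive")
    cycles = int(np.floor(length * f_lo + 1e-9))
    min_period = length / 10.0
    nyquist = heart_rate / 120.0
    return cycles, min_period, nyquist


def band_power(
    tachogram: UniformTachogram,
    band: FrequencyBand,
    segment_length_s: float = 100.0,
) -> float:
    """Signal power of the tachogram inside ``band``, in ms².

    Welch periodogram (Hann taper, 50% overlap, per-segment mean
    removal) integrated over [band.lo, band.hi) by the trapezoid rule.
    The 100 s default segment keeps at least 4 LF cycles per segment.
    A pure tone of amplitude ``a`` inside the band yields ``a**2 / 2``.
    """
    x = tachogram.values
    if len(x) == 0:
        raise ValueError("empty signal")
    n_cycles = len(x) / tachogram.fs * band.lo
    if n_cycles < 10:
        warnings.warn(
            f"only {n_cycles:.1f} cycles of {band.lo} Hz in the signal; "
            "band power is poorly determined",
            stacklevel=2,
        )
    nperseg = min(len(x), int(round(segment_length_s * tachogram.fs)))
    freqs, psd = welch(
        x,
        fs=tachogram.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )
    mask = (freqs >= band.lo) & (freqs < band.hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def normalize_powers(LFp: float, HFp: float) -> tuple[float, float]:
    """Normalized band powers (LFn, HFn) with LFn + HFn = 1 exactly.

    Total power is operationalized as LFp + HFp, so the pair carries a
    single degree of freedom: HFn = 1 - LFn always. Both powers zero is
    flagged as undefined (ValueError) rather than propagating NaN.
    """
    if LFp < 0 or HFp < 0:
        raise ValueError("band powers must be nonnegative")
    tp = LFp + HFp
    if tp == 0:
        raise ValueError("normalized powers undefined: LFp + HFp = 0")
    lfn = LFp / tp
    return lfn, 1.0 - lfn


def metric_family(
    LFp,
    HFp,
    which: str = "P1",
    consts: MetricConstants = MetricConstants(),
):
    """Evaluate one of the 1-D stress metrics P1–P5 (vectorized).

    Zero denominators (HFp = 0 for P1, P2, P5) are flagged by returning
    NaN for the affected entries.
    """
    lf = np.asarray(LFp, dtype=float)
    hf = np.asarray(HFp, dtype=float)
    c = consts
    with np.errstate(divide="ignore", invalid="ignore"):
        if which == "P1":
            out = np.where(hf != 0, lf / hf, np.nan)
        elif which == "P2":
            out = np.where(hf != 0, c.b1 * lf**2 / hf + c.b2, np.nan)
        elif which == "P3":
            out = c.c1 * lf - c.c2 * hf + c.c3
        elif which == "P4":
            out = c.d1 * lf**2 - c.d2 * hf + c.d3
        elif which == "P5":
            out = np.where(hf != 0, c.e1 * lf / hf**2 + c.e2, np.nan)
        else:
            raise ValueError("which must be one of P1..P5")
    if np.ndim(LFp) == 0 and np.ndim(HFp) == 0:
        return float(out)
    return out


FEATURE_COLUMNS = [
    "t_center_s",
    "LFp_ms2",
    "HFp_ms2",
    "TP_ms2",
    "LFn",
    "HFn",
    "ratio_p",
    "LFiA_ms",
    "HFiA_ms",
    "ratio_iA",
    "label",
]


def _window_label(start: float, end: float, labels: pd.DataFrame | None):
    """Label of the segment fully containing [start, end), else None."""
    if labels is None:
        return None
    eps = 1e-9
    for row in labels.itertuples(index=False):
        if row.start_s - eps <= start and end <= row.end_s + eps:
            return row.label
    return None


def window_features(
    tachogram: UniformTachogram,
    grid: WindowGrid,
    iA_lf=None,
    iA_hf=None,
    labels: pd.DataFrame | None = None,
    trim: float = 0.2,
    trim_mode: str = "per_tail",
    lf_band: FrequencyBand = LF_BAND,
    hf_band: FrequencyBand = HF_BAND,
) -> pd.DataFrame:
    """Per-window feature table: band powers, normalized powers, iA means.

    ``iA_lf`` / ``iA_hf`` are the LF and HF :class:`~hrv2d.envelope.BandEnvelope`
    objects computed on the same tachogram (may be None, leaving the iA
    columns NaN). When a segment table is supplied, only windows fully
    inside a labeled segment are emitted — a window straddling a
    boundary has no ground-truth state. Without labels every window is
    emitted with ``label = None``.
    """
    from .envelope import trimmed_mean  # local import to avoid a cycle

    rows = []
    for start, end in grid.windows:
        if labels is not None:
            label = _window_label(start, end, labels)
            if label is None:
                continue
        else:
            label = None
        x = tachogram.slice(start, end)
        if len(x) == 0:
            continue
        win = UniformTachogram(fs=tachogram.fs, t0=start, values=x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lfp = band_power(win, lf_band)
            hfp = band_power(win, hf_band)
        tp = lfp + hfp
        if tp > 0:
            lfn, hfn = normalize_powers(lfp, hfp)
        else:
            lfn = hfn = np.nan
        ratio_p = lfp / hfp if hfp > 0 else np.nan
        lfia = hfia = ratio_ia = np.nan
        if iA_lf is not None:
            lfia = trimmed_mean(iA_lf.slice(start, end), trim, mode=trim_mode)
        if iA_hf is not None:
            hfia = trimmed_mean(iA_hf.slice(start, end), trim, mode=trim_mode)
            if iA_lf is not None and hfia > 0:
                ratio_ia = lfia / hfia
        rows.append(
            {
                "t_center_s": 0.5 * (start + end),
                "LFp_ms2": lfp,
                "HFp_ms2": hfp,
                "TP_ms2": tp,
                "LFn": lfn,
                "HFn": hfn,
                "ratio_p": ratio_p,
                "LFiA_ms": lfia,
                "HFiA_ms": hfia,
                "ratio_iA": ratio_ia,
                "label": label,
            }
        )
    if not rows:
        raise ValueError("no window fits inside the labeled segments")
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
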