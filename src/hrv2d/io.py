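"""File formats and the end-to-end pipeline.

Interchange formats are deliberately minimal and text-only:

* RR text — one NN interval in milliseconds per line, ``'\\n'``
  terminated, ``'.'`` decimal separator; beat times are accumulated
  with the first beat at t = 0.
* Beat CSV — header ``time_s,nni_ms``; ``time_s`` is the timestamp of
  the beat that ends the interval on the same row, taken verbatim.
* Segment CSV — header ``label,start_s,end_s``; segments must be
  non-overlapping and increasing, gaps (unlabeled time) are allowed.
* Feature CSV — the per-window feature table of
  :func:`hrv2d.features.window_features`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .categorize import (
    CategorizationReport,
    LabeledFeatureSet,
    apply_buffers,
    categorization_accuracy,
    decision_map,
    fit_categorizer_1d,
    fit_categorizer_2d,
    per_subject_scenario_means,
    standardize_by_baseline,
    wilcoxon_scenarios,
)
from .config import RunConfig
from .envelope import bandpass_filter, hilbert_envelope
from .features import HF_BAND, LF_BAND, sliding_windows, window_features
from .preprocess import (
    BeatSeries,
    beats_from_intervals,
    intervals_from_beats,
    remove_sharp_peaks,
    resample_uniform,
)

logger = logging.getLogger("hrv2d")

__all__ = [
    "read_rr",
    "write_rr",
    "read_labels",
    "write_labels",
    "read_features",
    "write_features",
    "run_pipeline",
]


def read_rr(path) -> BeatSeries:
    """Read a beat series from RR text or two-column beat CSV."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    first = text.lstrip().splitlines()[0]
    if "," in first:
        return _read_beat_csv(path)
    intervals = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            value = float(line)
        except ValueError:
            raise ValueError(f"{path}: non-numeric value {line!r} on line {lineno}") from None
        if value <= 0:
            raise ValueError(f"{path}: non-positive interval on line {lineno}")
        intervals.append(value)
    if not intervals:
        raise ValueError(f"{path}: no intervals found")
    return beats_from_intervals(np.asarray(intervals), t0=0.0)


def _read_beat_csv(path: Path) -> BeatSeries:
    df = pd.read_csv(path)
    expected = ["time_s", "nni_ms"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}")
    times = df["time_s"].to_numpy(float)
    nni = df["nni_ms"].to_numpy(float)
    if len(times) < 1:
        raise ValueError(f"{path}: no rows")
    if np.any(nni <= 0):
        bad = int(np.flatnonzero(nni <= 0)[0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: non-positive interval on line {bad}")
    # time_s stamps the beat ending each interval; prepend the opening beat
    beat_times = np.concatenate(([times[0] - nni[0] / 1000.0], times))
    return intervals_from_beats(beat_times)


def write_rr(series: BeatSeries, path) -> None:
    """Write intervals as RR text (one ms value per line)."""
    lines = "".join(f"{v:.6g}\n" for v in series.intervals)
    Path(path).write_text(lines, encoding="utf-8")


def write_beat_csv(series: BeatSeries, path) -> None:
    """Write a beat CSV (`time_s,nni_ms`): one row per interval."""
    df = pd.DataFrame(
        {"time_s": series.beat_times[1:], "nni_ms": series.intervals}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_labels(path) -> pd.DataFrame:
    """Read and validate a segment table (`label,start_s,end_s`)."""
    path = Path(path)
    if not path.read_text(encoding="utf-8").strip():
        raise ValueError(f"{path}: empty file")
    df = pd.read_csv(path)
    expected = ["label", "start_s", "end_s"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no segments")
    starts = df["start_s"].to_numpy(float)
    ends = df["end_s"].to_numpy(float)
    if np.any(ends <= starts):
        raise ValueError(f"{path}: segment with end_s <= start_s")
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError(f"{path}: overlapping or out-of-order segments")
    return df


def write_labels(segments: pd.DataFrame, path) -> None:
    segments.to_csv(path, index=False, float_format="%.10g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False, float_format="%.10g")


def extract_features(
    beats: BeatSeries,
    segments: pd.DataFrame | None,
    config: RunConfig = RunConfig(),
    clean: bool = True,
) -> pd.DataFrame:
    """Beat series -> per-window feature table (powers + envelopes)."""
    if clean:
        beats, n_replaced = remove_sharp_peaks(
            beats, config.peak_threshold, config.peak_context
        )
        logger.info("sharp-peak removal replaced %d intervals", n_replaced)
    tach = resample_uniform(beats, fs=config.resample_fs)
    env_lf = hilbert_envelope(bandpass_filter(tach, LF_BAND), LF_BAND)
    env_hf = hilbert_envelope(bandpass_filter(tach, HF_BAND), HF_BAND)
    grid = sliding_windows(
        tach.t0, tach.t0 + tach.duration, config.window_length, config.step
    )
    labels = apply_buffers(segments, config.buffer) if segments is not None else None
    return window_features(
        tach, grid, env_lf, env_hf, labels,
        trim=config.trim, trim_mode=config.trim_mode,
    )


def run_pipeline(
    config: RunConfig,
    rr_path=None,
    labels_path=None,
    beats: BeatSeries | None = None,
    segments: pd.DataFrame | None = None,
    feature_pair: tuple[str, str] = ("LFiA_ms", "HFiA_ms"),
    restrict_labels=None,
    baseline_label: str | None = None,
    out_dir=None,
) -> tuple[pd.DataFrame, CategorizationReport]:
    """Full analysis: read, clean, featurize, categorize, report.

    Inputs may be paths or in-memory objects. The report holds the 2-D
    categorization accuracy for ``feature_pair``, the 1-D accuracies of
    each single feature, pairwise scenario rank-sum p-values, and a
    decision-region raster for plotting. Deterministic for fixed inputs
    and config.
    """
    config.log()
    if beats is None:
        if rr_path is None:
            raise ValueError("need rr_path or beats")
        beats = read_rr(rr_path)
    if segments is None and labels_path is not None:
        segments = read_labels(labels_path)

    features = extract_features(beats, segments, config)

    report = None
    if segments is not None:
        fset = LabeledFeatureSet(features, feature_pair)
        if restrict_labels is not None:
            fset = fset.restrict(restrict_labels)
        if baseline_label is not None:
            fset = standardize_by_baseline(fset, baseline_label)
        model = fit_categorizer_2d(fset, config.svm_degree, config.svm_c)
        ca = categorization_accuracy(model, fset)
        pred = model.predict(fset.X)
        confusion = pd.crosstab(
            pd.Series(fset.y, name="true"), pd.Series(pred, name="predicted")
        )
        ca_1d = {}
        for which in feature_pair:
            m1 = fit_categorizer_1d(fset, which, config.svm_degree, config.svm_c)
            ca_1d[which] = categorization_accuracy(m1, fset)
        p_values = {}
        labels = fset.labels
        for col in feature_pair:
            means = per_subject_scenario_means(fset, col)
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    va = means[means["label"] == a][col].to_numpy()
                    vb = means[means["label"] == b][col].to_numpy()
                    if len(va) and len(vb):
                        p_values[(col, a, b)] = wilcoxon_scenarios(va, vb)
        X = fset.X
        pad_x = 0.1 * (np.ptp(X[:, 0]) or 1.0)
        pad_y = 0.1 * (np.ptp(X[:, 1]) or 1.0)
        bounds = (
            X[:, 0].min() - pad_x, X[:, 0].max() + pad_x,
            X[:, 1].min() - pad_y, X[:, 1].max() + pad_y,
        )
        raster, xg, yg = decision_map(model, bounds, 150)
        report = CategorizationReport(
            ca=ca, confusion=confusion, feature_pair=feature_pair,
            ca_1d=ca_1d, p_values=p_values, raster=raster,
            raster_extent=bounds,
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_features(features, out_dir / "features.csv")
        if report is not None:
            (out_dir / "report.txt").write_text(report.summary() + "\n", encoding="utf-8")
    return features, report
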