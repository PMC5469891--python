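"""Stress-state categorization in the 2-D LF-HF plane.

A window of an HRV recording is summarized by a pair of band features —
(LFiA, HFiA), (LFp, HFp) or their normalized counterparts — and the
scenario labels of a protocol supply ground truth. A support vector
machine with a polynomial kernel partitions the feature plane into
decision regions; categorization accuracy (CA) is the percentage of
windows assigned to their true scenario. One-dimensional metrics are
categorized through the same machinery by pinning the second input to a
constant, which makes 1-D and 2-D accuracies directly comparable: the
2-D categorizer can always fall back on axis-parallel (or diagonal)
boundaries, so adding the second feature cannot hurt on the training
data.

Baseline standardization subtracts, per subject and feature, the median
over that subject's first resting period, which moves every subject's
resting state to the origin and makes subjects comparable. Scenario
contrasts are assessed by two-sided Wilcoxon rank-sum tests on one
average value per subject and scenario (exact null distribution for
small groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LabeledFeatureSet",
    "TrainedCategorizer",
    "CategorizationReport",
    "apply_buffers",
    "standardize_by_baseline",
    "fit_categorizer_2d",
    "fit_categorizer_1d",
    "categorization_accuracy",
    "wilcoxon_scenarios",
    "decision_map",
    "per_subject_scenario_means",
]


@dataclass
class LabeledFeatureSet:
    """Labeled window features for one feature pair.

    ``frame`` must contain the two feature columns named by
    ``feature_pair``, a ``label`` column, and (optionally) a
    ``subject`` column; rows with missing labels or non-finite features
    are rejected.
    """

    frame: pd.DataFrame
    feature_pair: tuple[str, str] = ("LFiA_ms", "HFiA_ms")
    subject_column: str = "subject"

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if self.subject_column not in df.columns:
            df[self.subject_column] = "subject-0"
        for col in (*self.feature_pair, "label"):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        df = df[df["label"].notna()]
        if not np.isfinite(df[list(self.feature_pair)].to_numpy(float)).all():
            raise ValueError("features must be finite")
        self.frame = df.reset_index(drop=True)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_pair)].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def labels(self) -> list:
        return sorted(pd.unique(self.frame["label"]))

    def restrict(self, labels) -> "LabeledFeatureSet":
        """Subset to the given scenario labels."""
        keep = self.frame["label"].isin(list(labels))
        return LabeledFeatureSet(
            self.frame[keep], self.feature_pair, self.subject_column
        )


@dataclass
class TrainedCategorizer:
    """A fitted polynomial-kernel SVM over the (scaled) feature plane.

    For 1-D fits the second coordinate is replaced by a constant (0
    after scaling) before training and prediction, so predictions do
    not depend on the second feature at all.
    """

    scaler: StandardScaler
    svc: SVC
    feature_pair: tuple[str, str]
    degree: int
    C: float
    mode: str = "2d"  # "2d", or "x"/"y" for 1-D on that coordinate

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = self.scaler.transform(X)
        if self.mode == "x":
            Z[:, 1] = 0.0
        elif self.mode == "y":
            Z[:, 0] = 0.0
        return Z

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self._transform(X))

    @property
    def classes_(self) -> np.ndarray:
        return self.svc.classes_


@dataclass
class CategorizationReport:
    """Accuracy, confusion counts, decision raster and scenario p-values."""

    ca: float
    confusion: pd.DataFrame
    feature_pair: tuple[str, str]
    ca_1d: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    raster: np.ndarray | None = None
    raster_extent: tuple | None = None

    def summary(self) -> str:
        lines = [f"2D CA({self.feature_pair[0]}, {self.feature_pair[1]}) = {self.ca:.1f}%"]
        for name, ca in self.ca_1d.items():
            lines.append(f"1D CA({name}) = {ca:.1f}%")
        for key, p in self.p_values.items():
            lines.append(f"Wilcoxon {' / '.join(map(str, key))}: p = {p:.4g}")
        return "\n".join(lines)


def apply_buffers(segments: pd.DataFrame, buffer: float) -> pd.DataFrame:
    """Shrink each labeled segment by ``buffer`` seconds at both ends.

    Removes residuals from adjacent activities before windows are
    labeled. Segments that would vanish are dropped.
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    out = segments.copy()
    out["start_s"] = out["start_s"] + buffer
    out["end_s"] = out["end_s"] - buffer
    return out[out["end_s"] > out["start_s"]].reset_index(drop=True)


def standardize_by_baseline(
    features: LabeledFeatureSet, baseline_label: str
) -> LabeledFeatureSet:
    """Subtract each subject's baseline-scenario median, per feature.

    After the transform the baseline median of every subject sits at the
    origin; applying the transform twice is the identity after the
    first application (the new baseline medians are zero).
    """
    df = features.frame.copy()
    subj_col = features.subject_column
    if not (df["label"] == baseline_label).any():
        raise ValueError(f"baseline label {baseline_label!r} not present")
    for subject, group in df.groupby(subj_col):
        base = group[group["label"] == baseline_label]
        if base.empty:
            raise ValueError(
                f"subject {subject!r} has no {baseline_label!r} baseline rows"
            )
        for col in features.feature_pair:
            df.loc[group.index, col] = group[col] - base[col].median()
    return LabeledFeatureSet(df, features.feature_pair, subj_col)


def _check_fittable(features: LabeledFeatureSet) -> None:
    counts = features.frame["label"].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 distinct labels to fit a categorizer")
    if (counts < 3).any():
        raise ValueError("each class needs at least 3 rows")


def fit_categorizer_2d(
    features: LabeledFeatureSet, degree: int = 3, C: float = 1.0
) -> TrainedCategorizer:
    """Fit the polynomial-kernel SVM on both features (z-scaled)."""
    _check_fittable(features)
    scaler = StandardScaler().fit(features.X)
    svc = SVC(kernel="poly", degree=degree, C=C)
    svc.fit(scaler.transform(features.X), features.y)
    return TrainedCategorizer(
        scaler=scaler, svc=svc, feature_pair=features.feature_pair,
        degree=degree, C=C, mode="2d",
    )


def fit_categorizer_1d(
    features: LabeledFeatureSet,
    which_feature: str,
    degree: int = 3,
    C: float = 1.0,
) -> TrainedCategorizer:
    """Fit the same pipeline with the other coordinate held constant.

    The constant is 0 after scaling; since the pinned coordinate is
    identical for every point, its value cannot influence the fit and
    the categorizer is effectively one-dimensional.
    """
    _check_fittable(features)
    if which_feature not in features.feature_pair:
        raise ValueError(
            f"{which_feature!r} is not one of the set's features {features.feature_pair}"
        )
    mode = "x" if which_feature == features.feature_pair[0] else "y"
    scaler = StandardScaler().fit(features.X)
    Z = scaler.transform(features.X)
    Z[:, 1 if mode == "x" else 0] = 0.0
    svc = SVC(kernel="poly", degree=degree, C=C)
    svc.fit(Z, features.y)
    return TrainedCategorizer(
        scaler=scaler, svc=svc, feature_pair=features.feature_pair,
        degree=degree, C=C, mode=mode,
    )


def categorization_accuracy(
    model: TrainedCategorizer,
    features: LabeledFeatureSet,
    n_folds: int | None = None,
) -> float:
    """Categorization accuracy in percent.

    Default is resubstitution (accuracy on the data the model was
    trained on). With ``n_folds`` a stratified k-fold estimate is
    computed instead by refitting the same pipeline per fold.
    """
    if len(features.frame) == 0:
        raise ValueError("empty feature set")
    if n_folds is None:
        correct = (model.predict(features.X) == features.y).sum()
        return 100.0 * correct / len(features.frame)
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=0)
    X, y = features.X, features.y
    correct = 0
    fit = fit_categorizer_2d if model.mode == "2d" else None
    for train, test in skf.split(X, y):
        sub = LabeledFeatureSet(
            features.frame.iloc[train], features.feature_pair, features.subject_column
        )
        if fit is not None:
            m = fit_categorizer_2d(sub, model.degree, model.C)
        else:
            which = features.feature_pair[0 if model.mode == "x" else 1]
            m = fit_categorizer_1d(sub, which, model.degree, model.C)
        correct += (m.predict(X[test]) == y[test]).sum()
    return 100.0 * correct / len(y)


def wilcoxon_scenarios(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two scenarios.

    Inputs are one average value per subject and scenario. For groups of
    up to 10 without ties the exact null distribution is enumerated
    (e.g. fully separated 5-vs-5 groups give p = 2/252); larger or tied
    samples use the normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def per_subject_scenario_means(
    features: LabeledFeatureSet, feature: str, average: str = "mean"
) -> pd.DataFrame:
    """One average feature value per subject and scenario label."""
    if average not in ("mean", "median"):
        raise ValueError("average must be 'mean' or 'median'")
    grouped = features.frame.groupby([features.subject_column, "label"])[feature]
    agg = grouped.mean() if average == "mean" else grouped.median()
    return agg.reset_index()


def decision_map(
    model: TrainedCategorizer,
    bounds: tuple[float, float, float, float],
    resolution: int | tuple[int, int] = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted label for every cell of a regular grid over the plane.

    ``bounds`` is (x_min, x_max, y_min, y_max); returns (labels_raster,
    x_grid, y_grid) with the raster shaped (ny, nx) for plotting.
    """
    if isinstance(resolution, int):
        nx = ny = resolution
    else:
        nx, ny = resolution
    if nx <= 0 or ny <= 0:
        raise ValueError("resolution must be positive")
    x_min, x_max, y_min, y_max = bounds
    if not np.all(np.isfinite([x_min, x_max, y_min, y_max])) or x_min >= x_max or y_min >= y_max:
        raise ValueError("bounds must be finite with min < max")
    xg = np.linspace(x_min, x_max, nx)
    yg = np.linspace(y_min, y_max, ny)
    XX, YY = np.meshgrid(xg, yg)
    pred = model.predict(np.column_stack([XX.ravel(), YY.ravel()]))
    return pred.reshape(ny, nx), xg, yg
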