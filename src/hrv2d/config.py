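"""Run-level configuration for the hrv2d pipeline.

All tunable constants of the analysis live here so that a run is fully
described by one :class:`RunConfig` object, which every pipeline entry
point logs before doing any work.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any

import yaml

logger = logging.getLogger("hrv2d")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a full analysis run.

    Parameters
    ----------
    window_length : float
        Sliding-window length in seconds. 300 s keeps 12 cycles of the
        0.04 Hz lower LF edge inside every window.
    step : float
        Sliding increment in seconds.
    buffer : float
        Seconds trimmed from the start and end of every labeled segment
        before windows are assigned a label, to exclude residuals from
        adjacent activities.
    trim : float
        Trim fraction for the envelope trimmed mean (see ``trim_mode``).
    trim_mode : str
        ``"per_tail"`` removes ``floor(trim*n)`` values from each tail,
        ``"total"`` removes ``floor(trim*n/2)`` from each tail.
    resample_fs : float
        Uniform tachogram sampling rate in Hz; Nyquist must exceed the
        0.4 Hz upper HF edge.
    peak_threshold : float
        Relative deviation from the running median above which an NN
        interval counts as a sharp peak.
    peak_context : int
        Odd number of intervals in the running-median neighborhood.
    svm_degree, svm_c : int, float
        Polynomial-kernel degree and regularization of the categorizer.
    seed : int
        Seed for every stochastic step (simulation only; the analysis
        itself is deterministic).
    """

    window_length: float = 300.0
    step: float = 10.0
    buffer: float = 120.0
    trim: float = 0.2
    trim_mode: str = "per_tail"
    resample_fs: float = 4.0
    peak_threshold: float = 0.3
    peak_context: int = 11
    svm_degree: int = 3
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.step <= 0:
            raise ValueError("window_length and step must be positive")
        if self.buffer < 0:
            raise ValueError("buffer must be >= 0")
        if not 0 <= self.trim < 0.5:
            raise ValueError("trim must lie in [0, 0.5)")
        if self.trim_mode not in ("per_tail", "total"):
            raise ValueError("trim_mode must be 'per_tail' or 'total'")
        if self.resample_fs <= 2 * 0.4:
            raise ValueError("resample_fs must exceed twice the 0.4 Hz HF edge")
        if not 0 < self.peak_threshold < 1:
            raise ValueError("peak_threshold must lie in (0, 1)")
        if self.peak_context < 3 or self.peak_context % 2 == 0:
            raise ValueError("peak_context must be odd and >= 3")
        if self.svm_degree < 1 or self.svm_c <= 0:
            raise ValueError("svm_degree must be >= 1 and svm_c > 0")

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def log(self) -> None:
        """Log every resolved value (audit trail for reproducibility)."""
        for key, value in self.as_dict().items():
            logger.info("config %s = %r", key, value)
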