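"""The SurvivalCurve container shared by solvers, fitting and I/O."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = ["SurvivalCurve"]


@dataclass
class SurvivalCurve:
    """A survival curve: log10 survival ratio sampled at increasing times.

    ``condition`` records what produced the curve — a constant
    temperature (float) or a Profile — purely as metadata.
    """

    times: np.ndarray
    log10S: np.ndarray
    condition: Any = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.log10S = np.asarray(self.log10S, dtype=float)
        if self.times.shape != self.log10S.shape or self.times.ndim != 1:
            raise ValueError("times and log10S must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be >= 0")

    def __len__(self) -> int:
        return self.times.size

    def interpolate(self, at_times) -> np.ndarray:
        """Linear interpolation of log10S onto the requested times."""
        at_times = np.asarray(at_times, dtype=float)
        if np.any(at_times < self.times[0]) or np.any(at_times > self.times[-1]):
            raise ValueError("requested times outside the curve's range")
        return np.interp(at_times, self.times, self.log10S)
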