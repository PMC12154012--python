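"""Secondary models: condition vector -> primary-model parameter.

A secondary model maps the momentary condition vector ``C = [T, ...]``
(temperature first, in deg C) to the value of one primary-model
parameter.  Two temperature laws are provided:

* log-logistic rate coefficient  ``b(T) = ln(1 + exp(k (T - Tc)))`` —
  essentially zero below the critical temperature Tc, asymptotically
  linear with slope k above it;
* Bigelow decimal-reduction time ``delta(T) = delta_ref * 10**((Tref - T)/z)``
  — a z-degree temperature rise shrinks delta tenfold;

plus a constant (condition-independent) secondary for parameters such as
the Weibull shape n, and the exact conversion between the two Weibull
parameterizations, ``b = delta**(-n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "b_of_T",
    "delta_of_T",
    "b_from_delta",
    "delta_from_b",
    "LogLogisticSecondary",
    "BigelowSecondary",
    "ConstantSecondary",
    "DerivedBSecondary",
    "SECONDARY_CATALOG",
    "build_secondary",
]


def _temperature(C) -> float:
    """First component of a condition vector, or the scalar itself."""
    if isinstance(C, np.ndarray):
        return float(C[0]) if C.ndim else float(C)
    if isinstance(C, (int, float)):
        return float(C)
    return float(C[0])


def b_of_T(T, k: float, Tc: float):
    """Log-logistic secondary model for the Weibull rate coefficient.

    ``b(T) = ln(1 + exp(k (T - Tc)))``; evaluated through logaddexp so
    the asymptotic linear branch is exact for large k (T - Tc).
    """
    if k <= 0:
        raise ValueError(f"slope k must be > 0, got {k}")
    out = np.logaddexp(0.0, k * (np.asarray(T, dtype=float) - Tc))
    return float(out) if out.ndim == 0 else out


def delta_of_T(T, delta_ref: float, Tref: float, z: float):
    """Bigelow secondary model ``delta(T) = delta_ref * 10**((Tref - T)/z)``."""
    if z <= 0:
        raise ValueError(f"z-value must be > 0, got {z}")
    if delta_ref <= 0:
        raise ValueError(f"delta_ref must be > 0, got {delta_ref}")
    out = delta_ref * 10.0 ** ((Tref - np.asarray(T, dtype=float)) / z)
    return float(out) if out.ndim == 0 else out


def b_from_delta(delta, n: float):
    """Convert decimal-reduction time to rate coefficient: ``b = delta**(-n)``."""
    if n <= 0:
        raise ValueError(f"shape exponent n must be > 0, got {n}")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("delta must be > 0")
    out = delta ** (-n)
    return float(out) if out.ndim == 0 else out


def delta_from_b(b, n: float):
    """Convert rate coefficient to decimal-reduction time: ``delta = b**(-1/n)``."""
    if n <= 0:
        raise ValueError(f"shape exponent n must be > 0, got {n}")
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("b must be > 0")
    out = b ** (-1.0 / n)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LogLogisticSecondary:
    """``b(T) = ln(1 + exp(k (T - Tc)))``; k in 1/degC, Tc in degC."""

    k: float
    Tc: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"slope k must be > 0, got {self.k}")

    def __call__(self, C) -> float:
        # scalar softplus with the exact linear branch for large arguments
        x = self.k * (_temperature(C) - self.Tc)
        return math.log1p(math.exp(x)) if x < 35.0 else x


@dataclass(frozen=True)
class BigelowSecondary:
    """``delta(T) = delta_ref * 10**((Tref - T)/z)``; delta in min, T/z in degC."""

    delta_ref: float
    Tref: float
    z: float

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError(f"z-value must be > 0, got {self.z}")
        if self.delta_ref <= 0:
            raise ValueError(f"delta_ref must be > 0, got {self.delta_ref}")

    def __call__(self, C) -> float:
        return self.delta_ref * 10.0 ** ((self.Tref - _temperature(C)) / self.z)


@dataclass(frozen=True)
class ConstantSecondary:
    """A condition-independent parameter (e.g. the Weibull shape n)."""

    value: float

    def __call__(self, C) -> float:
        return self.value


@dataclass(frozen=True)
class DerivedBSecondary:
    """Weibull ``b(T)`` obtained from a delta-law via ``b = delta(T)**(-n)``.

    Lets a Bigelow-parameterized organism drive the b-form rate equations
    without any loss: the two parameterizations are algebraically
    identical curves.
    """

    delta_secondary: BigelowSecondary
    n: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"shape exponent n must be > 0, got {self.n}")

    def __call__(self, C) -> float:
        return self.delta_secondary(C) ** (-self.n)


SECONDARY_CATALOG = {
    "log_logistic": LogLogisticSecondary,
    "bigelow": BigelowSecondary,
    "constant": ConstantSecondary,
}


def build_secondary(spec: dict):
    """Build a secondary model from a config mapping.

    Examples: ``{"model": "log_logistic", "k": 0.348, "Tc": 66.34}`` or
    ``{"model": "bigelow", "delta_ref": 1.36, "Tref": 120.0, "z": 7.2}``
    or ``{"model": "constant", "value": 0.545}``.
    """
    spec = dict(spec)
    name = spec.pop("model")
    spec.pop("param", None)
    try:
        cls = SECONDARY_CATALOG[name]
    except KeyError:
        raise KeyError(
            f"unknown secondary model {name!r}; available: {sorted(SECONDARY_CATALOG)}"
        ) from None
    return cls(**spec)
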