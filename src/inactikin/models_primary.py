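"""Algebraic primary survival models under constant lethal conditions.

A primary model is an algebraic function of time that describes the
survival curve ``log10 S(t) = f(t; beta)`` of a target microorganism held
at a constant condition vector ``C`` (temperature, nonthermal agents,
water activity).  Every model in the catalog exposes three views of the
same curve:

* ``log10_survival(t)`` — forward evaluation,
* ``inverse_time(y)``   — the time at which the curve reaches a given
  log10 survival ratio (needed by the path-independent rate construction
  and by the recursive solver),
* ``deriv(t)``          — the slope ``d log10 S / dt`` of the constant-
  condition curve.

Survival is stored and exchanged as ``log10 S`` throughout the package;
models whose natural units are ``ln S`` or cell counts ``N`` convert at
the boundary (``log10 S = ln S / ln 10 = log10(N/N0)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "LN10",
    "NoInverseError",
    "PrimaryModel",
    "WeibullModel",
    "ChickModel",
    "BuckowModel",
    "ZhuChenModel",
    "KosekiModel",
    "MODEL_CATALOG",
    "get_model",
    "weibull_log10S",
    "weibull_inverse",
    "weibull_deriv",
    "table1_survival",
]

LN10 = math.log(10.0)

ArrayLike = Union[float, np.ndarray]


class NoInverseError(ValueError):
    """The survival level cannot be reached by this model (e.g. b = 0)."""


# ---------------------------------------------------------------------------
# Weibull model, rate-coefficient (b) and decimal-reduction-time (delta) forms
# ---------------------------------------------------------------------------

def weibull_log10S(t: ArrayLike, b: float, n: float) -> ArrayLike:
    """Weibull survival curve ``log10 S = -b * t**n``.

    Parameters
    ----------
    t : time (min), >= 0
    b : rate coefficient (min^-n), >= 0
    n : shape exponent (dimensionless), > 0; n < 1 gives concave-up
        (tailing) curves, n > 1 concave-down (shouldered) curves.
    """
    if n <= 0:
        raise ValueError(f"shape exponent n must be > 0, got {n}")
    if b < 0:
        raise ValueError(f"rate coefficient b must be >= 0, got {b}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = -b * t**n
    return float(out) if out.ndim == 0 else out


def weibull_inverse(y: ArrayLike, b: float, n: float, clamp: bool = False) -> ArrayLike:
    """Time at which the Weibull curve reaches log10 survival ratio ``y``.

    ``t = (-y / b)**(1/n)``.  With ``clamp=True`` a (noisy) positive ``y``
    is treated as 0; otherwise it is a domain error.  ``b = 0`` with
    ``y < 0`` raises :class:`NoInverseError` (the curve never leaves 0).
    """
    if n <= 0:
        raise ValueError(f"shape exponent n must be > 0, got {n}")
    y = np.asarray(y, dtype=float)
    if np.any(y > 0):
        if clamp:
            y = np.minimum(y, 0.0)
        else:
            raise ValueError("log10 survival ratio must be <= 0 (set clamp=True for noisy data)")
    if b == 0:
        if np.all(y == 0):
            out = np.zeros_like(y)
            return float(out) if out.ndim == 0 else out
        raise NoInverseError("b = 0: no finite time reaches log10S < 0")
    if b < 0:
        raise ValueError(f"rate coefficient b must be >= 0, got {b}")
    out = (-y / b) ** (1.0 / n)
    return float(out) if out.ndim == 0 else out


def weibull_deriv(t: ArrayLike, b: float, n: float) -> ArrayLike:
    """Slope ``d log10 S / dt = -n * b * t**(n-1)`` of the Weibull curve.

    For ``n < 1`` the slope diverges at t = 0 (infinite initial slope);
    querying it there is an error handled upstream by the solver's
    analytic first-step rule.
    """
    if n <= 0:
        raise ValueError(f"shape exponent n must be > 0, got {n}")
    if b < 0:
        raise ValueError(f"rate coefficient b must be >= 0, got {b}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if n < 1 and np.any(t == 0) and b > 0:
        raise ValueError("slope is singular at t = 0 for n < 1")
    with np.errstate(divide="ignore"):
        out = -n * b * t ** (n - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class WeibullModel:
    """Weibull primary model in either parameterization.

    ``log10 S = -b t**n`` with rate coefficient ``b``, or equivalently
    ``log10 S = -(t/delta)**n`` with ``delta`` the time to the first
    decimal reduction.  The two are linked by ``b = delta**(-n)``;
    either may be supplied and the other is filled in.
    """

    n: float
    b: float | None = None
    delta: float | None = None
    name: str = field(default="weibull", init=False)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"shape exponent n must be > 0, got {self.n}")
        if self.b is None and self.delta is None:
            raise ValueError("supply b or delta")
        if self.delta is not None and self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.b is not None and self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if self.b is None:
            self.b = self.delta ** (-self.n)
        elif self.delta is None:
            self.delta = self.b ** (-1.0 / self.n) if self.b > 0 else math.inf
        else:
            expected = self.delta ** (-self.n)
            if abs(self.b - expected) > 1e-9 * max(abs(expected), 1e-300):
                raise ValueError(
                    f"inconsistent parameterization: b={self.b} but delta**(-n)={expected}"
                )

    @property
    def params(self) -> dict[str, float]:
        return {"b": self.b, "delta": self.delta, "n": self.n}

    def log10_survival(self, t: ArrayLike) -> ArrayLike:
        return weibull_log10S(t, self.b, self.n)

    def inverse_time(self, y: ArrayLike, clamp: bool = False) -> ArrayLike:
        return weibull_inverse(y, self.b, self.n, clamp=clamp)

    def deriv(self, t: ArrayLike) -> ArrayLike:
        return weibull_deriv(t, self.b, self.n)


# ---------------------------------------------------------------------------
# Directly-developed rate-equation models and their constant-condition
# closed forms: Chick, Buckow, Zhu-Chen, Koseki
# ---------------------------------------------------------------------------

@dataclass
class ChickModel:
    """First-order (log-linear) inactivation: ``ln(N/N0) = -kL * t``."""

    kL: float
    name: str = field(default="chick", init=False)

    def __post_init__(self) -> None:
        if self.kL < 0:
            raise ValueError(f"kL must be >= 0, got {self.kL}")

    @property
    def params(self) -> dict[str, float]:
        return {"kL": self.kL}

    def log10_survival(self, t: ArrayLike) -> ArrayLike:
        t = np.asarray(t, dtype=float)
        out = -self.kL * t / LN10
        return float(out) if out.ndim == 0 else out

    def inverse_time(self, y: ArrayLike, clamp: bool = False) -> ArrayLike:
        y = np.asarray(y, dtype=float)
        if np.any(y > 0):
            if clamp:
                y = np.minimum(y, 0.0)
            else:
                raise ValueError("log10 survival ratio must be <= 0")
        if self.kL == 0:
            if np.all(y == 0):
                out = np.zeros_like(y)
                return float(out) if out.ndim == 0 else out
            raise NoInverseError("kL = 0: no finite time reaches log10S < 0")
        out = -y * LN10 / self.kL
        return float(out) if out.ndim == 0 else out

    def deriv(self, t: ArrayLike) -> ArrayLike:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, -self.kL / LN10)
        return float(out) if out.ndim == 0 else out


@dataclass
class BuckowModel:
    """n-th order inactivation ``dN/dt = -kL * N**nB`` (nB != 1).

    Constant-condition closed form:
    ``ln(N/N0) = 1/(1-nB) * ln(1 + kL * N0**(nB-1) * t * (nB-1))``.
    The reaction order nB = 1 is rejected (the closed form is singular
    there; the first-order Chick model covers it).
    """

    kL: float
    nB: float
    N0: float
    name: str = field(default="buckow", init=False)

    def __post_init__(self) -> None:
        if self.kL <= 0:
            raise ValueError(f"kL must be > 0, got {self.kL}")
        if self.nB == 1:
            raise ValueError("reaction order nB = 1 is degenerate; use the Chick model")
        if self.N0 <= 0:
            raise ValueError(f"N0 must be > 0, got {self.N0}")

    @property
    def params(self) -> dict[str, float]:
        return {"kL": self.kL, "nB": self.nB, "N0": self.N0}

    def _kappa(self) -> float:
        # effective rate constant of the argument 1 + kappa * t
        return self.kL * self.N0 ** (self.nB - 1.0) * (self.nB - 1.0)

    def log10_survival(self, t: ArrayLike) -> ArrayLike:
        t = np.asarray(t, dtype=float)
        arg = 1.0 + self._kappa() * t
        if np.any(arg <= 0):
            raise ValueError("time beyond complete-kill point for nB < 1")
        out = np.log(arg) / (1.0 - self.nB) / LN10
        return float(out) if out.ndim == 0 else out

    def inverse_time(self, y: ArrayLike, clamp: bool = False) -> ArrayLike:
        y = np.asarray(y, dtype=float)
        if np.any(y > 0):
            if clamp:
                y = np.minimum(y, 0.0)
            else:
                raise ValueError("log10 survival ratio must be <= 0")
        out = (np.exp((1.0 - self.nB) * y * LN10) - 1.0) / self._kappa()
        return float(out) if out.ndim == 0 else out

    def deriv(self, t: ArrayLike) -> ArrayLike:
        t = np.asarray(t, dtype=float)
        out = -self.kL * self.N0 ** (self.nB - 1.0) / (1.0 + self._kappa() * t) / LN10
        return float(out) if out.ndim == 0 else out


@dataclass
class ZhuChenModel:
    """Lag/decay model with a residual tail.

    Rate equation ``dN/dt = -kmax * (N - Nres) / (1 + (C/C0) e^{-kmax t})``
    (constant lethal level).  The constant-condition closed form, with
    ``c = C/C0``, ``r = Nres/N0`` and ``E = e^{kmax t}``::

        log10 S = log10[ (1 + c + (E - 1) r) / (c + E) ]

    This grouping is the one consistent with the rate equation: its time
    derivative equals the rate equation exactly (verified analytically
    and by numerical integration in the test suite).  S decays from 1 at
    t = 0 to the residual fraction r as t -> infinity.
    """

    kmax: float
    C_over_C0: float
    Nres: float
    N0: float
    name: str = field(default="zhu_chen", init=False)

    def __post_init__(self) -> None:
        if self.kmax <= 0:
            raise ValueError(f"kmax must be > 0, got {self.kmax}")
        if self.C_over_C0 < 0:
            raise ValueError(f"C/C0 must be >= 0, got {self.C_over_C0}")
        if not (0 < self.Nres < self.N0):
            raise ValueError(f"need 0 < Nres < N0, got Nres={self.Nres}, N0={self.N0}")

    @property
    def params(self) -> dict[str, float]:
        return {
            "kmax": self.kmax,
            "C_over_C0": self.C_over_C0,
            "Nres": self.Nres,
            "N0": self.N0,
        }

    def survival_ratio(self, t: ArrayLike) -> ArrayLike:
        t = np.asarray(t, dtype=float)
        c, r = self.C_over_C0, self.Nres / self.N0
        E = np.exp(self.kmax * t)
        out = (1.0 + c + (E - 1.0) * r) / (c + E)
        return float(out) if out.ndim == 0 else out

    def log10_survival(self, t: ArrayLike) -> ArrayLike:
        out = np.log10(self.survival_ratio(t))
        return float(out) if np.ndim(out) == 0 else out

    def inverse_time(self, y: ArrayLike, clamp: bool = False) -> ArrayLike:
        y = np.asarray(y, dtype=float)
        if np.any(y > 0):
            if clamp:
                y = np.minimum(y, 0.0)
            else:
                raise ValueError("log10 survival ratio must be <= 0")
        c, r = self.C_over_C0, self.Nres / self.N0
        S = 10.0**y
        if np.any(S <= r):
            raise NoInverseError("survival ratio at or below the residual tail Nres/N0")
        E = (1.0 + c - r - c * S) / (S - r)
        out = np.log(E) / self.kmax
        return float(out) if out.ndim == 0 else out

    def deriv(self, t: ArrayLike) -> ArrayLike:
        t = np.asarray(t, dtype=float)
        c, r = self.C_over_C0, self.Nres / self.N0
        E = np.exp(self.kmax * t)
        dS = -self.kmax * E * (1.0 + c) * (1.0 - r) / (c + E) ** 2
        out = dS / (self.survival_ratio(t) * LN10)
        return float(out) if out.ndim == 0 else out


@dataclass
class KosekiModel:
    """Tailing model with a floor ``Nmin``:
    ``N(t) = [(N0^mK - Nmin^mK) e^{-mK kmax t} + Nmin^mK]^{1/mK}``.

    Evaluated in N/N0 units internally to avoid overflow at large counts.
    The shape exponent is called ``mK`` here to keep it distinct from the
    path weight ``m`` of the history-integral rate equations.
    """

    kmax: float
    Nmin: float
    mK: float
    N0: float
    name: str = field(default="koseki", init=False)

    def __post_init__(self) -> None:
        if self.kmax <= 0:
            raise ValueError(f"kmax must be > 0, got {self.kmax}")
        if self.mK <= 0:
            raise ValueError(f"shape mK must be > 0, got {self.mK}")
        if not (0 < self.Nmin < self.N0):
            raise ValueError(f"need 0 < Nmin < N0, got Nmin={self.Nmin}, N0={self.N0}")

    @property
    def params(self) -> dict[str, float]:
        return {"kmax": self.kmax, "Nmin": self.Nmin, "mK": self.mK, "N0": self.N0}

    @property
    def _rm(self) -> float:
        return (self.Nmin / self.N0) ** self.mK

    def survival_ratio(self, t: ArrayLike) -> ArrayLike:
        t = np.asarray(t, dtype=float)
        rm = self._rm
        out = ((1.0 - rm) * np.exp(-self.mK * self.kmax * t) + rm) ** (1.0 / self.mK)
        return float(out) if out.ndim == 0 else out

    def log10_survival(self, t: ArrayLike) -> ArrayLike:
        out = np.log10(self.survival_ratio(t))
        return float(out) if np.ndim(out) == 0 else out

    def inverse_time(self, y: ArrayLike, clamp: bool = False) -> ArrayLike:
        y = np.asarray(y, dtype=float)
        if np.any(y > 0):
            if clamp:
                y = np.minimum(y, 0.0)
            else:
                raise ValueError("log10 survival ratio must be <= 0")
        rm = self._rm
        Sm = (10.0**y) ** self.mK
        if np.any(Sm <= rm):
            raise NoInverseError("survival ratio at or below the tail floor Nmin/N0")
        out = -np.log((Sm - rm) / (1.0 - rm)) / (self.mK * self.kmax)
        return float(out) if out.ndim == 0 else out

    def deriv(self, t: ArrayLike) -> ArrayLike:
        t = np.asarray(t, dtype=float)
        rm = self._rm
        decay = (1.0 - rm) * np.exp(-self.mK * self.kmax * t)
        out = -self.kmax * decay / (decay + rm) / LN10
        return float(out) if out.ndim == 0 else out


PrimaryModel = Union[WeibullModel, ChickModel, BuckowModel, ZhuChenModel, KosekiModel]

MODEL_CATALOG: dict[str, type] = {
    "weibull": WeibullModel,
    "chick": ChickModel,
    "buckow": BuckowModel,
    "zhu_chen": ZhuChenModel,
    "koseki": KosekiModel,
}


def get_model(name: str, **params: float) -> PrimaryModel:
    """Instantiate a catalog model by its string identifier."""
    try:
        cls = MODEL_CATALOG[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_CATALOG)}"
        ) from None
    return cls(**params)


def table1_survival(model: str, params: dict[str, float], t: ArrayLike) -> ArrayLike:
    """Closed-form ``log10 S(t)`` of a directly-developed rate-equation model
    (chick, buckow, zhu_chen or koseki) at a constant lethal level."""
    if model not in ("chick", "buckow", "zhu_chen", "koseki"):
        raise KeyError(f"not a directly-developed rate-equation model: {model!r}")
    return get_model(model, **params).log10_survival(t)
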