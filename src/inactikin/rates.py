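"""Inactivation rate equations constructed from a primary survival model.

Under a time-varying lethal-agent profile the survival ODE
``d log10 S / dt = r(...)`` can be built from a constant-condition
primary model in more than one way, and the choice matters:

* **path-independent** (unique): the momentary rate equals the slope of
  the constant-condition curve at the momentary condition, taken at the
  time corresponding to the momentary survival ratio,
  ``r = f'(f^-1(log10 S))``.  For the Weibull model this is
  ``r = -n b(T)^(1/n) (-log10 S)^((n-1)/n)``.
* **path-dependent** (an infinite family): any rate law whose value also
  depends on the history of the path, all collapsing to the same primary
  model at constant conditions.  Implemented members:

  - ``derivative``: the naive time-derivative of the primary model,
    ``r = -n b(T(t)) t^(n-1)`` (clock time, not survival state);
  - ``history_state``: like path-independent but with the rate
    coefficient replaced by the history average
    ``Bbar = (m+1) \\int_0^t tau^m b(T(tau)) dtau / t^(m+1)``;
  - ``history_derivative``: the derivative form driven by ``Bbar``.

  ``m`` is an arbitrary real path weight; at constant temperature
  ``Bbar == b`` for every m, which is why the whole family degenerates
  to the same survival curve there.  An optional multiplier
  ``exp(a dT/dt)`` (also 1 at constant conditions) can be layered on any
  member to illustrate that the family is genuinely infinite.

The directly-developed rate equations (Chick, Buckow, Zhu-Chen, Koseki)
are expressed on the cell count N, as printed in their sources; the
solver converts to log10 S at its boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .models_primary import (
    BuckowModel,
    ChickModel,
    KosekiModel,
    PrimaryModel,
    WeibullModel,
    ZhuChenModel,
    get_model,
)
from .models_secondary import (
    BigelowSecondary,
    ConstantSecondary,
    DerivedBSecondary,
    LogLogisticSecondary,
)

__all__ = [
    "WeibullFamily",
    "ParameterizedPrimary",
    "ConstantFamily",
    "path_independent_rate",
    "history_increment",
    "table1_rate",
    "PathIndependentWeibullRate",
    "DerivativeWeibullRate",
    "HistoryStateWeibullRate",
    "HistoryDerivativeWeibullRate",
    "Table1DirectRate",
    "ExponentialRampFactor",
    "build_weibull_rate",
    "RATE_VARIANTS",
]

# below this survival depth the state-singular rates (n < 1) hand the
# step to the frozen-parameter analytic update instead of RK4
_Y_SWITCH = 1e-9


# ---------------------------------------------------------------------------
# Parameterized primary-model families (primary model + secondary models)
# ---------------------------------------------------------------------------

@dataclass
class WeibullFamily:
    """A Weibull primary model whose parameters follow secondary models.

    ``b_secondary`` maps the condition vector to the rate coefficient b
    (log-logistic in T, or derived from a Bigelow delta-law), and
    ``n_secondary`` maps it to the shape n (constant in most organisms).
    """

    b_secondary: Callable[[np.ndarray], float]
    n_secondary: Callable[[np.ndarray], float]

    @classmethod
    def from_log_logistic(cls, k: float, Tc: float, n: float) -> "WeibullFamily":
        return cls(LogLogisticSecondary(k=k, Tc=Tc), ConstantSecondary(n))

    @classmethod
    def from_bigelow(cls, delta_ref: float, Tref: float, z: float, n: float) -> "WeibullFamily":
        sec = BigelowSecondary(delta_ref=delta_ref, Tref=Tref, z=z)
        return cls(DerivedBSecondary(sec, n), ConstantSecondary(n))

    def b(self, C) -> float:
        return float(self.b_secondary(C))

    def n(self, C) -> float:
        return float(self.n_secondary(C))

    def at(self, C) -> WeibullModel:
        return WeibullModel(b=self.b(C), n=self.n(C))


@dataclass
class ParameterizedPrimary:
    """Any catalog primary model with one secondary model per parameter."""

    model_name: str
    secondaries: Mapping[str, Callable[[np.ndarray], float]]

    def at(self, C) -> PrimaryModel:
        return get_model(self.model_name,
                         **{p: float(s(C)) for p, s in self.secondaries.items()})


@dataclass
class ConstantFamily:
    """A fixed primary model, independent of the conditions."""

    model: PrimaryModel

    def at(self, C) -> PrimaryModel:
        return self.model


# ---------------------------------------------------------------------------
# Momentary rate operations
# ---------------------------------------------------------------------------

def path_independent_rate(model: PrimaryModel, log10S: float) -> float:
    """The unique path-independent momentary rate ``f'(f^-1(log10 S))``.

    The primary model must already carry the parameter values for the
    momentary condition vector.  A (noisy) positive log10S is clamped to
    0 with a warning.  The rate is -inf where the constant-condition
    curve has infinite slope (Weibull n < 1 at log10S = 0); solvers
    avoid that point through their analytic first-step rule.
    """
    if log10S > 0:
        warnings.warn("log10S > 0 clamped to 0 in path_independent_rate", stacklevel=2)
        log10S = 0.0
    if isinstance(model, WeibullModel):
        return _weibull_pi_rate(model.b, model.n, log10S)
    t_star = model.inverse_time(log10S)
    return float(model.deriv(t_star))


def _weibull_pi_rate(b: float, n: float, y: float) -> float:
    """Weibull path-independent rate ``-n b^(1/n) (-y)^((n-1)/n)``."""
    if b <= 0.0:
        return 0.0
    if y >= 0.0:
        if n > 1.0:
            return 0.0
        if n == 1.0:
            return -b
        return -math.inf  # infinite initial slope for n < 1
    return -n * b ** (1.0 / n) * (-y) ** ((n - 1.0) / n)


def history_increment(t: float, m: float, b_at_T: float) -> float:
    """Integrand ``t^m b(T(t))`` of the weighted exposure integral I_m.

    Carried as an auxiliary ODE state alongside log10S.  For m < 0 the
    integrand has an integrable singularity at t = 0; the solver's
    analytic first step keeps quadrature away from it.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    if t == 0.0 and m < 0:
        return math.inf
    return t**m * b_at_T


def table1_rate(model: str, params: dict, N: float, t: float = 0.0) -> float:
    """Momentary ``dN/dt`` of a directly-developed rate equation.

    ``t`` enters only the Zhu-Chen lag term through the elapsed exposure
    ``\\int kmax dt = kmax t`` (constant lethal level).  Below the tail
    floor (Zhu-Chen Nres, Koseki Nmin) the rate is 0.
    """
    return Table1DirectRate(get_model(model, **params)).rate_dNdt(t, N)


# ---------------------------------------------------------------------------
# Rate-equation objects consumed by the RK4 solver
# ---------------------------------------------------------------------------
# Interface: state_kind ("log10S" | "count"), aux_dim, initial_state(),
# rhs(t, y, aux, profile) -> (dy, daux), needs_analytic_step(t, y),
# analytic_step(t0, t1, y, aux, profile) -> (y1, aux1).  The analytic
# step is the frozen-parameter (locally-constant-condition) exact update,
# used where the right-hand side is singular.


@dataclass
class _WeibullRateBase:
    family: WeibullFamily
    state_kind: str = field(default="log10S", init=False)
    aux_dim: int = field(default=0, init=False)
    # number of initial solver steps taken by the analytic frozen-parameter
    # update instead of RK4: the right-hand sides carry t**(n-1)- and
    # (-log10S)**((n-1)/n)-type factors whose curvature is extreme during
    # the first few steps; the analytic update is exact there at constant
    # conditions and second-order accurate otherwise
    startup_steps: int = field(default=20, init=False)

    def initial_state(self) -> float:
        return 0.0

    def initial_aux(self) -> tuple:
        return (0.0,) * self.aux_dim


@dataclass
class PathIndependentWeibullRate(_WeibullRateBase):
    """Unique state-only rate: ``-n b(T)^(1/n) (-log10S)^((n-1)/n)``."""

    kind = "path_independent"

    def rhs(self, t, y, aux, profile):
        C = profile.conditions(t)
        return _weibull_pi_rate(self.family.b(C), self.family.n(C), y), ()

    def needs_analytic_step(self, t, y) -> bool:
        # near log10S = 0 the n < 1 rate is (nearly) singular; the frozen-b
        # update is exact at constant conditions and stable always
        return -y < _Y_SWITCH

    def analytic_step(self, t0, t1, y, aux, profile):
        C = profile.conditions(0.5 * (t0 + t1))
        b, n = self.family.b(C), self.family.n(C)
        if b <= 0.0:
            return y, aux
        u = (-y) ** (1.0 / n) + b ** (1.0 / n) * (t1 - t0)
        return -(u**n), aux


@dataclass
class DerivativeWeibullRate(_WeibullRateBase):
    """Clock-time derivative of the primary model: ``-n b(T(t)) t^(n-1)``."""

    kind = "derivative"

    def rhs(self, t, y, aux, profile):
        C = profile.conditions(t)
        n = self.family.n(C)
        if t == 0.0 and n < 1.0:
            return -math.inf, ()
        return -n * self.family.b(C) * t ** (n - 1.0), ()

    def needs_analytic_step(self, t, y) -> bool:
        return t == 0.0

    def analytic_step(self, t0, t1, y, aux, profile):
        C = profile.conditions(0.5 * (t0 + t1))
        b, n = self.family.b(C), self.family.n(C)
        return y - b * (t1**n - t0**n), aux


@dataclass
class _HistoryRateBase(_WeibullRateBase):
    """Common machinery for the history-integral (I_m) variants."""

    m: float = 1.0
    aux_dim: int = field(default=1, init=False)

    def __post_init__(self) -> None:
        if self.m <= -1.0:
            raise ValueError(f"path weight m must be > -1 for a convergent history integral, got {self.m}")

    def _bbar(self, t, I, C) -> float:
        """History average Bbar = (m+1) I_m / t^(m+1); limit b(T(t)) at t=0."""
        if t <= 0.0:
            return self.family.b(C)
        return (self.m + 1.0) * I / t ** (self.m + 1.0)

    def _aux_increment(self, t0, t1, b_mid) -> float:
        # frozen-b exact integral of tau^m b over [t0, t1]
        return b_mid * (t1 ** (self.m + 1.0) - t0 ** (self.m + 1.0)) / (self.m + 1.0)


@dataclass
class HistoryStateWeibullRate(_HistoryRateBase):
    """State-form rate with the history-averaged coefficient Bbar."""

    kind = "history_state"

    def rhs(self, t, y, aux, profile):
        C = profile.conditions(t)
        b = self.family.b(C)
        bbar = self._bbar(t, aux[0], C)
        dy = _weibull_pi_rate(bbar, self.family.n(C), y)
        return dy, (history_increment(t, self.m, b),)

    def needs_analytic_step(self, t, y) -> bool:
        return -y < _Y_SWITCH or (t == 0.0 and self.m < 0)

    def analytic_step(self, t0, t1, y, aux, profile):
        C = profile.conditions(0.5 * (t0 + t1))
        b_mid, n = self.family.b(C), self.family.n(C)
        bbar = self._bbar(t0, aux[0], C) if t0 > 0.0 else b_mid
        aux1 = (aux[0] + self._aux_increment(t0, t1, b_mid),)
        if bbar <= 0.0:
            return y, aux1
        u = (-y) ** (1.0 / n) + bbar ** (1.0 / n) * (t1 - t0)
        return -(u**n), aux1


@dataclass
class HistoryDerivativeWeibullRate(_HistoryRateBase):
    """Derivative-form rate with the history-averaged coefficient Bbar."""

    kind = "history_derivative"

    def rhs(self, t, y, aux, profile):
        C = profile.conditions(t)
        b = self.family.b(C)
        n = self.family.n(C)
        if t == 0.0 and (n < 1.0 or self.m < 0):
            return -math.inf, (math.inf if self.m < 0 else (b if self.m == 0 else 0.0),)
        bbar = self._bbar(t, aux[0], C)
        return -n * bbar * t ** (n - 1.0), (history_increment(t, self.m, b),)

    def needs_analytic_step(self, t, y) -> bool:
        return t == 0.0

    def analytic_step(self, t0, t1, y, aux, profile):
        C = profile.conditions(0.5 * (t0 + t1))
        b_mid, n = self.family.b(C), self.family.n(C)
        bbar = self._bbar(t0, aux[0], C) if t0 > 0.0 else b_mid
        aux1 = (aux[0] + self._aux_increment(t0, t1, b_mid),)
        return y - bbar * (t1**n - t0**n), aux1


@dataclass
class Table1DirectRate:
    """A directly-developed rate equation on the cell count N.

    The lethal level is constant over the run (these equations were
    developed for constant processing conditions); the Zhu-Chen lag term
    uses the elapsed exposure kmax*t directly.
    """

    model: PrimaryModel
    N0: float | None = None
    kind = "table1_direct"
    state_kind = "count"
    aux_dim = 0
    startup_steps = 0

    def __post_init__(self) -> None:
        if self.N0 is None:
            self.N0 = getattr(self.model, "N0", None)
        if self.N0 is not None and self.N0 <= 0:
            raise ValueError(f"N0 must be > 0, got {self.N0}")

    def initial_state(self) -> float:
        if self.N0 is None:
            raise ValueError("an initial count N0 is required to integrate this rate")
        return float(self.N0)

    def initial_aux(self) -> tuple:
        return ()

    def rate_dNdt(self, t: float, N: float) -> float:
        m = self.model
        if N <= 0.0:
            return 0.0
        if isinstance(m, ChickModel):
            return -m.kL * N
        if isinstance(m, BuckowModel):
            return -m.kL * N**m.nB
        if isinstance(m, ZhuChenModel):
            if N <= m.Nres:
                return 0.0
            lag = 1.0 + m.C_over_C0 * math.exp(-m.kmax * t)
            return -m.kmax * (N - m.Nres) / lag
        if isinstance(m, KosekiModel):
            if N <= m.Nmin:
                return 0.0
            return -m.kmax * (1.0 - (m.Nmin / N) ** m.mK) * N
        raise TypeError(f"no direct rate equation for model {m.name!r}")

    def rhs(self, t, y, aux, profile):
        return self.rate_dNdt(t, y), ()

    def needs_analytic_step(self, t, y) -> bool:
        return False


@dataclass
class ExponentialRampFactor:
    """Multiply any rate by ``exp(a dT/dt)`` — one more path-dependent
    member of the family (the factor is 1 at constant temperature).

    The analytic (frozen-parameter) step of the wrapped rate is scaled by
    the midpoint factor, which is exact wherever the factor is exact."""

    inner: object
    a: float

    @property
    def kind(self) -> str:
        return f"{self.inner.kind}*exp_ramp"

    @property
    def state_kind(self) -> str:
        return self.inner.state_kind

    @property
    def aux_dim(self) -> int:
        return self.inner.aux_dim

    @property
    def startup_steps(self) -> int:
        return self.inner.startup_steps

    def initial_state(self):
        return self.inner.initial_state()

    def initial_aux(self):
        return self.inner.initial_aux()

    def _factor(self, t, profile) -> float:
        return math.exp(self.a * profile.temperature_deriv(t))

    def rhs(self, t, y, aux, profile):
        dy, daux = self.inner.rhs(t, y, aux, profile)
        return dy * self._factor(t, profile), daux

    def needs_analytic_step(self, t, y) -> bool:
        return self.inner.needs_analytic_step(t, y)

    def analytic_step(self, t0, t1, y, aux, profile):
        y1, aux1 = self.inner.analytic_step(t0, t1, y, aux, profile)
        f = self._factor(0.5 * (t0 + t1), profile)
        return y + f * (y1 - y), aux1


RATE_VARIANTS = ("path_independent", "derivative", "history_state", "history_derivative")


def build_weibull_rate(family: WeibullFamily, variant: str, m: float = 1.0,
                       exp_multiplier_a: float = 0.0):
    """Construct a Weibull-family rate equation by variant name.

    ``m`` applies to the history variants only; a nonzero
    ``exp_multiplier_a`` wraps the rate in the exp(a dT/dt) factor.
    """
    if variant == "path_independent":
        rate = PathIndependentWeibullRate(family)
    elif variant == "derivative":
        rate = DerivativeWeibullRate(family)
    elif variant == "history_state":
        rate = HistoryStateWeibullRate(family, m=m)
    elif variant == "history_derivative":
        rate = HistoryDerivativeWeibullRate(family, m=m)
    else:
        raise KeyError(f"unknown rate variant {variant!r}; available: {RATE_VARIANTS}")
    if exp_multiplier_a != 0.0:
        rate = ExponentialRampFactor(rate, exp_multiplier_a)
    return rate
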