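"""Lethal-agent profiles: the path C(t) a process takes through condition space.

A profile maps time (min) to the condition vector ``C = [T, ...]``:
temperature first (deg C), then any further agents the user declares as
constants (nonthermal agent levels, water activity).  Builders cover
constant holds, linear heating/cooling ramps, ramp-hold-cool composites,
tabulated temperature logs, and the two-stage ramp-then-oscillation test
profile used throughout the package to exercise dynamic predictions.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Profile",
    "ConstantProfile",
    "PiecewiseLinearProfile",
    "TabulatedProfile",
    "RampSineProfile",
    "constant_profile",
    "linear_ramp",
    "ramp_hold_cool",
    "tabulated_profile",
    "ramp_sine_profile",
]


@dataclass
class Profile:
    """Base class; subclasses implement ``temperature`` and ``temperature_deriv``.

    ``extras`` are additional (constant) condition components appended
    after temperature in the vector returned by :meth:`conditions`.
    """

    t_end: float
    extras: tuple[float, ...] = ()
    is_continuous: bool = True

    def temperature(self, t: float) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def temperature_deriv(self, t: float) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def conditions(self, t: float) -> np.ndarray:
        return np.array([self.temperature(t), *self.extras], dtype=float)

    def _check_domain(self, t: float) -> None:
        if t < 0 or t > self.t_end * (1 + 1e-12) + 1e-12:
            raise ValueError(f"time {t} outside profile domain [0, {self.t_end}]")


@dataclass
class ConstantProfile(Profile):
    T: float = 25.0

    def __post_init__(self) -> None:
        self._C = np.array([self.T, *self.extras], dtype=float)

    def temperature(self, t: float) -> float:
        self._check_domain(t)
        return self.T

    def temperature_deriv(self, t: float) -> float:
        self._check_domain(t)
        return 0.0

    def conditions(self, t: float) -> np.ndarray:
        self._check_domain(t)
        return self._C


@dataclass
class PiecewiseLinearProfile(Profile):
    """Continuous piecewise-linear temperature profile through node points."""

    times: Sequence[float] = (0.0,)
    temps: Sequence[float] = (25.0,)

    def __post_init__(self) -> None:
        self._t = [float(x) for x in self.times]
        self._T = [float(x) for x in self.temps]
        if len(self._t) != len(self._T):
            raise ValueError("times and temps must have equal length")
        if any(b <= a for a, b in zip(self._t, self._t[1:])):
            raise ValueError("profile times must be strictly increasing")
        self.t_end = self._t[-1]

    def temperature(self, t: float) -> float:
        self._check_domain(t)
        return float(np.interp(t, self._t, self._T))

    def temperature_deriv(self, t: float) -> float:
        self._check_domain(t)
        if len(self._t) == 1:
            return 0.0
        i = bisect.bisect_right(self._t, t) - 1
        i = min(max(i, 0), len(self._t) - 2)
        return (self._T[i + 1] - self._T[i]) / (self._t[i + 1] - self._t[i])


@dataclass
class TabulatedProfile(PiecewiseLinearProfile):
    """Measured temperature log: linear interpolation between rows, no
    extrapolation outside the recorded time range."""

    def _check_domain(self, t: float) -> None:
        if t < self._t[0] or t > self._t[-1] * (1 + 1e-12) + 1e-12:
            raise ValueError(
                f"time {t} outside tabulated range [{self._t[0]}, {self._t[-1]}]"
            )


@dataclass
class RampSineProfile(Profile):
    """Two-stage dynamic test profile: a linear heating ramp followed by a
    sinusoidal oscillation::

        T(t) = T0 + HR * t              for t <= t_switch
        T(t) = A * sin(w * t) + T_mid   for t >  t_switch

    Times in minutes, sine argument in radians, temperatures in deg C.
    With the default constants (T0=25, HR=100, t_switch=0.5, A=5, w=5,
    T_mid=75) the two branches do NOT meet at the switch: the ramp ends at
    75 while the sine branch starts at 5*sin(2.5) + 75 ~= 77.99 degC, a
    deliberate upward jump of ~2.99 degC.  This is the single
    discontinuous builder in the catalog and is flagged as such.
    """

    T0: float = 25.0
    HR: float = 100.0
    t_switch: float = 0.5
    A: float = 5.0
    w: float = 5.0
    T_mid: float = 75.0
    is_continuous: bool = field(default=False, init=False)

    def temperature(self, t: float) -> float:
        self._check_domain(t)
        if t <= self.t_switch:
            return self.T0 + self.HR * t
        return self.A * math.sin(self.w * t) + self.T_mid

    def temperature_deriv(self, t: float) -> float:
        self._check_domain(t)
        if t <= self.t_switch:
            return self.HR
        return self.A * self.w * math.cos(self.w * t)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def constant_profile(T: float, t_end: float, extras: Sequence[float] = ()) -> ConstantProfile:
    """A constant hold at temperature T for t_end minutes."""
    return ConstantProfile(t_end=t_end, extras=tuple(extras), T=T)


def linear_ramp(T0: float, HR: float, t_end: float,
                extras: Sequence[float] = ()) -> PiecewiseLinearProfile:
    """Linear heating (HR > 0) or cooling (HR < 0) from T0 at HR deg C/min."""
    if HR == 0:
        raise ValueError("use constant_profile for a zero heating rate")
    return PiecewiseLinearProfile(
        t_end=t_end, extras=tuple(extras),
        times=(0.0, t_end), temps=(T0, T0 + HR * t_end),
    )


def ramp_hold_cool(T0: float, HR: float, T_hold: float, hold_time: float,
                   CR: float, T_final: float | None = None,
                   extras: Sequence[float] = ()) -> PiecewiseLinearProfile:
    """Heat from T0 to T_hold at HR, hold, then cool at CR back to T_final
    (default: back to T0).  Rates in deg C/min, CR given as a positive number."""
    if HR <= 0 or CR <= 0:
        raise ValueError("HR and CR must be > 0")
    if hold_time < 0:
        raise ValueError(f"hold_time must be >= 0, got {hold_time}")
    if T_hold <= T0:
        raise ValueError("T_hold must exceed T0")
    if T_final is None:
        T_final = T0
    t1 = (T_hold - T0) / HR
    t2 = t1 + hold_time
    t3 = t2 + (T_hold - T_final) / CR
    times, temps = [0.0, t1], [T0, T_hold]
    if hold_time > 0:
        times.append(t2)
        temps.append(T_hold)
    times.append(t3)
    temps.append(T_final)
    return PiecewiseLinearProfile(t_end=t3, extras=tuple(extras),
                                  times=tuple(times), temps=tuple(temps))


def tabulated_profile(times: Sequence[float], temps: Sequence[float],
                      extras: Sequence[float] = ()) -> TabulatedProfile:
    """Profile from a measured (time, temperature) table, linearly interpolated."""
    return TabulatedProfile(t_end=float(times[-1]), extras=tuple(extras),
                            times=tuple(times), temps=tuple(temps))


def ramp_sine_profile(t_end: float = 3.0, extras: Sequence[float] = ()) -> RampSineProfile:
    """The standard two-stage dynamic test profile (see :class:`RampSineProfile`)."""
    return RampSineProfile(t_end=t_end, extras=tuple(extras))
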