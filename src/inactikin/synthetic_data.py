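"""Synthetic survival data with known ground truth, plus published fixtures.

The generator produces solver-exact "true" curves under any constant or
dynamic profile and adds independent homoscedastic Gaussian noise on the
log10 survival ratio — the noise model implicit in least-squares fitting
of log-transformed plate counts.  Identical spec + seed always yields
identical output.

``published_fixtures`` bundles the literature parameter sets used in the
worked examples: the Salmonella enteritidis Weibull/log-logistic set
(k = 0.348 1/degC, Tc = 66.34 degC, n = 0.545), the Bacillus
sporothermodurans IC4 (McIlvaine pH5) Bigelow set (z = 7.20 degC,
delta_ref = 1.36 min, n = 1.25), the two-stage dynamic test profile,
and the 16-condition case-study RMSE comparison table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import SurvivalCurve
from .profiles import Profile, ramp_sine_profile
from .rates import WeibullFamily, build_weibull_rate
from .solver import SolverSettings, solve_recursive, solve_rk4

__all__ = [
    "SyntheticSpec",
    "generate_survival",
    "generate_isothermal_dataset",
    "published_fixtures",
    "case_study_rmse_table",
]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic survival curve.

    ``family`` is a :class:`~inactikin.rates.WeibullFamily`;
    ``rate_variant`` selects which member of the rate-equation family
    generates the truth (they only differ under dynamic profiles).
    """

    family: WeibullFamily
    profile: Profile
    times: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0
    rate_variant: str = "path_independent"
    m: float = 1.0
    force_zero_at_t0: bool = True
    dt: float = 1e-3
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def generate_survival(spec: SyntheticSpec) -> SurvivalCurve:
    """Solver-generated true curve plus additive Gaussian noise.

    The truth is computed by the recursive scheme for the
    path-independent variant (exact at constant conditions) and by RK4
    for the path-dependent variants, then interpolated to the requested
    sampling times.  With ``force_zero_at_t0`` a t = 0 sample stays at
    exactly 0 before noise is added.
    """
    t_end = float(spec.times[-1])
    settings = SolverSettings(dt=min(spec.dt, t_end), t_end=t_end)
    if spec.rate_variant == "path_independent":
        sol = solve_recursive(spec.family, spec.profile, settings)
    else:
        rate = build_weibull_rate(spec.family, spec.rate_variant, m=spec.m)
        sol = solve_rk4(rate, spec.profile, settings)
    truth = sol.interpolate(spec.times)
    if spec.force_zero_at_t0 and spec.times[0] == 0.0:
        truth[0] = 0.0
    rng = np.random.default_rng(spec.seed)
    noisy = truth + rng.normal(0.0, spec.noise_sd, size=truth.shape)
    return SurvivalCurve(spec.times, noisy, condition=spec.profile, label=spec.label)


def generate_isothermal_dataset(temps, delta_ref: float, Tref: float, z: float,
                                n: float, points_per_curve: int = 10,
                                noise_sd: float = 0.1, seed: int = 0,
                                target_reduction: float = 6.0,
                                ) -> dict[float, SurvivalCurve]:
    """Isothermal curves at several holding temperatures for one organism.

    Sampling times at each temperature span the interval up to the
    ``target_reduction``-log10 point of the true curve, evenly spaced
    (no t = 0 point: it carries no parameter information).  Each curve
    gets an independent noise stream spawned from ``seed``.
    """
    temps = [float(T) for T in temps]
    streams = np.random.SeedSequence(seed).spawn(len(temps))
    out: dict[float, SurvivalCurve] = {}
    for T, ss in zip(temps, streams):
        delta_T = delta_ref * 10.0 ** ((Tref - T) / z)
        t_max = delta_T * target_reduction ** (1.0 / n)
        times = np.linspace(t_max / points_per_curve, t_max, points_per_curve)
        truth = -((times / delta_T) ** n)
        rng = np.random.default_rng(ss)
        noisy = truth + rng.normal(0.0, noise_sd, size=times.shape)
        out[T] = SurvivalCurve(times, noisy, condition=T, label=f"T={T}")
    return out


def case_study_rmse_table() -> pd.DataFrame:
    """The packaged 16-condition prediction-RMSE comparison table.

    One row per dynamic condition from the four published case studies,
    with the prediction RMSE (log10 units) of the path-independent rate
    equation and of the derivative (path-dependent) rate equation."""
    ref = importlib.resources.files("inactikin") / "data" / "case_study_rmse.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def published_fixtures() -> dict:
    """Literature parameter sets and tables used by examples and tests."""
    return {
        "salmonella_enteritidis": {"k": 0.348, "Tc": 66.34, "n": 0.545},
        "bsporo_mcilvaine_ph5": {"z": 7.20, "delta_ref": 1.36, "n": 1.25},
        "dynamic_profile": ramp_sine_profile(),
        "rmse_table": case_study_rmse_table(),
    }
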