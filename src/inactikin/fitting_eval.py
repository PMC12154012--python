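"""Parameter estimation and prediction scoring.

The standard two-stage workflow of predictive microbiology:

1. fit the Weibull primary model ``log10 S = -(t/delta)**n`` to each
   isothermal survival curve (usually with a single shape n shared
   across temperatures);
2. fit a secondary model to the per-temperature parameter table —
   Bigelow ``delta(T)`` (a linear regression on log10 delta) or the
   log-logistic ``b(T)``;
3. optionally refine all parameters simultaneously against survival
   curves measured under dynamic (nonisothermal) conditions, with the
   model evaluated through the ODE solvers;
4. score predictions with the degrees-of-freedom-corrected RMSE
   ``sqrt(sum (measured - calculated)^2 / (me - p))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .curves import SurvivalCurve
from .models_secondary import b_of_T, delta_of_T
from .profiles import Profile
from .rates import WeibullFamily, build_weibull_rate
from .solver import SolverSettings, solve_recursive, solve_rk4

__all__ = [
    "FitResult",
    "rmse",
    "fit_primary_isothermal",
    "fit_secondary",
    "refine_dynamic",
    "compare_rate_variants",
]


@dataclass
class FitResult:
    """Estimates with standard errors, residuals, and the fit RMSE."""

    estimates: dict
    stderr: dict
    p: int
    residuals: np.ndarray
    rmse: float
    success: bool = True
    message: str = ""
    extra: dict = field(default_factory=dict)


def rmse(measured: SurvivalCurve, calculated: SurvivalCurve, p: int = 0) -> float:
    """Root-mean-squared prediction error in log10 units.

    The calculated curve is interpolated to the measured times (the data
    are never resampled).  ``p`` is the number of parameters estimated
    from the measured curve itself: 0 for a pure prediction, the fitted
    parameter count when scoring a fit.
    """
    me = len(measured)
    if me <= p:
        raise ValueError(f"need more points than parameters: me={me}, p={p}")
    calc = calculated.interpolate(measured.times)
    resid = measured.log10S - calc
    return float(np.sqrt(np.sum(resid**2) / (me - p)))


def _stderr_from_jac(res, n_obs: int) -> np.ndarray:
    """Asymptotic standard errors from the least-squares jacobian."""
    dof = max(n_obs - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    try:
        JtJ_inv = np.linalg.pinv(res.jac.T @ res.jac)
        return np.sqrt(np.maximum(np.diag(JtJ_inv) * s2, 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate jacobian
        return np.full(res.x.size, np.nan)


def fit_primary_isothermal(curves: dict[float, SurvivalCurve],
                           share_n: bool = True,
                           clamp_positive: bool = True) -> FitResult:
    """Fit the Weibull delta-form to isothermal curves.

    ``curves`` maps holding temperature (deg C) to its survival curve.
    With ``share_n`` (the usual case: the shape is temperature-
    independent for most organisms) a single n and one delta per
    temperature are estimated jointly; otherwise each curve gets its own
    (delta, n).  Points at t = 0 carry no information about the
    parameters and noisy slightly-positive log10S values are tolerated
    (``clamp_positive``).

    Returns estimates ``{"n": ..., "delta": {T: ...}}``.
    """
    if not curves:
        raise ValueError("no curves supplied")
    temps = sorted(curves)
    for T, c in curves.items():
        if len(c) < 2:
            raise ValueError(f"curve at {T} degC has fewer than 2 points")
    if not share_n:
        estimates, stderrs, resids, p_total = {"n": {}, "delta": {}}, {"n": {}, "delta": {}}, [], 0
        for T in temps:
            sub = fit_primary_isothermal({T: curves[T]}, share_n=True,
                                         clamp_positive=clamp_positive)
            estimates["n"][T] = sub.estimates["n"]
            estimates["delta"][T] = sub.estimates["delta"][T]
            stderrs["n"][T] = sub.stderr["n"]
            stderrs["delta"][T] = sub.stderr["delta"][T]
            resids.append(sub.residuals)
            p_total += sub.p
        resid = np.concatenate(resids)
        me = resid.size
        if me <= p_total:
            raise ValueError("fewer data points than parameters")
        return FitResult(estimates, stderrs, p_total, resid,
                         float(np.sqrt(np.sum(resid**2) / (me - p_total))))

    ts = [np.asarray(curves[T].times, float) for T in temps]
    ys = [np.asarray(curves[T].log10S, float) for T in temps]
    if clamp_positive:
        ys = [np.minimum(y, 0.0) for y in ys]
    me = sum(y.size for y in ys)
    p = 1 + len(temps)
    if me <= p:
        raise ValueError(f"fewer data points ({me}) than parameters ({p})")

    # initial guesses: n = 1, delta from the last point of each curve
    deltas0 = []
    for t, y in zip(ts, ys):
        yl = min(y[-1], -1e-6)
        deltas0.append(t[-1] / (-yl))
    x0 = np.log([1.0, *deltas0])  # optimize in log-space: positivity for free

    def resid_fn(x):
        n = math.exp(x[0])
        out = []
        for (t, y, lx) in zip(ts, ys, x[1:]):
            delta = math.exp(lx)
            with np.errstate(invalid="ignore"):
                out.append(-((t / delta) ** n) - y)
        return np.concatenate(out)

    res = least_squares(resid_fn, x0, method="lm", max_nfev=2000 * p)
    if not res.success:
        raise RuntimeError(f"isothermal fit did not converge: {res.message}")
    n_hat = math.exp(res.x[0])
    delta_hat = {T: math.exp(v) for T, v in zip(temps, res.x[1:])}
    se_log = _stderr_from_jac(res, me)
    # delta-method back-transform: se(exp(x)) = exp(x) * se(x)
    stderr = {"n": n_hat * se_log[0],
              "delta": {T: d * s for (T, d), s in zip(delta_hat.items(), se_log[1:])}}
    resid = res.fun
    return FitResult({"n": n_hat, "delta": delta_hat}, stderr, p, resid,
                     float(np.sqrt(np.sum(resid**2) / (me - p))),
                     message=res.message)


def fit_secondary(param_table, model: str, Tref: float | None = None) -> FitResult:
    """Fit a secondary model to a (temperature, parameter) table.

    ``param_table`` is a sequence of (T, value) pairs or a DataFrame with
    two columns.  ``model='bigelow'`` regresses log10 delta linearly on
    T (slope = -1/z) and reports ``delta_ref`` at the user-chosen
    reference temperature ``Tref`` (required: the reference is a free
    convention, not an estimable quantity).  ``model='log_logistic'``
    fits b(T) = ln(1 + exp(k (T - Tc))) by nonlinear least squares.
    """
    tab = np.asarray(pd.DataFrame(param_table).iloc[:, :2], dtype=float)
    T, val = tab[:, 0], tab[:, 1]
    if np.unique(T).size < 2:
        raise ValueError("need at least two distinct temperatures")
    if np.any(val <= 0):
        raise ValueError("secondary-model fits require positive parameter values")

    if model == "bigelow":
        if Tref is None:
            raise ValueError("bigelow fit requires a reference temperature Tref")
        if T.size < 2:
            raise ValueError("need at least 2 rows")
        # linear regression of log10 delta on T
        X = np.column_stack([np.ones_like(T), T])
        coef, *_ = np.linalg.lstsq(X, np.log10(val), rcond=None)
        intercept, slope = coef
        if slope >= 0:
            raise ValueError("fitted z-value is not positive: delta does not decrease with T")
        z = -1.0 / slope
        delta_ref = 10.0 ** (intercept + slope * Tref)
        fitted = delta_of_T(T, delta_ref, Tref, z)
        resid = np.log10(val) - np.log10(fitted)
        dof = max(T.size - 2, 1)
        s = math.sqrt(float(np.sum(resid**2)) / dof)
        Sxx = float(np.sum((T - T.mean()) ** 2))
        se_slope = s / math.sqrt(Sxx)
        se_z = se_slope / slope**2
        se_int = s * math.sqrt(1.0 / T.size + (Tref - T.mean()) ** 2 / Sxx)
        return FitResult(
            {"delta_ref": float(delta_ref), "Tref": float(Tref), "z": float(z)},
            {"z": float(se_z), "delta_ref": float(delta_ref * math.log(10) * se_int)},
            p=2, residuals=resid,
            rmse=float(np.sqrt(np.sum(resid**2) / dof)),
        )

    if model == "log_logistic":
        if T.size < 3:
            raise ValueError("log-logistic fit needs at least 3 rows")
        # initial guess: k from the slope of the upper half, Tc where b ~ ln 2
        order = np.argsort(T)
        Ts, bs = T[order], val[order]
        hi = slice(T.size // 2, None)
        k0 = max(float(np.polyfit(Ts[hi], bs[hi], 1)[0]), 1e-3)
        Tc0 = float(np.interp(math.log(2), bs, Ts))

        def resid_fn(x):
            k, Tc = math.exp(x[0]), x[1]
            return b_of_T(T, k, Tc) - val

        res = least_squares(resid_fn, [math.log(k0), Tc0], method="lm", max_nfev=5000)
        if not res.success:
            raise RuntimeError(f"log-logistic fit did not converge: {res.message}")
        k_hat, Tc_hat = math.exp(res.x[0]), float(res.x[1])
        se = _stderr_from_jac(res, T.size)
        dof = max(T.size - 2, 1)
        return FitResult(
            {"k": k_hat, "Tc": Tc_hat},
            {"k": k_hat * se[0], "Tc": se[1]},
            p=2, residuals=res.fun,
            rmse=float(np.sqrt(np.sum(res.fun**2) / dof)),
        )

    raise KeyError(f"unknown secondary model {model!r}")


def refine_dynamic(dynamic_curves: list[SurvivalCurve],
                   initial: dict,
                   Tref: float,
                   variant: str = "path_independent",
                   m: float = 1.0,
                   dt: float = 1e-2,
                   fit_n: bool = True) -> FitResult:
    """Refine (delta_ref, z, n) by simultaneously fitting the chosen rate
    equation to survival curves measured under dynamic conditions.

    Each curve must carry its Profile in ``condition``.  ``initial``
    supplies starting values {'delta_ref', 'z', 'n'} (typically from the
    isothermal pipeline).  The model curves are produced by the
    recursive scheme for the path-independent variant and by RK4
    otherwise, at the supplied dt.
    """
    if not dynamic_curves:
        raise ValueError("no dynamic curves supplied")
    for c in dynamic_curves:
        if not isinstance(c.condition, Profile):
            raise ValueError("each dynamic curve must carry its Profile in .condition")
    me = sum(len(c) for c in dynamic_curves)
    p = 3 if fit_n else 2
    if me <= p:
        raise ValueError("fewer data points than parameters")

    x0 = np.log([initial["delta_ref"], initial["z"], initial["n"]])
    if not fit_n:
        x0 = x0[:2]
    n_fixed = float(initial["n"])

    def predict(curve, delta_ref, z, n):
        family = WeibullFamily.from_bigelow(delta_ref, Tref, z, n)
        settings = SolverSettings(dt=dt, t_end=float(curve.times[-1]))
        if variant == "path_independent":
            sol = solve_recursive(family, curve.condition, settings)
        else:
            rate = build_weibull_rate(family, variant, m=m)
            sol = solve_rk4(rate, curve.condition, settings)
        return sol.interpolate(curve.times)

    def resid_fn(x):
        delta_ref, z = math.exp(x[0]), math.exp(x[1])
        n = math.exp(x[2]) if fit_n else n_fixed
        out = []
        for c in dynamic_curves:
            out.append(predict(c, delta_ref, z, n) - c.log10S)
        return np.concatenate(out)

    res = least_squares(resid_fn, x0, method="lm", max_nfev=200)
    if not res.success:
        raise RuntimeError(f"dynamic refinement did not converge: {res.message}")
    est = {"delta_ref": math.exp(res.x[0]), "z": math.exp(res.x[1]),
           "n": math.exp(res.x[2]) if fit_n else n_fixed, "Tref": Tref}
    se = _stderr_from_jac(res, me)
    stderr = {"delta_ref": est["delta_ref"] * se[0], "z": est["z"] * se[1]}
    if fit_n:
        stderr["n"] = est["n"] * se[2]
    resid = res.fun
    return FitResult(est, stderr, p, resid,
                     float(np.sqrt(np.sum(resid**2) / (me - p))),
                     message=res.message,
                     extra={"variant": variant, "sse": float(np.sum(resid**2))})


def compare_rate_variants(table, col_a: str | None = None,
                          col_b: str | None = None) -> int:
    """Count the conditions where rate variant A beats variant B.

    ``table`` holds one row per dynamic condition with the prediction
    RMSE of each variant; the count is of strict inequalities
    (RMSE_A < RMSE_B) — ties favour neither.  By default the first two
    numeric columns are compared.
    """
    df = pd.DataFrame(table)
    if df.empty:
        raise ValueError("empty comparison table")
    num = df.select_dtypes("number")
    if col_a is None or col_b is None:
        if num.shape[1] < 2:
            raise ValueError("need two numeric RMSE columns")
        col_a, col_b = num.columns[:2]
    a = df[col_a].astype(float).to_numpy()
    b = df[col_b].astype(float).to_numpy()
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("RMSE values must be >= 0")
    return int(np.sum(a < b))
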