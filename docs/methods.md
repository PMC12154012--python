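# Methods

## Scope and state variables

A pasteurization/sterilization process is modelled as a system whose
momentary state is `[log10 S, C]`: the log10 survival ratio of the
target microorganism plus the condition vector
`C = [T, NT…, aw]` (temperature in °C first, then any declared
nonthermal agent levels and water activity). Survival is stored and
exchanged as `log10 S` throughout; models printed in `ln S` or count
units convert at the boundary (`log10 S = ln S / ln 10 = log10(N/N0)`).
Profiles (`inactikin.profiles`) map time in minutes to `C`; only
temperature has built-in secondary laws here, but the full vector is
carried so user-supplied secondaries for other agents slot in without
interface changes.

## Primary models

`models_primary` provides algebraic constant-condition survival laws,
each with forward evaluation, analytic inverse (time at a given
survival level) and analytic slope:

* **Weibull**, in both parameterizations: `log10 S = -b t^n` and
  `log10 S = -(t/δ)^n`, linked exactly by `b = δ^-n`. `n < 1` gives
  concave-up (tailing) curves with an infinite initial slope; `n > 1`
  concave-down (shouldered) curves.
* **Chick**: `ln S = -kL t` (first-order).
* **Buckow**: n-th order `dN/dt = -kL N^nB` with closed form
  `ln S = 1/(1-nB) · ln(1 + kL N0^(nB-1) (nB-1) t)`. `nB = 1` is
  rejected: the closed form is singular there and the first-order model
  covers it.
* **Zhu–Chen**: lag/decay with residual tail. With `c = C/C0`,
  `r = Nres/N0`, `E = e^(kmax t)` the survival ratio is
  `S = (1 + c + (E-1) r) / (c + E)`. Among the candidate groupings of
  this expression, this is the one whose time derivative equals the
  printed rate equation
  `dN/dt = -kmax (N - Nres) / (1 + c e^(-kmax t))` — verified
  analytically (`dS/dt = -kmax E (1+c)(1-r)/(c+E)^2` on both routes)
  and numerically in the test suite by finite differences and by RK4
  integration. `S(0) = 1` and `S(∞) = r` follow directly.
* **Koseki**: tail-floor model
  `N = [(N0^mK - Nmin^mK) e^(-mK kmax t) + Nmin^mK]^(1/mK)`, evaluated
  internally in `N/N0` units to avoid overflow at large counts. The
  shape exponent is named `mK` to keep it distinct from the path weight
  `m` of the history-integral rate equations, which is an unrelated
  quantity.

Every inverse round-trips against its forward map to 1e-9 relative
(property-tested), which is what the path-independent construction and
the recursive solver rely on.

## Secondary models

* log-logistic rate coefficient `b(T) = ln(1 + exp(k (T - Tc)))`,
  evaluated through a guarded softplus so the linear branch is exact for
  large `k (T - Tc)`; `b(Tc) = ln 2`, `b ≈ 0` below `Tc`.
* Bigelow `δ(T) = δ_ref · 10^((Tref - T)/z)`; a `z`-degree rise shrinks
  `δ` exactly tenfold.
* constants for condition-independent parameters (typically the Weibull
  shape `n`).

The reference temperature `Tref` is a free convention, not an estimable
quantity, so it is a required user input wherever a Bigelow law appears;
worked examples and the acceptance study use 120 °C, the mid-range of
the isothermal temperatures in the bundled spore case. A
Bigelow-parameterized organism can drive the b-form machinery through
the exact conversion `b(T) = δ(T)^-n` (`DerivedBSecondary`); the two
parameterizations agree to better than 1e-10 on any grid, which is
asserted in the acceptance suite.

## Rate-equation constructions

Given a Weibull family (`b` and `n` secondaries), `rates` builds:

* `path_independent` — the unique state-only rate
  `-n b(T)^(1/n) (-log10 S)^((n-1)/n)`, i.e. `f'(f⁻¹(log10 S))` at the
  momentary condition. Its defining property: the rate at a state does
  not depend on the path that reached it.
* `derivative` — the clock-time derivative `-n b(T(t)) t^(n-1)`.
* `history_state` / `history_derivative` — the state form and the
  derivative form with `b` replaced by the history average
  `B̄(t) = (m+1) ∫₀ᵗ τ^m b(T(τ)) dτ / t^(m+1)`, `m > -1` any real
  weight. The integral is carried as one auxiliary ODE state integrated
  alongside `log10 S` (O(1) per step, error control shared with the
  main state) rather than re-quadratured each step; the carried value
  agrees with adaptive quadrature to 1e-6 in the tests.
* an optional multiplier `exp(a·dT/dt)` wrappable around any member.

At constant temperature `B̄ ≡ b` and the multiplier is 1, so every
member integrates back to the same Weibull curve — the family-collapse
property asserted to < 1e-4 log10 over six decades in the acceptance
suite. As `t → 0⁺`, `B̄ → b(T(0))` (L'Hôpital), which is the value used
at `t = 0`.

The directly-developed equations (Chick, Buckow, Zhu–Chen, Koseki) are
expressed on the count `N`, matching their printed forms; the solver
converts to `log10 S` at its boundary. Below the tail floors (Zhu–Chen
`Nres`, Koseki `Nmin`) the rate is clamped to zero. These equations
assume a constant lethal level over the run (the Zhu–Chen lag term uses
the elapsed exposure `kmax·t` directly).

No machinery is provided to *search* over `m` or otherwise optimize
within the path-dependent family: since infinitely many members fit any
constant-condition data equally well, only fixed, user-chosen variants
are exposed for comparison.

## Solvers and numerical choices

**Recursive scheme** (`solve_recursive`): from `log10 S = 0` at `t = 0`,
each step evaluates the primary model at the average condition over the
step (midpoint by default — second-order and cheap; trapezoidal
endpoint mean by flag), finds the time on that constant-condition curve
corresponding to the current survival, advances it by `dt` and
re-evaluates. At constant conditions the recursion telescopes to the
closed form exactly, for any `dt`, and it never evaluates the singular
initial slope of `n < 1` — so it is the reference scheme there.
Segments where the survival level is unreachable (e.g. `b = 0` below
`Tc`) advance with zero progress.

**RK4** (`solve_rk4`): classical fixed-step 4th order on the augmented
state, for any rate equation. Default `dt = 1e-3` min, which resolves
the fastest transients exercised here (heating rates up to 100 °C/min);
an optional convergence check halves `dt` until successive curves
differ by less than `tol` (default 1e-4 log10). `log10 S` is clamped at
0 from above; no floor is imposed by the solver — tails come from the
models.

Two right-hand-side singularities require care with `n < 1`:
`(-log10 S)^((n-1)/n)` diverges at `log10 S = 0`, and `t^(n-1)` (plus
`τ^m` with `m < 0` in the history integrand) diverges at `t = 0`.
Both are handled by the *analytic startup rule*: a step is taken by the
frozen-parameter exact update (for the state forms,
`(-log10 S)^(1/n) += B^(1/n) dt` with `B` at the step midpoint; for the
derivative forms, `Δlog10 S = -B (t1^n - t0^n)`; history integrals
advance by their frozen-`b` closed form) whenever (a) the run is within
its first 20 steps, or (b) the state is within 1e-9 of `log10 S = 0`.
The frozen-parameter update is exact at constant conditions and
second-order accurate otherwise. The window covers several steps, not
just the first, because RK4's internal stages see low-order
intermediate values of the history integral exactly where `t^(n-1)` is
steepest; with a single-step rule that interaction leaves a ~2e-4
residual at constant temperature, an order above the package's 1e-4
validation band, while the 20-step window brings the whole family suite
to ~1e-7 with no change in asymptotic order.

Cross-checks: recursive vs RK4 agree to ~2e-7 on 50→80 °C ramps at
`dt = 1e-3` (tolerances asserted: 5e-3 for `n < 1`, 1e-3 for `n ≥ 1`);
`dt`-halving differences shrink monotonically.

**Stiffness limitation.** The count-space equations can be stiff where
the local rate constant exceeds `~1/dt`: for Buckow with `nB > 1` the
initial constant is `kL N0^(nB-1)`, enormous at high inocula, and
fixed-step RK4 would need a much smaller `dt`. The validation suite
exercises the sub-first-order regime (`nB < 1`), where the rate
constant varies only ~16-fold across six decades; stiff parameter sets
need either a reduced `dt` or an implicit solver, which is out of
scope.

## Fitting

All fits are nonlinear least squares on `log10 S`
(`scipy.optimize.least_squares`, Levenberg–Marquardt), in log-parameter
space so positivity constraints come for free; standard errors are
asymptotic, from the jacobian at the optimum with the delta-method
back-transform.

* `fit_primary_isothermal`: Weibull δ-form per temperature with one
  shared shape `n` by default (the shape is temperature-independent for
  most organisms); independent per-curve `(δ, n)` by flag. Noisy
  slightly-positive `log10 S` values are clamped to 0 for fitting.
* `fit_secondary`: Bigelow as a linear regression of `log10 δ` on `T`
  (slope `= -1/z`; an increasing trend, i.e. `z ≤ 0`, is an error);
  log-logistic `b(T)` by nonlinear least squares with slope/critical-
  temperature initial guesses taken from the data.
* `refine_dynamic`: simultaneous refinement of `(δ_ref, z, n)` against
  multiple dynamic curves, the model evaluated through the solvers
  (recursive for the path-independent variant, RK4 otherwise) at a
  user-set `dt` (default 1e-2 min — refinement calls the solver inside
  the objective, so a coarser grid than prediction is used).

**RMSE** uses the `me - p` denominator, with `p = 0` by default for
pure predictions (no parameter was estimated from the scored curve) and
`p` = fitted-parameter count when scoring a fit; both are exposed, as
the convention is a reporting choice. Calculated curves are always
interpolated to the measured times, never the reverse.

`compare_rate_variants` counts strict wins between two RMSE columns;
ties favour neither. The packaged `case_study_rmse.csv` carries the 16
published dynamic heat-treatment conditions (four spore/vegetative case
studies) with the prediction RMSE of the path-independent and the
derivative rate equations as printed; the 14-of-16 headline is
recomputed from this table, not hard-coded. The underlying raw survival
measurements exist only as figures in the cited primary studies, so the
RMSE magnitudes themselves are inputs here, not reproduced outputs.

## Synthetic data

`generate_survival` produces solver-exact truth under any profile and
adds independent homoscedastic Gaussian noise on `log10 S` — the noise
model implicit in least-squares fitting of log-transformed counts.
`generate_isothermal_dataset` builds per-temperature curves whose
sampling spans the six-decade point of the true curve, with
per-temperature noise streams spawned from one seed (identical spec +
seed → identical data, byte for byte).

What the generator does *not* emulate: Poisson plating/count noise and
its heteroscedasticity, detection limits, come-up-time contamination of
"isothermal" curves, between-batch resistance variation, or sub-lethal
adaptation history. Passing recovery tests therefore show the pipeline
is correct and well-conditioned under its own assumptions, not that
real survival data meet those assumptions.

The recovery study conditions — 4 temperatures (115–130 °C), 10 points
per curve, 0.1 log10 noise, 50 replicates — with truth
`δ_ref = 1.36 min, Tref = 120 °C, z = 7.20 °C, n = 1.25` yield `z` and
`n` within 10% of truth in 100% of replicates (asserted ≥ 90%).

## Dynamic test profile

The bundled two-stage profile is `T = 25 + 100t` °C for `t ≤ 0.5` min,
then `T = 5 sin(5t) + 75` (sine in radians, time in minutes). The two
branches deliberately do **not** meet: the sine branch starts at
`5 sin(2.5) + 75 ≈ 77.99` °C, a ~2.99 °C upward jump at the switch.
The profile is kept exactly as specified, flagged as the single
discontinuous builder in the catalog, and handled without smoothing
(the solvers only ever evaluate the profile pointwise).

## Validation problem sizes

The acceptance suite integrates with `dt = 1e-3` min over six-decade
horizons: the family-collapse check covers 3 temperatures × 10 variant/
weight combinations (~354k grid points), the direct-rate check ~35k
points across the four count-space models, the divergence and
solver-agreement checks 3- and 6-minute dynamic runs, and the recovery
study 50 replicates × 40 points. The whole suite and the acceptance
script each run in seconds on one core.
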