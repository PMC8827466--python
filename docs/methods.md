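# Methods

## Model

Deaths in an age × calendar-year cell are treated as Poisson counts with the
person-years of exposure as offset: `D(x,t) ~ Poisson(E(x,t)·μ(x,t))`. The
log hazard is expanded on a rich equally-spaced B-spline basis — cubic
splines with 5-year knot spacing by default, giving
`ceil((upper−lower)/spacing) + degree` basis functions (19 over ages
31–110) — and fitted by maximizing the penalized log-likelihood

    ℓ(θ) − ½ θᵀ(λ DᵀD)θ,

where `D` is the order-2 difference operator on adjacent coefficients. In
two dimensions the basis is the tensor product of age and year bases and the
penalty is the additive anisotropic form
`λ_age·(P_age ⊗ I) + λ_year·(I ⊗ P_year)`. Each stratum (sex × occupational
class) is fitted independently with its own smoothing weights.

The optimum is found by iteratively reweighted penalized least squares
(IRLS): working weights `W = diag(μ̂E)`, update
`θ ← (BᵀWB + λP)⁻¹ BᵀWz`. Convergence is declared when the largest absolute
coefficient change falls below 1e-6, within 200 iterations; non-convergence
is flagged on the fit object and treated as failure by the λ-selector. The
start is deterministic: penalized least squares of `log((D+0.5)/(E+0.5))`
on the basis. Cells with zero exposure are dropped from the likelihood —
they carry no information under the Poisson model. A fit on all-zero death
counts is rejected outright (the log-hazard optimum would sit at −∞).

Smoothing weights are selected on a discrete grid, `log10 λ ∈ {−2,…,6}`
per dimension (81 pairs in 2D), by minimizing
`BIC = deviance + log(n)·ED`, with `n` the number of positive-exposure
cells and `ED = tr[(BᵀWB + λP)⁻¹BᵀWB]` the effective dimension. Exact BIC
ties are broken toward the larger (smoother) λ; the full BIC profile is
recorded on the returned fit. A discrete grid rather than continuous
optimization keeps runs reproducible and the profiles inspectable. Grid
scans are warm-started from the previous fit's coefficients. Note that when
the true log hazard is exactly bilinear in age and year — as in the default
synthetic scenario — BIC correctly runs into the top of the grid, since the
bilinear surface lies in the null space of both order-2 penalties and the
smoothest fit is unbiased; the grid top (λ = 10⁶) is already
indistinguishable from the λ→∞ limit at the data sizes used.

Useful analytic limits exploited by the test suite: with an order-2 penalty,
λ→∞ forces the log hazard to be linear in age (the Gompertz fit) in 1D and
bilinear in 2D; with λ = 0 and one basis function per data point the fit is
saturated and reproduces the observed counts.

## From hazard to indicators

The fitted smooth is evaluated on a fine age grid (step 0.01 years,
ages 31–110; for a 2D fit the year basis is contracted at the requested
calendar year, with no extrapolation outside the fitted age or year window).
Survival is `S(x) = exp(−∫₃₁ˣ μ)` by cumulative trapezoidal integration —
radix 1 at age 31, the first observed age, so every "proportion surviving"
is conditional on reaching 31 — and the age-at-death density is `f = μ·S`.

* **Modal age at death M**: argmax of `f` on `[floor, 110]` with the floor
  at 45 by default (safely below any plausible adult mode; excludes any
  residual young-adult mortality hump). The discrete argmax (ties broken
  toward the older age) is refined by the vertex of the parabola through the
  three surrounding grid points, giving sub-grid precision (grid-refinement
  tests show |ΔM| ≤ 0.01 between steps 0.01 and 0.005). A maximum sitting on
  the search floor or the upper grid end is returned flagged, not as a
  silent number; flagged rows propagate through the trend table and are
  excluded from gap summaries with a warning.
* **SD(M+)**: `sqrt(∫_M (x−M)² f dx / ∫_M f dx)` — dispersion of deaths
  above the mode measured about the mode itself (the Kannisto convention),
  not about the conditional mean. For a pure Gompertz hazard this depends on
  the slope `b` only, which the tests verify.
* **Conditional life expectancies** use the attained-age convention:
  `e_x = x + ∫ₓ¹¹⁰ S dt / S(x)`, so `e_75 ≥ e_65 ≥ 65` always. The domain
  end 110 is a hard truncation point for all integrals; with realistic adult
  hazards `S(110) < 1e-3`, so endpoint effects sit far below reported
  precision (the constant-hazard closed form on the truncated domain is an
  exact oracle for this choice).
* **Survivorship**: `S` interpolated linearly at any target age (including
  the off-grid fitted mode); quantile ages invert the monotone survival
  curve the same way.

Integrals over `[M, 110]` prepend an interpolated point exactly at `M`, so
the left edge of the domain is honored to first order regardless of where
`M` falls between grid points.

## Synthetic data

The generator emulates stratified register-style mortality surfaces with
Gompertz–Makeham hazards,

    μ(x,t) = c·(1−r_c)^(t−t₀) + a·(1−r)^(t−t₀)·e^{bx},

sampled as Poisson counts given per-cell exposures. A proportional annual
decline `r` in the Gompertz level moves the modal age upward by
`−ln(1−r)/b` years per calendar year — a near-linear secular rise, the
simplest mechanism with closed-form ground truth (`M = (1/b)ln(b/a_t)`
when `c = 0`, independent of the truncation age since the mode solves the
local condition `b = a_t e^{bx}`).

The default scenario has 3 occupational classes × 2 sexes over 45 years
(1971–2015), ages 31–110, pure Gompertz (`c = 0`): shared within-sex slopes
(males `b = 0.10`, females `b = 0.11`), class levels set through
`a = b·e^{−bM₀}` with reference-year modes 77/75/73.5 (males, upper/lower
non-manual/manual) and 80/79/78 (females), and improvement 1.5 %/yr (males)
and 1.3 %/yr (females). This yields true modes rising from the mid-70s into
the mid-80s, a male upper-vs-manual modal-age gap of 3.5 years, and a
survival-to-mode proportion `exp(−(1−(a_t/b)e^{31b}))` ≈ 0.37 — just below
40 % — in every stratum-year. Exposures default to an age-flat 2·10⁴
person-years per cell, set for estimability of `M` to ±0.25 years rather
than for demographic realism (an optional age-shaped profile halving above
80 is provided). The Makeham term and its own improvement rate are
supported but off by default, which keeps the closed-form mode exact.

What the generator does *not* emulate: occupational-class composition
change and reassignment, migration censoring, cohort structure, young-adult
excess mortality humps, overdispersion, and age-dependent improvement
schedules (except where tests construct them explicitly via the hazard
override). Passing tests therefore demonstrate correctness of the
estimation machinery under a clean proportional-improvement Gompertz world,
not robustness to all features of real register data.

## Robustness analyses

* **Left truncation**: the pipeline refits after truncating the age range
  at 31/35/40 and reports the largest |ΔM| per stratum-year with a pass
  flag at 0.1 years. On the default scenario the observed maximum is below
  0.01 years — the mode's location does not depend on mortality well below
  it.
* **1D vs 2D smoothing**: `M`-trends from one 2D fit versus year-by-year 1D
  fits, with fluctuation quantified as the mean squared second difference
  of each series (the simplest roughness measure; the raw series are
  reported alongside). At 10⁴ person-years per cell the 2D series is
  smoother by several orders of magnitude in every stratum while tracking
  the same trend. The 5-year-pooled 1D variant is not implemented; only
  yearly 1D fits are compared.

## Problem sizes and determinism

Default test and acceptance runs use the full 6-stratum, 45-year,
80-age scenario (a full pipeline run is ~10 s on one core: 81 λ-pairs ×
6 strata of IRLS fits with ~230 tensor coefficients). The multi-seed
parameter-recovery property uses 8 seeds of that scenario; the noisy
modal-age recovery check uses 20 replicates of single-year 1D fits at
exposure 10⁵. All randomness flows through a single integer seed via
`numpy.random.default_rng`; reruns with the same config and seed are
byte-identical.

## Known limitations

* No extrapolation beyond the fitted age/year window, no forecasting, no
  overdispersion modelling, and no decomposition of changes in `M` by age
  or cause (the mode is not a differentiable function of age-specific
  rates).
* BIC selection is per stratum on a fixed grid; refining λ between grid
  points is deliberately out of scope.
* Sharp kinks in the true log-hazard surface (e.g. an improvement schedule
  that changes slope abruptly within a 5-year knot span) are rounded by the
  cubic basis and can bias the fitted mode by a few tenths of a year; the
  scenario tests use smooth schedules, and users fitting real data with
  suspected kinks should reduce the knot spacing.
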