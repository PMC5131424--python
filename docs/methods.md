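# Methods

## The CoDe curve

`code_q` evaluates the five-term death-probability curve documented in the
README. Implementation details that matter numerically:

* Each Kannisto-type regime term is computed as `b / (e^{−b(x−M)} + b/g)`,
  which is algebraically identical to `b·e^{b(x−M)}/(1+(b/g)e^{b(x−M)})`
  but overflow-safe at both tails (it tends to `g` as x→∞ and to 0 as
  x→−∞). The adolescent term uses `scipy.special.expit`.
* The continuity constants are
  `c1 = K(−h; b1) − K(−h; b2)` and `c2 = K(0; b2) + c1 − K(0; b3)` with
  `K(t; b) = b·e^{bt}/(1+(b/g)e^{bt})`; they depend only on the slopes, h
  and g. Both vanish when the slopes coincide, collapsing the model to a
  single logistic plus the young-age and adolescent terms.
* Indicator boundaries are real-valued comparisons exactly as written
  (`x ≤ M−h`, `M−h < x ≤ M`, `x > M`); M is continuous, so with integer
  age grids the breakpoints generally fall between grid points.
* The scalar evaluation returns the raw sum, which can exceed 1 for extreme
  parameters because the old-age limit is `a + g + c2`. `code_schedule`
  clips at 1 with a `RuntimeWarning` so life tables stay valid while the
  algebra stays testable. Note the limit is approached only algebraically
  (the young-age term decays like A/x).
* `h = 30`, `g = 0.7` and hump centre 16 are shipped defaults on
  `CoDeParams`, not hard-coded: `g = 0.5` is a documented sensitivity
  setting, and `FitOptions` exposes all three.
* Validation: B, b1, b2, b3, g strictly positive; M ∈ [40, 110] with
  h < M; A and a are allowed to be exactly zero so that degenerate
  single-term curves (useful as analytic oracles) are representable.

## Life tables

Radix 1, so d(x) is directly the age-at-death density the objective uses.
Separation factors default to a(x) = 0.5 with a(0) = 0.14: the exact HMD
infant-separation rule is an external protocol that varies by protocol
version, so a simple documented constant is used and exposed rather than a
silent reimplementation. Closure policies:

* `terminal-one` — force q = 1 at the last age (closed table; Σd = 1);
* `open` — keep the last q as given; `Σd + terminal survivorship = 1`.

Model-based tables ("model-extend") evaluate the fitted curve to age 120
and close there (`model_lifetable`); this is what fitting and decomposition
use, so components carry no closure artifacts at the last observed age.
`e(x) = Σ_{y≥x} L(y) / l(x)`, with e set to 0 where l has vanished.

`empirical_mode` restricts to ages ≥ 5 by default (excluding the infant
peak) and breaks exact ties toward the older age.

## Fitting

The objective is expressed as a residual vector — each half's residuals
scaled by `1/sqrt(2·n·var)` so the sum of squares equals F — and minimised
with `scipy.optimize.least_squares` (trf, box bounds, tolerances 1e−15).
Observed variances are computed once across the fitted ages and held fixed.
The observed and model d(x) are both open-table densities
`q(x)·Π_{y<x}(1−q(y))` over the fit range (default ages 0–100), which is
identical to restricting a model-extended closed table to those ages.

* Multi-start: a data-driven heuristic start (A ≈ q(0), a ≈ median adult q,
  M ≈ adult mode of observed d, slopes 0.1) plus `n_starts − 1`
  Latin-hypercube draws within bounds (`scipy.stats.qmc`, seeded).
  Default bounds: A ∈ (1e−6, 0.5), B ∈ (0.01, 10), a ∈ (1e−8, 0.05),
  b1,b2,b3 ∈ (0.02, 0.5), M ∈ (60, 105).
* Ages with observed q = 0 are dropped from the log-q half by default
  (`zero_q_policy="drop"`); a `"floor"` at 1e−6 is available for workflows
  that need every age in both halves.
* CoDe fits require coverage up to age 90 (Siler up to 60); shorter
  schedules raise `IdentifiabilityError` rather than returning an
  underdetermined optimum.
* The Siler model is a rate model; its predictions are converted to
  probabilities via the standard q = m/(1+(1−a)m) conversion before
  scoring, so CoDe and Siler R² values for the same schedule are directly
  comparable.
* `fit_series` warm-starts each year by adding the previous year's solution
  to the start set, so a year's result is never worse than the cold
  multi-start alone; per-year failures are collected without aborting the
  series.

## Decomposition

Sequential substitution from the start-year parameters in the order
young (A, B, a) → delay (M) → middle (b1, b2) → old (b3); each component is
the e0 difference between consecutive substituted model-extended life
tables. B travels with the young group: it is a fitted parameter, and the
four groups must cover every differing parameter for the components to
telescope exactly to the model-based Δe0 (its e0 impact is small — see the
A×10 / B×10 sensitivity below). The split is path dependent — changing the
order changes components, never the total — and `average_orders=True`
averages over all 24 orders. When observed e0 values are supplied, the
difference between the observed and model-based change is reported as
`unexplained`, absorbing fit error at both endpoints.

`compression_gain` operationalises "compression around the mode" as the
integral (unit-grid sum) of the positive part of `d_end − d_shift`, where
`d_shift` is the start distribution with only M moved to the end value — a
pure shift, so the gain is exactly zero when shapes agree. No fixed age
window is imposed. The per-source split substitutes young / middle / old
groups one at a time on top of the shift-only baseline; sources interact
through the life table, so the split sums to the total only up to an
`interaction` residual, reported explicitly rather than folded in.

`delay_pace` is 10× the least-squares slope of fitted M on calendar year —
a regression pace, not an endpoint difference — and `param_sensitivity`
reports e0(modified) − e0(original) for a multiplicative tweak of one
parameter (e.g. A×10 costs several years of e0 while B×10 adds a fraction
of a year, because B sits in the denominator of the young-age term).

## Synthetic data

The generator is the package's test bed and defines what the test suite
demonstrates. Presets are parameter fixtures in realistic ranges for
post-war low-mortality countries: `early` (1950-like: q(0) ≈ 0.033,
background 2.5e−3, M = 77.8, nearly equal slopes — a single logistic fits
such years well) and `late` (2010-like: q(0) ≈ 0.0025, background 4e−4,
M = 88.3, b2 = 0.135 > b1 = 0.10, b3 = 0.115 — visible compression), with
b1 = 0.10 in both since the young-adult slope is empirically stable;
`equal_slopes` collapses the three regimes. Noise is per-age binomial death
counts at a given exposure, seeded; a series generator applies linear
per-parameter drifts, validated year by year.

What the noise model does *not* emulate: overdispersion, correlation across
ages or years, migration/denominator error, or age heaping. Passing
recovery tests therefore show the estimator is correct and well-conditioned
under sampling noise, not that real schedules are free of systematic
artifacts. Problem sizes throughout (ages 0–100, exposures 1e4–1e8,
61-year series, 10 noisy replicates) keep every experiment deterministic
and desk-scale.

## Known limitations

* Single-year period tables only; no abridged, cohort or cause-deleted
  variants.
* No standard errors or confidence intervals on fitted parameters.
* The decomposition is a substitution decomposition: component values
  depend on the substitution order (the default order is reported with the
  result), and only the total is order-invariant.
* HMD files must be supplied locally; only the 1×1 period layouts are
  parsed.
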