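# codemort

Fitting and decomposition tools for the **CoDe model**, a 10-parameter
parametric description of the full age pattern of death probabilities that
separates **delay** of mortality (the adult schedule shifting to higher
ages) from **compression** (the age-at-death distribution changing shape) —
and attributes changes in life expectancy at birth to each.

It is aimed at demographers and epidemiologists working with single-year
period mortality schedules in the Human Mortality Database (HMD) 1×1 layout,
and at anyone who needs a smooth, interpretable parameterisation of q(x)
from birth to the oldest ages.

## The model

The probability of dying between exact ages x and x+1 is the sum of five
components:

```
q(x) = A/(x + B)                                  infancy and childhood
     + a·e^(x−16) / (1 + e^(x−16))                accident hump + background
     + I(x ≤ M−h)   · K(x; b1)                    young adulthood
     + I(M−h < x ≤ M) · [K(x; b2) + c1]           late adulthood
     + I(x > M)     · [K(x; b3) + c2]             old age
```

where `K(x; b) = b·e^{b(x−M)} / (1 + (b/g)·e^{b(x−M)})` is a Kannisto-type
logistic centred on the modal age at death `M` and levelling off toward the
asymptote `g`, and `c1`, `c2` are closed-form constants that make the curve
continuous at the regime boundaries `M−h` and `M`. Defaults: `h = 30`,
`g = 0.7`, hump centre 16. Five parameters carry the time trends: `A`
(infant mortality), `a` (background mortality), `M` (delay), `b2`
(compression in late adulthood), `b3` (compression above the mode).

Parameters are estimated by minimising the variance-weighted combined MSE

```
F = ( MSE[log q]/var[log q] + MSE[d]/var[d] ) / 2  =  1 − mean R²
```

so the fit balances relative errors in death probabilities (young ages)
against absolute errors in the age-at-death density d(x) (ages around the
mode). The classical Siler rate model is included as a comparison fit.

Given fitted parameter sets for two years, `decompose_e0` attributes the
change in life expectancy at birth to sequential parameter substitution —
young (A, B, a) → delay (M) → middle (b1, b2) → old (b3) — with the four
components telescoping exactly to the model-based Δe0, and
`compression_gain` measures the extra deaths concentrated around the mode
relative to a pure shift of the start-year distribution.

## Worked example

```python
import numpy as np
from codemort import (FitOptions, NoiseSpec, decompose_e0,
                      fit_code, generate, preset)

# 1. simulate a 2010-style schedule observed in a population of 1M per age
truth = preset("late")
sched, _ = generate(truth, noise=NoiseSpec(exposure=1_000_000, seed=42))

# 2. fit the CoDe model
res = fit_code(sched, FitOptions(seed=0))
print(f"r2(log q) = {res.r2_logq:.5f}   r2(d) = {res.r2_d:.5f}")
print(f"fitted M  = {res.params.M:.2f}  (truth {truth.M})")

# 3. decompose the e0 change from a 1950-style schedule to the fit
dec = decompose_e0(preset("early"), res.params)
print(f"total e0 change   = {dec.total_model_change:6.2f} years")
print(f"  delay (M)       = {dec.delta_delay:6.2f}")
print(f"  young (A, B, a) = {dec.delta_young:6.2f}")
print(f"  middle (b1, b2) = {dec.delta_middle:6.2f}")
print(f"  old (b3)        = {dec.delta_old:6.2f}")
```

prints

```
r2(log q) = 0.99986   r2(d) = 0.99997
fitted M  = 88.29  (truth 88.3)
total e0 change   =  18.59 years
  delay (M)       =  10.07
  young (A, B, a) =   8.94
  middle (b1, b2) =  -0.29
  old (b3)        =  -0.14
```

The fit recovers the generating modal age to a hundredth of a year at this
exposure, and the decomposition says what such a 1950→2010-style transition
means: about 10 of the 18.6 years of e0 gain come from delay (the schedule
shifting right), most of the rest from lower young-age mortality, while
compression above the mode costs a small fraction of a year.

The same workflow is available from the shell:

```
codemort simulate --preset late --exposure 1e6 --seed 42 --out syn
codemort fit syn_schedule.csv --seed 0 --out fit
codemort decompose params_1950.json fit.json
```

plus `fit-series`, `lifetable` and `compare-models` subcommands; real HMD
Mx_1x1 or period life-table files (registration required, supplied locally)
are read directly by `fit`/`fit-series` with `--sex` and `--kind`.

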