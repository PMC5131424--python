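"""Synthetic mortality schedules with known CoDe truth.

Every downstream recovery test compares against the truth record shipped
with the generated data, never against published estimates.  The presets are
fixtures in the qualitative ranges seen in post-war low-mortality countries:
``early`` resembles a 1950-style schedule (high infant/background mortality,
modal age near 78, nearly equal slopes), ``late`` a 2010-style one (low
young-age mortality, modal age near 88, steeper late-adult and old-age
slopes), and ``equal_slopes`` collapses the three regimes to one logistic.

Sampling noise emulates small-population fluctuation in unsmoothed data:
death counts are drawn per age as Binomial(exposure, q(x)), independently
across ages, with a seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .model import CoDeParams, InputError, MortalitySchedule, code_schedule

PRESETS: dict[str, CoDeParams] = {
    "early": CoDeParams(A=0.02, B=0.6, a=0.0025,
                        b1=0.10, b2=0.105, b3=0.095, M=77.8),
    "late": CoDeParams(A=0.003, B=1.2, a=0.0004,
                       b1=0.10, b2=0.135, b3=0.115, M=88.3),
    "equal_slopes": CoDeParams(A=0.01, B=1.0, a=0.001,
                               b1=0.10, b2=0.10, b3=0.10, M=79.6),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Binomial sampling-noise specification.

    ``exposure`` is persons per age; ``math.inf`` (or None upstream) means
    noise-free.  ``replicates`` supports Monte-Carlo experiments that draw
    several schedules from one spec (replicate r uses seed + r).
    """

    exposure: float = math.inf
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if not self.exposure > 0:
            raise InputError(f"exposure must be positive, got {self.exposure}")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")


class GenerationError(RuntimeError):
    """Parameters drifted out of domain or produced invalid probabilities."""


def preset(name: str) -> CoDeParams:
    """Named CoDe parameter fixture: 'early', 'late' or 'equal_slopes'."""
    try:
        return PRESETS[name]
    except KeyError:
        raise InputError(f"unknown preset {name!r}; "
                         f"choose from {sorted(PRESETS)}") from None


def generate(p: CoDeParams, ages=None,
             noise: NoiseSpec | None = None) -> tuple[MortalitySchedule, dict]:
    """Generate a schedule from known parameters, with its truth record.

    Noise-free (no spec, or infinite exposure) returns the model schedule
    exactly.  Otherwise per-age death counts are Binomial(exposure, q(x))
    and the returned values are counts / exposure; identical seeds give
    identical schedules.
    """
    ages = np.arange(101) if ages is None else np.asarray(ages, dtype=int)
    truth: dict = {"params": p.to_dict()}
    base = code_schedule(ages, p)
    if noise is None or math.isinf(noise.exposure):
        truth["noise"] = None
        return base, truth

    exposure = int(round(noise.exposure))
    if exposure <= 0:
        raise GenerationError(f"exposure rounds to {exposure}")
    q = base.values
    if np.any((q < 0) | (q > 1)):
        raise GenerationError("model probabilities outside [0, 1] after clipping")
    rng = np.random.default_rng(noise.seed)
    deaths = rng.binomial(exposure, q)
    values = deaths / exposure
    truth["noise"] = {"exposure": exposure, "seed": noise.seed}
    meta = dict(base.meta)
    meta.update({"synthetic": True, "exposure": exposure, "seed": noise.seed})
    return MortalitySchedule(ages=ages, values=values,
                             value_kind="probability", meta=meta), truth


def generate_series(p0: CoDeParams, trends: Mapping[str, float],
                    years, noise: NoiseSpec | None = None
                    ) -> tuple[dict[int, MortalitySchedule], dict]:
    """Generate one schedule per year with linear parameter drifts.

    Year ``t`` (the i-th year of the sorted sequence) uses parameters
    ``p0 + i * trend`` per drifting field, validated each year; a drift that
    leaves the parameter domain raises naming the offending year.  Noisy
    years draw with seed + year index so years are independent but the
    whole series is reproducible.
    """
    years = sorted(int(y) for y in years)
    if not years:
        raise InputError("empty year sequence")
    unknown = set(trends) - set(p0.to_dict())
    if unknown:
        raise InputError(f"unknown trend parameter(s): {sorted(unknown)}")
    schedules: dict[int, MortalitySchedule] = {}
    truth: dict = {"p0": p0.to_dict(), "trends": dict(trends),
                   "years": years, "params_by_year": {}}
    for i, year in enumerate(years):
        try:
            p_t = p0.replace(**{k: getattr(p0, k) + i * v
                                for k, v in trends.items()})
        except ValueError as exc:
            raise GenerationError(
                f"year {year}: drifted parameters invalid ({exc})") from exc
        year_noise = (None if noise is None or math.isinf(noise.exposure)
                      else NoiseSpec(exposure=noise.exposure,
                                     seed=noise.seed + i,
                                     replicates=noise.replicates))
        sched, t = generate(p_t, noise=year_noise)
        sched.meta["year"] = year
        schedules[year] = sched
        truth["params_by_year"][year] = t["params"]
    if noise is not None and not math.isinf(noise.exposure):
        truth["noise"] = {"exposure": noise.exposure, "base_seed": noise.seed}
    else:
        truth["noise"] = None
    return schedules, truth
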