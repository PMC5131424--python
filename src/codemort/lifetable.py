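"""Period life-table construction from a death-probability schedule.

Given q(x) on a unit age grid the table propagates survivors l(x) from a
radix of 1, so d(x) = l(x)*q(x) is directly the age-at-death density used in
model fitting.  Person-years L(x) use the standard separation-factor
approximation L(x) = l(x+1) + a(x)*d(x), where a(x) is the average fraction
of the interval lived by those dying in it.  Remaining life expectancy is
e(x) = sum_{y >= x} L(y) / l(x).

Defaults: a(x) = 0.5 at all ages except age 0, where infant deaths cluster
early in the interval and a(0) = 0.14 is used.  Both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import InputError, MortalitySchedule

# Separation factors: mid-interval everywhere except infancy.
DEFAULT_A_FRAC = 0.5
DEFAULT_A_FRAC_AGE0 = 0.14

_CLOSURES = ("terminal-one", "open")


@dataclass
class LifeTable:
    """Complete single-year period life table with radix l(0) = 1."""

    ages: np.ndarray
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    a_frac: np.ndarray
    L: np.ndarray
    e: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def e0(self) -> float:
        """Life expectancy at the first table age (at birth if ages[0]=0)."""
        return float(self.e[0])

    @property
    def terminal_survivorship(self) -> float:
        """Survivorship just past the last table age (0 for closed tables)."""
        return float(self.l[-1] * (1.0 - self.q[-1]))


def _resolve_a_frac(ages: np.ndarray, a_frac) -> np.ndarray:
    if a_frac is None:
        out = np.full(ages.size, DEFAULT_A_FRAC)
        out[ages == 0] = DEFAULT_A_FRAC_AGE0
        return out
    a = np.asarray(a_frac, dtype=float)
    if a.ndim == 0:
        a = np.full(ages.size, float(a))
    if a.shape != ages.shape:
        raise InputError("a_frac must be a scalar or match the age grid")
    if np.any((a < 0) | (a > 1)):
        raise InputError("a_frac values must lie in [0, 1]")
    return a


def lifetable_from_q(s: MortalitySchedule, closure: str = "terminal-one",
                     a_frac=None) -> LifeTable:
    """Build a life table from a probability schedule.

    Parameters
    ----------
    s : MortalitySchedule
        Probability schedule (``value_kind == "probability"``), gap-free.
    closure : str
        ``"terminal-one"`` forces q = 1 at the last age so the table is
        closed (sum of d equals the radix); ``"open"`` keeps the final q as
        given, leaving survivorship beyond the last age unaccounted.
    a_frac : scalar or array, optional
        Separation factor(s); defaults to 0.5 with 0.14 at age 0.
    """
    if closure not in _CLOSURES:
        raise InputError(f"closure must be one of {_CLOSURES}, got {closure!r}")
    if s.value_kind != "probability":
        raise InputError("life tables require a probability schedule; "
                         "convert rates first (hmd_io.mx_to_qx)")
    if s.has_gaps:
        raise InputError("schedule has missing values; cannot build life table")
    q = s.values.copy()
    if np.any((q < 0) | (q > 1)):
        raise InputError("death probabilities must lie in [0, 1]")
    if closure == "terminal-one":
        q[-1] = 1.0

    ages = s.ages
    a = _resolve_a_frac(ages, a_frac)

    # survivors at exact age: cumulative product of survival probabilities
    l = np.empty(q.size)
    l[0] = 1.0
    if q.size > 1:
        l[1:] = np.cumprod(1.0 - q[:-1])
    d = l * q
    l_next = l * (1.0 - q)
    L = l_next + a * d
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)

    meta = dict(s.meta)
    meta["closure"] = closure
    return LifeTable(ages=ages.copy(), q=q, l=l, d=d, a_frac=a, L=L, e=e,
                     meta=meta)


def dx_from_q(s: MortalitySchedule, closure: str = "open",
              a_frac=None) -> np.ndarray:
    """Age-at-death distribution d(x) of a schedule.

    With the default ``"open"`` closure the vector sums to the radix minus
    the survivorship beyond the last age; ``"terminal-one"`` closes it so it
    sums to 1.
    """
    return lifetable_from_q(s, closure=closure, a_frac=a_frac).d


def empirical_mode(d: np.ndarray, min_age: float = 5,
                   ages: np.ndarray | None = None) -> int:
    """Adult modal age of an age-at-death distribution.

    Restricts to ages >= ``min_age`` (excluding the infant peak), returns
    the age of the maximum, breaking exact ties toward the older age.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0 or not np.any(d > 0):
        raise InputError("age-at-death distribution is empty or all zero")
    if ages is None:
        ages = np.arange(d.size)
    else:
        ages = np.asarray(ages)
    keep = ages >= min_age
    if not keep.any():
        raise InputError(f"no ages at or above min_age={min_age}")
    d_sub, ages_sub = d[keep], ages[keep]
    idx = np.flatnonzero(d_sub == d_sub.max())[-1]
    return int(ages_sub[idx])
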