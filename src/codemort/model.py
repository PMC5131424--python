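"""Parametric mortality curves: the CoDe model and the Siler comparison model.

The CoDe (Compression-and-Delay) model describes single-year-of-age death
probabilities q(x) over the full age range by five additive components:

* infant/childhood mortality, ``A / (x + B)``;
* the adolescent "accident hump" plus background mortality, a logistic
  ``a * sigmoid(x - m_hump)`` that rises sharply around ``m_hump`` (16 by
  default) and plateaus at the background level ``a``;
* three Kannisto-type logistic terms with slopes ``b1`` (young adulthood,
  ages up to ``M - h``), ``b2`` (late adulthood, ``M - h`` to ``M``) and
  ``b3`` (old age, above ``M``), each centred on the modal age at death
  ``M`` and levelling off toward the asymptote ``g``.

Only one of the three regime terms is active at any age; the level offsets
``c1`` and ``c2`` splice the regimes together so the curve is continuous at
``x = M - h`` and ``x = M``.

The Siler model is the classical three-term description of the death *rate*,
``m(x) = a1*exp(-a2*x) + c + b*exp(b*(x - M))``, used here as a comparison
model that cannot separate compression below and above the modal age.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import expit

# Shipped defaults for the three fixed CoDe constants.  They are ordinary
# parameters (overridable per instance), not hard-coded values: g = 0.5 is a
# documented sensitivity setting, for example.
DEFAULT_H = 30.0
DEFAULT_G = 0.7
DEFAULT_M_HUMP = 16.0


class ParameterDomainError(ValueError):
    """A parameter value lies outside its admissible domain."""


class InputError(ValueError):
    """Malformed input data (empty grids, non-contiguous ages, ...)."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterDomainError(msg)


@dataclass(frozen=True)
class CoDeParams:
    """The ten parameters of the CoDe death-probability curve.

    Attributes
    ----------
    A : float
        Infant-mortality level; q(0) is approximately ``A / B``.
    B : float
        Offset (years) controlling how fast childhood mortality falls.
    a : float
        Background-mortality plateau of the adolescent logistic.
    b1, b2, b3 : float
        Slopes (per year) of the logistic regime terms in young adulthood,
        late adulthood, and old age respectively.
    M : float
        Modal age at death (years); centres the three regime terms.
    h : float
        Width (years) of the late-adulthood window ``(M - h, M]``.
    g : float
        Old-age asymptote of each logistic regime term (probability).
    m_hump : float
        Centre (years) of the adolescent rise.
    """

    A: float
    B: float
    a: float
    b1: float
    b2: float
    b3: float
    M: float
    h: float = DEFAULT_H
    g: float = DEFAULT_G
    m_hump: float = DEFAULT_M_HUMP

    def __post_init__(self) -> None:
        _require(self.A >= 0, f"A must be nonnegative, got {self.A}")
        _require(self.B > 0, f"B must be strictly positive, got {self.B}")
        _require(0 <= self.a <= 1, f"a must lie in [0, 1], got {self.a}")
        for name in ("b1", "b2", "b3"):
            v = getattr(self, name)
            _require(v > 0, f"{name} must be strictly positive, got {v}")
        _require(0 < self.g <= 1, f"g must lie in (0, 1], got {self.g}")
        _require(40 <= self.M <= 110, f"M must lie in [40, 110], got {self.M}")
        _require(self.h < self.M,
                 f"h must be smaller than M (got h={self.h}, M={self.M}); "
                 "the young-adult breakpoint M - h must be a positive age")
        _require(self.h > 0, f"h must be positive, got {self.h}")

    def replace(self, **changes: float) -> "CoDeParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        """Flat mapping keyed by symbol name, suitable for JSON."""
        return {f.name: float(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CoDeParams":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ParameterDomainError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class ContinuityConstants:
    """Level offsets splicing the three regime terms into a continuous curve.

    ``c1`` is added on ``(M - h, M]``, ``c2`` on ``(M, inf)``.  Both vanish
    when the slopes collapse (c1 = 0 iff the b1/b2 terms agree at ``M - h``;
    additionally c2 = 0 when b2 = b3 as well).
    """

    c1: float
    c2: float


@dataclass(frozen=True)
class SilerParams:
    """Parameters of the Siler death-rate model
    ``m(x) = a1*exp(-a2*x) + c + b*exp(b*(x - M))``."""

    a1: float
    a2: float
    c: float
    b: float
    M: float

    def __post_init__(self) -> None:
        _require(self.a1 >= 0, f"a1 must be nonnegative, got {self.a1}")
        _require(self.a2 > 0, f"a2 must be strictly positive, got {self.a2}")
        _require(self.c >= 0, f"c must be nonnegative, got {self.c}")
        _require(self.b > 0, f"b must be strictly positive, got {self.b}")

    def replace(self, **changes: float) -> "SilerParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SilerParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class MortalitySchedule:
    """A per-age vector of death probabilities q(x) or central rates m(x).

    Ages are integers labelling one-year intervals [x, x+1), contiguous and
    strictly increasing.  ``value_kind`` is ``"probability"`` or ``"rate"``.
    NaN gaps (e.g. from missing HMD cells) are only admitted when
    ``allow_gaps=True``; downstream fitting rejects them explicitly.
    """

    ages: np.ndarray
    values: np.ndarray
    value_kind: str = "probability"
    meta: dict = field(default_factory=dict)
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.size == 0:
            raise InputError("empty age grid")
        if self.ages.shape != self.values.shape:
            raise InputError("ages and values must have the same length")
        if self.ages.size > 1 and not np.all(np.diff(self.ages) == 1):
            raise InputError("ages must be strictly increasing and unit-spaced")
        if self.value_kind not in ("probability", "rate"):
            raise InputError(f"value_kind must be 'probability' or 'rate', "
                             f"got {self.value_kind!r}")
        finite = np.isfinite(self.values)
        if not self.allow_gaps and not finite.all():
            raise InputError("schedule contains missing values; pass "
                             "allow_gaps=True to carry gaps explicitly")
        vals = self.values[finite]
        if self.value_kind == "probability":
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise InputError("probabilities must lie in [0, 1]")
        elif vals.size and vals.min() < 0:
            raise InputError("rates must be nonnegative")

    def __len__(self) -> int:
        return int(self.ages.size)

    @property
    def has_gaps(self) -> bool:
        return bool(np.isnan(self.values).any())


# ---------------------------------------------------------------------------
# CoDe curve evaluation
# ---------------------------------------------------------------------------

def _logistic_term(x: np.ndarray | float, b: float, M: float, g: float):
    """Kannisto-type regime term b*e^{b(x-M)} / (1 + (b/g)*e^{b(x-M)}).

    Evaluated as b / (e^{-b(x-M)} + b/g), which is overflow-safe at both
    tails: the term tends to g as x -> inf and to 0 as x -> -inf.
    """
    t = -b * (np.asarray(x, dtype=float) - M)
    with np.errstate(over="ignore"):
        denom = np.exp(t) + b / g
    return b / denom


def continuity_constants(p: CoDeParams) -> ContinuityConstants:
    """Closed-form level offsets c1, c2 that make the curve continuous.

    c1 equates the b1 and b2 terms at x = M - h; c2 equates the (offset) b2
    term and the b3 term at x = M.  The expressions depend only on the
    slopes, h and g — not on M.
    """
    def k(b: float, t: float) -> float:
        e = np.exp(b * t)
        return b * e / (1.0 + (b / p.g) * e)

    c1 = k(p.b1, -p.h) - k(p.b2, -p.h)
    c2 = k(p.b2, 0.0) + c1 - k(p.b3, 0.0)
    return ContinuityConstants(c1=float(c1), c2=float(c2))


def code_q(x, p: CoDeParams):
    """Evaluate the CoDe death probability q(x) at real-valued age(s) x.

    Returns the raw five-term sum (it may exceed 1 for extreme parameters;
    :func:`code_schedule` clips at schedule level).  Scalar in, scalar out.
    """
    xs = np.asarray(x, dtype=float)
    if np.any(xs < 0):
        raise ParameterDomainError("age must be nonnegative")
    cc = continuity_constants(p)

    young = p.A / (xs + p.B)
    adolescent = p.a * expit(xs - p.m_hump)

    r1 = _logistic_term(xs, p.b1, p.M, p.g)
    r2 = _logistic_term(xs, p.b2, p.M, p.g) + cc.c1
    r3 = _logistic_term(xs, p.b3, p.M, p.g) + cc.c2
    regime = np.where(xs <= p.M - p.h, r1, np.where(xs <= p.M, r2, r3))

    out = young + adolescent + regime
    if np.ndim(x) == 0:
        return float(out)
    return out


def code_schedule(ages, p: CoDeParams, meta: dict | None = None) -> MortalitySchedule:
    """Evaluate the CoDe curve on an integer age grid as a schedule.

    Values above 1 (possible for extreme parameters, since the old-age
    asymptote a + g + c2 can exceed 1) are clipped with a warning so the
    result is always a valid probability schedule.
    """
    ages = np.asarray(ages, dtype=int)
    if ages.size == 0:
        raise InputError("empty age grid")
    q = np.asarray(code_q(ages.astype(float), p), dtype=float)
    if np.any(q > 1.0):
        warnings.warn(
            f"CoDe curve exceeds 1 at {int((q > 1).sum())} age(s); "
            "clipping to 1 in the schedule", RuntimeWarning, stacklevel=2)
        q = np.minimum(q, 1.0)
    m = {"model": "code", "params": p.to_dict()}
    if meta:
        m.update(meta)
    return MortalitySchedule(ages=ages, values=q, value_kind="probability",
                             meta=m)


def asymptote(p: CoDeParams) -> float:
    """Limit of code_q(x) as x -> inf: a + g + c2."""
    return float(p.a + p.g + continuity_constants(p).c2)


def siler_m(x, s: SilerParams):
    """Evaluate the Siler death rate m(x) = a1*e^{-a2 x} + c + b*e^{b(x-M)}."""
    xs = np.asarray(x, dtype=float)
    if np.any(xs < 0):
        raise ParameterDomainError("age must be nonnegative")
    out = s.a1 * np.exp(-s.a2 * xs) + s.c + s.b * np.exp(s.b * (xs - s.M))
    if np.ndim(x) == 0:
        return float(out)
    return out
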