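"""Delay-versus-compression decomposition of life-expectancy change.

Given CoDe parameter sets fitted to a start and an end year, the change in
model-based life expectancy at birth is attributed to four parameter groups
by sequential substitution: starting from the start-year parameters, each
group is replaced in turn by its end-year values and the e0 difference
between consecutive substituted models is that group's contribution.

Groups (in the default substitution order):

* ``young``  — A, B, a: infant/childhood and background mortality;
* ``delay``  — M: a pure shift of the adult schedule;
* ``middle`` — b1, b2: compression between young adulthood and the mode;
* ``old``    — b3: compression above the modal age.

B travels with the young group so that after all four substitutions the
parameters equal the end set exactly and the components telescope to the
full model-based change.  The decomposition is path dependent (components
depend on the order; the total never does); an option to average over all
24 orders exists but is off by default.

All life tables here use "model-extend" closure: the fitted curve is
evaluated out to age 120 and the table is closed there, so components are
free of closure artifacts at the last observed age.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .lifetable import LifeTable, lifetable_from_q
from .model import CoDeParams, InputError, code_schedule

GROUPS: dict[str, tuple[str, ...]] = {
    "young": ("A", "B", "a"),
    "delay": ("M",),
    "middle": ("b1", "b2"),
    "old": ("b3",),
}
DEFAULT_ORDER: tuple[str, ...] = ("young", "delay", "middle", "old")

EXTENSION_AGE = 120


class ConfigurationError(ValueError):
    """Incompatible fixed constants between the two parameter sets."""


@dataclass
class DecompositionResult:
    """Contributions (years) of each parameter group to the e0 change."""

    e0_start: float
    e0_end_model: float
    delta_young: float
    delta_delay: float
    delta_middle: float
    delta_old: float
    order: tuple[str, ...]
    e0_obs_change: float | None = None
    unexplained: float | None = None

    @property
    def total_model_change(self) -> float:
        return self.e0_end_model - self.e0_start


def model_lifetable(p: CoDeParams, max_age: int = EXTENSION_AGE,
                    a_frac=None) -> LifeTable:
    """Life table of a CoDe curve extended to ``max_age`` and closed there."""
    import warnings

    with warnings.catch_warnings():
        # clipping near the closing age is expected for steep curves
        warnings.simplefilter("ignore", RuntimeWarning)
        s = code_schedule(np.arange(max_age + 1), p)
    return lifetable_from_q(s, closure="terminal-one", a_frac=a_frac)


def model_e0(p: CoDeParams, max_age: int = EXTENSION_AGE) -> float:
    """Model-based life expectancy at birth (model-extend closure)."""
    return model_lifetable(p, max_age).e0


def _check_constants(p_start: CoDeParams, p_end: CoDeParams) -> None:
    for name in ("h", "g", "m_hump"):
        v0, v1 = getattr(p_start, name), getattr(p_end, name)
        if v0 != v1:
            raise ConfigurationError(
                f"fixed constant {name} differs between parameter sets "
                f"({v0} vs {v1}); decomposition requires a common value")


def _substitution_path(p_start: CoDeParams, p_end: CoDeParams,
                       order: tuple[str, ...]) -> dict[str, float]:
    """e0 contribution of each group along a substitution order."""
    cur = p_start
    e_prev = model_e0(cur)
    contributions: dict[str, float] = {}
    for grp in order:
        cur = cur.replace(**{n: getattr(p_end, n) for n in GROUPS[grp]})
        e_next = model_e0(cur)
        contributions[grp] = e_next - e_prev
        e_prev = e_next
    return contributions


def decompose_e0(p_start: CoDeParams, p_end: CoDeParams,
                 obs_e0: tuple[float, float] | None = None,
                 order: tuple[str, ...] = DEFAULT_ORDER,
                 average_orders: bool = False) -> DecompositionResult:
    """Attribute the model-based e0 change to the four parameter groups.

    Parameters
    ----------
    p_start, p_end : CoDeParams
        Fitted parameter sets for the two years (same h, g, m_hump).
    obs_e0 : (float, float), optional
        Observed life expectancies; when given, the part of the observed
        change not captured by the fitted curves is reported as
        ``unexplained``.
    order : tuple of str
        Substitution sequence over the group names.
    average_orders : bool
        Average the contributions over all 24 substitution orders instead
        of using a single path (the total is order-invariant either way).
    """
    _check_constants(p_start, p_end)
    if sorted(order) != sorted(GROUPS):
        raise InputError(f"order must be a permutation of {sorted(GROUPS)}, "
                         f"got {order}")
    e0_start = model_e0(p_start)
    e0_end = model_e0(p_end)

    if average_orders:
        orders = list(itertools.permutations(GROUPS))
        acc = {g: 0.0 for g in GROUPS}
        for perm in orders:
            c = _substitution_path(p_start, p_end, perm)
            for g in GROUPS:
                acc[g] += c[g]
        contributions = {g: acc[g] / len(orders) for g in GROUPS}
    else:
        contributions = _substitution_path(p_start, p_end, tuple(order))

    obs_change = unexplained = None
    if obs_e0 is not None:
        obs_change = float(obs_e0[1]) - float(obs_e0[0])
        unexplained = obs_change - (e0_end - e0_start)

    return DecompositionResult(
        e0_start=e0_start, e0_end_model=e0_end,
        delta_young=contributions["young"],
        delta_delay=contributions["delay"],
        delta_middle=contributions["middle"],
        delta_old=contributions["old"],
        order=tuple(order), e0_obs_change=obs_change,
        unexplained=unexplained)


def delay_pace(M_series, years=None) -> float:
    """Average pace of mortality delay in years per decade.

    Ten times the least-squares slope of fitted modal age on calendar year.
    Accepts a mapping year -> M or a value array plus an explicit year axis
    (defaulting to consecutive years).
    """
    if isinstance(M_series, dict):
        years = np.array(sorted(M_series), dtype=float)
        vals = np.array([M_series[int(y)] for y in years], dtype=float)
    else:
        vals = np.asarray(M_series, dtype=float)
        years = (np.arange(vals.size, dtype=float) if years is None
                 else np.asarray(years, dtype=float))
    if vals.size < 2:
        raise InputError("delay_pace needs at least two fitted years")
    slope = np.polyfit(years, vals, 1)[0]
    return float(10.0 * slope)


def shift_only_distribution(p_start: CoDeParams, M_new: float,
                            max_age: int = EXTENSION_AGE) -> np.ndarray:
    """Age-at-death distribution after a pure shift of the modal age.

    Replaces M by ``M_new`` leaving every shape parameter unchanged, then
    returns d(x) on the grid 0..max_age (model-extend closure).  Parameter
    validation rejects shifts that break the regime ordering (M_new <= h).
    """
    shifted = p_start.replace(M=float(M_new))
    return model_lifetable(shifted, max_age).d


@dataclass
class CompressionGain:
    """Extra deaths concentrated around the mode, as a fraction of all deaths.

    ``total`` integrates the positive part of (d_end - d_shift_only); the
    per-source terms substitute one shape group at a time on top of the
    shift-only baseline and need not sum exactly to the total — the
    shortfall is the ``interaction`` residual.
    """

    total: float
    young: float
    middle: float
    old: float
    interaction: float


def compression_gain(p_start: CoDeParams, p_end: CoDeParams,
                     max_age: int = EXTENSION_AGE) -> CompressionGain:
    """Measure mortality compression net of pure delay between two fits.

    Compares the end-year distribution with the start-year distribution
    shifted to the end-year modal age without any change of shape; the
    surface between the two around the mode (positive part of the density
    difference) is the total compression gain.  The split substitutes the
    young (A, B, a), middle (b1, b2) and old (b3) groups one at a time.
    """
    _check_constants(p_start, p_end)
    d_shift = shift_only_distribution(p_start, p_end.M, max_age)
    d_end = model_lifetable(p_end, max_age).d
    total = float(np.sum(np.clip(d_end - d_shift, 0.0, None)))

    shifted = p_start.replace(M=p_end.M)
    split = {}
    for grp in ("young", "middle", "old"):
        sub = shifted.replace(**{n: getattr(p_end, n) for n in GROUPS[grp]})
        d_sub = model_lifetable(sub, max_age).d
        split[grp] = float(np.sum(np.clip(d_sub - d_shift, 0.0, None)))
    return CompressionGain(total=total, young=split["young"],
                           middle=split["middle"], old=split["old"],
                           interaction=total - sum(split.values()))


def param_sensitivity(p: CoDeParams, name: str, factor: float,
                      max_age: int = EXTENSION_AGE) -> float:
    """Change in e0 (years) when one parameter is multiplied by ``factor``.

    The modified parameter must stay inside its domain; validation raises
    otherwise.
    """
    if not hasattr(p, name):
        raise InputError(f"unknown parameter {name!r}")
    modified = p.replace(**{name: getattr(p, name) * factor})
    return model_e0(modified, max_age) - model_e0(p, max_age)
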