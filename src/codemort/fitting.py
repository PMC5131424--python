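"""Weighted least-squares estimation of CoDe and Siler parameters.

The objective balances the full age pattern: it is the average of the
variance-normalized mean squared errors of log q(x) (relative errors,
emphasising young ages) and of the age-at-death density d(x) (emphasising
ages around the mode),

    F = ( MSE[log q]/var[log q] + MSE[d]/var[d] ) / 2 ,

with variances taken across the fitted ages of the *observed* series and
held fixed during optimization.  Since R^2 = 1 - MSE/var on each half, F
equals 1 minus the average R^2, so minimizing F maximizes the mean R^2.

The minimizer is a bounded trust-region least-squares search
(scipy.optimize.least_squares) restarted from a data-driven heuristic point
plus Latin-hypercube draws; everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .hmd_io import mx_to_qx
from .lifetable import DEFAULT_A_FRAC, DEFAULT_A_FRAC_AGE0, empirical_mode
from .model import (CoDeParams, InputError, MortalitySchedule, SilerParams,
                    code_q, siler_m)


class FittingError(RuntimeError):
    """Optimizer failure or degenerate input."""


class IdentifiabilityError(FittingError):
    """The schedule does not cover enough ages to identify all terms."""


CODE_FREE = ("A", "B", "a", "b1", "b2", "b3", "M")
SILER_FREE = ("a1", "a2", "c", "b", "M")

DEFAULT_CODE_BOUNDS: dict[str, tuple[float, float]] = {
    "A": (1e-6, 0.5), "B": (0.01, 10.0), "a": (1e-8, 0.05),
    "b1": (0.02, 0.5), "b2": (0.02, 0.5), "b3": (0.02, 0.5),
    "M": (60.0, 105.0),
}
DEFAULT_SILER_BOUNDS: dict[str, tuple[float, float]] = {
    "a1": (1e-6, 1.0), "a2": (0.01, 5.0), "c": (1e-9, 0.05),
    "b": (0.02, 0.5), "M": (60.0, 105.0),
}


@dataclass(frozen=True)
class FitOptions:
    """Options controlling a fit.

    ``fixed`` maps parameter names to values held constant (the constants
    h, g, m_hump are always fixed at the given values for CoDe fits).
    ``zero_q_policy`` decides how observed q = 0 ages enter the log-q half:
    ``"drop"`` excludes them, ``"floor"`` replaces them with 1e-6.
    """

    age_range: tuple[int, int] = (0, 100)
    fixed: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 8
    seed: int = 0
    zero_q_policy: str = "drop"
    h: float = 30.0
    g: float = 0.7
    m_hump: float = 16.0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise InputError("n_starts must be >= 1")
        if self.zero_q_policy not in ("drop", "floor"):
            raise InputError("zero_q_policy must be 'drop' or 'floor'")


@dataclass
class FitResult:
    """Fitted parameters plus goodness-of-fit summary."""

    params: CoDeParams | SilerParams
    objective: float
    r2_logq: float
    r2_d: float
    r2_avg: float
    converged: bool
    n_evals: int
    start_objectives: list = field(default_factory=list)


@dataclass(frozen=True)
class _ScoreData:
    """Observed arrays and fixed weights over the fit age range."""

    ages: np.ndarray          # fitted ages (float)
    q_obs: np.ndarray
    logq_obs: np.ndarray      # log q at logq_mask ages
    logq_mask: np.ndarray     # bool over ages
    d_obs: np.ndarray
    var_logq: float
    var_d: float


def _dx_open(q: np.ndarray) -> np.ndarray:
    """Open-table age-at-death density q(x) * prod_{y<x} (1 - q(y))."""
    qc = np.clip(q, 0.0, 1.0)
    surv = np.empty_like(qc)
    surv[0] = 1.0
    if qc.size > 1:
        surv[1:] = np.cumprod(1.0 - qc[:-1])
    return qc * surv


def _prepare_observed(s: MortalitySchedule, opts: FitOptions) -> _ScoreData:
    if s.value_kind != "probability":
        a = np.full(len(s), DEFAULT_A_FRAC)
        a[s.ages == 0] = DEFAULT_A_FRAC_AGE0
        q_all = np.asarray(mx_to_qx(s.values, a))
    else:
        q_all = s.values
    lo, hi = opts.age_range
    keep = (s.ages >= lo) & (s.ages <= hi)
    ages = s.ages[keep].astype(float)
    q = q_all[keep]
    if ages.size == 0:
        raise InputError(f"no ages inside fit range {opts.age_range}")
    if np.isnan(q).any():
        bad = s.ages[keep][np.isnan(q)]
        raise InputError(f"missing values at age(s) {bad.tolist()} inside "
                         "the fit range; supply a gap-free schedule")

    if opts.zero_q_policy == "floor":
        q_for_log = np.maximum(q, 1e-6)
        logq_mask = np.ones(q.size, dtype=bool)
    else:
        logq_mask = q > 0
        q_for_log = q
    if logq_mask.sum() < 2:
        raise InputError("fewer than two positive q values in fit range")
    logq_obs = np.log(q_for_log[logq_mask])
    d_obs = _dx_open(q)

    var_logq = float(np.var(logq_obs))
    var_d = float(np.var(d_obs))
    if var_logq <= 0 or var_d <= 0:
        raise FittingError(
            "observed log q or d has zero variance across the fit range "
            "(flat schedule); the variance-weighted objective is undefined — "
            "supply a non-degenerate schedule or narrow the age range")
    return _ScoreData(ages=ages, q_obs=q, logq_obs=logq_obs,
                      logq_mask=logq_mask, d_obs=d_obs,
                      var_logq=var_logq, var_d=var_d)


def score_predictions(q_model: np.ndarray, data: _ScoreData) -> tuple[float, float, float]:
    """Score a model q-vector: (objective, r2_logq, r2_d)."""
    q_model = np.asarray(q_model, dtype=float)
    logq_m = np.log(np.maximum(q_model[data.logq_mask], 1e-300))
    mse_logq = float(np.mean((logq_m - data.logq_obs) ** 2))
    d_m = _dx_open(q_model)
    mse_d = float(np.mean((d_m - data.d_obs) ** 2))
    r2_logq = 1.0 - mse_logq / data.var_logq
    r2_d = 1.0 - mse_d / data.var_d
    obj = 0.5 * (mse_logq / data.var_logq + mse_d / data.var_d)
    return obj, r2_logq, r2_d


def objective(p: CoDeParams | SilerParams, s: MortalitySchedule,
              opts: FitOptions | None = None) -> float:
    """Weighted combined MSE of a parameter set against a schedule."""
    opts = opts or FitOptions()
    data = _prepare_observed(s, opts)
    q_model = _model_q(p, data.ages)
    return score_predictions(q_model, data)[0]


def _model_q(p: CoDeParams | SilerParams, ages: np.ndarray) -> np.ndarray:
    if isinstance(p, CoDeParams):
        return np.asarray(code_q(ages, p))
    # Siler is a rate model; score on the probability scale
    m = np.asarray(siler_m(ages, p))
    a = np.full(ages.size, DEFAULT_A_FRAC)
    a[ages == 0] = DEFAULT_A_FRAC_AGE0
    return np.asarray(mx_to_qx(m, a))


# ---------------------------------------------------------------------------
# Multi-start bounded least squares
# ---------------------------------------------------------------------------

def _residuals(q_model: np.ndarray, data: _ScoreData) -> np.ndarray:
    """Residual vector whose sum of squares equals the objective."""
    logq_m = np.log(np.maximum(q_model[data.logq_mask], 1e-300))
    n1 = data.logq_obs.size
    r1 = (logq_m - data.logq_obs) / np.sqrt(2.0 * n1 * data.var_logq)
    d_m = _dx_open(q_model)
    n2 = data.d_obs.size
    r2 = (d_m - data.d_obs) / np.sqrt(2.0 * n2 * data.var_d)
    return np.concatenate([r1, r2])


def _heuristic_start_code(data: _ScoreData, free: list[str],
                          fixed: dict[str, float]) -> dict[str, float]:
    q, ages = data.q_obs, data.ages
    start: dict[str, float] = {"B": 1.0, "b1": 0.1, "b2": 0.1, "b3": 0.1}
    start["A"] = max(float(q[0]), 1e-5)
    adult = (ages >= 25) & (ages <= 35)
    start["a"] = max(float(np.median(q[adult])) if adult.any() else 1e-4, 1e-6)
    try:
        start["M"] = float(empirical_mode(data.d_obs, min_age=40,
                                          ages=ages)) + 0.5
    except InputError:
        start["M"] = 80.0
    return start


def _heuristic_start_siler(data: _ScoreData, free: list[str],
                           fixed: dict[str, float]) -> dict[str, float]:
    q, ages = data.q_obs, data.ages
    start = {"a1": max(float(q[0]), 1e-5), "a2": 0.5, "b": 0.1}
    adult = (ages >= 25) & (ages <= 35)
    start["c"] = max(float(np.median(q[adult])) if adult.any() else 1e-4, 1e-8)
    try:
        start["M"] = float(empirical_mode(data.d_obs, min_age=40,
                                          ages=ages)) + 0.5
    except InputError:
        start["M"] = 80.0
    return start


def _run_fit(s: MortalitySchedule, opts: FitOptions, model: str,
             extra_starts: list[dict[str, float]] | None = None) -> FitResult:
    data = _prepare_observed(s, opts)
    if model == "code":
        all_names, bounds_default = CODE_FREE, DEFAULT_CODE_BOUNDS
        heuristic = _heuristic_start_code
    else:
        all_names, bounds_default = SILER_FREE, DEFAULT_SILER_BOUNDS
        heuristic = _heuristic_start_siler

    span = data.ages.max() - data.ages.min()
    if model == "code" and (data.ages.max() < 90 or span < 60):
        raise IdentifiabilityError(
            "CoDe fits need a schedule covering at least ages 0-90 so all "
            f"five terms are identified; got ages {int(data.ages.min())}-"
            f"{int(data.ages.max())}")
    if model == "siler" and (data.ages.max() < 60 or span < 30):
        raise IdentifiabilityError(
            "Siler fits need a schedule reaching at least age 60; got ages "
            f"{int(data.ages.min())}-{int(data.ages.max())}")

    fixed = dict(opts.fixed)
    free = [n for n in all_names if n not in fixed]
    if not free:
        raise InputError("all parameters fixed; nothing to fit")
    bounds = {**bounds_default, **dict(opts.bounds)}
    lb = np.array([bounds[n][0] for n in free])
    ub = np.array([bounds[n][1] for n in free])

    def make_params(x: np.ndarray):
        vals = dict(zip(free, x))
        vals.update(fixed)
        if model == "code":
            return CoDeParams(h=opts.h, g=opts.g, m_hump=opts.m_hump, **vals)
        return SilerParams(**vals)

    def resid(x: np.ndarray) -> np.ndarray:
        q_model = _model_q(make_params(x), data.ages)
        r = _residuals(q_model, data)
        return np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)

    # start points: heuristic, warm starts from caller, Latin-hypercube draws
    starts: list[np.ndarray] = []
    h0 = heuristic(data, free, fixed)
    starts.append(np.clip(np.array([h0.get(n, 0.5 * (bounds[n][0] + bounds[n][1]))
                                    for n in free]), lb, ub))
    for w in (extra_starts or []):
        starts.append(np.clip(np.array([w[n] for n in free]), lb, ub))
    n_lhs = max(opts.n_starts - 1, 0)
    if n_lhs:
        sampler = qmc.LatinHypercube(d=len(free), seed=opts.seed)
        unit = sampler.random(n_lhs)
        starts.extend(lb + unit * (ub - lb))

    best = None
    start_objs: list[float] = []
    n_evals = 0
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=4000)
        except Exception:
            continue
        n_evals += int(sol.nfev)
        obj = float(np.sum(sol.fun ** 2))
        start_objs.append(obj)
        if best is None or obj < best[1]:
            best = (sol, obj)
    if best is None:
        raise FittingError("optimizer failed from every start point")

    sol, _ = best
    params = make_params(sol.x)
    q_model = _model_q(params, data.ages)
    obj, r2_logq, r2_d = score_predictions(q_model, data)
    return FitResult(params=params, objective=obj, r2_logq=r2_logq,
                     r2_d=r2_d, r2_avg=0.5 * (r2_logq + r2_d),
                     converged=bool(sol.success), n_evals=n_evals,
                     start_objectives=start_objs)


def fit_code(s: MortalitySchedule, opts: FitOptions | None = None,
             extra_starts: list[dict[str, float]] | None = None) -> FitResult:
    """Fit the CoDe model to a probability schedule.

    Returns the best of ``opts.n_starts`` bounded local optimizations
    (heuristic start + Latin-hypercube draws), deterministic given the seed.
    """
    return _run_fit(s, opts or FitOptions(), "code", extra_starts)


def fit_siler(s: MortalitySchedule, opts: FitOptions | None = None,
              extra_starts: list[dict[str, float]] | None = None) -> FitResult:
    """Fit the Siler rate model, scored on the probability scale so CoDe
    and Siler fits to the same schedule are directly comparable."""
    return _run_fit(s, opts or FitOptions(), "siler", extra_starts)


@dataclass
class SeriesFitResult:
    """Per-year fits; failed years are isolated in ``failures``."""

    results: dict[int, FitResult]
    failures: dict[int, str]

    def param_series(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        years = np.array(sorted(self.results))
        vals = np.array([getattr(self.results[y].params, name)
                         for y in years])
        return years, vals


def fit_series(schedules: Mapping[int, MortalitySchedule],
               opts: FitOptions | None = None,
               model: str = "code") -> SeriesFitResult:
    """Fit every year of a series, warm-starting at the previous solution.

    The warm start is added on top of the cold multi-start set, so a year's
    result is never worse than the cold multi-start alone.  Per-year errors
    are collected in ``failures`` without aborting the series.
    """
    opts = opts or FitOptions()
    results: dict[int, FitResult] = {}
    failures: dict[int, str] = {}
    prev: dict[str, float] | None = None
    for year in sorted(schedules):
        extra = [prev] if prev is not None else None
        try:
            res = _run_fit(schedules[year], opts, model, extra)
        except Exception as exc:  # noqa: BLE001 - error isolation by design
            failures[year] = f"{type(exc).__name__}: {exc}"
            continue
        results[year] = res
        prev = {k: v for k, v in res.params.to_dict().items()
                if k in (CODE_FREE if model == "code" else SILER_FREE)}
    return SeriesFitResult(results=results, failures=failures)


def residual_frame(res: FitResult, s: MortalitySchedule,
                   opts: FitOptions | None = None):
    """Per-age observed/fitted values and residuals as a DataFrame."""
    import pandas as pd

    opts = opts or FitOptions()
    data = _prepare_observed(s, opts)
    q_model = _model_q(res.params, data.ages)
    return pd.DataFrame({
        "age": data.ages.astype(int),
        "q_obs": data.q_obs,
        "q_fit": q_model,
        "d_obs": data.d_obs,
        "d_fit": _dx_open(np.asarray(q_model)),
    })
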