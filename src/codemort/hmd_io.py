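"""Reading HMD-style mortality inputs and writing all package outputs.

Supports the Human Mortality Database 1x1 whitespace-delimited layout
(Mx_1x1 death rates, fltper_1x1/mltper_1x1 period life-table qx) and plain
CSV schedules.  The HMD requires registration, so files are always supplied
locally — nothing here touches the network.

Two input routes exist: (a) Mx files converted through :func:`mx_to_qx`, or
(b) qx read directly from HMD period life-table files.  Route (b) is
preferred when available since the HMD has already applied its own
infant-separation protocol.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetable import DEFAULT_A_FRAC, LifeTable
from .model import CoDeParams, InputError, MortalitySchedule, SilerParams


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""


_SEX_COLUMNS = {"female": "Female", "male": "Male", "total": "Total",
                "f": "Female", "m": "Male", "t": "Total"}


def mx_to_qx(m, a_frac=DEFAULT_A_FRAC):
    """Convert central death rates to death probabilities.

    Standard one-year interval conversion q = m / (1 + (1 - a)*m), where
    ``a`` is the average fraction of the interval lived by those dying.
    Monotone increasing in m and capped at 1 (the raw formula exceeds 1
    once a*m > 1); the terminal open interval (where q = 1 by convention)
    is the caller's responsibility.
    """
    m_arr = np.asarray(m, dtype=float)
    a_arr = np.asarray(a_frac, dtype=float)
    if np.any(m_arr[np.isfinite(m_arr)] < 0):
        raise InputError("death rates must be nonnegative")
    if np.any((a_arr < 0) | (a_arr > 1)):
        raise InputError("a_frac must lie in [0, 1]")
    q = np.minimum(m_arr / (1.0 + (1.0 - a_arr) * m_arr), 1.0)
    if np.ndim(m) == 0 and np.ndim(a_frac) == 0:
        return float(q)
    return q


def _parse_age_label(label: str) -> tuple[int, bool]:
    """Parse an HMD age label; '110+' style open intervals flag terminal."""
    label = label.strip()
    if label.endswith("+"):
        return int(label[:-1]), True
    return int(label), False


def read_hmd_1x1(path, sex: str = "total", kind: str = "rate",
                 max_age: int = 100) -> dict[int, MortalitySchedule]:
    """Read an HMD 1x1 file into one schedule per year.

    Parameters
    ----------
    path : path-like
        HMD layout: a description line, a blank line, a column-header line
        (``Year  Age  Female  Male  Total``), then whitespace-delimited rows.
    sex : str
        Which column to extract: female / male / total.
    kind : str
        ``"rate"`` for Mx files, ``"probability"`` for period life-table qx.
    max_age : int
        Truncation age (inclusive); the open 110+ interval is dropped by the
        default 0-100 window.

    Missing cells ('.') become NaN gaps; fitting rejects them with a clear
    message rather than silently interpolating.
    """
    sex_key = sex.lower()
    if sex_key not in _SEX_COLUMNS:
        raise InputError(f"unknown sex selector {sex!r}; "
                         f"use one of {sorted(set(_SEX_COLUMNS))}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path.name}: not an HMD 1x1 file (fewer than 3 lines)")
    header = lines[2].split()
    if len(header) < 3 or header[0] != "Year" or header[1] != "Age":
        raise ParseError(f"{path.name}: line 3: expected column header "
                         f"starting 'Year Age ...', got {lines[2]!r}")
    col = _SEX_COLUMNS[sex_key]
    if col not in header:
        # plain (Year, Age, value) layout: take the third column
        if len(header) == 3:
            value_idx = 2
        else:
            raise ParseError(f"{path.name}: line 3: no column {col!r} in header")
    else:
        value_idx = header.index(col)

    rows: list[tuple[int, int, bool, float]] = []
    for lineno, raw in enumerate(lines[3:], start=4):
        if not raw.strip():
            continue
        tok = raw.split()
        if len(tok) != len(header):
            raise ParseError(f"{path.name}: line {lineno}: expected "
                             f"{len(header)} fields, got {len(tok)}")
        try:
            year = int(tok[0])
            age, is_open = _parse_age_label(tok[1])
            v = tok[value_idx]
            value = float("nan") if v == "." else float(v)
        except ValueError as exc:
            raise ParseError(f"{path.name}: line {lineno}: {exc}") from None
        rows.append((year, age, is_open, value))
    if not rows:
        raise ParseError(f"{path.name}: no data rows")

    frame = pd.DataFrame(rows, columns=["year", "age", "open", "value"])
    out: dict[int, MortalitySchedule] = {}
    for year, grp in frame.groupby("year", sort=True):
        terminal_open = bool(grp["open"].any())
        grp = grp[grp["age"] <= max_age].sort_values("age")
        out[int(year)] = MortalitySchedule(
            ages=grp["age"].to_numpy(),
            values=grp["value"].to_numpy(),
            value_kind=kind,
            meta={"source": path.name, "year": int(year), "sex": sex_key,
                  "terminal_open": terminal_open},
            allow_gaps=True,
        )
    return out


def read_csv_schedule(path, kind: str | None = None,
                      meta: dict | None = None) -> MortalitySchedule:
    """Read a plain CSV schedule with columns age, value [, kind]."""
    frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}
    if "age" not in cols or "value" not in cols:
        raise ParseError(f"{Path(path).name}: need columns 'age' and 'value', "
                         f"got {list(frame.columns)}")
    if kind is None:
        kind = (str(frame[cols["kind"]].iloc[0])
                if "kind" in cols else "probability")
    return MortalitySchedule(ages=frame[cols["age"]].to_numpy(),
                             values=frame[cols["value"]].to_numpy(),
                             value_kind=kind, meta=meta or {"source": str(path)})


def write_schedule_csv(s: MortalitySchedule, path) -> None:
    pd.DataFrame({"age": s.ages, "value": s.values,
                  "kind": s.value_kind}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result serialization (round-trip safe)
# ---------------------------------------------------------------------------

_LT_COLUMNS = ["age", "q", "l", "d", "L", "e"]


def write_lifetable_csv(lt: LifeTable, path) -> None:
    """Write a life table as CSV in the documented column order."""
    pd.DataFrame({"age": lt.ages, "q": lt.q, "l": lt.l, "d": lt.d,
                  "L": lt.L, "e": lt.e}).to_csv(path, index=False)


def read_lifetable_csv(path) -> LifeTable:
    frame = pd.read_csv(path)
    missing = [c for c in _LT_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{Path(path).name}: missing life-table columns "
                         f"{missing}")
    ages = frame["age"].to_numpy(dtype=int)
    q = frame["q"].to_numpy(dtype=float)
    l = frame["l"].to_numpy(dtype=float)
    d = frame["d"].to_numpy(dtype=float)
    L = frame["L"].to_numpy(dtype=float)
    e = frame["e"].to_numpy(dtype=float)
    # reconstruct separation factors where deaths occurred
    l_next = l * (1.0 - q)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(d > 0, (L - l_next) / np.where(d > 0, d, 1.0),
                     DEFAULT_A_FRAC)
    return LifeTable(ages=ages, q=q, l=l, d=d, a_frac=a, L=L, e=e,
                     meta={"source": str(path)})


def write_params_json(p: CoDeParams | SilerParams, path) -> None:
    """Serialize parameters as a flat JSON object keyed by symbol name."""
    payload = {"kind": "code_params" if isinstance(p, CoDeParams)
               else "siler_params"}
    payload.update(p.to_dict())
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_params_json(path) -> CoDeParams | SilerParams:
    d = json.loads(Path(path).read_text())
    kind = d.pop("kind", "code_params")
    if kind == "siler_params":
        return SilerParams.from_dict(d)
    return CoDeParams.from_dict(d)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(obj, path, format: str = "json") -> None:
    """Write a FitResult, DecompositionResult or LifeTable to disk.

    JSON for result objects; life tables also support CSV.  Decomposition
    results additionally support a one-row CSV in component order
    (matching the decomposition table layout).
    """
    from .decomposition import DecompositionResult  # local: avoid cycle
    from .fitting import FitResult

    path = Path(path)
    if isinstance(obj, LifeTable):
        if format == "csv":
            write_lifetable_csv(obj, path)
            return
        payload = {"kind": "lifetable"}
        payload.update(_to_jsonable(obj))
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    if isinstance(obj, FitResult):
        payload = {"kind": "fit_result"}
        payload.update(_to_jsonable(obj))
        payload["params"] = obj.params.to_dict()
        payload["model"] = "code" if isinstance(obj.params, CoDeParams) else "siler"
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    if isinstance(obj, DecompositionResult):
        if format == "csv":
            row = {
                "total_change": obj.total_model_change,
                "delay": obj.delta_delay,
                "young": obj.delta_young,
                "middle": obj.delta_middle,
                "old": obj.delta_old,
                "unexplained": obj.unexplained,
            }
            pd.DataFrame([row]).to_csv(path, index=False)
            return
        payload = {"kind": "decomposition"}
        payload.update(_to_jsonable(obj))
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    raise InputError(f"cannot serialize object of type {type(obj).__name__}")


def read_results(path):
    """Read back a JSON result written by :func:`write_results`."""
    from .decomposition import DecompositionResult
    from .fitting import FitResult

    d = json.loads(Path(path).read_text())
    kind = d.pop("kind", None)
    if kind == "fit_result":
        model = d.pop("model", "code")
        cls = CoDeParams if model == "code" else SilerParams
        d["params"] = cls.from_dict(d["params"])
        return FitResult(**d)
    if kind == "decomposition":
        if d.get("order") is not None:
            d["order"] = tuple(d["order"])
        return DecompositionResult(**d)
    if kind == "lifetable":
        arrays = {k: np.asarray(d[k]) for k in
                  ("ages", "q", "l", "d", "a_frac", "L", "e")}
        return LifeTable(**arrays, meta=d.get("meta", {}))
    raise ParseError(f"{Path(path).name}: unknown result kind {kind!r}")
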