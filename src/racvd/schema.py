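"""Cohort CSV schema: column types, bounds and record-level invariants.

The on-disk dialect is comma-separated UTF-8 with "." decimals; an empty
cell is the single missing marker. One row per subject.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SchemaError

SEX_LEVELS = ("male", "female")
SMOKING_LEVELS = ("current", "former", "never")

# name -> (kind, lower bound, upper bound); bounds are inclusive, None = unbounded
_FLOAT = "float"
_BOOL = "bool"
_CAT = "cat"


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str
    lo: float | None = None
    hi: float | None = None
    required: bool = False  # must be non-missing in every row
    levels: tuple = ()


COLUMNS: dict[str, ColumnSpec] = {
    c.name: c
    for c in [
        ColumnSpec("id", _CAT, required=True),
        ColumnSpec("cohort_id", _CAT, required=True),
        ColumnSpec("age", _FLOAT, 16, 110, required=True),
        ColumnSpec("sex", _CAT, required=True, levels=SEX_LEVELS),
        ColumnSpec("smoking", _CAT, levels=SMOKING_LEVELS),
        ColumnSpec("sbp", _FLOAT, 50, 300),
        ColumnSpec("dbp", _FLOAT, 30, 200),
        ColumnSpec("tc", _FLOAT, 0, 20),
        ColumnSpec("hdl", _FLOAT, 0, 10),
        ColumnSpec("ldl", _FLOAT, 0, 15),
        ColumnSpec("tg", _FLOAT, 0, 30),
        ColumnSpec("tc_hdl_ratio", _FLOAT, 0, 30),
        ColumnSpec("bmi", _FLOAT, 10, 80),
        ColumnSpec("family_history_cvd", _BOOL),
        ColumnSpec("diabetes", _BOOL),
        ColumnSpec("hypertension", _BOOL),
        ColumnSpec("antihypertensive_use", _BOOL),
        ColumnSpec("lipid_lowering_use", _BOOL),
        ColumnSpec("rf_pos", _BOOL),
        ColumnSpec("acpa_pos", _BOOL),
        ColumnSpec("esr", _FLOAT, 0, 200),
        ColumnSpec("crp", _FLOAT, 0, 500),
        ColumnSpec("sjc28", _FLOAT, 0, 28),
        ColumnSpec("tjc28", _FLOAT, 0, 28),
        ColumnSpec("patient_vas", _FLOAT, 0, 100),
        ColumnSpec("physician_vas", _FLOAT, 0, 100),
        ColumnSpec("das28esr", _FLOAT, 0, 10),
        ColumnSpec("haq", _FLOAT, 0, 3),
        ColumnSpec("ra_duration", _FLOAT, 0, 90),
        ColumnSpec("dmard_use", _BOOL),
        ColumnSpec("biologic_use", _BOOL),
        ColumnSpec("steroid_use", _BOOL),
        ColumnSpec("prior_cvd", _BOOL),
        ColumnSpec("followup_time", _FLOAT, 0, None, required=True),
        ColumnSpec("cvd_event", _BOOL, required=True),
    ]
}

COLUMN_ORDER = list(COLUMNS)

#: Lipid variables imputed on the log scale.
LIPID_COLUMNS = ("tc", "hdl", "ldl", "tg")

RATIO_TOL = 1e-9


def empty_frame(n: int = 0) -> pd.DataFrame:
    """An all-missing frame with the full schema."""
    return pd.DataFrame({c: [np.nan] * n for c in COLUMN_ORDER})


def _check_bounds(df: pd.DataFrame, spec: ColumnSpec, errors: list[str]) -> None:
    col = df[spec.name]
    if spec.kind == _FLOAT:
        bad = pd.Series(False, index=df.index)
        if spec.lo is not None:
            bad |= col < spec.lo
        if spec.hi is not None:
            bad |= col > spec.hi
        if spec.name == "followup_time":
            bad |= col <= 0
        for row in df.index[bad.fillna(False)][:5]:
            errors.append(
                f"row {row}: {spec.name}={col[row]!r} outside [{spec.lo}, {spec.hi}]"
            )
    elif spec.kind == _BOOL:
        ok = col.isna() | col.isin([0, 1, 0.0, 1.0, True, False])
        for row in df.index[~ok][:5]:
            errors.append(f"row {row}: {spec.name}={col[row]!r} is not 0/1")
    elif spec.levels:
        ok = col.isna() | col.isin(spec.levels)
        for row in df.index[~ok][:5]:
            errors.append(f"row {row}: {spec.name}={col[row]!r} not in {spec.levels}")


def validate(df: pd.DataFrame, passthrough: tuple[str, ...] = ()) -> pd.DataFrame:
    """Validate and coerce a cohort frame against the schema.

    Returns a typed copy. Raises :class:`SchemaError` naming the offending
    row/column on the first violations found.
    """
    unknown = [c for c in df.columns if c not in COLUMNS and c not in passthrough]
    if unknown:
        raise SchemaError(f"unknown columns: {unknown}")
    missing_cols = [c for c, s in COLUMNS.items() if s.required and c not in df.columns]
    if missing_cols:
        raise SchemaError(f"required columns absent: {missing_cols}")

    out = df.copy()
    for name, spec in COLUMNS.items():
        if name not in out.columns:
            out[name] = np.nan
            continue
        if spec.kind in (_FLOAT, _BOOL):
            try:
                out[name] = pd.to_numeric(out[name], errors="raise")
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"column {name}: non-numeric value ({exc})") from exc

    errors: list[str] = []
    if out["id"].duplicated().any():
        dup = out["id"][out["id"].duplicated()].iloc[0]
        errors.append(f"duplicate id {dup!r}")
    for name, spec in COLUMNS.items():
        if spec.required and out[name].isna().any():
            row = out.index[out[name].isna()][0]
            errors.append(f"row {row}: required column {name} is missing")
        _check_bounds(out, spec, errors)

    both = out["tc"].notna() & out["hdl"].notna() & out["tc_hdl_ratio"].notna()
    if both.any():
        dev = (out.loc[both, "tc_hdl_ratio"] - out.loc[both, "tc"] / out.loc[both, "hdl"]).abs()
        for row in dev.index[dev > 1e-6][:5]:
            errors.append(f"row {row}: tc_hdl_ratio inconsistent with tc/hdl")

    if errors:
        raise SchemaError("; ".join(errors))
    return out[COLUMN_ORDER + [c for c in passthrough if c in out.columns]]
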