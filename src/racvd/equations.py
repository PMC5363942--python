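"""Risk calculators as data: evaluation, units, categorization.

A risk equation is a versioned YAML file carrying coefficients, transforms,
reference values, baseline survival (or Weibull parameters for the fatal-CVD
SCORE form), validity ranges and worked-example test vectors. Files carry a
checksum over their payload and their test vectors are re-evaluated at load
time, so a corrupted or mistranscribed coefficient set refuses to load.

Forms
-----
cox_baseline_survival
    risk = 1 - S0(h)^exp(lp - lp_ref), sex- or stratum-specific blocks; terms
    are expressions over subject columns (e.g. ``log(tc_mgdl)``).
score_weibull_fatal
    the two-cause (coronary / non-coronary) fatal-CVD model with Weibull age
    shape, evaluated from current age to current age + 10.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import EquationError, UnitError

CHOLESTEROL_MMOL_TO_MGDL = 38.67

RISK_BIN_EDGES = (0.0, 0.05, 0.10, 0.20, 1.0)
RISK_BIN_LABELS = ("<5%", "5-<10%", "10-<20%", ">=20%")


def convert_units(value, from_unit: str, to_unit: str):
    """Cholesterol unit conversion (mmol/L <-> mg/dL); round-trip exact to 1e-9."""
    pair = (from_unit, to_unit)
    if from_unit == to_unit:
        return value
    if pair == ("mmol/L", "mg/dL"):
        return np.multiply(value, CHOLESTEROL_MMOL_TO_MGDL)
    if pair == ("mg/dL", "mmol/L"):
        return np.divide(value, CHOLESTEROL_MMOL_TO_MGDL)
    raise UnitError(f"unsupported conversion {from_unit} -> {to_unit}")


def adjust_outcome_subset(risk, fraction: float):
    """Scale predicted risks to an outcome subset (e.g. the non-heart-failure
    fraction of a calculator's composite endpoint); proportional on the
    probability scale, capped at 1."""
    if fraction <= 0 or fraction > 1:
        raise EquationError(f"outcome fraction must be in (0, 1], got {fraction}")
    return np.minimum(np.asarray(risk, dtype=float) * fraction, 1.0)


def categorize(risk):
    """Assign 10-year risks to the <5 / 5-<10 / 10-<20 / >=20 % categories
    (left-closed bins; the last is closed on both sides)."""
    r = np.asarray(risk, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise EquationError("risks must lie in [0,1]")
    idx = np.clip(np.digitize(np.atleast_1d(r), RISK_BIN_EDGES[1:], right=False), 0, 3)
    cats = np.asarray(RISK_BIN_LABELS, dtype=object)[idx]
    return cats[0] if r.ndim == 0 else cats


# ---------------------------------------------------------------------------
# equation files


@dataclass
class RiskEquation:
    name: str
    form: str
    horizon: float
    outcome: str
    payload: dict
    source: str = ""

    @property
    def strata(self):
        return sorted(self.payload.get("strata", {}))


def _canonical_payload(doc: dict) -> str:
    return json.dumps({k: v for k, v in doc.items() if k != "checksum"},
                      sort_keys=True, default=float)


def payload_checksum(doc: dict) -> str:
    return hashlib.sha256(_canonical_payload(doc).encode()).hexdigest()


def _data_path(name: str) -> Path:
    return Path(str(resources.files("racvd").joinpath("data", f"{name}.yaml")))


def available_equations() -> list[str]:
    folder = Path(str(resources.files("racvd").joinpath("data")))
    return sorted(p.stem for p in folder.glob("*.yaml"))


def load_equation(name_or_path: str | Path, verify: bool = True) -> RiskEquation:
    """Load a shipped (by name) or external (by path) equation file, verifying
    its checksum and worked-example test vectors."""
    path = Path(name_or_path)
    if not path.exists():
        path = _data_path(str(name_or_path))
    if not path.exists():
        raise EquationError(f"no equation file {name_or_path!r}")
    doc = yaml.safe_load(path.read_text())
    for key in ("name", "form", "horizon", "outcome"):
        if key not in doc:
            raise EquationError(f"{path.name}: missing field {key!r}")
    if verify:
        stored = doc.get("checksum")
        if stored != payload_checksum(doc):
            raise EquationError(f"{path.name}: checksum mismatch (file corrupted?)")
    eq = RiskEquation(doc["name"], doc["form"], float(doc["horizon"]),
                      doc["outcome"], doc, source=doc.get("source", ""))
    if verify:
        for vec in doc.get("test_vectors", []):
            subject = pd.DataFrame([vec["subject"]])
            got = float(evaluate(eq, subject, stratum=vec.get("stratum"))[0])
            if abs(got - vec["risk"]) > vec.get("tol", 1e-4):
                raise EquationError(
                    f"{path.name}: test vector failed ({got:.5f} != {vec['risk']:.5f})"
                )
    return eq


def save_equation(doc: dict, path: str | Path) -> None:
    doc = dict(doc)
    doc["checksum"] = payload_checksum(doc)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# evaluation


def _prepare_columns(df: pd.DataFrame, unit_system: str) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for c in df.columns:
        v = df[c]
        if v.dtype == object:
            if c == "sex":
                cols["male"] = (v == "male").to_numpy(dtype=float)
            elif c == "smoking":
                cols["current_smoker"] = (v == "current").to_numpy(dtype=float)
            continue
        cols[c] = v.to_numpy(dtype=float)
    if "sex" in df.columns and "male" not in cols:
        cols["male"] = (df["sex"] == "male").to_numpy(dtype=float)
    if "smoking" in df.columns and "current_smoker" not in cols:
        cols["current_smoker"] = (df["smoking"] == "current").to_numpy(dtype=float)
    for lipid in ("tc", "hdl", "ldl"):
        if lipid in cols:
            mmol = cols[lipid] if unit_system == "mmol/L" else convert_units(
                cols[lipid], "mg/dL", "mmol/L")
            cols[lipid] = mmol
            cols[f"{lipid}_mgdl"] = convert_units(mmol, "mmol/L", "mg/dL")
    if "tc" in cols and "hdl" in cols:
        ratio = cols["tc"] / cols["hdl"]
        if "tc_hdl_ratio" in cols:
            cols["tc_hdl_ratio"] = np.where(np.isnan(cols["tc_hdl_ratio"]),
                                            ratio, cols["tc_hdl_ratio"])
        else:
            cols["tc_hdl_ratio"] = ratio
    if "age" in cols:
        cols["age10"] = cols["age"] / 10.0
    # derived design codings (log terms, per-10 scalings) for fitted-model files
    from .design import _DERIVED

    for name, fn in _DERIVED.items():
        if name in cols:
            continue
        try:
            cols[name] = np.asarray(fn(df), dtype=float)
        except (KeyError, TypeError):
            pass
    return cols


def _eval_expr(expr: str, cols: dict[str, np.ndarray], n: int) -> np.ndarray:
    env = {"log": np.log, "sqrt": np.sqrt, "__builtins__": {}}
    try:
        out = eval(expr, env, cols)  # noqa: S307 - package-shipped expressions
    except NameError as exc:
        raise EquationError(f"missing covariate for term {expr!r}: {exc}") from exc
    out = np.asarray(out, dtype=float)
    return np.broadcast_to(out, (n,)).copy() if out.ndim == 0 else out


def _check_age_range(eq: RiskEquation, cols, clamp: bool) -> dict:
    rng = eq.payload.get("age_range")
    if not rng or "age" not in cols:
        return cols
    lo, hi = rng
    age = cols["age"]
    if np.any((age < lo) | (age > hi)):
        if not clamp:
            raise EquationError(f"{eq.name}: age outside validity range [{lo}, {hi}]")
        cols = dict(cols)
        cols["age"] = np.clip(age, lo, hi)
        if "age10" in cols:
            cols["age10"] = cols["age"] / 10.0
    return cols


def _eval_cox_form(eq: RiskEquation, df: pd.DataFrame, stratum, clamp_age) -> np.ndarray:
    doc = eq.payload
    cols = _prepare_columns(df, doc.get("unit_system", "mmol/L"))
    cols = _check_age_range(eq, cols, clamp_age)
    n = len(df)
    risks = np.full(n, np.nan)

    block_by = doc.get("blocks_by", "stratum")
    if block_by == "stratum":
        if stratum is not None:
            labels = np.full(n, stratum, dtype=object)
        elif "stratum" in df.columns:
            labels = df["stratum"].to_numpy()
        else:
            raise EquationError(f"{eq.name}: stratum required (pass stratum= or a column)")
    else:  # sex-specific
        if "male" not in cols:
            raise EquationError(f"{eq.name}: sex required")
        labels = np.where(cols["male"] == 1, "male", "female")

    for label, block in doc["blocks"].items():
        mask = labels == label
        if not mask.any():
            continue
        lp = np.zeros(n)
        for term in block["terms"]:
            lp += float(term["coef"]) * _eval_expr(term["expr"], cols, n)
        s0 = float(block["baseline_survival"])
        lp_ref = float(block.get("lp_reference", 0.0))
        risks[mask] = 1.0 - s0 ** np.exp(lp[mask] - lp_ref)
    if np.isnan(risks).any():
        unknown = sorted(set(labels) - set(doc["blocks"]))
        raise EquationError(f"{eq.name}: no coefficient block for {unknown}")
    return risks


def _eval_score_form(eq: RiskEquation, df: pd.DataFrame, clamp_age) -> np.ndarray:
    doc = eq.payload
    cols = _prepare_columns(df, doc.get("unit_system", "mmol/L"))
    cols = _check_age_range(eq, cols, clamp_age)
    n = len(df)
    for req in ("age", "tc", "sbp", "current_smoker", "male"):
        if req not in cols:
            raise EquationError(f"{eq.name}: missing covariate {req!r}")
    sex_label = np.where(cols["male"] == 1, "male", "female")
    risk = np.zeros(n)
    for cause in ("chd", "non_chd"):
        pars = doc["causes"][cause]
        w = (pars["beta_chol"] * (cols["tc"] - 6.0)
             + pars["beta_sbp"] * (cols["sbp"] - 120.0)
             + pars["beta_smoker"] * cols["current_smoker"])
        alpha = np.where(sex_label == "male", pars["alpha"]["male"], pars["alpha"]["female"])
        p = np.where(sex_label == "male", pars["p"]["male"], pars["p"]["female"])

        def s0(age):
            return np.exp(-np.exp(alpha) * np.clip(age - 20.0, 0.0, None) ** p)

        s_now = s0(cols["age"]) ** np.exp(w)
        s_10 = s0(cols["age"] + 10.0) ** np.exp(w)
        risk += 1.0 - np.clip(s_10 / np.clip(s_now, 1e-300, None), 0.0, 1.0)
    return np.clip(risk, 0.0, 1.0)


def evaluate(eq: RiskEquation, subjects: pd.DataFrame, stratum: str | None = None,
             clamp_age: bool = True) -> np.ndarray:
    """Deterministic 10-year (horizon) risk for each subject row."""
    if eq.form == "cox_baseline_survival":
        return _eval_cox_form(eq, subjects, stratum, clamp_age)
    if eq.form == "score_weibull_fatal":
        return _eval_score_form(eq, subjects, clamp_age)
    raise EquationError(f"unknown functional form {eq.form!r}")
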