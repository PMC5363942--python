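"""Cohort data handling: I/O, exclusions, truncation, event rates, KM, IPW.

A cohort dataset is a pandas DataFrame in the column schema of
:mod:`racvd.schema`, wrapped together with a cohort->stratum map and
provenance metadata.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lifelines import KaplanMeierFitter
from sklearn.linear_model import LogisticRegression

from . import schema
from .exceptions import ConfigurationError, FitError, SchemaError

log = logging.getLogger(__name__)

#: Default high/low CVD-risk stratum assignment: the five centers with the
#: highest event rates form the high-risk stratum, all others the low-risk one.
HIGH_RISK_COHORTS = (
    "Netherlands/Nijmegen",
    "Netherlands/Enschede",
    "US/Olmsted",
    "US/BRASS",
    "Sweden",
)


def default_strata_map(cohort_ids) -> dict[str, str]:
    return {c: ("high" if c in HIGH_RISK_COHORTS else "low") for c in cohort_ids}


def validate_strata_map(strata: dict[str, str], cohort_ids) -> None:
    missing = [c for c in cohort_ids if c not in strata]
    if missing:
        raise ConfigurationError(f"strata map lacks cohorts: {missing}")
    labels = set(strata.values())
    if not labels <= {"high", "low"}:
        raise ConfigurationError(f"strata labels must be 'high'/'low', got {labels}")


@dataclass
class CohortDataset:
    """Subject-level data plus stratum map and provenance."""

    data: pd.DataFrame
    strata: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.strata:
            self.strata = default_strata_map(self.data["cohort_id"].unique())
        validate_strata_map(self.strata, self.data["cohort_id"].unique())

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def cohort_ids(self) -> list[str]:
        return list(pd.unique(self.data["cohort_id"]))

    def stratum_of(self) -> pd.Series:
        return self.data["cohort_id"].map(self.strata)

    def with_data(self, data: pd.DataFrame) -> "CohortDataset":
        return replace(self, data=data.reset_index(drop=True))

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = {"strata": self.strata, "provenance": self.provenance}
        path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=2))


def load_cohort(
    path: str | Path,
    passthrough: tuple[str, ...] = (),
    strata: dict[str, str] | None = None,
) -> CohortDataset:
    """Load and validate a cohort CSV (empty cell = missing)."""
    path = Path(path)
    raw = pd.read_csv(path, dtype={"id": str, "cohort_id": str})
    df = schema.validate(raw, passthrough=passthrough)
    meta = path.with_suffix(".meta.json")
    provenance = {"source": str(path)}
    if strata is None and meta.exists():
        sidecar = json.loads(meta.read_text())
        strata = sidecar.get("strata")
        provenance.update(sidecar.get("provenance", {}))
    return CohortDataset(df, strata=strata or {}, provenance=provenance)


def save_strata_map(strata: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(strata))


def load_strata_map(path: str | Path) -> dict[str, str]:
    return yaml.safe_load(Path(path).read_text())


# -- harmonization steps --------------------------------------------------

def exclude_prior_cvd(ds: CohortDataset) -> CohortDataset:
    """Drop subjects with CVD before baseline; missing flags count as no history."""
    flag = ds.data["prior_cvd"]
    n_missing = int(flag.isna().sum())
    if n_missing:
        log.warning("prior_cvd missing for %d subjects; treated as no history", n_missing)
    keep = ~(flag == 1)
    n_excluded = int((~keep).sum())
    log.info("excluded %d subjects with prior CVD", n_excluded)
    out = ds.with_data(ds.data.loc[keep])
    out.provenance = {**ds.provenance, "excluded_prior_cvd": n_excluded}
    return out


def truncate_followup(ds: CohortDataset, horizon: float = 12.0) -> CohortDataset:
    """Truncate follow-up at `horizon` years; later events become censorings.

    The boundary is closed: an event at exactly `horizon` is kept as an event.
    """
    if horizon <= 0:
        raise ConfigurationError("truncation horizon must be positive")
    df = ds.data.copy()
    late = df["followup_time"] > horizon
    df.loc[late, "cvd_event"] = 0
    df.loc[late, "followup_time"] = horizon
    return ds.with_data(df)


# -- rates and curves ------------------------------------------------------

def person_year_rate(ds: CohortDataset | pd.DataFrame, by_cohort: bool = True) -> pd.DataFrame:
    """Events, person-years and events per 100 person-years, per cohort and overall."""
    df = ds.data if isinstance(ds, CohortDataset) else ds
    if df.empty:
        raise ConfigurationError("empty dataset")

    def _one(sub: pd.DataFrame, label: str) -> dict:
        py = float(sub["followup_time"].sum())
        if py <= 0:
            raise ConfigurationError(f"zero person-years in {label}")
        ev = float(sub["cvd_event"].sum())
        return {"cohort": label, "n": len(sub), "events": ev, "person_years": py,
                "rate_per_100py": 100.0 * ev / py}

    rows = []
    if by_cohort:
        for cid, sub in df.groupby("cohort_id", sort=False):
            rows.append(_one(sub, cid))
    rows.append(_one(df, "OVERALL"))
    return pd.DataFrame(rows)


def km_curve(
    ds: CohortDataset | pd.DataFrame,
    group: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kaplan-Meier event-free probability with Greenwood CIs.

    Returns a long table (group, time, survival, ci_lower, ci_upper).
    """
    df = ds.data if isinstance(ds, CohortDataset) else ds
    if df.empty:
        raise ConfigurationError("empty dataset")
    groups = [("all", df)] if group is None else list(df.groupby(group, sort=False))
    out = []
    for label, sub in groups:
        kmf = KaplanMeierFitter(alpha=alpha)
        kmf.fit(sub["followup_time"], sub["cvd_event"])
        surv = kmf.survival_function_.iloc[:, 0]
        ci = kmf.confidence_interval_
        out.append(pd.DataFrame({
            "group": label,
            "time": surv.index.to_numpy(),
            "survival": surv.to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)


def km_risk_at(times, events, horizon: float, alpha: float = 0.05):
    """Observed risk 1 - S(horizon) by KM with Greenwood CI (risk scale)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if len(times) == 0:
        return np.nan, (np.nan, np.nan)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    s = float(kmf.survival_function_at_times(horizon).iloc[0])
    ci = kmf.confidence_interval_
    idx = ci.index.to_numpy()
    pos = np.searchsorted(idx, horizon, side="right") - 1
    if pos < 0:
        lo, hi = 1.0, 1.0
    else:
        lo, hi = float(ci.iloc[pos, 0]), float(ci.iloc[pos, 1])
    # survival CI -> risk CI (bounds swap)
    return 1.0 - s, (1.0 - hi, 1.0 - lo)


# -- IPW-adjusted rates ----------------------------------------------------

DEFAULT_IPW_ADJUSTORS = (
    "age", "sex", "sbp", "tc", "hdl", "bmi", "smoking",
    "diabetes", "hypertension", "family_history_cvd",
)


def ipw_adjusted_rates(
    ds: CohortDataset,
    adjustors: tuple[str, ...] = DEFAULT_IPW_ADJUSTORS,
) -> pd.DataFrame:
    """Per-cohort event rates adjusted for covariate differences by stabilized IPW.

    The cohort-membership model is a multinomial logit on the adjustors;
    weights are (marginal cohort probability) / (fitted membership probability).
    """
    df = ds.data
    X = pd.DataFrame(index=df.index)
    for a in adjustors:
        if a not in df.columns:
            raise SchemaError(f"unknown adjustor {a!r}")
        if a == "sex":
            X["male"] = (df["sex"] == "male").astype(float)
        elif a == "smoking":
            X["current_smoker"] = (df["smoking"] == "current").astype(float)
            X["former_smoker"] = (df["smoking"] == "former").astype(float)
        else:
            X[a] = pd.to_numeric(df[a], errors="coerce")
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ConfigurationError(
            f"adjustors must be observed or imputed for all records; missing in {bad}"
        )
    y = df["cohort_id"].to_numpy()
    Xs = (X - X.mean()) / X.std(ddof=0).replace(0, 1.0)
    model = LogisticRegression(max_iter=2000, C=1e6)
    try:
        model.fit(Xs.to_numpy(), y)
    except Exception as exc:  # pragma: no cover - sklearn failure path
        raise FitError(f"cohort membership model failed ({exc}); reduce adjustors") from exc
    proba = model.predict_proba(Xs.to_numpy())
    if np.any(proba.max(axis=0) > 1 - 1e-10):
        raise FitError("separation in membership model; reduce the adjustor list")
    cols = {c: i for i, c in enumerate(model.classes_)}
    p_own = proba[np.arange(len(df)), [cols[c] for c in y]]
    marginal = df["cohort_id"].value_counts(normalize=True)
    w = marginal.loc[y].to_numpy() / np.clip(p_own, 1e-12, None)

    rows = []
    for cid, sub in df.groupby("cohort_id", sort=False):
        wi = w[df["cohort_id"].to_numpy() == cid]
        ev = float(np.sum(wi * sub["cvd_event"].to_numpy(dtype=float)))
        py = float(np.sum(wi * sub["followup_time"].to_numpy(dtype=float)))
        crude = person_year_rate(sub, by_cohort=False)
        rows.append({
            "cohort": cid, "n": len(sub), "weight_sum": float(wi.sum()),
            "rate_per_100py": float(crude.loc[0, "rate_per_100py"]),
            "adjusted_rate_per_100py": 100.0 * ev / py,
        })
    return pd.DataFrame(rows)
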