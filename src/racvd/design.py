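"""Model design columns and the published reference profile.

Model covariates are named by their design transform, never by raw column:
``age10`` is age in decades (the age coefficient is per 10 years, and the
scaling is explicit everywhere), ``male``/``current_smoker`` are indicator
codings of the categorical schema columns, ``esr10``/``crp10``/``*_vas10``/
``ra_duration10`` are per-10-unit codings of RA characteristics, and
``log_*`` are natural-log codings.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SchemaError

#: Covariate profile at which linear predictors are centered, so that the
#: baseline survival is published on the same scale as the fitted models
#: (age 55.3 y, female, non-smoker, normotensive, TC:HDL 2.17, DAS28ESR 4.0,
#: HAQ 0.73). Expressed in design units (age10 = age / 10).
REFERENCE_PROFILE: dict[str, float] = {
    "age10": 5.53,
    "male": 0.0,
    "current_smoker": 0.0,
    "hypertension": 0.0,
    "tc_hdl_ratio": 2.17,
    "das28esr": 4.0,
    "haq": 0.73,
}

def _ratio(d):
    computed = d["tc"] / d["hdl"] if "tc" in d.columns and "hdl" in d.columns else None
    if "tc_hdl_ratio" in d.columns:
        stored = pd.to_numeric(d["tc_hdl_ratio"], errors="coerce")
        return stored.fillna(computed) if computed is not None else stored
    return computed


_DERIVED = {
    "age10": lambda d: d["age"] / 10.0,
    "tc_hdl_ratio": _ratio,
    "male": lambda d: (d["sex"] == "male").astype(float).where(d["sex"].notna()),
    "current_smoker": lambda d: (d["smoking"] == "current").astype(float).where(d["smoking"].notna()),
    "ever_smoker": lambda d: d["smoking"].isin(["current", "former"]).astype(float).where(d["smoking"].notna()),
    "log_sbp": lambda d: np.log(d["sbp"]),
    "log_dbp": lambda d: np.log(d["dbp"]),
    "log_esr": lambda d: np.log(d["esr"].clip(lower=1.0)),
    "log_crp": lambda d: np.log(d["crp"].clip(lower=0.1)),
    "esr10": lambda d: d["esr"] / 10.0,
    "crp10": lambda d: d["crp"] / 10.0,
    "patient_vas10": lambda d: d["patient_vas"] / 10.0,
    "physician_vas10": lambda d: d["physician_vas"] / 10.0,
    "ra_duration10": lambda d: d["ra_duration"] / 10.0,
    "rf_or_acpa": lambda d: ((d["rf_pos"] == 1) | (d["acpa_pos"] == 1)).astype(float).where(
        d["rf_pos"].notna() | d["acpa_pos"].notna()
    ),
}

#: Raw schema column each derived design column depends on (for missingness
#: bookkeeping: a design column is observed iff its source columns are).
DESIGN_SOURCES: dict[str, tuple[str, ...]] = {
    "age10": ("age",),
    "male": ("sex",),
    "current_smoker": ("smoking",),
    "ever_smoker": ("smoking",),
    "log_sbp": ("sbp",),
    "log_dbp": ("dbp",),
    "log_esr": ("esr",),
    "log_crp": ("crp",),
    "esr10": ("esr",),
    "crp10": ("crp",),
    "patient_vas10": ("patient_vas",),
    "physician_vas10": ("physician_vas",),
    "ra_duration10": ("ra_duration",),
    "rf_or_acpa": ("rf_pos", "acpa_pos"),
}


def source_columns(covariate: str) -> tuple[str, ...]:
    return DESIGN_SOURCES.get(covariate, (covariate,))


#: The CVD risk-factor candidate list entered into penalized selection.
CANDIDATE_COVARIATES = (
    "age10", "male", "current_smoker", "ever_smoker",
    "sbp", "dbp", "log_sbp", "log_dbp",
    "tc", "hdl", "ldl", "tg", "tc_hdl_ratio",
    "bmi", "family_history_cvd", "diabetes", "hypertension",
    "antihypertensive_use", "lipid_lowering_use",
)

#: Base CVD adjustor set of the final calculators.
BASE_COVARIATES = ("age10", "male", "current_smoker", "hypertension", "tc_hdl_ratio")


def design_matrix(
    df: pd.DataFrame,
    covariates,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Build the numeric design matrix for the named model covariates."""
    out = pd.DataFrame(index=df.index)
    absent = []
    for name in covariates:
        if name in _DERIVED:
            try:
                out[name] = _DERIVED[name](df)
            except KeyError:
                absent.append(name)
        elif name in df.columns:
            out[name] = pd.to_numeric(df[name], errors="coerce")
        else:
            absent.append(name)
    if absent:
        raise SchemaError(f"missing covariate columns: {absent}")
    if not allow_missing and out.isna().any().any():
        bad = list(out.columns[out.isna().any()])
        raise SchemaError(f"covariates contain missing values: {bad}")
    return out


def center_reference(covariates, reference: dict[str, float] | None = None) -> pd.Series:
    """Reference values (0 where the profile does not name the covariate)."""
    ref = dict(REFERENCE_PROFILE)
    if reference:
        ref.update(reference)
    return pd.Series({c: float(ref.get(c, 0.0)) for c in covariates})
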