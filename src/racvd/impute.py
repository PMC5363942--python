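"""Multiple imputation with log-scale lipid handling and Rubin pooling.

Chained equations are delegated to statsmodels' MICE (predictive mean
matching per variable) on a numeric working frame. Lipids (TC, HDL, LDL,
triglycerides) enter the chains on the natural-log scale and are
back-transformed, so imputed values are strictly positive; the TC:HDL ratio
is recomputed from completed TC and HDL, never imputed directly. The event
indicator and follow-up time are always included as predictors.

Variables missing for an entire cohort (block-missing RA characteristics)
are not imputed by default: their chained draws for unmeasured centers are
re-masked, so downstream models using them are fitted on the centers that
measured them.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.imputation.mice import MICEData

from .cohort import CohortDataset
from .exceptions import ConfigurationError, FitError

log = logging.getLogger(__name__)

#: Variables entered into the chained equations (working-frame names).
_CONTINUOUS = ["age", "sbp", "dbp", "bmi", "log_tc", "log_hdl", "log_ldl", "log_tg",
               "esr", "crp", "sjc28", "tjc28", "patient_vas", "physician_vas",
               "das28esr", "haq", "ra_duration"]
_BINARY = ["male", "current_smoker", "ever_smoker", "family_history_cvd", "diabetes",
           "hypertension", "antihypertensive_use", "lipid_lowering_use",
           "rf_pos", "acpa_pos", "dmard_use", "biologic_use", "steroid_use"]


@dataclass
class ImputationSet:
    """m completed datasets plus bookkeeping."""

    datasets: list[pd.DataFrame]
    methods: dict[str, str]
    seed: int
    block_missing: dict[str, list[str]] = field(default_factory=dict)  # var -> cohorts
    strata: dict[str, str] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def save(self, outdir) -> None:
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets):
            df.to_csv(outdir / f"imputed_{i:02d}.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps({
            "m": self.m, "seed": self.seed, "methods": self.methods,
            "block_missing": self.block_missing,
        }, indent=2))


def _working_frame(df: pd.DataFrame) -> pd.DataFrame:
    w = pd.DataFrame(index=df.index)
    w["male"] = (df["sex"] == "male").astype(float).where(df["sex"].notna())
    w["current_smoker"] = (df["smoking"] == "current").astype(float).where(df["smoking"].notna())
    w["ever_smoker"] = df["smoking"].isin(["current", "former"]).astype(float).where(df["smoking"].notna())
    for c in _CONTINUOUS:
        if c.startswith("log_"):
            src = c[4:]
            w[c] = np.log(pd.to_numeric(df[src], errors="coerce").clip(lower=1e-3))
        else:
            w[c] = pd.to_numeric(df[c], errors="coerce")
    for c in _BINARY:
        if c in w.columns:
            continue
        w[c] = pd.to_numeric(df[c], errors="coerce")
    w["cvd_event"] = pd.to_numeric(df["cvd_event"], errors="coerce")
    w["followup_time"] = pd.to_numeric(df["followup_time"], errors="coerce")
    for i, cid in enumerate(sorted(df["cohort_id"].unique())[:-1]):
        w[f"cohort_{i}"] = (df["cohort_id"] == cid).astype(float)
    return w


def _apply_completed(df: pd.DataFrame, completed: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    sex_missing = out["sex"].isna()
    if sex_missing.any():
        out.loc[sex_missing, "sex"] = np.where(
            completed.loc[sex_missing, "male"] > 0.5, "male", "female")
    smoking_missing = out["smoking"].isna()
    if smoking_missing.any():
        cur = completed.loc[smoking_missing, "current_smoker"] > 0.5
        ever = completed.loc[smoking_missing, "ever_smoker"] > 0.5
        out.loc[smoking_missing, "smoking"] = np.where(cur, "current",
                                                       np.where(ever, "former", "never"))
    for c in _CONTINUOUS:
        src = c[4:] if c.startswith("log_") else c
        vals = np.exp(completed[c]) if c.startswith("log_") else completed[c]
        mask = out[src].isna()
        out.loc[mask, src] = vals[mask]
    for c in _BINARY:
        if c in ("male", "current_smoker", "ever_smoker"):
            continue
        mask = out[c].isna()
        out.loc[mask, c] = (completed.loc[mask, c] > 0.5).astype(float)
    out["tc_hdl_ratio"] = out["tc"] / out["hdl"]
    return out


def find_block_missing(df: pd.DataFrame) -> dict[str, list[str]]:
    """Variables that are missing for every subject of at least one cohort."""
    blocks: dict[str, list[str]] = {}
    for var in df.columns:
        if var in ("id", "cohort_id"):
            continue
        frac = df[var].isna().groupby(df["cohort_id"]).mean()
        cohorts = sorted(frac.index[frac >= 1.0])
        if cohorts:
            blocks[var] = cohorts
    return blocks


def impute(
    ds: CohortDataset | pd.DataFrame,
    m: int = 10,
    n_iter: int = 10,
    seed: int = 0,
    impute_block_missing: bool = False,
    k_pmm: int = 20,
) -> ImputationSet:
    """Multiple imputation by chained equations; deterministic under `seed`.

    Fully missing non-block variables raise; block-missing variables are
    imputed only when `impute_block_missing` is set, otherwise left missing
    for the unmeasured cohorts and flagged in the result.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    df = ds.data if isinstance(ds, CohortDataset) else ds
    strata = ds.strata if isinstance(ds, CohortDataset) else {}
    blocks = find_block_missing(df)
    for var, cohorts in blocks.items():
        if len(cohorts) == len(df["cohort_id"].unique()):
            raise FitError(f"{var} is missing for 100% of records and not block-declared")
        log.info("block-missing: %s absent in %s", var, cohorts)

    work = _working_frame(df)
    methods = {c: "pmm" for c in work.columns if work[c].isna().any()}
    if not methods:  # nothing to do: m identical copies
        return ImputationSet([df.copy() for _ in range(m)], {}, seed,
                             block_missing=blocks, strata=strata)

    datasets = []
    for i in range(m):
        np.random.seed((seed + 7919 * i) % (2**31 - 1))
        mdata = MICEData(work.copy(), perturbation_method="gaussian", k_pmm=k_pmm)
        with warnings.catch_warnings():
            # parameter-perturbation draws can hit near-singular covariances;
            # PMM only uses the resulting predictions for donor matching
            warnings.simplefilter("ignore", RuntimeWarning)
            mdata.update_all(n_iter)
        completed = mdata.data
        out = _apply_completed(df, completed)
        if not impute_block_missing:
            for var, cohorts in blocks.items():
                out.loc[out["cohort_id"].isin(cohorts), var] = np.nan
            out["tc_hdl_ratio"] = out["tc"] / out["hdl"]
        datasets.append(out)
    return ImputationSet(datasets, methods, seed, block_missing=blocks, strata=strata)


# ---------------------------------------------------------------------------
# Rubin pooling


@dataclass
class PooledEstimate:
    """Rubin-pooled coefficients with variance decomposition."""

    params: pd.Series
    within: pd.Series
    between: pd.Series
    total_var: pd.Series
    df: pd.Series
    m: int

    @property
    def se(self) -> pd.Series:
        return np.sqrt(self.total_var)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = pd.Series(stats.t.ppf(1 - alpha / 2, self.df), index=self.params.index)
        return pd.DataFrame({
            "lower": self.params - tcrit * self.se,
            "upper": self.params + tcrit * self.se,
        })

    def p_values(self) -> pd.Series:
        tval = self.params / self.se
        return pd.Series(2 * stats.t.sf(np.abs(tval), self.df), index=self.params.index)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame({
            "coef": self.params, "se": self.se, "hr": np.exp(self.params),
            "hr_ci_lower": np.exp(ci["lower"]), "hr_ci_upper": np.exp(ci["upper"]),
            "p": self.p_values(), "df": self.df,
        })


def rubin_pool(estimates, variances=None, df_com: float | None = None) -> PooledEstimate:
    """Pool per-imputation estimates by Rubin's rules.

    Parameters
    ----------
    estimates : list of pd.Series (aligned names), or list of (params, cov) pairs
    variances : list of pd.Series of squared standard errors, if not passing pairs
    df_com : complete-data degrees of freedom for the Barnard-Rubin adjustment
        (None = large-sample limit).
    """
    if variances is None:
        pairs = estimates
        estimates = [p for p, _ in pairs]
        variances = [
            pd.Series(np.diag(c), index=p.index) if isinstance(c, pd.DataFrame) else c
            for p, c in pairs
        ]
    m = len(estimates)
    if m < 2:
        raise ConfigurationError("Rubin pooling needs m >= 2")
    names = list(estimates[0].index)
    for e in estimates[1:]:
        if list(e.index) != names:
            raise ConfigurationError("mismatched coefficient names across imputations")
    Q = pd.concat(estimates, axis=1)
    U = pd.concat(variances, axis=1)
    qbar = Q.mean(axis=1)
    within = U.mean(axis=1)
    between = Q.var(axis=1, ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    # Rubin's large-sample df, with the Barnard-Rubin small-sample adjustment
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * between / within
        df_old = (m - 1) * (1.0 + 1.0 / r) ** 2  # r = 0 -> infinite df
        if df_com is not None:
            lam = (1.0 + 1.0 / m) * between / total
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
            df_final = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df_final = df_old
    df_final = df_final.clip(upper=1e12).replace(np.inf, 1e12)
    return PooledEstimate(qbar, within, between, total, df_final, m)
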