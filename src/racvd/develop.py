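"""Risk-calculator development: base model selection, one-by-one RA
characteristics, and finalization of the DAS28ESR and HAQ calculators.

The development sequence mirrors multi-center practice: LASSO-penalized
stratified Cox selection of traditional CVD risk factors on each imputed
dataset (majority set across imputations), then each RA disease
characteristic assessed one at a time on top of the selected CVD adjustors —
fitted on the centers that measured it — and finally two calculators (base +
DAS28ESR, base + HAQ) refitted and Rubin-pooled with per-stratum 10-year
baseline survival.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import StepFunction, StratifiedCoxModel
from .design import BASE_COVARIATES, CANDIDATE_COVARIATES, center_reference, source_columns
from .exceptions import FitError
from .impute import ImputationSet, PooledEstimate, rubin_pool
from .lasso import CoxLassoModel

log = logging.getLogger(__name__)

#: RA characteristics assessed one-by-one, with their unit conventions
#: (per-10-unit codings for ESR, CRP, the global VAS scales and disease
#: duration; log codings for the skewed inflammatory markers).
RA_CHARACTERISTICS = (
    ("rf_pos", "linear"),
    ("acpa_pos", "linear"),
    ("rf_or_acpa", "linear"),
    ("esr10", "per 10 mm/hr"),
    ("log_esr", "log-transformed"),
    ("crp10", "per 10 mg/L"),
    ("log_crp", "log-transformed"),
    ("das28esr", "linear"),
    ("sjc28", "linear"),
    ("tjc28", "linear"),
    ("patient_vas10", "per 10 mm"),
    ("physician_vas10", "per 10 mm"),
    ("ra_duration10", "per 10 years"),
    ("haq", "linear"),
)


def _with_stratum(df: pd.DataFrame, strata: dict) -> pd.DataFrame:
    if "stratum" in df.columns:
        return df
    out = df.copy()
    out["stratum"] = out["cohort_id"].map(strata)
    return out


@dataclass
class PooledCoxModel:
    """Rubin-pooled stratified Cox calculator with published-scale baseline."""

    covariates: list[str]
    pooled: PooledEstimate
    reference: pd.Series
    baseline_survival: dict[str, StepFunction]
    logliks: list[float] = field(default_factory=list)
    selected_sets: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return self.pooled.params

    def baseline_survival_10y(self) -> dict[str, float]:
        return {s: float(fn(10.0)) for s, fn in self.baseline_survival.items()}

    def summary(self) -> pd.DataFrame:
        return self.pooled.summary()

    def predict_risk(self, data, horizon: float = 10.0, stratum: str | None = None):
        from .cohort import CohortDataset
        from .design import design_matrix

        df = data.data if isinstance(data, CohortDataset) else data
        X = design_matrix(df, self.covariates, allow_missing=False)
        lp = (X.to_numpy() - self.reference.to_numpy()) @ self.params.to_numpy()
        if stratum is not None:
            labels = np.full(len(df), stratum, dtype=object)
        elif isinstance(data, CohortDataset):
            labels = data.stratum_of().to_numpy()
        else:
            labels = df["stratum"].to_numpy()
        s0_by = {s: self.baseline_survival[s](horizon) for s in np.unique(labels)}
        s0 = np.array([s0_by[s] for s in labels])
        return 1.0 - s0 ** np.exp(lp)

    def to_equation_doc(self, name: str, outcome: str = "all_cvd") -> dict:
        lp_ref = float(self.params.to_numpy() @ self.reference.to_numpy())
        blocks = {
            s: {
                "baseline_survival": float(fn(10.0)),
                "lp_reference": lp_ref,
                "terms": [{"coef": float(self.params[c]), "expr": c}
                          for c in self.covariates],
            }
            for s, fn in self.baseline_survival.items()
        }
        return {"name": name, "form": "cox_baseline_survival", "horizon": 10.0,
                "outcome": outcome, "blocks_by": "stratum", "blocks": blocks,
                "reference": {k: float(v) for k, v in self.reference.items()}}


def _pooled_fit(imp: ImputationSet, covariates, subset_col: str | None = None) -> PooledCoxModel:
    """Fit the covariate set on every imputed dataset and Rubin-pool.

    `subset_col` restricts each fit to rows where that design covariate's
    source columns are observed (block-missing centers drop out).
    """
    pairs, logliks, baselines = [], [], []
    for df in imp.datasets:
        df = _with_stratum(df, imp.strata)
        if subset_col is not None:
            keep = pd.Series(True, index=df.index)
            for src in source_columns(subset_col):
                keep &= df[src].notna()
            df = df.loc[keep]
        res = StratifiedCoxModel(df, covariates, strata_col="stratum").fit()
        pairs.append((res.params, res.cov))
        logliks.append(res.loglik)
        baselines.append(res.baseline_survival)
    pooled = rubin_pool(pairs)

    # average the baseline cumulative hazards across imputations on a merged grid
    merged: dict[str, StepFunction] = {}
    for s in baselines[0]:
        grid = np.unique(np.concatenate([b[s].times for b in baselines]))
        h = np.mean([-np.log(np.clip(b[s](grid), 1e-300, None)) for b in baselines], axis=0)
        merged[s] = StepFunction(grid, np.exp(-h), initial=1.0)
    return PooledCoxModel(list(covariates), pooled, center_reference(covariates),
                          merged, logliks)


@dataclass
class SelectionResult:
    per_dataset_sets: list[tuple[str, ...]]
    selected: list[str]
    model: PooledCoxModel
    unanimous: bool


def select_base_model(
    imp: ImputationSet,
    candidates=CANDIDATE_COVARIATES,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """LASSO selection per imputed dataset, majority-rule reconciliation,
    unpenalized refit of the winning set, Rubin pooling."""
    if not candidates:
        raise FitError("empty candidate list")
    sets = []
    for i, df in enumerate(imp.datasets):
        df = _with_stratum(df, imp.strata)
        path = CoxLassoModel(df, candidates, strata_col="stratum").fit(
            cv_folds=folds, seed=seed + i)
        sets.append(tuple(path.selected))
    votes = pd.Series([c for s in sets for c in s]).value_counts()
    selected = [c for c in candidates if votes.get(c, 0) > len(imp.datasets) / 2]
    if not selected:
        raise FitError("LASSO selected no covariate in a majority of imputations")
    unanimous = all(set(s) == set(selected) for s in sets)
    if not unanimous:
        log.info("selection not unanimous across imputations: %s", sets)
    model = _pooled_fit(imp, selected)
    model.selected_sets = sets
    return SelectionResult(sets, selected, model, unanimous)


def assess_ra_characteristics(
    imp: ImputationSet,
    base_covariates=BASE_COVARIATES,
    characteristics=RA_CHARACTERISTICS,
) -> pd.DataFrame:
    """Each RA characteristic added (alone) to the CVD adjustors, fitted on
    the centers where it is measured; pooled HR with 95% CI and p-value."""
    rows = []
    for char, tag in characteristics:
        srcs = source_columns(char)
        any_observed = any(imp.datasets[0][s].notna().any() for s in srcs)
        if not any_observed:
            warnings.warn(f"{char}: absent everywhere, skipped", stacklevel=2)
            rows.append({"characteristic": char, "transform": tag, "skipped": True,
                         "reason": "absent in all cohorts"})
            continue
        covs = list(base_covariates) + [char]
        try:
            model = _pooled_fit(imp, covs, subset_col=char)
        except FitError as exc:
            rows.append({"characteristic": char, "transform": tag, "skipped": True,
                         "reason": str(exc)})
            continue
        summ = model.summary().loc[char]
        keep = pd.Series(True, index=imp.datasets[0].index)
        for s in srcs:
            keep &= imp.datasets[0][s].notna()
        rows.append({
            "characteristic": char, "transform": tag, "skipped": False,
            "n_used": int(keep.sum()),
            "hr": summ["hr"], "hr_ci_lower": summ["hr_ci_lower"],
            "hr_ci_upper": summ["hr_ci_upper"], "p": summ["p"],
        })
    return pd.DataFrame(rows)


def finalize_models(
    imp: ImputationSet,
    base_covariates=BASE_COVARIATES,
) -> tuple[PooledCoxModel, PooledCoxModel]:
    """The two calculators: base + DAS28ESR (Model A) and base + HAQ (Model B),
    each refitted on the centers measuring the RA characteristic, pooled, with
    10-year baseline survival per stratum."""
    model_a = _pooled_fit(imp, list(base_covariates) + ["das28esr"], subset_col="das28esr")
    model_b = _pooled_fit(imp, list(base_covariates) + ["haq"], subset_col="haq")
    return model_a, model_b


def forward_ra_step(
    imp: ImputationSet,
    current_covariates,
    remaining=RA_CHARACTERISTICS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One forward step over remaining RA characteristics with a pooled Wald
    entry test at `alpha`; returns the candidate table sorted by p."""
    report = assess_ra_characteristics(imp, current_covariates, remaining)
    fit = report[~report["skipped"]].copy()
    fit["enters"] = fit["p"] < alpha
    return fit.sort_values("p").reset_index(drop=True)
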