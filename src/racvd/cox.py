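"""Stratified Cox estimation, Breslow baseline survival, and diagnostics.

`StratifiedCoxModel` is constructed from subject-level data and a covariate
list; `fit()` returns a `StratifiedCoxResults` carrying coefficients, their
covariance, per-stratum baseline survival centered at the published
reference profile, and prediction/diagnostic methods. Partial-likelihood
maximization is delegated to lifelines (Efron ties by default; Breslow via
the in-package engine), while the baseline survival uses the in-package
Breslow estimator so the centering matches the reference profile rather than
the training means.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .cohort import CohortDataset
from .design import center_reference, design_matrix
from .exceptions import FitError, SchemaError


class StepFunction:
    """Right-continuous step function; constant `initial` before the first knot."""

    def __init__(self, times, values, initial: float = 1.0):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.initial = float(initial)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, self.initial, self.values[np.clip(idx, 0, None)])
        return float(out) if out.ndim == 0 else out

    @property
    def last_time(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0


def _prepare_fit_frame(data, covariates, duration_col, event_col, strata_col, strata_map):
    if isinstance(data, CohortDataset):
        df = data.data
        strata_map = strata_map or data.strata
    else:
        df = data
    X = design_matrix(df, covariates, allow_missing=True)
    fit_df = X.copy()
    fit_df[duration_col] = pd.to_numeric(df[duration_col], errors="coerce")
    fit_df[event_col] = pd.to_numeric(df[event_col], errors="coerce")
    if strata_col in df.columns:
        fit_df[strata_col] = df[strata_col]
    elif strata_map and "cohort_id" in df.columns:
        fit_df[strata_col] = df["cohort_id"].map(strata_map)
    else:
        fit_df[strata_col] = "all"
    if fit_df[strata_col].isna().any():
        raise SchemaError("stratum unresolved for some subjects")
    return fit_df


class StratifiedCoxModel:
    """Proportional-hazards model with a separate baseline hazard per stratum.

    Parameters
    ----------
    data : DataFrame or CohortDataset
        Subject-level data in the cohort schema (or already-built design
        columns of the same names).
    covariates : sequence of str
        Design-column names (see :mod:`racvd.design`); age enters as
        ``age10`` so the per-decade scaling is explicit.
    reference : mapping, optional
        Centering profile in design units; defaults to the published
        reference profile for covariates it names, 0 elsewhere.
    ties : 'efron' or 'breslow'
    """

    def __init__(
        self,
        data,
        covariates,
        duration_col: str = "followup_time",
        event_col: str = "cvd_event",
        strata_col: str = "stratum",
        strata_map: dict[str, str] | None = None,
        reference: dict[str, float] | None = None,
        ties: str = "efron",
    ):
        self.covariates = list(covariates)
        if not self.covariates:
            raise FitError("empty covariate list")
        if ties not in ("efron", "breslow"):
            raise FitError(f"unknown ties method {ties!r}")
        self.duration_col, self.event_col, self.strata_col = duration_col, event_col, strata_col
        self.ties = ties
        self.reference = center_reference(self.covariates, reference)
        self.frame = _prepare_fit_frame(
            data, self.covariates, duration_col, event_col, strata_col, strata_map
        )
        if self.frame[self.covariates].isna().any().any():
            bad = [c for c in self.covariates if self.frame[c].isna().any()]
            raise SchemaError(f"covariates contain missing values (impute first): {bad}")
        for s, sub in self.frame.groupby(strata_col):
            if sub[event_col].sum() < 1:
                raise FitError(f"stratum {s!r} has no events")

    @classmethod
    def from_dataset(cls, ds: CohortDataset, covariates, **kwargs) -> "StratifiedCoxModel":
        return cls(ds, covariates, strata_map=ds.strata, **kwargs)

    def fit(self, robust: bool = False) -> "StratifiedCoxResults":
        if self.frame[self.event_col].sum() < 2:
            # a single event cannot identify coefficients (monotone likelihood);
            # return a flagged degenerate result instead of diverging
            nan = pd.Series(np.nan, index=self.covariates)
            cov = pd.DataFrame(np.nan, index=self.covariates, columns=self.covariates)
            return StratifiedCoxResults(self, nan, cov, np.nan)
        if self.ties == "breslow":
            from .lasso import breslow_newton_fit

            params, cov, ll = breslow_newton_fit(
                self.frame, self.covariates, self.duration_col, self.event_col, self.strata_col
            )
            params = pd.Series(params, index=self.covariates)
            cov = pd.DataFrame(cov, index=self.covariates, columns=self.covariates)
        else:
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(
                        self.frame,
                        duration_col=self.duration_col,
                        event_col=self.event_col,
                        strata=[self.strata_col],
                        robust=robust,
                    )
            except ConvergenceError as exc:
                raise FitError(f"partial likelihood did not converge (separation?): {exc}") from exc
            params = cph.params_.copy()
            params.index = [i if isinstance(i, str) else i[-1] for i in params.index]
            params = params.reindex(self.covariates)
            cov = pd.DataFrame(
                np.asarray(cph.variance_matrix_), index=params.index, columns=params.index
            )
            ll = float(cph.log_likelihood_)
        res = StratifiedCoxResults(self, params, cov, ll)
        if self.ties == "efron":
            res._cph = cph
        return res


class StratifiedCoxResults:
    """Fitted stratified Cox model: estimates, uncertainty, baseline survival."""

    def __init__(self, model: StratifiedCoxModel, params: pd.Series,
                 cov: pd.DataFrame, loglik: float):
        self.model = model
        self.params = params
        self.cov = cov
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=params.index)
        self.loglik = loglik
        self.reference = model.reference
        self.ties = model.ties
        self.n = len(model.frame)
        self.n_events = int(model.frame[model.event_col].sum())
        self._cph = None
        self.degenerate = bool(params.isna().any())
        self.baseline_survival = (
            {} if self.degenerate
            else {s: breslow_baseline(self, s) for s in self.strata_labels}
        )

    @property
    def strata_labels(self):
        return sorted(self.model.frame[self.model.strata_col].unique())

    # -- reporting ---------------------------------------------------------
    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo, hi = self.params - z * self.bse, self.params + z * self.bse
        zval = self.params / self.bse
        return pd.DataFrame({
            "coef": self.params, "hr": np.exp(self.params), "se": self.bse,
            "z": zval, "p": 2 * stats.norm.sf(np.abs(zval)),
            "hr_ci_lower": np.exp(lo), "hr_ci_upper": np.exp(hi),
        })

    def hazard_ratios(self, decimals: int = 2) -> pd.Series:
        return np.exp(self.params).round(decimals)

    # -- prediction --------------------------------------------------------
    def linear_predictor(self, data) -> np.ndarray:
        """Centered linear predictor beta' (x - x_ref)."""
        df = data.data if isinstance(data, CohortDataset) else data
        X = design_matrix(df, self.params.index, allow_missing=True)
        if X.isna().any().any():
            bad = list(X.columns[X.isna().any()])
            raise SchemaError(f"prediction requires covariates {bad} (missing values found)")
        centered = X.to_numpy() - self.reference.reindex(self.params.index).to_numpy()
        return centered @ self.params.to_numpy()

    def _resolve_strata(self, data, stratum=None) -> np.ndarray:
        df = data.data if isinstance(data, CohortDataset) else data
        if stratum is not None:
            labels = np.full(len(df), stratum, dtype=object)
        elif isinstance(data, CohortDataset):
            labels = data.stratum_of().to_numpy()
        elif self.model.strata_col in df.columns:
            labels = df[self.model.strata_col].to_numpy()
        else:
            raise SchemaError("stratum unresolvable: pass stratum= or include a stratum column")
        unknown = set(labels) - set(self.strata_labels)
        if unknown:
            raise FitError(f"unknown strata {sorted(unknown)}; fitted: {self.strata_labels}")
        return labels

    def predict_risk(self, data, horizon: float = 10.0, stratum: str | None = None) -> np.ndarray:
        """Absolute event probability 1 - S0_s(h)^exp(lp - lp_ref) by horizon."""
        lp = self.linear_predictor(data)
        labels = self._resolve_strata(data, stratum)
        s0_by = {s: self.baseline_survival[s](horizon) for s in np.unique(labels)}
        s0 = np.array([s0_by[s] for s in labels])
        return 1.0 - s0 ** np.exp(lp)

    def predict_cumhaz(self, data, times, stratum: str | None = None) -> np.ndarray:
        """Per-subject cumulative hazard at per-subject times."""
        lp = self.linear_predictor(data)
        labels = self._resolve_strata(data, stratum)
        times = np.asarray(times, dtype=float)
        h0 = np.empty(len(times))
        for s in np.unique(labels):
            m = labels == s
            h0[m] = -np.log(np.clip(self.baseline_survival[s](times[m]), 1e-300, None))
        return h0 * np.exp(lp)

    def baseline_survival_at(self, stratum: str, t: float) -> float:
        return float(self.baseline_survival[stratum](t))

    # -- diagnostics ---------------------------------------------------------
    def ph_test(self, time_transform: str = "rank") -> pd.DataFrame:
        """Scaled-Schoenfeld proportional-hazards test per covariate.

        Degenerate inputs (a single event) yield a flagged all-NA table.
        """
        if self.n_events < 2:
            return pd.DataFrame(
                {"test_statistic": np.nan, "p": np.nan, "degenerate": True},
                index=list(self.params.index),
            )
        if self._cph is None:
            raise FitError("PH test requires the Efron-ties (lifelines) fit")
        res = proportional_hazard_test(self._cph, self.model.frame,
                                       time_transform=time_transform)
        tab = res.summary.copy()
        tab.index = [i[0] if isinstance(i, tuple) else i for i in tab.index]
        tab = tab.loc[[c for c in self.params.index if c in tab.index],
                      ["test_statistic", "p"]]
        tab["degenerate"] = False
        # approximate global test: sum of per-covariate chi-squares
        global_stat = float(tab["test_statistic"].sum())
        tab.loc["GLOBAL"] = [global_stat,
                             stats.chi2.sf(global_stat, df=len(self.params)), False]
        return tab

    # -- persistence ---------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "covariates": list(self.params.index),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "reference": {k: float(v) for k, v in self.reference.items()},
            "ties": self.ties,
            "log_likelihood": self.loglik,
            "baseline_survival": {
                s: {"times": fn.times.tolist(), "values": fn.values.tolist()}
                for s, fn in self.baseline_survival.items()
            },
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


def cox_fit(data, covariates, strata_map=None, ties="efron", **kwargs) -> StratifiedCoxResults:
    """Functional wrapper: fit a stratified Cox model."""
    return StratifiedCoxModel(data, covariates, strata_map=strata_map, ties=ties, **kwargs).fit()


def ph_check(results: StratifiedCoxResults, time_transform: str = "rank") -> pd.DataFrame:
    """Functional wrapper around :meth:`StratifiedCoxResults.ph_test`."""
    return results.ph_test(time_transform=time_transform)


def breslow_baseline(results: StratifiedCoxResults, stratum: str) -> StepFunction:
    """Breslow baseline survival S0_s(t) = exp(-H0_s(t)) for one stratum,
    centered at the reference profile (so S0 is the survival of a reference
    subject). Queries beyond the last observed time carry the last value."""
    model = results.model
    frame = model.frame
    sub = frame[frame[model.strata_col] == stratum]
    if sub.empty:
        raise FitError(f"stratum {stratum!r} not present in the fitted data")
    X = sub[list(results.params.index)].to_numpy()
    lp = (X - results.reference.to_numpy()) @ results.params.to_numpy()
    t = sub[model.duration_col].to_numpy(dtype=float)
    d = sub[model.event_col].to_numpy(dtype=float)

    order = np.argsort(t, kind="mergesort")
    t, d, elp = t[order], d[order], np.exp(lp[order])
    # risk-set sums of exp(lp): subjects with time >= t_k
    rev_cum = np.cumsum(elp[::-1])[::-1]
    event_mask = d == 1
    ev_times, first_idx = np.unique(t[event_mask], return_index=True)
    # counts and denominators per distinct event time
    increments = []
    for te in ev_times:
        at_risk = rev_cum[np.searchsorted(t, te, side="left")]
        d_k = float(np.sum((t == te) & event_mask))
        increments.append(d_k / at_risk)
    h0 = np.cumsum(increments)
    return StepFunction(ev_times, np.exp(-h0), initial=1.0)


def predict_risk(fit_or_results, subjects, horizon: float = 10.0, stratum=None):
    """Module-level predictor accepting fitted results or a RiskEquation."""
    from .equations import RiskEquation, evaluate

    if isinstance(fit_or_results, RiskEquation):
        return evaluate(fit_or_results, subjects, stratum=stratum)
    return fit_or_results.predict_risk(subjects, horizon=horizon, stratum=stratum)


# ---------------------------------------------------------------------------
# non-linearity check via restricted cubic splines


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline nonlinear basis, k-2 columns."""
    x = np.asarray(x, dtype=float)
    k = len(knots)
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    norm = (tk - t1) ** 2

    def plus3(v):
        return np.clip(v, 0, None) ** 3

    cols = []
    for j in range(k - 2):
        tj = knots[j]
        term = (
            plus3(x - tj)
            - plus3(x - tk1) * (tk - tj) / (tk - tk1)
            + plus3(x - tk) * (tk1 - tj) / (tk - tk1)
        )
        cols.append(term / norm)
    return np.column_stack(cols)


def nonlinearity_check(
    data,
    covariate: str,
    base_covariates,
    duration_col="followup_time",
    event_col="cvd_event",
    strata_map=None,
    n_knots: int = 4,
) -> dict:
    """Likelihood-ratio test of a linear term against a restricted cubic
    spline (knots at the 5/35/65/95 percentiles) for a continuous covariate."""
    df = data.data if isinstance(data, CohortDataset) else data
    covs = [c for c in base_covariates if c != covariate] + [covariate]
    X = design_matrix(df, covs, allow_missing=True)
    keep = X.notna().all(axis=1) & df[duration_col].notna()
    df, X = df.loc[keep], X.loc[keep]
    x = X[covariate].to_numpy(dtype=float)
    if len(np.unique(x)) < 10:
        raise FitError(f"{covariate}: needs >= 10 distinct values for a spline check")

    qs = np.linspace(0.05, 0.95, n_knots)
    knots = np.unique(np.quantile(x, qs))
    if len(knots) < 3:
        raise FitError(f"{covariate}: degenerate knot placement")
    spline = rcs_basis(x, knots)

    base = StratifiedCoxModel(df, covs, duration_col, event_col,
                              strata_map=strata_map).fit()
    aug_frame = base.model.frame.copy()
    spline_names = [f"_rcs{j}" for j in range(spline.shape[1])]
    for j, name in enumerate(spline_names):
        aug_frame[name] = spline[:, j]
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(aug_frame, duration_col=duration_col, event_col=event_col,
                strata=[base.model.strata_col])
    lr = 2.0 * (float(cph.log_likelihood_) - base.loglik)
    dof = spline.shape[1]
    return {
        "covariate": covariate,
        "lr_statistic": max(lr, 0.0),
        "df": dof,
        "p": float(stats.chi2.sf(max(lr, 0.0), dof)),
        "knots": knots.tolist(),
    }
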