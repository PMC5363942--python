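"""Discrimination, calibration, cross-validation and reclassification.

Observed decile risks come from Kaplan-Meier at the horizon (robust to
censoring); the goodness-of-fit chi-square compares observed event counts
with expected events accumulated over each subject's own exposure time,
E_i = H_i(min(t_i, horizon)). The standardized incidence ratio is total
observed over total expected, with exact Poisson limits on the observed
count.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import km_risk_at
from .equations import RISK_BIN_LABELS, categorize
from .exceptions import ConfigurationError, FitError

# ---------------------------------------------------------------------------
# discrimination


def harrells_c(predictions, times, events, alpha: float = 0.05) -> dict:
    """Harrell's concordance for censored data.

    Usable pairs: the subject with the shorter time had an event (pairs
    censored first are not orderable); prediction ties score 1/2. The CI is a
    Noether-type normal approximation on the concordance proportion.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(p) == len(t) == len(e)):
        raise ConfigurationError("prediction/time/event lengths differ")
    # pair (i, j) usable iff t_i < t_j and e_i = 1, or t_i == t_j and e_i != e_j
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    usable = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (e[None, :] == 0))
    if not usable.any():
        raise FitError("no usable pairs (all censored?)")
    higher = p[:, None] > p[None, :]
    tied = p[:, None] == p[None, :]
    n_pairs = float(usable.sum())
    concordant = float((usable & higher).sum())
    ties = float((usable & tied).sum())
    c = (concordant + 0.5 * ties) / n_pairs
    se = np.sqrt(max(c * (1 - c), 1e-12) / n_pairs)
    z = stats.norm.ppf(1 - alpha / 2)
    return {"c": c, "ci_lower": max(c - z * se, 0.0), "ci_upper": min(c + z * se, 1.0),
            "concordant": concordant, "tied": ties, "pairs": n_pairs}


# ---------------------------------------------------------------------------
# expected events / SIR


def expected_events_from_risk(risk_at_horizon, followup, horizon: float = 10.0) -> np.ndarray:
    """Per-subject expected events over observed exposure, from horizon risks.

    Converts each predicted risk to a cumulative hazard H(h) = -log(1 - r)
    and scales it linearly in time up to the subject's exposure
    min(followup, horizon) — the exposure-aware transformation of predicted
    into expected events.
    """
    r = np.clip(np.asarray(risk_at_horizon, dtype=float), 0.0, 1.0 - 1e-12)
    f = np.asarray(followup, dtype=float)
    if np.any(f < 0):
        raise ConfigurationError("negative follow-up time")
    H = -np.log1p(-r)
    return H * np.minimum(f, horizon) / horizon


def expected_events(model_or_risk, subjects=None, followup=None, horizon: float = 10.0):
    """Expected events either from a fitted model (exact cumulative hazard at
    each subject's exposure) or from a vector of horizon risks (linear-in-time
    hazard scaling)."""
    if hasattr(model_or_risk, "predict_cumhaz"):
        f = np.asarray(subjects["followup_time"] if followup is None else followup, dtype=float)
        if np.any(f < 0):
            raise ConfigurationError("negative follow-up time")
        return model_or_risk.predict_cumhaz(subjects, np.minimum(f, horizon))
    return expected_events_from_risk(model_or_risk, followup, horizon)


def sir(observed: float, expected: float, alpha: float = 0.05) -> dict:
    """Standardized incidence ratio O/E with exact Poisson CI on O."""
    if expected <= 0:
        raise ConfigurationError("expected events must be positive")
    o = float(observed)
    lo = stats.chi2.ppf(alpha / 2, 2 * o) / 2 if o > 0 else 0.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (o + 1)) / 2
    return {"sir": o / expected, "ci_lower": lo / expected, "ci_upper": hi / expected,
            "observed": o, "expected": float(expected)}


# ---------------------------------------------------------------------------
# decile calibration


@dataclass
class CalibrationResult:
    """Observed vs expected events in groups of predicted risk."""

    table: pd.DataFrame          # per-decile summary
    chi2: float
    df: int
    p: float
    sir: dict
    merged_groups: bool = False

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def decile_gof(
    predictions,
    times,
    events,
    horizon: float = 10.0,
    df_penalty: int = 0,
    expected: np.ndarray | None = None,
    n_groups: int = 10,
) -> CalibrationResult:
    """Survival-adapted decile goodness-of-fit.

    Groups subjects by deciles of predicted risk; per group reports mean
    predicted risk, KM observed risk at the horizon with CI, observed event
    count and expected events; the chi-square is sum (O-E)^2/E on
    ``n_groups - 1 - df_penalty`` degrees of freedom (``df_penalty=1`` when
    evaluating in the data used to fit the model, 0 externally).
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(np.unique(p)) < n_groups:
        raise FitError(f"need >= {n_groups} distinct prediction values")
    E = expected_events_from_risk(p, t, horizon) if expected is None else np.asarray(expected)
    e_h = e * (t <= horizon)  # only events within the horizon are compared

    groups = pd.qcut(p, n_groups, labels=False, duplicates="drop")
    n_eff = int(groups.max()) + 1
    merged = n_eff < n_groups

    rows = []
    for g in range(n_eff):
        m = groups == g
        obs_risk, (lo, hi) = km_risk_at(t[m], e[m], horizon)
        rows.append({
            "group": g + 1, "n": int(m.sum()),
            "mean_predicted": float(p[m].mean()),
            "observed_km_risk": obs_risk, "observed_ci_lower": lo, "observed_ci_upper": hi,
            "observed_events": float(e_h[m].sum()), "expected_events": float(E[m].sum()),
        })
    tab = pd.DataFrame(rows)
    small = tab["expected_events"] < 1.0
    if small.any():
        warnings.warn("merging groups with expected events < 1", stacklevel=2)
        merged = True
        keep, acc = [], None
        for _, row in tab.iterrows():
            acc = row if acc is None else _merge_rows(acc, row)
            if acc["expected_events"] >= 1.0:
                keep.append(acc)
                acc = None
        if acc is not None:
            if keep:
                keep[-1] = _merge_rows(keep[-1], acc)
            else:
                keep.append(acc)
        tab = pd.DataFrame(keep).reset_index(drop=True)
    chi2 = float((((tab["observed_events"] - tab["expected_events"]) ** 2)
                  / tab["expected_events"]).sum())
    dof = max(len(tab) - 1 - df_penalty, 1)
    overall = sir(e_h.sum(), E.sum())
    return CalibrationResult(tab, chi2, dof, float(stats.chi2.sf(chi2, dof)),
                             overall, merged)


def _merge_rows(a, b):
    out = a.copy()
    n = a["n"] + b["n"]
    out["mean_predicted"] = (a["mean_predicted"] * a["n"] + b["mean_predicted"] * b["n"]) / n
    for k in ("n", "observed_events", "expected_events"):
        out[k] = a[k] + b[k]
    out["observed_km_risk"] = np.nan  # recomputation would need raw rows; flagged
    return out


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    predictions: np.ndarray       # out-of-fold horizon risks, original row order
    expected: np.ndarray          # out-of-fold expected events over exposure
    folds: np.ndarray
    c: dict
    sir: dict
    calibration: CalibrationResult
    apparent_c: dict | None = None


def kfold_cv(
    data,
    covariates,
    k: int = 10,
    seed: int = 0,
    horizon: float = 10.0,
    duration_col: str = "followup_time",
    event_col: str = "cvd_event",
    strata_col: str = "stratum",
    strata_map: dict | None = None,
    df_penalty: int = 1,
) -> CVResult:
    """Out-of-fold performance of a stratified Cox specification.

    Folds are stratified on (risk stratum x event status); every subject is
    predicted exactly once out-of-fold; c, SIR and the decile test are
    computed on the pooled out-of-fold predictions.
    """
    from .cohort import CohortDataset
    from .cox import StratifiedCoxModel

    df = data.data if isinstance(data, CohortDataset) else data
    if isinstance(data, CohortDataset):
        strata_map = strata_map or data.strata
    df = df.reset_index(drop=True)
    if strata_col not in df.columns:
        df = df.copy()
        df[strata_col] = df["cohort_id"].map(strata_map)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if df[event_col].sum() < k:
        raise ConfigurationError("fewer events than folds")

    labels = df[strata_col].astype(str) + "|" + df[event_col].astype(int).astype(str)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.full(len(df), np.nan)
    expect = np.full(len(df), np.nan)
    fold_id = np.full(len(df), -1)
    for fk, (tr, te) in enumerate(skf.split(df, labels)):
        if df.loc[tr, event_col].sum() == 0 or df.loc[te, event_col].sum() == 0:
            warnings.warn("fold without events; reshuffling", stacklevel=2)
            return kfold_cv(data, covariates, k=k, seed=seed + 1, horizon=horizon,
                            duration_col=duration_col, event_col=event_col,
                            strata_col=strata_col, strata_map=strata_map,
                            df_penalty=df_penalty)
        res = StratifiedCoxModel(df.iloc[tr], covariates, duration_col, event_col,
                                 strata_col).fit()
        test = df.iloc[te]
        pred[te] = res.predict_risk(test, horizon=horizon)
        expect[te] = res.predict_cumhaz(
            test, np.minimum(test[duration_col].to_numpy(dtype=float), horizon))
        fold_id[te] = fk

    t = df[duration_col].to_numpy(dtype=float)
    e = df[event_col].to_numpy(dtype=int)
    c = harrells_c(pred, t, e)
    cal = decile_gof(pred, t, e, horizon=horizon, df_penalty=df_penalty, expected=expect)
    overall = sir((e * (t <= horizon)).sum(), expect.sum())
    res_all = StratifiedCoxModel(df, covariates, duration_col, event_col, strata_col).fit()
    apparent = harrells_c(res_all.predict_risk(df, horizon=horizon), t, e)
    return CVResult(pred, expect, fold_id, c, overall, cal, apparent)


# ---------------------------------------------------------------------------
# reclassification


@dataclass
class ReclassificationTable:
    """4x4 cross-classification of two calculators' risk categories."""

    counts_no_event: np.ndarray      # reference category (rows) x model (cols)
    counts_event: np.ndarray
    observed_risk: np.ndarray | None = None   # per-cell KM 10-y risk
    observed_ci: np.ndarray | None = None     # (4,4,2)
    labels: tuple = RISK_BIN_LABELS
    model_name: str = "model"
    reference_name: str = "reference"

    @property
    def total(self) -> int:
        return int(self.counts_no_event.sum() + self.counts_event.sum())

    def summary_percentages(self, decimals: int | None = 0) -> dict:
        """Percent of all subjects in the same / higher / lower category
        (model relative to reference); computed on events + non-events."""
        counts = self.counts_no_event + self.counts_event
        total = counts.sum()
        if total == 0:
            raise ConfigurationError("empty reclassification table")
        same = np.trace(counts)
        higher = np.triu(counts, k=1).sum()
        lower = np.tril(counts, k=-1).sum()
        pct = {
            "same": 100.0 * same / total,
            "higher": 100.0 * higher / total,
            "lower": 100.0 * lower / total,
        }
        if decimals is not None:
            pct = {k: round(v) if decimals == 0 else round(v, decimals)
                   for k, v in pct.items()}
        return pct

    @classmethod
    def from_counts(cls, counts_no_event, counts_event, **kwargs) -> "ReclassificationTable":
        a = np.asarray(counts_no_event, dtype=float)
        b = np.asarray(counts_event, dtype=float)
        if a.shape != b.shape or a.shape[0] != a.shape[1]:
            raise ConfigurationError("count grids must be square and congruent")
        return cls(a, b, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ref_lab in enumerate(self.labels):
            for j, mod_lab in enumerate(self.labels):
                row = {
                    self.reference_name: ref_lab, self.model_name: mod_lab,
                    "n_without_events": self.counts_no_event[i, j],
                    "n_with_events": self.counts_event[i, j],
                }
                if self.observed_risk is not None:
                    row["observed_10y_risk"] = self.observed_risk[i, j]
                    row["observed_ci_lower"] = self.observed_ci[i, j, 0]
                    row["observed_ci_upper"] = self.observed_ci[i, j, 1]
                rows.append(row)
        return pd.DataFrame(rows)


def reclassification(
    pred_model,
    pred_reference,
    times,
    events,
    horizon: float = 10.0,
    model_name: str = "model",
    reference_name: str = "reference",
) -> ReclassificationTable:
    """Cross-classify two calculators' risk categories with per-cell KM risk."""
    pm = np.asarray(pred_model, dtype=float)
    pr = np.asarray(pred_reference, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(pm) == len(pr) == len(t) == len(e)):
        raise ConfigurationError("misaligned prediction vectors")
    cat_m = pd.Categorical(categorize(pm), categories=RISK_BIN_LABELS)
    cat_r = pd.Categorical(categorize(pr), categories=RISK_BIN_LABELS)
    k = len(RISK_BIN_LABELS)
    no_ev = np.zeros((k, k))
    ev = np.zeros((k, k))
    risk = np.full((k, k), np.nan)
    ci = np.full((k, k, 2), np.nan)
    for i in range(k):
        for j in range(k):
            m = (cat_r.codes == i) & (cat_m.codes == j)
            no_ev[i, j] = int((m & (e == 0)).sum())
            ev[i, j] = int((m & (e == 1)).sum())
            if m.any():
                if (e[m] == 1).any():
                    r, (lo, hi) = km_risk_at(t[m], e[m], horizon)
                else:
                    r, (lo, hi) = 0.0, (0.0, 0.0)
                risk[i, j], ci[i, j] = r, (lo, hi)
    return ReclassificationTable(no_ev, ev, risk, ci,
                                 model_name=model_name, reference_name=reference_name)


# ---------------------------------------------------------------------------
# plot-ready tables


def calibration_plot_data(predictions, times, events, horizon: float = 10.0,
                          n_groups: int = 10) -> pd.DataFrame:
    """Decile table of predicted vs KM-observed risk, ready for plotting."""
    cal = decile_gof(predictions, times, events, horizon=horizon, n_groups=n_groups)
    return cal.table[["group", "n", "mean_predicted", "observed_km_risk",
                      "observed_ci_lower", "observed_ci_upper"]]


def scatter_compare(pred_x, pred_y, frac: float = 0.5) -> pd.DataFrame:
    """Paired predictions with identity reference and a lowess trend."""
    x = np.asarray(pred_x, dtype=float)
    y = np.asarray(pred_y, dtype=float)
    if len(x) != len(y):
        raise ConfigurationError("misaligned prediction vectors")
    trend = lowess(y, x, frac=frac, return_sorted=False)
    return pd.DataFrame({"x": x, "y": y, "identity": x, "trend": trend})
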