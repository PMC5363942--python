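"""Synthetic multi-cohort survival data with known ground truth.

Generates per-cohort baseline covariates mimicking a pooled multi-center RA
population (13 centers, heterogeneous event rates, block-missing RA
characteristics, heavy lipid missingness in two centers), then draws CVD
event times from a proportional-hazards model with a cohort-specific
constant (or Weibull) baseline hazard.

Each cohort's baseline hazard is either calibrated so the expected marginal
event rate (events per 100 person-years under the configured censoring
process) matches a target rate, or fixed directly through a 10-year baseline
survival at the reference covariate profile.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from . import schema
from .cohort import CohortDataset
from .design import REFERENCE_PROFILE, design_matrix
from .exceptions import ConfigurationError, SchemaError

# ---------------------------------------------------------------------------
# configuration types


@dataclass
class CohortSpec:
    """One simulated center."""

    name: str
    n: int
    rate_per_100py: float | None = None      # marginal CVD event rate target
    baseline_survival_10y: float | None = None  # alternative: S0(10) at reference
    stratum: str = "low"
    country: str = ""
    mean_followup_years: float | None = None  # calibrates this cohort's accrual window
    covariates: dict = field(default_factory=dict)  # per-cohort generator overrides

    def validate(self) -> None:
        if self.mean_followup_years is not None and self.mean_followup_years <= 0:
            raise ConfigurationError(f"cohort {self.name}: mean follow-up must be positive")
        if self.n <= 0:
            raise ConfigurationError(f"cohort {self.name}: n must be positive")
        if (self.rate_per_100py is None) == (self.baseline_survival_10y is None):
            raise ConfigurationError(
                f"cohort {self.name}: specify exactly one of rate_per_100py / baseline_survival_10y"
            )
        if self.rate_per_100py is not None and self.rate_per_100py <= 0:
            raise ConfigurationError(f"cohort {self.name}: rate must be positive")
        if self.baseline_survival_10y is not None and not 0 < self.baseline_survival_10y < 1:
            raise ConfigurationError(
                f"cohort {self.name}: baseline survival must be in (0,1)"
            )


@dataclass
class MissingnessRule:
    """Per-variable missingness for a set of cohorts (None = every cohort)."""

    variable: str
    fraction: float
    cohorts: tuple[str, ...] | None = None
    mechanism: str = "mcar"  # 'mcar' or 'mar' (conditions on age and sex)

    def validate(self) -> None:
        if self.variable not in schema.COLUMNS:
            raise SchemaError(f"missingness rule targets unknown variable {self.variable!r}")
        if schema.COLUMNS[self.variable].required:
            raise SchemaError(f"cannot inject missingness into required column {self.variable!r}")
        if not 0 <= self.fraction <= 1:
            raise ConfigurationError(f"{self.variable}: missing fraction must be in [0,1]")
        if self.mechanism not in ("mcar", "mar"):
            raise ConfigurationError(f"{self.variable}: unknown mechanism {self.mechanism!r}")


@dataclass
class SimConfig:
    """Full generator configuration.

    ``coefficients`` are true log hazard ratios keyed by design-column name;
    age must enter as ``age10`` (per 10 years) — a coefficient keyed ``age``
    is rejected so the decade scaling stays explicit. The hazard for subject
    i in cohort c is ``h0_c * exp(sum_j beta_j (x_ij - ref_j))`` with ``ref``
    the reference profile.
    """

    cohorts: list[CohortSpec]
    coefficients: dict[str, float]
    reference: dict[str, float] = field(default_factory=lambda: dict(REFERENCE_PROFILE))
    covariates: dict = field(default_factory=dict)   # global generator overrides
    weibull_shape: float = 1.0                       # 1.0 = exponential baseline
    dropout_rate: float = 0.03                       # exponential dropout, per year
    accrual_window: tuple[float, float] = (1.0, 12.0)  # administrative censor range
    prior_cvd_fraction: float = 0.0
    missingness: list[MissingnessRule] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not self.cohorts:
            raise ConfigurationError("at least one cohort required")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ConfigurationError("cohort names must be unique")
        for c in self.cohorts:
            c.validate()
        if "age" in self.coefficients:
            raise ConfigurationError(
                "age coefficient must be keyed 'age10' (per 10 years), not 'age'"
            )
        if self.weibull_shape <= 0:
            raise ConfigurationError("weibull_shape must be positive")
        if self.dropout_rate < 0:
            raise ConfigurationError("dropout_rate must be >= 0")
        a, b = self.accrual_window
        if not (0 < a <= b):
            raise ConfigurationError("accrual window must satisfy 0 < min <= max")
        if not 0 <= self.prior_cvd_fraction <= 1:
            raise ConfigurationError("prior_cvd_fraction must be in [0,1]")
        for r in self.missingness:
            r.validate()
            if r.cohorts is not None:
                unknown = set(r.cohorts) - set(names)
                if unknown:
                    raise ConfigurationError(
                        f"missingness rule for {r.variable}: unknown cohorts {sorted(unknown)}"
                    )

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["accrual_window"] = list(self.accrual_window)
        for r in d["missingness"]:
            if r["cohorts"] is not None:
                r["cohorts"] = list(r["cohorts"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["cohorts"] = [CohortSpec(**c) for c in d["cohorts"]]
        d["missingness"] = [
            MissingnessRule(
                variable=r["variable"], fraction=r["fraction"],
                cohorts=tuple(r["cohorts"]) if r.get("cohorts") else None,
                mechanism=r.get("mechanism", "mcar"),
            )
            for r in d.get("missingness", [])
        ]
        d["accrual_window"] = tuple(d.get("accrual_window", (1.0, 12.0)))
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# default study-shaped configuration

#: (name, country, n, events-per-100-person-years, mean follow-up in years
#: [person-years / n], stratum) for the 13 centers. Per-cohort mean follow-up
#: differs widely (1.6-8.4 y) and is what makes the pooled person-year-
#: weighted rate (~1.3) exceed the subject-weighted mean of cohort rates.
DEFAULT_COHORT_TABLE = [
    ("Netherlands/Nijmegen", "Netherlands", 1049, 1.8, 7.84, "high"),
    ("Sweden", "Sweden", 404, 1.6, 4.79, "high"),
    ("US/Olmsted", "USA", 661, 1.4, 8.05, "high"),
    ("Netherlands/Enschede", "Netherlands", 585, 1.3, 2.98, "high"),
    ("US/BRASS", "USA", 1090, 1.2, 4.94, "high"),
    ("Norway", "Norway", 161, 1.1, 8.38, "low"),
    ("US/UCLA", "USA", 147, 1.0, 2.71, "low"),
    ("South Africa", "South Africa", 191, 0.8, 5.21, "low"),
    ("Greece", "Greece", 197, 0.7, 2.17, "low"),
    ("Spain", "Spain", 509, 0.6, 1.59, "low"),
    ("UK", "UK", 313, 0.5, 5.89, "low"),
    ("Canada", "Canada", 186, 0.2, 5.00, "low"),
    ("Mexico", "Mexico", 145, 0.1, 5.36, "low"),
]

#: True log hazard ratios of the DAS28ESR calculator (Model A), used as the
#: default generating truth. Age enters per decade.
MODEL_A_TRUTH = {
    "age10": 0.482, "male": 0.479, "current_smoker": 0.416,
    "hypertension": 0.531, "tc_hdl_ratio": 0.340, "das28esr": 0.126,
}

#: HAQ-calculator truth (Model B).
MODEL_B_TRUTH = {
    "age10": 0.473, "male": 0.476, "current_smoker": 0.419,
    "hypertension": 0.640, "tc_hdl_ratio": 0.416, "haq": 0.313,
}

#: Cohorts missing ~75% of lipid measurements (27.6% of all subjects, so
#: roughly 20% of lipid data is missing overall).
LIPID_MISSING_COHORTS = ("Netherlands/Nijmegen", "Spain")

_BLOCKS = {
    "crp": ("Netherlands/Nijmegen",),
    "das28esr": ("US/BRASS",),
    "sjc28": ("US/BRASS", "US/UCLA"),
    "tjc28": ("US/BRASS", "US/UCLA"),
    "patient_vas": ("US/BRASS", "US/UCLA", "Canada", "Mexico"),
    "physician_vas": ("US/BRASS", "US/UCLA", "Canada", "Mexico",
                      "Greece", "Spain", "South Africa", "UK"),
    "haq": ("Sweden", "Spain", "Greece"),
}


def default_missingness_plan() -> list[MissingnessRule]:
    """Study-shaped missingness: 75% lipid loss in two centers, block-missing
    RA characteristics by center, and modest scattered missingness."""
    rules = [
        MissingnessRule(v, 0.75, LIPID_MISSING_COHORTS) for v in ("tc", "hdl", "ldl", "tg")
    ]
    rules += [MissingnessRule(v, 1.0, cohorts) for v, cohorts in _BLOCKS.items()]
    rules += [
        MissingnessRule("family_history_cvd", 0.35, None, "mar"),
        MissingnessRule("bmi", 0.08, None, "mar"),
        MissingnessRule("sbp", 0.05, None),
        MissingnessRule("dbp", 0.05, None),
        MissingnessRule("smoking", 0.05, None),
        MissingnessRule("esr", 0.12, None),
        MissingnessRule("crp", 0.08, None),
        MissingnessRule("das28esr", 0.08, None),
        MissingnessRule("haq", 0.10, None),
        MissingnessRule("sjc28", 0.06, None),
        MissingnessRule("tjc28", 0.06, None),
        MissingnessRule("patient_vas", 0.05, None),
        MissingnessRule("physician_vas", 0.05, None),
        MissingnessRule("rf_pos", 0.03, None),
        MissingnessRule("acpa_pos", 0.10, None),
    ]
    return rules


def default_config(truth: str = "A", missingness: bool = True, seed: int = 0,
                   n_scale: float = 1.0) -> SimConfig:
    """The 13-cohort study-shaped configuration with published effect sizes."""
    cohorts = [
        CohortSpec(name=name, country=country, n=max(int(round(n * n_scale)), 10),
                   rate_per_100py=rate, mean_followup_years=fup, stratum=stratum)
        for name, country, n, rate, fup, stratum in DEFAULT_COHORT_TABLE
    ]
    coef = dict(MODEL_A_TRUTH if truth.upper() == "A" else MODEL_B_TRUTH)
    return SimConfig(
        cohorts=cohorts,
        coefficients=coef,
        missingness=default_missingness_plan() if missingness else [],
        seed=seed,
    )


def two_strata_config(
    n_per_stratum: int = 3000,
    baseline_survival=(0.921, 0.963),
    coefficients: dict | None = None,
    seed: int = 0,
) -> SimConfig:
    """Two cohorts (one per stratum) with fixed 10-year baseline survivals;
    convenient for coefficient/baseline recovery studies."""
    s_high, s_low = baseline_survival
    return SimConfig(
        cohorts=[
            CohortSpec("high_center", n_per_stratum, baseline_survival_10y=s_high, stratum="high"),
            CohortSpec("low_center", n_per_stratum, baseline_survival_10y=s_low, stratum="low"),
        ],
        coefficients=dict(coefficients if coefficients is not None else MODEL_A_TRUTH),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# covariate generation

_DEFAULT_MARGINALS = {
    "age": {"dist": "normal", "mean": 55.3, "sd": 14.0, "lo": 18, "hi": 90},
    "sex_male_p": 0.24,
    "smoking_p": (0.21, 0.31, 0.48),  # current, former, never
    "sbp": {"dist": "normal", "mean": 136.0, "sd": 21.9, "lo": 80, "hi": 230},
    "dbp": {"dist": "normal", "mean": 79.6, "sd": 11.1, "lo": 40, "hi": 140},
    "tc": {"dist": "lognormal", "mean": 5.2, "sd": 1.1, "lo": 2.0, "hi": 12.0},
    "hdl": {"dist": "lognormal", "mean": 1.5, "sd": 0.4, "lo": 0.4, "hi": 4.0},
    "tg": {"dist": "lognormal", "mean": 1.4, "sd": 0.8, "lo": 0.3, "hi": 10.0},
    "bmi": {"dist": "normal", "mean": 27.0, "sd": 5.4, "lo": 14, "hi": 60},
    "hypertension_p": 0.42,
    "diabetes_p": 0.07,
    "family_history_p": 0.24,
    "lipid_lowering_p": 0.09,
    "rf_p": 0.65,
    "acpa_p": 0.60,
    "das28esr": {"mean": 4.0, "sd": 1.7, "load": 0.65},
    "haq": {"mean": 0.73, "sd": 0.7, "load": 0.45},
    "sjc28": {"mean": 6.3, "sd": 6.2, "load": 0.60},
    "tjc28": {"mean": 6.2, "sd": 6.6, "load": 0.60},
    "patient_vas": {"mean": 39.0, "sd": 25.7, "load": 0.50},
    "physician_vas": {"mean": 35.0, "sd": 22.0, "load": 0.50},
    "esr": {"log_mean": 3.0, "log_sd": 0.8, "load": 0.50},
    "crp": {"log_mean": 2.0, "log_sd": 1.1, "load": 0.50},
    "ra_duration": {"dist": "lognormal", "mean": 6.4, "sd": 9.2, "lo": 0.0, "hi": 60.0},
    "dmard_p": 0.47,
    "biologic_p": 0.16,
    "steroid_p": 0.27,
}


def _lognormal(rng, n, mean, sd, lo, hi):
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.clip(rng.lognormal(mu, np.sqrt(sigma2), n), lo, hi)


def _draw(rng, n, spec):
    if spec["dist"] == "normal":
        return np.clip(rng.normal(spec["mean"], spec["sd"], n), spec["lo"], spec["hi"])
    if spec["dist"] == "lognormal":
        return _lognormal(rng, n, spec["mean"], spec["sd"], spec.get("lo", 0.0),
                          spec.get("hi", np.inf))
    if spec["dist"] == "bernoulli":
        p = spec["p"]
        if not 0 <= p <= 1:
            raise ConfigurationError(f"bernoulli p={p} outside [0,1]")
        return (rng.random(n) < p).astype(float)
    raise ConfigurationError(f"unknown distribution spec {spec!r}")


def _latent_scaled(rng, n, z, mean, sd, load, lo, hi):
    eps = rng.normal(size=n)
    x = mean + sd * (load * z + np.sqrt(1.0 - load**2) * eps)
    return np.clip(x, lo, hi)


def _generate_covariates(rng: np.random.Generator, spec: CohortSpec, config: SimConfig) -> pd.DataFrame:
    n = spec.n
    m = dict(_DEFAULT_MARGINALS)
    m.update(config.covariates)
    m.update(spec.covariates)

    df = schema.empty_frame(n)
    df["cohort_id"] = spec.name
    df["age"] = _draw(rng, n, m["age"]) if "dist" in m["age"] else m["age"]
    df["sex"] = np.where(rng.random(n) < m["sex_male_p"], "male", "female")
    p_cur, p_for, _ = m["smoking_p"]
    u = rng.random(n)
    df["smoking"] = np.where(u < p_cur, "current", np.where(u < p_cur + p_for, "former", "never"))
    df["sbp"] = _draw(rng, n, m["sbp"])
    df["dbp"] = np.minimum(_draw(rng, n, m["dbp"]), df["sbp"] - 10.0)
    df["tc"] = _draw(rng, n, m["tc"])
    df["hdl"] = _draw(rng, n, m["hdl"])
    df["tg"] = _draw(rng, n, m["tg"])
    # Friedewald-consistent LDL with a little assay noise
    df["ldl"] = np.clip(df["tc"] - df["hdl"] - df["tg"] / 2.2 + rng.normal(0, 0.25, n), 0.3, 12.0)
    df["tc_hdl_ratio"] = df["tc"] / df["hdl"]
    df["bmi"] = _draw(rng, n, m["bmi"])

    if isinstance(m["hypertension_p"], dict):  # explicit override, independent draw
        df["hypertension"] = _draw(rng, n, m["hypertension_p"])
    else:
        # diagnosis correlates with measured blood pressure, calibrated to the
        # target marginal prevalence; the hazard acts through the diagnosis
        slope = 0.06
        sbp_c = df["sbp"].to_numpy() - np.mean(df["sbp"].to_numpy())

        def _prev(a):
            return float(np.mean(expit(a + slope * sbp_c))) - m["hypertension_p"]

        alpha = brentq(_prev, -20, 20)
        df["hypertension"] = (rng.random(n) < expit(alpha + slope * sbp_c)).astype(float)

    df["antihypertensive_use"] = np.where(
        df["hypertension"] == 1, rng.random(n) < 0.50, rng.random(n) < 0.02
    ).astype(float)
    df["diabetes"] = (rng.random(n) < m["diabetes_p"]).astype(float)
    df["family_history_cvd"] = (rng.random(n) < m["family_history_p"]).astype(float)
    df["lipid_lowering_use"] = (rng.random(n) < m["lipid_lowering_p"]).astype(float)
    df["rf_pos"] = (rng.random(n) < m["rf_p"]).astype(float)
    df["acpa_pos"] = (rng.random(n) < m["acpa_p"]).astype(float)

    # one latent disease-activity factor drives the correlated RA measures
    z = rng.normal(size=n)
    for var, lo, hi in [("das28esr", 0.3, 9.5), ("haq", 0.0, 3.0),
                        ("patient_vas", 0.0, 100.0), ("physician_vas", 0.0, 100.0)]:
        s = m[var]
        df[var] = _latent_scaled(rng, n, z, s["mean"], s["sd"], s["load"], lo, hi)
    for var in ("sjc28", "tjc28"):
        s = m[var]
        df[var] = np.round(_latent_scaled(rng, n, z, s["mean"], s["sd"], s["load"], 0, 28))
    for var in ("esr", "crp"):
        s = m[var]
        eps = rng.normal(size=n)
        df[var] = np.exp(s["log_mean"] + s["log_sd"] * (s["load"] * z
                         + np.sqrt(1 - s["load"] ** 2) * eps))
    df["esr"] = df["esr"].clip(1, 150)
    df["crp"] = df["crp"].clip(0.2, 300)
    df["ra_duration"] = _draw(rng, n, m["ra_duration"])
    df["dmard_use"] = (rng.random(n) < m["dmard_p"]).astype(float)
    df["biologic_use"] = (rng.random(n) < m["biologic_p"]).astype(float)
    df["steroid_use"] = (rng.random(n) < m["steroid_p"]).astype(float)
    df["prior_cvd"] = (rng.random(n) < config.prior_cvd_fraction).astype(float)
    return df


# ---------------------------------------------------------------------------
# event-time generation

def _expected_exposure(nu: np.ndarray, a: float, b: float) -> np.ndarray:
    """E[min(Exp(nu), U(a,b))] for total exit hazard nu and uniform
    administrative censoring on [a, b]."""
    nu = np.clip(nu, 1e-12, None)
    if b > a:
        mean_exp = (np.exp(-nu * a) - np.exp(-nu * b)) / (nu * (b - a))
    else:
        mean_exp = np.exp(-nu * a)
    return (1.0 - mean_exp) / nu


def _accrual_window(spec: CohortSpec, config: SimConfig) -> tuple[float, float]:
    """Administrative-censoring window for one cohort: the global default, or
    one calibrated so the expected follow-up matches the cohort's target mean."""
    if spec.mean_followup_years is None:
        return config.accrual_window
    if spec.rate_per_100py is not None:
        exit_rate = config.dropout_rate + spec.rate_per_100py / 100.0
    else:
        exit_rate = config.dropout_rate - np.log(spec.baseline_survival_10y) / 10.0
    target = spec.mean_followup_years

    def gap(c):
        a, b = 0.3 * c, min(1.7 * c, 13.0)
        return float(_expected_exposure(np.array([exit_rate]), a, b)[0]) - target

    try:
        c = brentq(gap, 0.05, 40.0, xtol=1e-10)
    except ValueError as exc:
        raise ConfigurationError(
            f"cohort {spec.name}: mean follow-up {target}y not attainable "
            f"under dropout {config.dropout_rate}/y"
        ) from exc
    return (0.3 * c, min(1.7 * c, 13.0))


def _calibrate_h0(k: np.ndarray, target_rate: float, config: SimConfig,
                  window: tuple[float, float], name: str) -> float:
    """Baseline hazard such that expected events / expected person-years
    equals the target (events per year), given realized hazard multipliers."""
    mu, (a, b) = config.dropout_rate, window

    def marginal_rate(log_h0):
        lam = np.exp(log_h0) * k
        t = _expected_exposure(lam + mu, a, b)
        return float(np.sum(lam * t) / np.sum(t)) - target_rate

    try:
        return float(np.exp(brentq(marginal_rate, np.log(1e-10), np.log(1e3), xtol=1e-12)))
    except ValueError as exc:
        raise ConfigurationError(
            f"cohort {name}: requested rate {100 * target_rate}/100py is not attainable "
            f"under the configured censoring (accrual {a}-{b}y, dropout {mu}/y)"
        ) from exc


def generate_multicohort(config: SimConfig, seed: int | None = None) -> CohortDataset:
    """Draw a full multi-cohort dataset; deterministic in (config, seed)."""
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    frames = []
    truth = {}
    for spec in config.cohorts:
        df = _generate_covariates(rng, spec, config)
        X = design_matrix(df, list(config.coefficients), allow_missing=False)
        beta = np.array([config.coefficients[c] for c in X.columns])
        ref = np.array([config.reference.get(c, 0.0) for c in X.columns])
        k = np.exp((X.to_numpy() - ref) @ beta)

        window = _accrual_window(spec, config)
        if spec.baseline_survival_10y is not None:
            h0 = -np.log(spec.baseline_survival_10y) / 10.0
        else:
            h0 = _calibrate_h0(k, spec.rate_per_100py / 100.0, config, window, spec.name)
        truth[spec.name] = {"h0": float(h0), "accrual_window": list(window)}

        lam = h0 * k
        shape = config.weibull_shape
        u = rng.random(spec.n)
        if shape == 1.0:
            t_event = -np.log(u) / lam
        else:
            # H(t) = lam * t^shape  =>  t = (-log U / lam)^(1/shape)
            t_event = (-np.log(u) / lam) ** (1.0 / shape)
        a, b = window
        t_admin = rng.uniform(a, b, spec.n)
        if config.dropout_rate > 0:
            t_drop = rng.exponential(1.0 / config.dropout_rate, spec.n)
        else:
            t_drop = np.full(spec.n, np.inf)
        t_cens = np.minimum(t_admin, t_drop)
        df["followup_time"] = np.maximum(np.minimum(t_event, t_cens), 1e-4)
        df["cvd_event"] = (t_event <= t_cens).astype(float)
        frames.append(df)

    data = pd.concat(frames, ignore_index=True)
    data["id"] = [f"S{i:06d}" for i in range(len(data))]
    strata = {c.name: c.stratum for c in config.cohorts}
    ds = CohortDataset(
        data, strata=strata,
        provenance={"seed": int(seed), "config_digest": config.digest(),
                    "baseline_hazards": truth},
    )
    if config.missingness:
        ds = inject_missingness(ds, config.missingness, seed=seed + 1)
    return ds


# ---------------------------------------------------------------------------
# missingness injection

def inject_missingness(
    ds: CohortDataset,
    plan: list[MissingnessRule],
    seed: int = 0,
) -> CohortDataset:
    """Blank cells per plan. MCAR masks uniformly; MAR scales the masking
    probability with age (older more often missing) and sex, keeping the
    target fraction in expectation. Deterministic under a fixed seed."""
    rng = np.random.default_rng(seed)
    df = ds.data.copy()
    z_age = (df["age"] - df["age"].mean()) / max(float(df["age"].std(ddof=0)), 1e-9)
    male = (df["sex"] == "male").astype(float)
    for rule in plan:
        rule.validate()
        if rule.cohorts is not None:
            unknown = set(rule.cohorts) - set(ds.cohort_ids)
            if unknown:
                raise ConfigurationError(f"missingness rule: unknown cohorts {sorted(unknown)}")
        if rule.fraction == 0:
            continue
        in_scope = (
            pd.Series(True, index=df.index)
            if rule.cohorts is None
            else df["cohort_id"].isin(rule.cohorts)
        )
        if rule.mechanism == "mar" and rule.fraction < 1:
            score = np.exp(0.5 * z_age + 0.3 * male)
            p = rule.fraction * score / float(score[in_scope].mean())
            p = np.clip(p, 0.0, 1.0)
        else:
            p = np.full(len(df), rule.fraction)
        mask = in_scope.to_numpy() & (rng.random(len(df)) < p)
        df.loc[mask, rule.variable] = np.nan
    # the lipid ratio is derived, never independently observed
    df["tc_hdl_ratio"] = df["tc"] / df["hdl"]
    out = ds.with_data(df)
    out.provenance = {**ds.provenance, "missingness_seed": int(seed)}
    return out


def write_dataset(ds: CohortDataset, config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Persist dataset CSV, config YAML and a JSON provenance sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": outdir / "cohort.csv",
        "config": outdir / "sim_config.yaml",
        "provenance": outdir / "provenance.json",
    }
    ds.save(paths["data"])
    config.save(paths["config"])
    paths["provenance"].write_text(json.dumps(
        {"seed": ds.provenance.get("seed"), "config_digest": config.digest(),
         "n": ds.n}, indent=2))
    return paths
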