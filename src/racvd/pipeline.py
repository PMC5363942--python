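"""Configuration-driven orchestration: simulate -> harmonize -> impute ->
develop -> validate -> compare -> report.

Each stage writes versioned CSV/JSON artifacts into the output directory and
appends input digests to a manifest, so re-running with unchanged inputs
reproduces byte-identical numeric outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cohort as co
from . import develop, equations, metrics, simulate
from .impute import impute as run_impute
from .design import CANDIDATE_COVARIATES
from .exceptions import ConfigurationError

log = logging.getLogger(__name__)

STAGES = ("simulate", "prepare", "impute", "develop", "validate", "compare", "report")


@dataclass
class PipelineConfig:
    outdir: str = "racvd_out"
    seed: int = 0
    sim: simulate.SimConfig | None = None
    data_path: str | None = None
    strata: dict[str, str] = field(default_factory=dict)
    m_imputations: int = 10
    mice_iterations: int = 5
    truncation_years: float = 12.0
    horizon: float = 10.0
    cv_folds: int = 10
    lasso_folds: int = 10
    candidates: tuple = CANDIDATE_COVARIATES
    comparator: str = "frs_general_cvd"
    frs_non_hf_fraction: float | None = None
    exclude_cohorts: tuple = ()

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        sim = doc.pop("sim", None)
        cfg = cls(**doc)
        if sim is not None:
            cfg.sim = simulate.SimConfig.from_dict(sim)
        return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Pipeline:
    """Stateful runner; stages communicate through attributes and disk."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": {}}
        self.ds = None
        self.imp = None
        self.model_a = None
        self.model_b = None
        self.cv_a = None
        self.cv_b = None
        self.report_values: dict = {}

    def _record(self, stage: str, paths: dict[str, Path]) -> None:
        self.manifest["stages"][stage] = {k: _digest(p) for k, p in paths.items() if p.exists()}
        (self.out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    # -- stages -------------------------------------------------------------
    def stage_simulate(self):
        cfg = self.cfg.sim or simulate.default_config(seed=self.cfg.seed)
        self.ds = simulate.generate_multicohort(cfg, seed=self.cfg.seed)
        paths = simulate.write_dataset(self.ds, cfg, self.out / "simulated")
        self._record("simulate", paths)

    def stage_prepare(self):
        if self.ds is None:
            if self.cfg.data_path is None:
                raise ConfigurationError("no dataset: run simulate or set data_path")
            self.ds = co.load_cohort(self.cfg.data_path,
                                     strata=self.cfg.strata or None)
        if self.cfg.exclude_cohorts:
            keep = ~self.ds.data["cohort_id"].isin(self.cfg.exclude_cohorts)
            self.ds = self.ds.with_data(self.ds.data.loc[keep])
            self.ds.strata = {k: v for k, v in self.ds.strata.items()
                              if k not in self.cfg.exclude_cohorts}
        self.ds = co.exclude_prior_cvd(self.ds)
        rates = co.person_year_rate(self.ds)
        self.ds = co.truncate_followup(self.ds, self.cfg.truncation_years)
        p = self.out / "event_rates.csv"
        rates.to_csv(p, index=False)
        km = co.km_curve(self.ds, group="cohort_id")
        km_path = self.out / "km_curves.csv"
        km.to_csv(km_path, index=False)
        self.report_values["overall_rate_per_100py"] = float(
            rates.loc[rates["cohort"] == "OVERALL", "rate_per_100py"].iloc[0])
        self._record("prepare", {"event_rates": p, "km_curves": km_path})

    def stage_impute(self):
        self.imp = run_impute(self.ds, m=self.cfg.m_imputations,
                              n_iter=self.cfg.mice_iterations, seed=self.cfg.seed)
        outdir = self.out / "imputed"
        self.imp.save(outdir)
        self._record("impute", {"manifest": outdir / "manifest.json"})

    def stage_develop(self):
        sel = develop.select_base_model(self.imp, self.cfg.candidates,
                                        folds=self.cfg.lasso_folds, seed=self.cfg.seed)
        report = develop.assess_ra_characteristics(self.imp, sel.selected)
        self.model_a, self.model_b = develop.finalize_models(self.imp, sel.selected)
        paths = {}
        paths["ra_report"] = self.out / "ra_characteristics.csv"
        report.to_csv(paths["ra_report"], index=False)
        for tag, model in (("model_a", self.model_a), ("model_b", self.model_b)):
            pth = self.out / f"{tag}.yaml"
            equations.save_equation(model.to_equation_doc(f"fitted_{tag}"), pth)
            paths[tag] = pth
            model.summary().to_csv(self.out / f"{tag}_coefficients.csv")
        self.report_values["selected_covariates"] = sel.selected
        self._record("develop", paths)

    def stage_validate(self):
        # out-of-fold performance on the first completed dataset (validation on
        # every imputation would multiply runtime for little extra information)
        perf = {}
        df = develop._with_stratum(self.imp.datasets[0], self.imp.strata)
        for tag, extra in (("model_a", "das28esr"), ("model_b", "haq")):
            sub = df[df[extra].notna()].reset_index(drop=True)
            covs = [c for c in (self.model_a if tag == "model_a" else self.model_b).covariates]
            cv = metrics.kfold_cv(sub, covs, k=self.cfg.cv_folds, seed=self.cfg.seed,
                                  horizon=self.cfg.horizon)
            if tag == "model_a":
                self.cv_a, self._df_a = cv, sub
            else:
                self.cv_b, self._df_b = cv, sub
            perf[tag] = {
                "c": cv.c["c"], "c_ci": [cv.c["ci_lower"], cv.c["ci_upper"]],
                "sir": cv.sir["sir"], "sir_ci": [cv.sir["ci_lower"], cv.sir["ci_upper"]],
                "decile_p": cv.calibration.p,
            }
            cv.calibration.to_csv(self.out / f"calibration_{tag}.csv")
        p = self.out / "performance.json"
        p.write_text(json.dumps(perf, indent=2))
        self.report_values["performance"] = perf
        self._record("validate", {"performance": p})

    def stage_compare(self):
        eq = equations.load_equation(self.cfg.comparator)
        df = self._df_a
        risk_ref = equations.evaluate(eq, df)
        if self.cfg.frs_non_hf_fraction:
            risk_ref = equations.adjust_outcome_subset(risk_ref, self.cfg.frs_non_hf_fraction)
        paths = {}
        for stratum in ("high", "low"):
            m = (df["stratum"] == stratum).to_numpy()
            tab = metrics.reclassification(
                self.cv_a.predictions[m], risk_ref[m],
                df["followup_time"].to_numpy()[m], df["cvd_event"].to_numpy()[m],
                horizon=self.cfg.horizon, model_name="model_a", reference_name=eq.name)
            pth = self.out / f"reclassification_{stratum}.csv"
            tab.to_frame().to_csv(pth, index=False)
            paths[f"reclassification_{stratum}"] = pth
            self.report_values[f"reclassification_{stratum}"] = tab.summary_percentages()
        scat = metrics.scatter_compare(risk_ref, self.cv_a.predictions)
        scat_path = self.out / "scatter_model_a_vs_comparator.csv"
        scat.to_csv(scat_path, index=False)
        paths["scatter"] = scat_path
        self._record("compare", paths)

    def stage_report(self):
        p = self.out / "report.json"
        p.write_text(json.dumps(self.report_values, indent=2, default=str))
        self._record("report", {"report": p})

    def run(self, stages=STAGES) -> dict:
        for s in stages:
            if s not in STAGES:
                raise ConfigurationError(f"unknown stage {s!r} (choose from {STAGES})")
        for s in STAGES:
            if s in stages:
                log.info("stage: %s", s)
                getattr(self, f"stage_{s}")()
        return self.report_values


def run(stages, config: PipelineConfig) -> dict:
    return Pipeline(config).run(tuple(stages))
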