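"""Stratified Cox estimation against independent oracles, baseline survival,
prediction arithmetic, and the penalized path."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from conftest import make_frame
from racvd import simulate as sim
from racvd.cox import StepFunction, StratifiedCoxModel, nonlinearity_check, rcs_basis
from racvd.design import CANDIDATE_COVARIATES
from racvd.exceptions import FitError, SchemaError
from racvd.lasso import CoxLassoModel, _fit_path, partial_loglik


def naive_partial_loglik(X, t, d, strata, beta):
    """O(n^2) textbook Breslow partial likelihood, written independently."""
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    ll = 0.0
    for i in range(len(t)):
        if d[i] != 1:
            continue
        risk = [j for j in range(len(t)) if strata[j] == strata[i] and t[j] >= t[i]]
        ll += X[i] @ beta - np.log(np.sum(np.exp(X[risk] @ beta)))
    return ll


@pytest.fixture(scope="module")
def frame_1cov():
    rng = np.random.default_rng(17)
    n = 40
    x = (rng.random(n) < 0.5).astype(float)
    lam = 0.1 * np.exp(0.7 * x)
    T = rng.exponential(1 / lam)
    C = rng.uniform(2, 15, n)
    df = pd.DataFrame({
        "x": x,
        "followup_time": np.minimum(T, C),
        "cvd_event": (T <= C).astype(float),
        "stratum": "all",
    })
    assert not df["followup_time"].duplicated().any()  # tie-free by construction
    return df


class TestPartialLikelihoodOracles:
    def test_single_binary_covariate_matches_brute_force(self, frame_1cov):
        df = frame_1cov
        res = StratifiedCoxModel(df, ["x"], strata_col="stratum",
                                 reference={"x": 0.0}).fit()

        def negll(b):
            return -naive_partial_loglik(df[["x"]].to_numpy(),
                                         df["followup_time"].to_numpy(),
                                         df["cvd_event"].to_numpy(),
                                         df["stratum"].to_numpy(), [b])

        brute = minimize_scalar(negll, bounds=(-4, 4), method="bounded",
                                options={"xatol": 1e-10})
        assert abs(res.params["x"] - brute.x) < 1e-6

    def test_engine_loglik_matches_naive_on_n200(self, small_df):
        df = small_df.head(200)
        X = pd.DataFrame({"age10": df["age"] / 10, "haq": df["haq"]})
        t = df["followup_time"].to_numpy()
        d = df["cvd_event"].to_numpy()
        strata = df["stratum"].to_numpy()
        for beta in ([0.0, 0.0], [0.4, -0.2], [1.0, 0.5]):
            mine = partial_loglik(X.to_numpy(), t, d, strata, beta)
            naive = naive_partial_loglik(X.to_numpy(), t, d, strata, beta)
            assert abs(mine - naive) < 1e-8

    def test_null_covariate_near_zero(self):
        cfg = sim.two_strata_config(n_per_stratum=4000,
                                    coefficients={"age10": 0.0}, seed=8)
        ds = sim.generate_multicohort(cfg, seed=8)
        df = ds.data.copy()
        df["stratum"] = ds.stratum_of().to_numpy()
        res = StratifiedCoxModel(df, ["age10"], strata_col="stratum").fit()
        assert abs(res.params["age10"]) < 3 * res.bse["age10"]

    def test_efron_and_breslow_agree_without_ties(self, frame_1cov):
        a = StratifiedCoxModel(frame_1cov, ["x"], strata_col="stratum").fit()
        b = StratifiedCoxModel(frame_1cov, ["x"], strata_col="stratum",
                               ties="breslow").fit()
        assert abs(a.params["x"] - b.params["x"]) < 1e-5

    def test_zero_events_in_stratum_rejected(self):
        df = make_frame([
            {"followup_time": 1.0, "cvd_event": 1, "cohort_id": "a"},
            {"followup_time": 2.0, "cvd_event": 0, "cohort_id": "b"},
        ])
        df["stratum"] = ["s1", "s2"]
        with pytest.raises(FitError, match="s2"):
            StratifiedCoxModel(df, ["age10"], strata_col="stratum")


class TestBreslowBaseline:
    def test_reduces_to_nelson_aalen_without_covariate_effect(self, toy_km_frame):
        from racvd.cox import StratifiedCoxResults

        rng = np.random.default_rng(0)
        df = toy_km_frame.copy()
        df["stratum"] = "all"
        df["x"] = rng.normal(size=len(df))
        model = StratifiedCoxModel(df, ["x"], strata_col="stratum",
                                   reference={"x": 0.0})
        fitted = model.fit()
        # force a zero coefficient: the Breslow baseline must reduce to the
        # Nelson-Aalen survival of the raw data
        res = StratifiedCoxResults(model, fitted.params * 0.0, fitted.cov,
                                   fitted.loglik)
        s0 = res.baseline_survival["all"]
        # hand Nelson-Aalen: d/n at 1,3,5,6 with risk sets 6,4,2,1
        h = np.cumsum([1 / 6, 1 / 4, 1 / 2, 1 / 1])
        np.testing.assert_allclose(s0(np.array([1.0, 3.0, 5.0, 6.0])),
                                   np.exp(-h), rtol=1e-6)

    def test_hand_computed_increments_with_covariate(self):
        # 5 subjects, events at t=1,2,4; known lp exactly reproduces Breslow sums
        df = pd.DataFrame({
            "x": [1.0, 0.0, 1.0, 0.0, 0.0],
            "followup_time": [1.0, 2.0, 3.0, 4.0, 5.0],
            "cvd_event": [1, 1, 0, 1, 0],
            "stratum": "all",
        })
        res = StratifiedCoxModel(df, ["x"], strata_col="stratum",
                                 reference={"x": 0.0}).fit()
        b = float(res.params["x"])
        e = np.exp(b * df["x"].to_numpy())
        h1 = 1 / e.sum()
        h2 = 1 / e[1:].sum()
        h4 = 1 / e[3:].sum()
        s0 = res.baseline_survival["all"]
        np.testing.assert_allclose(
            s0(np.array([1.0, 2.0, 4.0])),
            np.exp(-np.cumsum([h1, h2, h4])), rtol=1e-9)

    def test_starts_at_one_and_carries_last_value(self, small_df):
        res = StratifiedCoxModel(small_df, ["age10"], strata_col="stratum").fit()
        s0 = res.baseline_survival["high"]
        assert s0(0.0) == 1.0
        assert s0(-1.0) == 1.0
        assert s0(s0.last_time + 100.0) == s0(s0.last_time)

    def test_nonincreasing(self, small_df):
        res = StratifiedCoxModel(small_df, ["age10", "male"], strata_col="stratum").fit()
        for s0 in res.baseline_survival.values():
            assert (np.diff(s0.values) <= 1e-12).all()
            assert s0.values[0] <= 1.0


@pytest.fixture(scope="module")
def fitted(small_df):
    covs = ["age10", "male", "current_smoker", "hypertension",
            "tc_hdl_ratio", "das28esr"]
    return StratifiedCoxModel(small_df, covs, strata_col="stratum").fit()


class TestPrediction:
    def _reference_subject(self):
        return make_frame([{
            "age": 55.3, "sex": "female", "smoking": "never", "hypertension": 0,
            "tc": 2.17 * 1.4, "hdl": 1.4, "das28esr": 4.0,
        }])

    def test_reference_subject_risk_is_one_minus_s0(self, fitted):
        subj = self._reference_subject()
        for stratum in ("high", "low"):
            risk = fitted.predict_risk(subj, horizon=10.0, stratum=stratum)[0]
            assert np.isclose(risk, 1.0 - fitted.baseline_survival_at(stratum, 10.0),
                              atol=1e-10)

    def test_risk_monotone_in_positive_coefficient_covariate(self, fitted):
        subj = pd.concat([self._reference_subject()] * 3, ignore_index=True)
        subj["das28esr"] = [2.0, 4.0, 6.0]
        risks = fitted.predict_risk(subj, stratum="high")
        assert risks[0] < risks[1] < risks[2]

    def test_missing_covariate_named(self, fitted):
        subj = self._reference_subject()
        subj["das28esr"] = np.nan
        with pytest.raises(SchemaError, match="das28esr"):
            fitted.predict_risk(subj, stratum="high")

    def test_unknown_stratum_rejected(self, fitted):
        with pytest.raises(FitError, match="mid"):
            fitted.predict_risk(self._reference_subject(), stratum="mid")

    def test_cumhaz_consistent_with_risk(self, fitted, small_df):
        sub = small_df.head(50)
        risk = fitted.predict_risk(sub, horizon=10.0)
        H = fitted.predict_cumhaz(sub, np.full(len(sub), 10.0))
        np.testing.assert_allclose(risk, 1.0 - np.exp(-H), rtol=1e-10)

    def test_summary_exposes_hr_and_ci(self, fitted):
        summ = fitted.summary()
        assert {"coef", "hr", "se", "p", "hr_ci_lower", "hr_ci_upper"} <= set(summ.columns)
        assert ((summ["hr_ci_lower"] <= summ["hr"])
                & (summ["hr"] <= summ["hr_ci_upper"])).all()

    def test_json_roundtrip_fields(self, fitted, tmp_path):
        p = tmp_path / "fit.json"
        doc = fitted.to_json(p)
        assert p.exists()
        assert doc["ties"] == "efron"
        assert set(doc["baseline_survival"]) == {"high", "low"}


class TestPHCheck:
    def test_type_one_error_near_alpha_under_ph(self):
        rng = np.random.default_rng(31)
        rejections = 0
        reps = 200
        for _ in range(reps):
            n = 300
            x = rng.normal(0, 1, n)
            lam = 0.08 * np.exp(0.5 * x)
            T = rng.exponential(1 / lam)
            C = rng.uniform(1, 12, n)
            df = pd.DataFrame({"x": x, "followup_time": np.minimum(T, C),
                               "cvd_event": (T <= C).astype(float), "stratum": "all"})
            res = StratifiedCoxModel(df, ["x"], strata_col="stratum").fit()
            rejections += res.ph_test().loc["x", "p"] < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_power_against_time_varying_effect(self):
        rng = np.random.default_rng(32)
        hits = 0
        reps = 20
        for _ in range(reps):
            n = 2000
            x = rng.normal(0, 1, n)
            # effect reverses over time: early hazard up, late hazard down
            u = rng.random(n)
            t1 = -np.log(u) / (0.25 * np.exp(1.0 * x))
            T = np.where(t1 < 2.0, t1, 2.0 + (t1 - 2.0) * np.exp(1.6 * x))
            C = rng.uniform(1, 12, n)
            df = pd.DataFrame({"x": x, "followup_time": np.minimum(T, C),
                               "cvd_event": (T <= C).astype(float), "stratum": "all"})
            res = StratifiedCoxModel(df, ["x"], strata_col="stratum").fit()
            hits += res.ph_test().loc["x", "p"] < 0.05
        assert hits / reps > 0.8

    def test_single_event_degenerate(self):
        df = make_frame([
            {"followup_time": 1.0, "cvd_event": 1},
            {"followup_time": 2.0, "cvd_event": 0},
            {"followup_time": 3.0, "cvd_event": 0},
        ])
        df["stratum"] = "all"
        res = StratifiedCoxModel(df, ["age10"], strata_col="stratum").fit()
        tab = res.ph_test()
        assert tab["degenerate"].all()
        assert tab["p"].isna().all()


class TestNonlinearity:
    def _sim(self, rng, n, quadratic):
        x = rng.uniform(-2, 2, n)
        effect = 0.35 * x + (0.5 * x**2 if quadratic else 0.0)
        lam = 0.05 * np.exp(effect)
        T = rng.exponential(1 / lam)
        C = rng.uniform(1, 12, n)
        return pd.DataFrame({"x": x, "followup_time": np.minimum(T, C),
                             "cvd_event": (T <= C).astype(float), "stratum": "all"})

    def test_type_one_error_near_alpha_for_linear_truth(self):
        rng = np.random.default_rng(41)
        rej = sum(
            nonlinearity_check(self._sim(rng, 600, False), "x", ["x"])["p"] < 0.05
            for _ in range(100)
        )
        assert 0.01 <= rej / 100 <= 0.11

    def test_power_against_quadratic_truth(self):
        rng = np.random.default_rng(42)
        hits = sum(
            nonlinearity_check(self._sim(rng, 2000, True), "x", ["x"])["p"] < 0.05
            for _ in range(20)
        )
        assert hits / 20 > 0.8

    def test_too_few_distinct_values_rejected(self, small_df):
        with pytest.raises(FitError):
            nonlinearity_check(small_df, "male", ["age10", "male"])

    def test_rcs_basis_linear_in_tails(self):
        knots = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.array([-5.0, -4.0, 8.0, 9.0])
        b = rcs_basis(x, knots)
        # natural spline: second differences vanish outside the boundary knots
        left = b[1] - b[0]
        right = b[3] - b[2]
        assert np.allclose(b[0], 0) and np.allclose(left, 0)
        assert np.all(np.isfinite(right))


class TestLassoPath:
    def test_largest_lambda_gives_empty_model(self, small_df):
        model = CoxLassoModel(small_df, CANDIDATE_COVARIATES, strata_col="stratum")
        lambdas = model._lambda_grid()
        coefs = _fit_path(model.Xs, model.t, model.d, model.strata, lambdas[:1])
        assert np.allclose(coefs[0], 0.0, atol=1e-10)

    def test_zero_penalty_matches_unpenalized_fit(self, small_df):
        covs = ["age10", "male", "hypertension", "tc_hdl_ratio"]
        unpen = StratifiedCoxModel(small_df, covs, strata_col="stratum",
                                   ties="breslow").fit()
        model = CoxLassoModel(small_df, covs, strata_col="stratum")
        coefs = _fit_path(model.Xs, model.t, model.d, model.strata,
                          np.array([1e-8]))
        np.testing.assert_allclose(coefs[0] / model.sd,
                                   unpen.params.to_numpy(), atol=1e-4)

    def test_path_and_selection_invariants(self, small_df):
        res = CoxLassoModel(small_df, CANDIDATE_COVARIATES,
                            strata_col="stratum").fit(cv_folds=5, seed=0)
        assert set(res.selected) <= set(CANDIDATE_COVARIATES)
        assert res.lambda_1se >= res.lambda_min
        assert np.allclose(res.coefs[0], 0.0, atol=1e-10)
        nonzero = (res.coefs != 0).sum(axis=1)
        assert nonzero[0] <= nonzero[-1]
        assert len(res.path_frame()) == len(res.lambdas)

    def test_cv_deterministic_in_seed(self, small_df):
        covs = ["age10", "male", "hypertension", "tc_hdl_ratio", "tc", "hdl"]
        a = CoxLassoModel(small_df, covs, strata_col="stratum").fit(cv_folds=5, seed=3)
        b = CoxLassoModel(small_df, covs, strata_col="stratum").fit(cv_folds=5, seed=3)
        assert a.lambda_1se == b.lambda_1se
        np.testing.assert_array_equal(a.cv_mean, b.cv_mean)

    def test_fewer_events_than_folds_rejected(self, frame_1cov):
        few = frame_1cov.copy()
        few.loc[few.index[5:], "cvd_event"] = 0
        n_events = int(few["cvd_event"].sum())
        with pytest.raises(FitError):
            CoxLassoModel(few, ["x"], strata_col="stratum").fit(cv_folds=n_events + 1)

    def test_constant_candidate_rejected(self, small_df):
        df = small_df.copy()
        df["flat"] = 1.0
        with pytest.raises(FitError, match="flat"):
            CoxLassoModel(df, ["age10", "flat"], strata_col="stratum")


def test_step_function_interpolation():
    f = StepFunction([1.0, 2.0, 3.0], [0.9, 0.8, 0.7], initial=1.0)
    np.testing.assert_allclose(f(np.array([0.5, 1.0, 2.5, 99.0])),
                               [1.0, 0.9, 0.8, 0.7])
    assert f(0.0) == 1.0
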