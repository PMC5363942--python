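"""Discrimination, calibration, CV and reclassification machinery."""
import numpy as np
import pandas as pd
import pytest

from racvd.exceptions import ConfigurationError, FitError
from racvd.metrics import (
    ReclassificationTable,
    calibration_plot_data,
    decile_gof,
    expected_events_from_risk,
    harrells_c,
    kfold_cv,
    reclassification,
    scatter_compare,
    sir,
)


def brute_force_c(pred, t, e):
    """Pairwise loop implementation, independent of the vectorized path."""
    conc = ties = usable = 0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (t[i] < t[j] and e[i] == 1) or (t[i] == t[j] and e[i] == 1 and e[j] == 0):
                usable += 1
                if pred[i] > pred[j]:
                    conc += 1
                elif pred[i] == pred[j]:
                    ties += 1
    return (conc + 0.5 * ties) / usable


class TestHarrellsC:
    def test_perfect_ranking_gives_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        pred = np.array([0.9, 0.7, 0.5, 0.3])
        assert harrells_c(pred, t, e)["c"] == 1.0

    def test_random_predictions_near_half(self):
        rng = np.random.default_rng(8)
        n = 2000
        t = rng.exponential(5, n)
        e = (rng.random(n) < 0.4).astype(int)
        res = harrells_c(rng.random(n), t, e)
        se = np.sqrt(0.25 / res["pairs"])
        assert abs(res["c"] - 0.5) < 3 * max(se, 0.01)

    def test_matches_brute_force_with_censoring_and_ties(self):
        rng = np.random.default_rng(9)
        n = 120
        t = np.round(rng.exponential(5, n), 1)  # induces time ties
        e = (rng.random(n) < 0.5).astype(int)
        pred = np.round(rng.random(n), 1)       # induces prediction ties
        res = harrells_c(pred, t, e)
        assert abs(res["c"] - brute_force_c(pred, t, e)) < 1e-12

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        n = 300
        pred = rng.random(n)
        t = rng.exponential(5, n)
        e = (rng.random(n) < 0.5).astype(int)
        a = harrells_c(pred, t, e)["c"]
        b = harrells_c(np.log(pred + 1.0), t, e)["c"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_all_censored_rejected(self):
        with pytest.raises(FitError):
            harrells_c([0.1, 0.2], [1.0, 2.0], [0, 0])

    def test_bounded_ci(self):
        res = harrells_c([0.9, 0.1], [1.0, 5.0], [1, 1])
        assert 0.0 <= res["ci_lower"] <= res["c"] <= res["ci_upper"] <= 1.0


class TestExpectedEventsAndSIR:
    def test_linearity_in_hazard(self):
        risk = np.array([0.05, 0.10, 0.20])
        fup = np.array([10.0, 10.0, 10.0])
        e1 = expected_events_from_risk(risk, fup)
        doubled = 1 - (1 - risk) ** 2  # doubled cumulative hazard
        e2 = expected_events_from_risk(doubled, fup)
        np.testing.assert_allclose(e2, 2 * e1, rtol=1e-12)

    def test_small_risk_totals_match_sum_of_risks(self):
        rng = np.random.default_rng(11)
        risk = rng.uniform(0.001, 0.049, 400)
        fup = np.full(400, 10.0)  # nobody censored before the horizon
        total = expected_events_from_risk(risk, fup).sum()
        assert abs(total - risk.sum()) / risk.sum() < 0.02

    def test_exposure_scales_expectation(self):
        e_full = expected_events_from_risk([0.2], [10.0])[0]
        e_half = expected_events_from_risk([0.2], [5.0])[0]
        assert e_half == pytest.approx(e_full / 2)

    def test_negative_followup_rejected(self):
        with pytest.raises(ConfigurationError):
            expected_events_from_risk([0.1], [-1.0])

    def test_sir_point_values(self):
        assert sir(100, 100.0)["sir"] == pytest.approx(1.0)
        assert sir(83, 100.0)["sir"] == pytest.approx(0.83)

    def test_sir_exact_poisson_ci_hand_values(self):
        # published exact limits for 10 observed events: (4.795, 18.390)
        res = sir(10, 10.0)
        assert res["ci_lower"] == pytest.approx(0.4795389, abs=1e-6)
        assert res["ci_upper"] == pytest.approx(1.8390356, abs=1e-6)

    def test_sir_zero_expected_rejected(self):
        with pytest.raises(ConfigurationError):
            sir(5, 0.0)


class TestDecileGof:
    def _calibrated(self, seed, n=4000):
        rng = np.random.default_rng(seed)
        lam = np.exp(rng.normal(np.log(0.01), 0.5, n))
        risk = 1 - np.exp(-lam * 10)
        T = rng.exponential(1 / lam)
        C = np.minimum(rng.uniform(1, 12, n), rng.exponential(1 / 0.03, n))
        return risk, np.minimum(T, C), (T <= C).astype(int)

    def test_internal_penalty_uses_eight_df(self):
        risk, t, e = self._calibrated(1)
        internal = decile_gof(risk, t, e, df_penalty=1)
        external = decile_gof(risk, t, e, df_penalty=0)
        assert internal.df == 8
        assert external.df == 9
        assert internal.chi2 == pytest.approx(external.chi2)

    def test_table_shape_and_totals(self):
        risk, t, e = self._calibrated(2)
        cal = decile_gof(risk, t, e)
        assert len(cal.table) == 10
        assert cal.table["n"].sum() == len(risk)
        within = int((e * (t <= 10.0)).sum())
        assert cal.table["observed_events"].sum() == within
        assert cal.sir["observed"] == within

    def test_calibrated_predictions_rarely_rejected(self):
        # any single 5%-level test may reject by chance; the rejection
        # frequency over seeds is the meaningful check
        rejections = sum(
            decile_gof(*self._calibrated(seed, n=2000)).p < 0.05
            for seed in range(20)
        )
        assert rejections <= 4

    def test_inflated_predictions_strongly_rejected(self):
        risk, t, e = self._calibrated(4, n=5000)
        inflated = np.clip(risk * 2, 0, 0.99)
        cal = decile_gof(inflated, t, e)
        assert cal.p < 0.001
        assert cal.sir["sir"] < 1.0  # overestimation flagged by SIR too

    def test_constant_predictions_rejected(self):
        with pytest.raises(FitError):
            decile_gof(np.full(100, 0.1), np.ones(100), np.ones(100, dtype=int))

    def test_sparse_groups_merged_with_warning(self):
        rng = np.random.default_rng(6)
        n = 300
        risk = rng.uniform(0.0005, 0.01, n)  # tiny expected counts
        t = rng.uniform(0.5, 2.0, n)
        e = (rng.random(n) < 0.01).astype(int)
        with pytest.warns(UserWarning, match="merging"):
            cal = decile_gof(risk, t, e)
        assert cal.merged_groups
        assert len(cal.table) < 10


@pytest.fixture(scope="module")
def cv_result(small_df):
    covs = ["age10", "male", "hypertension", "tc_hdl_ratio"]
    return kfold_cv(small_df, covs, k=5, seed=3)


class TestKFoldCV:
    def test_every_subject_predicted_once(self, cv_result, small_df):
        assert np.isfinite(cv_result.predictions).all()
        assert (cv_result.folds >= 0).all()
        assert len(np.unique(cv_result.folds)) == 5

    def test_same_seed_same_folds(self, small_df):
        covs = ["age10", "male"]
        a = kfold_cv(small_df, covs, k=5, seed=4)
        b = kfold_cv(small_df, covs, k=5, seed=4)
        np.testing.assert_array_equal(a.folds, b.folds)
        np.testing.assert_allclose(a.predictions, b.predictions)

    def test_performance_fields(self, cv_result):
        assert 0.5 < cv_result.c["c"] < 1.0
        assert 0.5 < cv_result.sir["sir"] < 2.0
        assert cv_result.calibration.df == 8  # internal evaluation convention

    def test_cv_c_below_apparent_on_overfit_prone_data(self):
        rng = np.random.default_rng(12)
        diffs = []
        for s in range(15):
            n = 250
            noise = {f"z{j}": rng.normal(0, 1, n) for j in range(8)}
            t = rng.exponential(8, n)
            c_ = rng.uniform(1, 12, n)
            df = pd.DataFrame({
                **noise,
                "followup_time": np.minimum(t, c_),
                "cvd_event": (t <= c_).astype(float),
                "stratum": "all",
            })
            cv = kfold_cv(df, list(noise), k=5, seed=s)
            diffs.append(cv.apparent_c["c"] - cv.c["c"])
        assert np.mean(diffs) > 0

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({
            "x": np.arange(20.0),
            "followup_time": np.linspace(1, 5, 20),
            "cvd_event": [1.0] + [0.0] * 19,
            "stratum": "all",
        })
        with pytest.raises(ConfigurationError):
            kfold_cv(df, ["x"], k=5, seed=0)


# Cross-classification grids (reference rows x model columns) transcribed from
# the published high/low-risk-center comparison of the DAS28 calculator vs the
# general-population score; used as fixed numeric input.
HIGH_NO_EVENT = [[329, 320, 52, 1], [15, 241, 289, 35], [1, 64, 371, 203], [0, 3, 107, 424]]
HIGH_EVENT = [[5, 9, 4, 0], [0, 9, 22, 7], [0, 4, 32, 30], [0, 0, 12, 108]]
LOW_NO_EVENT = [[414, 19, 0, 0], [163, 176, 12, 0], [29, 247, 139, 2], [0, 52, 173, 67]]
LOW_EVENT = [[1, 1, 0, 0], [1, 7, 2, 0], [2, 9, 3, 0], [0, 0, 9, 7]]


class TestReclassification:
    def test_printed_low_risk_percentages(self):
        tab = ReclassificationTable.from_counts(LOW_NO_EVENT, LOW_EVENT)
        assert tab.summary_percentages() == {"same": 53, "higher": 2, "lower": 45}

    def test_printed_high_risk_percentages(self):
        tab = ReclassificationTable.from_counts(HIGH_NO_EVENT, HIGH_EVENT)
        pct = tab.summary_percentages()
        assert pct["higher"] == 36
        assert pct["lower"] == 8
        # the computed diagonal (56%) is what the counts imply
        assert pct["same"] == 56

    def test_percentages_sum_to_hundred_before_rounding(self):
        tab = ReclassificationTable.from_counts(HIGH_NO_EVENT, HIGH_EVENT)
        pct = tab.summary_percentages(decimals=None)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_identical_predictions_all_same(self):
        rng = np.random.default_rng(13)
        pred = rng.uniform(0, 0.4, 500)
        t = rng.exponential(8, 500)
        e = (rng.random(500) < 0.2).astype(int)
        tab = reclassification(pred, pred, t, e)
        assert tab.summary_percentages() == {"same": 100, "higher": 0, "lower": 0}

    def test_counts_conserve_n_and_split_by_event(self):
        rng = np.random.default_rng(14)
        n = 800
        pa, pb = rng.uniform(0, 0.5, n), rng.uniform(0, 0.5, n)
        t = rng.exponential(8, n)
        e = (rng.random(n) < 0.25).astype(int)
        tab = reclassification(pa, pb, t, e)
        assert tab.total == n
        assert tab.counts_event.sum() == e.sum()
        frame = tab.to_frame()
        assert len(frame) == 16
        assert "observed_10y_risk" in frame.columns

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            reclassification([0.1], [0.1, 0.2], [1.0, 2.0], [0, 1])


class TestPlotData:
    def test_calibrated_deciles_sit_near_identity(self):
        rng = np.random.default_rng(15)
        n = 6000
        lam = np.exp(rng.normal(np.log(0.012), 0.5, n))
        risk = 1 - np.exp(-lam * 10)
        T = rng.exponential(1 / lam)
        C = rng.uniform(8, 12, n)
        tab = calibration_plot_data(risk, np.minimum(T, C), (T <= C).astype(int))
        assert len(tab) == 10
        inside = ((tab["observed_ci_lower"] - 0.02 <= tab["mean_predicted"])
                  & (tab["mean_predicted"] <= tab["observed_ci_upper"] + 0.02))
        assert inside.sum() >= 8

    def test_scatter_trend_deterministic(self):
        rng = np.random.default_rng(16)
        x = rng.uniform(0, 0.5, 300)
        y = x * 0.8 + rng.normal(0, 0.02, 300)
        a = scatter_compare(x, y)
        b = scatter_compare(x, y)
        pd.testing.assert_frame_equal(a, b)
        assert {"x", "y", "identity", "trend"} <= set(a.columns)
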