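"""Leverages, degrees of freedom, prediction intervals, streaming prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from roastcal.online import (
    degrees_of_freedom,
    leverage_new,
    prediction_interval,
    predict_stream,
)
from roastcal.pipeline import calibrate_records
from roastcal.pls import fit_pls
from roastcal.synthetic import simulate_roast

from conftest import make_linear_problem


@pytest.fixture(scope="module")
def model_data():
    X, y = make_linear_problem(30, 8, rank=5, noise_sd=0.3, seed=0)
    return fit_pls(X, y, 4), X, y


class TestLeverage:
    def test_calibration_sample_keeps_its_leverage(self, model_data):
        m, X, _ = model_data
        T = m.scores
        h_cal = np.diag(T @ np.linalg.solve(T.T @ T, T.T))
        assert np.allclose(leverage_new(m, X), h_cal, atol=1e-10)

    def test_zero_scores_zero_leverage(self, model_data):
        m, X, _ = model_data
        assert leverage_new(m, np.zeros((1, X.shape[1])))[0] == pytest.approx(0.0)

    def test_outlying_sample_exceeds_calibration_leverages(self, model_data):
        m, X, _ = model_data
        h_cal = leverage_new(m, X)
        far = 20.0 * X[np.argmax(h_cal)][None, :]
        assert leverage_new(m, far)[0] > h_cal.max()


class TestDegreesOfFreedom:
    def test_naive_fallback_arithmetic(self):
        assert degrees_of_freedom(67, n_components=6, method="naive") == 60

    def test_never_exceeds_n_minus_one(self):
        df = degrees_of_freedom(20, rmse_fit=1.0, rmse_cv=1.0, method="pseudo")
        assert df <= 19

    def test_pseudo_df_shrinks_with_model_complexity(self):
        from roastcal.selection import monte_carlo_cv
        X, y = make_linear_problem(40, 12, rank=10, noise_sd=1.0, seed=1)
        cv = monte_carlo_cv(X, y, max_components=10, n_repeats=100, seed=2)
        dfs = [degrees_of_freedom(40, rmse_fit=cv.rmse_fit[k],
                                  rmse_cv=cv.rmse_cv[k], method="pseudo")
               for k in (0, 4, 9)]
        assert dfs[0] > dfs[1] > dfs[2]

    def test_nonpositive_naive_df_rejected(self):
        with pytest.raises(ValueError):
            degrees_of_freedom(5, n_components=5, method="naive")


class TestPredictionInterval:
    def test_normal_limit(self):
        lo, hi = prediction_interval(np.array([0.0]), sde=1.0, df=1e6,
                                     leverage=np.array([0.0]), n_cal=10**9)
        assert (hi[0] - lo[0]) / 2 == pytest.approx(1.959964, abs=1e-4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=5.0),
           st.floats(min_value=0.01, max_value=5.0))
    def test_width_increases_with_leverage(self, h, dh):
        lo1, hi1 = prediction_interval(np.array([1.0]), 2.0, 30.0,
                                       np.array([h]), 50)
        lo2, hi2 = prediction_interval(np.array([1.0]), 2.0, 30.0,
                                       np.array([h + dh]), 50)
        assert hi2[0] - lo2[0] > hi1[0] - lo1[0]

    def test_width_floor_from_unit_leverage_term(self):
        from scipy import stats
        n, df, sde = 50, 30.0, 2.0
        lo, hi = prediction_interval(np.array([0.0]), sde, df,
                                     np.array([0.3]), n)
        floor = 2 * stats.t.ppf(0.975, df) * sde * np.sqrt(1 + 1.0 / n)
        assert hi[0] - lo[0] >= floor

    def test_interval_contains_center(self):
        y = np.array([3.0, -1.0])
        lo, hi = prediction_interval(y, 1.0, 10.0, np.array([0.2, 0.8]), 20)
        assert np.all(lo <= y) and np.all(y <= hi)


@pytest.fixture(scope="module")
def bundle(campaign_small):
    return calibrate_records(campaign_small, "colorette", seed=3,
                             cv_repeats=50, do_cars=False)


class TestPredictStream:
    def test_stream_matches_batch_on_drop_spectra(self, bundle, campaign_small):
        rec = campaign_small[5]
        series = predict_stream(bundle, rec.spectra)
        batch = bundle.predict_records([rec])
        assert series["y_hat"].iloc[-1] == batch[0]

    def test_streaming_rerun_is_bit_identical(self, bundle, campaign_small):
        rec = campaign_small[5]
        a = predict_stream(bundle, rec.spectra)
        b = predict_stream(bundle, rec.spectra)
        assert a.equals(b)

    def test_noiseless_roast_predicts_monotone_colorette(self, campaign_zero_noise,
                                                         default_config):
        bundle = calibrate_records(campaign_zero_noise, "colorette", seed=4,
                                   cv_repeats=30, do_cars=False)
        rec = simulate_roast(default_config.zero_noise(), 840.0, seed=1)
        series = predict_stream(bundle, rec.spectra)
        ok = series["y_hat"].notna() & (series["time_s"] > 200.0)
        yhat = series.loc[ok, "y_hat"].to_numpy()
        assert np.all(np.diff(yhat) <= 1e-6)

    def test_extrapolation_flag_and_wider_interval(self, bundle, campaign_small):
        rec = campaign_small[0]
        series = predict_stream(bundle, rec.spectra)
        flagged = series[series["extrapolated"] & series["y_hat"].notna()]
        if len(flagged):
            width_flag = (flagged["pri_upper"] - flagged["pri_lower"]).median()
            last = series.iloc[-1]
            width_drop = last["pri_upper"] - last["pri_lower"]
            assert width_flag > width_drop * 0.99

    def test_interval_brackets_rmsep_band_center(self, bundle, campaign_small):
        series = predict_stream(bundle, campaign_small[3].spectra).dropna()
        assert np.all(series["pri_lower"] <= series["y_hat"])
        assert np.all(series["y_hat"] <= series["pri_upper"])

    def test_empty_early_spectra_flagged(self, bundle, default_config):
        rec = simulate_roast(default_config.zero_noise(), 600.0, seed=2)
        series = predict_stream(bundle, rec.spectra)
        early = series[series["time_s"] < 60.0]
        assert early["y_hat"].isna().all()
        assert early["extrapolated"].all()
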