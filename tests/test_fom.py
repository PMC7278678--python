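"""Figures of merit: error metrics, NAS quantities, the LOD family."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from roastcal.fom import (
    asen,
    convert_brew_concentration,
    extrapolated_leverages,
    lod_3rmsep,
    lod_nas,
    lod_pseudounivariate,
    lod_range,
    lod_sample_specific,
    loq,
    nas_decompose,
    r2_calibration,
    r2_prediction,
    rer,
    residual_diagnostics,
    rmse,
    rpd,
    selectivity,
    sensitivity_b,
    sensitivity_nas,
)


class TestErrorMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y) == 0.0
        assert r2_calibration(y, y) == 1.0

    def test_rmse_hand_value(self):
        assert rmse([0.0, 0.0], [0.0, 2.0]) == pytest.approx(np.sqrt(2.0))

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2_calibration(np.full(4, y.mean()), y) == pytest.approx(0.0)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            r2_calibration([1.0, 1.0], [2.0, 2.0])


class TestR2Prediction:
    def test_perfect_external_predictions(self):
        y_cal = np.array([1.0, 2.0, 3.0, 4.0])
        y_ext = np.array([1.5, 3.5])
        assert r2_prediction(y_ext, y_ext, y_cal) == 1.0

    def test_mean_predictor_near_zero(self):
        rng = np.random.default_rng(0)
        y_cal = rng.normal(10.0, 2.0, 2000)
        y_ext = rng.normal(10.0, 2.0, 2000)
        q2 = r2_prediction(np.full_like(y_ext, y_cal.mean()), y_ext, y_cal)
        assert abs(q2) < 0.1

    def test_differs_from_external_r2_under_skewed_external_set(self):
        rng = np.random.default_rng(1)
        y_cal = rng.normal(0.0, 3.0, 100)
        # external set with much smaller spread than calibration
        y_ext = rng.normal(0.0, 0.5, 50)
        y_hat = y_ext + rng.normal(0.0, 0.4, 50)
        q2f3 = r2_prediction(y_hat, y_ext, y_cal)
        r2_ext = r2_calibration(y_hat, y_ext)
        assert abs(q2f3 - r2_ext) > 0.1


class TestRerRpd:
    def test_rer_hand_value_and_scaling(self):
        y = np.array([0.0, 100.0])
        assert rer(y, 10.0) == pytest.approx(10.0)
        assert rer(y, 20.0) == pytest.approx(5.0)

    def test_rer_needs_two_samples(self):
        with pytest.raises(ValueError):
            rer([1.0], 1.0)

    def test_rpd_matches_tss_oracle_and_shift_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(5.0, 4.0, 30)
        oracle = np.sqrt(((y - y.mean()) ** 2).sum() / (y.size - 1)) / 2.0
        assert rpd(y, 2.0) == pytest.approx(oracle)
        assert rpd(y + 100.0, 2.0) == pytest.approx(rpd(y, 2.0))


class TestSensitivity:
    def test_sen_b_hand_value(self):
        assert sensitivity_b([0.6, 0.8]) == pytest.approx(1.0)

    def test_sen_b_inverse_scaling(self):
        b = np.array([0.3, -0.1, 0.2])
        assert sensitivity_b(5.0 * b) == pytest.approx(sensitivity_b(b) / 5.0)

    def test_single_variable_model(self):
        assert sensitivity_b([-0.25]) == pytest.approx(4.0)

    def test_asen_pair(self):
        a, inv = asen(0.3, 0.1)
        assert a == pytest.approx(3.0)
        assert inv == pytest.approx(1.0 / 3.0)
        assert a * inv == pytest.approx(1.0)

    def test_asen_zero_noise_rejected(self):
        with pytest.raises(ValueError):
            asen(1.0, 0.0)


class TestNAS:
    b = np.array([1.0, 2.0, -2.0])

    def test_parallel_spectrum_unchanged(self):
        v = 3.0 * self.b
        nas = nas_decompose(self.b, v[None, :])
        assert np.allclose(nas.nas[0], v)

    def test_orthogonal_spectrum_vanishes(self):
        v = np.array([2.0, -1.0, 0.0])  # v . b == 0
        nas = nas_decompose(self.b, v[None, :])
        assert np.allclose(nas.nas[0], 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_projection_identities(self, seed):
        rng = np.random.default_rng(seed)
        b = rng.normal(size=5)
        X = rng.normal(size=(4, 5))
        nas = nas_decompose(b, X)
        again = nas_decompose(b, nas.nas)
        assert np.allclose(again.nas, nas.nas, atol=1e-12)  # idempotent
        assert np.all(nas.nas_norms <= nas.v_norms + 1e-12)
        sel = selectivity(nas)
        assert 0.0 <= sel <= 100.0

    def test_sen_nas_identical_samples(self):
        v = 2.0 * self.b
        X = np.tile(v, (5, 1))
        nas = nas_decompose(self.b, X)
        c = np.full(5, 4.0)
        assert sensitivity_nas(nas, c) == pytest.approx(np.linalg.norm(v) / 4.0)

    def test_sen_nas_halves_when_c_doubles(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 3))
        c = rng.uniform(1.0, 2.0, 6)
        nas = nas_decompose(self.b, X)
        assert sensitivity_nas(nas, 2 * c) == pytest.approx(
            sensitivity_nas(nas, c) / 2.0)

    def test_sen_nas_median_robust_to_outlier(self):
        X = np.tile(self.b, (7, 1))
        c = np.ones(7)
        nas = nas_decompose(self.b, X)
        clean = sensitivity_nas(nas, c)
        c_bad = c.copy()
        c_bad[0] = 1e-6  # corrupted reference -> huge per-sample sensitivity
        assert sensitivity_nas(nas, c_bad) == pytest.approx(clean)

    def test_selectivity_extremes(self):
        par = nas_decompose(self.b, (2.0 * self.b)[None, :])
        assert selectivity(par) == pytest.approx(100.0)
        orth = nas_decompose(self.b, np.array([[2.0, -1.0, 0.0]]))
        assert selectivity(orth) == pytest.approx(0.0)


class TestLODFamily:
    def test_lod_3rmsep_printed_values(self):
        assert lod_3rmsep(4.54) == pytest.approx(13.6, abs=0.05)
        assert lod_3rmsep(80.3) == pytest.approx(241.0, abs=0.5)
        assert lod_3rmsep(0.0) == 0.0

    def test_h0min_hand_value(self):
        h0 = extrapolated_leverages(np.array([1.0, 2.0, 3.0]))
        assert h0.min() == pytest.approx(2.0)  # ybar^2 / sum centered^2 = 4/2

    def test_h0_shifts_with_constant_offset(self):
        y = np.array([1.0, 2.0, 3.0])
        k = 10.0
        h0 = extrapolated_leverages(y + k)
        ybar = y.mean() + k
        ss = ((y - y.mean()) ** 2).sum()
        expected = (ybar**2 + (y - y.mean()) ** 2) / ss
        assert np.allclose(h0, expected)

    def test_lod_pu_zero_for_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert lod_pseudounivariate(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_lod_nas_hand_value_and_noise_scaling(self):
        assert lod_nas(0.1, 0.2) == pytest.approx(1.5)
        assert lod_nas(0.2, 0.2) == pytest.approx(3.0)
        assert loq(lod_nas(0.1, 0.2)) == pytest.approx(3 * 1.5)

    def test_lod_range_degenerate_and_monotone(self):
        lo, hi = lod_range(0.5, 0.01, 0.0, 0.3, 0.3)
        assert lo == hi
        assert lod_range(0.5, 0.0, 0.0, 0.1, 0.9) == (0.0, 0.0)
        lo2, hi2 = lod_range(0.5, 0.01, 0.2, 0.1, 0.9)
        assert hi2 >= lo2

    def test_lod_ss_within_range_and_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        h = rng.uniform(0.1, 0.9, 20)
        sen, vx, vy = 0.4, 0.02, 0.05
        vals, med = lod_sample_specific(sen, vx, vy, h)
        lo, hi = lod_range(sen, vx, vy, h.min(), h.max())
        assert np.all(vals >= lo - 1e-12) and np.all(vals <= hi + 1e-12)
        oracle = np.array([3.3 * np.sqrt(vx / sen**2 * (1 + hi_) + hi_ * vy)
                           for hi_ in h])
        assert np.allclose(vals, oracle)
        assert med == pytest.approx(np.median(oracle))

    def test_lod_ss_single_sample(self):
        vals, med = lod_sample_specific(0.4, 0.02, 0.0, np.array([0.5]))
        assert med == vals[0]

    def test_loq_values(self):
        assert loq(5.94) == pytest.approx(17.82)
        assert loq(0.0) == 0.0
        assert loq(7.0) == pytest.approx(3.5 * loq(2.0))


class TestBrewConversion:
    def test_printed_value(self):
        assert convert_brew_concentration(35.7) == pytest.approx(0.595, abs=5e-4)

    def test_zero_and_dose_scaling(self):
        assert convert_brew_concentration(0.0) == 0.0
        assert convert_brew_concentration(10.0, coffee_dose_g=24.0) == \
            pytest.approx(convert_brew_concentration(10.0) / 2.0)


class TestResidualDiagnostics:
    def test_gaussian_residuals_pass(self):
        rng = np.random.default_rng(5)
        pred = np.linspace(0, 10, 60)
        resid = rng.normal(0, 1.0, 60)
        out = residual_diagnostics(resid, pred, n_permutations=500, seed=0)
        assert out["shapiro_p"] > 0.01
        assert out["perm_p_deg1"] > 0.05
        assert out["perm_p_deg2"] > 0.05

    def test_quadratic_trend_detected(self):
        rng = np.random.default_rng(6)
        pred = np.linspace(-3, 3, 60)
        resid = 0.8 * pred**2 - 0.8 * pred.var() + rng.normal(0, 0.3, 60)
        out = residual_diagnostics(resid, pred, n_permutations=500, seed=0)
        assert out["perm_p_deg2"] < 0.01

    def test_constant_residuals_reported_undefined(self):
        out = residual_diagnostics(np.ones(3), np.arange(3.0),
                                   n_permutations=10)
        assert np.isnan(out["shapiro_p"])
        assert "undefined" in out["note"]
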