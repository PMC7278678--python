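"""Pretreatment chain: binning, averaging, baseline, exclusion, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from roastcal.containers import SpectraMatrix
from roastcal.preprocess import (
    PreprocessState,
    average_time,
    baseline_correct,
    bin_to_unit_mz,
    detection_thresholds,
    estimate_noise_deltax,
    l1_normalize_then_center,
    select_channels,
)
from roastcal.pipeline import fit_preprocessor


class TestBinning:
    def test_nearest_integer_binning(self):
        out = bin_to_unit_mz([149.96, 150.04], [3.0, 4.0])
        assert out[149] == pytest.approx(7.0)
        assert out[148] == 0.0 and out[150] == 0.0

    def test_out_of_range_dropped(self):
        out = bin_to_unit_mz([100.0, 360.0], [1.0, 5.0])
        assert out.sum() == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=1.0, max_value=349.4), min_size=1,
                    max_size=50))
    def test_total_ion_current_conserved(self, mzs):
        mzs = sorted(mzs)
        intens = np.arange(1.0, len(mzs) + 1.0)
        out = bin_to_unit_mz(mzs, intens)
        assert out.sum() == pytest.approx(intens.sum())


def _matrix(intensity, dt=1.0):
    intensity = np.atleast_2d(np.asarray(intensity, dtype=float))
    t = (np.arange(intensity.shape[0]) + 0.5) * dt
    mz = np.arange(1, intensity.shape[1] + 1)
    return SpectraMatrix(t, mz, intensity)


class TestAverageTime:
    def test_window_means(self):
        sm = _matrix(np.arange(10.0)[:, None])
        out = average_time(sm, 5.0)
        assert out.intensity[:, 0] == pytest.approx([2.0, 7.0])
        assert out.time_s == pytest.approx([2.5, 7.5])

    def test_constant_matrix_unchanged(self):
        sm = _matrix(np.full((10, 3), 4.2))
        out = average_time(sm, 5.0)
        assert np.allclose(out.intensity, 4.2)

    def test_native_window_is_identity(self):
        sm = _matrix(np.random.default_rng(0).random((6, 2)), dt=5.0)
        out = average_time(sm, 5.0)
        assert np.array_equal(out.intensity, sm.intensity)


class TestBaseline:
    def test_constant_channel_zeroed(self):
        sm = _matrix(np.full((20, 1), 5.0))
        assert np.all(baseline_correct(sm).intensity == 0.0)

    def test_spike_retained_over_baseline(self):
        v = np.full(20, 5.0)
        v[10] = 15.0
        out = baseline_correct(_matrix(v[:, None]))
        # 10th percentile of the vector is the baseline 5, so the spike keeps
        # its height above baseline
        assert out.intensity[10, 0] == pytest.approx(10.0)

    def test_all_zero_stays_zero(self):
        sm = _matrix(np.zeros((15, 4)))
        assert np.all(baseline_correct(sm).intensity == 0.0)


class TestChannelSelection:
    def test_caffeine_and_low_mz_always_excluded(self):
        X = np.full((40, 350), 10.0)
        thr = np.zeros(350)
        kept = select_channels(X, thr)
        assert 58 not in kept
        for mz in range(193, 198):
            assert mz not in kept
        assert 59 in kept and 350 in kept

    @pytest.mark.parametrize("frac_below, retained", [(0.04, True), (0.05, True),
                                                      (0.06, False)])
    def test_five_percent_rule_boundary(self, frac_below, retained):
        n = 100
        X = np.full((n, 350), 10.0)
        X[: int(round(frac_below * n)), 99] = 0.0  # m/z 100 below threshold
        kept = select_channels(X, np.full(350, 1.0))
        assert (100 in kept) is retained

    def test_degenerate_calibration_rejected(self):
        X = np.zeros((10, 350))
        with pytest.raises(ValueError):
            select_channels(X, np.full(350, 1.0))


class TestNormalization:
    def test_row_l1_normalized_before_centering(self):
        state = PreprocessState(retained_channels=np.array([60, 61, 62]),
                                column_means=np.zeros(3))
        X = np.array([[2.0, 3.0, 5.0], [1.0, 1.0, 2.0]])
        out = l1_normalize_then_center(X, state, fit_mode=True)
        rows = out + state.column_means
        assert rows[0] == pytest.approx([0.2, 0.3, 0.5])
        assert np.allclose(rows.sum(axis=1), 1.0)

    def test_fit_mode_centers_columns(self, descriptors_small):
        X, _, _, _ = descriptors_small
        assert np.all(np.abs(X.mean(axis=0)) < 1e-12)

    def test_apply_mode_reproduces_fit_output(self):
        rng = np.random.default_rng(4)
        X = rng.random((8, 5)) + 0.1
        state = PreprocessState(retained_channels=np.arange(60, 65),
                                column_means=np.zeros(5))
        fitted = l1_normalize_then_center(X, state, fit_mode=True)
        applied = l1_normalize_then_center(X, state, fit_mode=False)
        assert np.array_equal(fitted, applied)

    def test_zero_sum_row_rejected(self):
        state = PreprocessState(retained_channels=np.array([60, 61]),
                                column_means=np.zeros(2))
        with pytest.raises(ValueError, match="empty spectrum"):
            l1_normalize_then_center(np.array([[0.0, 0.0]]), state, fit_mode=True)


class TestNoiseEstimate:
    def test_identical_rows_give_zero(self):
        assert estimate_noise_deltax(np.ones((5, 4))) == 0.0

    def test_matches_gaussian_sd(self):
        rng = np.random.default_rng(0)
        rows = rng.normal(0.0, 0.3, size=(4000, 6))
        assert estimate_noise_deltax(rows) == pytest.approx(0.3, rel=0.05)

    def test_homogeneous_in_scale(self):
        rng = np.random.default_rng(1)
        rows = rng.random((10, 3))
        assert estimate_noise_deltax(7.0 * rows) == pytest.approx(
            7.0 * estimate_noise_deltax(rows))

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            estimate_noise_deltax(np.ones((1, 4)))


class TestStateAndPipelineOrder:
    def test_state_round_trips_bit_exactly(self, tmp_path, descriptors_small):
        _, state, _, _ = descriptors_small
        path = tmp_path / "state.json"
        state.to_json(path)
        back = PreprocessState.from_json(path)
        assert np.array_equal(back.retained_channels, state.retained_channels)
        assert np.array_equal(back.column_means, state.column_means)
        assert back.noise_deltax == state.noise_deltax
        assert back.norm_reference_total == state.norm_reference_total

    def test_state_rejects_caffeine_channels(self):
        with pytest.raises(ValueError):
            PreprocessState(retained_channels=np.array([100, 194]),
                            column_means=np.zeros(2))

    def test_caffeine_excluded_despite_strong_signal(self, campaign_small):
        _, state = fit_preprocessor(campaign_small)
        assert not np.any((state.retained_channels >= 193)
                          & (state.retained_channels <= 197))
        assert state.retained_channels.min() >= 59

    def test_noise_channels_excluded(self, campaign_small):
        _, state = fit_preprocessor(campaign_small)
        # channels without a catalogued compound carry only baseline noise
        assert state.retained_channels.size < 25
        assert 150 in state.retained_channels

    def test_thresholds_are_blank_region_sd(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(0, 0.2, (500, 3))
        thr = detection_thresholds(rows, k_sigma=3.0)
        assert thr == pytest.approx(3.0 * rows.std(axis=0, ddof=1))
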