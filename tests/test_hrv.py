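"""Windowing geometry, the three time-domain features, and session trends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadsync.ecg import NNSeries, beats_to_nn
from dyadsync.errors import ConfigurationError, InputError
from dyadsync.hrv import (
    FEATURES,
    WindowSpec,
    feature_matrix,
    hr_feature,
    linear_trend,
    make_windows,
    rmssd_feature,
    sdnn_feature,
)
from tests.conftest import make_fv


class TestMakeWindows:
    @pytest.mark.parametrize(
        "duration, length, overlap, expected",
        [
            (900.0, 300.0, 100.0, [0.0, 200.0, 400.0, 600.0]),
            (140.0, 60.0, 20.0, [0.0, 40.0, 80.0]),
            (59.0, 60.0, 20.0, []),
        ],
    )
    def test_window_starts_from_stated_rule(self, duration, length, overlap, expected):
        spec = WindowSpec(length_s=length, overlap_s=overlap)
        np.testing.assert_allclose(make_windows(duration, spec), expected)

    def test_default_overlap_is_one_third_of_length(self):
        spec = WindowSpec(length_s=300.0)
        assert spec.overlap == pytest.approx(100.0)
        assert spec.step_s == pytest.approx(200.0)

    def test_origin_shifts_the_grid(self):
        spec = WindowSpec(length_s=300.0, overlap_s=100.0, origin_s=420.0)
        np.testing.assert_allclose(make_windows(1120.0, spec), [420.0, 620.0, 820.0])

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            WindowSpec(length_s=60.0, overlap_s=60.0)
        with pytest.raises(InputError):
            make_windows(-5.0, WindowSpec(60.0))


class TestFeatures:
    def test_hr_examples(self):
        assert hr_feature(np.full(20, 800.0)) == pytest.approx(75.0)
        assert hr_feature(np.array([1000.0])) == pytest.approx(60.0)
        assert hr_feature(np.array([600.0, 900.0])) == pytest.approx(80.0)

    def test_sdnn_examples(self):
        assert sdnn_feature(np.full(10, 700.0)) == pytest.approx(0.0)
        assert sdnn_feature(np.array([800.0, 850.0, 900.0])) == pytest.approx(50.0)
        assert sdnn_feature(np.array([700.0, 900.0])) == pytest.approx(141.42, abs=0.005)

    def test_rmssd_examples(self):
        assert rmssd_feature(np.full(10, 700.0)) == pytest.approx(0.0)
        assert rmssd_feature(np.array([800.0, 850.0, 900.0])) == pytest.approx(50.0)
        assert rmssd_feature(np.array([800.0, 900.0, 800.0])) == pytest.approx(100.0)

    def test_rmssd_skips_differences_across_a_rejected_beat(self):
        # intervals at 0.8 s spacing except a gap after the 2nd interval
        nn = np.array([800.0, 800.0, 900.0, 900.0])
        t = np.array([0.8, 1.6, 3.3, 4.2])  # 3rd interval starts at 2.4, not 1.6
        # adjacent diffs: only (900, 900) -> 0; (800,800) -> 0; gap breaks (800,900)
        assert rmssd_feature(nn, t) == pytest.approx(0.0)
        # without times every successive difference is used
        assert rmssd_feature(nn) == pytest.approx(np.sqrt((0 + 100**2 + 0) / 3))

    @given(
        st.lists(st.floats(min_value=400.0, max_value=1500.0), min_size=3, max_size=40),
        st.floats(min_value=-200.0, max_value=200.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_translation_invariance(self, nn, c):
        nn = np.asarray(nn)
        assert sdnn_feature(nn + c) == pytest.approx(sdnn_feature(nn), abs=1e-9)
        assert rmssd_feature(nn + c) == pytest.approx(rmssd_feature(nn), abs=1e-9)
        if abs(c) > 1e-6 and np.mean(nn) + c > 0:
            assert hr_feature(nn + c) != pytest.approx(hr_feature(nn), abs=1e-12)

    def test_deviation_scaling(self):
        rng = np.random.default_rng(5)
        nn = 800.0 + rng.normal(0, 30, 50)
        scaled = 800.0 + 3.0 * (nn - 800.0)
        assert sdnn_feature(scaled) == pytest.approx(3.0 * sdnn_feature(nn))
        assert rmssd_feature(scaled) == pytest.approx(3.0 * rmssd_feature(nn))


def _brute_force_features(nn, spec):
    """Window-by-window recomputation from scratch (the agreement oracle)."""
    out = {f: [] for f in FEATURES}
    starts = []
    s = spec.origin_s
    while s + spec.length_s <= nn.duration_s:
        sel = [
            k
            for k, t in enumerate(nn.interval_times_s)
            if s <= t < s + spec.length_s
        ]
        vals = nn.intervals_ms[sel]
        starts.append(s)
        if len(sel) >= spec.min_beats:
            out["HR"].append(60000.0 / np.mean(vals))
            out["SDNN"].append(np.std(vals, ddof=1))
            out["rMSSD"].append(rmssd_feature(vals, nn.interval_times_s[sel]))
        else:
            for f in FEATURES:
                out[f].append(np.nan)
        s += spec.step_s
    return starts, out


class TestFeatureMatrix:
    def test_constant_beats_give_constant_features(self):
        beats = np.arange(0.0, 1800.0 + 0.4, 0.8)
        nn = beats_to_nn(1, beats)
        fvs = feature_matrix(nn, WindowSpec(300.0, overlap_s=100.0))
        assert len(fvs["HR"]) == 8
        assert np.all(fvs["HR"].valid_mask)
        np.testing.assert_allclose(fvs["HR"].values, 75.0)
        np.testing.assert_allclose(fvs["SDNN"].values, 0.0, atol=1e-8)
        np.testing.assert_allclose(fvs["rMSSD"].values, 0.0, atol=1e-8)

    def test_valid_windows_never_nan_on_generator_output(self, small_classroom):
        for pid, beats in small_classroom.beat_series.items():
            nn = beats_to_nn(pid, beats)
            for fv in feature_matrix(nn, WindowSpec(60.0)).values():
                assert not np.any(np.isnan(fv.values[fv.valid_mask]))

    def test_agrees_with_brute_force_recomputation(self, small_classroom):
        beats = small_classroom.beat_series[1]
        nn = beats_to_nn(1, beats)
        for spec in (WindowSpec(60.0), WindowSpec(300.0, overlap_s=150.0)):
            fvs = feature_matrix(nn, spec)
            starts, oracle = _brute_force_features(nn, spec)
            for f in FEATURES:
                np.testing.assert_allclose(fvs[f].window_starts_s, starts, atol=1e-9)
                np.testing.assert_allclose(fvs[f].values, oracle[f], rtol=1e-9)

    def test_validity_mask_shared_across_features(self, small_classroom):
        nn = beats_to_nn(2, small_classroom.beat_series[2])
        fvs = feature_matrix(nn, WindowSpec(60.0))
        np.testing.assert_array_equal(fvs["HR"].valid_mask, fvs["SDNN"].valid_mask)
        np.testing.assert_array_equal(fvs["HR"].valid_mask, fvs["rMSSD"].valid_mask)

    def test_empty_or_short_series_raises_with_participant_id(self):
        with pytest.raises(InputError, match="participant 7"):
            feature_matrix(
                NNSeries(7, np.empty(0), np.empty(0)), WindowSpec(60.0)
            )
        short = beats_to_nn(9, np.arange(0.0, 50.0, 0.8))
        with pytest.raises(InputError, match="participant 9"):
            feature_matrix(short, WindowSpec(60.0))


class TestLinearTrend:
    def test_hand_computed_slope(self):
        fv = make_fv(1, [3.0, 2.0, 1.0], length_s=60.0)
        fit = linear_trend(fv)
        assert fit.slope == pytest.approx(-1.0 / fv.window_spec.step_s)

    def test_constant_values_have_zero_slope(self):
        assert linear_trend(make_fv(1, [5.0] * 6)).slope == pytest.approx(0.0, abs=1e-12)

    def test_increasing_values_have_positive_slope(self):
        assert linear_trend(make_fv(1, [1.0, 2.0, 4.0, 8.0])).slope > 0

    def test_too_few_valid_windows_rejected(self):
        with pytest.raises(InputError, match="at least 3"):
            linear_trend(make_fv(1, [1.0, 2.0]))
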