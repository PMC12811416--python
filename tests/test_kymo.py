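"""Mobile/static separation, kymograph geometry, dash quantification."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from axoquant import kymo
from axoquant import synthetic as syn
from axoquant.types import Calibration, Movie, PolylineROI


def _static_movie(n_frames, cal, seed=0):
    rng = np.random.default_rng(seed)
    frame = rng.uniform(0, 100, size=(20, 60))
    return Movie(np.tile(frame, (n_frames, 1, 1)), cal)


class TestSeparation:
    def test_time_constant_movie_maps_to_zero(self, movie_cal):
        movie = _static_movie(160, movie_cal)
        out = kymo.separate_mobile_static(movie)
        assert np.abs(out.frames).max() <= 1e-6 * np.ptp(movie.frames)

    def test_impulse_response_is_difference_of_kernels(self, movie_cal):
        n = 301
        frames = np.zeros((n, 4, 4))
        frames[150, 2, 2] = 1.0
        out = kymo.separate_mobile_static(Movie(frames, movie_cal))
        series = np.zeros(n)
        series[150] = 1.0
        expect = (ndimage.gaussian_filter1d(series, 4.0, mode="reflect")
                  - ndimage.gaussian_filter1d(series, 50.0, mode="reflect"))
        np.testing.assert_allclose(out.frames[:, 2, 2], expect, atol=1e-12)
        # untouched pixels stay zero
        assert np.abs(out.frames[:, 0, 0]).max() == 0.0

    def test_comet_retained_while_static_suppressed(self, movie_cal):
        axis = PolylineROI(np.array([[10.0, 10.0], [110.0, 10.0]]), 1.0)
        comet = syn.Comet(start_time_s=40.0, start_pos_um=2.0,
                          velocity_um_s=0.1, lifetime_s=20.0)
        # static spots placed away from the comet's 2-4 um path (px 30-50)
        spots = [syn.StaticSpot(70.0, 10.0), syn.StaticSpot(100.0, 10.0)]
        movie, _ = syn.make_comet_movie(axis, [comet], spots, (21, 120), 200,
                                        movie_cal)
        out = kymo.separate_mobile_static(movie)
        # static spot pixel: suppressed by >= 95 %
        static_after = np.abs(out.frames[:, 10, 70]).max()
        assert static_after <= 0.05 * movie.frames[0, 10, 70]
        # comet peak retains >= 50 % of its pre-filter amplitude (100)
        assert out.frames.max() >= 50.0

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            kymo.SeparationParams(sigma_mobile=50.0, sigma_static=4.0)

    def test_short_movie_warns(self, movie_cal):
        with pytest.warns(UserWarning, match="frames"):
            kymo.separate_mobile_static(_static_movie(30, movie_cal))


class TestBuildKymograph:
    def test_static_movie_gives_identical_rows(self, movie_cal):
        movie = _static_movie(12, movie_cal)
        roi = PolylineROI(np.array([[5.0, 10.0], [55.0, 10.0]]), 1.0)
        kg = kymo.build_kymograph(movie, roi)
        for r in range(1, kg.n_rows):
            np.testing.assert_array_equal(kg.values[r], kg.values[0])
        assert kg.total_time_s == pytest.approx(12 * 0.5)

    def test_comet_slope_matches_velocity(self, movie_cal):
        axis = PolylineROI(np.array([[10.0, 10.0], [110.0, 10.0]]), 1.0)
        comet = syn.Comet(start_time_s=10.0, start_pos_um=1.0,
                          velocity_um_s=0.12, lifetime_s=30.0)
        movie, _ = syn.make_comet_movie(axis, [comet], [], (21, 120), 120,
                                        movie_cal)
        kg = kymo.build_kymograph(movie, axis)
        rows = np.nonzero(kg.values.max(axis=1) > 10.0)[0]
        cent = [(kg.values[r] * np.arange(kg.values.shape[1])).sum()
                / kg.values[r].sum() for r in rows]
        slope_px = np.polyfit(rows, cent, 1)[0]
        v = slope_px * kg.space_step_um / kg.time_step_s
        assert v == pytest.approx(0.12, rel=0.02)

    def test_reversed_roi_mirrors_kymograph(self, movie_cal):
        movie = _static_movie(6, movie_cal, seed=5)
        roi = PolylineROI(np.array([[5.0, 10.0], [55.0, 10.0]]), 1.0)
        kg = kymo.build_kymograph(movie, roi)
        kg_rev = kymo.build_kymograph(movie, roi.reversed())
        np.testing.assert_allclose(kg_rev.values, kg.values[:, ::-1], atol=1e-9)

    def test_roi_outside_image_rejected(self, movie_cal):
        movie = _static_movie(6, movie_cal)
        roi = PolylineROI(np.array([[5.0, 10.0], [500.0, 10.0]]), 1.0)
        with pytest.raises(ValueError, match="bounds"):
            kymo.build_kymograph(movie, roi)


class TestDashParams:
    @pytest.fixture
    def kg(self):
        # 360-row kymograph of a 3-min 2-fps movie, 0.1 um columns
        return kymo.Kymograph(np.zeros((360, 400)), space_step_um=0.1,
                              time_step_s=0.5)

    def test_hand_computed_example(self, kg):
        # endpoints (0,0)-(30,40): track 3 um, lifetime 20 s, rate 0.15 um/s
        p = kymo.dash_params(kymo.Dash(0, 0, 30, 40), kg)
        assert p.track_length_um == pytest.approx(3.0)
        assert p.lifetime_s == pytest.approx(20.0)
        assert p.growth_rate_um_per_s == pytest.approx(0.15)

    def test_full_height_dash_spans_acquisition_time(self, kg):
        p = kymo.dash_params(kymo.Dash(10, 0, 50, 360), kg)
        assert p.lifetime_s == 180.0

    def test_vertical_dash_is_a_stationary_comet(self, kg):
        p = kymo.dash_params(kymo.Dash(25, 10, 25, 60), kg)
        assert p.track_length_um == 0.0
        assert p.growth_rate_um_per_s == 0.0

    def test_zero_time_span_rejected(self, kg):
        with pytest.raises(ValueError, match="dy"):
            kymo.dash_params(kymo.Dash(0, 7, 30, 7), kg)

    @settings(max_examples=200, derandomize=True)
    @given(x0=st.floats(-200, 200), y0=st.floats(0, 300),
           dx=st.floats(-150, 150), dy=st.floats(0.01, 60))
    def test_endpoint_delta_equals_trigonometric_form(self, x0, y0, dx, dy):
        # identity: rate * lifetime == track; L cos/sin == |dx|/dy
        kg = kymo.Kymograph(np.zeros((360, 400)), 0.1, 0.5)
        d = kymo.Dash(x0, y0, x0 + dx, y0 + dy)
        p = kymo.dash_params(d, kg)
        assert p.growth_rate_um_per_s * p.lifetime_s == pytest.approx(
            p.track_length_um, rel=1e-12, abs=1e-300)
        L = d.length_px
        theta = math.atan2(d.dy, abs(d.dx))
        assert L * math.cos(theta) == pytest.approx(abs(d.dx), rel=1e-9, abs=1e-9)
        assert L * math.sin(theta) == pytest.approx(d.dy, rel=1e-9, abs=1e-9)


class TestDetect:
    def test_blank_kymograph_yields_no_dashes(self):
        kg = kymo.Kymograph(np.zeros((100, 200)), 0.1, 0.5)
        assert kymo.detect_dashes(kg) == []

    def test_single_comet_detected_with_true_slope(self, movie_cal):
        axis = PolylineROI(np.array([[10.0, 10.0], [110.0, 10.0]]), 1.0)
        comet = syn.Comet(start_time_s=30.0, start_pos_um=2.0,
                          velocity_um_s=0.1, lifetime_s=25.0)
        movie, _ = syn.make_comet_movie(axis, [comet], [], (21, 120), 160,
                                        movie_cal)
        sep = kymo.separate_mobile_static(movie)
        kg = kymo.build_kymograph(sep, axis)
        dashes = kymo.detect_dashes(kg)
        assert len(dashes) == 1
        p = kymo.dash_params(dashes[0], kg)
        assert p.growth_rate_um_per_s == pytest.approx(0.1, rel=0.10)

    def test_two_time_separated_comets_give_two_dashes(self, movie_cal):
        axis = PolylineROI(np.array([[10.0, 10.0], [110.0, 10.0]]), 1.0)
        comets = [syn.Comet(10.0, 2.0, 0.1, 20.0),
                  syn.Comet(55.0, 6.0, 0.08, 20.0)]
        movie, _ = syn.make_comet_movie(axis, comets, [], (21, 120), 160,
                                        movie_cal)
        sep = kymo.separate_mobile_static(movie)
        kg = kymo.build_kymograph(sep, axis)
        assert len(kymo.detect_dashes(kg)) == 2


class TestSummary:
    def test_singleton_summary(self):
        out = kymo.summarize_dynamics([kymo.CometParams(2.0, 20.0)])
        assert out["n"] == 1
        assert out["track_length_um_mean"] == 2.0
        assert out["track_length_um_se"] == 0.0

    def test_duplicating_samples_scales_se_by_sqrt2(self):
        params = [kymo.CometParams(1.0, 10.0), kymo.CometParams(3.0, 20.0),
                  kymo.CometParams(2.0, 15.0)]
        s1 = kymo.summarize_dynamics(params)
        s2 = kymo.summarize_dynamics(params * 2)
        assert s2["track_length_um_mean"] == s1["track_length_um_mean"]
        ratio = s1["track_length_um_se"] / s2["track_length_um_se"]
        # duplicated list: sd shrinks slightly (ddof), n doubles
        assert ratio == pytest.approx(math.sqrt(2), rel=0.12)

    def test_mean_is_arithmetic_mean(self):
        params = [kymo.CometParams(1.0, 10.0), kymo.CometParams(2.0, 30.0)]
        out = kymo.summarize_dynamics(params)
        assert out["lifetime_s_mean"] == pytest.approx(20.0)
        assert out["growth_rate_um_per_s_mean"] == pytest.approx(
            (0.1 + 2.0 / 30.0) / 2)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            kymo.summarize_dynamics([])
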