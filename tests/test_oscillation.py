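"""Registration, kymographs, detrending, phase, periods and wave lag."""

import numpy as np
import pytest

from somitometry import oscillation as osc
from somitometry import synthgen
from somitometry.grids import EventSeries, ImageGrid


def ma_gain(window: int, period_frames: float) -> float:
    """Transfer gain of a centred moving average of ``window`` samples."""
    x = np.pi * window / period_frames
    return np.sin(x) / (window * np.sin(np.pi / period_frames))


def default_axis(movie: ImageGrid) -> np.ndarray:
    h = movie.data.shape[1]
    px = movie.pixel_size[0]
    margin = 20.0
    length = movie.data.shape[2] * px - 2 * margin
    return np.array([[margin, h * px / 2], [margin + length, h * px / 2]])


class TestRegistration:
    def test_recovers_known_drift_within_one_pixel(self):
        spec = synthgen.ClockSpec(seed=1, n_frames=30,
                                  drift_px_per_frame=(0.2, 0.3))
        movie, truth = synthgen.generate_clock_movie(spec)
        _, report = osc.register_frames(movie)
        err = np.abs(report["shifts_px"] - truth.frame_shifts_px)
        assert err.max() <= 1.0

    def test_static_movie_zero_shifts(self, clock_movie):
        movie, _ = clock_movie
        _, report = osc.register_frames(movie)
        assert np.abs(report["shifts_px"]).max() == pytest.approx(0.0,
                                                                  abs=0.1)
        assert not report["low_confidence"].any()

    def test_pure_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(0)
        movie = ImageGrid(rng.normal(100, 10, (5, 40, 40)).clip(0),
                          (2.0, 2.0), frame_interval=10.0)
        with pytest.warns(UserWarning, match="coherent"):
            _, report = osc.register_frames(movie)
        assert report["low_confidence"].all()


class TestKymograph:
    def test_static_frames_give_identical_rows(self):
        grad = np.tile(np.linspace(0, 100, 60), (40, 1))
        movie = ImageGrid(np.repeat(grad[None], 10, axis=0), (2.0, 2.0),
                          frame_interval=5.0)
        axis = np.array([[10.0, 40.0], [110.0, 40.0]])
        kymo = osc.build_kymograph(movie, axis, half_width=6.0,
                                   median_radius=1)
        assert np.ptp(kymo.matrix, axis=0).max() == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_travelling_wave_stripe_slope_sign(self, clock_movie):
        movie, truth = clock_movie
        kymo = osc.build_kymograph(movie, default_axis(movie), half_width=10)
        # posterior->anterior wave: the phase at larger x lags, so the crest
        # position moves toward larger column index over time
        crest = np.argmax(kymo.matrix[:, 20:-20], axis=1)
        frames = np.arange(len(crest))
        moving = np.abs(np.diff(crest)) < 30  # ignore wrap-around jumps
        slope = np.polyfit(frames[1:][moving], crest[1:][moving], 1)[0]
        assert np.sign(slope) == truth.direction

    def test_zero_halfwidth_equals_bilinear_oracle(self):
        rng = np.random.default_rng(3)
        frame = rng.random((30, 50)) * 100
        movie = ImageGrid(np.repeat(frame[None], 3, axis=0), (2.0, 2.0),
                          frame_interval=5.0)
        axis = np.array([[4.0, 30.0], [90.0, 30.0]])
        kymo = osc.build_kymograph(movie, axis, half_width=0.0)
        # oracle: direct bilinear interpolation along the line
        s = np.arange(kymo.matrix.shape[1]) * kymo.spatial_step
        xs, ys = (4.0 + s) / 2.0, np.full_like(s, 15.0)
        c0 = np.floor(xs).astype(int)
        fx = xs - c0
        vals = frame[15, c0] * (1 - fx) + frame[15, np.minimum(c0 + 1, 49)] * fx
        np.testing.assert_allclose(kymo.matrix[0], vals, atol=1e-8)

    def test_axis_outside_image_rejected(self, clock_movie):
        movie, _ = clock_movie
        with pytest.raises(ValueError, match="exits"):
            osc.build_kymograph(movie, np.array([[0.0, 0.0], [1e5, 0.0]]))


class TestDetrend:
    def test_constant_series_all_zero(self):
        out = osc.detrend_trace(np.full(120, 7.0), window=50)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_sinusoid_amplitude_follows_analytic_attenuation(self):
        t = np.arange(300)
        period = 30.0
        raw = 5.0 + 0.02 * t + np.cos(2 * np.pi * t / period)
        out = osc.detrend_trace(raw, window=50)
        interior = out[60:-60]
        # the moving average keeps gain g of the sinusoid; the detrended
        # amplitude is |1 - g| (the implementation's centred window is 51)
        expected = abs(1 - ma_gain(51, period))
        got = (interior.max() - interior.min()) / 2
        assert got == pytest.approx(expected, rel=0.05)
        # trend removed: interior mean ~ 0
        assert abs(interior.mean()) < 0.05

    def test_long_period_heavily_attenuated(self):
        t = np.arange(400)
        raw = np.cos(2 * np.pi * t / 300.0)   # period >> window
        out = osc.detrend_trace(raw, window=50)
        expected = abs(1 - ma_gain(51, 300.0))
        got = np.abs(out[100:-100]).max()
        assert got <= expected * 1.2
        assert got < 0.25  # documented low-frequency cut-off

    def test_short_gaps_interpolated_long_gaps_rejected(self):
        raw = np.sin(np.arange(120.0))
        raw[40:42] = np.nan
        out = osc.detrend_trace(raw, window=50)
        assert np.isfinite(out).all()
        raw[60:70] = np.nan
        with pytest.raises(ValueError, match="split"):
            osc.detrend_trace(raw, window=50)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            osc.detrend_trace(np.zeros(30), window=50)


class TestPhase:
    def test_cosine_phase_slope(self):
        t = np.arange(600.0)
        T = 50.0
        phase = osc.instantaneous_phase(np.cos(2 * np.pi * t / T))
        slope = np.polyfit(t[100:-100], phase[100:-100], 1)[0]
        assert slope == pytest.approx(2 * np.pi / T, rel=0.02)

    def test_quarter_period_offset_gives_half_pi(self):
        t = np.arange(600.0)
        T = 60.0
        p1 = osc.instantaneous_phase(np.cos(2 * np.pi * t / T))
        p2 = osc.instantaneous_phase(np.cos(2 * np.pi * (t - T / 4) / T))
        dphi = (p1 - p2)[100:-100]
        assert np.abs(dphi - np.pi / 2).max() <= 0.1

    def test_noisy_trace_recovers_period_within_5_percent(self):
        rng = np.random.default_rng(4)
        t = np.arange(600.0)
        T = 40.0
        raw = np.cos(2 * np.pi * t / T) + rng.normal(0, 0.2, t.size)
        det = osc.detrend_trace(raw, window=50)
        phase = osc.instantaneous_phase(det)
        slope = np.polyfit(t[100:-100], phase[100:-100], 1)[0]
        assert 2 * np.pi / slope == pytest.approx(T, rel=0.05)

    def test_zero_series_rejected(self):
        with pytest.raises(ValueError):
            osc.instantaneous_phase(np.zeros(100))


class TestPeakToPeakPeriod:
    def test_noiseless_sinusoid_exact(self):
        t = np.arange(0, 1200, 10.0)          # dt = 10 min, 4 cycles
        det = np.cos(2 * np.pi * t / 300.0)   # T = 300 min
        res = osc.peak_to_peak_period(det, 10.0)
        assert res["period_hours"] == pytest.approx(5.0, abs=1e-9)
        assert res["sd_hours"] == 0.0

    def test_noisy_clock_mean_within_10_minutes(self):
        errs = []
        for sd in range(10):
            rng = np.random.default_rng(sd)
            t = np.arange(0, 1200, 10.0)
            det = np.cos(2 * np.pi * t / 300.0) \
                + rng.normal(0, 0.2, t.size)    # 20 % amplitude noise
            det = osc.detrend_trace(det, window=50)
            res = osc.peak_to_peak_period(det, 10.0)
            errs.append(res["period_hours"] * 60 - 300.0)
        assert abs(np.mean(errs)) <= 10.0

    def test_damped_oscillation_still_measured(self):
        t = np.arange(0, 900, 10.0)
        det = np.exp(-t / 600.0) * np.cos(2 * np.pi * t / 300.0)
        res = osc.peak_to_peak_period(det, 10.0)
        assert res["period_hours"] == pytest.approx(5.0, abs=10 / 60)

    def test_too_few_peaks_diagnostic(self):
        with pytest.raises(ValueError, match="peak"):
            osc.peak_to_peak_period(np.cos(np.linspace(0, np.pi, 50)), 10.0)

    def test_time_shift_invariance(self):
        t = np.arange(0, 900, 10.0)
        base = np.cos(2 * np.pi * t / 300.0)
        shifted = np.cos(2 * np.pi * (t - 40.0) / 300.0)
        r0 = osc.peak_to_peak_period(base, 10.0)
        r1 = osc.peak_to_peak_period(shifted, 10.0)
        assert r1["period_hours"] == r0["period_hours"]
        assert np.allclose(np.diff(r1["peak_times"]),
                           np.diff(r0["peak_times"]))

    def test_period_consistent_with_phase_slope(self, clock_movie):
        movie, truth = clock_movie
        kymo = osc.build_kymograph(movie, default_axis(movie), half_width=10)
        trace = kymo.matrix[:, :20].mean(axis=1)
        det = osc.detrend_trace(trace, window=50)
        res = osc.peak_to_peak_period(det, kymo.frame_interval)
        phase = osc.instantaneous_phase(det)
        n = len(phase)
        slope = np.polyfit(np.arange(n)[15:-15] * kymo.frame_interval,
                           phase[15:-15], 1)[0]
        period_from_phase = 2 * np.pi / slope / 60.0
        assert abs(res["period_hours"] - period_from_phase) * 60 \
            <= kymo.frame_interval


class TestPhaseLag:
    def _kymo(self, direction=1, seed=0):
        spec = synthgen.ClockSpec(seed=seed, n_frames=90, direction=direction)
        movie, truth = synthgen.generate_clock_movie(spec)
        kymo = osc.build_kymograph(movie, default_axis(movie), half_width=10)
        return kymo, truth

    def test_posterior_to_anterior_wave_positive_lag(self):
        kymo, truth = self._kymo(direction=1)
        n = kymo.matrix.shape[1]
        post, ant = (0, n // 8), (n // 2 - n // 16, n // 2 + n // 16)
        res = osc.phase_lag(kymo, post, ant)
        dx = (np.mean(ant) - np.mean(post)) * kymo.spatial_step
        expected = dx / truth.wavelength_um * truth.period_min
        assert res["lag_min"] == pytest.approx(expected, rel=0.10)

    def test_reversed_wave_flips_sign(self):
        kymo, _ = self._kymo(direction=-1)
        n = kymo.matrix.shape[1]
        res = osc.phase_lag(kymo, (0, n // 8),
                            (n // 2 - n // 16, n // 2 + n // 16))
        assert res["lag_min"] < 0

    def test_synchronous_oscillation_zero_lag(self):
        spec = synthgen.ClockSpec(seed=2, n_frames=90, wavelength=1e9)
        movie, _ = synthgen.generate_clock_movie(spec)
        kymo = osc.build_kymograph(movie, default_axis(movie), half_width=10)
        n = kymo.matrix.shape[1]
        res = osc.phase_lag(kymo, (0, n // 8), (7 * n // 8, n))
        assert abs(res["lag_min"]) <= kymo.frame_interval

    def test_roi_outside_kymograph_rejected(self):
        kymo, _ = self._kymo()
        with pytest.raises(ValueError, match="ROI"):
            osc.phase_lag(kymo, (0, 10), (0, 10 ** 6))


class TestEventPeriod:
    def test_exact_spacing(self):
        res = osc.event_period(EventSeries(np.array([0.0, 300, 600, 900])))
        assert res["period_hours"] == pytest.approx(5.0)
        assert res["sd_hours"] == 0.0
        assert res["n_intervals"] == 3

    def test_jittered_events_mean_within_10_minutes(self):
        means = []
        for sd in range(10):
            series = synthgen.generate_event_times(300.0, 15.0, 10, seed=sd)
            means.append(osc.event_period(series)["period_hours"] * 60)
        assert abs(np.mean(means) - 300.0) <= 10.0

    def test_single_event_rejected(self):
        with pytest.raises(ValueError, match="two events"):
            osc.event_period(EventSeries(np.array([100.0])))

    def test_clock_coupling_event_period_matches_oscillation(self):
        # one somite (pair) per oscillation cycle: the somite-formation
        # period equals the reporter period within one frame interval
        spec = synthgen.ClockSpec(seed=0, n_frames=120, couple_events=True)
        movie, truth = synthgen.generate_clock_movie(spec)
        kymo = osc.build_kymograph(movie, default_axis(movie), half_width=10)
        trace = kymo.matrix[:, :20].mean(axis=1)
        det = osc.detrend_trace(trace, window=50)
        p_osc = osc.peak_to_peak_period(det, kymo.frame_interval)
        p_event = osc.event_period(EventSeries(truth.event_times_min))
        assert abs(p_osc["period_hours"] - p_event["period_hours"]) * 60 \
            <= kymo.frame_interval
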