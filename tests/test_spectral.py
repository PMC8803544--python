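"""Spectral estimation, respiratory-peak detection and aliasing arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import respkit as rk


def sinusoid_trace(freq_hz, t=420, tr_s=0.8, column=1, amp=0.1, seed=0):
    rng = np.random.default_rng(seed)
    params = rng.normal(0, 1e-4, size=(t, 6))
    params[:, column] += amp * np.sin(2 * np.pi * freq_hz * np.arange(t) * tr_s)
    return rk.MotionTrace(params=params, tr_s=tr_s)


def make_spectrum(peak_by_column, tr_s=0.8, n_bins=129):
    """Hand-built MotionSpectrum with a sharp peak per column."""
    freqs = np.linspace(0, 0.5 / tr_s, n_bins)[1:]
    power = np.full((freqs.size, 6), 1e-6)
    for col, f in peak_by_column.items():
        power[np.argmin(np.abs(freqs - f)), col] = 1.0
    return rk.MotionSpectrum(freqs_hz=freqs, power=power, tr_s=tr_s, phase_axis="y")


class TestMotionSpectrum:
    def test_sinusoid_peak_recovered(self):
        trace = sinusoid_trace(0.40)
        spec = rk.motion_spectrum(trace)
        df = spec.freqs_hz[1] - spec.freqs_hz[0]
        peak = spec.freqs_hz[np.argmax(spec.power[:, 1])]
        assert abs(peak - 0.40) <= df

    def test_nyquist_grid_edge(self):
        spec = rk.motion_spectrum(sinusoid_trace(0.3, tr_s=0.8))
        assert spec.freqs_hz[-1] == pytest.approx(0.625, abs=1e-12)

    def test_white_noise_rarely_shows_prominent_peak(self):
        # false-alarm calibration for the 5x-median prominence level
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trace = rk.MotionTrace(params=rng.normal(0, 0.01, (420, 6)), tr_s=0.8)
            spec = rk.motion_spectrum(trace)
            band = (spec.freqs_hz >= 0.2) & (spec.freqs_hz <= 0.6)
            p = spec.power[band, 1]
            hits += np.max(p) > 5 * np.median(p)
        assert hits <= 5

    def test_parseval_total_power_close_to_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4096, 6))
        trace = rk.MotionTrace(params=x, tr_s=0.8)
        spec = rk.motion_spectrum(trace, detrend=False)
        df = spec.freqs_hz[1] - spec.freqs_hz[0]
        total = spec.power.sum(axis=0) * df
        np.testing.assert_allclose(total, x.var(axis=0), rtol=0.05)

    def test_too_short_trace_rejected(self):
        trace = rk.MotionTrace(params=np.zeros((16, 6)), tr_s=0.8)
        with pytest.raises(ValueError, match="32"):
            rk.motion_spectrum(trace)


class TestFindRespPeak:
    def test_single_axis_sinusoid(self):
        spec = rk.motion_spectrum(sinusoid_trace(0.35))
        df = spec.freqs_hz[1] - spec.freqs_hz[0]
        pk = rk.find_resp_peak(spec)
        assert abs(pk.peak_hz - 0.35) <= df
        assert not pk.low_prominence
        assert pk.parameter_used == ("trans_y",)

    def test_median_of_three_axes(self):
        spec = make_spectrum({0: 0.30, 1: 0.35, 2: 0.40})
        pk = rk.find_resp_peak(spec, axes=[0, 1, 2])
        assert pk.peak_hz == pytest.approx(0.35, abs=0.01)

    def test_flat_spectrum_flagged_low_prominence(self):
        freqs = np.linspace(0, 0.625, 129)[1:]
        spec = rk.MotionSpectrum(
            freqs_hz=freqs, power=np.ones((freqs.size, 6)), tr_s=0.8, phase_axis="y"
        )
        assert rk.find_resp_peak(spec).low_prominence

    def test_band_above_nyquist_mentions_alias(self):
        spec = rk.motion_spectrum(sinusoid_trace(0.1, tr_s=2.5))
        with pytest.raises(ValueError, match="alias"):
            rk.find_resp_peak(spec, band_hz=(0.3, 0.6))


class TestAliasFrequency:
    @pytest.mark.parametrize(
        "true_hz, tr_s, expected",
        [
            (0.4, 0.8, 0.4),  # below Nyquist: unchanged
            (0.4, 2.5, 0.0),  # exact fold onto DC
            (0.5, 2.0, 0.0),
            (0.45, 2.0, 0.05),
            (1.0, 0.8, 0.25),  # 1 Hz at fs 1.25 folds to 0.25
        ],
    )
    def test_folding_formula(self, true_hz, tr_s, expected):
        assert rk.alias_frequency(true_hz, tr_s) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(f=st.floats(0, 10), tr=st.floats(0.1, 5.0))
    def test_idempotent_and_in_range(self, f, tr):
        a = rk.alias_frequency(f, tr)
        assert 0 <= a <= 0.5 / tr + 1e-12
        assert rk.alias_frequency(a, tr) == pytest.approx(a, abs=1e-9)

    def test_matches_fft_of_decimated_sinusoid(self):
        # independent oracle: FFT peak of the sampled sinusoid
        rng = np.random.default_rng(11)
        for _ in range(10):
            tr = rng.uniform(0.5, 3.0)
            f = rng.uniform(0.05, 1.2)
            n = 4096
            x = np.sin(2 * np.pi * f * np.arange(n) * tr)
            spec = np.abs(np.fft.rfft(x * np.hanning(n)))
            grid = np.fft.rfftfreq(n, tr)
            f_peak = grid[np.argmax(spec)]
            assert abs(f_peak - rk.alias_frequency(f, tr)) <= 2 * (grid[1] - grid[0])


class TestCohortSpectra:
    def test_rows_ordered_by_mean_fd(self):
        traces = [sinusoid_trace(0.4, amp=a, seed=i) for i, a in enumerate([0.3, 0.1])]
        specs = [rk.motion_spectrum(t) for t in traces]
        stack = rk.cohort_spectra(specs)
        assert np.all(np.diff(stack.mean_fd_mm) >= 0)
        assert stack.power.shape[0] == 2
        assert np.allclose(stack.power.max(axis=1), 1.0)

    def test_respiratory_band_visible_in_stack(self):
        cohort = rk.gen_cohort(8, seed=5, n_runs=1, with_bold=False)
        specs = [rk.motion_spectrum(s.runs[0].motion) for s in cohort]
        stack = rk.cohort_spectra(specs)
        band = (stack.freqs_hz >= 0.25) & (stack.freqs_hz <= 0.55)
        above_drift = stack.freqs_hz >= 0.1
        # above the drift region, every subject's power peaks inside the
        # respiratory band
        np.testing.assert_array_equal(
            stack.power[:, band].max(axis=1),
            stack.power[:, above_drift].max(axis=1),
        )

    def test_single_subject_stack(self):
        spec = rk.motion_spectrum(sinusoid_trace(0.4))
        assert rk.cohort_spectra([spec]).power.shape[0] == 1

    def test_mixed_grids_need_resample_flag(self):
        a = rk.motion_spectrum(sinusoid_trace(0.3, tr_s=0.8))
        b = rk.motion_spectrum(sinusoid_trace(0.3, tr_s=0.72))
        with pytest.raises(ValueError, match="resample"):
            rk.cohort_spectra([a, b])
        stack = rk.cohort_spectra([a, b], resample=True)
        assert stack.power.shape == (2, a.freqs_hz.size)

    def test_run_averaging_requires_common_grid(self):
        a = rk.motion_spectrum(sinusoid_trace(0.3, tr_s=0.8))
        b = rk.motion_spectrum(sinusoid_trace(0.3, tr_s=0.72))
        with pytest.raises(ValueError, match="common"):
            rk.average_spectra([a, b])
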