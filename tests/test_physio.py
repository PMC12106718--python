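"""Physiological trace cleaning and measure derivation."""

import numpy as np
import pytest
from scipy import signal

from physiocca import (DegenerateInputError, InvalidArgumentError, PhysioTrace,
                       clean_cardiac_trace, clean_respiratory_trace,
                       compute_heart_rate, derive_respiration_measure,
                       generate_cardiac_trace, generate_respiratory_trace,
                       resample_to_frames)


def _cleaned(x, fs, kind="respiratory"):
    return PhysioTrace(x, fs, kind=kind, state="cleaned")


class TestRespiratoryGenerator:
    def test_pure_sinusoid_without_modulation(self):
        t = generate_respiratory_trace(60, 100, mod_depth=0.0, noise_sd=0.0)
        assert t.samples.size == 6000
        assert np.isclose(np.abs(t.samples).max(), 1.0, atol=1e-3)

    def test_sample_count_is_duration_times_rate(self):
        t = generate_respiratory_trace(864, 400, noise_sd=0.0)
        assert t.samples.size == 345_600

    def test_analytic_envelope_recovered_by_hilbert_oracle(self):
        t = generate_respiratory_trace(300, 50, mod_depth=0.5, noise_sd=0.0)
        tt = np.arange(t.samples.size) / 50
        expected = 1 + 0.5 * np.sin(2 * np.pi * 0.03 * tt)
        env = np.abs(signal.hilbert(t.samples))
        interior = slice(50 * 20, -50 * 20)
        rel = np.abs(env[interior] - expected[interior]) / expected[interior]
        assert rel.max() < 0.02

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            generate_respiratory_trace(-1, 100)
        with pytest.raises(InvalidArgumentError):
            generate_respiratory_trace(10, 0.5)  # fs below Nyquist of carrier
        with pytest.raises(InvalidArgumentError):
            generate_respiratory_trace(10, 100, mod_depth=1.5)


class TestCardiacGenerator:
    @pytest.mark.parametrize("bpm,ibi", [(60.0, 1.0), (75.0, 0.8)])
    def test_constant_rate_gives_exact_spacing(self, bpm, ibi):
        t = generate_cardiac_trace(60, 200, mean_hr_bpm=bpm, hr_sd_bpm=0.0, seed=0)
        peaks, _ = signal.find_peaks(t.samples, distance=int(0.3 * 200))
        spacing = np.diff(peaks) / 200
        assert np.allclose(spacing, ibi, atol=1.5 / 200)

    def test_variable_rate_matches_stored_ibis(self):
        t = generate_cardiac_trace(120, 200, mean_hr_bpm=70, hr_sd_bpm=5, seed=3)
        hr = compute_heart_rate(clean_cardiac_trace(t))
        truth = 60.0 / t.meta["ibis_s"]
        mids = (t.meta["beat_times_s"][:-1] + t.meta["beat_times_s"][1:]) / 2 * 200
        recovered = np.interp(mids, np.arange(hr.size), hr)
        assert np.corrcoef(recovered, truth[: recovered.size])[0, 1] > 0.95

    def test_negative_sd_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_cardiac_trace(10, 100, 60, hr_sd_bpm=-1)


class TestCleanRespiratory:
    def test_output_is_zero_mean_unit_sd(self):
        raw = generate_respiratory_trace(120, 400, seed=2)
        out = clean_respiratory_trace(raw)
        assert abs(out.samples.mean()) < 1e-9
        assert abs(out.samples.std() - 1) < 1e-9
        assert out.state == "cleaned"

    def test_spike_is_removed(self):
        raw = generate_respiratory_trace(120, 400, noise_sd=0.0)
        spiked = raw.samples.copy()
        spiked[400 * 60] += 50.0
        clean_ref = clean_respiratory_trace(raw).samples
        clean_spk = clean_respiratory_trace(
            PhysioTrace(spiked, 400, "respiratory")).samples
        mask = np.ones(clean_ref.size, bool)
        mask[400 * 59: 400 * 61] = False  # 1 s neighborhood around the spike
        assert np.abs(clean_spk[mask] - clean_ref[mask]).max() < 0.05

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            clean_respiratory_trace(PhysioTrace(np.ones(4000), 400, "respiratory"))

    def test_idempotent_on_interior(self):
        raw = generate_respiratory_trace(120, 100, mod_depth=0.0, noise_sd=0.0)
        once = clean_respiratory_trace(raw)
        twice = clean_respiratory_trace(
            PhysioTrace(once.samples, 100, "respiratory"))
        n = once.samples.size
        sl = slice(int(0.05 * n), int(0.95 * n))
        # the moving-median outlier rule may re-flag smooth extrema, which
        # bounds idempotence around 1e-5 rather than machine precision
        assert np.abs(twice.samples[sl] - once.samples[sl]).max() < 1e-4


class TestRespirationMeasures:
    def test_rvt_of_constant_amplitude_sinusoid_is_two(self):
        fs = 50
        t = np.arange(120 * fs) / fs
        trace = _cleaned(np.sin(2 * np.pi * 0.3 * t), fs)
        rvt = derive_respiration_measure(trace, "RVT")
        interior = slice(int(5 * fs), -int(5 * fs))
        assert np.abs(rvt[interior] - 2.0).max() < 0.1

    def test_rvt_tracks_amplitude_modulation(self):
        fs = 50
        t = np.arange(300 * fs) / fs
        env = 1 + 0.5 * np.sin(2 * np.pi * 0.03 * t)
        trace = _cleaned(env * np.sin(2 * np.pi * 0.3 * t), fs)
        rvt = derive_respiration_measure(trace, "RVT")
        interior = slice(int(10 * fs), -int(10 * fs))
        rel = np.abs(rvt[interior] - 2 * env[interior]) / (2 * env[interior])
        assert rel.max() < 0.05

    def test_rv_of_white_noise_estimates_sigma(self, rng):
        fs = 100
        sigma = 0.7
        trace = _cleaned(sigma * rng.standard_normal(100 * fs + 20 * fs), fs)
        rv = derive_respiration_measure(trace, "RV")
        assert abs(rv.mean() - sigma) / sigma < 0.05

    def test_measures_invariant_to_sign_flip(self):
        fs = 50
        t = np.arange(60 * fs) / fs
        x = (1 + 0.3 * np.sin(2 * np.pi * 0.05 * t)) * np.sin(2 * np.pi * 0.3 * t)
        for m in ("RVT", "ENV", "RV"):
            a = derive_respiration_measure(_cleaned(x, fs), m)
            b = derive_respiration_measure(_cleaned(-x, fs), m)
            assert np.allclose(a, b, atol=1e-10)

    def test_rvt_nonnegative(self, rng):
        fs = 50
        x = rng.standard_normal(60 * fs)
        trace = _cleaned(signal.sosfiltfilt(
            signal.butter(2, 0.5, fs=fs, output="sos"), x), fs)
        assert derive_respiration_measure(trace, "RVT").min() >= 0

    def test_too_few_breaths_is_degenerate(self):
        fs = 50
        t = np.arange(12 * fs) / fs
        with pytest.raises(DegenerateInputError):
            derive_respiration_measure(_cleaned(np.sin(2 * np.pi * 0.05 * t), fs), "RVT")


def _component_amplitude(x, f, fs):
    t = np.arange(x.size) / fs
    return 2 * np.hypot(x @ np.sin(2 * np.pi * f * t), x @ np.cos(2 * np.pi * f * t)) / x.size


class TestCleanCardiac:
    @pytest.mark.parametrize("f_noise", [0.05, 50.0])
    def test_out_of_band_attenuated_20db(self, f_noise):
        fs = 400
        pulse = generate_cardiac_trace(120, fs, 60, 0, seed=0).samples
        t = np.arange(pulse.size) / fs
        contaminated = pulse + 2.0 * np.sin(2 * np.pi * f_noise * t)
        z = (contaminated - contaminated.mean()) / contaminated.std()
        amp_in = _component_amplitude(z, f_noise, fs)
        cleaned = clean_cardiac_trace(PhysioTrace(contaminated, fs, "cardiac"))
        amp_out = _component_amplitude(cleaned.samples, f_noise, fs)
        assert amp_out / amp_in < 10 ** (-20 / 20)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            clean_cardiac_trace(PhysioTrace(np.zeros(4000), 400, "cardiac"))


class TestHeartRate:
    def test_regular_beats_give_constant_hr(self):
        t = generate_cardiac_trace(90, 200, 60, 0, seed=0)
        hr = compute_heart_rate(clean_cardiac_trace(t))
        assert np.allclose(hr, 60.0, atol=0.5)

    def test_alternating_ibis_match_direct_oracle(self):
        fs = 200
        ibis = np.tile([0.75, 0.85], 40)
        beats = 0.5 + np.concatenate([[0.0], np.cumsum(ibis)])
        x = np.zeros(int(beats[-1] * fs) + fs)
        for b in beats:
            x[int(b * fs)] = 1.0
        x = signal.sosfiltfilt(signal.butter(2, 20, fs=fs, output="sos"), x)
        hr = compute_heart_rate(PhysioTrace(x, fs, "cardiac", state="cleaned"))
        mids = ((beats[:-1] + beats[1:]) / 2 * fs)[5:-5]
        oracle = (60.0 / ibis)[5:-5]
        recovered = np.interp(mids, np.arange(hr.size), hr)
        assert np.abs(recovered - oracle).max() < 1.0
        assert np.isclose(oracle.max(), 80.0) and np.isclose(oracle.min(), 60 / 0.85)

    def test_implausible_beat_replaced_within_range(self):
        fs = 200
        beats = list(np.arange(0, 40, 1.0)) + list(np.arange(42.5, 80, 1.0))
        x = np.zeros(int(80 * fs) + fs)
        for b in beats:
            x[int(b * fs)] = 1.0
        x = signal.sosfiltfilt(signal.butter(2, 20, fs=fs, output="sos"), x)
        hr = compute_heart_rate(PhysioTrace(x, fs, "cardiac", state="cleaned"))
        assert hr.min() >= 30.0 and hr.max() <= 180.0

    def test_too_few_beats_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_heart_rate(PhysioTrace(np.zeros(2000), 100, "cardiac",
                                           state="cleaned"))


class TestResampleToFrames:
    def test_constant_series(self):
        fr = resample_to_frames(np.full(1000, 3.3), 100, 9, 1.0)
        assert np.allclose(fr.values, 3.3)
        assert len(fr) == 9

    def test_linear_ramp_matches_window_means(self):
        fs, tr, n = 100, 0.72, 50
        x = np.linspace(0, 1, int(fs * tr * n) + 10)
        fr = resample_to_frames(x, fs, n, tr)
        edges = np.floor(np.arange(n + 1) * fs * tr).astype(int)
        expected = [x[edges[k]:edges[k + 1]].mean() for k in range(n)]
        assert np.allclose(fr.values, expected, atol=1e-12)

    def test_study_geometry_consumes_full_recording(self):
        x = np.arange(345_600, dtype=float)
        fr = resample_to_frames(x, 400, 1200, 0.72)
        assert len(fr) == 1200
        # last frame averages the final 288 samples
        assert np.isclose(fr.values[-1], x[-288:].mean())

    def test_short_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            resample_to_frames(np.ones(100), 100, 50, 1.0)
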