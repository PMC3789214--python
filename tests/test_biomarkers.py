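import numpy as np
import pytest

from eegdx.biomarkers import (
    ALPHA_SEARCH, BETA_SEARCH, BiomarkerDef, alpha_theta_transition,
    barlow_parameters, default_registry, dfa_exponent, envelope_correlation,
    envelope_statistics, extract_battery, fast_registry, fit_spectral_peak,
    frequency_stability, hjorth_parameters, mfdfa_width, oscillation_bursts,
    phase_bursts, power_ratio, spectral_band_features, wackermann_parameters,
)
from eegdx.signal_core import (
    ALPHA, BETA, DELTA, THETA, BandDefinition, Recording, Spectrum,
    analytic_envelope_phase, bandpass_filter, welch_psd,
)

from conftest import FS, sine


def flat_spectrum(value=1.0, df=0.25, fmax=50.0):
    f = np.arange(df, fmax, df)
    return Spectrum(frequencies=f, power=np.full(f.size, value))


class TestSpectralBandFeatures:
    def test_white_noise_relative_power_is_bandwidth_ratio(self):
        feats = spectral_band_features(flat_spectrum(), ALPHA)
        assert feats["relative_power"] == pytest.approx(5 / 44, abs=0.02)

    def test_pure_tone_central_frequency_and_bandwidth(self):
        sp = welch_psd(sine(10.0, duration=60.0), FS)
        feats = spectral_band_features(sp, ALPHA)
        assert feats["central_frequency"] == pytest.approx(10.0, abs=0.1)
        assert feats["bandwidth"] <= 2 * sp.df

    def test_two_tone_central_frequency_weighted_mean(self):
        x = sine(9.0, duration=60.0) + sine(12.0, duration=60.0)
        feats = spectral_band_features(welch_psd(x, FS), ALPHA)
        # equal powers -> weighted mean 10.5 (oracle: direct sum)
        assert feats["central_frequency"] == pytest.approx(10.5, abs=0.1)

    def test_zero_power_flagged(self):
        sp = flat_spectrum(0.0)
        sp.power[:] = 0
        feats = spectral_band_features(sp, ALPHA)
        assert all(np.isnan(v) for v in feats.values())


class TestPowerRatio:
    def test_equal_power_bands(self):
        b1 = BandDefinition("a", 8, 13)
        b2 = BandDefinition("b", 20, 25)
        assert power_ratio(flat_spectrum(), b1, b2) == pytest.approx(1.0)

    def test_white_noise_theta_alpha(self):
        assert power_ratio(flat_spectrum(), THETA, ALPHA) == pytest.approx(
            3 / 5, abs=0.1)

    def test_alpha_dominant_signal(self, rng):
        x = rng.standard_normal(int(60 * FS)) + 3 * sine(10.0, 60.0)
        sp = welch_psd(x, FS)
        assert power_ratio(sp, THETA, ALPHA) < 1


class TestFitSpectralPeak:
    def _psd_with_peaks(self, peaks, noise_sd=0.0, seed=0):
        f = np.arange(0.25, 50, 0.25)
        p = f ** -1.0
        rng = np.random.default_rng(seed)
        p *= np.exp(noise_sd * rng.standard_normal(f.size))
        for amp, center, sigma in peaks:
            p = p + amp * np.exp(-0.5 * ((f - center) / sigma) ** 2)
        return Spectrum(frequencies=f, power=p)

    def test_injected_beta_peak_recovered(self):
        sp = self._psd_with_peaks([(0.5, 19.6, 1.0)], noise_sd=0.05)
        pk = fit_spectral_peak(sp, BETA_SEARCH)
        assert pk.present
        assert pk.center == pytest.approx(19.6, abs=0.2)
        assert pk.width == pytest.approx(1.0 * 2.355, rel=0.2)
        assert pk.uncorrected_power >= pk.corrected_power

    def test_pure_one_over_f_has_no_peak(self):
        sp = self._psd_with_peaks([], noise_sd=0.05)
        assert not fit_spectral_peak(sp, BETA_SEARCH).present

    def test_two_peaks_both_reported(self):
        sp = self._psd_with_peaks([(0.5, 16.0, 0.8), (0.3, 24.0, 0.8)],
                                  noise_sd=0.03)
        pk = fit_spectral_peak(sp, BETA_SEARCH)
        assert pk.present and pk.second is not None
        centers = sorted([pk.center, pk.second.center])
        assert centers[0] == pytest.approx(16.0, abs=0.3)
        assert centers[1] == pytest.approx(24.0, abs=0.3)


class TestAlphaThetaTransition:
    def test_trough_between_theta_and_alpha(self):
        f = np.arange(0.5, 50, 0.25)
        p = (np.exp(-0.5 * ((f - 5) / 1.0) ** 2)
             + 2 * np.exp(-0.5 * ((f - 10) / 1.0) ** 2) + 0.01)
        sp = Spectrum(frequencies=f, power=p)
        trough, at_boundary = alpha_theta_transition(sp, apf=10.0)
        # oracle: grid argmin of the constructed spectrum in [4, 10]
        m = (f >= 4) & (f <= 10)
        assert trough == pytest.approx(f[m][np.argmin(p[m])], abs=0.25)
        assert not at_boundary

    def test_monotone_spectrum_flagged(self):
        f = np.arange(0.5, 50, 0.25)
        sp = Spectrum(frequencies=f, power=f ** -1.0)
        _, at_boundary = alpha_theta_transition(sp, apf=10.0)
        assert at_boundary

    def test_undefined_apf(self):
        sp = flat_spectrum()
        trough, flag = alpha_theta_transition(sp, apf=np.nan)
        assert np.isnan(trough) and flag


class TestHjorth:
    def test_sinusoid_mobility_is_angular_frequency(self):
        h = hjorth_parameters(sine(10.0), FS)
        assert h["mobility"] == pytest.approx(2 * np.pi * 10, rel=0.02)
        assert h["complexity"] == pytest.approx(1.0, rel=0.02)

    def test_white_noise_activity(self, rng):
        x = rng.standard_normal(100_000)
        assert hjorth_parameters(x, FS)["activity"] == pytest.approx(1.0, rel=0.05)

    def test_constant_signal_flagged(self):
        h = hjorth_parameters(np.ones(1000), FS)
        assert h["activity"] == 0 and np.isnan(h["mobility"])


class TestBarlow:
    def test_pure_tone(self):
        b = barlow_parameters(sine(10.0), FS)
        assert b["mean_frequency"] == pytest.approx(10.0, rel=0.02)
        assert b["spectral_purity"] == pytest.approx(1.0, rel=0.02)

    def test_mean_amplitude_rectified_convention(self):
        b = barlow_parameters(sine(6.0, amplitude=0.5), FS)
        assert b["mean_amplitude"] == pytest.approx(0.5 * 2 / np.pi, rel=0.02)

    def test_white_noise_purity_below_one(self, rng):
        # discrete-difference moments give 2/sqrt(6) ~ 0.816 for white noise
        b = barlow_parameters(rng.standard_normal(100_000), FS)
        assert b["spectral_purity"] == pytest.approx(2 / np.sqrt(6), abs=0.02)


class TestWackermann:
    def test_rank_one_field_has_unit_complexity(self):
        x = sine(10.0, duration=20.0)
        rec = Recording(np.stack([x, x, x]), FS, ["C3", "C4", "Cz"])
        w = wackermann_parameters(rec)
        assert w["spatial_complexity"] == pytest.approx(1.0, abs=0.05)

    def test_independent_noise_isotropic_limit(self, rng):
        # average-referencing leaves a rank-(n-1) isotropic field: Omega -> n-1
        data = rng.standard_normal((4, int(30 * FS)))
        rec = Recording(data, FS, ["a", "b", "c", "d"])
        assert wackermann_parameters(rec)["spatial_complexity"] == pytest.approx(
            3.0, abs=0.1)

    def test_common_tone_global_frequency(self, rng):
        x = sine(10.0, duration=20.0)
        data = np.stack([x + 0.01 * rng.standard_normal(x.size),
                         -x + 0.01 * rng.standard_normal(x.size)])
        rec = Recording(data, FS, ["C3", "C4"])
        assert wackermann_parameters(rec)["global_frequency"] == pytest.approx(
            10.0, rel=0.05)


class TestDFA:
    def test_white_noise_exponent(self, rng):
        vals = [dfa_exponent(rng.standard_normal(60_000), FS, (0.02, 2.0))
                for _ in range(5)]
        assert np.median(vals) == pytest.approx(0.5, abs=0.1)

    def test_brownian_exponent(self, rng):
        vals = [dfa_exponent(np.cumsum(rng.standard_normal(60_000)), FS,
                             (0.02, 2.0)) for _ in range(5)]
        assert np.median(vals) == pytest.approx(1.5, abs=0.1)


class TestMFDFA:
    def test_monofractal_gaussian_width_small(self, rng):
        w = [mfdfa_width(rng.standard_normal(2 ** 15), 100.0, window_range=(0.16, 30.0))
             for _ in range(3)]
        assert np.median(w) <= 0.25

    def test_multiplicative_cascade_width_large(self, rng):
        # binomial cascade: known strongly multifractal surrogate
        x = np.ones(2 ** 14)
        scale = x.size
        while scale > 1:
            scale //= 2
            for start in range(0, x.size, 2 * scale):
                w = 0.3 if rng.random() < 0.5 else 0.7
                x[start:start + scale] *= 2 * w
                x[start + scale:start + 2 * scale] *= 2 * (1 - w)
        assert mfdfa_width(x, 100.0, window_range=(0.16, 16.0)) > 0.3

    def test_single_q_gives_zero_width(self, rng):
        w = mfdfa_width(rng.standard_normal(2 ** 14), 100.0, q_range=(2,),
                        window_range=(0.16, 16.0))
        assert w == 0.0


def brute_force_bursts(env, thr, fs):
    """Independent run-length oracle (plain loop)."""
    durations, sizes = [], []
    run, area = 0, 0.0
    for v in env:
        if v > thr:
            run += 1
            area += v - thr
        elif run:
            durations.append(run / fs)
            sizes.append(area / fs)
            run, area = 0, 0.0
    if run:
        durations.append(run / fs)
        sizes.append(area / fs)
    return durations, sizes


class TestOscillationBursts:
    def test_constant_envelope_undefined(self):
        assert not oscillation_bursts(np.ones(10_000), FS).defined

    def test_square_wave_durations(self):
        env = np.tile(np.r_[np.full(1000, 2.0), np.full(1000, 0.1)], 50)
        stats = oscillation_bursts(env, FS, threshold=1.0)
        assert stats.defined
        assert stats.duration_p95 == pytest.approx(1000 / FS, rel=0.01)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            env = np.abs(rng.standard_normal(20_000))
            thr = float(np.median(env))
            stats = oscillation_bursts(env, FS)
            durations, sizes = brute_force_bursts(env, thr, FS)
            assert stats.duration_p95 == pytest.approx(
                np.percentile(durations, 95))
            assert stats.size_p95 == pytest.approx(np.percentile(sizes, 95))


class TestPhaseBursts:
    def test_pure_sinusoid_single_flagged_period(self):
        _, phase = analytic_envelope_phase(sine(10.0))
        stats = phase_bursts(phase, FS)
        assert not stats.defined and stats.n_bursts == 1
        assert stats.duration_p95 == pytest.approx(10.0, rel=0.01)

    def test_injected_resets_every_second(self):
        # phase advancing at 10 Hz with a backward jump once per second
        t = np.arange(int(60 * FS)) / FS
        phase = 2 * np.pi * 10 * t
        for k in range(1, 60):
            phase[int(k * FS):] -= np.pi / 2
        stats = phase_bursts(phase, FS)
        assert stats.defined
        assert stats.duration_p95 == pytest.approx(1.0, rel=0.05)

    def test_matches_brute_force_slip_oracle(self, rng):
        for seed in range(5):
            x = bandpass_filter(
                np.random.default_rng(seed).standard_normal(int(60 * FS)),
                ALPHA, FS)
            _, phase = analytic_envelope_phase(x)
            stats = phase_bursts(phase, FS)
            # oracle: explicit loop over slip samples
            slips = np.diff(phase) < 0
            durations, sizes = [], []
            start = None
            for i, s in enumerate(slips):
                if not s and start is None:
                    start = i
                elif s and start is not None:
                    durations.append((i - start) / FS)
                    sizes.append(phase[i] - phase[start])
                    start = None
            if not slips[-1] and start is not None:
                durations.append((len(slips) - start) / FS)
                sizes.append(phase[-1] - phase[start])
            if stats.defined:
                assert stats.duration_p95 == pytest.approx(
                    np.percentile(durations, 95))
                assert stats.size_p95 == pytest.approx(
                    np.percentile(sizes, 95))


class TestEnvelopeStatistics:
    def test_constant_envelope(self):
        s = envelope_statistics(np.full(1000, 3.0))
        assert s["median"] == 3.0 and s["variance"] == 0.0 and s["range"] == 0.0

    def test_rayleigh_skewness(self, rng):
        # narrowband Gaussian limit: Rayleigh skewness 2 sqrt(pi)(pi-3)/(4-pi)^1.5
        env = rng.rayleigh(size=200_000)
        expected = 2 * np.sqrt(np.pi) * (np.pi - 3) / (4 - np.pi) ** 1.5
        assert envelope_statistics(env)["skewness"] == pytest.approx(
            expected, abs=0.05)

    def test_alternating_two_point(self):
        env = np.tile([1.0, 3.0], 100)
        s = envelope_statistics(env)
        assert s["median"] == 2.0 and s["range"] == 2.0


class TestEnvelopeCorrelation:
    def test_identical_channels(self):
        e = np.abs(np.random.default_rng(0).standard_normal((1, 5000)))
        m = envelope_correlation(np.vstack([e, e]))
        assert m[0, 1] == pytest.approx(1.0)

    def test_independent_channels(self, rng):
        e = np.abs(rng.standard_normal((2, 50_000)))
        assert abs(envelope_correlation(e)[0, 1]) < 0.05

    def test_monotone_transform_invariance(self, rng):
        e = np.abs(rng.standard_normal((2, 5000)))
        m1 = envelope_correlation(e)
        e2 = np.vstack([np.exp(e[0]), e[1]])
        m2 = envelope_correlation(e2)
        assert np.allclose(m1, m2)


class TestFrequencyStability:
    def test_stationary_tone_near_zero_dispersion(self):
        st = frequency_stability(sine(10.0, duration=60.0), FS, ALPHA)
        assert st["sd_central_freq"] <= 0.25

    def test_alternating_tone_dispersion(self):
        # 9 Hz / 11 Hz alternating between 5 s windows: two-point sd = 1
        segs = [sine(9.0 if k % 2 == 0 else 11.0, duration=5.0)
                for k in range(12)]
        st = frequency_stability(np.concatenate(segs), FS, ALPHA)
        assert st["sd_central_freq"] == pytest.approx(1.0, abs=0.15)
        assert st["sd_max_wavelet_freq"] == pytest.approx(1.0, abs=0.3)

    def test_cycles_per_window_counts_f_times_t(self):
        st = frequency_stability(sine(10.0, duration=60.0), FS, ALPHA)
        assert st["cycles_per_window_median"] == pytest.approx(50, abs=1)

    def test_too_few_windows_flagged(self):
        st = frequency_stability(sine(10.0, duration=20.0), FS, ALPHA)
        assert all(np.isnan(v) for v in st.values())


class TestExtractBattery:
    def test_registry_row_count_documented_constant(self):
        assert len(default_registry()) == 175

    def test_tensor_shape_and_determinism(self, noise_recording):
        reg = fast_registry()
        t1 = extract_battery(noise_recording, reg)
        t2 = extract_battery(noise_recording, reg)
        assert t1.values.shape == (len(reg), 4)
        assert np.array_equal(t1.values, t2.values, equal_nan=True)

    def test_missing_cz_flags_correlation_rows(self, rng):
        rec = Recording(rng.standard_normal((2, int(60 * FS))), FS,
                        ["C3", "C4"])
        t = extract_battery(rec, fast_registry())
        assert np.all(np.isnan(t.row("beta_env_corr_cz")))
        assert np.any(np.isfinite(t.row("beta_env_variance")))

    def test_scale_covariance_classes(self, noise_recording):
        """Scaling the recording by 3 leaves scale-invariant biomarkers
        unchanged and scales variance-like ones by 9."""
        reg = fast_registry()
        t1 = extract_battery(noise_recording, reg)
        scaled = Recording(noise_recording.data * 3.0, FS,
                           noise_recording.channel_labels, "noise", 1)
        t3 = extract_battery(scaled, reg)
        invariant = ["alpha_env_corr_cz", "beta_env_corr_cz", "alpha_dfa",
                     "beta_dfa", "alpha_relative_power", "beta_relative_power",
                     "power_ratio_theta_alpha", "alpha_central_frequency",
                     "hjorth_mobility"]
        for name in invariant:
            a, b = t1.row(name), t3.row(name)
            ok = np.isfinite(a) & np.isfinite(b)
            assert np.allclose(a[ok], b[ok], rtol=0.02), name
        for name in ["alpha_env_variance", "beta_env_variance"]:
            a, b = t1.row(name), t3.row(name)
            ok = np.isfinite(a) & np.isfinite(b)
            assert np.allclose(b[ok] / a[ok], 9.0, rtol=0.02), name
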