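"""Wavelet transform, Kalman filtering, denoising, R-peak detection,
and pulse segmentation, each against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbgm.exceptions import ConfigError
from cbgm.preprocessing import (
    DenoiseConfig,
    RPeakConfig,
    daubechies_filter,
    denoise,
    detect_r_peaks,
    kalman_filter_sequence,
    kalman_steady_state,
    segment_pulses,
    wavelet_decompose,
    wavelet_reconstruct,
    _filters,
)
from cbgm.synthetic_ecg import SynthConfig, make_template, render_template, synthesize


# --------------------------------------------------------------------------
# wavelet transform
# --------------------------------------------------------------------------

class TestWavelet:
    def test_db2_matches_closed_form(self):
        # the N=2 Daubechies filter has an exact radical expression
        s3, s2 = np.sqrt(3.0), 4.0 * np.sqrt(2.0)
        expected = np.array([1 + s3, 3 + s3, 3 - s3, 1 - s3]) / s2
        assert np.allclose(daubechies_filter(2), expected, atol=1e-12)

    @pytest.mark.parametrize("n", [256, 300, 1000, 2048, 4096])
    def test_perfect_reconstruction(self, n, rng):
        x = rng.normal(size=n)
        pyr = wavelet_decompose(x, DenoiseConfig())
        err = np.linalg.norm(wavelet_reconstruct(pyr) - x) / np.linalg.norm(x)
        assert err <= 1e-8

    @given(st.integers(min_value=256, max_value=4096), st.integers(0, 2**31 - 1))
    @settings(max_examples=12, deadline=None)
    def test_perfect_reconstruction_property(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        pyr = wavelet_decompose(x, DenoiseConfig())
        err = np.linalg.norm(wavelet_reconstruct(pyr) - x) / np.linalg.norm(x)
        assert err <= 1e-8

    def test_energy_conserved_across_bands(self, rng):
        x = rng.normal(size=1024)
        pyr = wavelet_decompose(x, DenoiseConfig())
        e = sum(np.sum(d**2) for d in pyr.details) + np.sum(pyr.approximation**2)
        assert abs(e - np.sum(x**2)) / np.sum(x**2) <= 1e-6

    def test_zero_signal_gives_zero_pyramid(self):
        pyr = wavelet_decompose(np.zeros(512), DenoiseConfig())
        assert all(np.all(d == 0) for d in pyr.details)
        assert np.all(pyr.approximation == 0)

    def test_impulse_details_match_filter_bank_oracle(self):
        """One decomposition level of a unit impulse must equal a direct
        periodized filter-bank convolution computed independently."""
        n, k = 64, 17
        x = np.zeros(n)
        x[k] = 1.0
        cfg = DenoiseConfig(n_levels=1)
        pyr = wavelet_decompose(x, cfg)
        lo, hi = _filters(cfg.wavelet_name)
        # oracle: brute-force modular sums
        ca = np.array(
            [sum(lo[m] * x[(2 * i + m) % n] for m in range(lo.size))
             for i in range(n // 2)]
        )
        cd = np.array(
            [sum(hi[m] * x[(2 * i + m) % n] for m in range(hi.size))
             for i in range(n // 2)]
        )
        assert np.allclose(pyr.details[0], cd, atol=1e-12)
        assert np.allclose(pyr.approximation, ca, atol=1e-12)

    def test_too_short_signal_and_bad_wavelet(self):
        with pytest.raises(ValueError):
            wavelet_decompose(np.zeros(8), DenoiseConfig(n_levels=4))
        with pytest.raises(ConfigError):
            DenoiseConfig(wavelet_name="nosuch")


# --------------------------------------------------------------------------
# Kalman filter
# --------------------------------------------------------------------------

class TestKalman:
    def test_constant_observations_converge(self):
        """With q = 0 the posterior variance decays as p0/(1 + n p0), so
        the residual after n steps is |c - x0| / (n + 1)."""
        c = 0.05  # |c - x0| <= 0.1 puts the 100-step residual below 1e-3
        out = kalman_filter_sequence(np.full(100, c), q=0.0, r=1.0, x0=0.0, p0=1.0)
        assert abs(out[-1] - c) < 1e-3
        assert abs(out[-1] - c) == pytest.approx(abs(c) / 101, rel=1e-9)
        # monotone approach toward the constant, from any start
        out2 = kalman_filter_sequence(np.full(60, 3.5), q=0.0, r=1.0, x0=0.0, p0=1.0)
        assert np.all(np.diff(out2) >= -1e-12)

    def test_tiny_r_trusts_observations(self, rng):
        # r -> 0+ with nonvanishing process noise: gain -> 1, passthrough
        z = rng.normal(size=50)
        out = kalman_filter_sequence(z, q=1.0, r=1e-12, x0=0.0, p0=1.0)
        assert np.allclose(out, z, atol=1e-5)

    def test_steady_state_matches_riccati_fixed_point(self):
        """Iterated covariance must hit the positive root of
        P = (P+q) r / (P+q+r) for 20 random (q, r) pairs."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            q = float(10.0 ** rng.uniform(-4, 1))
            r = float(10.0 ** rng.uniform(-2, 2))
            p = 1.0
            for _ in range(200000):
                pp = p + q
                k = pp / (pp + r)
                p_new = (1 - k) * pp
                if abs(p_new - p) < 1e-14:
                    p = p_new
                    break
                p = p_new
            p_star, _ = kalman_steady_state(q, r)
            assert abs(p - p_star) <= 1e-6
            # and the fixed point satisfies the defining equation
            assert abs(p_star - (p_star + q) * r / (p_star + q + r)) < 1e-12

    def test_invalid_noise_variances(self):
        with pytest.raises(ConfigError):
            kalman_filter_sequence([1.0], q=0.0, r=0.0)
        with pytest.raises(ConfigError):
            kalman_filter_sequence([1.0], q=-1.0, r=1.0)


# --------------------------------------------------------------------------
# denoising
# --------------------------------------------------------------------------

class TestDenoise:
    def test_zero_in_zero_out(self):
        assert np.allclose(denoise(np.zeros(2048)), 0.0)

    def test_huge_process_noise_passes_signal_through(self, rng):
        x = rng.normal(size=1024)
        out = denoise(x, DenoiseConfig(q=1e6, r=1.0))
        assert np.linalg.norm(out - x) / np.linalg.norm(x) < 1e-3

    @pytest.mark.parametrize("snr_db", [0, 5, 10])
    def test_mse_strictly_improves_for_all_replicates(self, snr_db):
        for rep in range(10):
            cfg = SynthConfig(
                duration_s=15.0, seed=300 + rep, snr_db=snr_db,
                baseline_mv=0.0, powerline_mv=0.0,
            )
            noisy, _ = synthesize(cfg)
            clean, _ = synthesize(cfg.noiseless())
            den = denoise(noisy)
            assert np.mean((den - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_output_length_equals_input_length(self, rng):
        for n in (300, 1000, 4097):
            assert denoise(rng.normal(size=n)).size == n


# --------------------------------------------------------------------------
# R-peak detection
# --------------------------------------------------------------------------

def _match(det, true_r, fs, tol_s=0.05):
    tol = tol_s * fs
    used, matched = set(), 0
    for t in true_r:
        cand = [d for d in det if abs(d - t) <= tol and d not in used]
        if cand:
            used.add(min(cand, key=lambda d: abs(d - t)))
            matched += 1
    return matched / len(true_r), matched / max(len(det), 1)


class TestRPeakDetection:
    def test_sixty_percent_threshold_drops_half_amplitude_peak(self):
        """Two isolated QRS complexes with envelope ratio 0.5: only the
        large one survives a 60% threshold; at ratio 0.7 both survive."""
        fs = 360.0
        beat = render_template(make_template("N"), fs)
        half = (beat.size - 1) // 2
        x = np.zeros(int(6 * fs))
        c1, c2 = int(1.5 * fs), int(4.0 * fs)
        x[c1 - half : c1 + half + 1] += beat
        x[c2 - half : c2 + half + 1] += 0.5 * beat  # envelope scales linearly
        det = detect_r_peaks(x, fs)
        assert len(det) == 1 and abs(det[0] - c1) <= 2

        x[c2 - half : c2 + half + 1] += 0.2 * beat  # now 0.7 x amplitude
        det = detect_r_peaks(x, fs)
        assert len(det) == 2

    def test_clean_mixed_record_sensitivity_and_ppv(self):
        cfg = SynthConfig(
            duration_s=60.0, seed=1,
            class_proportions={c: 0.2 for c in "NAVLR"},
            baseline_mv=0.0, powerline_mv=0.0, white_sd=0.0,
        )
        sig, truth = synthesize(cfg)
        det = detect_r_peaks(sig, cfg.fs)
        sens, ppv = _match(det, truth.r_indices, cfg.fs)
        assert sens >= 0.99 and ppv >= 0.99

    def test_snr10_sensitivity(self):
        cfg = SynthConfig(duration_s=60.0, seed=1, snr_db=10)
        sig, truth = synthesize(cfg)
        sens, _ = _match(detect_r_peaks(sig, cfg.fs), truth.r_indices, cfg.fs)
        assert sens >= 0.99

    def test_all_zero_signal_yields_empty(self):
        assert detect_r_peaks(np.zeros(4000), 360.0).size == 0
        assert detect_r_peaks(np.array([]), 360.0).size == 0

    def test_refractory_suppresses_near_duplicates(self):
        fs = 360.0
        beat = render_template(make_template("N"), fs)
        half = (beat.size - 1) // 2
        x = np.zeros(int(4 * fs))
        c = int(2 * fs)
        x[c - half : c + half + 1] += beat
        det = detect_r_peaks(x, fs, RPeakConfig(refractory_ms=200.0))
        assert len(det) == 1

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            RPeakConfig(threshold_fraction=0.0)
        with pytest.raises(ConfigError):
            RPeakConfig(refractory_ms=-1.0)


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

class TestSegmentation:
    @pytest.mark.parametrize("fs", [250.0, 360.0, 500.0, 1000.0])
    def test_every_segment_has_length_300(self, fs, rng):
        x = rng.normal(size=int(20 * fs))
        beats = [(int((i + 2) * fs * 0.8), "N") for i in range(10)]
        ds = segment_pulses(x, fs, beats)
        assert len(ds) == 10
        assert all(s.values.size == 300 for s in ds)

    def test_window_is_150ms_each_side_with_linear_resampling(self, rng):
        """fs=360: the raw window is 54+54=108 samples, then linear
        interpolation to 300 — checked against a hand-built oracle."""
        fs, idx = 360.0, 5000
        x = rng.normal(size=8000)
        ds = segment_pulses(x, fs, [(idx, "V")], standardize=False)
        raw = x[idx - 54 : idx + 54]
        oracle = np.interp(np.linspace(0, 107, 300), np.arange(108), raw)
        assert np.allclose(ds.segments[0].values, oracle, atol=1e-12)

    def test_fs1000_window_is_identity_resample(self, rng):
        x = rng.normal(size=8000)
        ds = segment_pulses(x, 1000.0, [(5000, "N")], standardize=False)
        assert np.allclose(ds.segments[0].values, x[4850:5150], atol=1e-12)

    def test_boundary_beats_are_dropped(self, rng):
        x = rng.normal(size=2000)
        ds = segment_pulses(x, 360.0, [(10, "N"), (1000, "N"), (1990, "N")])
        assert len(ds) == 1
        assert ds.segments[0].r_index == 1000

    def test_standardization_and_constant_window(self):
        x = np.ones(2000)
        ds = segment_pulses(x, 360.0, [(1000, "N")])
        assert np.allclose(ds.segments[0].values, 0.0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        ds = segment_pulses(x, 360.0, [(1000, "N")])
        v = ds.segments[0].values
        assert abs(v.mean()) < 1e-9 and abs(v.std() - 1) < 1e-9
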