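"""Gating algorithm: MI registration, ROI signals, filtering, frequency
estimation, inspiration rejection, phase assignment and binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from retrogate import (GatingParams, TemplateModel, assign_cardiac_phase,
                       bandpass, bin_phases, detect_inspiration,
                       estimate_frequency, extract_signal, gate, map_roi,
                       mutual_information, register_template)


def _entropy_of_binned(x, n_bins=32):
    hist, _ = np.histogram(np.ravel(x), bins=n_bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return -np.sum(p * np.log(p))


def _template_1d(ref):
    n = len(ref)
    card = np.zeros(n, dtype=bool)
    resp = np.zeros(n, dtype=bool)
    card[n // 2 - 5:n // 2 + 5] = True
    resp[10:20] = True
    return TemplateModel(ref, card, resp)


class TestMutualInformation:
    def test_self_information_equals_marginal_entropy(self):
        rng = np.random.default_rng(0)
        x = rng.random(500)
        assert mutual_information(x, x) == pytest.approx(
            _entropy_of_binned(x), rel=1e-9)

    def test_constant_input_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            mutual_information(np.ones(100), np.arange(100.0))


class TestRegisterTemplate:
    def test_identical_projection_zero_shift(self):
        rng = np.random.default_rng(1)
        ref = rng.random(120)
        tpl = _template_1d(ref)
        assert register_template(ref, tpl, 8) == (0,)

    @pytest.mark.parametrize("shift", [3, -5])
    def test_recovers_circular_shift_1d(self, shift):
        rng = np.random.default_rng(2)
        ref = np.convolve(rng.random(120), np.ones(5) / 5, mode="same")
        tpl = _template_1d(ref)
        moved = np.roll(ref, shift)
        assert register_template(moved, tpl, 8) == (shift,)

    def test_matches_brute_force_on_noisy_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            ref = np.convolve(rng.random(100), np.ones(7) / 7, mode="same")
            tpl = _template_1d(ref)
            moved = np.roll(ref, 4) + 0.01 * rng.random(100)
            result = register_template(moved, tpl, 6)
            mis = {s: mutual_information(ref, np.roll(moved, -s))
                   for s in range(-6, 7)}
            brute = max(sorted(mis), key=lambda s: mis[s])
            assert result == (brute,)


class TestRegister2D:
    def test_2d_circular_shift_recovered(self):
        rng = np.random.default_rng(7)
        from scipy import ndimage

        ref = ndimage.gaussian_filter(rng.random((32, 32)), 1.5)
        card = np.pad(np.ones((8, 8), bool), 12)
        resp = np.zeros((32, 32), bool)
        resp[:4, :4] = True
        tpl = TemplateModel(ref, card, resp)
        moved = np.roll(ref, (5, -3), axis=(0, 1))
        result = register_template(moved, tpl, 8)
        assert result == (5, -3)
        # equals exhaustive brute force over the same grid
        best = max(
            ((dy, dx) for dy in range(-8, 9) for dx in range(-8, 9)),
            key=lambda s: mutual_information(
                ref, np.roll(moved, (-s[0], -s[1]), axis=(0, 1))))
        assert result == best


class TestMapRoi:
    def test_zero_translation_identity(self):
        m = np.zeros(50, bool)
        m[10:20] = True
        np.testing.assert_array_equal(map_roi(m, (0,)), m)

    def test_centroid_moves_by_translation(self):
        m = np.zeros((30, 30), bool)
        m[10:14, 10:14] = True
        out = map_roi(m, (2, 0))
        from scipy import ndimage

        c0 = ndimage.center_of_mass(m)
        c1 = ndimage.center_of_mass(out)
        assert c1[0] - c0[0] == pytest.approx(2.0)
        assert c1[1] - c0[1] == pytest.approx(0.0)

    def test_mask_shifted_out_errors(self):
        m = np.zeros(50, bool)
        m[0:6] = True
        with pytest.raises(ValueError, match="out of the projection"):
            map_roi(m, (-30,))


class TestExtractSignal:
    def test_constant_projections(self, default_stream):
        class Fake:
            projections = np.full((7, 9), 2.0)

        mask = np.zeros(9, bool)
        mask[:4] = True
        np.testing.assert_allclose(extract_signal(Fake(), mask),
                                   np.full(7, 8.0))

    def test_empty_roi_errors(self):
        class Fake:
            projections = np.zeros((3, 5))

        with pytest.raises(ValueError, match="empty ROI"):
            extract_signal(Fake(), np.zeros(5, bool))

    def test_cardiac_roi_spectrum_peaks_at_heart_rate(
            self, default_stream, default_gating):
        f_hz, bpm = estimate_frequency(
            default_gating.signals.cardiac_filt,
            default_stream.geometry.frame_rate_hz, (5.0, 12.0))
        assert bpm == pytest.approx(
            default_stream.phantom.heart_rate_bpm, rel=0.02)


class TestBandpass:
    fs = 40.0

    def test_in_band_sinusoid_amplitude_preserved(self):
        t = np.arange(2400) / self.fs
        x = np.sin(2 * np.pi * 8.0 * t)
        y = bandpass(x, self.fs, (5.0, 12.0))
        assert np.max(np.abs(y[200:-200])) == pytest.approx(1.0, rel=0.05)

    def test_dc_removed(self):
        x = np.full(2000, 3.7)
        y = bandpass(x, self.fs, (5.0, 12.0))
        assert np.linalg.norm(y) < 1e-6 * np.linalg.norm(x)

    def test_out_of_band_attenuated_20db(self):
        t = np.arange(4800) / self.fs
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 8.0 * t)
        y = bandpass(x, self.fs, (5.0, 12.0))
        spec = np.abs(np.fft.rfft(y * np.hanning(len(y))))
        freqs = np.fft.rfftfreq(len(y), 1 / self.fs)
        a1 = spec[np.argmin(np.abs(freqs - 1.0))]
        a8 = spec[np.argmin(np.abs(freqs - 8.0))]
        assert 20 * np.log10(a8 / a1) >= 20.0


class TestEstimateFrequency:
    def test_pure_sinusoid_400bpm_within_1bpm(self):
        t = np.arange(2400) / 40.0
        x = np.sin(2 * np.pi * (400 / 60) * t)
        _, bpm = estimate_frequency(x, 40.0, (5.0, 12.0))
        assert bpm == pytest.approx(400.0, abs=1.0)

    def test_600bpm_unit_conversion(self):
        t = np.arange(2400) / 40.0
        x = np.sin(2 * np.pi * 10.0 * t)
        f, bpm = estimate_frequency(x, 40.0, (5.0, 12.0))
        assert f == pytest.approx(10.0, abs=0.02)
        assert bpm == pytest.approx(600.0, abs=1.2)

    def test_constant_series_errors(self):
        with pytest.raises(ValueError, match="no periodic component"):
            estimate_frequency(np.ones(2400), 40.0, (5.0, 12.0))

    def test_error_at_most_spectral_resolution_across_band(self):
        fs, n = 40.0, 1200
        t = np.arange(n) / fs
        for f0 in (5.2, 6.667, 9.1, 11.5):
            x = np.sin(2 * np.pi * f0 * t)
            f, _ = estimate_frequency(x, fs, (5.0, 12.0))
            assert abs(f - f0) <= fs / n


class TestDetectInspiration:
    def test_raised_cosine_pulses_retain_70pct(self):
        fs, resp_hz = 40.0, 80 / 60
        t = np.arange(2400) / fs
        phase = (t * resp_hz) % 1.0
        x = np.where(phase < 0.3, np.sin(np.pi * phase / 0.3) ** 2, 0.0)
        xf = bandpass(x, fs, (0.5, 4.0))
        rej = detect_inspiration(xf, fs, resp_hz, 0.70)
        assert 1 - rej.mean() == pytest.approx(0.70, abs=0.02)

    def test_flat_signal_retains_everything(self):
        rej = detect_inspiration(np.zeros(1000), 40.0, 1.0)
        assert rej.sum() == 0

    def test_amplitude_scaling_leaves_rejection_unchanged(self):
        rng = np.random.default_rng(0)
        x = bandpass(rng.random(2000), 40.0, (0.5, 4.0))
        r1 = detect_inspiration(x, 40.0, 1.3)
        r2 = detect_inspiration(2.0 * x, 40.0, 1.3)
        np.testing.assert_array_equal(r1, r2)


class TestAssignCardiacPhase:
    fs = 200.0

    def _signal_with_peaks(self, peak_times, duration):
        """Sum of narrow raised-cosine bumps centred at the peak times."""
        t = np.arange(int(duration * self.fs)) / self.fs
        x = np.zeros_like(t)
        for tp in peak_times:
            x += np.exp(-0.5 * ((t - tp) / 0.02) ** 2)
        return t, x

    def test_midpoint_between_peaks_is_half(self):
        t, x = self._signal_with_peaks([0.05, 0.20, 0.35, 0.50], 0.6)
        frac, _ = assign_cardiac_phase(x, self.fs, 400.0)
        i = np.argmin(np.abs(t - 0.125))
        assert frac[i] == pytest.approx(0.5, abs=0.02)

    def test_sample_at_peak_is_zero(self):
        t, x = self._signal_with_peaks([0.05, 0.20, 0.35, 0.50], 0.6)
        frac, _ = assign_cardiac_phase(x, self.fs, 400.0)
        i = np.argmin(np.abs(t - 0.20))
        assert frac[i] == pytest.approx(0.0, abs=0.02) or \
            frac[i] == pytest.approx(1.0, abs=0.02)

    def test_variable_beat_lengths_interpolated_exactly(self):
        # beats 0.15 s then 0.20 s; t=0.25 is halfway through the second
        t, x = self._signal_with_peaks([0.0, 0.15, 0.35], 0.45)
        frac, _ = assign_cardiac_phase(x, self.fs, 400.0)
        i = np.argmin(np.abs(t - 0.25))
        assert frac[i] == pytest.approx(0.5, abs=0.02)

    def test_affine_rescaling_invariance(self):
        t, x = self._signal_with_peaks(np.arange(10) * 0.15 + 0.05, 1.6)
        f1, _ = assign_cardiac_phase(x, self.fs, 400.0)
        f2, _ = assign_cardiac_phase(3.5 * x - 11.0, self.fs, 400.0)
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_too_few_beats_errors(self):
        t, x = self._signal_with_peaks([0.1], 0.3)
        with pytest.raises(ValueError, match="unusable"):
            assign_cardiac_phase(x, self.fs, 400.0)


class TestBinPhases:
    def test_fraction_zero_first_bin(self):
        assert bin_phases(np.array([0.0]))[0] == 0

    def test_first_bin_edge_half_open(self):
        assert bin_phases(np.array([1 / 12]))[0] == 1
        assert bin_phases(np.array([1 / 12 - 1e-9]))[0] == 0

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bin_phases(np.array([1.0]))

    def test_uniform_fractions_multinomial(self):
        rng = np.random.default_rng(9)
        frac = rng.random(1200)
        bins = bin_phases(frac, 12)
        counts = np.bincount(bins, minlength=12)
        assert counts.sum() == 1200
        assert stats.chisquare(counts).pvalue > 0.001

    @given(st.integers(1, 20), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_partition_property(self, n_bins, seed):
        rng = np.random.default_rng(seed)
        frac = rng.random(200)
        bins = bin_phases(frac, n_bins)
        assert bins.min() >= 0 and bins.max() < n_bins
        assert np.bincount(bins, minlength=n_bins).sum() == 200


class TestGatePipeline:
    def test_heart_rate_recovered_within_2pct(self, default_stream,
                                              default_gating):
        assert default_gating.est_cardiac_bpm == pytest.approx(
            default_stream.phantom.heart_rate_bpm, rel=0.02)

    def test_resp_rate_recovered(self, default_stream, default_gating):
        assert default_gating.est_resp_rate == pytest.approx(
            default_stream.phantom.resp_rate_bpm, rel=0.02)

    def test_retained_fraction_near_70pct(self, default_gating):
        assert default_gating.retained_fraction == pytest.approx(0.70,
                                                                 abs=0.03)

    def test_bin_counts_partition_retained(self, default_gating):
        counts = default_gating.bin_counts()
        assert counts.sum() == default_gating.retained.sum()
        assert np.all(default_gating.bin_id[~default_gating.retained] == -1)

    def test_phase_truth_agreement(self, default_stream, default_gating):
        d = (default_gating.cardiac_fraction
             - default_stream.truth_cardiac_fraction)
        circ = np.abs((d + 0.5) % 1.0 - 0.5)
        assert circ.mean() < 0.05

    def test_deterministic(self, default_stream, default_template,
                           default_gating):
        res2 = gate(default_stream, default_template, GatingParams())
        np.testing.assert_array_equal(res2.cardiac_fraction,
                                      default_gating.cardiac_fraction)
        np.testing.assert_array_equal(res2.retained,
                                      default_gating.retained)
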