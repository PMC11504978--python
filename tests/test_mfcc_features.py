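import numpy as np
import pytest

from ducksex import (AudioSignal, CallSpec, FrameParams, MfccParams, apply_window,
                     assemble_features, build_mel_filterbank, delta,
                     filterbank_energies, frame_signal, mfcc, normalize_features,
                     power_spectrum, spectrogram, synth_call)
from ducksex.mfcc_features import FeatureMatrix, hz_to_mel
from ducksex.errors import ParameterError, ShapeError, StateError
from conftest import make_frames
from naive_oracles import naive_delta, naive_dft_power, naive_mel_triangle_energies, naive_mfcc_frame


class TestPowerSpectrum:
    def test_zero_frame(self):
        frames = make_frames(np.zeros((2, 64)), windowed=True)
        assert np.all(power_spectrum(frames, 64) == 0)

    def test_impulse_is_flat(self):
        f = np.zeros((1, 64))
        f[0, 0] = 1.0
        np.testing.assert_allclose(
            power_spectrum(make_frames(f, windowed=True), 64), 1.0)

    def test_parseval(self, rng):
        """Energy identity: two-sided sum of |X|^2 equals n_fft * sum x^2."""
        x = rng.normal(size=(4, 128))
        spec = power_spectrum(make_frames(x, windowed=True), 128)
        # reconstruct the two-sided sum from the one-sided grid
        twosided = spec[:, 0] + spec[:, -1] + 2 * spec[:, 1:-1].sum(axis=1)
        np.testing.assert_allclose(twosided, 128 * np.sum(x ** 2, axis=1), rtol=1e-10)

    def test_matches_naive_dft(self, rng):
        x = rng.normal(size=(1, 50))
        ours = power_spectrum(make_frames(x, windowed=True), 64)[0]
        np.testing.assert_allclose(ours, naive_dft_power(x[0], 64),
                                   rtol=1e-8, atol=1e-8)

    def test_requires_windowed(self, rng):
        with pytest.raises(StateError):
            power_spectrum(make_frames(rng.normal(size=(1, 64))), 64)

    def test_nfft_too_small(self, rng):
        with pytest.raises(ParameterError):
            power_spectrum(make_frames(rng.normal(size=(1, 100)), windowed=True), 64)


class TestMelFilterbank:
    def test_peaks_are_one_and_support_bounded(self):
        bank = build_mel_filterbank(44100, 2048, 26)
        for m in range(bank.n_filters):
            row = bank.weights[m]
            assert row.max() == 1.0
            assert row[bank.boundary_bins[m + 1]] == 1.0
            assert np.all(row[: bank.boundary_bins[m]] == 0)
            outside = row[bank.boundary_bins[m + 2] + 1:]
            assert outside.size == 0 or np.all(outside == 0)

    def test_boundaries_arithmetic_on_mel_scale(self):
        bank = build_mel_filterbank(44100, 2048, 26, fmin=0.0, fmax=22050.0)
        mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(22050.0), 28)
        expected = np.floor(2049 * (700 * (10 ** (mel_pts / 2595) - 1)) / 44100)
        np.testing.assert_array_equal(bank.boundary_bins,
                                      np.minimum(expected.astype(int), 1024))
        diffs = np.diff(mel_pts)
        np.testing.assert_allclose(diffs, diffs[0])

    def test_fmax_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            build_mel_filterbank(44100, 2048, 26, fmax=30000.0)


class TestFilterbankEnergies:
    def test_zero_spectrum_hits_floor(self):
        bank = build_mel_filterbank(44100, 256, 8)
        s = filterbank_energies(np.zeros((3, 129)), bank, floor=1e-10)
        np.testing.assert_array_equal(s, 1e-10)

    def test_energy_at_peak_bin_passes_unattenuated(self):
        bank = build_mel_filterbank(44100, 2048, 26)
        e = np.zeros((1, 1025))
        peak = bank.boundary_bins[5]   # peak bin of filter 4
        e[0, peak] = 7.0
        s = filterbank_energies(e, bank, floor=0.0)
        assert s[0, 4] == 7.0

    def test_linearity(self, rng):
        bank = build_mel_filterbank(44100, 512, 12)
        e = rng.uniform(size=(2, 257))
        np.testing.assert_allclose(filterbank_energies(2 * e, bank, floor=0.0),
                                   2 * filterbank_energies(e, bank, floor=0.0))

    def test_matches_naive_triangles(self, rng):
        bank = build_mel_filterbank(44100, 512, 12)
        e = rng.uniform(size=257)
        ours = filterbank_energies(e[None, :], bank, floor=1e-10)[0]
        naive = naive_mel_triangle_energies(e, bank.boundary_bins, 1e-10)
        np.testing.assert_allclose(ours, naive, rtol=1e-10)

    def test_shape_mismatch(self, rng):
        bank = build_mel_filterbank(44100, 512, 12)
        with pytest.raises(ShapeError):
            filterbank_energies(rng.uniform(size=(1, 100)), bank)


class TestMfcc:
    @pytest.mark.parametrize("convention,offset", [("standard", 1), ("printed", -1)])
    def test_matches_double_loop_oracle(self, rng, convention, offset):
        s = rng.uniform(0.1, 10.0, size=(5, 26))
        ours = mfcc(s, 12, convention)
        for i in range(5):
            naive = np.array([np.sqrt(2 / 26) * sum(
                np.log(s[i, m]) * np.cos(np.pi * n * (2 * m + offset) / 52)
                for m in range(26)) for n in range(1, 13)])
            np.testing.assert_allclose(ours[i], naive, rtol=1e-10)

    def test_constant_energies_give_near_zero_coefficients(self):
        """Flat log-spectrum: every kept DCT coefficient vanishes (oracle value)."""
        s = np.full((1, 26), 3.7)
        for convention, offset in (("standard", 1), ("printed", -1)):
            expected = np.array([np.sqrt(2 / 26) * np.log(3.7) * sum(
                np.cos(np.pi * n * (2 * m + offset) / 52) for m in range(26))
                for n in range(1, 13)])
            np.testing.assert_allclose(mfcc(s, 12, convention)[0], expected,
                                       atol=1e-12)

    def test_gain_shift_is_closed_form(self, rng):
        """Scaling S by c shifts coefficient n by log(c)*sqrt(2/M)*sum_m cos(...)."""
        s = rng.uniform(0.5, 2.0, size=(3, 26))
        c = 17.0
        shift = np.array([np.log(c) * np.sqrt(2 / 26) * sum(
            np.cos(np.pi * n * (2 * m + 1) / 52) for m in range(26))
            for n in range(1, 13)])
        np.testing.assert_allclose(mfcc(c * s, 12) - mfcc(s, 12),
                                   np.tile(shift, (3, 1)), atol=1e-10)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ParameterError):
            mfcc(np.array([[1.0, 0.0, 2.0]]), 2)


class TestDelta:
    def test_constant_features_have_zero_delta(self):
        assert np.all(delta(np.full((10, 12), 3.0), 2) == 0)

    def test_linear_ramp_recovers_slope(self):
        t = np.arange(20, dtype=float)
        d = delta(np.outer(t, [1.0, -2.0]), 2)
        np.testing.assert_allclose(d[2:-2, 0], 1.0)
        np.testing.assert_allclose(d[2:-2, 1], -2.0)

    @pytest.mark.parametrize("width", [1, 2, 3])
    def test_matches_naive_regression(self, rng, width):
        c = rng.normal(size=(15, 4))
        np.testing.assert_allclose(delta(c, width), naive_delta(c, width),
                                   rtol=1e-12, atol=1e-12)

    def test_short_input_warns_and_replicates(self, caplog):
        with caplog.at_level("WARNING"):
            d = delta(np.array([[1.0, 2.0]]), 2)
        assert np.all(d == 0)
        assert "edges replicated" in caplog.text


class TestAssembleFeatures:
    def test_width_is_36_and_deterministic(self, rng):
        frames = apply_window(frame_signal(
            AudioSignal(rng.normal(size=44100), 44100), FrameParams()))
        a = assemble_features(frames)
        b = assemble_features(frames)
        assert a.values.shape == (98, 36)
        np.testing.assert_array_equal(a.values, b.values)
        assert np.all(np.isfinite(a.values))

    def test_single_frame_deltas_are_zero(self, rng):
        frames = make_frames(rng.normal(size=(1, 1102)), windowed=True)
        fm = assemble_features(frames)
        assert fm.values.shape == (1, 36)
        assert np.all(fm.values[:, 12:] == 0)

    def test_end_to_end_matches_naive_chain(self, rng):
        """Pipeline MFCCs equal the explicit DFT + triangle + DCT chain."""
        params = MfccParams(n_fft=256, n_filters=10, n_coeffs=5)
        frames = make_frames(rng.normal(size=(3, 200)), windowed=True)
        fm = assemble_features(frames, params)
        bank = build_mel_filterbank(44100, 256, 10)
        for i in range(3):
            naive = naive_mfcc_frame(frames.frames[i], bank.boundary_bins, 256, 5,
                                     params.energy_floor, offset=1)
            np.testing.assert_allclose(fm.values[i, :5], naive, rtol=1e-8)

    def test_gain_invariance_of_delta_columns(self, rng):
        frames = rng.normal(size=(6, 1102))
        a = assemble_features(make_frames(frames, windowed=True))
        b = assemble_features(make_frames(100.0 * frames, windowed=True))
        np.testing.assert_allclose(a.values[:, 12:], b.values[:, 12:], atol=1e-9)


class TestNormalizeFeatures:
    def test_train_columns_standardized(self, rng):
        fm = FeatureMatrix(rng.normal(3.0, 2.0, size=(500, 36)))
        out, (mean, std) = normalize_features(fm)
        assert out.normalization == "zscored"
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-6)

    def test_constant_column_maps_to_zero(self):
        v = np.ones((10, 3))
        out, _ = normalize_features(FeatureMatrix(v))
        assert np.all(out.values == 0.0)

    def test_test_set_uses_train_statistics(self, rng):
        train = FeatureMatrix(rng.normal(0, 1, size=(200, 4)))
        test = FeatureMatrix(rng.normal(5, 3, size=(50, 4)))
        train_n, test_n, (mean, std) = normalize_features(train, test)
        np.testing.assert_allclose(test_n.values, (test.values - mean) / std)
        assert abs(test_n.values.mean()) > 0.5   # not re-centered on itself


class TestSpectrogram:
    def test_pure_tone_localized(self, tone_signal):
        freqs, times, logmag = spectrogram(tone_signal)
        peak_freq = freqs[np.argmax(logmag.mean(axis=1))]
        assert abs(peak_freq - 2500.0) <= freqs[1] - freqs[0]

    def test_silence_is_uniform_floor(self):
        _, _, logmag = spectrogram(AudioSignal(np.zeros(44100), 44100))
        assert np.all(logmag == logmag[0, 0])

    def test_female_call_contour_flat_then_rising(self):
        """Dominant bin stays flat, then rises over the terminal glide."""
        rng = np.random.default_rng(0)
        sig, _ = synth_call(CallSpec(sex="female", duration_s=0.4,
                                     glide_hz_range=(250.0, 300.0)), rng)
        freqs, times, logmag = spectrogram(sig)
        dom = freqs[np.argmax(logmag, axis=0)]
        body = dom[2: int(0.7 * len(dom))]
        assert body.max() - body.min() <= 2 * (freqs[1] - freqs[0])
        assert dom[-1] >= body.mean() + 150.0
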