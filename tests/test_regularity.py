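"""Modulation spectra and kurtosis: estimator identities and toy signals."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sst

from audiosfa import regularity
from audiosfa.regularity import (Spectrogram, correlation_modulation_spectrum,
                                 correlation_time_series, kurtosis,
                                 kurtosis_score, modulation_spectrum,
                                 spectrogram)
from audiosfa.stimuli import AudioStimulus

RATE = 8000.0


class TestSpectrogram:
    def test_pure_tone_dominant_row(self):
        t = np.arange(int(RATE)) / RATE
        S = spectrogram(AudioStimulus(np.sin(2 * np.pi * 1000 * t), RATE))
        dominant = S.freqs[np.argmax(S.power.mean(axis=0))]
        assert dominant == pytest.approx(1000.0, abs=50.0)
        row = S.power[:, np.argmax(S.power.mean(axis=0))]
        assert row.std() / row.mean() < 0.05

    def test_silence_is_zero_power(self):
        S = spectrogram(AudioStimulus(np.zeros(4000), RATE))
        assert not np.any(S.power)

    def test_am_tone_row_oscillates_at_am_rate(self):
        r = 10.0
        t = np.arange(int(2 * RATE)) / RATE
        x = (1 + 0.8 * np.sin(2 * np.pi * r * t)) * np.sin(2 * np.pi * 1000 * t)
        S = spectrogram(AudioStimulus(x, RATE))
        row = S.power[:, np.argmin(np.abs(S.freqs - 1000))]
        f = np.fft.rfftfreq(len(row), 1 / S.frame_rate)
        peak = f[np.argmax(np.abs(np.fft.rfft(row - row.mean())))]
        assert peak == pytest.approx(r, abs=1.0)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            spectrogram(AudioStimulus(np.zeros(100), RATE), window=0.5)


class TestModulationSpectrum:
    def test_constant_spectrogram_all_power_at_zero(self):
        P = np.tile(np.exp(-np.arange(16) / 4.0), (64, 1))
        ms = modulation_spectrum(Spectrogram(P, np.arange(64) / 100.0,
                                             np.arange(16) * 100.0, 100.0))
        assert ms.marginal_axis[np.argmax(ms.marginal)] == 0.0
        assert ms.marginal[ms.marginal_axis == 0][0] > 0.99

    def test_modulated_spectrogram_marginal_peaks_at_rate(self):
        fr, r, T, F = 200.0, 6.0, 400, 32
        tt = np.arange(T) / fr
        P = np.outer(1 + 0.5 * np.sin(2 * np.pi * r * tt), np.ones(F)) \
            * np.exp(-np.arange(F) / 8.0)[None, :]
        ms = modulation_spectrum(Spectrogram(P, tt, np.arange(F) * 50.0, fr))
        nz = np.abs(ms.marginal_axis) > 0.1
        assert abs(ms.marginal_axis[nz][np.argmax(ms.marginal[nz])]) == \
            pytest.approx(r, abs=fr / T + 1e-9)

    def test_marginal_normalized_and_axis_symmetric(self, vocal_ensemble):
        ms = modulation_spectrum(spectrogram(vocal_ensemble[0]))
        assert ms.marginal.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(np.sort(-ms.marginal_axis),
                                   np.sort(ms.marginal_axis), atol=1e-9)
        assert np.abs(ms.marginal_axis).max() <= 80.0 + 1e-9

    def test_too_few_frames_rejected(self):
        P = np.ones((4, 8))
        with pytest.raises(ValueError):
            modulation_spectrum(Spectrogram(P, np.arange(4.0), np.arange(8.0),
                                            100.0))


class TestCorrelationModulation:
    def test_fixed_correlation_concentrates_at_zero(self, rng):
        n1, n2 = rng.standard_normal((2, 10_000))
        X = np.column_stack([n1, 0.8 * n1 + 0.6 * n2])
        ms = correlation_modulation_spectrum((X, 1000.0))
        assert ms.marginal_axis[np.argmax(ms.marginal)] == 0.0
        assert ms.marginal[ms.marginal_axis == 0][0] > 0.9

    def test_alternating_correlation_peaks_at_alternation_rate(self, rng):
        fps, r, n = 1000.0, 2.0, 10_000
        n1, n2 = rng.standard_normal((2, n))
        sgn = np.sign(np.sin(2 * np.pi * r * np.arange(n) / fps))
        X = np.column_stack([n1, 0.9 * sgn * n1 + np.sqrt(0.19) * n2])
        ms = correlation_modulation_spectrum((X, fps))
        assert abs(ms.marginal_axis[np.argmax(ms.marginal)]) == \
            pytest.approx(r, abs=0.5)

    def test_entries_bounded_and_shape(self, rng):
        X = rng.standard_normal((2000, 6))
        cts = correlation_time_series((X, 1000.0))
        assert cts.values.shape[1] == 6 * 5 // 2
        assert np.all(cts.values >= -1.0) and np.all(cts.values <= 1.0)

    def test_dead_channel_pairs_zeroed(self, rng):
        X = rng.standard_normal((2000, 3))
        X[:, 2] = 5.0  # constant channel
        cts = correlation_time_series((X, 1000.0))
        # pairs (0,2) and (1,2) are columns 1 and 2 of the upper triangle
        assert not np.any(cts.values[:, 1:])


class TestKurtosis:
    def test_equal_magnitude_deviations_give_one(self):
        assert kurtosis(np.array([-1.0, 1.0, -1.0, 1.0])).k1 == \
            pytest.approx(1.0)

    def test_gaussian_sample_near_three(self):
        x = np.random.default_rng(0).standard_normal(10**6)
        assert kurtosis(x).k1 == pytest.approx(3.0, abs=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bias_correction_matches_textbook_estimator(self, seed):
        """The printed small-sample correction equals the standard
        bias-corrected (non-excess) kurtosis estimator."""
        x = np.random.default_rng(seed).gamma(2.0, size=37)
        ours = kurtosis(x, bias_correct=True).k0
        oracle = sst.kurtosis(x, fisher=False, bias=False)
        assert ours == pytest.approx(oracle, rel=1e-12)

    @given(st.floats(min_value=-50, max_value=50),
           st.floats(min_value=0.01, max_value=100))
    def test_affine_invariance(self, shift, scale):
        x = np.random.default_rng(99).laplace(size=500)
        k0 = kurtosis(x).k1
        k1 = kurtosis(scale * x + shift).k1
        assert k1 == pytest.approx(k0, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kurtosis(np.ones(10))
        with pytest.raises(ValueError):
            kurtosis(np.array([1.0, 2.0, 3.0]), bias_correct=True)
        with pytest.raises(ValueError):
            kurtosis(np.array([1.0, 2.0]), weights=np.array([0.9, 0.2]))
        with pytest.raises(ValueError):
            kurtosis(np.array([1.0, 2.0, 3.0]), weights=np.array([0.5, 0.5]))

    def test_weighted_moments(self):
        # point masses at +-1 with equal weight: k1 = 1
        x = np.array([-1.0, 0.0, 1.0])
        w = np.array([0.5, 0.0, 0.5])
        assert kurtosis(x, weights=w).k1 == pytest.approx(1.0)


class TestKurtosisScore:
    def test_self_score_is_exactly_one(self, vocal_ensemble):
        ms = modulation_spectrum(spectrogram(vocal_ensemble[0]))
        assert kurtosis_score(ms, ms) == 1.0

    def test_laplace_gaussian_reference_ratio(self):
        """On a dense symmetric grid the Laplace/Gaussian kurtosis ratio
        approaches the analytic value 6/3 = 2."""
        x = np.arange(-12.0, 12.0001, 0.005)
        wl = np.exp(-np.sqrt(2.0) * np.abs(x))
        wg = np.exp(-x**2 / 2.0)
        target = regularity.ModulationSpectrum(None, None, x, wl / wl.sum(), x)
        ref = regularity.ModulationSpectrum(None, None, x, wg / wg.sum(), x)
        assert kurtosis_score(target, ref) == pytest.approx(2.0, rel=0.01)

    def test_grid_mismatch_rejected(self, vocal_ensemble):
        ms = modulation_spectrum(spectrogram(vocal_ensemble[0]))
        other = regularity.ModulationSpectrum(
            None, None, ms.marginal_axis[:-2], ms.marginal[:-2],
            ms.marginal_axis[:-2])
        with pytest.raises(ValueError):
            kurtosis_score(ms, other)
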