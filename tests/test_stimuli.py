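"""Stimulus generators: determinism, power calibration, mixing contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from audiosfa import regularity, stimuli
from audiosfa.stimuli import (AudioStimulus, MixSpec, VocalizationParams,
                              amplitude_regularize, embed_at_snr,
                              make_applause_like, make_clutter,
                              make_pair_stimulus, make_vocalization,
                              make_white_noise)

RATE = 8000.0


@pytest.mark.parametrize("maker", [
    lambda s: make_vocalization(duration=0.3, seed=s, rate=RATE),
    lambda s: make_vocalization(VocalizationParams(preset="broadband"),
                                duration=0.3, seed=s, rate=RATE),
    lambda s: make_white_noise(duration=0.3, rate=RATE, seed=s),
    lambda s: make_applause_like(duration=0.3, rate=RATE, seed=s),
])
def test_generators_are_pure_functions_of_seed(maker):
    a, b, c = maker(7), maker(7), maker(8)
    np.testing.assert_array_equal(a.samples, b.samples)
    assert not np.array_equal(a.samples, c.samples)


def test_white_noise_power_calibration():
    # -20 dBW -> variance 0.01; 0 dBW -> variance 1
    w = make_white_noise(duration=0.5, power_dbw=-20.0, rate=50_000.0, seed=3)
    assert w.samples.var() == pytest.approx(0.01, rel=0.05)
    w0 = make_white_noise(duration=0.5, power_dbw=0.0, rate=50_000.0, seed=3)
    assert w0.samples.var() == pytest.approx(1.0, rel=0.05)


def test_vocalization_duration_bounds():
    with pytest.raises(ValueError):
        make_vocalization(duration=0.01, rate=RATE)
    with pytest.raises(ValueError):
        make_vocalization(duration=5.0, rate=RATE)
    with pytest.raises(ValueError):
        make_vocalization(VocalizationParams(envelope_cutoff_hz=5000.0),
                          duration=0.5, rate=RATE)


def test_stationary_harmonic_stack_peaks_at_zero_modulation():
    """With constant f0 and constant envelopes the temporal-modulation
    profile is maximal at 0 Hz."""
    p = VocalizationParams(f0_spread=0.0, f0_excursion=0.0, envelope_depth=0.0)
    v = make_vocalization(p, duration=1.0, seed=0, rate=RATE)
    ms = regularity.modulation_spectrum(regularity.spectrogram(v))
    assert ms.marginal_axis[np.argmax(ms.marginal)] == 0.0


def test_vocalization_modulation_power_is_low_frequency(vocal_ensemble):
    """A 4 Hz envelope cutoff confines >=80% of temporal-modulation power
    to |f| <= 8 Hz (ensemble average over exemplars)."""
    avg = regularity.average_marginal(
        [regularity.modulation_spectrum(regularity.spectrogram(v))
         for v in vocal_ensemble])
    frac = avg.marginal[np.abs(avg.marginal_axis) <= 8.0].sum()
    assert frac >= 0.80


def test_applause_zero_click_rate_is_silence():
    a = make_applause_like(duration=0.2, click_rate=0.0, rate=RATE, seed=0)
    assert not np.any(a.samples)


class TestAmplitudeRegularize:
    def test_flat_envelope_sinusoid_unchanged(self):
        t = np.arange(int(RATE)) / RATE  # integer number of cycles
        s = AudioStimulus(np.sin(2 * np.pi * 440 * t), RATE)
        out = amplitude_regularize(s)
        assert np.sqrt(np.mean((out.samples - s.samples) ** 2)) < 1e-6

    def test_gated_noise_trough_ratio_increases(self, rng):
        from scipy.signal import hilbert
        gate = (np.sin(2 * np.pi * 5 * np.arange(8000) / RATE) > 0) * 0.9 + 0.1
        s = AudioStimulus(rng.standard_normal(8000) * gate, RATE)

        def trough_ratio(x):
            env = np.abs(hilbert(x))
            w = 400
            env = np.convolve(env, np.ones(w) / w, mode="same")
            return np.percentile(env, 5) / np.median(env)

        out = amplitude_regularize(s)
        assert trough_ratio(out.samples) > trough_ratio(s.samples)

    def test_rms_preserved(self, rng):
        s = AudioStimulus(rng.standard_normal(4000) *
                          (1 + 0.5 * np.sin(np.arange(4000) / 200)), RATE)
        out = amplitude_regularize(s)
        assert out.rms == pytest.approx(s.rms, rel=1e-9)

    def test_silence_rejected(self):
        with pytest.raises(ValueError):
            amplitude_regularize(AudioStimulus(np.zeros(1000), RATE))


class TestClutter:
    def pool(self):
        return [make_vocalization(duration=0.3, seed=s, rate=RATE,
                                  exemplar_id=s) for s in range(5)]

    def test_token_duration_and_determinism(self):
        pool = self.pool()
        c1 = make_clutter(pool, n_components=20, duration=3.0, seed=4)
        c2 = make_clutter(pool, n_components=20, duration=3.0, seed=4)
        assert len(c1.samples) == int(3.0 * RATE)
        np.testing.assert_array_equal(c1.samples, c2.samples)
        assert c1.parts["component_ids"] == c2.parts["component_ids"]
        c3 = make_clutter(pool, n_components=20, duration=3.0, seed=5)
        assert c3.parts["component_ids"] != c1.parts["component_ids"]

    def test_component_longer_than_token_rejected(self):
        with pytest.raises(ValueError):
            make_clutter(self.pool(), duration=0.2, seed=0)


class TestEmbedAtSnr:
    def setup_method(self):
        self.sig = make_vocalization(duration=0.4, seed=1, rate=RATE)
        self.clut = make_clutter([make_vocalization(duration=0.3, seed=s,
                                                    rate=RATE)
                                  for s in range(4)], duration=1.0, seed=9)

    def test_snr_zero_equal_power(self):
        mix = embed_at_snr(self.sig, self.clut, MixSpec(snr=0.0))
        p_sig = np.mean(mix.parts["signal"] ** 2)
        p_clut = np.mean(mix.parts["scaled_clutter"] ** 2)
        assert p_clut == pytest.approx(p_sig, rel=1e-9)

    def test_snr_three_is_power_ratio_1000(self):
        mix = embed_at_snr(self.sig, self.clut, MixSpec(snr=3.0))
        ratio = np.mean(mix.parts["signal"] ** 2) / \
            np.mean(mix.parts["scaled_clutter"] ** 2)
        assert ratio == pytest.approx(1000.0, rel=1e-9)

    @given(st.floats(min_value=-7.0, max_value=3.0))
    def test_snr_round_trip(self, snr):
        mix = embed_at_snr(self.sig, self.clut, MixSpec(snr=snr))
        measured = np.log10(np.mean(mix.parts["signal"] ** 2) /
                            np.mean(mix.parts["scaled_clutter"] ** 2))
        assert measured == pytest.approx(snr, abs=1e-9)

    def test_silent_inputs_rejected(self):
        silent = AudioStimulus(np.zeros(100), RATE)
        with pytest.raises(ValueError):
            embed_at_snr(silent, self.clut, MixSpec(snr=0.0))
        with pytest.raises(ValueError):
            embed_at_snr(self.sig, silent, MixSpec(snr=0.0))


class TestPairStimulus:
    def test_label_conservation_and_gap_bounds(self):
        a = make_vocalization(duration=0.3, seed=1, rate=RATE)
        b = make_vocalization(duration=0.45, seed=2, rate=RATE)
        for seed in range(8):
            pair, labels = make_pair_stimulus(a, b, seed=seed)
            assert int(np.sum(labels == "A")) == len(a.samples)
            assert int(np.sum(labels == "B")) == len(b.samples)
            n_gap = int(np.sum(labels == "gap"))
            assert len(pair.samples) == len(a.samples) + len(b.samples) + n_gap
            first_len = len(a.samples) if pair.parts["order"] == "ab" \
                else len(b.samples)
            frac = n_gap / first_len
            assert 0.05 - 1e-3 <= frac <= 0.50 + 1e-3

    def test_determinism_and_rate_mismatch(self):
        a = make_vocalization(duration=0.3, seed=1, rate=RATE)
        b = make_vocalization(duration=0.3, seed=2, rate=RATE)
        p1, l1 = make_pair_stimulus(a, b, seed=3)
        p2, l2 = make_pair_stimulus(a, b, seed=3)
        np.testing.assert_array_equal(p1.samples, p2.samples)
        np.testing.assert_array_equal(l1, l2)
        c = make_vocalization(duration=0.3, seed=2, rate=16_000.0)
        with pytest.raises(ValueError):
            make_pair_stimulus(a, c)


def test_stimulus_invariants():
    with pytest.raises(ValueError):
        AudioStimulus(np.zeros(10), rate=0.0)
    with pytest.raises(ValueError):
        AudioStimulus(np.array([np.nan, 0.0]), rate=RATE)
    s = make_white_noise(duration=0.25, rate=RATE, seed=0)
    assert s.duration == pytest.approx(0.25)
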