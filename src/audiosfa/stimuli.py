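"""Synthetic auditory stimuli with controlled temporal-regularity structure.

Four stimulus classes are generated, chosen to span the combinations of
"continuity of components" and "continuity of correlations between
components" that the analysis pipeline quantifies:

* vocalization-like events (harmonic or broadband presets) — frequency
  components drift smoothly and their relative amplitudes co-vary slowly,
  so both kinds of continuity are present;
* clutter — an amplitude-regularized superposition of many vocalization-like
  events in a 3-s token, emulating background chatter;
* applause-like click textures — each transient is spectrally broadband, so
  the pattern of inter-channel correlations is persistent, but the waveform
  itself is a train of discontinuous events;
* Gaussian white noise — neither kind of continuity.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

DEFAULT_RATE = 50_000.0

__all__ = [
    "AudioStimulus",
    "MixSpec",
    "VocalizationParams",
    "make_vocalization",
    "make_white_noise",
    "make_applause_like",
    "make_clutter",
    "amplitude_regularize",
    "embed_at_snr",
    "make_pair_stimulus",
]


@dataclass
class AudioStimulus:
    """Labeled mono waveform.

    ``samples`` is amplitude in arbitrary units, ``rate`` in samples/second.
    ``label`` is one of {vocalization, clutter, applause_like, white_noise,
    mixture, pair, fixture}. ``parts`` optionally stores named constituent
    waveforms (e.g. signal/scaled clutter of a mixture) for auditing.
    """

    samples: np.ndarray
    rate: float
    label: str = "fixture"
    exemplar_id: int = 0
    seed: int = 0
    parts: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D (mono) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class MixSpec:
    """How a signal is embedded in background clutter.

    ``snr`` is the logarithm (base ``snr_log_base``) of the ratio of average
    powers, target over background. The study sweep runs from -7 (essentially
    no signal) to 3 (essentially no background).
    """

    snr: float
    snr_log_base: float = 10.0
    clutter_seed: int = 0
    placement: float | None = None  # start offset in seconds; None = random


@dataclass(frozen=True)
class VocalizationParams:
    """Parameters of a synthetic vocalization event.

    preset
        "harmonic": a stack of harmonics of a smoothly drifting fundamental
        (coo / harmonic-arch analogue). "broadband": flat-spectrum noise
        carrier under a common slow amplitude envelope (grunt / bark
        analogue).
    f0_mean, f0_spread, f0_excursion
        Class centre of the fundamental frequency (Hz); per-exemplar spread
        of the fundamental around that centre (octaves; voices differ in
        pitch); and the standard deviation of the within-event smooth
        log-frequency random walk (octaves).
    n_harmonics
        Number of harmonic partials in the "harmonic" preset.
    envelope_cutoff_hz
        Low-pass cutoff of the Gaussian-process amplitude envelopes; this is
        the knob that sets where temporal-modulation power concentrates.
    envelope_depth
        Log-amplitude standard deviation of the envelopes (0 = constant).
    """

    preset: str = "harmonic"
    f0_mean: float = 400.0
    f0_spread: float = 0.5
    f0_excursion: float = 0.25
    n_harmonics: int = 8
    envelope_cutoff_hz: float = 4.0
    envelope_depth: float = 1.0


def _slow_process(n: int, rate: float, cutoff_hz: float, rng: np.random.Generator,
                  depth: float = 1.0) -> np.ndarray:
    """Zero-mean Gaussian process low-passed at ``cutoff_hz``, length ``n``.

    Generated at a coarse control rate and interpolated up, so cost is
    independent of the audio rate.
    """
    if depth == 0.0 or cutoff_hz <= 0.0:
        return np.zeros(n)
    ctrl_rate = max(8.0 * cutoff_hz, 50.0)
    n_ctrl = max(int(math.ceil(n / rate * ctrl_rate)) + 8, 16)
    raw = rng.standard_normal(n_ctrl)
    sos = signal.butter(2, cutoff_hz / (ctrl_rate / 2.0), output="sos")
    smooth = signal.sosfiltfilt(sos, raw)
    sd = np.std(smooth)
    if sd > 0:
        smooth = smooth / sd * depth
    t_ctrl = np.arange(n_ctrl) / ctrl_rate
    t = np.arange(n) / rate
    return np.interp(t, t_ctrl, smooth)


def make_vocalization(class_params: VocalizationParams | None = None,
                      duration: float = 0.5,
                      seed: int = 0,
                      rate: float = DEFAULT_RATE,
                      exemplar_id: int = 0) -> AudioStimulus:
    """Synthesize one vocalization-like event.

    Both presets place their temporal-modulation power below roughly twice
    ``envelope_cutoff_hz``; components (harmonics or the noise band) persist
    for the whole event so inter-channel correlations also change slowly.
    """
    p = class_params or VocalizationParams()
    if not (0.1 <= duration <= 3.0):
        raise ValueError(f"duration must be in [0.1, 3] s, got {duration}")
    if p.envelope_cutoff_hz >= rate / 2:
        raise ValueError("envelope cutoff must be below the Nyquist frequency")
    if p.preset not in ("harmonic", "broadband"):
        raise ValueError(f"unknown preset {p.preset!r}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))

    if p.preset == "harmonic":
        # exemplar pitch around the class centre, then a smooth random walk
        f0_base = p.f0_mean * 2.0 ** rng.normal(0.0, p.f0_spread)
        f0_traj = f0_base * 2.0 ** _slow_process(
            n, rate, p.envelope_cutoff_hz, rng, depth=p.f0_excursion)
        phase0 = np.cumsum(2.0 * np.pi * f0_traj / rate)
        wave = np.zeros(n)
        for h in range(1, p.n_harmonics + 1):
            if h * np.max(f0_traj) >= rate / 2:
                break
            env = np.exp(_slow_process(n, rate, p.envelope_cutoff_hz, rng,
                                       depth=p.envelope_depth)) / h
            wave += env * np.sin(h * phase0 + rng.uniform(0, 2 * np.pi))
    else:
        carrier = rng.standard_normal(n)
        env = np.exp(_slow_process(n, rate, p.envelope_cutoff_hz, rng,
                                   depth=p.envelope_depth))
        wave = carrier * env

    # gentle onset/offset ramp (5 ms) to avoid edge clicks
    ramp = min(int(0.005 * rate), n // 4)
    if ramp > 0:
        w = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        wave[:ramp] *= w
        wave[-ramp:] *= w[::-1]
    rms = np.sqrt(np.mean(wave**2))
    if rms > 0:
        wave /= rms
    return AudioStimulus(wave, rate, "vocalization", exemplar_id, seed)


def make_white_noise(duration: float = 0.5, power_dbw: float = -20.0,
                     rate: float = DEFAULT_RATE, seed: int = 0,
                     exemplar_id: int = 0) -> AudioStimulus:
    """I.i.d. Gaussian noise with variance ``10**(power_dbw/10)``."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(10.0 ** (power_dbw / 10.0))
    n = int(round(duration * rate))
    return AudioStimulus(sigma * rng.standard_normal(n), rate, "white_noise",
                         exemplar_id, seed)


def make_applause_like(duration: float = 0.5, click_rate: float = 100.0,
                       rate: float = DEFAULT_RATE, seed: int = 0,
                       click_duration: float = 0.004,
                       exemplar_id: int = 0) -> AudioStimulus:
    """Poisson train of short broadband transients (clap texture).

    Each transient is a noise burst with an exponential decay, so every event
    excites all frequency channels coherently: correlation structure is
    stable over time even though the waveform itself is discontinuous.
    """
    if click_rate < 0:
        raise ValueError("click_rate must be nonnegative")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    wave = np.zeros(n)
    n_clicks = rng.poisson(click_rate * duration)
    n_click_samp = max(int(round(click_duration * rate)), 1)
    decay = np.exp(-np.arange(n_click_samp) / (0.3 * n_click_samp))
    for _ in range(n_clicks):
        start = rng.integers(0, max(n - n_click_samp, 1))
        burst = rng.standard_normal(n_click_samp) * decay
        wave[start:start + n_click_samp] += burst * rng.uniform(0.5, 1.0)
    rms = np.sqrt(np.mean(wave**2))
    if rms > 0:
        wave /= rms
    return AudioStimulus(wave, rate, "applause_like", exemplar_id, seed)


def amplitude_regularize(x: AudioStimulus, window: float = 0.05) -> AudioStimulus:
    """Flatten slow amplitude troughs by dividing out the smoothed envelope.

    The analytic-signal magnitude is smoothed with a moving average of
    ``window`` seconds, the waveform divided by it, and the result rescaled
    to the input RMS. The envelope's trough-to-median ratio (5th percentile /
    median) can only increase or stay put.
    """
    if not np.any(x.samples):
        raise ValueError("cannot amplitude-regularize an all-zero waveform")
    env = np.abs(signal.hilbert(x.samples))
    w = max(int(round(window * x.rate)), 1)
    # coverage-normalized moving average (no edge droop from zero padding)
    env = np.convolve(env, np.ones(w), mode="same") / \
        np.convolve(np.ones_like(env), np.ones(w), mode="same")
    env = np.maximum(env, 1e-3 * np.max(env))  # guard silent stretches
    out = x.samples / env
    out *= x.rms / np.sqrt(np.mean(out**2))
    return replace(x, samples=out, parts={})


def make_clutter(pool: list[AudioStimulus], n_components: int = 20,
                 duration: float = 3.0, seed: int = 0,
                 regularize: bool = True) -> AudioStimulus:
    """Superpose randomly chosen, randomly placed events into one token.

    Components are drawn from ``pool`` with replacement at unit gain; start
    positions are uniform subject to the whole event fitting inside the
    token. The mixture is then amplitude-regularized.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if not pool:
        raise ValueError("pool must be non-empty")
    rate = pool[0].rate
    n = int(round(duration * rate))
    for s in pool:
        if s.rate != rate:
            raise ValueError("all pool elements must share one sample rate")
        if len(s.samples) > n:
            raise ValueError(
                f"pool element of {s.duration:.3f} s exceeds token duration "
                f"{duration} s")
    rng = np.random.default_rng(seed)
    wave = np.zeros(n)
    chosen = rng.integers(0, len(pool), size=n_components)
    ids = []
    for idx in chosen:
        comp = pool[idx]
        start = int(rng.integers(0, n - len(comp.samples) + 1))
        wave[start:start + len(comp.samples)] += comp.samples
        ids.append(int(comp.exemplar_id))
    out = AudioStimulus(wave, rate, "clutter", seed=seed,
                        parts={"component_ids": ids})
    if regularize:
        reg = amplitude_regularize(out)
        reg.parts["component_ids"] = ids
        return reg
    return out


def embed_at_snr(sig: AudioStimulus, clutter: AudioStimulus,
                 spec: MixSpec) -> AudioStimulus:
    """Add ``sig`` into ``clutter`` scaled so the log power ratio equals ``spec.snr``.

    The background gain g solves
    ``log_base(mean(sig**2) / mean((g*clutter)**2)) = snr``,
    with powers averaged over each waveform's own support. The signal starts
    at ``spec.placement`` seconds (random if None, seeded by
    ``spec.clutter_seed``) and must fit entirely inside the token.
    """
    if sig.rate != clutter.rate:
        raise ValueError("signal and clutter sample rates differ")
    p_sig = np.mean(sig.samples**2)
    p_clut = np.mean(clutter.samples**2)
    if p_sig == 0 or p_clut == 0:
        raise ValueError("signal and clutter must both be non-silent")
    if len(sig.samples) > len(clutter.samples):
        raise ValueError("clutter token shorter than the embedded signal")
    gain = math.sqrt(p_sig / (spec.snr_log_base ** spec.snr * p_clut))
    if spec.placement is None:
        rng = np.random.default_rng(spec.clutter_seed)
        start = int(rng.integers(0, len(clutter.samples) - len(sig.samples) + 1))
    else:
        start = int(round(spec.placement * sig.rate))
        if start < 0 or start + len(sig.samples) > len(clutter.samples):
            raise ValueError("placement leaves the signal outside the token")
    scaled = gain * clutter.samples
    mix = scaled.copy()
    mix[start:start + len(sig.samples)] += sig.samples
    return AudioStimulus(
        mix, sig.rate, "mixture", sig.exemplar_id, spec.clutter_seed,
        parts={"signal": sig.samples.copy(), "scaled_clutter": scaled,
               "start": start})


def make_pair_stimulus(a: AudioStimulus, b: AudioStimulus, seed: int = 0
                       ) -> tuple[AudioStimulus, np.ndarray]:
    """Concatenate two stimuli in random order with a silent gap between.

    The gap is uniform in 5–50 % of the duration of whichever stimulus is
    presented first; each stimulus appears exactly once. Returns the
    waveform and a per-sample label array over {"A", "B", "gap"} where "A"
    always marks samples of ``a`` regardless of presentation order.
    """
    if a.rate != b.rate:
        raise ValueError("pair members must share a sample rate")
    rng = np.random.default_rng(seed)
    a_first = bool(rng.integers(0, 2))
    first, second = (a, b) if a_first else (b, a)
    gap_frac = rng.uniform(0.05, 0.50)
    n_gap = int(round(gap_frac * first.duration * a.rate))
    wave = np.concatenate([first.samples, np.zeros(n_gap), second.samples])
    lab_first = np.full(len(first.samples), "A" if a_first else "B")
    lab_second = np.full(len(second.samples), "B" if a_first else "A")
    labels = np.concatenate([lab_first, np.full(n_gap, "gap"), lab_second])
    stim = AudioStimulus(wave, a.rate, "pair", seed=seed,
                         parts={"order": "ab" if a_first else "ba",
                                "gap_samples": n_gap})
    return stim, labels
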