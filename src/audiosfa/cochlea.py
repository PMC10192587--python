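"""Simplified cochlear front-end: gammatone filterbank + temporal kernel + z-score.

The model maps a waveform to a T x N matrix of channel responses x(t):
42 fourth-order gammatone spectral filters with ERB-rate-spaced centre
frequencies (22.9 Hz to 20 208 Hz at the default 50 kHz rate, covering the
hearing range of the rhesus macaque), each followed by one temporal filter
built as the difference of two gamma-shaped kernels

    g(n) = a * n**m * exp(-b * n),      n in samples,

with g1: a=1.5, b=0.04, m=2 and g2: a=1.0, b=0.036, m=2. Each channel is
finally normalized to zero mean and unit variance over the presentation, so
the representation is invariant to global amplitude rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "TemporalKernel",
    "temporal_kernel_for_rate",
    "GammatoneBank",
    "Cochleagram",
    "erb_rate",
    "inverse_erb_rate",
    "build_gammatone_bank",
    "temporal_kernel_difference",
    "default_temporal_kernel",
    "apply_cochlear_model",
]

N_CHANNELS = 42
F_LO = 22.9
F_HI = 20208.0


@dataclass(frozen=True)
class TemporalKernel:
    """Parameters of one gamma-shaped kernel ``g(n) = a n^m exp(-b n)``."""

    a: float = 1.0
    b: float = 0.04
    m: float = 2.0
    length: int = 1000

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("decay b must be positive")
        if self.m < 0:
            raise ValueError("exponent m must be nonnegative")

    def evaluate(self, n: np.ndarray | None = None) -> np.ndarray:
        if n is None:
            n = np.arange(self.length, dtype=np.float64)
        n = np.asarray(n, dtype=np.float64)
        return self.a * n**self.m * np.exp(-self.b * n)


G1 = TemporalKernel(a=1.5, b=0.04, m=2.0)
G2 = TemporalKernel(a=1.0, b=0.036, m=2.0)


@dataclass
class GammatoneBank:
    """Specification of an ERB-spaced 4th-order gammatone filterbank."""

    center_freqs: np.ndarray
    rate: float
    order: int = 4
    # per-channel second-order-section cascades, shape (order, 6)
    coeffs: list = field(default_factory=list, repr=False)

    def filter(self, x: np.ndarray, channel: int) -> np.ndarray:
        return signal.sosfilt(self.coeffs[channel], x)


@dataclass
class Cochleagram:
    """T x N matrix of cochlear-channel responses.

    When ``normalized`` each column has mean 0 and variance 1 over time.
    """

    values: np.ndarray
    rate: float
    center_freqs: np.ndarray
    normalized: bool = True

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def erb_rate(f: np.ndarray | float) -> np.ndarray | float:
    """Frequency (Hz) -> ERB-rate scale (Glasberg & Moore)."""
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f, dtype=np.float64))


def inverse_erb_rate(e: np.ndarray | float) -> np.ndarray | float:
    return (10.0 ** (np.asarray(e, dtype=np.float64) / 21.4) - 1.0) / 0.00437


def erb_bandwidth(f: float) -> float:
    """Equivalent rectangular bandwidth at centre frequency ``f`` (Hz)."""
    return 24.7 * (1.0 + 4.37 * f / 1000.0)


def _gammatone_sos(fc: float, rate: float, order: int = 4) -> np.ndarray:
    """4th-order digital gammatone as a cascade of identical two-pole
    resonators (pole-mapping design), normalized to unit gain at ``fc``.

    Pole radius exp(-2 pi 1.019 ERB(fc) / rate) keeps every section stable
    even for centre frequencies far below the sample rate, where a single
    8th-order transfer function loses precision.
    """
    theta = 2.0 * np.pi * fc / rate
    r = np.exp(-2.0 * np.pi * 1.019 * erb_bandwidth(fc) / rate)
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    sos = np.tile(np.concatenate([[1.0, 0.0, 0.0], a]), (order, 1))
    # normalize the cascade's gain at the centre frequency
    _, h = signal.sosfreqz(sos, worN=np.array([theta]))
    sos[0, :3] /= np.abs(h[0])
    return sos


def build_gammatone_bank(n_filters: int = N_CHANNELS, f_lo: float = F_LO,
                         f_hi: float = F_HI, rate: float = 50_000.0
                         ) -> GammatoneBank:
    """ERB-rate-spaced 4th-order gammatone filters from f_lo to f_hi inclusive."""
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi >= rate / 2:
        raise ValueError(
            f"f_hi={f_hi} Hz is at or above the Nyquist frequency {rate / 2} Hz")
    if n_filters == 1:
        centers = np.array([f_lo])
    else:
        e = np.linspace(erb_rate(f_lo), erb_rate(f_hi), n_filters)
        centers = np.asarray(inverse_erb_rate(e))
        centers[0], centers[-1] = f_lo, f_hi  # pin endpoints exactly
    coeffs = [_gammatone_sos(fc, rate) for fc in centers]
    return GammatoneBank(center_freqs=centers, rate=rate, coeffs=coeffs)


def temporal_kernel_difference(params_g1: TemporalKernel = G1,
                               params_g2: TemporalKernel = G2,
                               rel_tol: float = 1e-6) -> np.ndarray:
    """Element-wise ``g1(n) - g2(n)``, truncated where it falls below
    ``rel_tol`` of its peak magnitude.

    Both kernels are evaluated on a common sample grid; a length mismatch in
    explicitly supplied grids is an error.
    """
    if params_g1.length != params_g2.length:
        raise ValueError("kernel lengths must match")
    n = np.arange(max(params_g1.length, 512), dtype=np.float64)
    diff = params_g1.evaluate(n) - params_g2.evaluate(n)
    peak = np.max(np.abs(diff))
    if peak == 0:
        return diff[:1]
    keep = np.nonzero(np.abs(diff) >= rel_tol * peak)[0]
    return diff[: keep[-1] + 1]


REFERENCE_RATE = 50_000.0


def default_temporal_kernel() -> np.ndarray:
    """The g1 - g2 difference kernel on its native 50 kHz sample grid."""
    return temporal_kernel_difference(G1, G2)


def temporal_kernel_for_rate(rate: float, rel_tol: float = 1e-6) -> np.ndarray:
    """The difference kernel resampled to ``rate``, preserving its physical
    time course (the kernel parameters are defined per sample at 50 kHz;
    the filter models the ear, so its ~10 ms shape must not stretch with
    the analysis rate)."""
    scale = REFERENCE_RATE / rate
    n = np.arange(0, int(np.ceil(1200 / scale)) + 1, dtype=np.float64)
    d = G1.evaluate(n * scale) - G2.evaluate(n * scale)
    peak = np.max(np.abs(d))
    keep = np.nonzero(np.abs(d) >= rel_tol * peak)[0]
    return d[: keep[-1] + 1]


def apply_cochlear_model(x, bank: GammatoneBank | None = None,
                         kernel: np.ndarray | None = None,
                         downsample: int = 1) -> Cochleagram:
    """Waveform -> normalized cochleagram.

    Per channel: gammatone filter, envelope extraction (magnitude of the
    analytic signal), convolution (mode "same") with the temporal kernel,
    optional polyphase decimation by ``downsample``, then
    z-scoring over time with the population variance. A channel with zero
    variance (e.g. silence) is an error.

    ``x`` is an AudioStimulus or a (samples, rate) pair.
    """
    if hasattr(x, "samples"):
        samples, rate = x.samples, x.rate
    else:
        samples, rate = np.asarray(x[0], dtype=np.float64), float(x[1])
    if not np.all(np.isfinite(samples)):
        raise ValueError("waveform must be finite")
    if bank is None:
        bank = build_gammatone_bank(rate=rate)
    if bank.rate != rate:
        raise ValueError("filterbank sample rate does not match the stimulus")
    if kernel is None:
        kernel = temporal_kernel_for_rate(rate)
    if len(samples) <= len(kernel):
        raise ValueError("waveform shorter than the temporal kernel")

    cols = []
    for sos in bank.coeffs:
        y = signal.sosfilt(sos, samples)
        # band envelope (analytic-signal magnitude): the channel response is
        # the slowly varying energy in the band, not the carrier itself
        y = np.abs(signal.hilbert(y))
        y = signal.fftconvolve(y, kernel, mode="same")
        if downsample > 1:
            y = signal.resample_poly(y, 1, downsample)
        cols.append(y)
    out = np.column_stack(cols)
    mu = out.mean(axis=0)
    sd = out.std(axis=0)  # population denominator
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(
            f"channel(s) {bad.tolist()} have zero variance; cannot normalize")
    out = (out - mu) / sd
    return Cochleagram(out, rate / downsample, bank.center_freqs.copy(),
                       normalized=True)
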