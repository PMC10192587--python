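"""Temporal-regularity metrics: modulation spectra and kurtosis scores.

Two complementary continuity measures are computed for any sound:

* the **component** modulation spectrum — the 2-D Fourier power of the
  log-amplitude spectrogram over (spectral modulation, temporal modulation);
  its marginal over temporal modulation says how much of the signal's
  spectral pattern changes slowly versus quickly;
* the **correlation** modulation spectrum — the same construction applied to
  the time-varying vector of sliding-window Pearson correlations between all
  channel pairs; it says how slowly the *co-variation structure* changes.

Each marginal is normalized to sum 1 over the temporal-modulation axis
(clipped to +/-80 Hz) and treated as an empirical probability density over
modulation frequency. Its (non-excess, MATLAB-convention) kurtosis measures
concentration at low modulations; dividing by the kurtosis of white noise
gives the dimensionless "kurtosis score" (>1 means more concentrated than
noise; for reference the Laplace/Gaussian kurtosis ratio is 6/3 = 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

logging.getLogger(__name__).addHandler(logging.NullHandler())
log = logging.getLogger(__name__)

__all__ = [
    "Spectrogram",
    "ModulationSpectrum",
    "CorrelationTimeSeries",
    "KurtosisResult",
    "spectrogram",
    "modulation_spectrum",
    "correlation_time_series",
    "correlation_modulation_spectrum",
    "kurtosis",
    "kurtosis_score",
    "average_marginal",
]

MOD_CLIP_HZ = 80.0


@dataclass
class Spectrogram:
    power: np.ndarray  # time x frequency
    times: np.ndarray
    freqs: np.ndarray
    frame_rate: float


@dataclass
class ModulationSpectrum:
    """2-D modulation power plus its temporal-modulation marginal.

    ``power`` is indexed (spectral modulation, temporal modulation);
    ``marginal`` is average power per temporal modulation on
    ``marginal_axis`` (|f| <= 80 Hz, symmetric about 0), normalized to sum 1.
    """

    power: np.ndarray
    spectral_axis: np.ndarray
    temporal_axis: np.ndarray
    marginal: np.ndarray
    marginal_axis: np.ndarray


@dataclass
class CorrelationTimeSeries:
    """Upper-triangular windowed channel-correlation vectors over time."""

    values: np.ndarray  # frames x n_pairs, entries in [-1, 1]
    window: float
    hop: float
    frame_rate: float


@dataclass
class KurtosisResult:
    k1: float
    k0: float | None
    n: int
    weighted: bool


def spectrogram(x, window: float = 0.025, hop: float = 0.005) -> Spectrogram:
    """Short-time power spectrogram (Hann window)."""
    if hasattr(x, "samples"):
        samples, rate = x.samples, x.rate
    else:
        samples, rate = np.asarray(x[0], dtype=np.float64), float(x[1])
    if not window > hop > 0:
        raise ValueError("need window > hop > 0")
    nperseg = int(round(window * rate))
    nhop = int(round(hop * rate))
    if nperseg > len(samples):
        raise ValueError("window longer than the signal")
    freqs, times, S = sps.spectrogram(samples, fs=rate, window="hann",
                                      nperseg=nperseg,
                                      noverlap=nperseg - nhop,
                                      mode="psd")
    return Spectrogram(S.T.copy(), times, freqs, frame_rate=rate / nhop)


def _marginal_from_power(power: np.ndarray, temporal_axis: np.ndarray,
                         clip_hz: float) -> tuple[np.ndarray, np.ndarray]:
    keep = np.abs(temporal_axis) <= clip_hz + 1e-12
    # enforce a symmetric axis (drops an unpaired Nyquist bin if present)
    keep &= np.isin(-np.round(temporal_axis, 9), np.round(temporal_axis[keep], 9))
    axis = temporal_axis[keep]
    marg = power[:, keep].mean(axis=0)
    total = marg.sum()
    if total <= 0:
        raise ValueError("modulation power is identically zero")
    return marg / total, axis


def modulation_spectrum(S: Spectrogram, log_amplitude: bool = True,
                        log_floor: float = 1e-6,
                        clip_hz: float = MOD_CLIP_HZ) -> ModulationSpectrum:
    """2-D Fourier power of the (log-amplitude) spectrogram.

    The spectrogram is floored at ``log_floor`` of its peak, log-compressed,
    and mean-subtracted before the 2-D FFT, following the standard
    modulation-power-spectrum procedure. The temporal-modulation marginal is
    the mean power across spectral modulations, clipped to ``+/-clip_hz``
    and normalized to sum 1.
    """
    P = S.power
    if P.shape[0] < 8:
        raise ValueError("need at least 8 time frames")
    if not np.all(np.isfinite(P)):
        raise ValueError("spectrogram must be finite")
    peak = P.max()
    if peak <= 0:
        # all-silent input: represent as uniform (zero-information) spectrum
        L = np.zeros_like(P)
    elif log_amplitude:
        L = np.log10(np.maximum(P, log_floor * peak))
    else:
        L = P
    L = L - L.mean()
    F = np.fft.fftshift(np.fft.fft2(L.T))  # rows: audio freq -> spectral mod
    power = np.abs(F) ** 2
    n_f, n_t = L.shape[1], L.shape[0]
    df = S.freqs[1] - S.freqs[0] if len(S.freqs) > 1 else 1.0
    spectral_axis = np.fft.fftshift(np.fft.fftfreq(n_f, d=df)) * 1000.0  # cyc/kHz
    temporal_axis = np.fft.fftshift(np.fft.fftfreq(n_t, d=1.0 / S.frame_rate))
    if peak <= 0:
        marg_keep = np.abs(temporal_axis) <= clip_hz
        axis = temporal_axis[marg_keep]
        marginal = np.zeros(axis.size)
    else:
        marginal, axis = _marginal_from_power(power, temporal_axis, clip_hz)
    return ModulationSpectrum(power, spectral_axis, temporal_axis, marginal, axis)


def correlation_time_series(C, window: float = 0.05, hop: float = 0.05
                            ) -> CorrelationTimeSeries:
    """Sliding-window Pearson correlations between all channel pairs.

    ``C`` is a Cochleagram, a Spectrogram, or a (T x N array, frame rate)
    pair. A zero-variance channel inside a window sets that channel's pair
    entries to 0 (with a logged warning) rather than NaN.
    """
    if hasattr(C, "values"):
        X, rate = C.values, C.rate
    elif hasattr(C, "power"):
        X, rate = C.power, C.frame_rate
    else:
        X, rate = np.asarray(C[0], dtype=np.float64), float(C[1])
    T, N = X.shape
    w = max(int(round(window * rate)), 4)
    h = max(int(round(hop * rate)), 1)
    if T < w:
        raise ValueError("signal shorter than one correlation window")
    iu = np.triu_indices(N, k=1)
    starts = range(0, T - w + 1, h)
    rows = np.empty((len(list(starts)), len(iu[0])))
    warned = False
    for i, s in enumerate(range(0, T - w + 1, h)):
        seg = X[s:s + w]
        mu = seg.mean(axis=0)
        Z = seg - mu
        sd = np.sqrt((Z**2).mean(axis=0))
        dead = sd == 0
        if np.any(dead):
            if not warned:
                log.warning("zero-variance channel(s) in a correlation window; "
                            "their pair entries set to 0")
                warned = True
            sd = np.where(dead, 1.0, sd)
        R = (Z / sd).T @ (Z / sd) / w
        if np.any(dead):
            R[dead, :] = 0.0
            R[:, dead] = 0.0
        rows[i] = np.clip(R[iu], -1.0, 1.0)
    return CorrelationTimeSeries(rows, window, hop, frame_rate=rate / h)


def correlation_modulation_spectrum(C, window: float = 0.05, hop: float = 0.05,
                                    clip_hz: float = MOD_CLIP_HZ
                                    ) -> ModulationSpectrum:
    """Modulation spectrum of the pairwise-correlation trajectory.

    The frames x pairs correlation matrix is mean-subtracted and 2-D Fourier
    transformed exactly like a spectrogram; averaging the power over the
    pair-index modulation axis yields the temporal-modulation marginal
    (equivalent, by Parseval, to averaging per-pair 1-D spectra).
    """
    cts = correlation_time_series(C, window=window, hop=hop)
    V = cts.values
    if V.shape[0] < 8:
        raise ValueError("need at least 8 correlation frames")
    # no mean subtraction: a constant correlation level is the extreme of
    # correlation continuity and belongs in the 0 Hz modulation bin
    L = V
    F = np.fft.fftshift(np.fft.fft2(L.T))
    power = np.abs(F) ** 2
    n_pairs, n_t = L.shape[1], L.shape[0]
    spectral_axis = np.fft.fftshift(np.fft.fftfreq(n_pairs, d=1.0))
    temporal_axis = np.fft.fftshift(np.fft.fftfreq(n_t, d=1.0 / cts.frame_rate))
    marginal, axis = _marginal_from_power(power, temporal_axis, clip_hz)
    return ModulationSpectrum(power, spectral_axis, temporal_axis, marginal, axis)


def kurtosis(data, weights=None, bias_correct: bool = False) -> KurtosisResult:
    """Non-excess kurtosis ``k1 = m4 / m2**2`` with optional weights and
    small-sample bias correction.

    With ``weights`` (a probability vector over ``data``), moments are taken
    about the weighted mean. A Gaussian gives 3, a Laplace 6. The corrected
    value is ``k0 = (n-1)/((n-2)(n-3)) * ((n+1) k1 - 3(n-1)) + 3``.
    """
    x = np.asarray(data, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 data points")
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != x.shape:
            raise ValueError("weights must match data in shape")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ValueError("weights must be nonnegative and sum to 1")
        mu = np.sum(w * x)
        m2 = np.sum(w * (x - mu) ** 2)
        m4 = np.sum(w * (x - mu) ** 4)
    else:
        mu = x.mean()
        m2 = np.mean((x - mu) ** 2)
        m4 = np.mean((x - mu) ** 4)
    if m2 == 0:
        raise ValueError("zero variance: kurtosis undefined")
    k1 = float(m4 / m2**2)
    k0 = None
    if bias_correct:
        if n < 4:
            raise ValueError("bias correction requires n >= 4")
        k0 = float((n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * k1 - 3 * (n - 1)) + 3)
    return KurtosisResult(k1=k1, k0=k0, n=n, weighted=weights is not None)


def _marginal_kurtosis(ms: ModulationSpectrum, weighted: bool = True) -> float:
    """Kurtosis of a modulation-frequency marginal.

    Default: weighted kurtosis of the modulation-frequency values with the
    marginal as probability. ``weighted=False`` instead treats the raw
    marginal power vector as the sample (sensitivity-analysis variant).
    """
    if weighted:
        return kurtosis(ms.marginal_axis, weights=ms.marginal).k1
    return kurtosis(ms.marginal).k1


def kurtosis_score(target: ModulationSpectrum, reference: ModulationSpectrum,
                   weighted: bool = True) -> float:
    """Kurtosis ratio of a target marginal over a reference (white noise).

    Both marginals must live on the same temporal-modulation grid.
    """
    if target.marginal_axis.shape != reference.marginal_axis.shape or \
            not np.allclose(target.marginal_axis, reference.marginal_axis):
        raise ValueError("marginals are on different modulation grids")
    k_ref = _marginal_kurtosis(reference, weighted)
    if k_ref == 0:
        raise ValueError("reference kurtosis is zero")
    return _marginal_kurtosis(target, weighted) / k_ref


def average_marginal(spectra: list[ModulationSpectrum]) -> ModulationSpectrum:
    """Average the marginals of several spectra (e.g. a stimulus category)."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    axis = spectra[0].marginal_axis
    for ms in spectra[1:]:
        if not np.allclose(ms.marginal_axis, axis):
            raise ValueError("marginals are on different modulation grids")
    marg = np.mean([ms.marginal for ms in spectra], axis=0)
    marg = marg / marg.sum()
    first = spectra[0]
    return ModulationSpectrum(first.power, first.spectral_axis,
                              first.temporal_axis, marg, axis)
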