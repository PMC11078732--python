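"""Frequency decomposition: band-pass + Hilbert and the 40-wavelet Morlet bank.

Phase convention throughout: radians in (-pi, pi], 0 at the oscillation peak
(cosine convention).  Epochs carry 0.5 s of padding on each side; analytic
signals are computed on the padded epoch and then trimmed to the [0, 2.5) s
maintenance window so filter edge artifacts never enter an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig

from .io_core import MAINTENANCE_WINDOW, LFPEpochs, maintenance_slice
from .preprocess import bandpass


def hilbert_phase_amp(epochs: LFPEpochs, band: tuple[float, float], *,
                      trim: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial band-pass + Hilbert phase and amplitude.

    Returns (phase, amplitude), each trials x time, trimmed to [0, 2.5) s
    relative to maintenance onset when ``trim`` is set.
    """
    filtered = bandpass(epochs.samples, epochs.fs, band, axis=1)
    analytic = sig.hilbert(filtered, axis=1)
    phase = np.angle(analytic)
    amp = np.abs(analytic)
    if trim:
        sl = maintenance_slice(epochs.window, epochs.fs)
        phase, amp = phase[:, sl], amp[:, sl]
    return phase, amp


# ---------------------------------------------------------------------------
# Morlet wavelet bank
# ---------------------------------------------------------------------------

@dataclass
class WaveletBank:
    """40 complex Morlet wavelets, 2-150 Hz log-spaced, 3-10 cycles log-spaced.

    Each kernel is normalized to unit energy so amplitudes are comparable
    across frequencies before any z-scoring.
    """

    fs: float
    freqs: np.ndarray
    n_cycles: np.ndarray
    kernels: list[np.ndarray]

    @classmethod
    def default(cls, fs: float, n_freqs: int = 40,
                fmin: float = 2.0, fmax: float = 150.0,
                cmin: float = 3.0, cmax: float = 10.0) -> "WaveletBank":
        freqs = np.logspace(np.log10(fmin), np.log10(fmax), n_freqs)
        cycles = np.logspace(np.log10(cmin), np.log10(cmax), n_freqs)
        kernels = [morlet_kernel(fs, f, c) for f, c in zip(freqs, cycles)]
        return cls(fs=fs, freqs=freqs, n_cycles=cycles, kernels=kernels)

    @classmethod
    def fixed_cycles(cls, fs: float, freqs: np.ndarray,
                     n_cycles: float) -> "WaveletBank":
        """Bank at explicit frequencies with a constant cycle count
        (the 70-140 Hz, 7-cycle gamma bank used for spike-count designs)."""
        freqs = np.asarray(freqs, dtype=float)
        cycles = np.full(freqs.shape, float(n_cycles))
        kernels = [morlet_kernel(fs, f, c) for f, c in zip(freqs, cycles)]
        return cls(fs=fs, freqs=freqs, n_cycles=cycles, kernels=kernels)


def morlet_kernel(fs: float, freq: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet kernel with unit energy (sum |w|^2 = 1)."""
    sigma_t = n_cycles / (2 * np.pi * freq)
    half = int(np.ceil(5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    kernel -= kernel.mean()  # zero-mean so DC does not leak in
    kernel /= np.sqrt(np.sum(np.abs(kernel) ** 2))
    return kernel


def _convolve_reflect(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-length complex convolution with reflection padding at the edges."""
    half = (len(kernel) - 1) // 2
    pad = min(half, x.shape[-1] - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    out = sig.fftconvolve(xp, kernel[None, :] if x.ndim == 2 else kernel,
                          mode="same", axes=-1)
    return out[..., pad: pad + x.shape[-1]]


def wavelet_transform(epochs: LFPEpochs, bank: WaveletBank, *,
                      trim: bool = True) -> np.ndarray:
    """Complex coefficients, trials x freqs x time.

    Phase = argument of the coefficient, amplitude = modulus.  Trimming drops
    the padded epoch edges, keeping the [0, 2.5) s maintenance window.
    """
    x = np.asarray(epochs.samples, dtype=float)
    n_trials, n_time = x.shape
    sl = maintenance_slice(epochs.window, epochs.fs) if trim else slice(None)
    n_out = len(range(*sl.indices(n_time)))
    out = np.empty((n_trials, len(bank.freqs), n_out), dtype=complex)
    for k, kernel in enumerate(bank.kernels):
        out[:, k, :] = _convolve_reflect(x, kernel)[:, sl]
    return out


def zscored_mean_amplitude(coeffs: np.ndarray) -> np.ndarray:
    """Per-frequency z-score of wavelet amplitude across all trials and
    samples, then average across frequencies -> trials x time.

    This is the standard guard against the 1/f power law dominating a
    broadband amplitude estimate.
    """
    amp = np.abs(coeffs)  # trials x freqs x time
    mu = amp.mean(axis=(0, 2), keepdims=True)
    sd = amp.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return ((amp - mu) / sd).mean(axis=1)


def reconstruction_r2(epochs: LFPEpochs, bank: WaveletBank,
                      win: float = 0.5, step: float = 0.025) -> np.ndarray:
    """Reconstruction quality control for the wavelet bank.

    The signal is reconstructed as the sum over frequencies of the real part
    of each wavelet-filtered signal.  Per frequency band, both the original
    and the reconstruction are band-limited to the wavelet's bandwidth and
    regressed against each other in sliding windows (500 ms, 25 ms step);
    the returned grid is freqs x windows of R^2 values, averaged over trials.
    Zero-variance windows yield NaN.
    """
    fs = epochs.fs
    x = np.asarray(epochs.samples, dtype=float)
    coeffs = wavelet_transform(epochs, bank, trim=False)
    recon = coeffs.real.sum(axis=1)  # trials x time

    n_time = x.shape[1]
    w = int(round(win * fs))
    s = int(round(step * fs))
    starts = np.arange(0, n_time - w + 1, s)
    out = np.full((len(bank.freqs), len(starts)), np.nan)

    for k, (f, c) in enumerate(zip(bank.freqs, bank.n_cycles)):
        # wavelet spectral FWHM-ish bandwidth: f / cycles on each side
        bw = f / c
        lo, hi = max(f - bw, 0.5), min(f + bw, fs / 2 * 0.95)
        xb = bandpass(x, fs, (lo, hi), axis=1)
        rb = bandpass(recon, fs, (lo, hi), axis=1)
        for j, a in enumerate(starts):
            xs = xb[:, a: a + w]
            rs = rb[:, a: a + w]
            r2s = []
            for t in range(x.shape[0]):
                vx, vr = xs[t].std(), rs[t].std()
                if vx == 0 or vr == 0:
                    continue
                r = np.corrcoef(xs[t], rs[t])[0, 1]
                r2s.append(r ** 2)
            if r2s:
                out[k, j] = float(np.mean(r2s))
    return out
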