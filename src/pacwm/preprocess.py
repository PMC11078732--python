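"""LFP cleaning: spike-transient removal, filtering/downsampling, artifact rejection.

The cleaning chain mirrors standard human microwire practice: action-potential
waveforms are interpolated out of the raw broadband signal, the trace is
zero-phase low-pass filtered at 175 Hz and resampled to 400 Hz, line noise at
60 and 120 Hz is removed with narrow zero-phase band-stops, and trials with
high-amplitude events or step artifacts are rejected by deterministic
z-score rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_core import FS_LFP, LFPEpochs


# ---------------------------------------------------------------------------
# filter design
# ---------------------------------------------------------------------------

def _fir_taps(fs: float, edge: float) -> tuple[int, float]:
    """Hamming-windowed-sinc tap count for a given band edge.

    Transition width = min(max(0.25 * edge, 2 Hz), edge); tap count from the
    Hamming approximation 3.3 / (width / fs), forced odd for a type-I filter.
    """
    width = min(max(edge * 0.25, 2.0), edge)
    n = int(np.ceil(3.3 / (width / fs)))
    if n % 2 == 0:
        n += 1
    return n, width


def design_lowpass(fs: float, cutoff: float) -> np.ndarray:
    n, _ = _fir_taps(fs, cutoff)
    return signal.firwin(n, cutoff, fs=fs, window="hamming")


def design_bandpass(fs: float, band: tuple[float, float]) -> np.ndarray:
    n, _ = _fir_taps(fs, band[0])
    return signal.firwin(n, band, fs=fs, pass_zero=False, window="hamming")


def design_bandstop(fs: float, band: tuple[float, float]) -> np.ndarray:
    # notches are 1 Hz wide: double the usual tap count so the stop band
    # actually reaches depth at the line frequency
    width = band[1] - band[0]
    n = int(np.ceil(6.6 / (width / fs)))
    if n % 2 == 0:
        n += 1
    return signal.firwin(n, band, fs=fs, pass_zero=True, window="hamming")


def filtfilt_fir(taps: np.ndarray, x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Forward-backward FIR filtering (zero phase lag)."""
    padlen = min(3 * len(taps), x.shape[axis] - 1)
    return signal.filtfilt(taps, [1.0], x, axis=axis, padlen=padlen)


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float],
             axis: int = -1) -> np.ndarray:
    """Zero-phase FIR band-pass, the workhorse for phase/amplitude extraction."""
    nyq = fs / 2
    if band[1] >= nyq:
        raise ValueError(f"band {band} exceeds Nyquist ({nyq} Hz)")
    return filtfilt_fir(design_bandpass(fs, band), x, axis=axis)


# ---------------------------------------------------------------------------
# spike transient removal
# ---------------------------------------------------------------------------

def remove_spike_transients(trace: np.ndarray, fs: float,
                            spike_times: np.ndarray,
                            window: tuple[float, float] = (-1e-3, 2e-3)) -> np.ndarray:
    """Interpolate out action-potential transients from a raw trace.

    Samples within [t - 1 ms, t + 2 ms] of each spike onset are replaced by the
    straight line joining the samples just outside the window; overlapping
    windows are merged, windows at the trace edge are clamped.  Spike times
    from *all* wires of the bundle should be supplied, since a spike can bleed
    into neighbouring wires.
    """
    trace = np.asarray(trace, dtype=float).copy()
    spike_times = np.sort(np.atleast_1d(np.asarray(spike_times, dtype=float)))
    if spike_times.size == 0:
        return trace
    starts = np.floor((spike_times + window[0]) * fs).astype(int)
    stops = np.ceil((spike_times + window[1]) * fs).astype(int)

    merged: list[list[int]] = []
    for a, b in zip(starts, stops):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    n = trace.size
    for a, b in merged:
        a = max(a, 0)
        b = min(b, n - 1)
        left = a - 1
        right = b + 1
        if left < 0 and right >= n:
            continue
        if left < 0:
            trace[: right] = trace[right]
            continue
        if right >= n:
            trace[left + 1:] = trace[left]
            continue
        span = right - left
        interp = trace[left] + (trace[right] - trace[left]) * \
            (np.arange(1, span) / span)
        trace[left + 1: right] = interp
    return trace


# ---------------------------------------------------------------------------
# filtering + downsampling
# ---------------------------------------------------------------------------

def filter_downsample(trace: np.ndarray, fs_in: float,
                      fs_out: float = FS_LFP) -> np.ndarray:
    """Low-pass at 175 Hz (zero phase), resample to 400 Hz, notch 60/120 Hz.

    Works for any integer-ratio-expressible input rate (32 kHz and 30 kHz
    sources alike) via polyphase resampling.
    """
    if fs_in < 2 * 175:
        raise ValueError("input rate too low for a 175 Hz low-pass")
    trace = np.asarray(trace, dtype=float)
    out = filtfilt_fir(design_lowpass(fs_in, 175.0), trace)

    from fractions import Fraction
    frac = Fraction(int(round(fs_out * 1000)), int(round(fs_in * 1000)))
    out = signal.resample_poly(out, frac.numerator, frac.denominator)

    for band in ((59.5, 60.5), (119.5, 120.5)):
        out = filtfilt_fir(design_bandstop(fs_out, band), out)
    return out


# ---------------------------------------------------------------------------
# artifact / jump rejection
# ---------------------------------------------------------------------------

@dataclass
class ArtifactReport:
    """Per-channel record of which rejection rules fired on which trials."""

    n_trials: int
    amplitude_rejected: np.ndarray
    jump_rejected: np.ndarray
    zero_variance: bool = False

    @property
    def valid(self) -> np.ndarray:
        return ~(self.amplitude_rejected | self.jump_rejected)

    def to_dict(self) -> dict:
        return {
            "n_trials": int(self.n_trials),
            "n_amplitude": int(self.amplitude_rejected.sum()),
            "n_jump": int(self.jump_rejected.sum()),
            "n_rejected": int((~self.valid).sum()),
            "zero_variance": bool(self.zero_variance),
        }


def detect_artifact_trials(epochs: LFPEpochs, amp_thresh: float = 4.0,
                           cap: float = 6.0, jump_thresh: float = 10.0,
                           jump_lag: int = 4) -> tuple[np.ndarray, ArtifactReport]:
    """Amplitude and jump rejection rules for one channel's epochs.

    Amplitude rule: z-score pooled over all samples of all trials, cap at
    ``cap`` SD, re-z-score the capped data, reject a trial if any
    \\|z\\| > ``amp_thresh``.  Jump rule: z-score the lag-``jump_lag`` sample
    differences of the capped signal, reject if any \\|z\\| > ``jump_thresh``.
    A zero-variance channel keeps all trials and flags the degeneracy.
    """
    x = np.asarray(epochs.samples, dtype=float)
    n_trials = x.shape[0]
    sd = x.std()
    if sd == 0:
        import warnings
        warnings.warn("zero-variance channel; all trials retained")
        report = ArtifactReport(n_trials, np.zeros(n_trials, bool),
                                np.zeros(n_trials, bool), zero_variance=True)
        return report.valid, report

    z = (x - x.mean()) / sd
    capped = np.clip(z, -cap, cap)
    z2 = (capped - capped.mean()) / capped.std()
    amp_rej = np.any(np.abs(z2) > amp_thresh, axis=1)

    d = capped[:, jump_lag:] - capped[:, :-jump_lag]
    dsd = d.std()
    if dsd == 0:
        jump_rej = np.zeros(n_trials, bool)
    else:
        dz = (d - d.mean()) / dsd
        jump_rej = np.any(np.abs(dz) > jump_thresh, axis=1)

    report = ArtifactReport(n_trials, amp_rej, jump_rej)
    return report.valid, report
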