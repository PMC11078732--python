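"""Phase-amplitude coupling: modulation index, surrogate normalization,
comodulograms, channel selection, load contrasts, single-trial PAC, theta
waveform asymmetry and nesting detection.

The modulation index (MI) quantifies how unevenly the mean high-frequency
amplitude is distributed over low-frequency phase bins: with ``N`` bins and
normalized bin profile ``p``, ``MI = (log N - H(p)) / log N`` where ``H`` is
the Shannon entropy.  MI is 0 for a flat profile and 1 when all amplitude
mass falls in one bin.  Raw MIs are z-scored against trial-shuffled
surrogates (phases of one trial paired with amplitudes of another), which
removes coupling explained by non-specific across-trial structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sig

from .io_core import LFPEpochs, make_rng
from .spectral import hilbert_phase_amp
from .stats import Z_CRIT_95, fdr_bh_adjusted, perm_ttest

THETA_BAND = (3.0, 7.0)
HIGH_GAMMA_BAND = (70.0, 140.0)
LOW_GAMMA_BAND = (30.0, 55.0)

#: comodulogram grid: phase centres 2-14 Hz step 2 (2 Hz fixed bandwidth),
#: amplitude centres 30-150 Hz step 5, amplitude bandwidth = 2x phase centre
PHASE_CENTRES = np.arange(2.0, 15.0, 2.0)
AMP_CENTRES = np.arange(30.0, 151.0, 5.0)

#: phase-grid centres that fall inside the 3-7 Hz theta band
THETA_PHASE_CENTRES = (4.0, 6.0)


def phase_bin_index(phase: np.ndarray, n_bins: int = 18) -> np.ndarray:
    """Map phases in (-pi, pi] onto bin indices 0..n_bins-1."""
    idx = np.floor((np.asarray(phase) + np.pi) / (2 * np.pi / n_bins)).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def modulation_index(phase: np.ndarray, amplitude: np.ndarray,
                     n_bins: int = 18) -> tuple[float, np.ndarray, float]:
    """MI of concatenated phase/amplitude streams.

    Returns (raw_MI, bin_profile, preferred_phase).  The bin profile is the
    normalized mean amplitude per phase bin; the preferred phase is the centre
    of the maximal bin.  An empty phase bin makes the mean amplitude
    undefined and raises, naming the offending bin.
    """
    phase = np.asarray(phase).ravel()
    amplitude = np.asarray(amplitude).ravel()
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    idx = phase_bin_index(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        empty = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"phase bin {empty} is empty; MI undefined")
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    means = sums / counts
    total = means.sum()
    if total <= 0:
        raise ValueError("non-positive amplitude profile; MI undefined")
    p = means / total
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.sum(np.where(p > 0, p * np.log(p), 0.0))
    mi = (np.log(n_bins) - h) / np.log(n_bins)
    centres = -np.pi + (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    return float(mi), p, float(centres[int(np.argmax(p))])


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of 0..n-1 with no fixed point."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def _mi_from_profile(sums: np.ndarray, counts: np.ndarray) -> float:
    means = sums / counts
    p = means / means.sum()
    h = -np.sum(np.where(p > 0, p * np.log(p), 0.0))
    return float((np.log(len(p)) - h) / np.log(len(p)))


@dataclass
class PACResult:
    """Surrogate-normalized PAC for one (phase band, amplitude band, condition)."""

    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    raw_mi: float
    surrogate_mu: float
    surrogate_sd: float
    z_mi: float
    condition: str
    n_trials_used: int
    preferred_phase: float


def surrogate_z(phase_trials: np.ndarray, amp_trials: np.ndarray,
                n_surr: int = 200, n_bins: int = 18,
                rng=None) -> tuple[float, float, float, float, float]:
    """Trial-shuffled surrogate normalization of the MI.

    Each surrogate pairs the phase stream of trial ``i`` with the amplitude
    stream of trial ``pi(i)`` for a random derangement ``pi`` (no trial may
    pair with itself), recomputes the concatenated MI, and a normal fit to
    the 200 surrogates yields the z-score.

    Returns (raw_mi, z_mi, mu, sd, preferred_phase).
    """
    rng = make_rng(rng)
    phase_trials = np.atleast_2d(phase_trials)
    amp_trials = np.atleast_2d(amp_trials)
    n_trials = phase_trials.shape[0]
    if n_trials < 10:
        raise ValueError("need at least 10 trials for surrogate normalization")

    idx = phase_bin_index(phase_trials, n_bins)  # trials x time
    # cross-trial bin sums: S[b][i, j] = sum of amp[j, t] where idx[i, t] == b
    counts = np.stack([np.bincount(row, minlength=n_bins) for row in idx])
    if np.any(counts.sum(axis=0) == 0):
        empty = int(np.flatnonzero(counts.sum(axis=0) == 0)[0])
        raise ValueError(f"phase bin {empty} is empty across all trials")
    S = np.empty((n_bins, n_trials, n_trials))
    for b in range(n_bins):
        S[b] = (idx == b).astype(float) @ amp_trials.T  # phase-trial x amp-trial

    diag = np.arange(n_trials)
    total_counts = counts.sum(axis=0)
    obs_sums = S[:, diag, diag].sum(axis=1)
    raw_mi = _mi_from_profile(obs_sums, total_counts)
    means = obs_sums / total_counts
    centres = -np.pi + (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    preferred = float(centres[int(np.argmax(means))])

    surr = np.empty(n_surr)
    for k in range(n_surr):
        perm = _derangement(n_trials, rng)
        sums = S[:, diag, perm].sum(axis=1)
        surr[k] = _mi_from_profile(sums, total_counts)
    mu = float(surr.mean())
    sd = float(surr.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate surrogate distribution (sd = 0)")
    return raw_mi, (raw_mi - mu) / sd, mu, sd, preferred


def pac_result(epochs: LFPEpochs, phase_band=THETA_BAND, amp_band=HIGH_GAMMA_BAND,
               trial_mask: np.ndarray | None = None, condition: str = "all",
               n_surr: int = 200, rng=None) -> PACResult:
    """Band-filter, Hilbert, trim, and surrogate-normalize one band pair."""
    phase, amp = hilbert_phase_amp(epochs, phase_band)
    _, gamma = hilbert_phase_amp(epochs, amp_band)
    mask = epochs.valid_trials.copy()
    if trial_mask is not None:
        mask &= np.asarray(trial_mask, bool)
    raw, z, mu, sd, pref = surrogate_z(phase[mask], gamma[mask],
                                       n_surr=n_surr, rng=rng)
    return PACResult(phase_band=phase_band, amp_band=amp_band, raw_mi=raw,
                     surrogate_mu=mu, surrogate_sd=sd, z_mi=z,
                     condition=condition, n_trials_used=int(mask.sum()),
                     preferred_phase=pref)


# ---------------------------------------------------------------------------
# comodulogram
# ---------------------------------------------------------------------------

@dataclass
class Comodulogram:
    """z-MI over the phase x amplitude frequency grid for one condition."""

    phase_centres: np.ndarray
    amp_centres: np.ndarray
    z_mi: np.ndarray     # phase x amp
    raw_mi: np.ndarray
    condition: str
    n_trials_used: int

    def mean_z(self, phase_centres, amp_range) -> float:
        """Average z over selected phase centres and an amplitude range."""
        pmask = np.isin(self.phase_centres, phase_centres)
        amask = (self.amp_centres >= amp_range[0]) & (self.amp_centres <= amp_range[1])
        return float(self.z_mi[np.ix_(pmask, amask)].mean())


def compute_comodulogram(epochs: LFPEpochs, trial_mask: np.ndarray | None = None,
                         condition: str = "all", n_surr: int = 200,
                         phase_centres: np.ndarray = PHASE_CENTRES,
                         amp_centres: np.ndarray = AMP_CENTRES,
                         rng=None) -> Comodulogram:
    """z-MI comodulogram over the full frequency grid.

    Phase bands are centre +/- 1 Hz (2 Hz fixed bandwidth); amplitude
    bandwidth equals twice the phase centre so the modulation side peaks are
    captured.
    """
    rng = make_rng(rng)
    mask = epochs.valid_trials.copy()
    if trial_mask is not None:
        mask &= np.asarray(trial_mask, bool)
    z = np.empty((len(phase_centres), len(amp_centres)))
    raw = np.empty_like(z)
    for i, pc in enumerate(phase_centres):
        phase, _ = hilbert_phase_amp(epochs, (pc - 1.0, pc + 1.0))
        phase = phase[mask]
        for j, ac in enumerate(amp_centres):
            lo, hi = ac - pc, ac + pc
            _, amp = hilbert_phase_amp(epochs, (lo, hi))
            r, zz, _, _, _ = surrogate_z(phase, amp[mask], n_surr=n_surr, rng=rng)
            raw[i, j], z[i, j] = r, zz
    return Comodulogram(phase_centres=np.asarray(phase_centres, float),
                        amp_centres=np.asarray(amp_centres, float),
                        z_mi=z, raw_mi=raw, condition=condition,
                        n_trials_used=int(mask.sum()))


def subsample_equal_loads(trials: pd.DataFrame, valid: np.ndarray,
                          rng=None) -> np.ndarray:
    """Equalize correct-trial counts across loads 1 and 3 (once per channel).

    Returns a boolean mask over trials; subsampling is uniform without
    replacement from the larger load.
    """
    rng = make_rng(rng)
    correct = trials["correct"].to_numpy(bool) & np.asarray(valid, bool)
    loads = trials["load"].to_numpy()
    idx1 = np.flatnonzero(correct & (loads == 1))
    idx3 = np.flatnonzero(correct & (loads == 3))
    n = min(idx1.size, idx3.size)
    keep = np.zeros(len(trials), bool)
    keep[rng.choice(idx1, n, replace=False)] = True
    keep[rng.choice(idx3, n, replace=False)] = True
    return keep


def select_pac_channels(comodulograms: dict[str, Comodulogram],
                        gamma: str = "high") -> dict[str, bool]:
    """Significant-PAC flags per channel from pooled-condition comodulograms.

    The z-MI is averaged over theta phase centres (4, 6 Hz) and either the
    high- (70-140 Hz) or low-gamma (30-55 Hz) amplitude centres; a channel is
    significant when the mean z exceeds the standard-normal 95th percentile
    (1.64, right-sided).
    """
    band = HIGH_GAMMA_BAND if gamma == "high" else LOW_GAMMA_BAND
    return {chan: como.mean_z(THETA_PHASE_CENTRES, band) > Z_CRIT_95
            for chan, como in comodulograms.items()}


def load_contrast(z_load1: np.ndarray, z_load3: np.ndarray,
                  n_perm: int = 10_000, rng=None) -> dict:
    """Paired permutation t-test of z-MI between loads across channels.

    Both conditions must have been computed on equal trial counts.  Returns
    the mean difference (load 3 - load 1), t and p.
    """
    z1 = np.asarray(z_load1, float)
    z3 = np.asarray(z_load3, float)
    if z1.size < 2:
        raise ValueError("need at least 2 significant channels")
    t, p = perm_ttest(z3, z1, paired=True, n_perm=n_perm, rng=rng)
    return {"delta_z": float((z3 - z1).mean()), "t": t, "p": p, "n": int(z1.size)}


def load_contrast_by_area(area_results: dict[str, tuple[np.ndarray, np.ndarray]],
                          n_perm: int = 10_000, rng=None) -> pd.DataFrame:
    """Load contrast per area with BH-FDR over the five areas."""
    rng = make_rng(rng)
    rows = []
    for area, (z1, z3) in area_results.items():
        res = load_contrast(z1, z3, n_perm=n_perm, rng=rng)
        rows.append({"area": area, **res})
    df = pd.DataFrame(rows)
    df["p_fdr"] = fdr_bh_adjusted(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# single-trial PAC
# ---------------------------------------------------------------------------

def single_trial_pac(epochs: LFPEpochs, phase_band=THETA_BAND,
                     amp_band=HIGH_GAMMA_BAND, n_bins: int = 18) -> np.ndarray:
    """Raw MI computed within each trial's maintenance window.

    Invalid trials yield NaN.  Single-trial MIs are left un-normalized; they
    feed the mixed-model analyses of trialwise PAC versus firing rate or
    reaction time.
    """
    phase, amp = hilbert_phase_amp(epochs, phase_band)
    _, gamma = hilbert_phase_amp(epochs, amp_band)
    out = np.full(phase.shape[0], np.nan)
    for t in range(phase.shape[0]):
        if not epochs.valid_trials[t]:
            continue
        mi, _, _ = modulation_index(phase[t], gamma[t], n_bins)
        out[t] = mi
    return out


# ---------------------------------------------------------------------------
# theta waveform asymmetry
# ---------------------------------------------------------------------------

def cycle_asymmetry_trace(x: np.ndarray, fs: float) -> tuple[float, float, int]:
    """Peak-trough and rise-decay asymmetry of one oscillatory trace.

    Cycles are delimited by extrema between zero crossings.  Per cycle,
    PT = t_peak_half / (t_peak_half + t_trough_half) uses the durations the
    signal spends above/below zero, and RD = t_rise / (t_rise + t_decay) uses
    the trough-to-peak and peak-to-trough durations.  Returns the cycle
    averages and the cycle count; a symmetric sinusoid gives (0.5, 0.5).
    """
    x = np.asarray(x, float)
    sgn = np.sign(x)
    sgn[sgn == 0] = 1
    rises = np.flatnonzero((sgn[:-1] < 0) & (sgn[1:] > 0)) + 1
    decays = np.flatnonzero((sgn[:-1] > 0) & (sgn[1:] < 0)) + 1

    pts, rds = [], []
    for k in range(len(rises) - 1):
        r0, r1 = rises[k], rises[k + 1]
        d = decays[(decays > r0) & (decays < r1)]
        if d.size != 1:
            continue
        d = int(d[0])
        peak = r0 + int(np.argmax(x[r0:d]))
        trough = d + int(np.argmin(x[d:r1]))
        t_peak_half = d - r0
        t_trough_half = r1 - d
        pts.append(t_peak_half / (t_peak_half + t_trough_half))
        # rise of this cycle's peak = previous trough -> peak
        prev_d = decays[decays < r0]
        if prev_d.size == 0:
            continue
        prev_trough = int(prev_d[-1]) + int(np.argmin(x[int(prev_d[-1]):r0]))
        t_rise = peak - prev_trough
        t_decay = trough - peak
        if t_rise > 0 and t_decay > 0:
            rds.append(t_rise / (t_rise + t_decay))

    n = len(pts)
    if n < 3:
        return np.nan, np.nan, n
    return float(np.mean(pts)), float(np.mean(rds)) if rds else np.nan, n


def cycle_asymmetry(epochs: LFPEpochs, band=THETA_BAND) -> pd.DataFrame:
    """Per-trial theta cycle asymmetries (band-passed maintenance window).

    Returns a DataFrame with ``pt`` (peak-trough), ``rd`` (rise-decay) and
    the cycle count per trial; trials with fewer than 3 cycles are NaN.
    """
    from .io_core import maintenance_slice
    from .preprocess import bandpass
    filtered = bandpass(epochs.samples, epochs.fs, band, axis=1)
    sl = maintenance_slice(epochs.window, epochs.fs)
    filtered = filtered[:, sl]
    rows = []
    for t in range(filtered.shape[0]):
        if not epochs.valid_trials[t]:
            rows.append({"pt": np.nan, "rd": np.nan, "n_cycles": 0})
            continue
        pt, rd, n = cycle_asymmetry_trace(filtered[t], epochs.fs)
        rows.append({"pt": pt, "rd": rd, "n_cycles": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nesting detection
# ---------------------------------------------------------------------------

@dataclass
class NestingResult:
    nested: bool
    waveform: np.ndarray
    n_windows: int
    reliable: bool


def detect_nesting(epochs: LFPEpochs, phase_band=THETA_BAND,
                   amp_band=HIGH_GAMMA_BAND, win: float = 0.5,
                   peak_window: float = 0.045, n_bins: int = 18,
                   min_windows: int = 10) -> NestingResult:
    """Test whether gamma bursts ride on a preferred theta phase.

    The preferred theta phase bin is where mean gamma amplitude is maximal.
    Within every occurrence of that bin, the timepoint of maximal gamma
    amplitude anchors a 500-ms window of the *raw* signal; the windows are
    averaged and the waveform is called nested when at least three local
    maxima fall within 45 ms (three cycles at 70 Hz) around the window
    centre.  Fewer than ``min_windows`` windows flags the result unreliable.
    """
    from .io_core import maintenance_slice
    fs = epochs.fs
    phase, _ = hilbert_phase_amp(epochs, phase_band)
    _, gamma = hilbert_phase_amp(epochs, amp_band)
    sl = maintenance_slice(epochs.window, fs)
    raw = epochs.samples[:, sl]

    _, profile, _ = modulation_index(phase[epochs.valid_trials],
                                     gamma[epochs.valid_trials], n_bins)
    pref_bin = int(np.argmax(profile))
    idx = phase_bin_index(phase, n_bins)

    half = int(round(win * fs / 2))
    windows = []
    for t in range(raw.shape[0]):
        if not epochs.valid_trials[t]:
            continue
        inbin = idx[t] == pref_bin
        if not inbin.any():
            continue
        runs = np.split(np.flatnonzero(inbin),
                        np.flatnonzero(np.diff(np.flatnonzero(inbin)) > 1) + 1)
        for run in runs:
            if run.size == 0:
                continue
            centre = run[int(np.argmax(gamma[t, run]))]
            if centre - half < 0 or centre + half + 1 > raw.shape[1]:
                continue
            windows.append(raw[t, centre - half: centre + half + 1])

    n_windows = len(windows)
    if n_windows == 0:
        return NestingResult(False, np.zeros(2 * half + 1), 0, False)
    waveform = np.mean(windows, axis=0)
    # a gamma-scale local maximum must rise above residual averaging noise
    prom = 0.02 * np.ptp(waveform)
    peaks, _ = sig.find_peaks(waveform, prominence=prom)
    centre = half
    lim = peak_window / 2 * fs
    n_near = int(np.sum(np.abs(peaks - centre) <= lim))
    return NestingResult(nested=n_near >= 3, waveform=waveform,
                         n_windows=n_windows, reliable=n_windows >= min_windows)
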