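"""Spike-field coherence as the mean vector length (MVL) of spike phases.

Each spike is assigned the LFP phase at its nearest sample, per wavelet
frequency.  Because the MVL is positively biased at low spike counts, all
condition contrasts equalize spike counts by repeated subsampling, and raw
MVLs are z-scored against spike-time jitter surrogates (uniform re-draw of the
spike's position within its own trial's maintenance window), which preserves
spike counts and trial assignment while destroying phase locking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import MAINTENANCE_WINDOW, make_rng

MIN_SPIKES_DEFAULT = 50
MIN_SPIKES_PREFERRED = 10  # preferred vs non-preferred contrast in category cells


def spikes_to_samples(timestamps: np.ndarray, onsets: np.ndarray, fs: float,
                      window: tuple[float, float] = MAINTENANCE_WINDOW
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Map session-clock spikes into (trial index, sample index) pairs.

    Spikes outside every trial's analysis window are dropped; the drop count
    is returned.
    """
    timestamps = np.asarray(timestamps, float)
    onsets = np.asarray(onsets, float)
    n_samp = int(round((window[1] - window[0]) * fs))
    trial_idx, sample_idx = [], []
    dropped = 0
    for t in timestamps:
        rel = t - onsets
        hits = np.flatnonzero((rel >= window[0]) & (rel < window[1]))
        if hits.size == 0:
            dropped += 1
            continue
        tr = int(hits[0])
        s = int(round((t - onsets[tr] - window[0]) * fs))
        trial_idx.append(tr)
        sample_idx.append(min(s, n_samp - 1))
    return np.asarray(trial_idx, int), np.asarray(sample_idx, int), dropped


def spike_phases(phase_tf: np.ndarray, trial_idx: np.ndarray,
                 sample_idx: np.ndarray) -> np.ndarray:
    """Nearest-sample LFP phase per spike per frequency.

    ``phase_tf`` is trials x freqs x time (wavelet phases); the result is
    n_spikes x freqs.  An empty spike set yields an empty array.
    """
    if len(trial_idx) == 0:
        return np.zeros((0, phase_tf.shape[1]))
    return phase_tf[trial_idx, :, sample_idx]


def mvl(phases: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mean vector length of circular data; 1 = perfect locking."""
    return np.abs(np.exp(1j * np.asarray(phases)).mean(axis=axis))


def mvl_subsampled(phases_by_condition: dict[str, np.ndarray],
                   min_spikes: int = MIN_SPIKES_DEFAULT, n_rep: int = 500,
                   rng=None) -> dict[str, np.ndarray]:
    """Spike-count-equalized MVL per condition.

    Subsamples each condition to the smallest condition's spike count,
    ``n_rep`` times, and averages the per-frequency MVLs.  A condition below
    ``min_spikes`` raises, carrying a reason usable as an exclusion code.
    """
    rng = make_rng(rng)
    counts = {c: p.shape[0] for c, p in phases_by_condition.items()}
    low = [c for c, n in counts.items() if n < min_spikes]
    if low:
        raise ValueError(f"insufficient spikes (<{min_spikes}) in condition(s) {low}")
    n_sub = min(counts.values())
    out = {}
    for cond, phases in phases_by_condition.items():
        n = phases.shape[0]
        acc = np.zeros(phases.shape[1])
        for _ in range(n_rep):
            sel = rng.choice(n, n_sub, replace=False)
            acc += mvl(phases[sel], axis=0)
        out[cond] = acc / n_rep
    return out


def jitter_z(phase_tf: np.ndarray, trial_idx: np.ndarray, sample_idx: np.ndarray,
             n_sub: int | None = None, n_surr: int = 500, n_rep: int = 100,
             rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Jitter-surrogate z-normalization of the MVL for one condition.

    Raw MVL: mean over ``n_rep`` subsamples of size ``n_sub`` (all spikes if
    None).  Surrogates re-draw each spike's sample uniformly within its own
    trial's window (spike count and trial assignment unchanged), subsample to
    the same size, and a normal fit yields z per frequency.

    Returns (raw_mvl, z_mvl), each of length n_freqs.
    """
    rng = make_rng(rng)
    n_spikes = len(trial_idx)
    n_time = phase_tf.shape[2]
    if n_spikes < 2:
        raise ValueError("need at least 2 spikes")
    if n_sub is None or n_sub >= n_spikes:
        n_sub = n_spikes

    phases = spike_phases(phase_tf, trial_idx, sample_idx)
    if n_sub == n_spikes:
        raw = mvl(phases, axis=0)
    else:
        acc = np.zeros(phases.shape[1])
        for _ in range(n_rep):
            acc += mvl(phases[rng.choice(n_spikes, n_sub, replace=False)], axis=0)
        raw = acc / n_rep

    surr = np.empty((n_surr, phases.shape[1]))
    for k in range(n_surr):
        jit_samples = rng.integers(0, n_time, size=n_spikes)
        ph = spike_phases(phase_tf, trial_idx, jit_samples)
        if n_sub < n_spikes:
            ph = ph[rng.choice(n_spikes, n_sub, replace=False)]
        surr[k] = mvl(ph, axis=0)
    mu = surr.mean(axis=0)
    sd = surr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate jitter surrogate distribution (sd = 0)")
    return raw, (raw - mu) / sd


@dataclass
class SFCSpectrum:
    """z-normalized MVL spectrum for one unit-channel pair and condition set."""

    unit_id: str
    channel_id: str
    same_region: bool
    freqs: np.ndarray
    raw_mvl: dict[str, np.ndarray]
    z_mvl: dict[str, np.ndarray]
    n_spikes_used: int


def sfc_pair(phase_tf: np.ndarray, freqs: np.ndarray,
             trial_idx: np.ndarray, sample_idx: np.ndarray,
             condition_of_trial: dict[str, np.ndarray], *,
             unit_id: str = "u", channel_id: str = "c", same_region: bool = True,
             min_spikes: int = MIN_SPIKES_DEFAULT, n_rep: int = 100,
             n_surr: int = 200, rng=None) -> SFCSpectrum:
    """Full SFC for one unit-channel pair across conditions.

    ``condition_of_trial`` maps condition name -> boolean mask over trials.
    Spike counts are equalized across conditions before the jitter
    z-normalization so contrasted conditions share ``n_spikes_used``.
    """
    rng = make_rng(rng)
    spike_masks = {c: m[trial_idx] for c, m in condition_of_trial.items()}
    counts = {c: int(m.sum()) for c, m in spike_masks.items()}
    low = [c for c, n in counts.items() if n < min_spikes]
    if low:
        raise ValueError(f"insufficient spikes (<{min_spikes}) in condition(s) {low}")
    n_sub = min(counts.values())

    raw_d, z_d = {}, {}
    for cond, m in spike_masks.items():
        raw, z = jitter_z(phase_tf, trial_idx[m], sample_idx[m],
                          n_sub=n_sub, n_surr=n_surr, n_rep=n_rep, rng=rng)
        raw_d[cond], z_d[cond] = raw, z
    return SFCSpectrum(unit_id=unit_id, channel_id=channel_id,
                       same_region=same_region, freqs=np.asarray(freqs, float),
                       raw_mvl=raw_d, z_mvl=z_d, n_spikes_used=n_sub)


def load_balanced_average(per_load: dict[int, np.ndarray]) -> np.ndarray:
    """Average SFC spectra computed within each load, across loads."""
    return np.mean([per_load[k] for k in sorted(per_load)], axis=0)


def condition_contrast(spectra: list[SFCSpectrum], cond_a: str, cond_b: str,
                       n_perm: int = 10_000, alpha_cluster: float = 0.025,
                       bonferroni: int = 1, rng=None) -> dict:
    """Per-frequency paired contrast across pairs with cluster correction.

    Returns per-frequency mean differences, the cluster list, and the
    Bonferroni-adjusted significance alpha (0.05 / ``bonferroni``) applied to
    the cluster p-values.
    """
    from .stats import cluster_perm_freq
    for s in spectra:
        if cond_a not in s.z_mvl or cond_b not in s.z_mvl:
            raise ValueError(f"pair {s.unit_id}-{s.channel_id} lacks a condition")
    diffs = np.stack([s.z_mvl[cond_a] - s.z_mvl[cond_b] for s in spectra])
    clusters = cluster_perm_freq(diffs, n_perm=n_perm,
                                 alpha_cluster=alpha_cluster, rng=rng)
    alpha = 0.05 / bonferroni
    return {"freqs": spectra[0].freqs, "mean_diff": diffs.mean(axis=0),
            "clusters": clusters, "alpha": alpha,
            "significant": [c for c in clusters if c.p < alpha]}


def rt_median_split(rt: np.ndarray, loads: np.ndarray,
                    usable: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fast/slow masks from per-load median splits (ties assigned to fast)."""
    rt = np.asarray(rt, float)
    fast = np.zeros(rt.size, bool)
    slow = np.zeros(rt.size, bool)
    for ld in np.unique(loads[usable]):
        m = usable & (loads == ld)
        med = np.median(rt[m])
        fast |= m & (rt <= med)
        slow |= m & (rt > med)
    return fast, slow


def gamma_amplitude_split_sfc(phases: np.ndarray, gamma_amp: np.ndarray,
                              preferred: np.ndarray, n_rep: int = 200,
                              min_spikes: int = MIN_SPIKES_PREFERRED,
                              rng=None) -> dict[str, float]:
    """Preferred - non-preferred MVL difference at high vs low gamma amplitude.

    ``phases``: per-spike phases (n_spikes,) at the frequency of interest (or
    already band-averaged); ``gamma_amp``: gamma amplitude at each spike time;
    ``preferred``: boolean per spike.  The amplitude median split defines the
    high/low classes; within each class the preferred/non-preferred MVLs are
    computed with equalized counts across all four cells.
    """
    rng = make_rng(rng)
    phases = np.asarray(phases).ravel()
    gamma_amp = np.asarray(gamma_amp).ravel()
    preferred = np.asarray(preferred, bool).ravel()
    high = gamma_amp > np.median(gamma_amp)
    cells = {(h, p): np.flatnonzero((high == h) & (preferred == p))
             for h in (True, False) for p in (True, False)}
    n_min = min(idx.size for idx in cells.values())
    if n_min < min_spikes:
        raise ValueError(f"a gamma/preference cell has <{min_spikes} spikes")

    def cell_mvl(idx):
        acc = 0.0
        for _ in range(n_rep):
            acc += float(mvl(phases[rng.choice(idx, n_min, replace=False)]))
        return acc / n_rep

    d_high = cell_mvl(cells[(True, True)]) - cell_mvl(cells[(True, False)])
    d_low = cell_mvl(cells[(False, True)]) - cell_mvl(cells[(False, False)])
    return {"high": d_high, "low": d_low, "n_per_cell": int(n_min)}
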