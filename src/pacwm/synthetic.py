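"""Synthetic working-memory sessions with known ground truth.

The generator emulates the structure every downstream stage is built to
detect: 140 trials split evenly into loads 1 and 3 with five stimulus
categories; LFP epochs composed of 1/f background (slope ~ -1.75, the
hippocampal regime), a theta (3-7 Hz) oscillation and a broadband gamma
(70-140 Hz) carrier whose instantaneous amplitude is a stated function of
theta phase, A(t) = A0 * (1 + kappa * cos(theta(t) - phi_pref)); and spike
trains with category-gain persistent activity, von Mises theta locking, a
theta-phase x gamma-amplitude interaction drive, and shared-gain
trial-to-trial noise correlations.  Reaction times can be coupled to the
per-trial coupling depth.

Every stochastic element draws from one explicit numpy Generator, so a fixed
seed reproduces a session bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import (EPOCH_WINDOW, FS_LFP, MAINTENANCE_WINDOW, LFPEpochs,
                      Session, SpikeTrain, make_rng, maintenance_slice)
from .preprocess import bandpass

THETA_FREQ_DEFAULT = 5.0


@dataclass
class UnitSpec:
    """Ground-truth generative parameters of one synthetic unit."""

    unit_id: str
    channel_id: str = "hc1"
    region: str = "hippocampus"
    base_rate: float = 5.0                 # Hz
    category_gains: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    kappa_vm: float = 0.0                  # von Mises theta locking
    beta_int: float = 0.0                  # phase x gamma-amplitude interaction
    gamma_gain: float = 0.0                # log-rate uplift when gamma is high
    preferred_phase: float = 0.0
    shared_gain_group: str | None = None   # units sharing a trial gain

    @property
    def category_tuned(self) -> bool:
        return len(set(self.category_gains)) > 1

    @property
    def pac_interacting(self) -> bool:
        """True for units driven by the theta-phase x gamma interaction.

        A detectable PAC neuron carries both the interaction drive and a
        gamma main effect, matching the two likelihood-ratio comparisons of
        the selection rule.
        """
        return self.beta_int > 0

    @property
    def locked(self) -> bool:
        return self.kappa_vm > 0


def default_units() -> list[UnitSpec]:
    """A small hippocampal roster covering every ground-truth class.

    Two category-tuned persistently active units, two interaction-driven PAC
    units, one unit of both kinds and one null unit; the working-memory units
    share one trial-gain group so PAC-category pairs carry positive noise
    correlations.
    """
    g = "wm"
    tuned = lambda k: tuple(3.0 if i == k else 1.0 for i in range(5))
    pac = dict(base_rate=12.0, beta_int=1.5, gamma_gain=0.8, kappa_vm=0.5)
    return [
        UnitSpec("u_cat1", category_gains=tuned(0), shared_gain_group=g),
        UnitSpec("u_cat2", category_gains=tuned(1), shared_gain_group=g),
        UnitSpec("u_pac1", shared_gain_group=g, **pac),
        UnitSpec("u_pac2", shared_gain_group=g, **pac),
        UnitSpec("u_both", category_gains=tuned(2), **pac),
        UnitSpec("u_null"),
    ]


@dataclass
class SyntheticConfig:
    """Study-condition parameters of a synthetic session."""

    n_trials: int = 140
    load_split: tuple[int, int] = (70, 70)
    n_categories: int = 5
    fs: float = FS_LFP
    theta_freq: float = THETA_FREQ_DEFAULT
    theta_amp: float = 15.0                     # microvolts
    pac_depth: dict = field(default_factory=lambda: {1: 0.6, 3: 0.3})
    pac_preferred_phase: float = 0.0
    pac_trial_jitter: float = 0.3               # relative per-trial spread of kappa
    gamma_band: tuple[float, float] = (70.0, 140.0)
    gamma_amp: float = 5.0
    gamma_burst_sd: float = 0.5            # log-sd of phase-independent bursts
    one_over_f_exponent: float = 1.75
    noise_amp: float = 10.0
    channels: tuple = (("hc1", "hippocampus"),)
    units: list[UnitSpec] = field(default_factory=default_units)
    shared_gain_sd: float = 0.35
    rt_intercept: float = 1.35
    rt_load_coef: float = 0.13
    rt_pac_slope: float = -0.08                 # s per z of trial coupling depth
    rt_noise_sd: float = 0.15
    p_correct: float = 0.94
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in dict(self.pac_depth).items():
            if not 0 <= v <= 1:
                raise ValueError(f"pac_depth[{k}]={v} outside [0, 1]")
        if self.shared_gain_sd < 0:
            raise ValueError("shared_gain_sd must be >= 0")
        for u in self.units:
            if u.base_rate < 0:
                raise ValueError(f"{u.unit_id}: negative base rate")
            if len(u.category_gains) != self.n_categories:
                raise ValueError(f"{u.unit_id}: category_gains length mismatch")


# ---------------------------------------------------------------------------
# trial table
# ---------------------------------------------------------------------------

def make_trials(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Build the trial table: loads interleaved at random, distinct
    categories per load-3 trial, event times on a session clock."""
    rng = make_rng(rng)
    n1, n3 = config.load_split
    loads = rng.permutation(np.r_[np.ones(n1, int), np.full(n3, 3, int)])
    rows = []
    clock = 1.0
    for i, load in enumerate(loads):
        cats = rng.choice(config.n_categories, size=load, replace=False) + 1
        fixation = 1.0
        pic_onsets = []
        t = clock + fixation
        for _ in range(load):
            pic_onsets.append(t)
            t += 2.0 + 0.1  # 2 s picture + blank
        maint = t + 0.05
        probe = maint + 2.7
        rows.append({"trial_id": i, "load": int(load),
                     "encoded_categories": [int(c) for c in cats],
                     "correct": True, "rt": 1.0,
                     "maintenance_onset": maint,
                     "picture_onsets": pic_onsets, "probe_onset": probe})
        clock = probe + 2.5
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _pink_noise(n: int, exponent: float, rng) -> np.ndarray:
    """FFT-shaped 1/f^exponent noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _gamma_carrier(n: int, fs: float, band, rng) -> np.ndarray:
    """Band-limited white noise, unit RMS: a broadband high-gamma carrier
    (not a sinusoid), so coupling is detectable across the whole band."""
    x = bandpass(rng.standard_normal(n + 400), fs, band)[200: 200 + n]
    return x / x.std()


def simulate_lfp(config: SyntheticConfig, trials: pd.DataFrame, rng=None,
                 channel_id: str = "hc1", region: str = "hippocampus",
                 ) -> tuple[LFPEpochs, dict]:
    """Per-trial LFP epochs plus the generative ground truth.

    Each epoch spans the padded window [-0.5, 3.0) s around maintenance
    onset and is pink noise + theta + gamma carrier with envelope
    A0 * (1 + kappa_t * cos(theta - phi_pref)) * B(t), where B(t) is a
    slow lognormal burst process (unit mean) that makes gamma amplitude
    fluctuate independently of theta phase, as real high-gamma does.  The
    per-trial depth kappa_t scatters around the load-level depth by
    ``pac_trial_jitter``.
    """
    rng = make_rng(rng)
    fs = config.fs
    if fs < 2.5 * config.gamma_band[1]:
        raise ValueError("fs must be >= 2.5x the top gamma frequency")
    n = int(round((EPOCH_WINDOW[1] - EPOCH_WINDOW[0]) * fs))
    t = EPOCH_WINDOW[0] + np.arange(n) / fs
    n_trials = len(trials)
    loads = trials["load"].to_numpy()

    samples = np.empty((n_trials, n))
    theta_phase = np.empty((n_trials, n))
    gamma_env = np.empty((n_trials, n))
    kappa_t = np.empty(n_trials)
    for i in range(n_trials):
        kap = config.pac_depth[int(loads[i])]
        kap *= 1.0 + config.pac_trial_jitter * (2 * rng.random() - 1)
        kappa_t[i] = min(max(kap, 0.0), 1.0)
        phi0 = rng.uniform(-np.pi, np.pi)
        theta = 2 * np.pi * config.theta_freq * t + phi0
        env = config.gamma_amp * (
            1 + kappa_t[i] * np.cos(theta - config.pac_preferred_phase))
        if config.gamma_burst_sd > 0:
            # ~50 ms Gaussian-smoothed noise: burst timescale of high gamma
            from scipy.ndimage import gaussian_filter1d
            slow = gaussian_filter1d(rng.standard_normal(n), sigma=0.05 * fs)
            slow /= slow.std()
            env = env * np.exp(config.gamma_burst_sd * slow
                               - config.gamma_burst_sd ** 2 / 2)
        carrier = _gamma_carrier(n, fs, config.gamma_band, rng)
        samples[i] = (config.noise_amp * _pink_noise(n, config.one_over_f_exponent, rng)
                      + config.theta_amp * np.cos(theta)
                      + env * carrier)
        theta_phase[i] = np.angle(np.exp(1j * theta))
        gamma_env[i] = env

    epochs = LFPEpochs(channel_id=channel_id, region=region, fs=fs,
                       samples=samples, window=EPOCH_WINDOW,
                       valid_trials=np.ones(n_trials, bool))
    truth = {"phi_pref": config.pac_preferred_phase, "kappa_trial": kappa_t,
             "theta_phase": theta_phase, "gamma_env": gamma_env}
    return epochs, truth


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _poisson_segment(rate: float, t0: float, t1: float, rng) -> np.ndarray:
    n = rng.poisson(rate * max(t1 - t0, 0.0))
    return np.sort(rng.uniform(t0, t1, n)) if n else np.empty(0)


def simulate_spikes(config: SyntheticConfig, trials: pd.DataFrame,
                    lfp_truth: dict, rng=None,
                    ) -> tuple[list[SpikeTrain], dict]:
    """Spike trains on the session clock, plus ground-truth unit labels.

    Maintenance-period rates follow an inhomogeneous Poisson process
    lambda(t) = base * g_cat * exp(kappa_vm cos(theta - phi0)
    + (beta_int cos(theta - phi_pref) + gamma_gain) * 1[gamma high]) * G(t),
    normalized so the mean rate stays at base * g_cat; G(t)
    = exp(sd * eta(t) - sd^2 / 2) is a slow shared-excitability process common
    to all units of a gain group, so paired units co-fluctuate across the
    sliding time bins within each trial (the statistic noise-correlation
    analyses measure) as well as from trial to trial.  The gamma_gain term
    gives interaction-driven units the gamma main effect a selectable PAC
    neuron requires on the log-rate scale.  Encoding windows use the category
    gain of the shown picture; other task periods fire at the base rate.
    Spikes are generated by thinning at the LFP sample resolution; the
    per-sample probability is capped at 0.9 and the cap count reported.
    """
    rng = make_rng(rng)
    fs = config.fs
    sl = maintenance_slice(EPOCH_WINDOW, fs)
    theta = lfp_truth["theta_phase"][:, sl]
    env = lfp_truth["gamma_env"][:, sl]
    high = env > np.median(env)  # global split, as in the analysis design
    phi_pref = lfp_truth["phi_pref"]
    n_trials, n_time = theta.shape
    onsets = trials["maintenance_onset"].to_numpy(float)
    cats = trials["encoded_categories"].tolist()
    pic_onsets = trials["picture_onsets"].tolist()

    from scipy.ndimage import gaussian_filter1d
    groups = sorted({u.shared_gain_group for u in config.units
                     if u.shared_gain_group})
    # shared excitability: a slow (~150 ms) process common to all units of a
    # group; it fluctuates *within* trials, which is what the sliding-bin
    # noise-correlation statistic measures, and its per-trial mean varies too
    eta = {}
    for g in groups:
        e = gaussian_filter1d(rng.standard_normal((n_trials, n_time)),
                              sigma=0.15 * fs, axis=1)
        eta[g] = e / e.std()

    out = []
    truth_units = {}
    n_capped = 0
    for u in config.units:
        gains = np.asarray(u.category_gains, float)
        if u.shared_gain_group:
            G = np.exp(config.shared_gain_sd * eta[u.shared_gain_group]
                       - config.shared_gain_sd ** 2 / 2)
        else:
            G = np.ones((n_trials, n_time))
        spikes = []
        for i in range(n_trials):
            g_cat = float(gains[[c - 1 for c in cats[i]]].mean())
            mod = np.exp(u.kappa_vm * np.cos(theta[i] - u.preferred_phase)
                         + (u.beta_int * np.cos(theta[i] - phi_pref)
                            + u.gamma_gain) * high[i])
            mod /= mod.mean()
            lam = u.base_rate * g_cat * G[i] * mod  # G varies within trial
            p = lam / fs
            capped = p > 0.9
            n_capped += int(capped.sum())
            p = np.minimum(p, 0.9)
            hits = np.flatnonzero(rng.random(n_time) < p)
            spikes.append(onsets[i] + (hits + 0.5) / fs)
            # encoding windows: category-gain rates, persistent-activity source
            g_enc = float(G[i].mean())
            for onset, cat in zip(pic_onsets[i], cats[i]):
                rate = u.base_rate * float(gains[cat - 1]) * g_enc
                spikes.append(_poisson_segment(rate, onset, onset + 2.0, rng))
            # fixation before picture 1 (baseline) and post-probe at base rate
            first_pic = pic_onsets[i][0]
            spikes.append(_poisson_segment(u.base_rate, first_pic - 1.0,
                                           first_pic, rng))
        ts = np.sort(np.concatenate(spikes))
        out.append(SpikeTrain(unit_id=u.unit_id, region=u.region,
                              channel_id=u.channel_id, timestamps=ts))
        truth_units[u.unit_id] = {
            "category_tuned": u.category_tuned,
            "pac_interacting": u.pac_interacting,
            "locked": u.locked,
            "shared_gain_group": u.shared_gain_group,
            "kappa_vm": u.kappa_vm, "beta_int": u.beta_int,
        }
    return out, {"units": truth_units, "n_capped_samples": n_capped}


# ---------------------------------------------------------------------------
# session
# ---------------------------------------------------------------------------

def simulate_session(config: SyntheticConfig | None = None, seed: int | None = None
                     ) -> tuple[Session, dict]:
    """Compose trials, LFP and spikes into a full session + ground truth.

    Reaction times follow rt = intercept + load_coef * 1[load 3]
    + pac_slope * z(kappa_t) + noise, so a negative slope couples faster
    responses to stronger trialwise coupling; accuracy is Bernoulli.
    """
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = make_rng(config.seed)
    trials = make_trials(config, rng)

    lfp = []
    truths = {}
    for channel_id, region in config.channels:
        epochs, truth = simulate_lfp(config, trials, rng, channel_id, region)
        lfp.append(epochs)
        truths[channel_id] = truth

    first = config.channels[0][0]
    units, unit_truth = simulate_spikes(config, trials, truths[first], rng)

    kappa = truths[first]["kappa_trial"]
    z_kappa = (kappa - kappa.mean()) / kappa.std() if kappa.std() > 0 else kappa * 0
    loads = trials["load"].to_numpy()
    rt = (config.rt_intercept + config.rt_load_coef * (loads == 3)
          + config.rt_pac_slope * z_kappa
          + config.rt_noise_sd * rng.standard_normal(len(trials)))
    trials["rt"] = np.maximum(rt, 0.2)
    trials["correct"] = rng.random(len(trials)) < config.p_correct

    session = Session(trials=trials, lfp=lfp, units=units,
                      metadata={"seed": config.seed, "synthetic": True})
    truth = {"channels": truths, **unit_truth,
             "rt_pac_slope": config.rt_pac_slope, "config_seed": config.seed}
    return session, truth


def simulate_population_rates(n_trials_per_cat: int = 25, n_categories: int = 5,
                              n_tuned: int = 3, n_untuned: int = 3,
                              offset: float = 1.2, noise_sd: float = 1.0,
                              shared_sd: float = 2.0, base: float = 10.0,
                              distribution: str = "gaussian", rng=None
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial x unit rate matrix for decoding/geometry studies.

    ``n_tuned`` units each gain ``offset`` for one category (unit j prefers
    category j); ``n_untuned`` units carry no category signal.  A shared
    Gaussian draw of ``shared_sd`` per trial is added to *all* units,
    injecting the noise correlations through which untuned units can enhance
    the population code.  ``distribution="poisson"`` draws counts around the
    same means instead (the chance-level construction for untuned decoders).

    Returns (rates, labels, tuned_mask).
    """
    rng = make_rng(rng)
    labels = np.repeat(np.arange(n_categories), n_trials_per_cat)
    n = labels.size
    k = n_tuned + n_untuned
    means = np.full((n, k), base)
    for j in range(min(n_tuned, n_categories)):
        means[labels == j, j] += offset
    if distribution == "poisson":
        rates = rng.poisson(np.maximum(means, 0)).astype(float)
    elif distribution == "gaussian":
        rates = means + noise_sd * rng.standard_normal((n, k))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    if shared_sd > 0:
        rates = rates + shared_sd * rng.standard_normal(n)[:, None]
    tuned_mask = np.r_[np.ones(n_tuned, bool), np.zeros(n_untuned, bool)]
    return rates, labels, tuned_mask


# ---------------------------------------------------------------------------
# two-neuron geometry construction
# ---------------------------------------------------------------------------

def simulate_two_neuron_geometry(n_trials_per_cat: int = 200, offset: float = 2.0,
                                 noise_sd: float = 1.0, shared_sd: float = 0.0,
                                 rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Rates of one tuned and one untuned neuron over two categories.

    Neuron 1 gains ``offset`` for category 1 (the signal lies on its
    coordinate axis); both neurons receive independent noise of
    ``noise_sd`` plus a shared draw of ``shared_sd`` per trial, so the
    injected noise direction is (1, 1)/sqrt(2).  Returns (rates, labels)
    with rates of shape (2 * n_trials_per_cat, 2) and labels in {0, 1}.
    """
    rng = make_rng(rng)
    n = 2 * n_trials_per_cat
    labels = np.repeat([0, 1], n_trials_per_cat)
    base = 10.0
    rates = base + noise_sd * rng.standard_normal((n, 2))
    rates[labels == 1, 0] += offset
    shared = shared_sd * rng.standard_normal(n)
    rates += shared[:, None]
    return rates, labels
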