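"""Selection of category neurons and PAC neurons.

Category neurons: units whose encoding-window (0.2-1.0 s post stimulus onset)
spike counts differ across the five picture categories by a permutation ANOVA,
with a post hoc one-sided permutation t-test of the maximal category against
the rest; a unit is selected when both tests pass.  The area-level count is
compared against a label-shuffle null.

PAC neurons: units whose maintenance-period spike counts depend on the
*interaction* of theta phase and gamma amplitude.  Spike counts in 10 theta
phase bins x {low, high} gamma amplitude are modelled by three nested Poisson
GLMs (phase as cosine/sine to respect circularity):

    model 1:  SC ~ 1 + cos + sin + G + cos:G + sin:G
    model 2:  SC ~ 1 + cos + sin + G
    model 3:  SC ~ 1 + cos + sin + cos:G + sin:G

A unit qualifies when model 1 beats both reduced models by likelihood-ratio
tests (p < 0.01, BH-FDR over the unit's channel combinations) in either load.
The model-3 comparison guards against spurious selection of units that merely
sit on a strongly PAC-coupled LFP without any amplitude sensitivity of their
own.  Bin occupancy enters as a log-exposure offset so unequal time spent per
bin cannot masquerade as a rate effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import Session, make_rng
from .stats import fdr_bh_adjusted, perm_anova, perm_ttest

N_PHASE_BINS = 10
GAMMA_DESIGN_FREQS = np.arange(70.0, 141.0, 5.0)
GAMMA_DESIGN_CYCLES = 7.0
ENCODING_WINDOW = (0.2, 1.0)


# ---------------------------------------------------------------------------
# category neurons
# ---------------------------------------------------------------------------

def presentation_counts(timestamps: np.ndarray, trials: pd.DataFrame,
                        window: tuple[float, float] = ENCODING_WINDOW
                        ) -> pd.DataFrame:
    """Spike count per picture presentation in the encoding window.

    One row per presented picture (all encoding positions; the probe is
    included when the trial table carries a ``probe_category`` column).
    """
    timestamps = np.asarray(timestamps, float)
    rows = []
    for _, tr in trials.iterrows():
        onsets = list(tr["picture_onsets"])
        cats = list(tr["encoded_categories"])
        events = list(zip(onsets, cats))
        if "probe_category" in tr.index and not pd.isna(tr["probe_category"]):
            events.append((tr["probe_onset"], int(tr["probe_category"])))
        for onset, cat in events:
            n = int(np.sum((timestamps >= onset + window[0]) &
                           (timestamps < onset + window[1])))
            rows.append({"trial_id": tr["trial_id"], "category": int(cat),
                         "count": n})
    return pd.DataFrame(rows)


@dataclass
class CategoryTuning:
    unit_id: str
    anova_p: float
    posthoc_p: float
    preferred_category: int
    selected: bool
    counts: pd.DataFrame = field(repr=False, default=None)


def category_tuning(unit_id: str, counts: pd.DataFrame, n_perm: int = 2000,
                    alpha: float = 0.05, rng=None) -> CategoryTuning:
    """Permutation ANOVA + post hoc test of one unit's presentation counts."""
    rng = make_rng(rng)
    if len(counts) < 10:
        raise ValueError(f"unit {unit_id}: fewer than 10 presentations")
    groups = [g["count"].to_numpy(float) for _, g in counts.groupby("category")]
    _, p_anova = perm_anova(groups, n_perm=n_perm, rng=rng)
    means = counts.groupby("category")["count"].mean()
    pref = int(means.idxmax())
    x = counts.loc[counts["category"] == pref, "count"].to_numpy(float)
    y = counts.loc[counts["category"] != pref, "count"].to_numpy(float)
    _, p_post = perm_ttest(x, y, n_perm=n_perm, sided="greater", rng=rng)
    return CategoryTuning(unit_id=unit_id, anova_p=p_anova, posthoc_p=p_post,
                          preferred_category=pref,
                          selected=(p_anova < alpha) and (p_post < alpha),
                          counts=counts)


def select_category_neurons(session: Session, n_perm: int = 2000,
                            rng=None) -> list[CategoryTuning]:
    """Category tuning for every unit with enough presentations."""
    rng = make_rng(rng)
    out = []
    for u in session.units:
        counts = presentation_counts(u.timestamps, session.trials)
        if len(counts) < 10:
            continue
        out.append(category_tuning(u.unit_id, counts, n_perm=n_perm, rng=rng))
    return out


def category_selection_null(tunings: list[CategoryTuning], n_shuffle: int = 500,
                            n_perm: int = 500, percentile: float = 99.0,
                            rng=None) -> dict:
    """Area-level null: reselect after shuffling category labels.

    Shuffles the category labels across presentations independently per
    shuffle, repeats the full two-test selection, and compares the observed
    count of selected units with the null's 99th percentile.
    """
    rng = make_rng(rng)
    observed = sum(t.selected for t in tunings)
    null = np.zeros(n_shuffle, int)
    for k in range(n_shuffle):
        n_sel = 0
        for t in tunings:
            shuffled = t.counts.copy()
            shuffled["category"] = rng.permutation(shuffled["category"].to_numpy())
            res = category_tuning(t.unit_id, shuffled, n_perm=n_perm, rng=rng)
            n_sel += res.selected
        null[k] = n_sel
    crit = float(np.percentile(null, percentile))
    p = float((np.sum(null >= observed) + 1) / (n_shuffle + 1))
    return {"observed": int(observed), "null_percentile": crit,
            "significant": observed > crit, "p": p, "null": null}


# ---------------------------------------------------------------------------
# PAC neurons
# ---------------------------------------------------------------------------

def build_phase_gamma_design(theta_phase: np.ndarray, gamma_amp: np.ndarray,
                             trial_idx: np.ndarray, sample_idx: np.ndarray,
                             trial_mask: np.ndarray, fs: float,
                             n_phase_bins: int = N_PHASE_BINS) -> pd.DataFrame:
    """Spike counts per (theta phase decile x gamma half) bin.

    ``theta_phase`` / ``gamma_amp`` are trials x time over the maintenance
    window; gamma amplitude is median-split into low/high across all included
    trials; phases fall into 10 fixed 36-degree bins.  ``exposure`` is the
    time (s) the LFP spent in each bin, used as the GLM offset; empty bins
    are recorded with occupancy 0.
    """
    trial_mask = np.asarray(trial_mask, bool)
    phase = theta_phase[trial_mask].ravel()
    amp = gamma_amp[trial_mask].ravel()
    high = amp > np.median(amp)

    pbin = np.floor((phase + np.pi) / (2 * np.pi / n_phase_bins)).astype(int)
    pbin = np.clip(pbin, 0, n_phase_bins - 1)

    keep = trial_mask[trial_idx]
    tidx = trial_idx[keep]
    sidx = sample_idx[keep]
    # map (trial, sample) onto the concatenated axis of included trials
    order = np.cumsum(trial_mask) - 1
    n_time = theta_phase.shape[1]
    flat = order[tidx] * n_time + sidx
    spike_bins = pbin[flat]
    spike_high = high[flat]

    centres = -np.pi + (np.arange(n_phase_bins) + 0.5) * 2 * np.pi / n_phase_bins
    rows = []
    for g in (0, 1):
        for b in range(n_phase_bins):
            occ = np.sum((pbin == b) & (high == bool(g))) / fs
            sc = int(np.sum((spike_bins == b) & (spike_high == bool(g))))
            rows.append({"phase_bin": b, "phase_centre": centres[b],
                         "gamma_high": g, "count": sc, "exposure": occ})
    return pd.DataFrame(rows)


def _design_matrices(design: pd.DataFrame):
    cos = np.cos(design["phase_centre"].to_numpy())
    sin = np.sin(design["phase_centre"].to_numpy())
    g = design["gamma_high"].to_numpy(float)
    one = np.ones_like(g)
    X1 = np.column_stack([one, cos, sin, g, cos * g, sin * g])
    X2 = np.column_stack([one, cos, sin, g])
    X3 = np.column_stack([one, cos, sin, cos * g, sin * g])
    return X1, X2, X3


@dataclass
class PACNeuronFit:
    """Model comparison for one unit over its channel combinations."""

    unit_id: str
    selected: bool
    chosen_channel: str | None
    table: pd.DataFrame  # per (channel, load): deviances, LR p-values, R^2


def fit_pac_models(design: pd.DataFrame, use_offset: bool = True,
                   r2_kind: str = "corr") -> dict:
    """Fit the three nested Poisson GLMs on one 20-bin design.

    Returns deviances, log-likelihoods, LR statistics and p-values
    (model 1 vs 2: df 2; model 1 vs 3: df 1) and the full-model R^2
    (squared correlation of observed and fitted counts by default;
    ``r2_kind="deviance"`` for the pseudo-R^2 alternative).
    """
    import statsmodels.api as sm

    if design["count"].sum() < 1:
        raise ValueError("design has no spikes")
    d = design[design["exposure"] > 0]
    y = d["count"].to_numpy(float)
    offset = np.log(d["exposure"].to_numpy()) if use_offset else None
    X1, X2, X3 = _design_matrices(d)

    def fit(X):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(y, X, family=sm.families.Poisson(),
                          offset=offset).fit(maxiter=200)

    f1, f2, f3 = fit(X1), fit(X2), fit(X3)
    lr12 = max(2 * (f1.llf - f2.llf), 0.0)
    lr13 = max(2 * (f1.llf - f3.llf), 0.0)
    p12 = float(sps.chi2.sf(lr12, df=2))
    p13 = float(sps.chi2.sf(lr13, df=1))
    fitted = f1.fittedvalues
    if r2_kind == "corr":
        r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2) if y.std() > 0 else 0.0
    else:
        null = fit(np.ones((len(y), 1)))
        r2 = float(1 - f1.deviance / null.deviance) if null.deviance > 0 else 0.0
    return {"deviance_m1": float(f1.deviance), "deviance_m2": float(f2.deviance),
            "deviance_m3": float(f3.deviance), "llf_m1": float(f1.llf),
            "llf_m2": float(f2.llf), "llf_m3": float(f3.llf),
            "lr_12": float(lr12), "lr_13": float(lr13),
            "lr_p_12": p12, "lr_p_13": p13, "r2_m1": r2,
            "params_m1": f1.params}


def select_pac_neuron(unit_id: str,
                      fits: dict[str, dict[str, dict]],
                      alpha: float = 0.01) -> PACNeuronFit:
    """Combine per-channel, per-load model fits into one selection decision.

    ``fits[channel][load]`` is the dict from :func:`fit_pac_models`.  Within
    each load, both LR p-value families are BH-FDR corrected across the
    unit's channel combinations; the unit is selected if any combination has
    both adjusted p-values below ``alpha`` in either load.  The chosen
    channel is the selected combination with the highest full-model R^2.
    """
    rows = []
    for chan, per_load in fits.items():
        for load, f in per_load.items():
            rows.append({"channel": chan, "load": load,
                         "lr_p_12": f["lr_p_12"], "lr_p_13": f["lr_p_13"],
                         "r2_m1": f["r2_m1"],
                         "deviance_m1": f["deviance_m1"],
                         "deviance_m2": f["deviance_m2"],
                         "deviance_m3": f["deviance_m3"]})
    table = pd.DataFrame(rows)
    table["p12_adj"] = np.nan
    table["p13_adj"] = np.nan
    for load in table["load"].unique():
        m = table["load"] == load
        table.loc[m, "p12_adj"] = fdr_bh_adjusted(table.loc[m, "lr_p_12"])
        table.loc[m, "p13_adj"] = fdr_bh_adjusted(table.loc[m, "lr_p_13"])
    hit = (table["p12_adj"] < alpha) & (table["p13_adj"] < alpha)
    table["selected_combo"] = hit
    selected = bool(hit.any())
    chosen = None
    if selected:
        chosen = str(table.loc[hit, :].sort_values("r2_m1").iloc[-1]["channel"])
    return PACNeuronFit(unit_id=unit_id, selected=selected,
                        chosen_channel=chosen, table=table)


# ---------------------------------------------------------------------------
# session-level drivers
# ---------------------------------------------------------------------------

def _channel_phase_gamma(session: Session, channel_id: str):
    """Theta phase (3-7 Hz Hilbert) and z-scored mean gamma amplitude
    (70-140 Hz, 7-cycle wavelets in 5 Hz steps) over the maintenance window."""
    from .pac import THETA_BAND
    from .spectral import (WaveletBank, hilbert_phase_amp, wavelet_transform,
                           zscored_mean_amplitude)
    ch = session.get_channel(channel_id)
    theta_phase, _ = hilbert_phase_amp(ch, THETA_BAND)
    bank = WaveletBank.fixed_cycles(ch.fs, GAMMA_DESIGN_FREQS, GAMMA_DESIGN_CYCLES)
    coeffs = wavelet_transform(ch, bank)
    gamma = zscored_mean_amplitude(coeffs)
    return theta_phase, gamma


def select_pac_neurons_session(session: Session, region: str = "hippocampus",
                               alpha: float = 0.01,
                               shuffle_rng=None) -> list[PACNeuronFit]:
    """Run the three-model selection for every unit of a region.

    Channel combinations are all LFP channels of the unit's region (the
    within-bundle set of the fixture sessions).  Designs are built per load
    from correct trials.  When ``shuffle_rng`` is given, the spike-to-LFP
    trial pairing is randomly permuted first (the selection-null surrogate:
    per-trial spike counts are preserved, the phase/amplitude relationship is
    destroyed).
    """
    from .sfc import spikes_to_samples
    trials = session.trials
    onsets = trials["maintenance_onset"].to_numpy(float)
    correct = trials["correct"].to_numpy(bool)
    loads = trials["load"].to_numpy()

    chans = [c.channel_id for c in session.channels(region)]
    cache = {c: _channel_phase_gamma(session, c) for c in chans}
    results = []
    for u in session.units:
        if u.region != region:
            continue
        trial_idx, sample_idx, _ = spikes_to_samples(
            u.timestamps, onsets, session.get_channel(chans[0]).fs)
        if shuffle_rng is not None:
            rng = make_rng(shuffle_rng)
            n = len(trials)
            perm = rng.permutation(n)
            trial_idx = perm[trial_idx]
        fits: dict[str, dict[str, dict]] = {}
        for c in chans:
            theta, gamma = cache[c]
            per_load = {}
            for ld in (1, 3):
                mask = correct & (loads == ld)
                valid = session.get_channel(c).valid_trials
                mask = mask & valid
                if mask.sum() < 5:
                    continue
                design = build_phase_gamma_design(
                    theta, gamma, trial_idx, sample_idx, mask,
                    session.get_channel(c).fs)
                if design["count"].sum() < 1:
                    continue
                try:
                    per_load[f"load{ld}"] = fit_pac_models(design)
                except Exception:
                    continue  # non-convergence: combo skipped
            if per_load:
                fits[c] = per_load
        if fits:
            results.append(select_pac_neuron(u.unit_id, fits, alpha=alpha))
    return results


def selection_null(session: Session, region: str = "hippocampus",
                   n_rep: int = 200, alpha: float = 0.01, rng=None) -> dict:
    """Population-level null for the PAC-neuron count.

    Repeats the entire selection after randomly re-pairing spikes with LFP
    trials; p is the fraction of repetitions with at least the observed
    count (resolution floor 1/(n_rep+1)).
    """
    rng = make_rng(rng)
    observed = sum(r.selected for r in
                   select_pac_neurons_session(session, region, alpha=alpha))
    null = np.zeros(n_rep, int)
    for k in range(n_rep):
        res = select_pac_neurons_session(session, region, alpha=alpha,
                                         shuffle_rng=rng)
        null[k] = sum(r.selected for r in res)
    p = float((np.sum(null >= observed) + 1) / (n_rep + 1))
    return {"observed": int(observed), "null": null, "p": p}


def overlap_independence_test(n_pac: int, n_cat: int, n_overlap: int,
                              n_total: int) -> float:
    """Right-tail hypergeometric p for the PAC/category-neuron overlap.

    Under independence the overlap of a size-``n_pac`` and a size-``n_cat``
    subset of ``n_total`` units is hypergeometric; returns
    P(overlap >= observed).  Empty selections give p = 1.
    """
    if n_pac == 0 or n_cat == 0:
        return 1.0
    return float(sps.hypergeom.sf(n_overlap - 1, n_total, n_cat, n_pac))
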