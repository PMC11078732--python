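"""Noise correlations, greedy ensemble decoding and population geometry.

Noise correlations are trial-to-trial co-fluctuations of two units' sliding
spike counts after conditioning on the stimulus; they are estimated per trial
across 101 sliding 200-ms bins and compared against a within-condition
trial-shuffle null.  Category decodability is probed with greedy forward
selection of a one-versus-one linear SVM ensemble, run with correlations
intact or removed (independent within-category trial permutation per unit).
The geometry of the code is summarized by the angle between the signal axis
(normal of the decision boundary) and the noise axis (first principal
component of category-mean-centred responses), folded into [0, 90] degrees:
noise orthogonal to signal leaves decodable information untouched, which is
how correlations can be information-*enhancing*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io_core import MAINTENANCE_WINDOW, make_rng

SLIDING_WIN = 0.2
SLIDING_STEP = 0.025

#: number of sliding bins covering the maintenance period
N_SLIDING_BINS = int(round(
    (MAINTENANCE_WINDOW[1] - MAINTENANCE_WINDOW[0]) / SLIDING_STEP)) + 1


def sliding_counts(timestamps: np.ndarray, onsets: np.ndarray,
                   win: float = SLIDING_WIN, step: float = SLIDING_STEP,
                   window: tuple[float, float] = MAINTENANCE_WINDOW) -> np.ndarray:
    """Trials x 101 sliding spike-count matrix over the maintenance period.

    Bin centres span [0, 2.5] s inclusive in 25-ms steps; each bin is the
    half-open interval [centre - win/2, centre + win/2).
    """
    timestamps = np.asarray(timestamps, float)
    onsets = np.asarray(onsets, float)
    centres = window[0] + np.arange(N_SLIDING_BINS) * step
    out = np.zeros((onsets.size, centres.size))
    if timestamps.size == 0:
        return out
    for i, onset in enumerate(onsets):
        rel = timestamps - onset
        rel = rel[(rel >= window[0] - win) & (rel < window[1] + win)]
        for j, c in enumerate(centres):
            out[i, j] = np.sum((rel >= c - win / 2) & (rel < c + win / 2))
    return out


def noise_correlation(counts_a: np.ndarray, counts_b: np.ndarray,
                      trial_mask: np.ndarray | None = None) -> float:
    """Mean within-trial Pearson r over sliding bins for one unit pair.

    Per included trial, r is computed across the 101 time bins; trials where
    either unit has zero variance are skipped.  Returns NaN if no trial is
    usable.
    """
    if trial_mask is None:
        trial_mask = np.ones(counts_a.shape[0], bool)
    rs = []
    for t in np.flatnonzero(trial_mask):
        a, b = counts_a[t], counts_b[t]
        if a.std() == 0 or b.std() == 0:
            continue
        rs.append(np.corrcoef(a, b)[0, 1])
    return float(np.mean(rs)) if rs else np.nan


def noise_correlation_null(counts_a: np.ndarray, counts_b: np.ndarray,
                           condition_labels: np.ndarray,
                           trial_mask: np.ndarray | None = None,
                           n_shuffle: int = 1000, rng=None) -> np.ndarray:
    """Within-condition trial-shuffle null of the mean pairwise r.

    Trials of unit b are permuted within each condition label so the marginal
    count distribution of each unit is untouched while the trial pairing —
    hence any genuine co-fluctuation — is destroyed.
    """
    rng = make_rng(rng)
    n = counts_a.shape[0]
    if trial_mask is None:
        trial_mask = np.ones(n, bool)
    labels = np.asarray(condition_labels)
    null = np.empty(n_shuffle)
    for k in range(n_shuffle):
        perm = np.arange(n)
        for lab in np.unique(labels[trial_mask]):
            idx = np.flatnonzero(trial_mask & (labels == lab))
            perm[idx] = rng.permutation(idx)
        null[k] = noise_correlation(counts_a, counts_b[perm], trial_mask)
    return null


def remove_noise_correlations(counts_by_unit: list[np.ndarray],
                              labels: np.ndarray, rng=None) -> list[np.ndarray]:
    """Independent within-category trial permutation per unit.

    Leaves every unit's per-category count multiset exactly intact (category
    labels stay attached to trials), but any across-unit co-fluctuation is
    destroyed.  Categories with a single trial are identity-mapped.
    """
    rng = make_rng(rng)
    labels = np.asarray(labels)
    out = []
    for counts in counts_by_unit:
        perm = np.arange(labels.size)
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if idx.size > 1:
                perm[idx] = rng.permutation(idx)
        out.append(counts[perm])
    return out


# ---------------------------------------------------------------------------
# greedy ensemble decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodingResult:
    ensemble_order: list[int]
    accuracy_curve: np.ndarray
    max_acc: float
    max_size: int
    condition: str  # "intact" | "removed"
    n_rep: int
    chance: float


def _balanced_subsample(labels: np.ndarray, rng) -> np.ndarray:
    """Trial indices subsampled to the smallest category count."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    n = counts.min()
    picks = [rng.choice(np.flatnonzero(labels == c), n, replace=False)
             for c in classes]
    return np.concatenate(picks)


def _split_accuracy(rates: np.ndarray, labels: np.ndarray, rng,
                    test_frac: float = 0.2, C: float = 1.0) -> float:
    """One 80/20 stratified split: z-score on train, linear one-vs-one SVM."""
    classes = np.unique(labels)
    train_idx, test_idx = [], []
    for c in classes:
        idx = rng.permutation(np.flatnonzero(labels == c))
        n_test = max(1, int(round(test_frac * idx.size)))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    train_idx = np.concatenate(train_idx)
    test_idx = np.concatenate(test_idx)
    mu = rates[train_idx].mean(axis=0)
    sd = rates[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (rates[train_idx] - mu) / sd
    Xte = (rates[test_idx] - mu) / sd
    clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    clf.fit(Xtr, labels[train_idx])
    return float(np.mean(clf.predict(Xte) == labels[test_idx]))


def _ensemble_accuracy(rates: np.ndarray, labels: np.ndarray, cols: list[int],
                       n_rep: int, remove_corr: bool, rng) -> float:
    acc = 0.0
    for _ in range(n_rep):
        sub = _balanced_subsample(labels, rng)
        R = rates[np.ix_(sub, cols)]
        lab = labels[sub]
        if remove_corr:
            shuffled = remove_noise_correlations(
                [R[:, j] for j in range(R.shape[1])], lab, rng)
            R = np.column_stack(shuffled)
        acc += _split_accuracy(R, lab, rng)
    return acc / n_rep


def greedy_decoding(rates: np.ndarray, labels: np.ndarray, n_rep: int = 500,
                    remove_corr: bool = False, max_size: int | None = None,
                    rng=None) -> DecodingResult:
    """Greedy forward selection of a decoding ensemble.

    ``rates``: trials x units firing-rate matrix (maintenance-period rates;
    the caller restricts to load-1 correct trials).  The best single unit is
    found first, then the unit adding most held-out accuracy, and so on until
    all units (or ``max_size``) are included.  Accuracies are means over
    ``n_rep`` category-balanced 80/20 splits; with ``remove_corr`` the
    within-category trial shuffle is re-drawn inside every repetition.  Ties
    in the greedy choice go to the lowest unit index.
    """
    rng = make_rng(rng)
    rates = np.asarray(rates, float)
    labels = np.asarray(labels)
    n_units = rates.shape[1]
    classes, counts = np.unique(labels, return_counts=True)
    if n_units < 1 or counts.min() < 2:
        raise ValueError("need >=1 unit and >=2 trials per category")
    if max_size is None:
        max_size = n_units

    chosen: list[int] = []
    curve = []
    remaining = list(range(n_units))
    while remaining and len(chosen) < max_size:
        best_acc, best_u = -1.0, None
        for u in remaining:
            acc = _ensemble_accuracy(rates, labels, chosen + [u],
                                     n_rep, remove_corr, make_rng(rng))
            if acc > best_acc + 1e-12:
                best_acc, best_u = acc, u
        chosen.append(best_u)
        remaining.remove(best_u)
        curve.append(best_acc)
    curve = np.asarray(curve)
    k = int(np.argmax(curve))
    return DecodingResult(ensemble_order=chosen, accuracy_curve=curve,
                          max_acc=float(curve[k]), max_size=k + 1,
                          condition="removed" if remove_corr else "intact",
                          n_rep=n_rep, chance=1.0 / classes.size)


def decoding_with_ablation(rates: np.ndarray, labels: np.ndarray,
                           pac_units: np.ndarray, n_rep: int = 100,
                           n_random: int = 50, rng=None) -> dict:
    """Maximal decoding before/after removing PAC units, intact vs removed.

    Also removes the same number of randomly chosen non-PAC units
    (``n_random`` draws, averaged) as the specificity control.  Requires at
    least one PAC unit and two remaining units after ablation.
    """
    rng = make_rng(rng)
    pac_units = np.asarray(pac_units, bool)
    n_units = rates.shape[1]
    non_pac = np.flatnonzero(~pac_units)
    n_pac = int(pac_units.sum())
    if n_pac == 0 or non_pac.size < 2:
        raise ValueError("need >=1 PAC unit and >=2 non-PAC units")

    out = {}
    for cond, rem in (("intact", False), ("removed", True)):
        full = greedy_decoding(rates, labels, n_rep=n_rep, remove_corr=rem,
                               rng=rng)
        ablated = greedy_decoding(rates[:, ~pac_units], labels, n_rep=n_rep,
                                  remove_corr=rem, rng=rng)
        rand_accs = []
        for _ in range(n_random):
            drop = rng.choice(non_pac, min(n_pac, non_pac.size - 2),
                              replace=False)
            keep = np.setdiff1d(np.arange(n_units), drop)
            res = greedy_decoding(rates[:, keep], labels, n_rep=max(n_rep // 4, 5),
                                  remove_corr=rem, rng=rng)
            rand_accs.append(res.max_acc)
        out[cond] = {"full": full, "pac_removed": ablated,
                     "random_removed_mean": float(np.mean(rand_accs))}
    return out


# ---------------------------------------------------------------------------
# signal / noise geometry
# ---------------------------------------------------------------------------

@dataclass
class GeometryResult:
    angle: float              # degrees in [0, 90]
    projection_sd: float
    condition: str
    n_rep: int
    per_rep_angles: np.ndarray = field(repr=False, default=None)


def _fold_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = abs(float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, 0, 1))))


def signal_noise_geometry(rates: np.ndarray, labels: np.ndarray,
                          ensemble: list[int] | None = None, n_rep: int = 50,
                          remove_corr: bool = False, center: bool = True,
                          rng=None) -> GeometryResult:
    """Angle between signal and noise axes plus signal-axis projection SD.

    Per repetition and per one-vs-one binary learner: the signal axis is the
    unit normal of the SVM decision boundary (trained on 80% of balanced
    trials); the noise axis is the first principal component of the training
    responses of the learner's two categories, mean-centred per category
    (``center=False`` uses the uncentred variant).  Angles are folded into
    [0, 90] degrees and averaged; the projection SD is the per-category SD of
    responses projected onto the signal axis, averaged over categories,
    learners and repetitions.
    """
    rng = make_rng(rng)
    rates = np.asarray(rates, float)
    labels = np.asarray(labels)
    if ensemble is not None:
        rates = rates[:, ensemble]
    if rates.shape[1] < 2:
        raise ValueError("geometry needs an ensemble of >=2 units")
    classes = np.unique(labels)

    angles, proj_sds = [], []
    for _ in range(n_rep):
        sub = _balanced_subsample(labels, rng)
        R = rates[sub]
        lab = labels[sub]
        if remove_corr:
            R = np.column_stack(remove_noise_correlations(
                [R[:, j] for j in range(R.shape[1])], lab, rng))
        mu, sd = R.mean(axis=0), R.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (R - mu) / sd
        for a_i in range(len(classes)):
            for b_i in range(a_i + 1, len(classes)):
                m = (lab == classes[a_i]) | (lab == classes[b_i])
                X, y = Z[m], lab[m]
                idx = rng.permutation(X.shape[0])
                n_tr = max(2, int(round(0.8 * idx.size)))
                tr = idx[:n_tr]
                clf = SVC(kernel="linear", C=1.0)
                try:
                    clf.fit(X[tr], y[tr])
                except ValueError as exc:
                    raise ValueError(
                        f"rank-deficient data for ensemble {ensemble}") from exc
                w = clf.coef_.ravel()
                signal_axis = w / np.linalg.norm(w)
                centred = X[tr].copy()
                if center:
                    for c in (classes[a_i], classes[b_i]):
                        cm = y[tr] == c
                        centred[cm] -= centred[cm].mean(axis=0)
                cov = np.cov(centred.T)
                evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
                noise_axis = evecs[:, int(np.argmax(evals))]
                angles.append(_fold_angle_deg(signal_axis, noise_axis))
                sds = [X[y == c] @ signal_axis for c in (classes[a_i], classes[b_i])]
                proj_sds.append(np.mean([s.std(ddof=1) for s in sds]))
    return GeometryResult(angle=float(np.mean(angles)),
                          projection_sd=float(np.mean(proj_sds)),
                          condition="removed" if remove_corr else "intact",
                          n_rep=n_rep, per_rep_angles=np.asarray(angles))


def rt_split_correlations(pairs: list[tuple[np.ndarray, np.ndarray]],
                          fast_mask: np.ndarray, slow_mask: np.ndarray,
                          min_trials: int = 5) -> pd.DataFrame:
    """Fast-minus-slow noise-correlation contrast per pair.

    ``pairs`` holds (counts_a, counts_b) sliding-count matrices; masks select
    the fast/slow RT trials (preferred-category correct trials, median split
    within load computed upstream).  Pairs with fewer than ``min_trials``
    usable trials in either split are excluded.
    """
    rows = []
    for k, (ca, cb) in enumerate(pairs):
        if fast_mask.sum() < min_trials or slow_mask.sum() < min_trials:
            continue
        r_fast = noise_correlation(ca, cb, fast_mask)
        r_slow = noise_correlation(ca, cb, slow_mask)
        rows.append({"pair": k, "r_fast": r_fast, "r_slow": r_slow,
                     "delta": r_fast - r_slow})
    return pd.DataFrame(rows)
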