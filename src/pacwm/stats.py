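"""Permutation inference, cluster correction, FDR and mixed-model contracts.

All permutation p-values use the (b + 1) / (m + 1) estimator so that no test
can report p = 0, and paired tests are implemented as sign-flips of the
pairwise differences, which is equivalent to permuting condition labels within
pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import make_rng

#: one-sided 95% point of the standard normal, the surrogate z threshold
Z_CRIT_95 = float(sps.norm.ppf(0.95))

#: Bonferroni family for the cross-regional coherence contrasts:
#: two MTL areas x three frontal areas x two cell populations
SFC_BONFERRONI_FAMILY = 2 * 3 * 2


def _perm_p(observed: float, null: np.ndarray, sided: str) -> float:
    null = np.asarray(null, dtype=float)
    m = null.size
    if sided == "two":
        b = np.sum(np.abs(null) >= abs(observed))
    elif sided == "greater":
        b = np.sum(null >= observed)
    elif sided == "less":
        b = np.sum(null <= observed)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return float((b + 1) / (m + 1))


def perm_ttest(x, y=None, *, paired: bool = False, n_perm: int = 10_000,
               sided: str = "two", rng=None) -> tuple[float, float]:
    """Permutation t-test; returns (t, p).

    Paired (or one-sample when ``y`` is None): sign-flip null on the
    differences.  Unpaired: group-label permutation null.
    """
    rng = make_rng(rng)
    x = np.asarray(x, dtype=float)
    if paired or y is None:
        d = x if y is None else x - np.asarray(y, dtype=float)
        if d.size < 2:
            raise ValueError("need at least 2 paired observations")
        sd = d.std(ddof=1)
        if sd == 0:
            warnings.warn("constant differences; p set to 1")
            return 0.0, 1.0
        t_obs = d.mean() / (sd / np.sqrt(d.size))
        signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
        flipped = signs * d
        null = flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / np.sqrt(d.size))
        return float(t_obs), _perm_p(t_obs, null, sided)

    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([x, y])
    if pooled.std(ddof=1) == 0:
        warnings.warn("constant data; p set to 1")
        return 0.0, 1.0

    def tstat(a, b):
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / a.size + vb / b.size)
        return (a.mean() - b.mean()) / se if se > 0 else 0.0

    t_obs = tstat(x, y)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = tstat(perm[: x.size], perm[x.size:])
    return float(t_obs), _perm_p(t_obs, null, sided)


def perm_anova(groups, n_perm: int = 10_000, rng=None) -> tuple[float, float]:
    """One-way permutation ANOVA over a list of 1-D samples; returns (F, p)."""
    rng = make_rng(rng)
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 observations each")
    pooled = np.concatenate(groups)
    sizes = np.array([g.size for g in groups])
    if pooled.std(ddof=1) == 0:
        warnings.warn("constant data; p set to 1")
        return 0.0, 1.0
    edges = np.cumsum(sizes)[:-1]

    def fstat(data):
        parts = np.split(data, edges)
        grand = data.mean()
        ssb = sum(p.size * (p.mean() - grand) ** 2 for p in parts)
        ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
        dfb, dfw = len(parts) - 1, data.size - len(parts)
        return (ssb / dfb) / (ssw / dfw) if ssw > 0 else np.inf

    f_obs = fstat(pooled)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = fstat(rng.permutation(pooled))
    return float(f_obs), _perm_p(f_obs, null, "greater")


@dataclass
class Cluster:
    """One supra-threshold cluster over contiguous frequency bins."""

    indices: np.ndarray
    mass: float
    sign: int
    p: float


def _find_clusters(tvals: np.ndarray, thresh: float):
    clusters = []
    for sign in (1, -1):
        above = sign * tvals > thresh
        idx = np.flatnonzero(above)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, breaks + 1):
            clusters.append((run, float(tvals[run].sum()), sign))
    return clusters


def cluster_perm_freq(diffs: np.ndarray, n_perm: int = 10_000,
                      alpha_cluster: float = 0.025, rng=None) -> list[Cluster]:
    """Cluster-based permutation test over frequencies.

    ``diffs`` is a pairs x freqs matrix of paired condition differences.
    Per-frequency t-values are thresholded at the two-sided parametric t
    critical value implied by the one-sided cluster alpha; cluster mass is the
    sum of t inside a contiguous run, compared (per sign) with the max-mass
    sign-flip null.  Returns an empty list if nothing is supra-threshold.
    """
    rng = make_rng(rng)
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n_pairs, n_freq = diffs.shape
    if n_pairs < 5:
        raise ValueError("need at least 5 pairs")
    thresh = float(sps.t.ppf(1 - alpha_cluster, n_pairs - 1))

    def tvals(d):
        sd = d.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        return d.mean(axis=0) / (sd / np.sqrt(n_pairs))

    obs = tvals(diffs)
    clusters = _find_clusters(obs, thresh)
    if not clusters:
        return []

    null_max = {1: np.zeros(n_perm), -1: np.zeros(n_perm)}
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=(n_pairs, 1))
        tperm = tvals(signs * diffs)
        perm_clusters = _find_clusters(tperm, thresh)
        for s in (1, -1):
            masses = [abs(m) for _, m, sign in perm_clusters if sign == s]
            null_max[s][i] = max(masses, default=0.0)

    out = []
    for run, mass, sign in clusters:
        p = _perm_p(abs(mass), null_max[sign], "greater")
        out.append(Cluster(indices=run, mass=mass, sign=sign, p=p))
    return sorted(out, key=lambda c: c.p)


def fdr_bh(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns the rejection mask."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    from statsmodels.stats.multitest import multipletests
    mask, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return mask


def fdr_bh_adjusted(pvals) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up q-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0)
    from statsmodels.stats.multitest import multipletests
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return adj


def mixed_glm(data: pd.DataFrame, response: str, fixed: list[str],
              groups: str, family: str = "gaussian"):
    """Mixed-effects GLM with random intercepts per group.

    Gaussian responses use REML linear mixed models; Poisson counts use a
    variational Bayes mixed GLM.  Returns a pandas DataFrame with columns
    ``coef``, ``se``, ``z``, ``p`` indexed by fixed-effect name (including the
    intercept).  Counts with strong overdispersion under the poisson family
    trigger a warning rather than silent misfit.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    formula = f"{response} ~ " + " + ".join(fixed)
    if family == "gaussian":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, data, groups=data[groups]).fit(reml=True)
        names = [n for n in fit.params.index if n != "Group Var"]
        return pd.DataFrame({
            "coef": fit.params[names], "se": fit.bse[names],
            "z": fit.params[names] / fit.bse[names], "p": fit.pvalues[names]})
    if family == "poisson":
        y = data[response].to_numpy()
        mu = max(y.mean(), 1e-9)
        if y.var() > 3 * mu:
            warnings.warn("counts look overdispersed for a poisson family")
        md = sm.PoissonBayesMixedGLM.from_formula(
            formula, {"grp": f"0 + C({groups})"}, data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit_vb()
        k = len(md.exog_names)
        coef = fit.fe_mean
        se = fit.fe_sd
        z = coef / se
        p = 2 * sps.norm.sf(np.abs(z))
        return pd.DataFrame({"coef": coef, "se": se, "z": z, "p": p},
                            index=md.exog_names[:k])
    raise ValueError(f"unknown family {family!r}")
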