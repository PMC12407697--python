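"""Repeatability and inference statistics.

Map repeatability across sessions is quantified by Spearman rank correlation
with a spatial permutation test: the null is built by shuffling the
second map's values across a fixed random 10% vertex subset (drawn once per
analysis to respect the spatial dependence of neighbouring vertices), and
the finite-null-size variability of the exceedance count k is absorbed by a
binomial 3-sigma upper bound, p = (k + 3*sqrt(n*p_hat*(1-p_hat))) / n.

Depth profiles (accuracy, percent signal change, correlation) are summarized
per depth by the mean across resampling units (participants, each entering
with the mean of their sessions), a 95% bootstrap percentile confidence
interval, a one-sided bootstrap test against chance, and Benjamini-Hochberg
FDR adjustment across depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PermutationResult:
    rho_observed: float
    n_permutations: int
    k_exceed: int
    sigma: float
    p_corrected: float
    subset_size: int
    seed: int


@dataclass(frozen=True)
class DepthInference:
    """Per-depth mean, bootstrap CI, raw and FDR-adjusted p-values."""

    depth_fractions: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray


def _valid_pairs(map1, map2):
    a = np.asarray(map1, dtype=float).ravel()
    b = np.asarray(map2, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("maps must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok]


def spearman(map1, map2) -> float:
    """Spearman rank correlation (mid-ranks for ties), missing values dropped
    pairwise."""
    a, b = _valid_pairs(map1, map2)
    if a.size < 3:
        raise ValueError("need at least 3 valid pairs")
    return float(sp_stats.spearmanr(a, b).statistic)


def binomial_correct(k: int, n: int) -> float:
    """Permutation p-value with a binomial 3-sigma upper bound.

    p_hat = k/n, sigma = sqrt(n*p_hat*(1-p_hat)), p = min(1, (k + 3*sigma)/n).
    A zero exceedance count is floored at the conventional 1/n (the raw
    formula would report an unattainable p = 0).
    """
    if n < 1 or k < 0 or k > n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    if k == 0:
        return 1.0 / n
    p_hat = k / n
    sigma = np.sqrt(n * p_hat * (1.0 - p_hat))
    return float(min(1.0, (k + 3.0 * sigma) / n))


def permutation_test(map1, map2, n_perm: int = 10000, subsample_frac: float = 0.1,
                     seed: int = 0) -> PermutationResult:
    """Spatial permutation test of the Spearman correlation of two maps.

    One random vertex subset of size ``subsample_frac * N`` is drawn once and
    fixed across permutations; the null distribution shuffles the second
    map's subset values.  Two-sided exceedance (|rho_null| >= |rho_obs|) with
    the binomial 3-sigma correction.
    """
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must lie in (0, 1]")
    a, b = _valid_pairs(map1, map2)
    rng = np.random.default_rng(seed)
    n_sub = int(round(subsample_frac * a.size))
    if n_sub < 3:
        raise ValueError("subset smaller than 3 vertices")
    sub = rng.choice(a.size, size=n_sub, replace=False)
    ra = sp_stats.rankdata(a[sub])
    rb = sp_stats.rankdata(b[sub])
    rho_obs = float(np.corrcoef(ra, rb)[0, 1])

    az = (ra - ra.mean()) / ra.std()
    bz = (rb - rb.mean()) / rb.std()
    perms = rng.permuted(np.tile(bz, (n_perm, 1)), axis=1)
    null = perms @ az / n_sub
    k = int(np.sum(np.abs(null) >= np.abs(rho_obs)))
    p_hat = k / n_perm
    sigma = float(np.sqrt(n_perm * p_hat * (1.0 - p_hat)))
    return PermutationResult(rho_observed=rho_obs, n_permutations=n_perm,
                             k_exceed=k, sigma=sigma,
                             p_corrected=binomial_correct(k, n_perm),
                             subset_size=n_sub, seed=seed)


def _resolve_rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95, seed=0):
    """Percentile bootstrap CI of the mean; resampling unit = input element
    (participant-level means).  Returns (mean, ci_low, ci_high)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    rng = _resolve_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(values.mean()), float(lo), float(hi)


def bootstrap_vs_chance(values, chance: float = 0.5, n_boot: int = 1000, seed=0) -> float:
    """One-sided bootstrap test of the mean against a chance level.

    p = fraction of bootstrap means <= chance, floored at 1/n_boot.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 resampling units")
    rng = _resolve_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    return float(max(np.mean(means <= chance), 1.0 / n_boot))


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def depth_profile_inference(profiles, depth_fractions, chance: float = 0.5,
                            n_boot: int = 1000, level: float = 0.95,
                            seed: int = 0) -> DepthInference:
    """Summarize per-unit depth profiles (units x depths) into mean, CI and
    FDR-adjusted bootstrap p-values per depth."""
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    fractions = np.asarray(depth_fractions, dtype=float)
    if profiles.shape[1] != fractions.size:
        raise ValueError("profiles and depth grid are inconsistent")
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 units")
    n_d = fractions.size
    mean = np.empty(n_d)
    lo = np.empty(n_d)
    hi = np.empty(n_d)
    p = np.empty(n_d)
    children = np.random.SeedSequence(seed).spawn(n_d)
    for d in range(n_d):
        rng = np.random.default_rng(children[d])
        mean[d], lo[d], hi[d] = bootstrap_ci(profiles[:, d], n_boot, level, seed=rng)
        p[d] = bootstrap_vs_chance(profiles[:, d], chance, n_boot, seed=rng)
    return DepthInference(depth_fractions=fractions, mean=mean, ci_low=lo,
                          ci_high=hi, p=p, p_fdr=fdr_bh(p))
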