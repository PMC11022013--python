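"""Group-comparison statistics.

Pairwise permutation tests on PC scores (Euclidean distance of group mean
score vectors, Bonferroni-corrected over pairs), distance-based PERMANOVA on
the per-square resorption matrix, and a multiple multivariate regression of
resorption on the log of centroid size with a permutation test of the
multivariate R^2.

All p-values use the conservative (b + 1) / (m + 1) estimator, so they are
bounded below by 1 / (n_perm + 1) and never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass
class PermutationTestResult:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    n_perm: int
    seed: int


@dataclass
class PERMANOVAResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    pairwise: list = field(default_factory=list)


@dataclass
class RegressionResult:
    coefficients: np.ndarray     # p response slopes vs ln(CS)
    intercepts: np.ndarray
    R2_multivariate: float
    p_perm: float
    n_perm: int


def _group_indices(labels) -> dict:
    labels = np.asarray(labels)
    return {g: np.nonzero(labels == g)[0] for g in np.unique(labels)}


def _mean_distance_statistic(X: np.ndarray, na: int) -> float:
    """Euclidean distance between the mean vectors of X[:na] and X[na:]."""
    return float(np.linalg.norm(X[:na].mean(axis=0) - X[na:].mean(axis=0)))


def _pooled_t2_statistic(X: np.ndarray, na: int) -> float:
    """Hotelling-type statistic: squared mean distance scaled by pooled
    variance (alternative between-group statistic)."""
    a, b = X[:na], X[na:]
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = (np.sum((a - a.mean(axis=0)) ** 2)
              + np.sum((b - b.mean(axis=0)) ** 2)) / (len(X) - 2)
    if pooled <= 0:
        return np.inf if np.any(diff) else 0.0
    return float((diff @ diff) / pooled)


def permutation_test_pc_scores(scores: np.ndarray, labels,
                               k_components: int = 3,
                               n_perm: int = 1000, seed: int = 0,
                               pairs=None,
                               statistic: str = "mean_distance",
                               method: str = "monte_carlo"
                               ) -> list[PermutationTestResult]:
    """Pairwise permutation tests on the first ``k_components`` PC scores.

    For each pair of groups the observed statistic (Euclidean distance
    between group mean score vectors by default) is compared against the
    distribution obtained by reshuffling the pair's labels; Bonferroni
    correction multiplies raw p-values by the number of pairs tested.

    ``method="exhaustive"`` enumerates every distinct assignment of the
    pair's labels instead of sampling; the p-value is then the exact
    fraction of assignments (including the observed one) whose statistic
    reaches the observed value.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if k_components > scores.shape[1]:
        raise ValueError(f"k_components={k_components} exceeds available "
                         f"components ({scores.shape[1]})")
    X = scores[:, :k_components]
    groups = _group_indices(labels)
    for g, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 specimens")
    if pairs is None:
        pairs = list(combinations(sorted(groups), 2))
    stat_fn = {"mean_distance": _mean_distance_statistic,
               "pooled_t2": _pooled_t2_statistic}[statistic]

    results = []
    m = len(pairs)
    rng = np.random.default_rng(seed)
    for pair in pairs:
        ia, ib = groups[pair[0]], groups[pair[1]]
        sub = np.vstack([X[ia], X[ib]])
        na = len(ia)
        obs = stat_fn(sub, na)
        if method == "exhaustive":
            total = hits = 0
            for chosen in combinations(range(len(sub)), na):
                rest = [i for i in range(len(sub)) if i not in chosen]
                order = np.asarray(list(chosen) + rest)
                total += 1
                if stat_fn(sub[order], na) >= obs - 1e-12:
                    hits += 1
            p_raw = hits / total
            n_eff = total
        elif method == "monte_carlo":
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(len(sub))
                if stat_fn(sub[perm], na) >= obs:
                    hits += 1
            p_raw = (hits + 1) / (n_perm + 1)
            n_eff = n_perm
        else:
            raise ValueError(f"unknown method {method!r}")
        results.append(PermutationTestResult(
            pair=tuple(pair), statistic=obs, p_raw=p_raw,
            p_adjusted=min(1.0, m * p_raw), n_perm=n_eff, seed=seed))
    return results


def _permanova_ss(d2: np.ndarray, groups: dict) -> tuple[float, float]:
    """Total and within-group sums of squares from squared distances."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for idx in groups.values():
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2 * len(idx))
    return ss_total, ss_within


def permanova(data: np.ndarray, labels, n_perm: int = 1000, seed: int = 0,
              pairwise: bool = False) -> PERMANOVAResult:
    """Distance-based PERMANOVA on a specimens x variables matrix.

    Uses Euclidean distances; pseudo-F follows the standard decomposition
    F = (SS_A / (a - 1)) / (SS_W / (N - a)), with the p-value from full
    label reshuffles. With ``pairwise=True`` all group pairs are also
    tested, Bonferroni-adjusted.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    groups = _group_indices(labels)
    a = len(groups)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    for g, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 specimens")
    n = X.shape[0]
    d2 = squareform(pdist(X, metric="sqeuclidean"))

    def f_stat(lbls) -> tuple[float, float, float]:
        gidx = _group_indices(lbls)
        ss_total, ss_within = _permanova_ss(d2, gidx)
        ss_between = ss_total - ss_within
        denom = ss_within / (n - a)
        if denom <= 0:
            return np.inf, ss_between, ss_within
        return (ss_between / (a - 1)) / denom, ss_between, ss_within

    F_obs, ss_b, ss_w = f_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        F_perm, _, _ = f_stat(labels[rng.permutation(n)])
        if F_perm >= F_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    ss_total = ss_b + ss_w
    result = PERMANOVAResult(pseudo_F=float(F_obs),
                             R2=float(ss_b / ss_total), p=p, n_perm=n_perm,
                             ss_between=float(ss_b), ss_within=float(ss_w),
                             ss_total=float(ss_total),
                             df_between=a - 1, df_within=n - a)
    if pairwise:
        m = len(list(combinations(sorted(groups), 2)))
        rows = []
        for pair in combinations(sorted(groups), 2):
            sel = np.isin(labels, pair)
            sub = permanova(X[sel], labels[sel], n_perm=n_perm, seed=seed)
            rows.append(PermutationTestResult(
                pair=pair, statistic=sub.pseudo_F, p_raw=sub.p,
                p_adjusted=min(1.0, m * sub.p), n_perm=n_perm, seed=seed))
        result.pairwise = rows
    return result


def regress_bm_on_size(bm: np.ndarray, centroid_sizes: np.ndarray,
                       n_perm: int = 1000, seed: int = 0) -> RegressionResult:
    """Multiple multivariate regression of %BR on ln(centroid size).

    Each resorption variable is regressed on log size by least squares; the
    multivariate R^2 is 1 - tr(E)/tr(T) (residual vs total cross-product
    traces) and its significance comes from permuting sizes across
    specimens.
    """
    Y = np.asarray(bm, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    cs = np.asarray(centroid_sizes, dtype=float)
    if np.any(cs <= 0):
        raise ValueError("centroid sizes must be positive")
    if len(cs) != len(Y) or len(Y) <= 3:
        raise ValueError("need matching sizes and n > 3")
    x = np.log(cs)
    if np.ptp(x) == 0:
        raise ValueError("constant centroid size: regression undefined")

    def r2(xv: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        xc = xv - xv.mean()
        Yc = Y - Y.mean(axis=0)
        slopes = (xc @ Yc) / (xc @ xc)
        resid = Yc - np.outer(xc, slopes)
        trT = float(np.sum(Yc ** 2))
        trE = float(np.sum(resid ** 2))
        return 1.0 - trE / trT, slopes, resid

    R2_obs, slopes, _ = r2(x)
    intercepts = Y.mean(axis=0) - slopes * x.mean()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        R2_perm, _, _ = r2(x[rng.permutation(len(x))])
        if R2_perm >= R2_obs:
            hits += 1
    return RegressionResult(coefficients=slopes, intercepts=intercepts,
                            R2_multivariate=float(R2_obs),
                            p_perm=(hits + 1) / (n_perm + 1), n_perm=n_perm)
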