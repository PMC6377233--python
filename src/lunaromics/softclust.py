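"""Fuzzy c-means soft clustering of mean expression profiles.

Profiles (features x condition means) are z-scored per feature, the fuzziness
exponent m is estimated from the data dimensions, and cluster number can be
chosen from an average-linkage dendrogram elbow.  Cluster memberships in
[0, 1] (rows summing to 1) measure how well each feature fits each cluster's
mean profile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist, pdist

logger = logging.getLogger(__name__)


def standardize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-score (mean 0, sd 1 with n-1 denominator) across conditions.

    Zero-variance features cannot be standardised and are dropped with a log
    message.
    """
    mat = profiles.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance features before clustering", (~keep).sum())
    mat = mat[keep]
    z = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, ddof=1, keepdims=True)
    return pd.DataFrame(z, index=profiles.index[keep], columns=profiles.columns)


def estimate_fuzziness(n_features: int, n_conditions: int) -> float:
    """Data-driven fuzziness exponent m (always > 1).

    ``m = 1 + (1418/N + 22.05) D^-2
           + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)``
    with N features and D conditions (the dimension-based estimate of
    Schwaemmle & Jensen used by Mfuzz-style workflows).
    """
    if n_features < 2:
        raise ValueError("need at least 2 features")
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    n, d = float(n_features), float(n_conditions)
    term1 = (1418.0 / n + 22.05) * d ** -2.0
    term2 = (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    return 1.0 + term1 + term2


def _kmeanspp_init(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style centroid seeding."""
    n = len(x)
    centroids = [x[rng.integers(n)]]
    for _ in range(1, c):
        d2 = np.min(cdist(x, np.array(centroids), "sqeuclidean"), axis=1)
        total = d2.sum()
        if total <= 0:
            centroids.append(x[rng.integers(n)])
            continue
        centroids.append(x[rng.choice(n, p=d2 / total)])
    return np.array(centroids)


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int,
    m: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fuzzy c-means clustering; returns (memberships, centroids).

    Alternating updates ``u_ij = 1 / sum_k (||x_i - v_j|| / ||x_i - v_k||)^{2/(m-1)}``
    and ``v_j = sum_i u_ij^m x_i / sum_i u_ij^m`` until the largest membership
    change drops below ``tol``; the weighted objective is non-increasing.  A
    feature coincident with a centroid receives membership 1 there.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    x = profiles.to_numpy(dtype=float)
    n = len(x)
    if m is None:
        m = estimate_fuzziness(n, x.shape[1])
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")
    rng = np.random.default_rng(seed)
    if c == 1:
        u = np.ones((n, 1))
        v = x.mean(axis=0, keepdims=True)
    else:
        v = _kmeanspp_init(x, c, rng)
        u = _memberships(x, v, m)
        for _ in range(max_iter):
            w = u ** m
            v = (w.T @ x) / w.sum(axis=0)[:, None]
            u_new = _memberships(x, v, m)
            change = np.max(np.abs(u_new - u))
            u = u_new
            if change < tol:
                break
    members = pd.DataFrame(
        u, index=profiles.index, columns=[f"cluster_{j + 1}" for j in range(c)]
    )
    centroids = pd.DataFrame(
        v, index=[f"cluster_{j + 1}" for j in range(c)], columns=profiles.columns
    )
    return members, centroids


def _memberships(x: np.ndarray, v: np.ndarray, m: float) -> np.ndarray:
    d2 = cdist(x, v, "sqeuclidean")
    coincident = d2 <= 1e-300
    # work relative to each feature's nearest centroid so small m (hard
    # limit) cannot overflow the power
    dmin = d2.min(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (d2 / dmin) ** (-1.0 / (m - 1.0))
        u = t / t.sum(axis=1, keepdims=True)
    hit = coincident.any(axis=1)
    if hit.any():
        u[hit] = coincident[hit] / coincident[hit].sum(axis=1, keepdims=True)
    return u


def fcm_objective(x: np.ndarray, u: np.ndarray, v: np.ndarray, m: float) -> float:
    return float(np.sum(u ** m * cdist(x, v, "sqeuclidean")))


def select_cluster_count(profiles: pd.DataFrame, c_range) -> int:
    """Dendrogram-elbow choice of cluster number.

    Average-linkage hierarchical clustering on Euclidean distances; the
    returned c maximises the relative drop in merge height between successive
    tree cuts within ``c_range`` (deterministic).
    """
    c_range = sorted(set(int(c) for c in c_range))
    n = len(profiles)
    if not c_range:
        raise ValueError("empty c_range")
    if c_range[0] < 2 or c_range[-1] > n - 1:
        raise ValueError("c_range must lie within [2, n_features - 1]")
    if len(c_range) == 1:
        return c_range[0]
    d = pdist(profiles.to_numpy(dtype=float))
    if np.allclose(d, d[0]):
        logger.warning("degenerate distance matrix; returning min(c_range)")
        return c_range[0]
    heights = linkage(d, method="average")[:, 2]
    # cutting into c clusters removes the last c-1 merges; the merge height
    # at that cut is heights[n - c]
    scores = {}
    for c in c_range:
        h_cut = heights[n - c]
        h_next = heights[n - c - 1] if n - c - 1 >= 0 else h_cut
        scores[c] = (h_cut - h_next) / h_cut if h_cut > 0 else 0.0
    return max(scores, key=lambda c: (scores[c], -c))
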