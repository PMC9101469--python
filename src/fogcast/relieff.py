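"""Relief-F feature ranking (Kononenko's extension, binary case).

Relief-F scores a feature by contrasting its values between each instance
and its nearest neighbours: features that agree among the *k* nearest
same-class neighbours (hits) and differ among the *k* nearest other-class
neighbours (misses) receive positive weight. With two classes the
prior-probability miss weighting of the multi-class algorithm reduces to 1,
so the update is

    W_f += sum_misses diff_f / (m k)  -  sum_hits diff_f / (m k)

where ``diff_f`` is the absolute difference on the min–max scaled feature
and ``m`` the number of sampled instances. Features constant over the data
receive weight exactly 0. Distances are normalized Manhattan distances on
the scaled features. Neighbour ties are broken by instance index, and tied
weights rank in catalog order, so rankings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ReliefFConfig", "FeatureRanking", "relieff_rank", "top_n"]


@dataclass(frozen=True)
class ReliefFConfig:
    """Relief-F settings.

    ``n_sampling="all"`` scores every instance (deterministic); an integer
    subsamples instances without replacement using ``seed``.
    """

    k_neighbors: int = 10
    n_sampling: object = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class FeatureRanking:
    weights: np.ndarray
    order: np.ndarray  # permutation of feature indices, best first
    config: ReliefFConfig


def relieff_rank(features, labels, config: ReliefFConfig = ReliefFConfig()) -> FeatureRanking:
    """Rank features by Relief-F weight on a binary-labeled window matrix."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (instances × features) matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size != 2:
        raise ValueError("Relief-F needs exactly two classes present")
    counts = np.bincount(y_idx)
    k = config.k_neighbors
    if k >= counts.min():
        raise ValueError(
            f"k_neighbors={k} must be smaller than the minority class size "
            f"({counts.min()}); reduce k or supply more minority windows"
        )

    m_total, n_feat = X.shape
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    constant = span == 0
    scale = np.where(constant, 1.0, span)
    Z = (X - lo) / scale
    Z[:, constant] = 0.0

    if config.n_sampling == "all" or config.n_sampling is None:
        sampled = np.arange(m_total)
    else:
        n_s = min(int(config.n_sampling), m_total)
        rng = np.random.default_rng(config.seed)
        sampled = np.sort(rng.choice(m_total, size=n_s, replace=False))
    m = sampled.size

    weights = np.zeros(n_feat)
    same = [np.flatnonzero(y_idx == c) for c in range(2)]
    for i in sampled:
        dist = np.abs(Z - Z[i]).sum(axis=1) / n_feat
        own = y_idx[i]
        hit_pool = same[own][same[own] != i]
        miss_pool = same[1 - own]
        hits = hit_pool[np.argsort(dist[hit_pool], kind="stable")[:k]]
        misses = miss_pool[np.argsort(dist[miss_pool], kind="stable")[:k]]
        diff_hits = np.abs(Z[hits] - Z[i]).sum(axis=0)
        diff_miss = np.abs(Z[misses] - Z[i]).sum(axis=0)
        weights += (diff_miss - diff_hits) / (m * k)
    weights[constant] = 0.0

    order = np.lexsort((np.arange(n_feat), -weights))
    return FeatureRanking(weights=weights, order=order, config=config)


def top_n(ranking: FeatureRanking, n: int) -> np.ndarray:
    """Indices of the ``n`` best-ranked features (subsets nest by design)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > ranking.order.size:
        raise ValueError(f"n={n} exceeds the catalog size {ranking.order.size}")
    return ranking.order[:n].copy()
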