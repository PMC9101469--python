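"""RUSBoost: AdaBoost with per-iteration random undersampling of the
majority class, over split-limited decision trees.

Freeze-prediction window sets are heavily imbalanced (few target windows per
trial), so each boosting iteration draws a balanced subsample — all minority
windows plus an equal number of majority windows — fits a small tree on it,
but measures the weighted error and reweights on the *full* training set, so
learner weights reflect true performance (Seiffert-style RUSBoost, two-class
AdaBoost core).

Trees are axis-aligned, grown best-first by weighted Gini gain, with at most
``max_splits`` internal nodes (5 by default, matching 100-tree ensembles of
5-split trees). The ensemble score of a window is
``Σ α_t (p_t(target) − ½)``; positive score → target, with ties resolved to
non-target (the conservative choice for a cueing system: fewer cues).
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RUSBoostConfig",
    "LimitedTree",
    "RUSBoostEnsemble",
    "fit_limited_tree",
    "rus_sample",
    "fit_rusboost",
    "predict",
]

_ALPHA_CAP = 0.5 * np.log(1e10)


@dataclass(frozen=True)
class RUSBoostConfig:
    n_learners: int = 100
    max_splits: int = 5
    target_class_ratio: float = 1.0  # majority:minority after undersampling
    learning_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        if self.max_splits < 1:
            raise ValueError("max_splits must be >= 1")
        if self.target_class_ratio <= 0:
            raise ValueError("target_class_ratio must be positive")


class LimitedTree:
    """Binary decision tree with at most ``max_splits`` internal nodes.

    Nodes are nested dicts: internal nodes carry ``feature``/``threshold``
    (``x[feature] <= threshold`` goes left), leaves carry ``score`` — the
    weighted probability of the target class.
    """

    def __init__(self, root: dict, n_features: int):
        self.root = root
        self.n_features = n_features

    def n_internal_nodes(self) -> int:
        def count(node):
            if "score" in node:
                return 0
            return 1 + count(node["left"]) + count(node["right"])

        return count(self.root)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])

        def fill(node, idx):
            if "score" in node:
                out[idx] = node["score"]
                return
            go_left = X[idx, node["feature"]] <= node["threshold"]
            fill(node["left"], idx[go_left])
            fill(node["right"], idx[~go_left])

        fill(self.root, np.arange(X.shape[0]))
        return out

    def predict_class(self, X) -> np.ndarray:
        return self.predict_proba(X) > 0.5

    def to_dict(self) -> dict:
        return {"root": self.root, "n_features": self.n_features}

    @classmethod
    def from_dict(cls, d: dict) -> "LimitedTree":
        return cls(d["root"], d["n_features"])


def _gini(p: np.ndarray) -> np.ndarray:
    return 2.0 * p * (1.0 - p)


def _best_split(X, y, w, idx):
    """Best weighted-Gini split over one node's instances.

    Returns (gain, feature, threshold, left_idx, right_idx) or None.
    """
    w_node = w[idx]
    W = w_node.sum()
    if W <= 0:
        return None
    T = w_node[y[idx]].sum()
    p_node = T / W
    if p_node in (0.0, 1.0):
        return None
    parent_impurity = W * 2.0 * p_node * (1.0 - p_node)
    best = None
    for j in range(X.shape[1]):
        xj = X[idx, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        ws = w_node[order]
        ts = np.where(y[idx][order], ws, 0.0)
        cw = np.cumsum(ws)[:-1]
        ct = np.cumsum(ts)[:-1]
        valid = np.diff(xs) > 0
        if not valid.any():
            continue
        W_L, T_L = cw[valid], ct[valid]
        W_R, T_R = W - W_L, T - T_L
        with np.errstate(invalid="ignore", divide="ignore"):
            p_L = np.where(W_L > 0, T_L / W_L, 0.0)
            p_R = np.where(W_R > 0, T_R / W_R, 0.0)
        children = W_L * _gini(p_L) + W_R * _gini(p_R)
        gains = parent_impurity - children
        pos = int(np.argmax(gains))
        gain = float(gains[pos])
        if best is None or gain > best[0] + 1e-15:
            cut = np.flatnonzero(valid)[pos]
            threshold = 0.5 * (xs[cut] + xs[cut + 1])
            best = (gain, j, float(threshold))
    if best is None or best[0] <= 1e-12:
        return None
    gain, j, threshold = best
    mask = X[idx, j] <= threshold
    return gain, j, threshold, idx[mask], idx[~mask]


def fit_limited_tree(features, labels, instance_weights, max_splits: int = 5) -> LimitedTree:
    """Grow a tree best-first by weighted Gini gain, capped at ``max_splits``
    internal nodes; growth also stops at node purity or zero gain."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    w = np.asarray(instance_weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("instance weights must have positive total mass")
    if y[w > 0].all() or not y[w > 0].any():
        pass  # single-class nodes are allowed; the tree is a single leaf

    def leaf(idx):
        w_node = w[idx]
        W = w_node.sum()
        score = float(w_node[y[idx]].sum() / W) if W > 0 else 0.5
        return {"score": score}

    root_idx = np.arange(X.shape[0])
    root = leaf(root_idx)
    heap = []
    counter = 0  # FIFO tie-break for equal gains → deterministic growth
    split = _best_split(X, y, w, root_idx)
    if split is not None:
        heapq.heappush(heap, (-split[0], counter, root, split))
        counter += 1
    n_internal = 0
    while heap and n_internal < max_splits:
        _, _, node, (gain, j, threshold, left_idx, right_idx) = heapq.heappop(heap)
        node.clear()
        node["feature"] = int(j)
        node["threshold"] = float(threshold)
        node["left"] = leaf(left_idx)
        node["right"] = leaf(right_idx)
        n_internal += 1
        for child, child_idx in ((node["left"], left_idx), (node["right"], right_idx)):
            child_split = _best_split(X, y, w, child_idx)
            if child_split is not None:
                heapq.heappush(heap, (-child_split[0], counter, child, child_split))
                counter += 1
    return LimitedTree(root, X.shape[1])


def rus_sample(labels, ratio: float, rng: np.random.Generator) -> np.ndarray:
    """Random undersampling: keep every minority instance, draw majority
    instances without replacement to a majority:minority ratio of ``ratio``
    (count rounded down). Returns sorted instance indices."""
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to undersample")
    minority_mask = y if n_pos <= n_neg else ~y
    minority = np.flatnonzero(minority_mask)
    majority = np.flatnonzero(~minority_mask)
    n_keep = min(int(ratio * minority.size), majority.size)
    kept = rng.choice(majority, size=n_keep, replace=False)
    return np.sort(np.concatenate([minority, kept]))


@dataclass
class RUSBoostEnsemble:
    trees: list
    alphas: list
    config: RUSBoostConfig
    n_features: int
    training_log: list = field(default_factory=list)  # per-iteration weighted error
    weight_sums: list = field(default_factory=list)  # instance-weight mass per iteration
    stopped_early_at: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config.__dict__,
                "n_features": self.n_features,
                "alphas": self.alphas,
                "trees": [t.to_dict() for t in self.trees],
                "training_log": self.training_log,
                "stopped_early_at": self.stopped_early_at,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RUSBoostEnsemble":
        d = json.loads(text)
        return cls(
            trees=[LimitedTree.from_dict(t) for t in d["trees"]],
            alphas=d["alphas"],
            config=RUSBoostConfig(**d["config"]),
            n_features=d["n_features"],
            training_log=d["training_log"],
            stopped_early_at=d["stopped_early_at"],
        )


def fit_rusboost(features, labels, config: RUSBoostConfig = RUSBoostConfig()) -> RUSBoostEnsemble:
    """Boost split-limited trees with per-iteration undersampling.

    Instance weights are maintained over the full training set. Each
    iteration: undersample, fit a tree on the sampled weighted data, measure
    the weighted error ε on the full set, set α = lr·½·ln((1−ε)/ε)
    (capped at ½·ln(1e10) when ε = 0), multiply weights by e^{±α} and
    renormalize. An iteration with ε ≥ ½ is discarded and resampled, up to
    10 retries; persistent failure on the first iteration raises, later it
    stops the ensemble early.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    D = np.full(n, 1.0 / n)
    trees, alphas, log, weight_sums = [], [], [], []
    stopped = None
    for t in range(config.n_learners):
        fitted = None
        for _ in range(10):
            idx = rus_sample(y, config.target_class_ratio, rng)
            tree = fit_limited_tree(X[idx], y[idx], D[idx], config.max_splits)
            pred = tree.predict_class(X)
            err = float(D[pred != y].sum())
            if err < 0.5:
                fitted = (tree, pred, err)
                break
        if fitted is None:
            if t == 0:
                raise RuntimeError(
                    "RUSBoost could not find a weak learner with weighted "
                    "error < 0.5 on the first iteration; the classes may be "
                    "indistinguishable in the selected features"
                )
            stopped = t
            logger.warning("RUSBoost stopped early at iteration %d", t)
            break
        tree, pred, err = fitted
        alpha = _ALPHA_CAP if err == 0.0 else min(
            config.learning_rate * 0.5 * np.log((1.0 - err) / err), _ALPHA_CAP
        )
        D = D * np.exp(np.where(pred != y, alpha, -alpha))
        D = D / D.sum()
        weight_sums.append(float(D.sum()))
        trees.append(tree)
        alphas.append(float(alpha))
        log.append(err)
    return RUSBoostEnsemble(
        trees=trees, alphas=alphas, config=config,
        n_features=X.shape[1], training_log=log, weight_sums=weight_sums,
        stopped_early_at=stopped,
    )


def predict(ensemble: RUSBoostEnsemble, features):
    """Ensemble decision per window.

    Returns ``(classes, scores)``; ``score = Σ α (p_target − ½)`` and the
    class is target iff the score is strictly positive.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != ensemble.n_features:
        raise ValueError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"ensemble was trained on {ensemble.n_features}"
        )
    scores = np.zeros(X.shape[0])
    for tree, alpha in zip(ensemble.trees, ensemble.alphas):
        scores += alpha * (tree.predict_proba(X) - 0.5)
    return scores > 0, scores
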