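"""Factor-importance ranking by four routes.

* Garson weight decomposition of a single-hidden-layer network
* ANOVA F-test on the linear terms of the quadratic refit
* random-forest impurity importance
* gradient-boosted-tree impurity importance

The tree ensembles are built in-package on a shared CART regression-tree
primitive (the datasets are desk-scale: tens of rows, four features), so
ranks are bit-reproducible under a pinned seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ann import AnnModel
from .design import DesignTable
from .rsm import AnovaTable

__all__ = [
    "ImportanceResult",
    "TreeEnsembleConfig",
    "RegressionTree",
    "garson",
    "f_test_rank",
    "fit_cart",
    "rf_importance",
    "gbrt_importance",
    "rank_table",
]


def ranks_from_scores(scores: np.ndarray) -> np.ndarray:
    """Dense ranks, 1 = largest score; ties broken by factor order."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


@dataclass
class ImportanceResult:
    method: str                       # garson | f_test | rf | gbrt
    scores: np.ndarray                # (4,)
    ranks: np.ndarray = field(default=None)  # type: ignore[assignment]
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.ranks is None:
            self.ranks = ranks_from_scores(self.scores)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "scores": [float(s) for s in self.scores],
            "ranks": [int(r) for r in self.ranks],
            "factors": self.factor_names,
        }


@dataclass
class TreeEnsembleConfig:
    """Hyperparameters shared by the RF and GBRT rankers."""

    n_trees: int = 500
    max_depth: int = 3
    min_leaf: int = 1
    learning_rate: float = 0.1   # GBRT only
    bootstrap: bool = True       # RF only
    max_features: int | None = 2  # per-split feature subsample (RF only)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in (0, 1]")


def garson(model: AnnModel) -> ImportanceResult:
    """Garson weight-product decomposition, normalized to percentage shares.

    For hidden unit e with input weights w_ae and output weight w_e, input a
    receives the share ``(|w_ae| / sum_a' |w_a'e|) * |w_e|``; summing over
    hidden units and normalizing across inputs gives percentages that sum to
    100.  A hidden unit whose input weights are all zero contributes nothing
    (no division blow-up).
    """
    W = np.abs(model.input_weights)          # (h, 4)
    wo = np.abs(model.layer_weights)         # (h,)
    row_sum = W.sum(axis=1)
    safe = row_sum > 0
    contrib = np.zeros_like(W)
    contrib[safe] = W[safe] / row_sum[safe, None] * wo[safe, None]
    raw = contrib.sum(axis=0)
    total = raw.sum()
    scores = (
        100.0 * raw / total if total > 0 else np.full(4, 25.0)
    )
    return ImportanceResult(method="garson", scores=scores)


def f_test_rank(anova_table: AnovaTable) -> ImportanceResult:
    """Rank the four factors by their linear-term ANOVA F values."""
    f_values = np.array([anova_table.row(letter).f for letter in "ABCD"], float)
    return ImportanceResult(
        method="f_test",
        scores=f_values,
        factor_names=list(anova_table.factor_names),
    )


class RegressionTree:
    """CART regression tree: binary splits minimizing residual SS.

    Deterministic given the data and configuration; candidate thresholds are
    midpoints between consecutive distinct feature values, scanned in
    (feature, threshold) order so ties resolve identically on every run.
    Accumulates impurity decrease per feature in ``importances_``.
    """

    def __init__(self, max_depth=3, min_leaf=1, max_features=None, rng=None):
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.max_features = max_features
        self.rng = rng
        self.nodes: list[tuple] = []  # (feature, threshold, left, right) | (None, value)
        self.importances_: np.ndarray | None = None

    @staticmethod
    def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
        """Best (threshold, sse_decrease) on one feature, or None."""
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        n = len(y)
        csum = np.cumsum(ys)
        csq = np.cumsum(ys**2)
        total_sse = csq[-1] - csum[-1] ** 2 / n
        best = None
        for i in range(min_leaf, n - min_leaf + 1):
            if i < n and xs[i - 1] == xs[i]:
                continue
            if i == n:
                break
            nl, nr = i, n - i
            sl, sr = csum[i - 1], csum[-1] - csum[i - 1]
            ql = csq[i - 1] - sl**2 / nl
            qr = (csq[-1] - csq[i - 1]) - sr**2 / nr
            dec = total_sse - ql - qr
            if best is None or dec > best[1] + 1e-15:
                best = ((xs[i - 1] + xs[i]) / 2.0, dec)
        return best

    def _grow(self, X, y, depth):
        node_id = len(self.nodes)
        self.nodes.append(None)  # placeholder
        if depth >= self.max_depth or len(y) < 2 * self.min_leaf or np.ptp(y) == 0:
            self.nodes[node_id] = (None, float(y.mean()))
            return node_id
        n_feat = X.shape[1]
        feats = np.arange(n_feat)
        if self.max_features is not None and self.max_features < n_feat:
            feats = np.sort(
                self.rng.choice(n_feat, size=self.max_features, replace=False)
            )
        best = None  # (dec, feature, threshold)
        for f in feats:
            cand = self._best_split(X[:, f], y, self.min_leaf)
            if cand is not None and (best is None or cand[1] > best[0] + 1e-15):
                best = (cand[1], int(f), cand[0])
        if best is None or best[0] <= 1e-15:
            self.nodes[node_id] = (None, float(y.mean()))
            return node_id
        dec, f, thr = best
        self.importances_[f] += dec
        mask = X[:, f] <= thr
        left = self._grow(X[mask], y[mask], depth + 1)
        right = self._grow(X[~mask], y[~mask], depth + 1)
        self.nodes[node_id] = (f, thr, left, right)
        return node_id

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.nodes = []
        self.importances_ = np.zeros(X.shape[1])
        self._grow(X, y, 0)
        return self

    def _predict_one(self, x):
        node = self.nodes[0]
        while node[0] is not None:
            f, thr, left, right = node
            node = self.nodes[left] if x[f] <= thr else self.nodes[right]
        return node[1]

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self._predict_one(row) for row in X])

    def sse(self, X, y):
        r = np.asarray(y, float) - self.predict(X)
        return float(r @ r)


def fit_cart(design: DesignTable, config: TreeEnsembleConfig | None = None) -> RegressionTree:
    """Fit a single CART regression tree to the design's coded settings."""
    config = config or TreeEnsembleConfig()
    mask = design.has_response
    tree = RegressionTree(
        max_depth=config.max_depth, min_leaf=config.min_leaf, max_features=None
    )
    return tree.fit(design.coded[mask], design.response[mask])


def rf_importance(
    design: DesignTable, config: TreeEnsembleConfig | None = None
) -> ImportanceResult:
    """Random-forest mean-impurity-decrease importance, normalized to 100."""
    config = config or TreeEnsembleConfig()
    mask = design.has_response
    X, y = design.coded[mask], design.response[mask]
    n = len(y)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    total = np.zeros(X.shape[1])
    for _ in range(config.n_trees):
        idx = rng.integers(0, n, size=n) if config.bootstrap else np.arange(n)
        tree = RegressionTree(
            max_depth=config.max_depth,
            min_leaf=config.min_leaf,
            max_features=config.max_features,
            rng=rng,
        )
        tree.fit(X[idx], y[idx])
        total += tree.importances_
    s = total.sum()
    scores = 100.0 * total / s if s > 0 else np.full(X.shape[1], 25.0)
    return ImportanceResult(
        method="rf", scores=scores, factor_names=list(design.factor_names)
    )


def gbrt_importance(
    design: DesignTable, config: TreeEnsembleConfig | None = None
) -> ImportanceResult:
    """Gradient-boosted regression trees: stagewise residual fitting with
    shrinkage; importance is accumulated impurity decrease, normalized to 100."""
    if config is None:
        config = TreeEnsembleConfig(
            n_trees=200, max_depth=2, learning_rate=0.1,
            bootstrap=False, max_features=None,
        )
    mask = design.has_response
    X, y = design.coded[mask], design.response[mask]
    pred = np.full(len(y), y.mean())
    total = np.zeros(X.shape[1])
    for _ in range(config.n_trees):
        resid = y - pred
        tree = RegressionTree(
            max_depth=config.max_depth, min_leaf=config.min_leaf, max_features=None
        )
        tree.fit(X, resid)
        pred = pred + config.learning_rate * tree.predict(X)
        total += tree.importances_
    s = total.sum()
    scores = 100.0 * total / s if s > 0 else np.full(X.shape[1], 25.0)
    return ImportanceResult(
        method="gbrt", scores=scores, factor_names=list(design.factor_names)
    )


def gbrt_staged_loss(design: DesignTable, config: TreeEnsembleConfig) -> np.ndarray:
    """Training MSE after each boosting round (diagnostic; non-increasing)."""
    mask = design.has_response
    X, y = design.coded[mask], design.response[mask]
    pred = np.full(len(y), y.mean())
    losses = [float(np.mean((y - pred) ** 2))]
    for _ in range(config.n_trees):
        tree = RegressionTree(max_depth=config.max_depth, min_leaf=config.min_leaf)
        tree.fit(X, y - pred)
        pred = pred + config.learning_rate * tree.predict(X)
        losses.append(float(np.mean((y - pred) ** 2)))
    return np.asarray(losses)


def rank_table(results: list[ImportanceResult], factor_names=None) -> pd.DataFrame:
    """Methods x factors integer rank matrix (1 = most important)."""
    if factor_names is None:
        for r in results:
            if r.factor_names:
                factor_names = r.factor_names
                break
        else:
            factor_names = [f"x{i+1}" for i in range(len(results[0].ranks))]
    return pd.DataFrame(
        [r.ranks for r in results],
        index=[r.method for r in results],
        columns=factor_names,
    )
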