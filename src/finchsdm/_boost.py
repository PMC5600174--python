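"""Stage-wise gradient boosting for Bernoulli deviance with best-first trees.

Each stage fits one least-squares regression tree to the current negative
gradient (y - p) on a fresh subsample drawn without replacement, grows it
best-first under a fixed split budget, replaces leaf means by a Newton step
for the Bernoulli loss, and shrinks the tree by the learning rate.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tree", "Booster", "bernoulli_deviance", "sigmoid"]

_EPS = 1e-12


def sigmoid(f: np.ndarray) -> np.ndarray:
    out = np.empty_like(f, dtype=float)
    pos = f >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-f[pos]))
    ef = np.exp(f[~pos])
    out[~pos] = ef / (1.0 + ef)
    return out


def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance, -2*mean(y log p + (1-y) log(1-p))."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _best_split(X, r, idx, min_leaf):
    """Best least-squares split of the samples ``idx``.

    Returns (gain, feature, threshold) or (0, -1, nan) if no admissible
    split improves the squared error.  Gain is the SSE reduction (the
    Friedman split improvement).
    """
    n = idx.size
    if n < 2 * min_leaf:
        return 0.0, -1, np.nan
    V = X[idx]  # n x p
    rsub = r[idx]
    total = rsub.sum()
    base = total * total / n

    order = np.argsort(V, axis=0, kind="stable")
    sv = np.take_along_axis(V, order, axis=0)
    csum = np.cumsum(rsub[order], axis=0)

    ln = np.arange(1, n)[:, None].astype(float)  # left counts, positions 0..n-2
    ok = (sv[:-1] < sv[1:]) & (ln >= min_leaf) & (n - ln >= min_leaf)
    if not ok.any():
        return 0.0, -1, np.nan
    ls = csum[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        gains = ls * ls / ln + (total - ls) ** 2 / (n - ln) - base
    gains[~ok] = -np.inf
    i, j = np.unravel_index(np.argmax(gains), gains.shape)
    if gains[i, j] <= 0.0:
        return 0.0, -1, np.nan
    return float(gains[i, j]), int(j), float(0.5 * (sv[i, j] + sv[i + 1, j]))


class Tree:
    """Regression tree grown best-first with a fixed split budget.

    Flat-array representation: ``children_left[k] == -1`` marks a leaf with
    prediction ``value[k]``; internal nodes route ``x[feature] <= threshold``
    left.  ``split_gain`` records the SSE improvement of every split,
    aligned with ``split_feature`` (for variable importance).
    """

    __slots__ = ("feature", "threshold", "children_left", "children_right",
                 "value", "split_feature", "split_gain")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.children_left: list[int] = []
        self.children_right: list[int] = []
        self.value: list[float] = []
        self.split_feature: list[int] = []
        self.split_gain: list[float] = []

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.children_left.append(-1)
        self.children_right.append(-1)
        self.value.append(0.0)
        return len(self.feature) - 1

    def fit(self, X, r, idx, max_splits, min_leaf, y=None, p=None):
        """Grow on samples ``idx`` of (X, r); set Newton leaf values.

        When ``y``/``p`` are given, leaf values are the Bernoulli Newton
        step sum(y-p)/sum(p(1-p)); otherwise the leaf mean of ``r``.
        """
        root = self._new_node()
        # frontier entries: (gain, feature, threshold, node_id, idx)
        frontier = [(*_best_split(X, r, idx, min_leaf), root, idx)]
        leaf_sets = {root: idx}
        for _ in range(max_splits):
            gains = [f[0] for f in frontier]
            best = int(np.argmax(gains))
            gain, feat, thr, node, nidx = frontier[best]
            if gain <= 0.0 or feat < 0:
                break
            frontier.pop(best)
            del leaf_sets[node]
            go_left = X[nidx, feat] <= thr
            li, ri = nidx[go_left], nidx[~go_left]
            lid, rid = self._new_node(), self._new_node()
            self.feature[node] = feat
            self.threshold[node] = float(thr)
            self.children_left[node] = lid
            self.children_right[node] = rid
            self.split_feature.append(feat)
            self.split_gain.append(gain)
            frontier.append((*_best_split(X, r, li, min_leaf), lid, li))
            frontier.append((*_best_split(X, r, ri, min_leaf), rid, ri))
            leaf_sets[lid] = li
            leaf_sets[rid] = ri
        for node, nidx in leaf_sets.items():
            if y is not None:
                num = float(np.sum(y[nidx] - p[nidx]))
                den = float(np.sum(p[nidx] * (1.0 - p[nidx])))
                self.value[node] = num / max(den, 1e-8)
            else:
                self.value[node] = float(np.mean(r[nidx]))
        self._finalize()
        return self

    def _finalize(self):
        self.feature = np.asarray(self.feature, dtype=np.int32)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.children_left = np.asarray(self.children_left, dtype=np.int32)
        self.children_right = np.asarray(self.children_right, dtype=np.int32)
        self.value = np.asarray(self.value, dtype=float)

    @property
    def n_splits(self) -> int:
        return len(self.split_feature)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def predict(self, X) -> np.ndarray:
        out = np.empty(X.shape[0], dtype=float)
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if self.children_left[node] < 0:
                out[idx] = self.value[node]
                continue
            go_left = X[idx, self.feature[node]] <= self.threshold[node]
            stack.append((self.children_left[node], idx[go_left]))
            stack.append((self.children_right[node], idx[~go_left]))
        return out


class Booster:
    """Gradient-boosted Bernoulli classifier supporting incremental growth."""

    def __init__(self, learning_rate=0.001, bag_fraction=2.0 / 3.0, max_splits=5,
                 min_leaf=5, rng=None):
        self.learning_rate = float(learning_rate)
        self.bag_fraction = float(bag_fraction)
        self.max_splits = int(max_splits)
        self.min_leaf = int(min_leaf)
        self.rng = np.random.default_rng(rng)
        self.trees: list[Tree] = []
        self.intercept = 0.0
        self._X = None
        self._y = None
        self._F = None
        self._tracked: list[tuple[np.ndarray, np.ndarray]] = []

    def init_data(self, X, y):
        X = np.ascontiguousarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("both classes must be present")
        base = y.mean()
        self.intercept = float(np.log(base / (1.0 - base)))
        self._X, self._y = X, y
        self._F = np.full(y.shape, self.intercept)
        return self

    def track(self, X_test) -> int:
        """Register a matrix whose raw scores are updated as trees are added."""
        X_test = np.ascontiguousarray(X_test, dtype=float)
        F = np.full(X_test.shape[0], self.intercept)
        for t in self.trees:
            F += self.learning_rate * t.predict(X_test)
        self._tracked.append((X_test, F))
        return len(self._tracked) - 1

    def tracked_proba(self, handle: int) -> np.ndarray:
        return sigmoid(self._tracked[handle][1])

    def grow(self, n_stages: int):
        """Add ``n_stages`` trees."""
        X, y = self._X, self._y
        n = y.size
        n_bag = max(2, int(round(self.bag_fraction * n)))
        for _ in range(n_stages):
            p = sigmoid(self._F)
            r = y - p
            bag = self.rng.permutation(n)[:n_bag]
            tree = Tree().fit(X, r, np.sort(bag), self.max_splits, self.min_leaf, y=y, p=p)
            self.trees.append(tree)
            if self.learning_rate != 0.0:
                self._F += self.learning_rate * tree.predict(X)
                for Xt, Ft in self._tracked:
                    Ft += self.learning_rate * tree.predict(Xt)
        return self

    def fit(self, X, y, n_trees: int):
        return self.init_data(X, y).grow(n_trees)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def decision_function(self, X) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=float)
        F = np.full(X.shape[0], self.intercept)
        if self.learning_rate != 0.0:
            for t in self.trees:
                F += self.learning_rate * t.predict(X)
        return F

    def predict_proba(self, X) -> np.ndarray:
        return sigmoid(self.decision_function(X))

    def proba_in_sample(self) -> np.ndarray:
        return sigmoid(self._F)

    def truncated_proba(self, X, n_trees: int) -> np.ndarray:
        """Probabilities using only the first ``n_trees`` trees."""
        X = np.ascontiguousarray(X, dtype=float)
        F = np.full(X.shape[0], self.intercept)
        for t in self.trees[:n_trees]:
            F += self.learning_rate * t.predict(X)
        return sigmoid(F)

    def raw_importance(self, n_features: int, n_trees: int | None = None) -> np.ndarray:
        """Per-feature sum of split improvements over the first ``n_trees`` trees."""
        imp = np.zeros(n_features)
        for t in self.trees[: (n_trees if n_trees is not None else len(self.trees))]:
            for f, g in zip(t.split_feature, t.split_gain):
                imp[f] += g
        return imp
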