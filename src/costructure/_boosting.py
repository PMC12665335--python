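"""Least-squares gradient boosting of depth-limited regression trees.

A compact exact implementation tuned for this package's workload: dense
tables of a few hundred rows and six predictors, fitted thousands of
times during repeated-CV grid search.  Trees are grown greedily on
squared-error improvement with exact split enumeration (every midpoint
between distinct sorted feature values), depth-limited, with sklearn's
default stopping rules (min 2 samples to split, leaves may hold 1).
Boosting starts from the target mean and adds ``learning_rate`` times
each tree's fit to the residuals; predictions can be truncated to any
iteration count, which is what lets one fit score a whole
``n_estimators`` grid axis.

Behavior is pinned by the test suite, including a cross-check against
scikit-learn's GradientBoostingRegressor on matched settings.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["GradientBoosting"]

# tree node array layout: feature | threshold | left | right | value
_F, _T, _L, _R, _V = 0, 1, 2, 3, 4
_LEAF = -1.0


@njit(cache=True)
def _fit_tree(X, y, order, max_depth, nodes):  # pragma: no cover - jitted
    """Grow one exact greedy CART on (X, y); returns number of nodes used.

    ``order`` is the per-feature argsort of X (n, d), computed once per
    boosting run and reused by every tree via stable partitioning.
    """
    n, d = X.shape
    # explicit stack of (node_id, start, end, depth) over an index buffer
    idx = np.empty(n, dtype=np.int64)
    for i in range(n):
        idx[i] = i
    # per-feature sorted index lists for the current node, rebuilt by
    # filtering the global order with a membership mask
    member = np.zeros(n, dtype=np.uint8)
    stack = np.empty((2 * max_depth + 2, 4), dtype=np.int64)

    # node bookkeeping: rows of each pending node are a contiguous slice of idx
    n_nodes = 1
    stack_top = 0
    stack[0, 0] = 0   # node id
    stack[0, 1] = 0   # slice start
    stack[0, 2] = n   # slice end
    stack[0, 3] = 0   # depth
    stack_top = 1

    buf = np.empty(n, dtype=np.int64)

    while stack_top > 0:
        stack_top -= 1
        node = stack[stack_top, 0]
        lo = stack[stack_top, 1]
        hi = stack[stack_top, 2]
        depth = stack[stack_top, 3]
        m = hi - lo

        s = 0.0
        for k in range(lo, hi):
            s += y[idx[k]]
        mean = s / m

        if depth >= max_depth or m < 2:
            nodes[node, _F] = _LEAF
            nodes[node, _V] = mean
            continue

        # mark membership for this node's rows
        for k in range(lo, hi):
            member[idx[k]] = 1

        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        sse_total = 0.0
        for k in range(lo, hi):
            diff = y[idx[k]] - mean
            sse_total += diff * diff

        for f in range(d):
            # collect node rows in feature-sorted order
            c = 0
            for k in range(n):
                r = order[k, f]
                if member[r] == 1:
                    buf[c] = r
                    c += 1
            # prefix scan for best split
            left_sum = 0.0
            left_sq = 0.0
            total_sum = s
            total_sq = 0.0
            for k in range(m):
                v = y[buf[k]]
                total_sq += v * v
            for k in range(m - 1):
                v = y[buf[k]]
                left_sum += v
                left_sq += v * v
                x_here = X[buf[k], f]
                x_next = X[buf[k + 1], f]
                if x_next <= x_here:
                    continue
                nl = k + 1
                nr = m - nl
                right_sum = total_sum - left_sum
                right_sq = total_sq - left_sq
                sse = (left_sq - left_sum * left_sum / nl) + (
                    right_sq - right_sum * right_sum / nr
                )
                gain = sse_total - sse
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best_f = f
                    best_thr = 0.5 * (x_here + x_next)

        for k in range(lo, hi):
            member[idx[k]] = 0

        if best_f < 0:
            nodes[node, _F] = _LEAF
            nodes[node, _V] = mean
            continue

        # stable partition of the slice
        cl = lo
        cr = 0
        for k in range(lo, hi):
            r = idx[k]
            if X[r, best_f] <= best_thr:
                idx[cl] = r
                cl += 1
            else:
                buf[cr] = r
                cr += 1
        for k in range(cr):
            idx[cl + k] = buf[k]

        left_id = n_nodes
        right_id = n_nodes + 1
        n_nodes += 2
        nodes[node, _F] = best_f
        nodes[node, _T] = best_thr
        nodes[node, _L] = left_id
        nodes[node, _R] = right_id

        stack[stack_top, 0] = left_id
        stack[stack_top, 1] = lo
        stack[stack_top, 2] = cl
        stack[stack_top, 3] = depth + 1
        stack_top += 1
        stack[stack_top, 0] = right_id
        stack[stack_top, 1] = cl
        stack[stack_top, 2] = hi
        stack[stack_top, 3] = depth + 1
        stack_top += 1

    return n_nodes


@njit(cache=True)
def _predict_tree(nodes, X, out):  # pragma: no cover - jitted
    for i in range(X.shape[0]):
        node = 0
        while nodes[node, _F] != _LEAF:
            f = int(nodes[node, _F])
            if X[i, f] <= nodes[node, _T]:
                node = int(nodes[node, _L])
            else:
                node = int(nodes[node, _R])
        out[i] = nodes[node, _V]


@njit(cache=True)
def _fit_boost(X, y, n_estimators, learning_rate, max_depth):  # pragma: no cover
    n, d = X.shape
    order = np.empty((n, d), dtype=np.int64)
    for f in range(d):
        order[:, f] = np.argsort(X[:, f], kind="mergesort")
    max_nodes = 2 ** (max_depth + 1)
    forest = np.zeros((n_estimators, max_nodes, 5))
    base = y.mean()
    resid = y - base
    pred = np.empty(n)
    for t in range(n_estimators):
        _fit_tree(X, resid, order, max_depth, forest[t])
        _predict_tree(forest[t], X, pred)
        for i in range(n):
            resid[i] -= learning_rate * pred[i]
    return base, forest


@njit(cache=True)
def _predict_boost(base, forest, learning_rate, X, n_iter):  # pragma: no cover
    n = X.shape[0]
    out = np.full(n, base)
    tmp = np.empty(n)
    for t in range(n_iter):
        _predict_tree(forest[t], X, tmp)
        for i in range(n):
            out[i] += learning_rate * tmp[i]
    return out


class GradientBoosting:
    """Deterministic least-squares boosting with staged prediction."""

    def __init__(self, n_estimators: int = 100, learning_rate: float = 0.1, max_depth: int = 3):
        self.n_estimators = int(n_estimators)
        self.learning_rate = float(learning_rate)
        self.max_depth = int(max_depth)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GradientBoosting":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.float64)
        self._base, self._forest = _fit_boost(
            X, y, self.n_estimators, self.learning_rate, self.max_depth
        )
        return self

    def predict(self, X: np.ndarray, n_iter: int | None = None) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        k = self.n_estimators if n_iter is None else int(n_iter)
        return _predict_boost(self._base, self._forest, self.learning_rate, X, k)
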