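"""Independent brute-force oracles used by unit and acceptance tests.

Everything here recomputes descriptors directly from their defining sums
with plain Python loops, deliberately sharing no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from pollinet import WeightedBipartiteNetwork


def net_from(w, measure: str = "encounter") -> WeightedBipartiteNetwork:
    """Wrap a raw matrix (rows plants, cols pollinators) without re-sorting."""
    w = np.asarray(w, float)
    plants = tuple(f"p{i + 1}" for i in range(w.shape[0]))
    polls = tuple(f"z{j + 1}" for j in range(w.shape[1]))
    return WeightedBipartiteNetwork(plants, polls, w, measure)


def iter_small_matrices(n: int = 3, max_entry: int = 2):
    """All n x n integer matrices with entries in 0..max_entry and no empty
    row or column."""
    for flat in itertools.product(range(max_entry + 1), repeat=n * n):
        w = np.array(flat, float).reshape(n, n)
        if w.sum(axis=1).min() > 0 and w.sum(axis=0).min() > 0:
            yield w


def strength_oracle(w: np.ndarray, level: str) -> list[float]:
    """Species strength by explicit dependence summation."""
    if level == "pollinator":
        w = w.T
    # strength of focal row-species i = sum over partners j of a_ij / A_j
    out = []
    for i in range(w.shape[0]):
        s = 0.0
        for j in range(w.shape[1]):
            if w[i, j] > 0:
                s += w[i, j] / w[:, j].sum()
        out.append(s)
    return out


def push_pull_oracle(w: np.ndarray, level: str) -> list[float]:
    """Mean per-partner dependence asymmetry by explicit loops."""
    if level == "pollinator":
        w = w.T
    out = []
    for i in range(w.shape[0]):
        diffs = []
        for j in range(w.shape[1]):
            if w[i, j] > 0:
                d_focal = w[i, j] / w[i, :].sum()
                d_partner = w[i, j] / w[:, j].sum()
                diffs.append(d_partner - d_focal)
        out.append(sum(diffs) / len(diffs))
    return out


def nodf_oracle(w: np.ndarray, pair_rule: str) -> float:
    """Weighted NODF by direct enumeration of every row and column pair."""

    def line_key(mat, i):
        row = mat[i]
        return int((row > 0).sum()) if pair_rule == "fill" else float(row.sum())

    def pair_score(mat, u, v):
        # u is the line with the strictly larger key
        hits = sum(1 for c in range(mat.shape[1]) if 0 < mat[v, c] < mat[u, c])
        return hits / (mat[v] > 0).sum()

    total, n_pairs = 0.0, 0
    for mat in (w, w.T):
        n = mat.shape[0]
        for u in range(n):
            for v in range(u + 1, n):
                n_pairs += 1
                ku, kv = line_key(mat, u), line_key(mat, v)
                if ku > kv:
                    total += pair_score(mat, u, v)
                elif kv > ku:
                    total += pair_score(mat, v, u)
    return 100.0 * total / n_pairs


def ols_oracle(x, y):
    """Closed-form simple OLS: slope, intercept, se(slope), F, r2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = (resid**2).sum() / (n - 2)
    se = np.sqrt(s2 / sxx)
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1 - (resid**2).sum() / sst
    f = (sst - (resid**2).sum()) / s2
    return slope, intercept, se, f, r2
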