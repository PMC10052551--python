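"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the mathematical definitions directly
(dense matrices, exhaustive loops, numeric optimizers) and deliberately
shares no code with the package's vectorized/sparse paths.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def dense_gat(x, adj_self, W, a, b, slope=0.2):
    """Dense per-pair attention layer; adj_self includes self-loops."""
    n = x.shape[0]
    z = x @ W
    out_dim = W.shape[1]
    e = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(n):
            if adj_self[i, j]:
                s = a[:out_dim] @ z[i] + a[out_dim:] @ z[j]
                e[i, j] = s if s > 0 else slope * s
    alpha = np.zeros((n, n))
    for i in range(n):
        row = e[i]
        m = row[adj_self[i] > 0].max()
        ex = np.where(adj_self[i] > 0, np.exp(row - m), 0.0)
        alpha[i] = ex / ex.sum()
    h = alpha @ z + b
    return np.where(h > 0, h, np.exp(np.minimum(h, 0.0)) - 1.0), alpha


def dense_sage(x, adj, W, b, relu=True):
    """Dense mean-aggregate + concat + linear (+ ReLU) layer."""
    deg = adj.sum(axis=1)
    deg_safe = np.where(deg == 0, 1.0, deg)
    h_n = (adj @ x) / deg_safe[:, None]
    h = np.concatenate([x, h_n], axis=1) @ W + b
    return np.maximum(h, 0.0) if relu else h


def brute_force_ap(scores: np.ndarray, y: np.ndarray) -> float:
    """11-point interpolated AP computed from first principles.

    For every prediction-set size k, precision and recall are counted
    directly; the grid value at r is the max precision among operating
    points (including the empty set at recall 0, precision 1) with
    recall >= r, or 0 if recall r is unreachable.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = y[order]
    n_pos = y.sum()
    points = [(0.0, 1.0)]
    for k in range(1, len(y) + 1):
        # only cuts at distinct thresholds are admissible operating points
        if k < len(y) and s[k] == s[k - 1]:
            continue
        tp = y[:k].sum()
        points.append((tp / n_pos, tp / k))
    total = 0.0
    for r in np.linspace(0, 1, 11):
        feas = [p for rec, p in points if rec >= r - 1e-12]
        total += max(feas) if feas else 0.0
    return total / 11.0


def brute_force_bipartite(mutations, outliers, ppi_edges):
    """Exhaustive triple filter over genes x genes x patients.

    mutations: set of (gene, patient); outliers: set of (gene, patient);
    ppi_edges: set of frozenset gene pairs.
    """
    genes = {g for g, _ in mutations} | {g for g, _ in outliers}
    patients = {p for _, p in mutations} | {p for _, p in outliers}
    edges = set()
    for i in genes:
        for j in genes:
            if i == j:
                continue
            for p in patients:
                if (
                    (i, p) in mutations
                    and (j, p) in outliers
                    and frozenset((i, j)) in ppi_edges
                ):
                    edges.add((i, j, p))
    return edges


def numeric_theta(s: np.ndarray, s_mean: np.ndarray) -> float:
    """One-parameter least squares fitted numerically."""
    res = optimize.minimize_scalar(
        lambda t: float(((s_mean - t * s) ** 2).sum()),
        method="brent",
        options={"xtol": 1e-12},
    )
    return float(res.x)
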