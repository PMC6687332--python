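"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (enumeration, the textbook
definition, or a straight-line restatement of a rule) and deliberately
shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def exact_ranksum_p(a, b) -> float:
    """Two-sided rank-sum p by full enumeration over label assignments.

    For untied data the rank-sum statistic's permutation distribution is
    symmetric, so the two-sided p is the symmetric tail probability
    P(|W - E[W]| >= |w_obs - E[W]|) over all C(n, n_a) assignments.
    """
    a, b = list(a), list(b)
    values = a + b
    n, na = len(values), len(a)
    ranks = {v: r for r, v in enumerate(sorted(values), start=1)}
    w_obs = sum(ranks[v] for v in a)
    ew = na * (n + 1) / 2.0
    hits = total = 0
    for combo in itertools.combinations(range(n), na):
        w = sum(ranks[values[i]] for i in combo)
        total += 1
        if abs(w - ew) >= abs(w_obs - ew) - 1e-12:
            hits += 1
    return hits / total


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg step-up from the definition: sort ascending,
    q_(i) = min_{j >= i} min(1, m * p_(j) / j), map back."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(1.0, running)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def classify_oracle(L: float, O: float, C: float, tau: float = 0.10, eps: float = 1e-6) -> str:
    """Straight-line restatement of the three-way recovery rule."""
    lo, hi = min(L, O), max(L, O)
    intermediate = lo <= C <= hi
    rel_l = abs(C - L) / max(abs(L), eps)
    rel_o = abs(C - O) / max(abs(O), eps)
    if (not intermediate) and rel_l > tau and rel_o > tau:
        return "Different"
    if abs(C - L) < abs(C - O):
        return "Recovered"
    if abs(C - O) < abs(C - L):
        return "NotRecovered"
    return "NotRecovered"  # exact tie


def hypergeom_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def agglomerative_heights(X: np.ndarray, method: str = "complete") -> list[float]:
    """Textbook quadratic agglomerative clustering; returns merge heights.

    Maintains the full inter-cluster distance matrix and repeatedly merges
    the closest pair under the requested linkage (complete or single or
    average over Euclidean point distances).
    """
    pts = [np.asarray(row, float) for row in X]
    clusters: list[list[int]] = [[i] for i in range(len(pts))]
    d = {
        (i, j): float(np.linalg.norm(pts[i] - pts[j]))
        for i in range(len(pts))
        for j in range(i + 1, len(pts))
    }

    def cluster_dist(ca, cb):
        dists = [d[(min(i, j), max(i, j))] for i in ca for j in cb]
        if method == "complete":
            return max(dists)
        if method == "single":
            return min(dists)
        if method == "average":
            return sum(dists) / len(dists)
        raise ValueError(method)

    heights = []
    while len(clusters) > 1:
        best = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                h = cluster_dist(clusters[ai], clusters[bi])
                if best is None or h < best[0]:
                    best = (h, ai, bi)
        h, ai, bi = best
        heights.append(h)
        merged = clusters[ai] + clusters[bi]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (ai, bi)]
        clusters.append(merged)
    return heights
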