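"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: alignment scores by
exhaustive enumeration of all global alignments, the K80 distance by
numerical maximization of the likelihood, connected components by
boolean transitive closure, correlations by definitional arithmetic.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize


def brute_force_alignment_score(a, b, substitution, gap_open, gap_extend):
    """Max global alignment score by enumerating every alignment.

    ``substitution(x, y)`` scores an aligned residue pair; a gap run of
    length k costs ``gap_open + (k - 1) * gap_extend`` (first position
    opens).  Exponential -- keep len <= 8.
    """
    best = -math.inf

    def rec(i, j, prev, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + substitution(a[i], b[j]))
        if i < len(a):
            cost = gap_extend if prev == "A" else gap_open
            rec(i + 1, j, "A", score - cost)
        if j < len(b):
            cost = gap_extend if prev == "B" else gap_open
            rec(i, j + 1, "B", score - cost)

    rec(0, 0, None, 0.0)
    return best


def ml_k80_distance(n_same: int, n_ts: int, n_tv: int) -> float:
    """K80 distance by numerical maximization of the site-count likelihood."""
    n = n_same + n_ts + n_tv

    def nll(x):
        at, bt = np.exp(x)
        e4b = np.exp(-4 * bt)
        e2ab = np.exp(-2 * (at + bt))
        p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
        p_tv = 0.5 - 0.5 * e4b
        p_same = 1.0 - p_ts - p_tv
        if p_ts <= 0 or p_tv <= 0 or p_same <= 0:
            return 1e12
        return -(n_same * np.log(p_same) + n_ts * np.log(p_ts)
                 + n_tv * np.log(p_tv)) / n

    res = optimize.minimize(
        nll, [np.log(0.1), np.log(0.05)], method="Nelder-Mead",
        options=dict(xatol=1e-13, fatol=1e-16, maxiter=40000, maxfev=40000))
    alpha_t, beta_t = np.exp(res.x)
    return float(alpha_t + 2.0 * beta_t)


def reachability_components(nodes, edges):
    """Connected components via boolean transitive closure (Warshall)."""
    nodes = sorted(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for a, b in edges:
        reach[index[a], index[b]] = reach[index[b], index[a]] = True
    for k in range(n):
        reach |= reach[:, [k]] & reach[[k], :]
    seen = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        comp = {nodes[j] for j in range(n) if reach[i, j]}
        seen.update(index[m] for m in comp)
        comps.append(frozenset(comp))
    return set(comps)


def definitional_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc)
                 / math.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2)))


def average_ranks(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, float)
    i = 0
    sorted_v = v[order]
    while i < v.size:
        j = i
        while j + 1 < v.size and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def definitional_spearman(x, y):
    return definitional_pearson(average_ranks(x), average_ranks(y))
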