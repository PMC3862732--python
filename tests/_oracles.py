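"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition (full
enumeration, O(m²) scans), independent of the implementation paths they
check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def bh_stepup(p):
    """q_(i) = min(1, min_{j>=i} p_(j)·m/j), mapped back to input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(1.0, min(sorted_p[j] * m / (j + 1) for j in range(i, m)))
    q = np.empty(m)
    q[order] = q_sorted
    return q


def bh_cutoff(p, fdr):
    """Largest p_(k) with p_(k) <= fdr·k/m, else None."""
    sorted_p = np.sort(np.asarray(p, dtype=float))
    m = len(sorted_p)
    best = None
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= fdr * k / m:
            best = float(sorted_p[k - 1])
    return best


def bh_selected(p, fdr):
    """Indices rejected by BH step-up at level fdr."""
    cut = bh_cutoff(p, fdr)
    if cut is None:
        return set()
    return {i for i, v in enumerate(p) if v <= cut}


def mann_whitney_enum(x, y, alternative="two-sided"):
    """Exact Mann-Whitney p by enumerating all group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_of(x, y)
    idx = list(range(len(pooled)))
    us = []
    for comb in combinations(idx, n1):
        rest = [i for i in idx if i not in comb]
        us.append(u_of(pooled[list(comb)], pooled[rest]))
    us = np.asarray(us)
    p_le = float(np.mean(us <= u_obs + 1e-9))
    p_ge = float(np.mean(us >= u_obs - 1e-9))
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


def triangle_eliminate(nodes, mi):
    """Brute-force DPI at tolerance 0: for every node triple forming a
    triangle, mark every edge attaining the triangle's minimum MI; remove
    all marked edges simultaneously.

    ``mi`` maps frozenset({u, v}) -> mutual information.
    """
    marked = set()
    for trio in combinations(sorted(nodes), 3):
        edges = [frozenset(e) for e in combinations(trio, 2)]
        if not all(e in mi for e in edges):
            continue
        lo = min(mi[e] for e in edges)
        for e in edges:
            if mi[e] == lo:
                marked.add(e)
    return {e for e in mi if e not in marked}


def pearson_two_pass(x, y):
    """Textbook two-pass Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den
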