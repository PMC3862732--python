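"""Pairwise correlation matrices, threshold censuses, and clustering.

Pearson (or Spearman) correlations over metabolite pairs with
pairwise-complete observation handling: each pair uses the samples where
both metabolites are present, the effective n is recorded per pair, and the
two-sided p-value comes from t = r·sqrt(n-2)/sqrt(1-r²) against the t
distribution with n-2 degrees of freedom. Censuses count unordered pairs
exceeding |r| cutoffs (strict inequality). Hierarchical clustering of the
correlation profiles uses city-block (L1) distance with average (UPGMA)
linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame  # symmetric, unit diagonal
    p: pd.DataFrame  # two-sided, symmetric
    n: pd.DataFrame  # per-pair effective sample size
    method: str = "pearson"


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p for a correlation coefficient at sample size n.

    t = r·sqrt(n-2)/sqrt(1-r²), t distribution with n-2 df. |r| = 1 is
    reported at the machine floor rather than 0.
    """
    if n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return P_FLOOR
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return max(float(2.0 * stats.t.sf(abs(t), n - 2)), P_FLOOR)


def pair_correlation(x, y, method: str = "pearson") -> tuple[float, float, int]:
    """(r, two-sided p, effective n) for one metabolite pair.

    Uses pairwise-complete observations; requires ≥ 3; constant vectors
    give an undefined (NaN) correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        return float("nan"), float("nan"), n
    xs, ys = x[ok], y[ok]
    if method == "spearman":
        xs = stats.rankdata(xs)
        ys = stats.rankdata(ys)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if np.std(xs) == 0 or np.std(ys) == 0:
        log.info("constant vector in pair; correlation undefined")
        return float("nan"), float("nan"), n
    r = float(np.corrcoef(xs, ys)[0, 1])
    r = min(1.0, max(-1.0, r))
    return r, correlation_p_value(r, n), n


def correlation_matrix(values: pd.DataFrame, method: str = "pearson") -> CorrelationMatrix:
    """All-pairs correlation with p-values and per-pair effective n.

    ``values`` is samples × metabolites with NaN missing markers. Pairs with
    fewer than 3 complete observations get missing entries.
    """
    cols = list(values.columns)
    m = len(cols)
    R = np.eye(m)
    P = np.full((m, m), np.nan)
    N = np.zeros((m, m), dtype=int)
    arr = values.to_numpy(dtype=float)
    for i in range(m):
        N[i, i] = int((~np.isnan(arr[:, i])).sum())
        for j in range(i + 1, m):
            r, p, n = pair_correlation(arr[:, i], arr[:, j], method=method)
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
            N[i, j] = N[j, i] = n
    return CorrelationMatrix(
        pd.DataFrame(R, index=cols, columns=cols),
        pd.DataFrame(P, index=cols, columns=cols),
        pd.DataFrame(N, index=cols, columns=cols),
        method,
    )


def threshold_counts(c: CorrelationMatrix, thresholds) -> dict[float, int]:
    """Unordered off-diagonal pairs with |r| strictly above each cutoff."""
    counts = {}
    r = c.r.to_numpy(dtype=float)
    iu = np.triu_indices(r.shape[0], k=1)
    upper = np.abs(r[iu])
    upper = upper[~np.isnan(upper)]
    for cutoff in thresholds:
        if not 0.0 < cutoff < 1.0:
            raise ValueError("thresholds must be in (0, 1)")
        counts[float(cutoff)] = int((upper > cutoff).sum())
    return counts


@dataclass
class HCAResult:
    labels: list  # metabolites clustered, in input order
    linkage: np.ndarray  # scipy linkage matrix (merge tree with heights)
    leaf_order: list  # metabolite names in canonical dendrogram order


def _canonical_leaves(link: np.ndarray, labels: list) -> list:
    """Leaf order with children at every merge ordered by their smallest
    leaf label, so the order depends only on the tree, not on input order."""
    n = len(labels)
    cache: dict[int, list] = {i: [labels[i]] for i in range(n)}
    for k, (a, b, _h, _c) in enumerate(link):
        left, right = cache.pop(int(a)), cache.pop(int(b))
        if min(right) < min(left):
            left, right = right, left
        cache[n + k] = left + right
    (order,) = cache.values()
    return order


def hca_order(c: CorrelationMatrix) -> HCAResult:
    """UPGMA clustering of correlation profiles, city-block distance.

    Metabolites whose correlation row contains missing entries are dropped
    with a notice before clustering. The returned leaf order is canonical
    (children sorted by smallest leaf label), hence invariant under input
    row permutation.
    """
    r = c.r.copy()
    complete = r.notna().all(axis=1)
    dropped = r.index[~complete].tolist()
    if dropped:
        log.info("dropping rows with missing correlations: %s", dropped)
        r = r.loc[complete, complete]
    if len(r) < 2:
        raise ValueError("need at least 2 complete rows to cluster")
    dist = pdist(r.to_numpy(dtype=float), metric="cityblock")
    link = hierarchy.linkage(dist, method="average")
    labels = list(r.index)
    return HCAResult(labels, link, _canonical_leaves(link, labels))
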