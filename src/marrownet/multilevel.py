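"""Multilevel (paired-sample) multivariate models.

For paired designs — two samples per subject, e.g. bone marrow and
peripheral blood from the same patient — the feature matrix splits exactly
into a between-subject part (subject means) and a within-subject part
(deviations from the subject mean). Multilevel PCA (mPCA) and multilevel
PLS discriminant analysis (mPLS-DA) operate on the within part only, so the
between-subject variation that dominates clinical data is removed before
modelling the compartment contrast.

mPCA is a singular value decomposition of the within matrix. mPLS-DA is a
univariate-response PLS (NIPALS with sequential deflation) against a ±1
class code, with leave-one-subject-out cross-validation (both of a
subject's samples held out together), an empirical permutation test that
swaps class labels within subject, and sensitivity/specificity at the
Youden-optimal threshold on the cross-validated scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


class DegenerateModelError(ValueError):
    """The class code carries no covariance with the data."""


@dataclass
class MultilevelSplit:
    subjects: np.ndarray  # unique subject ids, order of `between` rows
    between: np.ndarray  # subject means, one row per subject
    within: np.ndarray  # sample minus subject mean, one row per sample
    sample_subjects: np.ndarray  # subject id per sample row


@dataclass
class PCAResult:
    scores: np.ndarray  # samples × components
    loadings: np.ndarray  # features × components, orthonormal columns
    variance_fraction: np.ndarray  # per component, percent


@dataclass
class PLSDAResult:
    scores: np.ndarray  # within-matrix sample scores, samples × n_lv
    weights: np.ndarray  # features × n_lv
    x_variance_pct: np.ndarray  # data variance captured per LV, percent
    cv_predictions: np.ndarray  # leave-one-subject-out predicted class scores
    labels: np.ndarray  # ±1 class codes per sample
    sensitivity: float = float("nan")  # percent
    specificity: float = float("nan")  # percent
    permutation_p: float | None = None
    class_order: tuple = field(default_factory=tuple)  # (code -1 label, code +1 label)


def multilevel_split(X, subjects) -> MultilevelSplit:
    """Exact between/within decomposition of a paired matrix.

    Every subject must contribute the same number of samples (≥ 2); the
    within rows of each subject sum to the zero vector and
    ``between[subject] + within[row]`` reconstructs the input exactly.
    """
    X = np.asarray(X, dtype=float)
    subjects = np.asarray(subjects)
    uniq, counts = np.unique(subjects, return_counts=True)
    if counts.min() < 2:
        lonely = uniq[counts < 2].tolist()
        raise ValueError(f"subjects with a single sample: {lonely}")
    if len(set(counts)) != 1:
        raise ValueError("all subjects must have the same number of samples")
    between = np.vstack([X[subjects == s].mean(axis=0) for s in uniq])
    lookup = {s: i for i, s in enumerate(uniq)}
    within = X - between[[lookup[s] for s in subjects]]
    return MultilevelSplit(uniq, between, within, subjects)


def mpca(X, subjects, k: int = 2) -> PCAResult:
    """Multilevel PCA: SVD of the column-centered within matrix.

    Variance fractions come from the squared singular values. ``k`` beyond
    the matrix rank is truncated with a log notice.
    """
    split = multilevel_split(X, subjects)
    W = split.within - split.within.mean(axis=0)
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    tol = s.max(initial=0.0) * max(W.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if k > rank:
        log.info("requested %d components but rank is %d; truncating", k, rank)
        k = rank
    if k == 0:
        raise ValueError("within matrix has rank 0")
    var = 100.0 * s[:k] ** 2 / (s**2).sum()
    return PCAResult(U[:, :k] * s[:k], Vt[:k].T, var)


def _pls1_fit(X: np.ndarray, y: np.ndarray, n_lv: int):
    """NIPALS PLS1 with sequential deflation on column-centered data.

    Returns (x_mean, y_mean, W, P, q, T, x_variance_pct, coef) where
    ``coef`` maps centered X to centered predictions.
    """
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    ss_total = float((Xc**2).sum())
    if ss_total == 0:
        raise DegenerateModelError("within matrix is identically zero")
    Xd = Xc.copy()
    W, P, q, T, xvar = [], [], [], [], []
    for _ in range(n_lv):
        w = Xd.T @ yc
        norm_w = np.linalg.norm(w)
        if norm_w < 1e-12 * max(1.0, np.linalg.norm(Xd)):
            if not W:
                raise DegenerateModelError(
                    "class code has no covariance with the data; first weight undefined"
                )
            log.info("PLS deflation exhausted covariance after %d LVs", len(W))
            break
        w = w / norm_w
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p = Xd.T @ t / tt
        W.append(w)
        P.append(p)
        q.append(float(yc @ t) / tt)
        T.append(t)
        xvar.append(100.0 * tt * float(p @ p) / ss_total)
        Xd = Xd - np.outer(t, p)
    W = np.column_stack(W)
    P = np.column_stack(P)
    q = np.asarray(q)
    T = np.column_stack(T)
    # regression coefficients: B = W (PᵀW)⁻¹ q
    coef = W @ np.linalg.solve(P.T @ W, q)
    return x_mean, y_mean, W, P, q, T, np.asarray(xvar), coef


def _class_codes(labels) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    codes = np.where(labels == classes[1], 1.0, -1.0)
    return codes, (classes[0], classes[1])


def mplsda(X, subjects, labels, n_lv: int = 2, cv: bool = True) -> PLSDAResult:
    """Multilevel PLS-DA on the within matrix against a ±1 class code.

    With ``cv=True`` the per-sample class scores are leave-one-subject-out
    cross-validated and sensitivity/specificity are computed from them via
    :func:`cv_roc`.
    """
    codes, class_order = _class_codes(labels)
    split = multilevel_split(X, subjects)
    W_mat = split.within
    _, _, weights, _, _, T, xvar, _ = _pls1_fit(W_mat, codes, n_lv)
    cv_pred = np.full(len(codes), np.nan)
    sens = spec = float("nan")
    if cv:
        for subj in split.subjects:
            held = split.sample_subjects == subj
            x_mean, y_mean, *_rest, coef = _pls1_fit(W_mat[~held], codes[~held], n_lv)
            cv_pred[held] = (W_mat[held] - x_mean) @ coef + y_mean
        sens, spec = cv_roc(cv_pred, codes)
    return PLSDAResult(
        scores=T,
        weights=weights,
        x_variance_pct=xvar,
        cv_predictions=cv_pred,
        labels=codes,
        sensitivity=sens,
        specificity=spec,
        class_order=class_order,
    )


def cv_roc(scores, labels) -> tuple[float, float]:
    """Sensitivity/specificity (%) at the Youden-optimal threshold.

    Orientation is fixed by the class code (positive scores ↦ the +1
    class); no sign flip is applied. The threshold maximizing Youden's J is
    searched over interior midpoints (thresholds that predict both
    classes); when no such threshold beats chance (best J < 0, e.g.
    perfectly anti-ranked scores) the midpoint between the class median
    scores is used, reporting the degenerate performance honestly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels > 0]
    neg = scores[labels < 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    def _rates(theta):
        sens = float((pos >= theta).mean())
        spec = float((neg < theta).mean())
        return sens, spec

    order = np.sort(np.unique(scores))
    best = None
    for theta in (order[1:] + order[:-1]) / 2.0:
        sens, spec = _rates(theta)
        j = sens + spec - 1.0
        if best is None or j > best[0]:
            best = (j, sens, spec)
    if best is None or best[0] < 0:
        theta = (np.median(pos) + np.median(neg)) / 2.0
        sens, spec = _rates(theta)
        return 100.0 * sens, 100.0 * spec
    return 100.0 * best[1], 100.0 * best[2]


def _cv_separation_statistic(predictions, codes) -> float:
    """Rank statistic (Mann-Whitney U) of CV scores between the classes."""
    pos = predictions[codes > 0]
    neg = predictions[codes < 0]
    return float(stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic)


def permutation_validate(
    X, subjects, labels, n_perm: int = 99, seed: int = 0, n_lv: int = 2
) -> float:
    """Empirical permutation p-value of the mPLS-DA predictive ability.

    The reference statistic is the rank separation (Mann-Whitney U) of the
    leave-one-subject-out CV class scores between the true classes. The
    null distribution swaps class labels within subject; the identity
    pattern and the all-flip pattern (a global class relabeling, the same
    pairing partition as the identity) are excluded so a perfectly
    separable cohort yields p = 1/(n_perm+1). p = (1 + #{perm ≥ observed})
    / (n_perm + 1), never 0.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    codes, _ = _class_codes(labels)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)

    def _cv_stat(perm_codes) -> float:
        result = mplsda(X, subjects, perm_codes, n_lv=n_lv, cv=True)
        return _cv_separation_statistic(result.cv_predictions, result.labels)

    observed = _cv_stat(codes)
    count = 0
    for _ in range(n_perm):
        while True:
            flips = rng.random(len(uniq)) < 0.5
            if flips.any() and not flips.all():
                break
        flip_lookup = dict(zip(uniq, flips))
        perm = np.where([flip_lookup[s] for s in subjects], -codes, codes)
        if _cv_stat(perm) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)
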