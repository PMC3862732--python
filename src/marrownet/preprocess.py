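"""Matrix post-processing ahead of multivariate modelling.

Implements the standard spectra-style post-processing chain for intensity
matrices: probabilistic quotient normalization (per-sample dilution
correction against a reference profile), fixed-width binning on a positional
(ppm-like) axis with exclusion regions, and the generalized log transform
g(y) = ln((y + sqrt(y² + λ²)) / 2), a variance-stabilizing transform that
tends to ln(y) as λ → 0.

Matrices are pandas DataFrames: rows are samples, columns are features.
For binning the column labels must be numeric, strictly monotone positional
coordinates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def pqn_normalize(m: pd.DataFrame, reference: str | pd.Series = "median_sample"):
    """Probabilistic quotient normalization.

    Each sample is divided by the median of its feature-wise quotients
    against the reference profile (the feature-wise median sample by
    default). Returns ``(normalized matrix, dilution factors)``.
    """
    values = m.to_numpy(dtype=float)
    if isinstance(reference, str):
        if reference != "median_sample":
            raise ValueError(f"unknown reference {reference!r}")
        ref = np.nanmedian(values, axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (m.shape[1],):
            raise ValueError("explicit reference must have one value per feature")
    if np.any(ref == 0) or np.any(np.isnan(ref)):
        raise ValueError("reference profile has zero or missing features")
    with np.errstate(invalid="ignore"):
        quotients = values / ref[None, :]
    factors = np.nanmedian(quotients, axis=1)
    if np.any(np.isnan(factors)) or np.any(factors == 0):
        raise ValueError("sample with no usable features (all zero or missing)")
    normalized = pd.DataFrame(values / factors[:, None], index=m.index, columns=m.columns)
    return normalized, pd.Series(factors, index=m.index, name="dilution_factor")


def bin_features(
    m: pd.DataFrame,
    width: float,
    exclusions: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Sum features into contiguous half-open bins of fixed width.

    Bins are ``[a, a + width)`` anchored at the axis minimum after removing
    features falling inside any exclusion interval (closed intervals,
    solvent/reference-signal regions). Aggregation is by sum, conserving
    integrated intensity. Bin labels are bin centers.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    coords = np.asarray(m.columns, dtype=float)
    if len(coords) > 1 and not (np.all(np.diff(coords) > 0) or np.all(np.diff(coords) < 0)):
        raise ValueError("feature coordinates must be strictly monotone")
    keep = np.ones(len(coords), dtype=bool)
    for lo, hi in exclusions or []:
        lo, hi = min(lo, hi), max(lo, hi)
        keep &= ~((coords >= lo) & (coords <= hi))
    if not keep.any():
        return pd.DataFrame(index=m.index)
    coords = coords[keep]
    values = m.to_numpy(dtype=float)[:, keep]
    anchor = coords.min()
    idx = np.floor((coords - anchor) / width).astype(int)
    n_bins = idx.max() + 1
    out = np.zeros((values.shape[0], n_bins))
    for j, b in enumerate(idx):
        out[:, b] += values[:, j]
    centers = anchor + (np.arange(n_bins) + 0.5) * width
    occupied = np.zeros(n_bins, dtype=bool)
    occupied[idx] = True
    return pd.DataFrame(out[:, occupied], index=m.index, columns=centers[occupied])


def glog_transform(m: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Elementwise generalized log g(y) = ln((y + sqrt(y² + λ²)) / 2)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    values = m.to_numpy(dtype=float)
    if lam == 0 and np.any(values[~np.isnan(values)] == 0):
        raise ValueError("lambda = 0 with zero intensities gives -inf; choose lambda > 0")
    transformed = np.log((values + np.sqrt(values**2 + lam**2)) / 2.0)
    return pd.DataFrame(transformed, index=m.index, columns=m.columns)


def suggest_glog_lambda(m: pd.DataFrame, quantile: float = 0.05) -> float:
    """Default λ: the 5th percentile of the nonzero intensities."""
    values = m.to_numpy(dtype=float)
    nonzero = values[~np.isnan(values) & (values > 0)]
    if nonzero.size == 0:
        raise ValueError("matrix has no positive values")
    return float(np.quantile(nonzero, quantile))
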