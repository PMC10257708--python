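"""Binarization of continuous recordings and the correlation function g(r).

Continuous ROI signals are z-scored per row and thresholded at ``theta``
z-units (default 1): a node is "active" in a frame when its signal exceeds
one standard deviation above its mean.  The correlation function

    g(r) = (1 / N_r) * sum_{r_ij in [r, r + dr)} c_ij

averages pairwise Pearson correlations over distance bins of width ``dr``
(default 0.43 mm); N_r counts the pairs in each bin.  Power-law behaviour
g(r) ~ r^-eta over an intermediate distance window is the first of the
scale-invariance diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryRaster, NodeGeometry
from .powerlaw import PowerLawFitResult, fit_power_law_with_alternative

__all__ = [
    "BinaryRaster",
    "CorrelationFunction",
    "DEFAULT_FIT_WINDOW",
    "zscore_binarize",
    "pairwise_pearson",
    "correlation_function",
    "fit_correlation_function",
    "scan_fit_window",
]

#: Default distance window (mm) for fitting g(r) ~ r^-eta.
DEFAULT_FIT_WINDOW = (10.0, 90.0)


@dataclass(frozen=True)
class CorrelationFunction:
    """Distance-binned mean pairwise correlation.

    ``r`` holds left bin edges (mm); bins are half-open ``[r, r + dr)``.
    ``g`` is NaN for empty bins; ``pair_counts`` sums to N(N-1)/2.
    """

    r: np.ndarray
    g: np.ndarray
    pair_counts: np.ndarray
    dr: float

    @property
    def bin_centers(self) -> np.ndarray:
        return self.r + 0.5 * self.dr

    def occupied(self):
        """(bin centers, g, counts) restricted to non-empty bins."""
        m = self.pair_counts > 0
        return self.bin_centers[m], self.g[m], self.pair_counts[m]


def zscore_binarize(X: np.ndarray, theta: float = 1.0) -> BinaryRaster:
    """Per-row z-score then threshold: 1 where z > theta, else 0.

    Invariant under positive affine transforms of each row.  Rows with zero
    variance cannot be z-scored and are rejected.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be an (N, T) matrix")
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance rows cannot be binarized: {bad.tolist()}")
    z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return BinaryRaster(values=(z > theta).astype(np.int8), level=0)


def pairwise_pearson(data) -> np.ndarray:
    """Pairwise Pearson correlation matrix of the rows of an (N, T) matrix.

    Accepts a raster or raw signals.  Rows with zero variance yield NaN in
    their row/column (never a silent zero); the diagonal is exactly 1 for
    valid rows.
    """
    X = data.values if isinstance(data, BinaryRaster) else np.asarray(data)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("input must be (N, T)")
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(X)
    bad = sd == 0
    if bad.any():
        c[bad, :] = np.nan
        c[:, bad] = np.nan
    return c


def correlation_function(corr: np.ndarray, geometry: NodeGeometry,
                         dr: float = 0.43) -> CorrelationFunction:
    """Bin upper-triangle correlations by pairwise distance.

    Bins are half-open ``[r, r + dr)`` starting at 0; g is the mean
    correlation of the pairs in each bin.
    """
    corr = np.asarray(corr, dtype=float)
    n = geometry.n_nodes
    if corr.shape != (n, n):
        raise ValueError("correlation matrix does not match geometry size")
    if dr <= 0:
        raise ValueError("dr must be > 0")
    dist = geometry.distance_matrix()
    iu = np.triu_indices(n, k=1)
    d, c = dist[iu], corr[iu]
    n_bins = int(np.floor(d.max() / dr)) + 1
    idx = np.minimum((d / dr).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=np.nan_to_num(c), minlength=n_bins)
    # pairs with NaN correlation are excluded from the mean but kept in counts
    valid = np.bincount(idx, weights=np.isfinite(c).astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(valid > 0, sums / valid, np.nan)
    return CorrelationFunction(r=np.arange(n_bins) * dr, g=g,
                               pair_counts=counts, dr=dr)


def fit_correlation_function(cf: CorrelationFunction,
                             window=DEFAULT_FIT_WINDOW) -> PowerLawFitResult:
    """Power-law fit of g(r) over a distance window (default 10–90 mm).

    Bins with g <= 0 have no logarithm and are excluded; their count is
    reported in the result.
    """
    r, g, _ = cf.occupied()
    return fit_power_law_with_alternative(r, g, window=window)


def scan_fit_window(cf: CorrelationFunction, rmin_grid, rmax_grid):
    """Power-law fit of g(r) for every (rmin, rmax) window on a grid.

    Returns dict with 2-D arrays ``eta`` (−exponent), ``r_squared`` and a
    boolean ``valid`` mask; windows with fewer than 3 positive-g occupied
    bins are flagged invalid and carry NaN.
    """
    rmin_grid = np.asarray(rmin_grid, dtype=float)
    rmax_grid = np.asarray(rmax_grid, dtype=float)
    eta = np.full((rmin_grid.size, rmax_grid.size), np.nan)
    r2 = np.full_like(eta, np.nan)
    valid = np.zeros(eta.shape, dtype=bool)
    r, g, _ = cf.occupied()
    for a, rmin in enumerate(rmin_grid):
        for b, rmax in enumerate(rmax_grid):
            if rmax <= rmin:
                continue
            m = (r >= rmin) & (r <= rmax) & (g > 0)
            if m.sum() < 3:
                continue
            fit = fit_power_law_with_alternative(r[m], g[m])
            eta[a, b] = -fit.exponent
            r2[a, b] = fit.r2_powerlaw
            valid[a, b] = True
    return {"rmin": rmin_grid, "rmax": rmax_grid, "eta": eta,
            "r_squared": r2, "valid": valid}
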