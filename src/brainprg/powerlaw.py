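"""Least-squares power-law fitting and model comparison against an exponential.

Scaling relations here (correlation functions, coarse-grained variance,
covariance eigen-spectra) are deterministic curves, not probability
densities, so maximum-likelihood tail fitting does not apply.  Exponents are
instead estimated by ordinary least squares on log-transformed data, and the
power-law hypothesis is compared with an exponential alternative through the
ratio of explained variances

    R_EV = R2_powerlaw / R2_exponential,

where the power law is the linear model ``log y = a log x + b`` and the
exponential is ``log y = c x + d``, both fitted on exactly the same points.
``R_EV > 1`` favours the power law.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

__all__ = [
    "PowerLawFitResult",
    "fit_loglog_powerlaw",
    "fit_semilog_exponential",
    "model_comparison_ratio",
    "fit_power_law_with_alternative",
]


@dataclass(frozen=True)
class PowerLawFitResult:
    """Joint result of a power-law fit and its exponential alternative.

    Attributes
    ----------
    exponent, intercept, exponent_error, r2_powerlaw:
        Slope ``a``, intercept ``b``, standard error of ``a`` and coefficient
        of determination of the log-log regression.
    exp_rate, exp_intercept, r2_exponential:
        Slope ``c``, intercept ``d`` and R² of the semilog regression.
    r_ev:
        Explained-variance ratio ``R2_powerlaw / R2_exponential``
        (``inf`` if the exponential R² is zero).
    relative_error_percent:
        ``100 * exponent_error / |exponent|``.
    fit_window:
        ``(xmin, xmax)`` actually used, or ``None`` for all positive points.
    n_points, n_excluded:
        Points used and points dropped (non-positive x or y, out of window).
    """

    exponent: float
    intercept: float
    exponent_error: float
    r2_powerlaw: float
    exp_rate: float
    exp_intercept: float
    r2_exponential: float
    r_ev: float
    relative_error_percent: float
    fit_window: tuple[float, float] | None = None
    n_points: int = 0
    n_excluded: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["fit_window"] = list(self.fit_window) if self.fit_window else None
        return json.dumps(d, indent=2)


def _select_points(x, y, window):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    mask = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    if window is not None:
        lo, hi = window
        mask &= (x >= lo) & (x <= hi)
    n_excluded = int(x.size - mask.sum())
    return x[mask], y[mask], n_excluded


def _ols(u: np.ndarray, v: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of v on u -> (slope, intercept, slope stderr, R²).

    Degenerate case: constant v gives slope 0 and R² defined as 1 (the model
    reproduces the data exactly), matching the behaviour needed for exact
    power laws evaluated in log space.
    """
    if np.ptp(v) == 0.0:
        return 0.0, float(v[0]), 0.0, 1.0
    res = stats.linregress(u, v)
    r2 = float(res.rvalue**2)
    # linregress returns stderr = nan for n == 2 (zero dof); an exact 2-point
    # fit has no residual, report 0 there
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return float(res.slope), float(res.intercept), stderr, r2


def fit_loglog_powerlaw(x, y, window=None):
    """Fit ``log y = a log x + b`` by ordinary least squares.

    Parameters
    ----------
    x, y : array-like
        Positive data; non-positive entries are excluded (their count is
        available through :func:`fit_power_law_with_alternative`).
    window : (float, float), optional
        Inclusive range of x to fit over.

    Returns
    -------
    (a, b, stderr_a, r_squared)
    """
    xs, ys, _ = _select_points(x, y, window)
    if xs.size < 3:
        raise ValueError(
            f"power-law fit needs >=3 positive points in window, got {xs.size}"
        )
    return _ols(np.log(xs), np.log(ys))


def fit_semilog_exponential(x, y, window=None):
    """Fit ``log y = c x + d`` by ordinary least squares.

    Returns ``(c, d, stderr_c, r_squared)``.  Same point-selection rules as
    :func:`fit_loglog_powerlaw` so both models see identical data.
    """
    xs, ys, _ = _select_points(x, y, window)
    if xs.size < 3:
        raise ValueError(
            f"exponential fit needs >=3 positive points in window, got {xs.size}"
        )
    slope, intercept, stderr, r2 = _ols(xs, np.log(ys))
    return slope, intercept, stderr, r2


def model_comparison_ratio(r2_powerlaw: float, r2_exponential: float) -> float:
    """Explained-variance ratio R_EV; ``inf`` when the exponential R² is 0."""
    if r2_exponential == 0.0:
        return math.inf
    return r2_powerlaw / r2_exponential


def fit_power_law_with_alternative(x, y, window=None) -> PowerLawFitResult:
    """Fit both competing models on the same point set and bundle the result."""
    xs, ys, n_excluded = _select_points(x, y, window)
    if xs.size < 3:
        raise ValueError(
            f"fit needs >=3 positive points in window, got {xs.size}"
        )
    a, b, da, r2_pl = _ols(np.log(xs), np.log(ys))
    c, d, _, r2_exp = _ols(xs, np.log(ys))
    rel = 100.0 * da / abs(a) if a != 0.0 else math.inf if da > 0 else 0.0
    return PowerLawFitResult(
        exponent=a,
        intercept=b,
        exponent_error=da,
        r2_powerlaw=r2_pl,
        exp_rate=c,
        exp_intercept=d,
        r2_exponential=r2_exp,
        r_ev=model_comparison_ratio(r2_pl, r2_exp),
        relative_error_percent=rel,
        fit_window=tuple(window) if window is not None else None,
        n_points=int(xs.size),
        n_excluded=n_excluded,
    )
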