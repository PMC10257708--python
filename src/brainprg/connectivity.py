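"""Connectivity analyses: EDR fitting, normalization, strength, linear prediction.

The exponential distance rule (EDR) models large-scale coupling strength as
``C_ij ∝ exp(-gamma r_ij)`` with ``r_ij`` the Euclidean distance between
region centers.  :func:`fit_edr` recovers ``gamma`` by least squares on
``ln C_ij`` versus ``r_ij`` over short-range pairs (default < 50 mm), where
tract estimates are most reliable.

:func:`linear_prediction_scores` quantifies how well a coupling matrix
explains each signal linearly: the prediction of node i is ``(C X)_i``, the
weighted sum of all other signals, scored by Pearson correlation with the
actual signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ConnectivityMatrix, NodeGeometry

__all__ = [
    "ConnectivityMatrix",
    "EDRFit",
    "normalize_connectivity",
    "fit_edr",
    "node_strength",
    "linear_prediction_scores",
    "load_connectivity",
    "save_connectivity",
]

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class EDRFit:
    """Result of the exponential-distance-rule fit.

    gamma, gamma_error in 1/mm; r_squared is the R² of the log-linear
    regression; n_pairs is the number of (positive-weight, short-range)
    pairs actually used.
    """

    gamma: float
    gamma_error: float
    fit_max_distance: float
    r_squared: float
    n_pairs: int


def normalize_connectivity(raw) -> ConnectivityMatrix:
    """Divide weights by the largest entry so the maximum is 1.

    Accepts a raw square array or a :class:`ConnectivityMatrix`.  Asymmetric
    input (beyond 1e-9) is symmetrized by averaging with a warning; the
    diagonal is forced to zero.  Idempotent.
    """
    w = raw.weights if isinstance(raw, ConnectivityMatrix) else np.asarray(raw, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectivity must be square")
    if np.any(w < 0):
        raise ValueError("connectivity weights must be non-negative")
    if not np.allclose(w, w.T, atol=_SYM_TOL, rtol=0):
        warnings.warn("asymmetric connectivity; symmetrizing by (C + C.T)/2",
                      stacklevel=2)
        w = 0.5 * (w + w.T)
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    m = w.max()
    if m <= 0:
        raise ValueError("connectivity has no positive off-diagonal entry")
    return ConnectivityMatrix(weights=w / m, normalized=True)


def fit_edr(C: ConnectivityMatrix, geometry: NodeGeometry,
            max_distance: float = 50.0, n_bins: int | None = None) -> EDRFit:
    """Least-squares EDR fit of ``ln C_ij = -gamma r_ij + const``.

    Uses all upper-triangle pairs with positive weight and distance below
    ``max_distance``.  With ``n_bins`` set, fits distance-binned mean
    log-weights instead of raw pairs (an option; the default is raw pairs).

    Returns gamma = −slope with its standard error.
    """
    r = geometry.distance_matrix()
    iu = np.triu_indices(C.n_nodes, k=1)
    rr, ww = r[iu], C.weights[iu]
    mask = (ww > 0) & (rr < max_distance)
    n_pairs = int(mask.sum())
    if n_pairs < 3:
        raise ValueError(
            f"EDR fit needs >=3 positive-weight pairs below {max_distance} mm, "
            f"got {n_pairs}")
    x, y = rr[mask], np.log(ww[mask])
    if n_bins is not None:
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
        idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
        xb, yb = [], []
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                xb.append(x[sel].mean())
                yb.append(y[sel].mean())
        x, y = np.array(xb), np.array(yb)
    if np.ptp(y) == 0.0:
        # exactly flat (gamma = 0): regression slope 0 with no error
        return EDRFit(0.0, 0.0, max_distance, 1.0, n_pairs)
    res = stats.linregress(x, y)
    return EDRFit(gamma=-float(res.slope),
                  gamma_error=float(res.stderr),
                  fit_max_distance=max_distance,
                  r_squared=float(res.rvalue**2),
                  n_pairs=n_pairs)


def node_strength(C: ConnectivityMatrix) -> np.ndarray:
    """Per-node strength ``s_i = sum_{j != i} C_ij``."""
    return C.weights.sum(axis=1)


def linear_prediction_scores(C: ConnectivityMatrix, X: np.ndarray,
                             node_mask: tuple | None = None) -> np.ndarray:
    """Pearson correlation between each signal and its linear prediction (CX)_i.

    Parameters
    ----------
    C : ConnectivityMatrix
    X : (N, T) array of signals; rows must match C's nodes.
    node_mask : (source_idx, target_idx), optional
        Restrict the prediction to couplings from ``source_idx`` into
        ``target_idx`` (e.g. intra- or inter-hemispheric prediction).  Scores
        are returned for every node; nodes outside ``target_idx`` are NaN.

    Returns
    -------
    (N,) array of correlations; NaN (with a warning) for nodes whose signal
    or prediction has zero variance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != C.n_nodes:
        raise ValueError("X must be (N, T) with N matching the connectivity")
    n = C.n_nodes
    if node_mask is None:
        targets = np.arange(n)
        pred = C.weights @ X
    else:
        source, targets = (np.asarray(m, dtype=int) for m in node_mask)
        sub = np.zeros_like(C.weights)
        sub[np.ix_(targets, source)] = C.weights[np.ix_(targets, source)]
        pred = sub @ X
    scores = np.full(n, np.nan)
    for i in targets:
        xi, pi = X[i], pred[i]
        if np.ptp(xi) == 0.0 or np.ptp(pi) == 0.0:
            warnings.warn(f"zero-variance signal or prediction at node {i}; "
                          "score undefined", stacklevel=2)
            continue
        scores[i] = np.corrcoef(xi, pi)[0, 1]
    return scores


def load_connectivity(path, n_nodes: int | None = None) -> ConnectivityMatrix:
    """Read a connectivity from square delimited text or (i, j, w) triplets.

    Triplet files use 1-based node indices (neuroimaging convention);
    internally everything is 0-based.  A file is treated as a triplet list
    when it has exactly 3 columns and is not 3x3 square (a 3x3 matrix is
    read as a matrix).
    """
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] == 3 and (arr.shape[0] != 3 or n_nodes is not None):
        i = arr[:, 0].astype(int) - 1
        j = arr[:, 1].astype(int) - 1
        if n_nodes is None:
            n_nodes = int(max(i.max(), j.max())) + 1
        w = np.zeros((n_nodes, n_nodes))
        w[i, j] = arr[:, 2]
        w[j, i] = arr[:, 2]
        np.fill_diagonal(w, 0.0)
        return ConnectivityMatrix(weights=w)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("connectivity file is neither square nor a triplet list")
    return ConnectivityMatrix(weights=arr)


def save_connectivity(path, C: ConnectivityMatrix) -> None:
    np.savetxt(path, C.weights, fmt="%.8g")
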