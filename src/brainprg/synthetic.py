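"""Synthetic geometries, connectivities and binary rasters with known structure.

Every downstream stage of the pipeline (correlation function, PRG,
connectivity-based PRG, spin model) is exercised on data produced here, so
each generator targets a regime with an analytically known answer:

* independent Bernoulli rasters — variance and silence scaling exponents 1;
* fully correlated rasters — variance exponent exactly 2;
* dichotomized-Gaussian rasters with a power-law latent correlation kernel
  ``rho(r) = min(1, (r/r0)^-eta)`` — a distance-resolved correlation function
  whose binary-level exponent is computable from bivariate-normal orthant
  probabilities (:func:`dichotomized_gaussian_correlation`);
* EDR connectivities ``C_ij ∝ exp(-gamma r_ij)`` on uniform 3D geometries.

Two shuffling controls mirror the empirical null models: per-row time-frame
permutation (destroys all cross-correlations, preserves marginals) and
connectivity shuffling (preserves the weight multiset, destroys spatial
organization).

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import multivariate_normal, norm

from .core import BinaryRaster, ConnectivityMatrix, NodeGeometry

__all__ = [
    "NodeGeometry",
    "DEFAULT_EXTENT",
    "generate_positions",
    "generate_edr_connectivity",
    "generate_independent_raster",
    "generate_fully_correlated_raster",
    "generate_powerlaw_correlated_raster",
    "powerlaw_latent_kernel",
    "dichotomized_gaussian_correlation",
    "shuffle_time_frames",
    "shuffle_connectivity",
]

#: Default bounding box (mm) — human-cortex scale, giving pairwise distances
#: of the same order of magnitude as a whole-cortex parcellation.
DEFAULT_EXTENT = (140.0, 170.0, 100.0)


def generate_positions(n_nodes: int, extent=DEFAULT_EXTENT, seed: int = 0) -> NodeGeometry:
    """Uniform random node positions in a 3D box.

    Parameters
    ----------
    n_nodes : int
        Number of nodes (>= 2).
    extent : (float, float, float)
        Strictly positive box dimensions in mm.
    seed : int
        RNG seed; the same seed reproduces the same geometry bit-for-bit.
    """
    extent = np.asarray(extent, dtype=float)
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if extent.shape != (3,) or np.any(extent <= 0):
        raise ValueError("extent must be three strictly positive lengths (mm)")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, size=(n_nodes, 3)) * extent
    return NodeGeometry(positions=pos)


def generate_edr_connectivity(geometry: NodeGeometry, gamma: float) -> ConnectivityMatrix:
    """Exponential-distance-rule couplings ``C_ij ∝ exp(-gamma r_ij)``.

    Weights are normalized so the maximum off-diagonal entry is 1 and the
    diagonal is zero.  ``gamma`` is the decay rate in 1/mm; ``gamma = 0``
    gives a uniform (all-to-all) matrix.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    r = geometry.distance_matrix()
    w = np.exp(-gamma * r)
    np.fill_diagonal(w, 0.0)
    w /= w.max()
    return ConnectivityMatrix(weights=w, normalized=True)


def generate_independent_raster(n_nodes: int, n_frames: int, p: float,
                                seed: int = 0) -> BinaryRaster:
    """I.i.d. Bernoulli(p) raster — the uncorrelated reference regime."""
    _check_rate(p)
    rng = np.random.default_rng(seed)
    vals = (rng.random((n_nodes, n_frames)) < p).astype(np.int8)
    return BinaryRaster(values=vals, level=0)


def generate_fully_correlated_raster(n_nodes: int, n_frames: int, p: float,
                                     seed: int = 0) -> BinaryRaster:
    """One Bernoulli(p) series replicated to all nodes (correlation 1 everywhere)."""
    _check_rate(p)
    rng = np.random.default_rng(seed)
    row = (rng.random(n_frames) < p).astype(np.int8)
    return BinaryRaster(values=np.tile(row, (n_nodes, 1)), level=0)


def powerlaw_latent_kernel(geometry: NodeGeometry, eta: float,
                           psd_tol: float = 1e-8) -> np.ndarray:
    """Latent Gaussian correlation kernel ``rho(r) = min(1, (r/r0)^-eta)``.

    ``r0`` is the smallest pairwise distance in the geometry, so the kernel
    never exceeds 1.  The raw kernel need not be positive semidefinite; it is
    projected onto the PSD cone by clipping negative eigenvalues at 0 and the
    diagonal is renormalized back to 1.  Raises if the projection changes the
    kernel beyond ``psd_tol`` in max-norm by more than 50% of its range
    (the kernel is then not a usable covariance).
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    r = geometry.distance_matrix()
    r0 = r[r > 0].min()
    with np.errstate(divide="ignore"):
        rho = np.minimum(1.0, (r / r0) ** (-eta))
    np.fill_diagonal(rho, 1.0)
    evals, evecs = np.linalg.eigh(rho)
    if evals.min() < -psd_tol:
        evals = np.clip(evals, 0.0, None)
        rho_psd = (evecs * evals) @ evecs.T
        d = np.sqrt(np.diag(rho_psd))
        if np.any(d <= 0):
            raise ValueError("kernel is not PSD-projectable (zero diagonal after clip)")
        rho_psd = rho_psd / np.outer(d, d)
        if np.max(np.abs(rho_psd - rho)) > 0.5:
            raise ValueError("kernel too far from PSD; projection distorts it >0.5")
        rho = rho_psd
        np.fill_diagonal(rho, 1.0)
    return rho


def generate_powerlaw_correlated_raster(geometry: NodeGeometry, eta: float,
                                        theta: float = 1.0, n_frames: int = 1200,
                                        seed: int = 0) -> BinaryRaster:
    """Dichotomized-Gaussian raster with power-law distance correlations.

    A zero-mean unit-variance Gaussian field with covariance
    ``rho(r_ij) = min(1, (r_ij/r0)^-eta)`` is sampled per frame and
    thresholded at ``theta`` (z-units): entries are 1 where the latent field
    exceeds ``theta``.  The resulting binary correlations follow a slightly
    flattened power law of distance whose exact form is given by
    :func:`dichotomized_gaussian_correlation`.
    """
    rho = powerlaw_latent_kernel(geometry, eta)
    rng = np.random.default_rng(seed)
    # sample via eigen-factor (rho is PSD by construction)
    evals, evecs = np.linalg.eigh(rho)
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = factor @ rng.standard_normal((geometry.n_nodes, n_frames))
    return BinaryRaster(values=(z > theta).astype(np.int8), level=0)


def dichotomized_gaussian_correlation(rho, theta: float):
    """Binary Pearson correlation after thresholding a bivariate normal.

    For latent correlation ``rho`` and threshold ``theta``, the thresholded
    variables are Bernoulli(q) with ``q = 1 - Phi(theta)`` and joint success
    probability ``P11 = P(Z1 > theta, Z2 > theta)``; their Pearson
    correlation is ``(P11 - q^2) / (q (1 - q))``.  This is the numeric
    oracle used to predict the correlation-function exponent of the
    dichotomized-Gaussian fixture.  Accepts scalars or arrays.
    """
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(np.abs(rho_arr) > 1):
        raise ValueError("latent correlation must be in [-1, 1]")
    q = norm.sf(theta)
    out = np.empty_like(rho_arr)
    for i, rh in np.ndenumerate(rho_arr):
        if rh >= 1.0:
            out[i] = 1.0
            continue
        mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rh], [rh, 1.0]])
        # orthant probability P(Z1 > theta, Z2 > theta) via survival symmetry
        p11 = mvn.cdf([-theta, -theta])
        out[i] = (p11 - q * q) / (q * (1.0 - q))
    return out if np.asarray(rho).ndim else float(out[0])


def shuffle_time_frames(raster: BinaryRaster, seed: int = 0) -> BinaryRaster:
    """Permute time frames independently per row (destroys cross-correlations).

    Row marginals (activation rates) are preserved exactly.  Only defined for
    level-0 rasters: the control models shuffling the recording itself.
    """
    if raster.level != 0:
        raise ValueError("frame shuffling is defined for level-0 rasters only")
    rng = np.random.default_rng(seed)
    vals = raster.values
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        out[i] = vals[i, rng.permutation(vals.shape[1])]
    return BinaryRaster(values=out, level=0)


def shuffle_connectivity(C: ConnectivityMatrix, seed: int = 0) -> ConnectivityMatrix:
    """Permute upper-triangle weights, mirror to the lower triangle.

    Preserves the multiset of off-diagonal weights (hence the weight
    distribution) while destroying any relation between weight and node
    position; the diagonal stays zero.
    """
    rng = np.random.default_rng(seed)
    w = C.weights
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = w[iu].copy()
    rng.shuffle(vals)
    out = np.zeros_like(w)
    out[iu] = vals
    out = out + out.T
    return ConnectivityMatrix(weights=out, normalized=C.normalized)


def _check_rate(p: float) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError("activation rate p must satisfy 0 < p < 1")


def save_geometry(path, geometry: NodeGeometry) -> None:
    """Write positions as 3-column whitespace-delimited text (mm)."""
    np.savetxt(path, geometry.positions, fmt="%.6f")


def load_geometry(path) -> NodeGeometry:
    return NodeGeometry(positions=np.loadtxt(path, ndmin=2))
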