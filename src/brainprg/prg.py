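"""Phenomenological renormalization group (PRG) for binary multivariate activity.

The PRG coarse-grains an N-variable binary raster by repeatedly pairing the
two most similar remaining variables and summing them:

    sigma'_{i'} = sigma_{i*} + sigma_{j*},

yielding clusters of size K = 2^k after k steps.  Similarity is either the
pairwise Pearson correlation recomputed at each level (correlation mode) or
a structural coupling matrix coarse-grained alongside the activity
(connectivity mode, where the coarse weight between two clusters is the mean
of the four cross-pair weights and hence, at level k, the mean of 4^k
original weights).

Three observables are tracked as functions of K and fitted as power laws:

* ``variance_curve`` — mean variance of coarse variables, V(K) ~ K^alpha;
  alpha = 1 for independent variables, 2 for fully correlated ones.
* ``silence_curve`` — effective free energy F(K) = ln P_silence(K), the log
  of the mean per-cluster probability of a fully silent frame;
  F(K)/F(1) ~ K^beta, with beta = 1 for independent variables.
* ``eigenspectrum_curve`` — eigenvalues of the within-cluster covariance of
  the member level-0 signals versus relative rank, lambda ~ (rank/K)^-mu,
  collapsing across K at a scale-invariant fixed point.

When the retained count at some level is odd, the leftover variable is
dropped from deeper levels so every cluster has exactly 2^k members; drops
are recorded in the hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BinaryRaster, ConnectivityMatrix
from .powerlaw import PowerLawFitResult, fit_power_law_with_alternative
from .signals import pairwise_pearson

__all__ = [
    "Pairing",
    "CoarseGrainHierarchy",
    "ScalingCurve",
    "pair_greedy",
    "coarse_grain_raster",
    "coarse_grain_connectivity",
    "run_prg",
    "variance_curve",
    "silence_curve",
    "eigenspectrum_curve",
    "mu_eta_relation",
    "subsample_prg",
]

#: Minimum samples-per-variable ratio for trustworthy covariance spectra.
SAMPLES_PER_VARIABLE = 10


@dataclass(frozen=True)
class Pairing:
    """Disjoint index pairs covering all indices except at most one leftover."""

    pairs: tuple
    leftover: int | None = None


@dataclass
class ScalingCurve:
    """Observable values per cluster size K, normalized at K = 1."""

    K: np.ndarray
    values: np.ndarray
    reference: float  # raw value at k = 0 used for normalization


@dataclass
class CoarseGrainHierarchy:
    """Everything produced by one PRG run.

    ``rasters[k]`` is the level-k raster, ``pairings[k]`` the pairing that
    produced level k+1, ``memberships[k]`` maps each level-k variable to the
    array of level-0 node ids it aggregates, ``connectivities[k]`` the
    coarse coupling matrix (connectivity mode only) and ``discarded[k]`` the
    level-0 ids dropped when the count at level k was odd.
    """

    mode: str
    rasters: list
    pairings: list
    memberships: list
    connectivities: list | None
    discarded: list

    @property
    def k_max(self) -> int:
        return len(self.rasters) - 1

    def cluster_sizes(self) -> np.ndarray:
        return 2 ** np.arange(self.k_max + 1)


def pair_greedy(similarity: np.ndarray) -> Pairing:
    """Greedy maximal pairing: repeatedly take the largest remaining entry.

    Selects the globally maximal (signed) off-diagonal entry, removes both
    indices, and repeats among the remaining variables.  Equivalent to a
    single descending sweep over the sorted upper-triangle entries accepting
    pairs whose endpoints are both still free.  Ties are broken by the
    smallest first index, then smallest second.  Odd N leaves one leftover.
    """
    s = np.asarray(similarity, dtype=float)
    n = s.shape[0]
    if s.ndim != 2 or s.shape[1] != n:
        raise ValueError("similarity must be square")
    if n < 2:
        raise ValueError("need at least 2 variables to pair")
    if not np.all(np.isfinite(s[~np.eye(n, dtype=bool)])):
        raise ValueError("similarity entries must be finite")
    iu, ju = np.triu_indices(n, k=1)
    vals = s[iu, ju]
    # stable sort on (-value, i, j) implements the documented tie rule
    order = np.lexsort((ju, iu, -vals))
    used = np.zeros(n, dtype=bool)
    pairs = []
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        if used[i] or used[j]:
            continue
        used[i] = used[j] = True
        pairs.append((i, j))
        if len(pairs) == n // 2:
            break
    leftover = int(np.flatnonzero(~used)[0]) if n % 2 else None
    return Pairing(pairs=tuple(pairs), leftover=leftover)


def coarse_grain_raster(raster: BinaryRaster, pairing: Pairing) -> BinaryRaster:
    """Sum each pair of rows; the leftover row (odd N) is discarded."""
    v = raster.values
    n = v.shape[0]
    idx = np.array([p for pair in pairing.pairs for p in pair])
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("pairing indices out of range for raster")
    a = np.array([p[0] for p in pairing.pairs])
    b = np.array([p[1] for p in pairing.pairs])
    return BinaryRaster(values=v[a] + v[b], level=raster.level + 1)


def coarse_grain_connectivity(C: np.ndarray, pairing: Pairing) -> np.ndarray:
    """Coarse coupling between clusters = mean of the 4 cross-pair weights.

    For clusters m' = {i, j} and n' = {k, l}:
    C'_{m'n'} = (C_ik + C_il + C_jk + C_jl) / 4.  Output symmetric with zero
    diagonal.
    """
    C = np.asarray(C, dtype=float)
    a = np.array([p[0] for p in pairing.pairs])
    b = np.array([p[1] for p in pairing.pairs])
    out = 0.25 * (C[np.ix_(a, a)] + C[np.ix_(a, b)]
                  + C[np.ix_(b, a)] + C[np.ix_(b, b)])
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return out


def run_prg(raster: BinaryRaster, k_max: int = 6, mode: str = "correlation",
            C: ConnectivityMatrix | np.ndarray | None = None) -> CoarseGrainHierarchy:
    """Iterate pairing + summation to depth ``k_max``.

    correlation mode recomputes pairwise Pearson correlations of the current
    coarse variables at every level; connectivity mode pairs by the coarse
    coupling matrix, which is updated by :func:`coarse_grain_connectivity`
    (pairing then never depends on the activity).

    Requires T >= 10 * 2^k_max frames so covariance spectra at the deepest
    level keep >10 samples per variable.
    """
    if mode not in ("correlation", "connectivity"):
        raise ValueError("mode must be 'correlation' or 'connectivity'")
    if raster.level != 0:
        raise ValueError("PRG starts from a level-0 raster")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    T = raster.n_frames
    if T < SAMPLES_PER_VARIABLE * 2**k_max:
        admissible = int(np.floor(np.log2(max(T // SAMPLES_PER_VARIABLE, 1))))
        raise ValueError(
            f"T={T} frames supports clusters up to 2^{admissible} "
            f"(needs >= {SAMPLES_PER_VARIABLE} samples per variable); "
            f"requested k_max={k_max}")
    if 2**k_max > raster.n_nodes:
        raise ValueError("k_max too deep for the number of nodes")

    conn = None
    if mode == "connectivity":
        if C is None:
            raise ValueError("connectivity mode requires a coupling matrix")
        conn = C.weights if isinstance(C, ConnectivityMatrix) else np.asarray(C, float)
        if conn.shape[0] != raster.n_nodes:
            raise ValueError("coupling matrix size does not match raster")

    rasters = [raster]
    memberships = [[np.array([i]) for i in range(raster.n_nodes)]]
    pairings: list[Pairing] = []
    connectivities = [conn] if conn is not None else None
    discarded: list[np.ndarray] = []

    cur = raster
    cur_members = memberships[0]
    cur_conn = conn
    for _ in range(k_max):
        if mode == "correlation":
            sim = pairwise_pearson(cur)
            nan = ~np.isfinite(sim)
            np.fill_diagonal(nan, False)
            if nan.any():
                # constant variables have undefined correlation: rank them
                # below every real correlation so they pair up last
                warnings.warn("undefined correlations (constant variables); "
                              "ranked below all finite ones", stacklevel=2)
                sim = np.where(nan, -2.0, sim)
        else:
            sim = cur_conn
        pairing = pair_greedy(sim)
        pairings.append(pairing)
        if pairing.leftover is not None:
            discarded.append(cur_members[pairing.leftover].copy())
        else:
            discarded.append(np.array([], dtype=int))
        nxt = coarse_grain_raster(cur, pairing)
        cur_members = [np.concatenate([cur_members[i], cur_members[j]])
                       for i, j in pairing.pairs]
        if mode == "connectivity":
            cur_conn = coarse_grain_connectivity(cur_conn, pairing)
            connectivities.append(cur_conn)
        rasters.append(nxt)
        memberships.append(cur_members)
        cur = nxt
    return CoarseGrainHierarchy(mode=mode, rasters=rasters, pairings=pairings,
                                memberships=memberships,
                                connectivities=connectivities,
                                discarded=discarded)


def variance_curve(h: CoarseGrainHierarchy):
    """Mean variance of coarse variables vs K, normalized at K=1, with fit.

    V(K) is the average over retained level-k variables of their temporal
    variance; the power-law fit of the normalized curve gives the exponent
    alpha (V ~ K^alpha).
    """
    if h.k_max < 2:
        raise ValueError("need a hierarchy with k_max >= 2 to fit a slope")
    K = h.cluster_sizes().astype(float)
    V = np.array([r.values.var(axis=1, ddof=0).mean() for r in h.rasters])
    if V[0] == 0:
        raise ValueError("level-0 variance is zero; nothing to normalize by")
    curve = ScalingCurve(K=K, values=V / V[0], reference=float(V[0]))
    fit = fit_power_law_with_alternative(K, curve.values)
    return curve, fit


def silence_curve(h: CoarseGrainHierarchy):
    """Effective free energy F(K) = ln P_silence(K), normalized, with fit.

    P_silence(K) is the mean over retained clusters of the fraction of
    frames in which the coarse variable equals 0 (per-cluster silence,
    averaged before taking the log).  The fitted exponent beta comes from
    the log-log slope of F(K)/F(1) versus K.  Levels where no silent frame
    remains are excluded with a warning.  Only defined for {0,1} data.
    """
    v0 = h.rasters[0].values
    if v0.min() < 0 or v0.max() > 1:
        raise ValueError("silence observable requires a {0,1} level-0 raster")
    K = h.cluster_sizes().astype(float)
    P = np.array([(r.values == 0).mean(axis=1).mean() for r in h.rasters])
    if P[0] >= 1.0:
        raise ValueError("all-silent raster: F(1) = 0, scaling undefined")
    if P[0] <= 0.0:
        raise ValueError("no silent frame at level 0; F(1) undefined")
    keep = P > 0
    if not keep.all():
        warnings.warn(f"levels {np.flatnonzero(~keep).tolist()} have zero "
                      "silence probability; excluded from the fit", stacklevel=2)
    F = np.full_like(P, np.nan)
    F[keep] = np.log(P[keep])
    curve = ScalingCurve(K=K, values=F / F[0], reference=float(F[0]))
    fit = fit_power_law_with_alternative(K[keep], curve.values[keep])
    return curve, fit


def eigenspectrum_curve(h: CoarseGrainHierarchy, K_set=(8, 16, 32, 64),
                        rank_fraction_max: float = 0.4):
    """Within-cluster covariance spectra vs relative rank, pooled mu fit.

    For each cluster of size K (members traced back to level-0 nodes), the
    eigenvalues of the K×K covariance of the member level-0 signals are
    sorted descending and averaged rank-wise across clusters of that K.
    The exponent mu is fitted pooled over all K in ``K_set`` on
    lambda vs rank/K restricted to 1/K < rank/K < ``rank_fraction_max``
    (avoiding the finite-size truncation at high relative rank).

    Returns (dict K -> mean spectrum, PowerLawFitResult).
    """
    T = h.rasters[0].n_frames
    v0 = h.rasters[0].values.astype(float)
    spectra: dict[int, np.ndarray] = {}
    xs, ys = [], []
    sizes = set(int(k) for k in h.cluster_sizes())
    for K in K_set:
        if K not in sizes:
            raise ValueError(f"K={K} is not a level of this hierarchy")
        if K > 1 and T < SAMPLES_PER_VARIABLE * K:
            warnings.warn(f"K={K} violates the {SAMPLES_PER_VARIABLE}x samples"
                          " rule; excluded", stacklevel=2)
            continue
        k = int(np.log2(K))
        members = h.memberships[k]
        acc = np.zeros(K)
        for mem in members:
            cov = np.cov(v0[mem], ddof=0) if K > 1 else np.atleast_2d(np.var(v0[mem]))
            ev = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
            acc += ev
        spec = acc / len(members)
        spectra[K] = spec
        rank = np.arange(1, K + 1)
        rel = rank / K
        m = (rel > 1.0 / K) & (rel < rank_fraction_max) & (spec > 0)
        xs.append(rel[m])
        ys.append(spec[m])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    fit = fit_power_law_with_alternative(x, y)
    # report mu as the positive decay exponent
    fit = PowerLawFitResult(
        exponent=-fit.exponent, intercept=fit.intercept,
        exponent_error=fit.exponent_error, r2_powerlaw=fit.r2_powerlaw,
        exp_rate=fit.exp_rate, exp_intercept=fit.exp_intercept,
        r2_exponential=fit.r2_exponential, r_ev=fit.r_ev,
        relative_error_percent=fit.relative_error_percent,
        fit_window=fit.fit_window, n_points=fit.n_points,
        n_excluded=fit.n_excluded)
    return spectra, fit


def mu_eta_relation(D: float, eta: float) -> float:
    """Predicted spectrum exponent mu = (D - eta)/D for a translation-invariant
    D-dimensional system with g(r) ~ r^-eta."""
    if D <= 0:
        raise ValueError("D must be > 0")
    if not 0 <= eta <= D:
        raise ValueError("eta must lie in [0, D]")
    return (D - eta) / D


def subsample_prg(raster: BinaryRaster, fraction: float, seed: int = 0,
                  k_max: int = 6, mode: str = "correlation", C=None):
    """PRG exponents on a random node subset of the given fraction.

    Returns dict with alpha, beta (correlation-mode silence defined for
    {0,1} data), the retained node ids, and the hierarchy.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = raster.n_nodes
    n_keep = int(round(fraction * n))
    if n_keep < 2**k_max:
        raise ValueError(f"subset of {n_keep} nodes cannot support k_max={k_max}")
    if n_keep == n:
        idx = np.arange(n)
    else:
        idx = np.sort(np.random.default_rng(seed).choice(n, n_keep, replace=False))
    sub = BinaryRaster(values=raster.values[idx], level=0)
    subC = None
    if C is not None:
        w = C.weights if isinstance(C, ConnectivityMatrix) else np.asarray(C, float)
        subC = w[np.ix_(idx, idx)]
    h = run_prg(sub, k_max=k_max, mode=mode, C=subC)
    _, afit = variance_curve(h)
    out = {"alpha": afit.exponent, "alpha_fit": afit, "nodes": idx, "hierarchy": h}
    try:
        _, bfit = silence_curve(h)
        out["beta"] = bfit.exponent
        out["beta_fit"] = bfit
    except ValueError:
        out["beta"] = np.nan
    return out
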