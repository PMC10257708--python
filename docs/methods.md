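# Methods

This note documents the models and procedures implemented in `brainprg`,
the choices made where several reasonable implementations exist, and what
the synthetic-data generators do and do not emulate.

## Problem setting

Resting-state whole-brain recordings (e.g. parcellated fMRI time series)
show scale-invariant statistics: pairwise correlations decay as a power law
of inter-region distance, and coarse-grained activity statistics scale as
power laws of the coarse-graining cluster size. `brainprg` measures these
scaling features on binarized multivariate recordings and asks, through an
interacting spin model on a distance-dependent connectome, whether they are
consistent with dynamics near a second-order phase transition.

## Binarization

Continuous signals are z-scored per region over the full record and
thresholded: `sigma_i(t) = 1` if `z_i(t) > theta`, else 0, with
`theta = 1` z-unit by default. Binarization makes the activity comparable
to the ±1 spin model's and is invariant under positive affine transforms of
each signal. Zero-variance rows are rejected, never silently imputed.

## Correlation function g(r)

`g(r)` is the mean pairwise Pearson correlation over node pairs whose
Euclidean distance falls in `[r, r + dr)`, with `dr = 0.43` mm by default.
Bins are half-open to prevent double counting. The power-law exponent
`eta` comes from an ordinary-least-squares fit of `log g` on `log r` over a
distance window (default 10–90 mm, configurable); bins with `g <= 0` have
no logarithm, are excluded, and their count is reported.
`scan_fit_window` maps the sensitivity of `eta` to the window choice.

## Power-law fitting and model comparison

Scaling curves here are deterministic relations, not probability
densities, so likelihood-based tail estimators do not apply. Both
candidate models are fitted by OLS on exactly the same points —
`log y = a log x + b` (power law) and `log y = c x + d` (exponential) —
and compared through the explained-variance ratio
`R_EV = R2_PL / R2_Exp`; `R_EV > 1` favors the power law. The exponent
standard error is the OLS slope error; the relative estimation error is
`100 * Delta_a / |a|`. Natural logarithms are used internally (the base
cancels in exponents and R²). Weighted fitting (e.g. by pair counts) is
available as an option but off by default.

## Phenomenological renormalization group (PRG)

Starting from the `{0,1}` raster, the two most similar remaining variables
are paired and summed, giving clusters of size `K = 2^k` after `k` levels.

* **Correlation mode** recomputes pairwise Pearson correlations of the
  current coarse variables at every level and pairs by the maximal signed
  correlation (summing anti-correlated variables would cancel variance and
  break the interpretation of the growth exponent). Greedy selection of
  the global maximum is implemented as a single descending sweep over the
  sorted entries; ties break to the smallest first index, then second —
  an explicit, reproducible rule. Variables with undefined correlation
  (constant rows, which occur in ordered spin traces) are ranked below all
  finite correlations, so they pair with each other last.
* **Connectivity mode** pairs by a structural coupling matrix instead, and
  coarse-grains the matrix alongside the activity: the coarse weight
  between clusters `{i,j}` and `{k,l}` is the mean of the four
  cross-weights, so a level-k weight is exactly the mean of the `4^k`
  original cross-weights. Pairing in this mode never depends on the
  activity.

When the retained count at some level is odd, the leftover variable is
dropped from deeper levels and logged. This keeps every cluster at exactly
`2^k` members, which the observables assume; the alternative (carrying a
smaller cluster along) would mix cluster sizes within one level.

Observables, each normalized by its level-0 value and fitted as a power
law of `K` over `1 <= K <= 64` by default:

* **Variance** `V(K)`: mean temporal variance of the coarse variables;
  `V ~ K^alpha` with `alpha = 1` for independent and `alpha = 2` for fully
  correlated variables.
* **Silence free energy** `F(K) = ln P_silence(K)`: `P_silence` is the
  probability that a coarse variable is exactly 0 in a frame, averaged
  across retained clusters, then logged ("mean-then-log"). The
  whole-population alternative reading (all clusters silent
  simultaneously) would make `F` essentially K-independent and could not
  scale as `-K^beta` with `beta < 1`; per-cluster averaging is therefore
  used. Levels where no silent frame remains are excluded with a warning.
  `F(K)/F(1) = K` (so `beta = 1`) for independent variables; the silence
  observable is undefined for ±1 spin data, which has no silent state.
* **Eigen-spectrum**: for each cluster of size `K`, the eigenvalues of the
  K×K covariance of the member *level-0* signals, sorted descending and
  averaged rank-wise across clusters of equal `K`. At a scale-invariant
  fixed point the spectra collapse against relative rank and decay as
  `lambda ~ (rank/K)^-mu`. The exponent is fitted pooled over
  `K in {8, 16, 32, 64}` within `1/K < rank/K < 0.4`, avoiding both the
  leading collective mode and the finite-size truncation; smaller clusters
  are excluded because the estimate only stabilizes for `K > 8`.

Covariance spectra are only trusted when there are at least 10 times more
time frames than variables per cluster; `run_prg` enforces
`T >= 10 * 2^k_max` and reports the maximal admissible depth otherwise.

For a translation-invariant D-dimensional critical system the two
exponents are linked by `mu = (D - eta)/D` (`mu_eta_relation`); measured
brain exponents violate this relation, which is itself informative (no
translation invariance).

## Exponential distance rule and linear prediction

The EDR connectivity model is `C_ij ∝ exp(-gamma * r_ij)` with weights
normalized by the maximum entry. `fit_edr` estimates `gamma` by OLS of
`ln C_ij` on `r_ij` over positive-weight pairs closer than 50 mm (where
tractography weights are most reliable); per-pair fitting is the default
because it is unbiased under the noiseless model, with distance-binned
fitting as an option. Linear predictability of each signal from the rest
of the network is the Pearson correlation between `X_i` and `(C X)_i`;
source/target masks allow intra- and inter-hemispheric variants.
Prediction-score distributions are compared with Welch's t-test after
Fisher z-transformation; exponent distributions with Wilcoxon tests
(signed-rank for equal-length paired samples, rank-sum otherwise).

## Spin model

Configurations `sigma in {-1,+1}^N` follow
`P(sigma) ∝ exp(beta * sum_{i,j} C_ij sigma_i sigma_j)` with the sum over
ordered index pairs (each undirected pair counted twice) and `beta = 1/T`
the single free parameter. Because `beta` sits inside the energy, the
Metropolis acceptance for an uphill flip is `exp(-dE)` with
`dE = 4 beta sigma_i h_i`; applying an extra factor of `beta` in the
acceptance would count the temperature twice. In this convention two
coupled spins satisfy `<sigma1 sigma2> = tanh(2 beta c)` and the periodic
square lattice orders at `beta_c = ln(1+sqrt(2))/4`; both closed forms are
used as test oracles, along with exact 2^N enumeration for `N <= 15`.

Sampling: single-spin-flip Metropolis from a uniform random start, burn-in
of 500,000 attempts by default, one stored configuration per `N` attempts.
Local fields are cached and updated incrementally (O(N) per accepted
flip); an optional periodic rebuild guards against float drift and is
verified in tests to leave trajectories unchanged.

Observables per `beta` are averaged over 5 independent realizations. The
order parameter is `<|M|>` per realization (global spin-flip symmetry makes
`<M>` average to zero across realizations); `<M>` is also reported to show
the two ordered branches. The susceptibility
`chi = N (<M^2> - <|M|>^2)` is aggregated across realizations by the
*median*: single-spin-flip chains occasionally freeze into metastable
domain (stripe) states deep in the ordered phase, and a single trapped
chain otherwise injects large spurious variance into the mean.

`beta_c` is located at the susceptibility peak, refined by quadratic
interpolation through the three points around it — the standard
finite-size estimator; the scan must straddle both phases and the peak
must be interior. The search grid is anchored a priori at the mean-field
estimate `beta_MF = 1/(2 lambda_max(C))`: a geometric coarse scan over
`[0.2, 6] x beta_MF` (the top of this range sits deep in the ordered phase
for EDR-type connectomes) followed by a linear refinement over
`[0.75, 1.35]` times the coarse peak.

## Synthetic data

The generators produce data in regimes with known answers:

* uniform node positions in a 140 × 170 × 100 mm box — the bounding scale
  of a human cortex, giving pairwise distances of the same order as a
  whole-cortex parcellation (a few mm to ~170 mm);
* EDR connectivities with `gamma = 0.106` /mm as the default decay rate,
  the value estimated for human-scale connectomes;
* independent and fully correlated Bernoulli rasters (activation rate as
  specified, default near the `theta = 1` tail rate of a Gaussian, 0.16);
* dichotomized-Gaussian rasters: a latent Gaussian field with power-law
  distance kernel `rho(r) = min(1, (r/r0)^-eta)` — clipped at 1, projected
  to the nearest PSD matrix by eigenvalue clipping with renormalized
  diagonal — thresholded at `theta`. The binary-level correlation implied
  by a latent correlation is computed exactly from bivariate-normal
  orthant probabilities (`dichotomized_gaussian_correlation`), which
  serves as the independent oracle for the recovered exponent;
* the two null models used empirically: per-row time-frame shuffling
  (preserves marginals, destroys cross-correlations) and connectivity
  shuffling (preserves the weight multiset, destroys spatial structure).

What the generators do *not* emulate: hemodynamics, temporal
autocorrelation of BOLD signals, subject-to-subject variability, atlas
geometry, or measurement noise of tractography. Tests passing on these
surrogates therefore validate the *estimators* (they recover known
exponents under the stated generative assumptions), not the empirical
claims about brain recordings, which require the corresponding data.

## Problem sizes used in tests and the acceptance script

Analytic-limit checks use 512 series of 20,000 frames (deep enough for
K = 64 with >10 samples per variable at every level). The Metropolis
sampler is validated against exact enumeration on 5–10-spin systems with
200,000 stored configurations, and against the lattice critical point on a
32 × 32 torus. The spin-model study runs on a 256-node synthetic EDR
connectome with 10,000 stored configurations per realization and 5
realizations per temperature — a scaled-down surrogate of the full
1000-node protocol (50,000 configurations), chosen as a single-workstation
configuration. At this scale the located critical point carries a few
percent of uncertainty, to which the correlation exponent `eta` is quite
sensitive, and the eigen-spectrum exponent `mu` is inflated relative to
larger systems; the variance exponent `alpha` is already stable.

## Known limitations

* Greedy max-correlation pairing is a heuristic, not a maximum-weight
  matching; it is the method's definition, not an approximation we chose.
* OLS exponents on log-transformed curves inherit the usual small-sample
  bias and window sensitivity; `scan_fit_window` quantifies the latter.
* Single-spin-flip dynamics equilibrates slowly near and below the
  critical temperature; deep-ordered traces can freeze into domain states.
  Cluster algorithms were deliberately not implemented (the sampling
  protocol is part of the method definition).
* The silence observable requires `{0,1}` data and is undefined for spin
  traces; the `beta` exponent therefore has no model counterpart.
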