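# brainprg

Scale-invariance diagnostics for whole-brain activity, and a spin model to
interpret them.

`brainprg` is for researchers who have parcellated multivariate recordings
(region × time matrices, e.g. resting-state fMRI), region coordinates, and
optionally a structural connectome, and who want to ask: *do these
dynamics look critical?* It implements:

* **Binarization** of continuous signals (per-region z-score, threshold
  θ = 1 z-unit).
* The **correlation function** g(r) — mean pairwise Pearson correlation of
  regions at distance r — and its power-law exponent η̃ from
  `g(r) ~ r^−η̃`, with a full `[r_min, r_max]` window-sensitivity scan.
* The **phenomenological renormalization group (PRG)**: iteratively sum
  the two most correlated variables, building clusters of size `K = 2^k`,
  and track three observables against K:
  variance `V(K) ~ K^α̃`, silence free energy
  `F(K) = ln P_silence(K) ~ −K^β̃`, and the within-cluster covariance
  eigen-spectrum `λ ~ (rank/K)^−μ`. Independent signals give α̃ = β̃ = 1;
  fully correlated signals give α̃ = 2.
* The **connectivity-based PRG**, which pairs variables by a structural
  coupling matrix instead of correlations and coarse-grains the matrix
  alongside (the level-k weight is the exact mean of 4^k original
  cross-weights).
* **Power-law fitting** by least squares on log-log data with an
  exponential alternative fitted on the same points and compared through
  the explained-variance ratio `R_EV = R²_PL / R²_Exp` (> 1 favors the
  power law).
* The **exponential distance rule (EDR)** connectivity model
  `C_ij ∝ exp(−γ r_ij)`: fitting γ from a connectome, generating EDR
  connectomes, node strength, and linear signal prediction `X_pred = CX`.
* A **pairwise spin model** on a weighted connectome,
  `P(σ) ∝ exp(β Σ_ij C_ij σ_i σ_j)`, sampled by Metropolis dynamics, with
  β-scans, susceptibility-peak location of the critical point β_c, and an
  exact-enumeration oracle for small systems. Near β_c the model
  reproduces power-law g(r) and PRG scaling; away from it, it does not —
  which is what makes the measured exponents interpretable.
* **Synthetic generators** for every regime with a known answer
  (independent, fully correlated, distance-dependent dichotomized-Gaussian
  rasters, EDR connectomes) plus the two empirical null models
  (time-frame shuffling, connectivity shuffling).

See `docs/methods.md` for the full description of each procedure and the
numerical choices.

## Worked example

Generate a 128-node synthetic recording with power-law distance
correlations and an EDR connectome, then measure everything:

```bash
brainprg synth --n-nodes 128 --n-frames 2000 --kind powerlaw_field \
    --eta 0.5 --seed 42 --out data
brainprg corrfunc data/raster.tsv --geometry data/geometry.tsv --dr 4 --out gr.tsv
brainprg prg data/raster.tsv --k-max 5 --out prg.json
brainprg fit-edr data/connectivity.tsv --geometry data/geometry.tsv
```

prints

```
wrote geometry, connectivity and powerlaw_field raster to data
eta = 0.5734 +/- 0.0103 (R2 = 0.9939, R_EV = 1.087)
alpha = 1.3645  beta = 0.7969  mu = 0.2599
gamma = 0.1060 +/- 0.0000 1/mm (R2 = 1.0000, 1116 pairs)
```

Reading the numbers: the correlation function decays as a clean power law
(R² = 0.99) with exponent η̃ ≈ 0.57, close to the η = 0.5 built into the
generator, and the power law beats the exponential alternative
(R_EV > 1). The PRG variance exponent α̃ ≈ 1.36 sits between the
uncorrelated (1) and fully correlated (2) limits, the silence exponent
β̃ ≈ 0.80 is below the independent-variable value of 1, and the
eigen-spectrum decays with μ ≈ 0.26 — the signature pattern of spatially
correlated, scale-invariant activity. The EDR fit recovers the generating
decay rate γ = 0.106 mm⁻¹ exactly because the synthetic weights are
noiseless.

The same analyses run on your own data: `brainprg binarize` for
continuous signals, then the commands above, or `brainprg full
config.yaml` for an end-to-end run (binarize → g(r) → PRG in both modes →
fits → optional spin-model scan) with one master seed and a JSON report.
The spin model is exposed as `brainprg spin scan --connectivity C.tsv
--betas 0.1,0.15,... --out scan.tsv`.

As a library:

```python
from brainprg import synthetic, prg

raster = synthetic.generate_independent_raster(512, 20_000, p=0.2, seed=0)
h = prg.run_prg(raster, k_max=6)
curve, fit = prg.variance_curve(h)
print(fit.exponent)   # ~1.02: independent variables scale linearly
```

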