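# Methods

## The seizure-transition model

Each region of interest (ROI) is a theta-model phase oscillator,

    dtheta_i/dt = (1 - cos theta_i) + (1 + cos theta_i) * I_i(t),
    I_i(t) = I0 + sigma * xi_i(t) + (K/N) * sum_{j != i} a_ji * [1 - cos(theta_j - theta_s)],

with shared cortical excitability `I0`, unit-variance Gaussian noise `xi_i`
scaled by `sigma`, and symmetric non-negative coupling `A = (a_ji)` (in
practice PLV values in [0, 1]). For `I0 < 0` the single-node dynamics have a
stable fixed point `theta_s = -arccos((1+I0)/(1-I0))` (rest) and a saddle at
the positive arccos branch; the two annihilate at `I0 = 0` in a saddle-node
on invariant circle (SNIC) bifurcation, beyond which the phase rotates. We
identify rest with normal activity and rotation with the seizure state;
noise drives transitions between them for sub-threshold `I0`.

Assumptions worth stating explicitly: all nodes share `I0` and `theta_s`
(homogeneous local excitability); the network is static and independent of
excitability; coupling enters only through how far *other* nodes are from
rest, so a fully resting network receives zero interaction.

### Integration and noise convention

Simulations use Euler–Maruyama. The noise term is
`(1 + cos theta) * sigma * sqrt(dt) * z` with `z ~ N(0,1)` per node per step
(`noise_scaling="sqrt_dt"`, the default). A `"dt"` variant (noise folded
into the input current and multiplied by `dt`) is selectable because the
literature that fixes `sigma = 6` is not explicit about the discretization;
under the default convention the operating regime is escape-limited and
`P_sz` at the top of the excitability grid is of order 0.1 rather than 1.
All group-level quantities are comparisons under identical settings, so this
affects absolute BNI scales, not contrasts.

Gaussian increments come from numpy's PCG64 generator, drawn in chunks
outside the compiled stepping kernel. This makes trajectories bit-reproducible
for a given `(network, params, seed)`, independent of the JIT, and lets tests
inject a permuted noise matrix to verify node-permutation equivariance.

Standard parameter values: `K = 10`, `sigma = 6`, `dt = 1e-2`, `T = 4e6`
steps. The library default `ModelParams.n_steps` is the full `4e6`; tests,
examples and the acceptance script run at `n_steps = 1e5` with a 5% burn-in,
which is the package's desk-scale operating point (the first 5% of steps is
discarded before scoring in all cases; at the full horizon transients are
negligible, at short horizons the burn-in matters).

### Seizure-state classification

The underlying definition is the model's: a node is at rest when its input
current is negative and rotating when it is positive. As a per-sample
classifier on trajectories we use:

- `I0 <= 0`: raw indicator `1 - cos(theta_i - theta_s) > 1` (phase more than
  pi/2 from rest), smoothed by a centered moving average over 1 time unit
  (1/dt samples) and thresholded at 0.5. The smoothing suppresses brief
  noise excursions while scoring sustained rotations; window and threshold
  are `ModelParams` fields. For the excitability range used here
  (`I0 in [-1.7, -0.5]`) the slow SNIC bottleneck lies more than pi/2 from
  rest, so rotation dwell time is scored as seizure.
- `I0 > 0`: the resting state does not exist and the deterministic dynamics
  rotate indefinitely, so every sample is scored as seizure. A
  distance-from-rest indicator would be wrong here: near the bifurcation a
  rotating oscillator spends most of each lap in the bottleneck near
  `theta = 0`, which is where a naively-defined "rest" would sit.

`t_sz` is the per-node scored seizure time after burn-in and
`P_sz = mean_i t_sz_i / T_scored`.

## BNI and NI

`BNI = integral of P_sz over [lambda1, lambda2]` by trapezoidal quadrature
on the excitability grid. Defaults: `lambda1 = -1.7`, `lambda2 = -0.5`, 13
evenly spaced points (step 0.1). The grid and `K` must be shared across
subjects for BNI to be comparable; the unnormalized integral is reported,
with the range-normalized value alongside.

Node ictogenicity removes one node (row and column) at a time and recomputes
BNI: `NI_i = (BNI_pre - BNI_post_i) / BNI_pre`. Two implementation choices:

- **Common random numbers.** Per-grid-point seeds are derived from the master
  seed and shared between the intact-network run and every node-removal run,
  so NI differences reflect the removal rather than noise-realization
  variance. A corollary used by the tests: structurally identical reduced
  networks get identical NI.
- **Coupling normalization after removal.** The `K/N` prefactor uses the
  current network size (`N-1` after removal) by default — the literal
  reading of the model — with `coupling_n_mode="original"` available. Under
  the default, removing a node slightly strengthens the surviving
  connections, which is why leaf removal in a star network can yield small
  negative NI.

`nNI_i = NI_i / sum_j NI_j` sums to one exactly. When the NI total is zero
the subject is excluded with a warning; when it is negative the unit-sum
rescaling flips signs, so nNI should only be interpreted for subjects with
positive total NI.

## Functional network construction

Pipeline for ROI time series (channels x samples, sampling rate `fs`):

1. **Band-pass 4–8 Hz**: zero-phase 4th-order Butterworth (forward-backward).
   Only the band is dictated by the analysis design; the filter family and
   order are our choice and are recorded in the config.
2. **Instantaneous phase**: angle of the analytic (Hilbert) signal. One
   second is trimmed from each end before any PLV computation to limit
   boundary artifacts (configurable).
3. **PLV**: modulus of the time-averaged unit phasor of the phase
   difference; the circular mean phase difference is its argument (the
   argument of the mean phasor, not an arithmetic mean of wrapped
   differences).
4. **Surrogate significance**: 99 surrogate sets; in each, every channel is
   independently IAAFT-resampled and pushed through the same
   filter/phase/trim pipeline. An edge survives iff its empirical PLV
   strictly exceeds the `ceil(0.95 * 99)`-th smallest of its 99 null PLVs —
   the 95th order statistic, one-sided, per edge.
5. **Zero-lag rejection**: edges whose circular mean phase difference is
   strictly below one sample of phase at the low band edge,
   `2*pi*f_low/fs` (0.008*pi rad at 4 Hz / 1 kHz), are removed as likely
   volume-conduction artifacts. Equality is kept.
6. **Indirect-path pruning**: with edge length `1/PLV`, any edge whose
   endpoints are joined by a strictly shorter multi-hop path (Dijkstra) is
   removed; ties keep the edge. Removed edges lie on no shortest path, so
   the filter is idempotent. The `1/weight` length transform is a genuine
   choice (only monotone-decreasing is forced) and is recorded in metadata.

IAAFT surrogates preserve the exact amplitude distribution (final step is a
rank remap) and approximately the amplitude spectrum. The iteration loop
stops at spectral convergence (`1e-4` relative error), at a plateau (less
than 5% improvement per iteration — empirically the error floor, around
2e-4 for 20 s theta-band signals, is reached within ~10 iterations), or at
100 iterations, whichever comes first.

## Synthetic data

The generator stands in for a non-public EEG cohort; it produces the
*statistical structure* the analysis assumes, not biophysical EEG.

- **Topologies**: uniform-random (Bernoulli edges, weights uniform around a
  base weight), modular (dense within blocks, sparse between), star, or
  custom. Weights live in [0, 1] like PLVs.
- **Signals**: Sakaguchi–Kuramoto phase oscillators observed as
  `cos(phase) + measurement noise`. Natural frequencies are uniform within
  ±0.5 Hz of 6 Hz (inside the theta band); pairwise coupling is
  `5 rad/s x weight`; phase diffusion is `2.5 rad/sqrt(s)`; each edge gets an
  antisymmetric phase lag drawn from `[0.02*pi, 0.1*pi]`, so locked pairs
  settle at a nonzero mean phase difference and survive zero-lag rejection.
  The coupling/noise point was chosen so that directly coupled pairs lock
  partially (PLV ~ 0.6, against ~0.3 for non-edges at default density) —
  comparable to resting EEG values — rather than globally synchronizing,
  which would make edge recovery impossible for any method. Defaults give
  40 ROIs, 20 s at 1 kHz.
- **Cohorts**: group a networks are drawn from the base distribution; group
  b networks are drawn identically and then all edge weights are scaled by
  `effect` (default 1.3), clipped to [0, 1] with a warning. Scaling total
  coupling mass raises the input current of every node, hence seizure
  propensity — a planted, mechanistically transparent group difference used
  to validate the pipeline, not a claim about real disease networks. Group
  sizes default to 26 vs 21.

What the generator does **not** emulate: source leakage / volume conduction
(beyond the zero-lag pathology exercised by the identical-copies test),
1/f broadband background, non-stationarity, per-subject frequency profiles,
or spatially structured group differences. Passing tests therefore show the
pipeline recovers the structure it assumes from data of this kind; they say
nothing about robustness to leakage or artifacts in real recordings.

## Statistics

- **Mann-Whitney U**: U counts pairs (first sample greater; ties half). The
  effect-size z uses midranks, tie-corrected variance, and a 0.5 continuity
  correction toward the mean; p is two-sided, exact by enumeration for
  small tie-free samples (via scipy's exact method) and normal otherwise.
  The first argument is always the first-named group.
- **Friedman**: tie-corrected rank statistic, df = conditions - 1; reduces
  to the classical formula without ties (cross-checked against scipy).
  A fully tied matrix returns chi2 = 0, p = 1.
- **nNI bootstrap**: surrogate participant x ROI matrices are resampled with
  replacement from the pooled entries, destroying any ROI effect. Every
  surrogate contributes all of its per-ROI medians to a single pooled null
  (ROIs are exchangeable under pooled resampling, and pooling sharpens the
  tail estimate at fixed n_boot). One-sided p per ROI (high median =
  seizure-driving; a two-sided flag exists) with the add-one convention,
  z-scores against the null mean/SD, Benjamini-Hochberg FDR across ROIs.
  Default 10,000 surrogates (tests use 2,000).
- **MVPA**: unregularized logistic regression on NI/nNI spatial profiles,
  stratified 5-fold cross-validated AUC averaged over 20 repetitions
  (mean ± SD over all folds and repetitions). Permutation testing permutes
  labels, re-evaluates with the *identical* recorded folds and repetitions
  (so overfitting is matched between observed and permuted data), and uses
  the add-one p-value; default 1000 permutations. Folds that become
  single-class under a permutation score 0.5.

## Problem sizes and numerical choices

Tests and the acceptance script use: simulation horizon 1e5 steps (burn-in
5e3), 13-point excitability grid (7 points for cohort sweeps), cohorts of
15+15 networks with 16 ROIs, bootstrap n = 2000, and the full 40-ROI / 20 s
/ 1 kHz / 99-surrogate setting for the network-recovery check. These are the
package's desk-scale defaults; the full-size model horizon (4e6 steps) and
bootstrap (10,000) remain the library defaults for production runs.

Other numerics: adjacency symmetry is enforced to 1e-12 on load and the
diagonal zeroed; the indirect-path comparison uses a 1e-12 relative guard so
floating-point ties are kept; BNI quadrature is plain trapezoid (grid
spacing, not integration error, dominates); seeds are derived from the
master seed with `SeedSequence` over a keyed path and kept below 2^31.

## Known limitations

- Absolute BNI values depend on the noise convention and classifier window;
  only within-convention comparisons are meaningful.
- nNI is ill-defined for subjects with non-positive total NI (excluded with
  a warning; sign flips near zero totals).
- The MVPA permutation reuses stratified folds built from the original
  labels; under extreme class imbalance permuted folds can go single-class
  (scored at chance) slightly biasing the null toward 0.5.
- The synthetic cohort plants a global coupling effect; pipeline power
  against *spatially structured* group differences is not characterized.
- Monte-Carlo NI at the desk-scale horizon has noise of order 0.02-0.05 per
  node; full-horizon runs are needed for stable per-node maps.
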