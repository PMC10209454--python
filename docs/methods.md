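# Methods

This note documents the models, numerical choices and limitations behind
`msfnc`. It covers the synthetic generative model, the constrained-ICA
estimator, the connectivity/statistics stack, the selection and
classification protocols, and what the synthetic experiments do and do not
demonstrate.

## Synthetic generative model

The generator (`msfnc.simulate`) emulates the statistical skeleton of a
two-cohort case/control resting-state study on a desk-scale grid.

**Spatial model.** `F` fine networks are isotropic Gaussian blobs
(`blob_sd` = 1.8 voxels) at randomly placed, mutually separated centers on a
20×20×10 grid; each coarse network is the voxelwise max over ≥ 2 member fine
blobs, giving a two-order template (defaults: 10 fine + 5 coarse). The
analysis mask is the union of blob supports (≈ 3σ). Per subject, blob
centers are jittered (`jitter_sd` = 0.5 voxels) so the template is never
exactly the subject's map — constrained estimation must adapt it.

**Temporal model.** Subject fine time courses are multivariate normal with a
group-specific correlation matrix, then band-limited to 0.01–0.15 Hz (the
same linear filter on every channel preserves zero-lag correlations in
expectation) and standardized. Controls have correlation `base_within`
(0.35) inside a coarse group and `base_between` (0.05) elsewhere; patients
shift `n_diff_pairs` (5) between-group fine pairs by `delta_z` (0.6) on the
Fisher-z scale. Planted pairs are chosen node-disjoint where possible, so
each effect perturbs an independent 2×2 block and positive definiteness is
robust; if a requested configuration still breaks it, a Higham-style
alternating projection repairs the matrix with the planted entries held
fixed (eigenvalue floor 1e-3, convergence tolerance 1e-8) and fails loudly
if no repair exists. Coarse "truth" courses are the standardized member mean
plus an `α` = 0.3 unique component, which is also mixed into the volumes via
the coarse maps — this makes coarse–fine (cross-order) connectivity
informative rather than redundant.

**Volume rendering and normalization convention.** Volumes are
`maps × courses + white noise`, with noise scaled to an amplitude SNR
(default experiments use SNR 10). Emitted volumes are divided by each
voxel's analytic standard deviation, i.e. the generator produces data in the
variance-normalized convention of preprocessed rsfMRI. The planted subject
maps are reported in the same convention, and `population_template`
re-expresses the template maps likewise (flattened by the control-population
voxel std). This matters: a template in raw mixing units is a visibly worse
reference for variance-normalized data, because voxel normalization
reshapes blob profiles nonlinearly.

**Symptom scores.** Patient positive/negative scores are affine functions of
the subject's *sample* Fisher-z on designated planted pairs (defaults:
one pair each, disjoint; β = 6 and 5, noise sd 1, intercepts 15 and 14,
landing in a plausible PANSS subscale range), and total = positive +
negative exactly. Controls carry no scores.

**What the generator does not model:** physiological noise and motion,
scanner/site effects (the site column is written but identically
distributed), spatial autocorrelation of noise, hemodynamic convolution, and
non-Gaussian temporal dynamics. Passing tests therefore certify the
*pipeline's statistical machinery* — recovery, error control, power,
replication, leakage protection — not robustness to real-world artifacts.

## Constrained ICA

Whitening is spatial: the (time × voxels) matrix, with each volume demeaned
over voxels, is reduced by SVD to K uncorrelated unit-variance voxel maps,
K = the number of references in the current model order (the smallest
subspace containing all targets). Requests beyond the achieved rank are
fatal.

Each reference is estimated one-unit, with **no joint decorrelation across
components**: components from different references, and especially from
different model orders, may legitimately correlate. The update alternates a
FastICA-style negentropy fixed-point step (g = tanh) with a convex blend
toward the normalized projection of the reference into whitened space;
`λ` (default 0.5) sets the blend, with λ→0 blind ICA and λ→1 pure template
projection. Initialization is the reference projection itself, so extraction
is deterministic — no random restarts. E[G(ν)] for the negentropy baseline
is computed once by 64-point Gauss–Hermite quadrature.

Because neither the fixed-point step nor the blend is guaranteed monotone in
the blended objective, each iteration applies a step-halving safeguard: the
candidate step is shrunk (up to 6 halvings) until the objective does not
decrease; if no uphill step exists the iterate is a local maximizer of the
search direction and the run stops. The stored objective trace is therefore
non-decreasing by construction, which doubles as a diagnostic invariant.
Convergence is `1 − |⟨w_t, w_{t−1}⟩| < tol` (default 1e-6, max 1000
iterations); non-convergence returns the best iterate with a warning. Map
signs are flipped so reference correlation is non-negative, and maps are
z-scored over mask voxels.

Time courses are estimated by **joint least squares per model order**
(regressing the data on all of that order's estimated maps at once), then
variance-normalized. Single-map projection (`backproject_timecourse`) is
provided and used for diagnostics, but z-scored sparse maps share a
background offset that leaks correlated signal between networks; joint
unmixing removes that cross-talk (on planted data it raises time-course
recovery from ≈ 0.86 to ≈ 0.97 even with perfect maps).

## Connectivity, statistics, selection, classification

**Conditioning order** is fixed: discard → truncate → voxel z-score before
extraction; resample (cubic spline to TR = 2 s, linear fallback below 4
points) → linear detrend → zero-phase 5th-order Butterworth band-pass
(0.01–0.15 Hz) on network courses. Filtering uses even-reflection padding:
odd reflection of oscillatory series injects low-frequency edge energy into
the passband. Filtered columns are re-centered, so each course has mean
≈ 0 by construction.

**msFNC.** Pearson correlations are clamped to ±(1 − 1e-12) before `atanh`
so degenerate pairs stay finite; the diagonal is stored as 0 and excluded
from all downstream use. The canonical feature ordering sorts ICNs by
functional domain (fixed domain order), then model order, then id; the
strictly-upper-triangle vector carries pair labels, domain pairs and a
cross-order flag. Aggregation averages on the z scale.

**Group statistics.** Two-sample t-tests (pooled variance by default; Welch
via a flag — identical for equal group sizes) with control minus patient
orientation, BH-FDR across all features, and intensity
`−sign(t)·log₁₀(q)` with q floored at 1e-300. Note the sign: q < 1 makes
`log₁₀(q)` negative, so intensity carries the sign of t — positive where
controls are higher, negative where patients are higher. No covariate
correction is applied (none is modeled in the generator either).

**ReliefF** is the canonical numeric-feature variant: features min-max
normalized internally, Manhattan distances, every instance a target
(deterministic, m = n), k = 10 nearest hits and per-class misses, miss terms
weighted by class prior over (1 − prior of the target's class). Too-small
classes (< k+1) are fatal rather than silently under-neighbored. The
multi-round protocol subsamples 50 % per class without replacement (round
seeds spawned from the master seed), averages weights across 10 rounds, and
retains the top 70 % (`ceil(0.70·n)`); ranking ties break by feature label
for reproducibility. Cross-cohort replication intersects top-J sets (ranked
within the retained set by default) and min-max normalizes weights within
each cohort's selected set.

**Classification.** `LinearSVC` with C chosen from {0.01, 0.1, 1, 10, 100}
by stratified 10-fold CV on the training split of each iteration's
stratified 80/20 split; features are standardized with training-split
statistics only. The patient class is the positive class; accuracy,
precision, recall/sensitivity, specificity and F1 are reported per iteration
with means ± sd. Cross-dataset evaluation re-runs selection on cohort A
only and asserts disjoint subject ids (leakage guard).

## Problem sizes used in tests

Test and acceptance runs use the generator defaults (15-network two-order
template, T = 135, TR = 2 s, SNR 10) with cohorts of 30–50 subjects per
group, 20–50 replicates for Monte-Carlo rates, 1000 label permutations for
null FDR calibration, and reduced iteration counts (5–50) for the SVM
protocol; these sizes give stable rates while keeping the whole suite
fast on a single CPU. The end-to-end orchestration test uses a smaller
grid (14×14×8, 6+3 networks) purely to exercise the plumbing.

## Known limitations

- The constrained estimator optimizes a fixed convex blend; it does not
  adapt λ per component or iterate multi-objective weights.
- One-unit extraction cannot disentangle two references whose projections
  into the whitened space nearly coincide; diagnostics (reference
  similarity, convergence flags) surface this rather than prevent it.
- Symptom correlations are Pearson only; no covariates, no Spearman.
- The synthetic site column is cosmetic; multi-site harmonization is out of
  scope.
- Template derivation (group ICA + hand labeling) is out of scope: templates
  are inputs, and the generator's blob template stands in for them.
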