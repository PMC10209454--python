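# msfnc — multiscale network connectivity from spatially constrained ICA

`msfnc` is a Python library for case/control resting-state fMRI studies that
work with **intrinsic connectivity networks (ICNs) at several spatial scales
at once**. It is aimed at neuroimaging researchers who have a reference
template of ICN maps (e.g. hand-labeled group-ICA components from several
model orders) and want a reproducible pipeline from 4-D BOLD volumes to
group-difference maps, replicable predictive features and symptom
correlations — plus a synthetic cohort generator with planted ground truth so
every stage of the pipeline can be validated end to end.

## The method

**Spatially constrained ICA (ICA-with-reference).** For a subject's whitened
data `Z` (components × voxels) and a z-scored reference map `r`, each network
is estimated by the unit vector `w` maximizing

```
F(w) = (1 − λ) · Ĵ(wᵀZ) + λ · |ρ(wᵀZ, r)|,    Ĵ(y) = (E[G(y)] − E[G(ν)])²
```

with `G(u) = log cosh u` and `ν` standard normal — a blend of one-unit
negentropy (independence) and spatial correspondence to the reference.
Estimation runs independently per ICA model order, so one subject yields
subject-adapted maps and time courses for *all* template networks, coarse and
fine.

**Multiscale FNC (msFNC).** Network time courses are resampled to a common
TR, detrended and band-passed (0.01–0.15 Hz, zero-phase Butterworth); every
pair of networks — within and *across* model orders — gets a Fisher-z
Pearson correlation, giving an ICN × ICN matrix per subject and an
`n(n−1)/2` feature vector (127 ICNs → 8001 features).

**Statistics and prediction.** Group differences use two-sample t-tests with
Benjamini–Hochberg FDR and signed intensity values `−sign(t)·log₁₀(q)`.
Predictive features are chosen by multi-round ReliefF (10 rounds of
stratified 50 % subsamples, top 70 % by average weight retained) and
replicated by intersecting two cohorts' top-ranked sets. Classification is a
linear SVM under a repeated stratified 80/20 protocol with 10-fold CV picking
the cost parameter — with feature selection done on one cohort and
evaluation on the other, guarded against subject leakage. Symptom coupling
is the per-feature Pearson correlation with PANSS-like scores over patients.

## Worked example

```python
from msfnc import (make_ground_truth, sample_cohort, group_diff)

template, gt = make_ground_truth(seed=42)   # 5 coarse + 10 fine blob ICNs
cohort = sample_cohort(gt, n_tc=30, n_sz=30, T=135, seed=43,
                       render_volumes=False)
features = cohort.timecourse_features()     # 60 subjects x 105 msFNC pairs
stats = group_diff(features, cohort.manifest.groups)
print(stats.loc["fine05|fine08", ["t", "q", "intensity"]])
```

prints (one of the five planted Δz = 0.6 pairs):

```
t           -20.1152
q             0.0000
intensity   -25.3856
```

a strongly negative t (control minus patient) and negative intensity —
connectivity increased in the patient group, exactly as planted. The
scripts in `examples/` walk through each capability with printed output:
cohort simulation, constrained-ICA extraction (map/time-course recovery
correlations ≈ 0.97–0.99 at SNR 10), group statistics, two-cohort feature
replication (all 5 planted pairs in the common set), and cross-dataset
classification (accuracy 1.0 on planted effects, ≈ 0.57 after label
permutation).

A thin CLI mirrors the library (`msfnc simulate | extract | stats | select |
classify | correlate | run-all`); `msfnc run-all --out DIR --seed 7` executes
the full synthetic two-cohort study and writes every stage's CSV/JSON
artifacts.

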