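"""Cross-dataset linear-SVM protocol: select on cohort A, evaluate on B.

Feature selection never sees cohort B; the classifier is trained and
evaluated on B alone over repeated stratified 80/20 splits with 10-fold
CV choosing the soft-margin cost.  A null run with permuted labels shows
the chance floor.
"""

import numpy as np

from msfnc import cross_dataset_evaluate, make_ground_truth, sample_cohort

template, gt = make_ground_truth(seed=42)
ca = sample_cohort(gt, n_tc=50, n_sz=50, T=135, seed=60,
                   render_volumes=False, subject_prefix="a_")
cb = sample_cohort(gt, n_tc=50, n_sz=50, T=135, seed=61,
                   render_volumes=False, subject_prefix="b_")

report, chosen = cross_dataset_evaluate(
    ca.timecourse_features(), ca.manifest.groups,
    cb.timecourse_features(), cb.manifest.groups,
    n_iter=20, folds=10, seed=62,
)
print(f"transferred features: {len(chosen)} (selected on cohort A only)")
print("held-out performance on cohort B (mean +/- sd over 20 iterations):")
print(report.summary().round(4).to_string())

rng = np.random.default_rng(63)
null_report, _ = cross_dataset_evaluate(
    ca.timecourse_features(), ca.manifest.groups,
    cb.timecourse_features(), rng.permutation(cb.manifest.groups),
    n_iter=20, folds=10, seed=64,
)
print(f"\npermuted-label control accuracy: {null_report.mean('accuracy'):.3f} "
      "(chance ~ 0.5)")

# High accuracy with planted effects plus chance-level accuracy under
# permutation demonstrates that the protocol's signal comes from the planted
# group differences, not leakage.
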