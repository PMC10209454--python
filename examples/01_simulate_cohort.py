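"""Generate a synthetic two-scale resting-state cohort with planted truth.

Builds a blob template (5 coarse + 10 fine networks), plants group
differences of 0.6 Fisher-z on five fine-network pairs, samples a small
case/control cohort and attaches PANSS-like symptom scores.
"""

import numpy as np

from msfnc import attach_scores, make_ground_truth, sample_cohort

template, gt = make_ground_truth(seed=42)
print(f"template: {len(template)} ICNs, per-order counts {template.order_counts()}")
print(f"mask voxels: {int(template.mask.sum())} of {np.prod(gt.grid)}")
print(f"planted pairs (delta-z): "
      f"{[(gt.pair_label(p), d) for p, d in zip(gt.diff_pairs, gt.delta_z)]}")

cohort = sample_cohort(gt, n_tc=5, n_sz=5, T=135, tr=2.0, snr=10.0, seed=43)
manifest = attach_scores(gt, cohort.true_fnc, cohort.manifest, seed=44)
print(f"\ncohort: {manifest.group_counts()} subjects, "
      f"{cohort.scans[0].data.shape[1]} volumes each")
sz = manifest.table[manifest.table["group"] == "SZ"]
print("SZ symptom scores (total = positive + negative):")
print(sz[["subject_id", "panss_positive", "panss_negative", "panss_total"]]
      .round(1).to_string(index=False))

# The printed delta-z values are the planted case/control connectivity
# differences every later stage tries to rediscover; the scores are linearly
# driven by the first planted pair(s), so score-connectivity correlations
# are recoverable too.
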