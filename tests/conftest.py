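"""Shared fixtures: small synthetic templates and cohorts.

Everything is generated at test time from fixed seeds; session scope keeps
the heavier objects (rendered volumes) shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from msfnc import make_ground_truth, sample_cohort


@pytest.fixture(scope="session")
def template_gt():
    """Default two-order blob template (5 coarse + 10 fine) with planted
    group differences (delta-z 0.6 on 5 fine pairs)."""
    return make_ground_truth(seed=11)


@pytest.fixture(scope="session")
def small_cohort(template_gt):
    """Six rendered subjects at SNR 10, T=135 — spatial-recovery workhorse."""
    _, gt = template_gt
    return sample_cohort(gt, n_tc=3, n_sz=3, T=135, snr=10.0, seed=12)


@pytest.fixture(scope="session")
def tc_cohort(template_gt):
    """Time-course-level cohort (no volumes), 30+30 subjects."""
    _, gt = template_gt
    return sample_cohort(
        gt, n_tc=30, n_sz=30, T=135, snr=10.0, seed=13, render_volumes=False
    )


def pair_column(table: pd.DataFrame, label: str) -> str:
    """Find a pair feature column regardless of within-pair label order."""
    if label in table.columns:
        return label
    a, b = label.split("|")
    flipped = f"{b}|{a}"
    if flipped in table.columns:
        return flipped
    raise KeyError(label)


@pytest.fixture(scope="session")
def three_source_mixture():
    """Noiseless 3-source spatial mixture: super-Gaussian maps, known mixing."""
    rng = np.random.default_rng(5)
    n_vox, n_t = 600, 40
    sources = rng.laplace(size=(3, n_vox))
    sources = (sources - sources.mean(1, keepdims=True)) / sources.std(1, keepdims=True)
    mixing = rng.standard_normal((n_t, 3))
    data = (mixing @ sources).T          # voxels x time
    return data, sources, mixing
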