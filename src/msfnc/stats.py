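"""Group-difference statistics and symptom-score correlations.

Per connectivity feature: a two-sample t-test with the control group first
(so positive t means higher connectivity in controls), Benjamini-Hochberg
FDR across all features, and a signed significance score

    intensity = -sign(t) * log10(q)

which is positive where connectivity is higher in controls and negative
where it is higher in patients (log10 of an adjusted p below 1 is negative,
so the leading minus makes intensity carry the sign of t).  Symptom
analysis correlates each feature
with each PANSS scale over scored patients (Pearson, pairwise missing-data
dropping).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_Q_FLOOR = 1e-300


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def intensity_values(t: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Signed significance: -sign(t) * log10(q), with q floored at 1e-300."""
    q = np.clip(np.asarray(q, dtype=float), _Q_FLOOR, 1.0)
    return -np.sign(t) * np.log10(q)


def group_diff(
    features: pd.DataFrame,
    groups: np.ndarray,
    control: str = "TC",
    case: str = "SZ",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-feature control-vs-case t-test with BH-FDR and intensity values.

    Returns a table indexed by feature with columns ``mean_tc``, ``mean_sz``,
    ``t``, ``p``, ``q``, ``intensity``.  ``welch=True`` switches from the
    pooled-variance (Student) test to Welch's unequal-variance test.
    """
    groups = np.asarray(groups)
    a = features.loc[groups == control].to_numpy(dtype=float)
    b = features.loc[groups == case].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError(
            f"need >= 2 subjects per group, got {a.shape[0]} {control} / "
            f"{b.shape[0]} {case}"
        )
    t, p = sps.ttest_ind(a, b, axis=0, equal_var=not welch)
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "mean_tc": a.mean(axis=0),
            "mean_sz": b.mean(axis=0),
            "t": t,
            "p": p,
            "q": q,
            "intensity": intensity_values(t, q),
        },
        index=features.columns,
    )


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``x`` against the vector ``y``."""
    xm = x - x.mean(axis=0, keepdims=True)
    ym = y - y.mean()
    denom = np.sqrt((xm**2).sum(axis=0) * (ym**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm * ym[:, None]).sum(axis=0) / denom
    return np.where(denom == 0, np.nan, r)


def symptom_correlation(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    scales: tuple[str, ...] = ("panss_total", "panss_positive", "panss_negative"),
) -> pd.DataFrame:
    """Correlate each feature with each symptom scale over scored subjects.

    ``features`` and ``scores`` are aligned on their index (subjects);
    subjects with a missing value of a scale are dropped for that scale only.
    Returns a long table with columns ``feature``, ``scale``, ``r``, ``n``.
    """
    scores = scores.reindex(features.index)
    out = []
    for scale in scales:
        if scale not in scores.columns:
            continue
        valid = scores[scale].notna().to_numpy()
        n = int(valid.sum())
        if n < 3:
            raise ValueError(f"scale {scale}: need >= 3 scored subjects, got {n}")
        y = scores.loc[valid, scale].to_numpy(dtype=float)
        if y.std() == 0:
            raise ValueError(f"scale {scale}: zero variance across subjects")
        r = _pearson_columns(features.loc[valid].to_numpy(dtype=float), y)
        out.append(
            pd.DataFrame({"feature": features.columns, "scale": scale, "r": r, "n": n})
        )
    if not out:
        raise ValueError("none of the requested scales are present")
    return pd.concat(out, ignore_index=True)
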