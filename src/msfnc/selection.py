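"""ReliefF feature scoring and the multi-round selection protocol.

ReliefF scores each feature by contrasting its value differences between
nearest neighbors of the same class (hits, which lower the score) and of the
other class (misses, which raise it).  The selection protocol repeats ReliefF
on stratified 50% subsamples for several rounds, averages the weights, and
retains the top 70% of features; replication across two cohorts intersects
each cohort's top-J features.

Implementation notes: features are min-max normalized internally so value
differences are comparable across features; distances are Manhattan on the
normalized features; every instance serves as a target (no random target
sampling), so a ReliefF call is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


def relieff(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    k: int = 10,
) -> np.ndarray:
    """ReliefF weights for numeric features and (possibly multi-class) labels.

    For each target instance, the k nearest same-class hits and, per other
    class, the k nearest misses contribute ``|x_target - x_neighbor|`` on
    min-max normalized features; miss contributions are weighted by the miss
    class's prior over ``1 - prior(target class)``.  Weights are averaged
    over targets and neighbors; relevant features come out positive,
    irrelevant ones near zero or negative.
    """
    x = np.asarray(
        features.to_numpy() if isinstance(features, pd.DataFrame) else features,
        dtype=float,
    )
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("features must be instances x features aligned with labels")
    n, _ = x.shape
    classes, counts = np.unique(y, return_counts=True)
    if (counts < k + 1).any():
        small = classes[counts < k + 1]
        raise ValueError(
            f"k={k} needs >= {k + 1} instances per class; too small: {list(small)}"
        )
    prior = {c: cnt / n for c, cnt in zip(classes, counts)}

    lo, hi = x.min(axis=0), x.max(axis=0)
    rng_ = np.where(hi > lo, hi - lo, 1.0)
    xn = (x - lo) / rng_

    dist = cdist(xn, xn, metric="cityblock")
    np.fill_diagonal(dist, np.inf)

    w = np.zeros(x.shape[1])
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        hits = same[np.argsort(dist[i, same], kind="stable")[:k]]
        w -= np.abs(xn[hits] - xn[i]).sum(axis=0)
        for c in classes:
            if c == y[i]:
                continue
            other = np.flatnonzero(y == c)
            misses = other[np.argsort(dist[i, other], kind="stable")[:k]]
            scale = prior[c] / (1.0 - prior[y[i]])
            w += scale * np.abs(xn[misses] - xn[i]).sum(axis=0)
    return w / (n * k)


@dataclass
class WeightTable:
    """Per-feature weights from the multi-round protocol.

    ``table`` is indexed by feature label with one column per round plus
    ``avg_weight``, ``rank`` (1 = best) and ``retained`` (top fraction by
    average weight).
    """

    table: pd.DataFrame
    k: int
    rounds: int
    frac: float
    retain: float
    seed: int

    def __post_init__(self) -> None:
        ranks = np.sort(self.table["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.table) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")
        expected = ceil(self.retain * len(self.table))
        if int(self.table["retained"].sum()) != expected:
            raise ValueError("retained set size must be ceil(retain * n_features)")

    @property
    def features(self) -> list[str]:
        return self.table.index.tolist()

    def retained_features(self) -> list[str]:
        return self.table.index[self.table["retained"]].tolist()

    def top_features(self, j: int, within_retained: bool = True) -> list[str]:
        """Top-j features by average weight (rank order).

        By default ranking is restricted to the retained (top-fraction) set;
        ``within_retained=False`` ranks over all features instead.
        """
        t = self.table[self.table["retained"]] if within_retained else self.table
        return t.sort_values("rank").index[:j].tolist()

    def save(self, path) -> None:
        self.table.to_csv(path)


def _rank_stable(avg: pd.Series) -> np.ndarray:
    """Dense 1..n ranking, descending weight, lexicographic label tie-break."""
    order = sorted(range(len(avg)), key=lambda i: (-avg.iloc[i], str(avg.index[i])))
    ranks = np.empty(len(avg), dtype=int)
    ranks[order] = np.arange(1, len(avg) + 1)
    return ranks


def multiround_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    rounds: int = 10,
    frac: float = 0.5,
    k: int = 10,
    retain: float = 0.70,
    seed: int = 0,
) -> WeightTable:
    """Multi-round ReliefF: stratified subsample, score, average, retain.

    Each round scores a class-stratified ``frac`` subsample (without
    replacement); weights are averaged across rounds and the top ``retain``
    fraction of features (by average weight) is flagged as retained.
    """
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features))
        features.columns = [f"f{i}" for i in range(features.shape[1])]
    y = np.asarray(labels)
    per_round = {}
    for r in range(rounds):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        idx = _stratified_subsample(y, frac, rng)
        per_round[f"round_{r}"] = relieff(features.iloc[idx], y[idx], k=k)
    table = pd.DataFrame(per_round, index=features.columns)
    table["avg_weight"] = table.mean(axis=1)
    table["rank"] = _rank_stable(table["avg_weight"])
    n_keep = ceil(retain * len(table))
    table["retained"] = table["rank"] <= n_keep
    return WeightTable(
        table=table, k=k, rounds=rounds, frac=frac, retain=retain, seed=seed
    )


def _stratified_subsample(
    y: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-class fraction without replacement; deterministic under rng."""
    picks = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        n_pick = max(1, round(frac * len(members)))
        picks.append(rng.choice(members, size=n_pick, replace=False))
    return np.sort(np.concatenate(picks))


def common_features(
    table_a: WeightTable,
    table_b: WeightTable,
    j: int,
    within_retained: bool = True,
) -> pd.DataFrame:
    """Overlap of each cohort's top-j features, with normalized weights.

    Weights are min-max normalized to [0, 1] within each cohort's selected
    top-j set so they are comparable across cohorts.  An empty overlap is a
    valid (warned) outcome.
    """
    if set(table_a.features) != set(table_b.features):
        raise ValueError("feature label spaces differ between weight tables")
    top_a = table_a.top_features(j, within_retained)
    top_b = table_b.top_features(j, within_retained)
    common = [f for f in top_a if f in set(top_b)]
    if not common:
        warnings.warn("no overlapping features between the two top sets", stacklevel=2)

    def _norm(table: WeightTable, top: list[str]) -> pd.Series:
        w = table.table.loc[top, "avg_weight"]
        lo, hi = w.min(), w.max()
        return (w - lo) / (hi - lo) if hi > lo else pd.Series(1.0, index=w.index)

    na, nb = _norm(table_a, top_a), _norm(table_b, top_b)
    return pd.DataFrame(
        {
            "feature": common,
            "weight_a": na.loc[common].to_numpy() if common else [],
            "weight_b": nb.loc[common].to_numpy() if common else [],
        }
    )
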