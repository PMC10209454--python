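"""Multiscale functional network connectivity (msFNC).

Per subject: Pearson correlation between every pair of ICN time courses
pooled across all model orders, Fisher r-to-z transformed, stored as a
symmetric ICN x ICN matrix (diagonal fixed at 0 and excluded from all
downstream use).  The strictly-upper-triangle vectorization over a canonical
ICN ordering (functional domain first, then model order, then id) gives the
feature vector used by statistics, selection and classification; a pair is
"cross-order" when its two ICNs come from different model orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DOMAIN_ORDER
from .preprocess import TimeCourseSet

#: correlations are clamped to +/- (1 - _CLAMP) before atanh
_CLAMP = 1e-12


def _order_key(order: int | str):
    # numeric orders ascend (25 -> 100); string tags sort after, alphabetically
    return (0, float(order)) if isinstance(order, (int, float)) else (1, str(order))


def canonical_order(
    icn_ids: list[str], orders: list[int | str], domains: list[str]
) -> np.ndarray:
    """Permutation sorting ICNs by domain, then model order, then id."""
    dom_rank = {d: i for i, d in enumerate(DOMAIN_ORDER)}

    def key(i: int):
        return (
            dom_rank.get(domains[i], len(DOMAIN_ORDER)),
            domains[i],
            _order_key(orders[i]),
            icn_ids[i],
        )

    return np.array(sorted(range(len(icn_ids)), key=key), dtype=int)


@dataclass
class FNCMatrix:
    """Symmetric Fisher-z connectivity over all ICNs of all orders."""

    z: np.ndarray
    icn_ids: list[str]
    orders: list[int | str]
    domains: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.icn_ids)
        if self.z.shape != (n, n):
            raise ValueError("z must be square over icn_ids")
        if not np.isfinite(self.z).all():
            raise ValueError("non-finite connectivity values")
        if not np.allclose(self.z, self.z.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        np.fill_diagonal(self.z, 0.0)

    @property
    def n_icns(self) -> int:
        return len(self.icn_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.icn_ids, columns=self.icn_ids)


@dataclass
class FNCVector:
    """Strictly-upper-triangle feature view of an :class:`FNCMatrix`."""

    values: np.ndarray
    pairs: list[tuple[str, str]]
    cross_order: np.ndarray        # bool per pair
    domain_pairs: list[tuple[str, str]]
    order_pairs: list[tuple[int | str, int | str]] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.pairs) == len(self.cross_order) == len(self.domain_pairs)):
            raise ValueError("pair metadata lengths differ")

    @property
    def labels(self) -> list[str]:
        return [f"{a}|{b}" for a, b in self.pairs]

    def __len__(self) -> int:
        return len(self.values)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clamping so perfectly correlated pairs stay finite."""
    return np.arctanh(np.clip(r, -1 + _CLAMP, 1 - _CLAMP))


def compute_fnc(tcs: TimeCourseSet) -> FNCMatrix:
    """Pairwise Pearson correlation of ICN courses, Fisher r-to-z."""
    if tcs.n_timepoints < 8:
        raise ValueError("need at least 8 time points for stable correlation")
    sd = tcs.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [tcs.icn_ids[i] for i in dead]
        raise ValueError(f"zero-variance time courses for ICNs {names}")
    r = np.atleast_2d(np.corrcoef(tcs.data, rowvar=False))
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return FNCMatrix(
        z=z,
        icn_ids=list(tcs.icn_ids),
        orders=list(tcs.orders),
        domains=list(tcs.domains),
        subject_id=tcs.subject_id,
    )


def vectorize(fnc: FNCMatrix) -> FNCVector:
    """Canonical strictly-upper-triangle feature vector with pair labels."""
    perm = canonical_order(fnc.icn_ids, fnc.orders, fnc.domains)
    ids = [fnc.icn_ids[i] for i in perm]
    orders = [fnc.orders[i] for i in perm]
    doms = [fnc.domains[i] for i in perm]
    z = fnc.z[np.ix_(perm, perm)]
    iu = np.triu_indices(len(ids), k=1)
    pairs = [(ids[i], ids[j]) for i, j in zip(*iu)]
    cross = np.array([orders[i] != orders[j] for i, j in zip(*iu)], dtype=bool)
    dpairs = [(doms[i], doms[j]) for i, j in zip(*iu)]
    opairs = [(orders[i], orders[j]) for i, j in zip(*iu)]
    return FNCVector(
        values=z[iu],
        pairs=pairs,
        cross_order=cross,
        domain_pairs=dpairs,
        order_pairs=opairs,
        subject_id=fnc.subject_id,
    )


def aggregate_mean(
    fncs: list[FNCMatrix], group: str | None = None, groups: list[str] | None = None
) -> FNCMatrix:
    """Element-wise mean connectivity on the Fisher-z scale.

    With ``group`` given, ``groups`` must list each subject's label and only
    matching subjects enter the mean.
    """
    if group is not None:
        if groups is None or len(groups) != len(fncs):
            raise ValueError("group filtering needs one label per matrix")
        fncs = [f for f, g in zip(fncs, groups) if g == group]
    if not fncs:
        raise ValueError("no matrices to aggregate")
    ref = fncs[0]
    for f in fncs[1:]:
        if f.icn_ids != ref.icn_ids:
            raise ValueError("heterogeneous ICN sets cannot be aggregated")
    mean_z = np.mean([f.z for f in fncs], axis=0)
    return FNCMatrix(
        z=mean_z,
        icn_ids=list(ref.icn_ids),
        orders=list(ref.orders),
        domains=list(ref.domains),
        subject_id=f"mean(n={len(fncs)})",
    )


def feature_table(vectors: list[FNCVector]) -> pd.DataFrame:
    """Stack per-subject feature vectors into a subjects x features table."""
    if not vectors:
        raise ValueError("no feature vectors")
    labels = vectors[0].labels
    for v in vectors[1:]:
        if v.labels != labels:
            raise ValueError("feature vectors have mismatched pair labels")
    return pd.DataFrame(
        np.stack([v.values for v in vectors]),
        index=[v.subject_id for v in vectors],
        columns=labels,
    )


def pair_metadata(vector: FNCVector) -> pd.DataFrame:
    """Per-feature metadata table (ids, domains, cross-order flag)."""
    return pd.DataFrame(
        {
            "feature": vector.labels,
            "icn_a": [p[0] for p in vector.pairs],
            "icn_b": [p[1] for p in vector.pairs],
            "domain_a": [d[0] for d in vector.domain_pairs],
            "domain_b": [d[1] for d in vector.domain_pairs],
            "order_a": [o[0] for o in vector.order_pairs],
            "order_b": [o[1] for o in vector.order_pairs],
            "cross_order": vector.cross_order,
        }
    )
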