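"""Linear-SVM evaluation protocol with cross-dataset feature transfer.

The protocol repeats, for a configurable number of iterations: a stratified
80/20 train/test split, k-fold cross-validation on the training split to pick
the soft-margin cost C of a linear SVM, a refit on the full training split,
and held-out evaluation.  The patient class (SZ) is the positive class for
precision/recall/F1; specificity and sensitivity are reported alongside.
Cross-dataset evaluation selects features on one cohort only and runs the
protocol on the other, with a hard guard against subject overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .selection import WeightTable, multiround_select

POSITIVE_CLASS = "SZ"
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Standard binary metrics; zero-denominator metrics are 0 with a warning."""
    if min(tp, fp, fn, tn) < 0 or (tp + fp + fn + tn) == 0:
        raise ValueError("confusion counts must be nonnegative with a positive total")

    def _safe(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (0/0); reporting 0", stacklevel=3)
            return 0.0
        return num / den

    accuracy = (tp + tn) / (tp + fp + fn + tn)
    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")            # sensitivity
    specificity = _safe(tn, tn + fp, "specificity")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "sensitivity": recall,
        "specificity": specificity,
        "f1": f1,
    }


@dataclass
class ClassReport:
    """Per-iteration metrics and their summary for one protocol run."""

    iterations: pd.DataFrame
    n_iter: int
    test_frac: float
    folds: int
    positive_class: str = POSITIVE_CLASS
    n_features: int = 0
    seed: int = 0

    def summary(self) -> pd.DataFrame:
        metrics = [c for c in self.iterations.columns if c != "C"]
        return pd.DataFrame(
            {"mean": self.iterations[metrics].mean(), "sd": self.iterations[metrics].std()}
        )

    def mean(self, metric: str) -> float:
        return float(self.iterations[metric].mean())


def _fit_eval_once(
    x: np.ndarray,
    y: np.ndarray,
    test_frac: float,
    folds: int,
    c_grid: tuple[float, ...],
    rs: int,
) -> dict[str, float]:
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_frac, stratify=y, random_state=rs
    )
    scaler = StandardScaler().fit(x_tr)
    x_tr, x_te = scaler.transform(x_tr), scaler.transform(x_te)

    best_c, best_acc = c_grid[0], -1.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
    splits = list(skf.split(x_tr, y_tr))
    for c in c_grid:
        accs = []
        for tr, va in splits:
            clf = LinearSVC(C=c, max_iter=20000)
            clf.fit(x_tr[tr], y_tr[tr])
            accs.append(clf.score(x_tr[va], y_tr[va]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_c, best_acc = c, acc

    clf = LinearSVC(C=best_c, max_iter=20000)
    clf.fit(x_tr, y_tr)
    pred = clf.predict(x_te)
    pos = y_te == POSITIVE_CLASS
    hit = pred == y_te
    tp = int((pos & hit).sum())
    tn = int((~pos & hit).sum())
    fn = int((pos & ~hit).sum())
    fp = int((~pos & ~hit).sum())
    out = metrics_from_confusion(tp, fp, fn, tn)
    out["C"] = best_c
    return out


def run_protocol(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_iter: int = 100,
    test_frac: float = 0.2,
    folds: int = 10,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    seed: int = 0,
) -> ClassReport:
    """Repeated stratified split / CV-tuned linear SVM / held-out evaluation.

    Each iteration draws its own split from a seed derived from the master
    seed, so the whole report is reproducible.
    """
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"binary protocol needs 2 classes, got {list(classes)}")
    if (counts * (1 - test_frac) < folds).any():
        raise ValueError("too few subjects per class for the requested folds")
    root = np.random.SeedSequence(int(seed))
    iter_seeds = root.generate_state(n_iter) % (2**31 - 1)
    rows = [
        _fit_eval_once(x, y, test_frac, folds, c_grid, int(s)) for s in iter_seeds
    ]
    return ClassReport(
        iterations=pd.DataFrame(rows),
        n_iter=n_iter,
        test_frac=test_frac,
        folds=folds,
        n_features=x.shape[1],
        seed=seed,
    )


def cross_dataset_evaluate(
    features_a: pd.DataFrame,
    labels_a: np.ndarray,
    features_b: pd.DataFrame,
    labels_b: np.ndarray,
    j: int | None = None,
    selection: WeightTable | None = None,
    n_iter: int = 100,
    test_frac: float = 0.2,
    folds: int = 10,
    rounds: int = 10,
    k: int = 10,
    seed: int = 0,
) -> tuple[ClassReport, list[str]]:
    """Select features on cohort A only, evaluate the SVM protocol on cohort B.

    ``j`` restricts the transferred set to cohort A's top-j features; without
    it the whole retained (top-fraction) set transfers.  Subject overlap
    between the cohorts is a fatal leakage error.  Returns the report and the
    transferred feature list.
    """
    overlap = set(features_a.index) & set(features_b.index)
    if overlap:
        raise ValueError(
            f"leakage: {len(overlap)} subject ids appear in both cohorts "
            f"(e.g. {sorted(overlap)[:3]})"
        )
    if list(features_a.columns) != list(features_b.columns):
        raise ValueError("cohorts must share the feature label space")
    if selection is None:
        selection = multiround_select(
            features_a, labels_a, rounds=rounds, k=k, seed=seed
        )
    chosen = (
        selection.top_features(j) if j is not None else selection.retained_features()
    )
    report = run_protocol(
        features_b[chosen],
        labels_b,
        n_iter=n_iter,
        test_frac=test_frac,
        folds=folds,
        seed=seed,
    )
    return report, chosen
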