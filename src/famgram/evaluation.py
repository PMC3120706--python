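"""Confusion-matrix metrics and cross-validation protocols.

Three validation designs are provided:

* stratified k-fold cross-validation (default k=5), where every family's
  members are spread as evenly as possible over the folds;
* a single small-family split for datasets containing families with fewer
  than k members: such families contribute exactly one randomly chosen
  member to the test side and the rest to training, while larger families
  contribute a stratified 1/k fraction;
* a training-size sweep that grows the training set one stratified tenth
  at a time and tests on the remainder, to chart accuracy against the
  amount of training data.

Metrics follow the standard confusion-matrix definitions on the percent
scale: SE = 100*TP/(TP+FN), SP = 100*TN/(TN+FP),
Acc = 100*(TP+TN)/(TP+FP+TN+FN).  A zero denominator raises
:class:`UndefinedMetricError` rather than silently reporting 0, because
silent zeros corrupt averages.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import classifier as clf
from .errors import ParameterError, UndefinedMetricError
from .features import NgramVocabulary, featurize_dataset
from .io import LabeledDataset

__all__ = [
    "BinaryConfusion",
    "MulticlassConfusion",
    "metrics",
    "CvReport",
    "stratified_kfold",
    "cross_validate",
    "small_family_split",
    "training_size_sweep",
]


@dataclass(frozen=True)
class BinaryConfusion:
    """TP/FP/TN/FN counts for a one-vs-rest binary task."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MulticlassConfusion:
    """M x M count table; rows are true families, columns predicted."""

    labels: tuple[str, ...]
    table: np.ndarray  # (M, M) int

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str]
    ) -> "MulticlassConfusion":
        if len(y_true) != len(y_pred):
            raise ParameterError("y_true and y_pred must have equal length")
        labels = tuple(sorted(set(y_true) | set(y_pred)))
        idx = {lab: i for i, lab in enumerate(labels)}
        table = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            table[idx[t], idx[p]] += 1
        return cls(labels=labels, table=table)

    def accuracy(self) -> float:
        """Overall accuracy in percent: trace over total."""
        total = int(self.table.sum())
        if total == 0:
            raise UndefinedMetricError("empty confusion table")
        return 100.0 * float(np.trace(self.table)) / total

    def binarize(self, label: str) -> BinaryConfusion:
        """Collapse to one-vs-rest counts for the given family."""
        if label not in self.labels:
            raise ParameterError(f"unknown family {label!r}")
        i = self.labels.index(label)
        tp = int(self.table[i, i])
        fn = int(self.table[i].sum()) - tp
        fp = int(self.table[:, i].sum()) - tp
        tn = int(self.table.sum()) - tp - fn - fp
        return BinaryConfusion(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(cm: BinaryConfusion) -> tuple[float, float, float]:
    """(SE, SP, Acc) in percent; raises UndefinedMetricError on a zero denominator."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("SE undefined: no positive examples (TP+FN=0)")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("SP undefined: no negative examples (TN+FP=0)")
    if cm.total == 0:
        raise UndefinedMetricError("Acc undefined: empty confusion matrix")
    se = 100.0 * cm.tp / (cm.tp + cm.fn)
    sp = 100.0 * cm.tn / (cm.tn + cm.fp)
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    return se, sp, acc


@dataclass
class CvReport:
    """Cross-validation outcome: per-fold and pooled results."""

    fold_accuracies: list[float]
    fold_sizes: list[int]
    mean_accuracy: float  # example-weighted mean, percent
    per_family: dict[str, dict[str, float | None]]
    confusion: MulticlassConfusion
    k: int
    seed: int
    c: float
    ngram_types: list[int]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fold", "n_test", "accuracy"])
            for i, (n, acc) in enumerate(zip(self.fold_sizes, self.fold_accuracies), 1):
                writer.writerow([i, n, f"{acc:.2f}"])
            writer.writerow(["mean", sum(self.fold_sizes), f"{self.mean_accuracy:.2f}"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean_accuracy": round(self.mean_accuracy, 2),
            "fold_accuracies": [round(a, 2) for a in self.fold_accuracies],
            "fold_sizes": self.fold_sizes,
            "per_family": self.per_family,
            "k": self.k,
            "seed": self.seed,
            "c": self.c,
            "ngram_types": self.ngram_types,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def _check_labeled(ds: LabeledDataset) -> list[str]:
    y = ds.labels()
    if any(lab is None for lab in y):
        raise ParameterError("every record must carry a family label")
    return y  # type: ignore[return-value]


def stratified_kfold(
    ds: LabeledDataset, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split into k disjoint, covering, family-stratified folds.

    Fold sizes differ by at most one overall and per family.  Every family
    must have at least k members; smaller families should go through
    :func:`small_family_split` instead.
    """
    if k < 2:
        raise ParameterError("k must be at least 2")
    y = _check_labeled(ds)
    sizes = ds.family_sizes()
    too_small = sorted(f for f, n in sizes.items() if n < k)
    if too_small:
        raise ParameterError(
            f"family {too_small[0]!r} has {sizes[too_small[0]]} member(s), "
            f"fewer than k={k}; use small_family_split for such datasets"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train_idx.copy(), test_idx.copy())
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y)
    ]


def _assert_partition(splits, n: int) -> None:
    seen = np.concatenate([test for _, test in splits])
    if len(seen) != n or len(np.unique(seen)) != n:
        raise AssertionError("test folds do not partition the dataset")


def cross_validate(
    ds: LabeledDataset,
    vocab: NgramVocabulary,
    c: float = 1.0,
    k: int = 5,
    seed: int = 42,
) -> CvReport:
    """Run stratified k-fold CV of the full featurize-train-predict pipeline.

    Per-family SE/SP are computed from the confusion table pooled over all
    held-out predictions; a family-level metric with a zero denominator is
    reported as ``None``.
    """
    y = np.asarray(_check_labeled(ds))
    X, _ = featurize_dataset(ds, vocab)
    splits = stratified_kfold(ds, k=k, seed=seed)
    _assert_partition(splits, len(y))
    fold_acc: list[float] = []
    fold_sizes: list[int] = []
    true_all: list[str] = []
    pred_all: list[str] = []
    for train_idx, test_idx in splits:
        model = clf.train(X[train_idx], y[train_idx], c=c, vocab=vocab, seed=seed)
        pred = clf.predict_batch(model, X[test_idx])
        correct = sum(p == t for p, t in zip(pred, y[test_idx]))
        fold_acc.append(100.0 * correct / len(test_idx))
        fold_sizes.append(len(test_idx))
        true_all.extend(y[test_idx])
        pred_all.extend(pred)
    confusion = MulticlassConfusion.from_predictions(true_all, pred_all)
    mean_acc = float(np.average(fold_acc, weights=fold_sizes))
    per_family: dict[str, dict[str, float | None]] = {}
    for lab in confusion.labels:
        bc = confusion.binarize(lab)
        entry: dict[str, float | None] = {}
        try:
            se, sp, _ = metrics(bc)
            entry["se"], entry["sp"] = round(se, 2), round(sp, 2)
        except UndefinedMetricError:
            entry["se"] = entry["sp"] = None
        per_family[lab] = entry
    return CvReport(
        fold_accuracies=fold_acc,
        fold_sizes=fold_sizes,
        mean_accuracy=mean_acc,
        per_family=per_family,
        confusion=confusion,
        k=k,
        seed=seed,
        c=c,
        ngram_types=list(vocab.types),
    )


def small_family_split(
    ds: LabeledDataset, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One train/test split that accommodates families smaller than k.

    Families with >= k members contribute a random 1/k fraction (floor, at
    least one member) to the test side; families with fewer than k members
    contribute exactly one randomly chosen member.  Every family therefore
    appears on both sides, which requires at least 2 members each.
    """
    if k < 2:
        raise ParameterError("k must be at least 2")
    y = _check_labeled(ds)
    sizes = ds.family_sizes()
    singletons = sorted(f for f, n in sizes.items() if n < 2)
    if singletons:
        raise ParameterError(
            f"family {singletons[0]!r} has a single member and cannot be "
            "split into train and test"
        )
    rng = np.random.default_rng(seed)
    test: list[int] = []
    train: list[int] = []
    for fam in sorted(sizes):
        idx = np.asarray([i for i, lab in enumerate(y) if lab == fam])
        rng.shuffle(idx)
        n_test = max(1, len(idx) // k) if len(idx) >= k else 1
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.asarray(sorted(train)), np.asarray(sorted(test))


def training_size_sweep(
    ds: LabeledDataset,
    vocab: NgramVocabulary,
    c: float = 1.0,
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    seed: int = 42,
) -> dict[float, float]:
    """Accuracy as a function of training-set size.

    The dataset is cut into 10 stratified tenths; for each fraction f in
    ``fractions`` the first round(10*f) tenths (cumulative, so larger
    training sets contain the smaller ones) form the training set and the
    remaining tenths the test set.  Returns {fraction: accuracy%}.
    """
    for f in fractions:
        tenths = round(10 * f)
        if not np.isclose(tenths, 10 * f) or not 1 <= tenths <= 9:
            raise ParameterError(f"fractions must be multiples of 0.1 in [0.1, 0.9], got {f}")
    y = np.asarray(_check_labeled(ds))
    X, _ = featurize_dataset(ds, vocab)
    parts = [test for _, test in stratified_kfold(ds, k=10, seed=seed)]
    results: dict[float, float] = {}
    for f in sorted(set(fractions)):
        m = round(10 * f)
        train_idx = np.concatenate(parts[:m])
        test_idx = np.concatenate(parts[m:])
        model = clf.train(X[train_idx], y[train_idx], c=c, vocab=vocab, seed=seed)
        pred = clf.predict_batch(model, X[test_idx])
        correct = sum(p == t for p, t in zip(pred, y[test_idx]))
        results[float(f)] = 100.0 * correct / len(test_idx)
    return results
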