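"""One-vs-all linear max-margin family classifier.

For M family labels, M binary linear SVMs are trained: classifier *i* uses
family-*i* examples as positives and everything else as negatives.  A query
is assigned to the family whose decision function F_i(x) = w_i.x + b_i is
largest; exact ties go to the lexicographically smallest label so
predictions are reproducible across runs and platforms.

Feature vectors are used as-is: the concentration weighting applied during
feature extraction is the intended feature scaling, and standardising the
columns would silently undo it.  The trade-off between training error and
margin is the usual SVM parameter ``c`` (default 1.0).

Training is deterministic: the primal squared-hinge solver needs no random
initialisation, and the model-level ``seed`` recorded in the file exists so
any future stochastic component has a single source of randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .errors import CompatibilityError, ParameterError, TrainingError
from .features import NgramVocabulary

__all__ = ["FamilyModel", "train", "predict", "predict_batch", "save_model", "load_model"]

_FORMAT = "famgram-model/1"


@dataclass
class FamilyModel:
    """Per-family linear decision functions plus the vocabulary layout."""

    labels: tuple[str, ...]  # lexicographically sorted
    coef: np.ndarray  # (M, l)
    intercept: np.ndarray  # (M,)
    c: float
    vocab_signature: dict
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.coef.shape[1]

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.n_features:
            raise CompatibilityError(
                f"feature vector has {x.shape[-1]} dimensions but the model "
                f"was trained on {self.n_features} "
                f"(vocabulary types {self.vocab_signature.get('types')})"
            )
        return x @ self.coef.T + self.intercept


def train(
    X: np.ndarray,
    y: Sequence[str],
    c: float = 1.0,
    vocab: NgramVocabulary | None = None,
    seed: int = 0,
) -> FamilyModel:
    """Fit one binary max-margin separator per family label.

    Requires at least two distinct labels, each with at least one example.
    ``c`` is the error/margin trade-off (> 0).
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ParameterError(
            f"X has {X.shape[0] if X.ndim == 2 else '?'} rows but y has {len(y)} labels"
        )
    if not (isinstance(c, (int, float)) and c > 0):
        raise ParameterError(f"c must be a positive real, got {c!r}")
    labels = tuple(sorted(set(y)))
    if len(labels) < 2:
        raise TrainingError(
            f"training requires at least 2 distinct families, got {len(labels)}"
        )
    y_arr = np.asarray(y)
    coef = np.zeros((len(labels), X.shape[1]))
    intercept = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        target = (y_arr == lab).astype(int)
        # primal squared-hinge solve: deterministic, no random_state needed
        clf = LinearSVC(C=float(c), loss="squared_hinge", dual=False, tol=1e-8)
        clf.fit(X, target)
        w = clf.coef_[0]
        b = clf.intercept_[0]
        # sklearn orients the function toward class "1" (our positives)
        # only when both classes are present, which train() guarantees
        coef[i] = w
        intercept[i] = b
    signature = vocab.signature() if vocab is not None else {"types": None, "length": X.shape[1]}
    return FamilyModel(
        labels=labels,
        coef=coef,
        intercept=intercept,
        c=float(c),
        vocab_signature=signature,
        seed=seed,
    )


def predict(model: FamilyModel, x: np.ndarray) -> tuple[str, dict[str, float]]:
    """Assign ``x`` to the family with the largest decision value.

    Returns (label, per-family decision values).  Ties break to the
    lexicographically smallest label (labels are stored sorted, and argmax
    returns the first maximum).
    """
    scores = model.decision_values(np.asarray(x, dtype=float).ravel())
    best = int(np.argmax(scores))
    return model.labels[best], dict(zip(model.labels, map(float, scores)))


def predict_batch(model: FamilyModel, X: np.ndarray) -> list[str]:
    """Row-wise prediction, preserving input order."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return []
    scores = model.decision_values(X)
    return [model.labels[i] for i in np.argmax(scores, axis=1)]


def save_model(model: FamilyModel, path: str | Path) -> None:
    """Persist a model as a single self-describing JSON file."""
    payload = {
        "format": _FORMAT,
        "labels": list(model.labels),
        "coef": model.coef.tolist(),
        "intercept": model.intercept.tolist(),
        "c": model.c,
        "seed": model.seed,
        "vocab_signature": model.vocab_signature,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> FamilyModel:
    """Load a model written by :func:`save_model`, verifying the header."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise CompatibilityError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _FORMAT:
        raise CompatibilityError(f"{path} is not a famgram model file")
    try:
        return FamilyModel(
            labels=tuple(payload["labels"]),
            coef=np.asarray(payload["coef"], dtype=float),
            intercept=np.asarray(payload["intercept"], dtype=float),
            c=float(payload["c"]),
            vocab_signature=payload["vocab_signature"],
            seed=int(payload.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CompatibilityError(f"model file {path} is incomplete: {exc}") from exc
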