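"""Concentration-weighted n-gram feature vectors.

A sequence is embedded into a fixed vector space by sliding a window of
size *n* along it 5'→3' for each selected n-gram type and recording
occurrence frequencies.  The per-type blocks are combined with a
*concentration* weight

    C_i = N_i / sum_k N_k,        N_i = 4**i unique grams of type i,

so that longer grams (which carry more sequence information) outweigh
shorter ones.  The value stored for gram *j* of type *i* is

    x_j = C_i * t_j / T_i,

where ``t_j`` is the gram's count and ``T_i`` the total count of type-*i*
windows.  Because each type block sums to ``C_i`` and the concentrations
sum to 1, a fully valid sequence long enough for every type yields a
feature vector whose entries sum to exactly 1.

With the default types {1, 2, 3, 4} the space has 4 + 16 + 64 + 256 = 340
dimensions, laid out tetragrams first, then trigrams, bigrams and unigrams,
lexicographic (A < C < G < U) within each type.

Windows containing any letter outside {A, C, G, U} are skipped entirely:
they contribute to neither ``t_j`` nor ``T_i``.  This keeps the sum-to-1
normalisation intact in the presence of noise bases and makes the vectors
insensitive to isolated ambiguity codes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError
from .io import LabeledDataset, RnaSequence

__all__ = [
    "ALPHABET",
    "NgramVocabulary",
    "NgramCounts",
    "build_vocabulary",
    "count_ngrams",
    "featurize",
    "featurize_dataset",
    "family_center",
    "center_distance",
    "feature_variance_across_families",
    "write_feature_csv",
    "write_svmlight",
]

ALPHABET = "ACGU"
_VALID = frozenset(ALPHABET)


@dataclass(frozen=True)
class NgramVocabulary:
    """Ordered n-gram vocabulary with per-type concentration weights.

    ``types`` is sorted with the largest n first; ``grams`` lists all
    4**n grams per type in that order, lexicographic within a type.
    ``concentrations[i] = 4**i / sum(4**k for selected k)``.
    """

    types: tuple[int, ...]
    grams: tuple[str, ...]
    concentrations: dict[int, float]

    @property
    def length(self) -> int:
        return len(self.grams)

    def signature(self) -> dict:
        """Layout descriptor persisted with trained models."""
        return {"types": list(self.types), "length": self.length}

    def block_slice(self, n: int) -> slice:
        """Index range of the type-``n`` block within a feature vector."""
        if n not in self.types:
            raise ParameterError(f"type {n} is not in this vocabulary")
        start = 0
        for t in self.types:
            if t == n:
                return slice(start, start + 4**n)
            start += 4**t
        raise AssertionError("unreachable")

    def index_of(self, gram: str) -> int:
        offset = 0
        n = len(gram)
        for t in self.types:
            if t == n:
                break
            offset += 4**t
        else:
            raise ParameterError(f"no type of length {n} in vocabulary")
        idx = 0
        for ch in gram:
            idx = idx * 4 + ALPHABET.index(ch)
        return offset + idx


@dataclass(frozen=True)
class NgramCounts:
    """Sliding-window occurrence counts per selected type."""

    counts: dict[int, dict[str, int]]  # type -> gram -> t_j
    totals: dict[int, int]  # type -> T_i


def build_vocabulary(types: Iterable[int] = (1, 2, 3, 4)) -> NgramVocabulary:
    """Build the ordered vocabulary for the selected n-gram types.

    Concentrations are normalised over the *selected* types only, so a
    vocabulary restricted to, say, {1, 2, 3} is self-normalising.
    """
    tset = sorted(set(types), reverse=True)
    if not tset:
        raise ParameterError("at least one n-gram type is required")
    for n in tset:
        if not isinstance(n, int) or not 1 <= n <= 8:
            raise ParameterError(f"n-gram type must be an integer in 1..8, got {n!r}")
    total_unique = sum(4**n for n in tset)
    grams: list[str] = []
    for n in tset:
        grams.extend("".join(p) for p in product(ALPHABET, repeat=n))
    conc = {n: 4**n / total_unique for n in tset}
    return NgramVocabulary(types=tuple(tset), grams=tuple(grams), concentrations=conc)


def count_ngrams(seq: RnaSequence | str, vocab: NgramVocabulary) -> NgramCounts:
    """Count every valid window of each selected type along the sequence.

    A window is valid iff all its letters are in {A, C, G, U}; invalid
    windows are skipped and do not enter ``T_i``.  Sequences shorter than
    ``n`` simply yield ``T_n = 0``.
    """
    bases = seq.bases if isinstance(seq, RnaSequence) else seq
    counts: dict[int, dict[str, int]] = {}
    totals: dict[int, int] = {}
    for n in vocab.types:
        c: dict[str, int] = {}
        total = 0
        for i in range(len(bases) - n + 1):
            window = bases[i : i + n]
            if _VALID.issuperset(window):
                c[window] = c.get(window, 0) + 1
                total += 1
        counts[n] = c
        totals[n] = total
    return NgramCounts(counts=counts, totals=totals)


def featurize(
    seq: RnaSequence | str, vocab: NgramVocabulary, weighted: bool = True
) -> np.ndarray:
    """Map a sequence to its feature vector.

    With ``weighted=True`` (default) entries are ``C_i * t_j / T_i``; with
    ``weighted=False`` the concentration factor is dropped and each type
    block holds the raw relative frequencies ``t_j / T_i`` (useful for
    analysing what the weighting contributes).  A type with ``T_i = 0``
    contributes an all-zero block.
    """
    nc = count_ngrams(seq, vocab)
    vec = np.zeros(vocab.length)
    offset = 0
    for n in vocab.types:
        total = nc.totals[n]
        if total > 0:
            scale = (vocab.concentrations[n] if weighted else 1.0) / total
            for gram, t in nc.counts[n].items():
                idx = 0
                for ch in gram:
                    idx = idx * 4 + ALPHABET.index(ch)
                vec[offset + idx] = scale * t
        offset += 4**n
    return vec


def featurize_dataset(
    ds: LabeledDataset | Sequence[RnaSequence],
    vocab: NgramVocabulary,
    weighted: bool = True,
) -> tuple[np.ndarray, list[str | None]]:
    """Featurize every record; returns (n_records x l matrix, aligned labels)."""
    records = list(ds)
    if not records:
        raise ParameterError("cannot featurize an empty dataset")
    X = np.vstack([featurize(r, vocab, weighted=weighted) for r in records])
    y = [r.family for r in records]
    return X, y


def family_center(vectors: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Dimension-wise arithmetic mean of a family's feature vectors."""
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        raise ParameterError("family_center requires at least one vector")
    return arr.mean(axis=0)


def center_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two (center) vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def feature_variance_across_families(centers: Sequence[np.ndarray]) -> np.ndarray:
    """Per-dimension population variance across family center vectors.

    Quantifies how discrepant each feature is between families; features
    with larger cross-family variance are the ones a linear separator can
    exploit.
    """
    arr = np.asarray(list(centers), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ParameterError("need at least two centers of equal length")
    return arr.var(axis=0)


def write_feature_csv(
    X: np.ndarray,
    vocab: NgramVocabulary,
    path: str | Path,
    ids: Sequence[str] | None = None,
) -> None:
    """Write a headered CSV: optional id column, then one column per gram."""
    X = np.asarray(X, dtype=float)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = list(vocab.grams)
        if ids is not None:
            header = ["id"] + header
        writer.writerow(header)
        for k, row in enumerate(X):
            cells = [repr(v) for v in row]
            if ids is not None:
                cells = [ids[k]] + cells
            writer.writerow(cells)


def write_svmlight(
    X: np.ndarray, labels: Sequence[str], path: str | Path
) -> dict[str, int]:
    """Write the sparse ``label index:value`` format (1-based indices).

    String labels are mapped to integers by sorted order; the mapping is
    returned so callers can invert it.
    """
    label_map = {lab: i + 1 for i, lab in enumerate(sorted(set(labels)))}
    with open(path, "w", encoding="utf-8") as fh:
        for row, lab in zip(np.asarray(X, dtype=float), labels):
            nz = np.nonzero(row)[0]
            pairs = " ".join(f"{j + 1}:{row[j]:.10g}" for j in nz)
            fh.write(f"{label_map[lab]} {pairs}\n")
    return label_map
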