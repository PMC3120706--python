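"""Synthetic sequence generators for negative controls and benchmark data.

miRNA families group sequences presumed to descend from a common ancestor,
so a family is emulated by drawing one random ancestor and deriving each
member through independent base-wise mutation (substitutions plus
single-base indels).  Negative controls mirror the two classic
constructions used to probe alignment-free classifiers:

* *reversed* positives — the same bases read 3'→5', which preserves
  composition exactly while scrambling the directional n-gram profile;
* *composition-matched randoms* — i.i.d. sequences whose mononucleotide
  frequencies and length range match a reference set.

All generators are pure functions of their integer seed: the same call
produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError
from .features import ALPHABET
from .io import LabeledDataset, RnaSequence

__all__ = [
    "FamilyGeneratorSpec",
    "reverse_sequences",
    "random_matched_composition",
    "dinucleotide_shuffle",
    "generate_families",
    "trigram_pool_families",
    "make_benchmark",
]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class FamilyGeneratorSpec:
    """Parameters of the mutation-derived family generator.

    ``substitution_rate`` and ``indel_rate`` are per-base probabilities;
    an indel event is a deletion or a single-base insertion with equal
    probability.  ``base_composition`` orders probabilities as (A, C, G, U).
    """

    n_families: int
    members_per_family: int | Sequence[int]
    ancestor_length: int = 80
    substitution_rate: float = 0.10
    indel_rate: float = 0.02
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.ancestor_length < 1:
            raise ParameterError("n_families and ancestor_length must be >= 1")
        members = self.members_list()
        if len(members) != self.n_families or any(m < 1 for m in members):
            raise ParameterError("members_per_family must give >= 1 per family")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0 <= rate < 1:
                raise ParameterError(f"mutation rates must lie in [0, 1), got {rate}")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
            raise ParameterError("base_composition must be a probability 4-vector")

    def members_list(self) -> list[int]:
        if isinstance(self.members_per_family, int):
            return [self.members_per_family] * self.n_families
        return list(self.members_per_family)


def reverse_sequences(
    records: Iterable[RnaSequence], complement: bool = False
) -> list[RnaSequence]:
    """Reverse each sequence 5'→3' (no complementation unless requested).

    Plain reversal is an involution that preserves length and base
    composition exactly, making it the cleanest order-destroying negative
    control.  Output ids carry a ``_rev`` suffix (stripped again when the
    input already has one, so reversing twice restores the originals).
    """
    records = list(records)
    if not records:
        raise ParameterError("reverse_sequences requires at least one record")
    out = []
    for rec in records:
        bases = rec.bases[::-1]
        if complement:
            bases = bases.translate(_COMPLEMENT)
        new_id = rec.id[: -len("_rev")] if rec.id.endswith("_rev") else rec.id + "_rev"
        out.append(RnaSequence(id=new_id, bases=bases, family=rec.family))
    return out


def _pooled_composition(records: Sequence[RnaSequence]) -> np.ndarray:
    counts = np.zeros(4)
    for rec in records:
        for i, base in enumerate(ALPHABET):
            counts[i] += rec.bases.count(base)
    if counts.sum() == 0:
        raise ParameterError("reference contains no A/C/G/U bases")
    return counts / counts.sum()


def random_matched_composition(
    reference: Sequence[RnaSequence], n: int, seed: int = 0
) -> list[RnaSequence]:
    """Draw n i.i.d. sequences matching a reference set's base composition.

    Each output length is uniform over the reference length range; bases
    are drawn i.i.d. from the reference's pooled mononucleotide
    frequencies (an order-0 match; see :func:`dinucleotide_shuffle` for a
    stricter null).
    """
    reference = list(reference)
    if not reference or n < 1:
        raise ParameterError("need a non-empty reference and n >= 1")
    comp = _pooled_composition(reference)
    lengths = [len(r) for r in reference]
    lo, hi = min(lengths), max(lengths)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        bases = "".join(rng.choice(list(ALPHABET), size=length, p=comp))
        out.append(RnaSequence(id=f"rand_{i:04d}", bases=bases))
    return out


def dinucleotide_shuffle(
    records: Iterable[RnaSequence], seed: int = 0
) -> list[RnaSequence]:
    """Shuffle each sequence preserving its exact dinucleotide counts.

    A stricter null than i.i.d. composition matching: each output is a
    random Eulerian walk over the input's dinucleotide transition
    multigraph, so every adjacent base pair count is conserved.  Noise
    letters participate as ordinary symbols.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        out.append(
            RnaSequence(
                id=rec.id + "_dshuf",
                bases=_euler_shuffle(rec.bases, rng),
                family=rec.family,
            )
        )
    return out


def _euler_shuffle(s: str, rng: np.random.Generator) -> str:
    if len(s) < 3:
        return s
    # Altschul-Erikson: pick a random last-exit edge per vertex that keeps the
    # edge graph connected to the terminal vertex, then randomise the rest.
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    first, last = s[0], s[-1]
    vertices = sorted(edges.keys() | {last})
    for _ in range(1000):
        last_exit = {}
        for v in vertices:
            if v != last and edges.get(v):
                last_exit[v] = edges[v][int(rng.integers(len(edges[v])))]
        # connectivity check: every vertex's last-exit path must reach `last`
        ok = True
        for v in last_exit:
            seen = set()
            cur = v
            while cur != last and cur in last_exit and cur not in seen:
                seen.add(cur)
                cur = last_exit[cur]
            if cur != last:
                ok = False
                break
        if not ok:
            continue
        remaining = {v: list(es) for v, es in edges.items()}
        for v, e in last_exit.items():
            remaining[v].remove(e)
        for v in remaining:
            rng.shuffle(remaining[v])
        order = {
            v: remaining[v] + ([last_exit[v]] if v in last_exit else [])
            for v in remaining
        }
        walk = [first]
        cur = first
        while order.get(cur):
            cur = order[cur].pop(0)
            walk.append(cur)
        if len(walk) == len(s):
            return "".join(walk)
    return s  # degenerate graphs (e.g. homopolymers) shuffle to themselves


def _mutate(ancestor: str, sub: float, indel: float, rng: np.random.Generator) -> str:
    bases = []
    for ch in ancestor:
        u = rng.random()
        if u < indel / 2:
            continue  # deletion
        if rng.random() < sub:
            choices = [b for b in ALPHABET if b != ch]
            ch = choices[int(rng.integers(3))]
        bases.append(ch)
        if indel / 2 <= u < indel:
            bases.append(ALPHABET[int(rng.integers(4))])  # insertion after
    return "".join(bases) if bases else ancestor[: 1]


def generate_families(spec: FamilyGeneratorSpec) -> LabeledDataset:
    """Generate mutation-derived families from independent random ancestors.

    One ancestor per family is drawn from ``base_composition``; each member
    is an independently mutated copy.  Labels are ``fam_000``, ``fam_001``,
    ...; fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[RnaSequence] = []
    for f, n_members in enumerate(spec.members_list()):
        ancestor = "".join(
            rng.choice(list(ALPHABET), size=spec.ancestor_length, p=spec.base_composition)
        )
        label = f"fam_{f:03d}"
        for m in range(n_members):
            bases = _mutate(ancestor, spec.substitution_rate, spec.indel_rate, rng)
            records.append(RnaSequence(id=f"{label}_m{m:03d}", bases=bases, family=label))
    return LabeledDataset(records=tuple(records))


def trigram_pool_families(
    n_families: int,
    members_per_family: int,
    trigrams_per_member: int = 25,
    pool_size: int = 8,
    seed: int = 0,
) -> LabeledDataset:
    """Families whose members are concatenations of family-private trigrams.

    The 64 trigrams are partitioned into disjoint pools, one per family;
    every member is a fresh random concatenation from its family's pool.
    By construction the families occupy disjoint trigram support, which
    makes them linearly separable in trigram (and tetragram) space — a
    controlled setting for studying what the concentration weighting does.
    """
    if n_families * pool_size > 64:
        raise ParameterError("disjoint trigram pools cannot exceed 64 trigrams total")
    from itertools import product

    rng = np.random.default_rng(seed)
    all_trigrams = ["".join(p) for p in product(ALPHABET, repeat=3)]
    rng.shuffle(all_trigrams)
    records: list[RnaSequence] = []
    for f in range(n_families):
        pool = all_trigrams[f * pool_size : (f + 1) * pool_size]
        label = f"fam_{f:03d}"
        for m in range(members_per_family):
            picks = rng.integers(pool_size, size=trigrams_per_member)
            bases = "".join(pool[i] for i in picks)
            records.append(RnaSequence(id=f"{label}_m{m:03d}", bases=bases, family=label))
    return LabeledDataset(records=tuple(records))


def make_benchmark(kind: str, **params) -> LabeledDataset:
    """Emit a ready-to-run benchmark dataset of one of three designs.

    * ``single_family_reverse`` — one mutation-derived family labelled
      ``real`` plus its base-wise reversals labelled ``reversed``;
    * ``single_family_random`` — the same positives plus an equal number of
      composition-matched random sequences labelled ``random``;
    * ``multi_family`` — ``n_families`` mutation-derived families.

    ``params`` are forwarded to :class:`FamilyGeneratorSpec` (``members``
    for the binary kinds, plus ``ancestor_length``, ``substitution_rate``,
    ``indel_rate``, ``seed``).
    """
    if kind in ("single_family_reverse", "single_family_random"):
        members = int(params.pop("members", 100))
        seed = int(params.pop("seed", 0))
        spec = FamilyGeneratorSpec(
            n_families=1, members_per_family=members, seed=seed, **params
        )
        positives = [
            RnaSequence(id=r.id, bases=r.bases, family="real")
            for r in generate_families(spec)
        ]
        if kind == "single_family_reverse":
            negatives = [
                r.with_family("reversed") for r in reverse_sequences(positives)
            ]
        else:
            negatives = [
                r.with_family("random")
                for r in random_matched_composition(positives, members, seed=seed + 1)
            ]
        return LabeledDataset(records=tuple(positives + negatives))
    if kind == "multi_family":
        n_families = int(params.pop("n_families", 10))
        members = params.pop("members", 20)
        seed = int(params.pop("seed", 0))
        spec = FamilyGeneratorSpec(
            n_families=n_families, members_per_family=members, seed=seed, **params
        )
        return generate_families(spec)
    raise ParameterError(
        f"unknown benchmark kind {kind!r}; expected single_family_reverse, "
        "single_family_random or multi_family"
    )
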