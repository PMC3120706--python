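"""Sequence and label-table I/O.

Sequences are RNA (or DNA, transparently converted) read from standard
multi-line FASTA.  Family labels live in a sidecar two-column TSV
(``id<TAB>family``) rather than in FASTA headers, mirroring the usual
id-to-family organisation of miRNA family registries while keeping the
FASTA files standard.

Normalisation is deliberately gentle: bases are upper-cased and T becomes U,
but letters outside {A, C, G, U} (ambiguity codes, sequencing noise) are kept
verbatim.  Downstream feature extraction decides how to treat them, which is
what lets the classifier handle "abnormal" sequences containing noise bases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, FastaFormatError, LabelTableError

__all__ = [
    "RnaSequence",
    "LabeledDataset",
    "normalize_bases",
    "read_fasta",
    "write_fasta",
    "read_family_table",
    "attach_labels",
]


def normalize_bases(raw: str) -> str:
    """Upper-case and convert T to U; idempotent; other letters untouched."""
    return raw.upper().replace("T", "U")


@dataclass(frozen=True)
class RnaSequence:
    """One sequence record: id, normalised bases, optional family label.

    ``bases`` is upper-case with every T already converted to U.  Letters
    outside {A, C, G, U} are permitted "noise" and retained verbatim.
    """

    id: str
    bases: str
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise FastaFormatError(f"invalid sequence id {self.id!r}")
        if not self.bases:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "bases", normalize_bases(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def with_family(self, family: str) -> "RnaSequence":
        return replace(self, family=family)


@dataclass(frozen=True)
class LabeledDataset:
    """A list of records together with the set of family labels present."""

    records: tuple[RnaSequence, ...]
    families: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})[0]
            raise FastaFormatError(f"duplicate sequence id {dup!r} in dataset")
        fams = frozenset(r.family for r in self.records if r.family is not None)
        object.__setattr__(self, "families", fams)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> list[str]:
        """Per-record family labels, in record order."""
        return [r.family for r in self.records]  # type: ignore[misc]

    def family_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for r in self.records:
            if r.family is not None:
                sizes[r.family] = sizes.get(r.family, 0) + 1
        return sizes


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a FASTA file into normalised :class:`RnaSequence` records.

    The first whitespace-delimited token of each header becomes the id.
    Raises :class:`FastaFormatError` on empty sequences or duplicate ids and
    :class:`EmptyInputError` if the file holds no records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[RnaSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(RnaSequence(id=rec.id, bases=str(rec.seq)))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[RnaSequence], path: str | Path, width: int = 60) -> None:
    """Write records as multi-line FASTA; lossless round-trip of id and bases."""
    records = list(records)
    if not records:
        raise EmptyInputError("refusing to write an empty FASTA file")
    seqs = [SeqRecord(Seq(r.bases), id=r.id, description="") for r in records]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_family_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sequence id to family label.

    Blank lines are skipped.  A repeated (id, family) pair is tolerated;
    the same id mapped to two different families is a
    :class:`LabelTableError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label table not found: {path}")
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise LabelTableError(
                    f"{path}:{lineno}: expected two tab-separated columns, got {line!r}"
                )
            sid, fam = parts
            if sid in mapping and mapping[sid] != fam:
                raise LabelTableError(
                    f"{path}:{lineno}: id {sid!r} mapped to both "
                    f"{mapping[sid]!r} and {fam!r}"
                )
            mapping[sid] = fam
    return mapping


def attach_labels(
    records: Iterable[RnaSequence], labels: Mapping[str, str]
) -> tuple[LabeledDataset, int]:
    """Join records with a family mapping.

    Records whose id is absent from the mapping are dropped; the count of
    dropped records is returned alongside the dataset (and surfaced as a
    :class:`UserWarning` when nonzero).  An empty result raises
    :class:`EmptyInputError`.
    """
    kept: list[RnaSequence] = []
    dropped = 0
    for rec in records:
        if rec.id in labels:
            kept.append(rec.with_family(labels[rec.id]))
        else:
            dropped += 1
    if not kept:
        raise EmptyInputError("no record id matched the label table")
    if dropped:
        warnings.warn(f"{dropped} record(s) had no family label and were dropped")
    return LabeledDataset(records=tuple(kept)), dropped
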