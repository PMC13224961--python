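"""Reading, validating and writing sequence datasets.

Sequences are coding-strand nucleotide strings. On ingest they are
normalized — uppercased and transcribed back to the DNA alphabet (U→T) —
because the adapters sit on top of DNA-embedding backbones even when the
prediction target is an mRNA property. Symbols outside {A,C,G,T,U}
(including the ambiguity code N) are rejected rather than imputed: the
codon is the modeling unit and silent imputation would change codon
identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ContractError, ParseError, SchemaError, ValidationError

ALPHABET = frozenset("ACGT")

__all__ = [
    "SequenceRecord",
    "Dataset",
    "normalize_sequence",
    "read_fasta",
    "read_table",
    "write_fasta",
    "write_table",
    "write_predictions",
]


def normalize_sequence(seq: str, *, record_id: str = "?") -> str:
    """Uppercase, map U→T, and validate the alphabet.

    Raises :class:`ValidationError` naming the offending symbol and its
    1-based position. Idempotent: normalizing twice equals normalizing once.
    """
    s = seq.strip().upper().replace("U", "T")
    for pos, ch in enumerate(s):
        if ch not in ALPHABET:
            raise ValidationError(
                f"record '{record_id}': disallowed symbol {ch!r} at position "
                f"{pos + 1} (allowed: A, C, G, T, U)"
            )
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with an identifier and optional scalar target."""

    id: str
    seq: str
    target: float | None = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("record id must be a non-empty string")
        if len(self.seq) < 3:
            raise ValidationError(
                f"record '{self.id}': sequence length {len(self.seq)} < 3"
            )
        if self.target is not None and not math.isfinite(self.target):
            raise ValidationError(f"record '{self.id}': non-finite target")


@dataclass
class Dataset:
    """An ordered collection of records with unique ids.

    Either every record carries a target or none does.
    """

    records: list[SequenceRecord]
    name: str = "dataset"

    def __post_init__(self):
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id '{rec.id}'")
            seen.add(rec.id)
        with_target = sum(rec.target is not None for rec in self.records)
        if with_target not in (0, len(self.records)):
            raise ValidationError(
                "either all records must have targets or none "
                f"({with_target}/{len(self.records)} have one)"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def sequences(self) -> list[str]:
        return [rec.seq for rec in self.records]

    @property
    def has_targets(self) -> bool:
        return len(self.records) > 0 and self.records[0].target is not None

    @property
    def targets(self) -> np.ndarray:
        if not self.has_targets:
            raise ContractError(f"dataset '{self.name}' has no targets")
        return np.array([rec.target for rec in self.records], dtype=float)

    def sequence_length(self) -> int:
        """Common sequence length; raises if lengths vary."""
        lengths = {len(rec.seq) for rec in self.records}
        if len(lengths) != 1:
            offenders = [r.id for r in self.records if len(r.seq) != len(self.records[0].seq)]
            raise ValidationError(
                f"dataset '{self.name}' has variable sequence lengths "
                f"{sorted(lengths)}; offending ids include {offenders[:5]}"
            )
        return lengths.pop()

    def subset(self, indices: Sequence[int], name: str | None = None) -> "Dataset":
        return Dataset([self.records[i] for i in indices], name or self.name)


def read_fasta(path: str | Path) -> Dataset:
    """Read a FASTA file into a :class:`Dataset` (no targets).

    The record id is the first whitespace-delimited token of the header.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise ParseError(f"{path}: FASTA entry with empty header")
        raw = str(entry.seq)
        if not raw:
            raise ParseError(f"{path}: record '{entry.id}' has an empty sequence")
        records.append(SequenceRecord(entry.id, normalize_sequence(raw, record_id=entry.id)))
    return Dataset(records, name=path.stem)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_table(path: str | Path) -> Dataset:
    """Read a delimited (comma or tab) table with columns id, sequence, target."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    missing = {"id", "sequence", "target"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            target = float(row.target)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: non-numeric target {row.target!r} in row {row_no}"
            ) from None
        rid = str(row.id)
        records.append(SequenceRecord(rid, normalize_sequence(str(row.sequence), record_id=rid), target))
    return Dataset(records, name=path.stem)


def write_fasta(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in dataset:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_table(dataset: Dataset, path: str | Path, sep: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["id", "sequence", "target"]) + "\n")
        for rec in dataset:
            tgt = "" if rec.target is None else repr(float(rec.target))
            fh.write(sep.join([rec.id, rec.seq, tgt]) + "\n")


def write_predictions(dataset: Dataset, preds: Sequence[float], path: str | Path) -> None:
    """Write a TSV of predictions, preserving row order.

    Adds a ``target`` column when the dataset carries targets.
    """
    preds = np.asarray(preds, dtype=float)
    if preds.ndim != 1 or len(preds) != len(dataset):
        raise ContractError(
            f"prediction vector length {preds.size} != record count {len(dataset)}"
        )
    with open(path, "w") as fh:
        if dataset.has_targets:
            fh.write("id\tprediction\ttarget\n")
            for rec, p in zip(dataset, preds):
                fh.write(f"{rec.id}\t{float(p)!r}\t{float(rec.target)!r}\n")
        else:
            fh.write("id\tprediction\n")
            for rec, p in zip(dataset, preds):
                fh.write(f"{rec.id}\t{float(p)!r}\n")
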