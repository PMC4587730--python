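"""Reading, sanitizing and labelling protein sequence datasets.

Datasets are plain FASTA files (multi-line sequences allowed) plus a
tab-separated label table keyed by accession (header ``id<TAB>subtype``).
Alternatively, labels may be embedded in FASTA headers as ``id|subtype``.
Class order is significant: the position of a subtype in the ordered class
list is its 1-based class index, used throughout the voting and
decision-value analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Canonical amino-acid ordering (alphabetical one-letter codes).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_STANDARD = frozenset(AA_ALPHABET)


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


class LabelError(ValueError):
    """Raised when labels cannot be attached to a record set."""


@dataclass
class ProteinRecord:
    """A single protein sequence with an optional subtype label."""

    id: str
    sequence: str
    label: str | None = None


@dataclass
class LabeledDataset:
    """Ordered protein records plus an ordered subtype vocabulary.

    The 1-based position of a subtype in ``classes`` is its class index;
    all downstream vote and decision-value sign conventions refer to these
    indices.
    """

    records: list[ProteinRecord]
    classes: list[str]

    def __post_init__(self) -> None:
        known = set(self.classes)
        for rec in self.records:
            if rec.label is not None and rec.label not in known:
                raise LabelError(
                    f"record {rec.id!r} has label {rec.label!r} not in classes {self.classes}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_index(self, label: str) -> int:
        """1-based index of ``label`` in the class ordering."""
        return self.classes.index(label) + 1

    def label_indices(self) -> np.ndarray:
        """Integer label vector (values 1..K), ordered as the records."""
        lut = {c: i + 1 for i, c in enumerate(self.classes)}
        return np.array([lut[r.label] for r in self.records], dtype=int)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for r in self.records:
            if r.label is not None:
                counts[r.label] += 1
        return counts


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into records (no labels attached).

    The record id is the first whitespace-delimited header token; sequences
    are uppercased with line breaks removed. Raises :class:`FastaParseError`
    on text before the first header, entries with empty sequences, or
    duplicate ids.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno} precedes any FASTA header: {line.strip()!r}"
                )
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: entry {entry.id!r} has an empty sequence")
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequences at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for start in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[start : start + width] + "\n")


def sanitize_sequence(raw: str, policy: str = "drop") -> str:
    """Uppercase a raw sequence and deal with non-standard residue codes.

    policy="strict" raises on any character outside the 20 standard
    one-letter codes (B, Z, X, U, O, J, ``*`` and gap characters included);
    policy="drop" removes such positions with a warning. Whitespace is
    always removed. An empty result is an error under either policy.
    """
    if policy not in ("strict", "drop"):
        raise ValueError(f"unknown policy {policy!r}")
    if not raw:
        raise ValueError("empty input sequence")
    seq = "".join(raw.split()).upper()
    bad = [c for c in seq if c not in _STANDARD]
    if bad:
        if policy == "strict":
            raise ValueError(f"non-standard residue code(s) {sorted(set(bad))} in sequence")
        warnings.warn(
            f"dropped {len(bad)} non-standard residue position(s): {sorted(set(bad))}",
            stacklevel=2,
        )
        seq = "".join(c for c in seq if c in _STANDARD)
    if not seq:
        raise ValueError("sequence empty after removing non-standard residues")
    return seq


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>subtype`` table (header required) into a mapping."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:2]) != ["id", "subtype"]:
        raise LabelError(
            f"{path}: expected header 'id\\tsubtype', found {list(table.columns)}"
        )
    return dict(zip(table["id"], table["subtype"]))


def write_labels_tsv(dataset: LabeledDataset, path: str | Path) -> None:
    pd.DataFrame(
        {"id": dataset.ids, "subtype": [r.label for r in dataset.records]}
    ).to_csv(path, sep="\t", index=False)


def read_classes(path: str | Path) -> list[str]:
    """Read the ordered subtype vocabulary: one subtype per line."""
    with open(path) as fh:
        classes = [line.strip() for line in fh if line.strip()]
    if len(set(classes)) != len(classes):
        raise LabelError(f"{path}: duplicate subtype in class order file")
    return classes


def labels_from_headers(records: Sequence[ProteinRecord]) -> dict[str, str]:
    """Fallback label source: parse ``accession|subtype`` FASTA ids.

    Returns a mapping from the bare accession to the subtype; the records
    themselves keep their full ids.
    """
    table: dict[str, str] = {}
    for rec in records:
        if "|" not in rec.id:
            raise LabelError(f"id {rec.id!r} has no '|subtype' suffix to parse")
        accession, subtype = rec.id.rsplit("|", 1)
        table[rec.id] = subtype
    return table


def attach_labels(
    records: Sequence[ProteinRecord],
    labels: Mapping[str, str],
    classes: Sequence[str],
) -> LabeledDataset:
    """Attach subtype labels to records, preserving record order exactly.

    Every record id must appear in ``labels`` and every subtype must be in
    ``classes``; violations raise :class:`LabelError` naming the offender.
    """
    known = set(classes)
    labelled: list[ProteinRecord] = []
    for rec in records:
        if rec.id not in labels:
            raise LabelError(f"record {rec.id!r} missing from the label table")
        subtype = labels[rec.id]
        if subtype not in known:
            raise LabelError(f"record {rec.id!r}: unknown subtype {subtype!r}")
        labelled.append(ProteinRecord(id=rec.id, sequence=rec.sequence, label=subtype))
    return LabeledDataset(records=labelled, classes=list(classes))
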