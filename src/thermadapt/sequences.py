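"""Sequence records, multiple sequence alignments, and FASTA/Clustal I/O."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio import AlignIO, SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(CANONICAL_AA) | {"X"}

THERMAL_GROUPS = ("psychrophile", "mesophile", "thermophile")
FAMILIES = ("S11", "S12", "S13")


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    organism_id: str = ""
    thermal_group: str = "unknown"
    family: str = "unknown"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"{self.id}: non-canonical letters {sorted(bad)}")
        if self.thermal_group not in THERMAL_GROUPS + ("unknown",):
            raise ValueError(f"unknown thermal group {self.thermal_group!r}")
        if self.family not in FAMILIES + ("unknown",):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class EnvironmentRecord:
    """Observed environmental conditions for one organism.

    Defaults follow the convention of assuming pH 7.2 and 200 mM salt where
    no measurement is available.
    """

    organism_id: str
    temperature: float  # K
    pH: float = 7.2
    ionic_strength: float = 200.0  # mM

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")


class MSA:
    """A gapped multiple sequence alignment; '-' is the gap character."""

    def __init__(self, ids: list[str], rows: list[str]) -> None:
        if len(ids) != len(rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MSA) and self.ids == other.ids and self.rows == other.rows
        )


def read_sequences(path: str) -> list[SequenceRecord]:
    """Read a FASTA file; sequences uppercased, ids must be unique."""
    records = [
        SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sequence ids")
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_alignment(path: str) -> MSA:
    """Read an aligned FASTA or Clustal file into an MSA."""
    with open(path) as fh:
        head = fh.read(7)
    fmt = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(path, fmt)
    return MSA([rec.id for rec in aln], [str(rec.seq).upper() for rec in aln])


def write_alignment(msa: MSA, path: str) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")
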