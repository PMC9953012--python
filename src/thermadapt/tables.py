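"""Tabular metadata: proteome annotation tables and environment tables.

Annotation TSV columns: accession, go_terms (semicolon-joined), protein_name,
membrane_regions ("start-end" comma list, 1-based inclusive), signal_peptide
("start-end"), sequence. Environment TSV columns: organism_id, temperature,
pH, ionic_strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .sequences import EnvironmentRecord


@dataclass
class AnnotationRecord:
    accession: str
    go_terms: set[str] = field(default_factory=set)
    protein_name: str = ""
    membrane_regions: list[tuple[int, int]] = field(default_factory=list)
    signal_peptide: Optional[tuple[int, int]] = None
    sequence: str = ""

    def __post_init__(self) -> None:
        n = len(self.sequence)
        spans = list(self.membrane_regions)
        if self.signal_peptide is not None:
            spans.append(self.signal_peptide)
        for start, end in spans:
            if start < 1 or end < start:
                raise ValueError(f"{self.accession}: invalid span ({start},{end})")
            if n and end > n:
                raise ValueError(
                    f"{self.accession}: span ({start},{end}) outside sequence length {n}"
                )


def _fmt_spans(spans: Iterable[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in spans)


def _parse_spans(text: str) -> list[tuple[int, int]]:
    text = (text or "").strip()
    if not text:
        return []
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def write_annotation_table(records: Iterable[AnnotationRecord], path: str) -> None:
    rows = [
        {
            "accession": r.accession,
            "go_terms": ";".join(sorted(r.go_terms)),
            "protein_name": r.protein_name,
            "membrane_regions": _fmt_spans(r.membrane_regions),
            "signal_peptide": _fmt_spans([r.signal_peptide]) if r.signal_peptide else "",
            "sequence": r.sequence,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str) -> list[AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        signal = _parse_spans(row["signal_peptide"])
        records.append(
            AnnotationRecord(
                accession=row["accession"],
                go_terms={t for t in row["go_terms"].split(";") if t},
                protein_name=row["protein_name"],
                membrane_regions=_parse_spans(row["membrane_regions"]),
                signal_peptide=signal[0] if signal else None,
                sequence=row["sequence"],
            )
        )
    return records


def read_environment_table(path: str) -> list[EnvironmentRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        kwargs = {"organism_id": str(row["organism_id"]), "temperature": float(row["temperature"])}
        if "pH" in df.columns and pd.notna(row.get("pH")):
            kwargs["pH"] = float(row["pH"])
        if "ionic_strength" in df.columns and pd.notna(row.get("ionic_strength")):
            kwargs["ionic_strength"] = float(row["ionic_strength"])
        out.append(EnvironmentRecord(**kwargs))
    return out


def write_environment_table(records: Iterable[EnvironmentRecord], path: str) -> None:
    pd.DataFrame(
        [
            {
                "organism_id": r.organism_id,
                "temperature": r.temperature,
                "pH": r.pH,
                "ionic_strength": r.ionic_strength,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
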