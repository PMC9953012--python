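"""Rule-based selection of putative non-membrane serine proteases.

The filter keeps a protein when either its GO annotation gives direct
serine-type evidence (and no inhibitor term), or its name together with a
generic peptidase GO term implies serine proteolytic activity. Membrane-
flagged proteins are dropped unless all predicted membrane regions fall in
the first 70 residues and a signal peptide is present (N-terminal membrane
predictions that overlap a signal sequence are treated as false positives).
All GO/name matching is case-insensitive substring matching; the table is
assumed pre-annotated and no ontology traversal is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .tables import AnnotationRecord

DEFAULT_BLOCKLIST = ("ClpA", "ATP-binding subunit")


class ExclusionReason(str, Enum):
    go_inhibitor = "go_inhibitor"
    no_serine_evidence = "no_serine_evidence"
    membrane_flagged = "membrane_flagged"
    name_excluded = "name_excluded"


class MembraneStatus(str, Enum):
    clear = "clear"
    flagged = "flagged"
    rescued = "rescued"


@dataclass
class CurationResult:
    retained: list[str] = field(default_factory=list)
    excluded: list[tuple[str, ExclusionReason]] = field(default_factory=list)
    rescued: list[str] = field(default_factory=list)

    @property
    def retained_set(self) -> set[str]:
        return set(self.retained)


def passes_go_name_filter(record: AnnotationRecord) -> bool:
    go = [t.lower() for t in record.go_terms]
    name = (record.protein_name or "").lower()
    serine_type = any("serine-type" in t for t in go)
    inhibitor = any("inhibitor" in t for t in go)
    if serine_type and not inhibitor:
        return True
    if any("0008233" in t or "peptidase activity" in t for t in go) and "serine" in name:
        return True
    if "serine" in name and any(w in name for w in ("protease", "peptidase", "proteinase")):
        return True
    return False


def membrane_flag(record: AnnotationRecord) -> MembraneStatus:
    """Classify membrane evidence; rescue requires every region to end at <= 70."""
    n = len(record.sequence)
    for start, end in record.membrane_regions:
        if n and (start < 1 or end > n):
            raise ValueError(
                f"{record.accession}: membrane span ({start},{end}) outside sequence"
            )
    if not record.membrane_regions:
        return MembraneStatus.clear
    all_nterm = all(end <= 70 for _, end in record.membrane_regions)
    if all_nterm and record.signal_peptide is not None:
        return MembraneStatus.rescued
    return MembraneStatus.flagged


def curate(
    records: list[AnnotationRecord],
    name_blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST,
) -> CurationResult:
    """Apply the full curation rule-set, recording a reason per exclusion."""
    accs = [r.accession for r in records]
    if len(set(accs)) != len(accs):
        dupes = sorted({a for a in accs if accs.count(a) > 1})
        raise ValueError(f"duplicate accessions: {dupes}")
    blocklist = [b.lower() for b in name_blocklist]
    result = CurationResult()
    for rec in records:
        if not passes_go_name_filter(rec):
            reason = (
                ExclusionReason.go_inhibitor
                if any("inhibitor" in t.lower() for t in rec.go_terms)
                else ExclusionReason.no_serine_evidence
            )
            result.excluded.append((rec.accession, reason))
            continue
        name = (rec.protein_name or "").lower()
        if any(b in name for b in blocklist):
            result.excluded.append((rec.accession, ExclusionReason.name_excluded))
            continue
        status = membrane_flag(rec)
        if status is MembraneStatus.flagged:
            result.excluded.append((rec.accession, ExclusionReason.membrane_flagged))
            continue
        if status is MembraneStatus.rescued:
            result.rescued.append(rec.accession)
        result.retained.append(rec.accession)
    return result
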