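"""Reading, validating and filtering training tables of (allele, peptide) pairs.

Cleaning drops peptides with non-standard residues (B, J, O, U, X, Z or any
other non-amino-acid character), exact duplicate (allele, peptide, label)
rows, and peptides outside the 8-25 length range; every drop is itemized in
a report. Cleaned binder records are then grouped by (allele, length), and
groups below the minimum binder count are excluded from training.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .core_scoring import (
    AA_INDEX,
    MAX_PEPTIDE_LENGTH,
    MIN_PEPTIDE_LENGTH,
)
from .exceptions import AlleleFormatError, SchemaError
from .model_store import normalize_allele


@dataclass(frozen=True)
class TrainingRecord:
    """One row of the training table, with line-number provenance."""

    allele: str
    peptide: str
    label: str = "binder"
    source_tag: str = ""
    line: int = 0


@dataclass
class DropReport:
    """Itemized record of rows removed by :func:`clean_training`."""

    rows: List[Tuple[int, str, str, str]] = field(default_factory=list)

    def add(self, record: TrainingRecord, reason: str) -> None:
        self.rows.append((record.line, record.allele, record.peptide, reason))

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for _, _, _, reason in self.rows:
            out[reason] = out.get(reason, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.rows)

    def write(self, path) -> None:
        with Path(path).open("wt", encoding="utf-8") as fh:
            fh.write("line\tallele\tpeptide\treason\n")
            for line, allele, peptide, reason in self.rows:
                fh.write(f"{line}\t{allele}\t{peptide}\t{reason}\n")


def load_training_table(path) -> List[TrainingRecord]:
    """Parse a TSV with columns ``allele``, ``peptide`` and optional
    ``label`` / ``source``; no filtering is applied here."""
    path = Path(path)
    records: List[TrainingRecord] = []
    with path.open("rt", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: file is empty")
        header = [h.strip().lower() for h in header]
        for col in ("allele", "peptide"):
            if col not in header:
                raise SchemaError(f"{path}: missing required column {col!r}")
        idx = {name: header.index(name) for name in header}
        n_required = max(idx["allele"], idx["peptide"]) + 1
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < n_required:
                raise SchemaError(
                    f"{path}:{lineno}: expected at least {n_required} fields, "
                    f"got {len(row)}"
                )
            label = "binder"
            if "label" in idx and len(row) > idx["label"] and row[idx["label"]].strip():
                label = row[idx["label"]].strip().lower()
            source = ""
            if "source" in idx and len(row) > idx["source"]:
                source = row[idx["source"]].strip()
            records.append(
                TrainingRecord(
                    allele=row[idx["allele"]].strip(),
                    peptide=row[idx["peptide"]].strip(),
                    label=label,
                    source_tag=source,
                    line=lineno,
                )
            )
    return records


def clean_training(
    records: List[TrainingRecord],
) -> Tuple[List[TrainingRecord], DropReport]:
    """Apply the data-cleaning rules; all problems become report rows.

    Peptides are uppercased before validation. Drop reasons (checked in
    order): ``abnormal_residue``, ``length``, ``allele_format``,
    ``duplicate``. Exact duplicates keep the first occurrence; the same
    peptide under two alleles is not a duplicate.
    """
    kept: List[TrainingRecord] = []
    report = DropReport()
    seen: set = set()
    for rec in records:
        peptide = rec.peptide.upper()
        if any(ch not in AA_INDEX for ch in peptide) or not peptide:
            report.add(rec, "abnormal_residue")
            continue
        if not (MIN_PEPTIDE_LENGTH <= len(peptide) <= MAX_PEPTIDE_LENGTH):
            report.add(rec, "length")
            continue
        try:
            allele = normalize_allele(rec.allele)
        except AlleleFormatError:
            report.add(rec, "allele_format")
            continue
        label = rec.label if rec.label in ("binder", "nonbinder") else "binder"
        key = (allele, peptide, label)
        if key in seen:
            report.add(rec, "duplicate")
            continue
        seen.add(key)
        kept.append(
            TrainingRecord(
                allele=allele,
                peptide=peptide,
                label=label,
                source_tag=rec.source_tag,
                line=rec.line,
            )
        )
    return kept, report


def group_for_training(
    records: List[TrainingRecord],
    min_binders: int = 10,
) -> Tuple[Dict[Tuple[str, int], List[str]], List[Tuple[Tuple[str, int], int]]]:
    """Group cleaned binder records by (allele, length).

    Returns the mapping plus a report of excluded (key, count) pairs for
    groups with fewer than ``min_binders`` members. Nonbinder records never
    enter a training group.
    """
    groups: Dict[Tuple[str, int], List[str]] = {}
    for rec in records:
        if rec.label != "binder":
            continue
        groups.setdefault((rec.allele, len(rec.peptide)), []).append(rec.peptide)
    excluded = [
        (key, len(peps)) for key, peps in sorted(groups.items())
        if len(peps) < min_binders
    ]
    kept = {k: v for k, v in groups.items() if len(v) >= min_binders}
    return kept, excluded


def write_training_tsv(path, records: List[TrainingRecord]) -> None:
    """Write records back out in the canonical training-table dialect."""
    with Path(path).open("wt", encoding="utf-8") as fh:
        fh.write("allele\tpeptide\tlabel\tsource\n")
        for rec in records:
            fh.write(f"{rec.allele}\t{rec.peptide}\t{rec.label}\t{rec.source_tag}\n")
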