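"""Neoantigen candidate enumeration and filtering.

From a protein-level somatic mutation, every peptide window (default
lengths 8-13) covering the altered site is enumerated from the mutant
protein; substitution windows are paired with their positionally matching
wild-type windows. A candidate passes when its mutant IC50 predicts a
binder (< 500 nM) and, where a wild-type partner exists, the mutant IC50
is strictly smaller than the wild-type IC50.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO

from .core_scoring import Ic50Transform, classify_affinity
from .exceptions import PssmBindError, UncoverableAlleleError

DEFAULT_LENGTHS = range(8, 14)


@dataclass(frozen=True)
class ProteinMutation:
    """A protein-coordinate somatic mutation (1-based inclusive positions).

    * substitution: ``ref_aa`` (one residue, must match the protein at
      ``position``) replaced by ``alt_aa`` (one residue, different).
    * insertion: ``alt_aa`` inserted immediately after ``position``.
    * deletion: ``ref_aa`` residues starting at ``position`` removed.
    """

    protein_id: str
    position: int
    kind: str
    ref_aa: str = ""
    alt_aa: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if self.kind == "substitution":
            if len(self.ref_aa) != 1 or len(self.alt_aa) != 1:
                raise ValueError("substitution requires single ref_aa and alt_aa")
            if self.ref_aa == self.alt_aa:
                raise ValueError("substitution ref_aa and alt_aa must differ")
        if self.kind == "insertion" and not self.alt_aa:
            raise ValueError("insertion requires alt_aa")
        if self.kind == "deletion" and not self.ref_aa:
            raise ValueError("deletion requires ref_aa")


class MutationConsistencyError(PssmBindError, ValueError):
    """The stated reference residue(s) do not match the protein sequence."""


def _check_reference(protein: str, mutation: ProteinMutation) -> None:
    p = mutation.position
    if mutation.kind == "substitution":
        if p > len(protein):
            raise MutationConsistencyError(
                f"position {p} beyond protein length {len(protein)}"
            )
        observed = protein[p - 1]
        if observed != mutation.ref_aa:
            raise MutationConsistencyError(
                f"ref_aa {mutation.ref_aa!r} does not match protein "
                f"{mutation.protein_id!r} at position {p} (observed {observed!r})"
            )
    elif mutation.kind == "insertion":
        if p > len(protein):
            raise MutationConsistencyError(
                f"insertion anchor {p} beyond protein length {len(protein)}"
            )
        if mutation.ref_aa and protein[p - 1] != mutation.ref_aa:
            raise MutationConsistencyError(
                f"ref_aa {mutation.ref_aa!r} does not match protein at position {p}"
            )
    else:  # deletion
        end = p - 1 + len(mutation.ref_aa)
        if end > len(protein):
            raise MutationConsistencyError(
                f"deletion of {len(mutation.ref_aa)} residues at {p} overruns "
                f"protein length {len(protein)}"
            )
        observed = protein[p - 1:end]
        if observed != mutation.ref_aa:
            raise MutationConsistencyError(
                f"ref_aa {mutation.ref_aa!r} does not match protein at "
                f"position {p} (observed {observed!r})"
            )


def apply_mutation(protein: str, mutation: ProteinMutation) -> Tuple[str, List[int]]:
    """Mutated sequence plus the altered/junction positions in mutant coordinates."""
    _check_reference(protein, mutation)
    p = mutation.position
    if mutation.kind == "substitution":
        mutant = protein[: p - 1] + mutation.alt_aa + protein[p:]
        altered = [p]
    elif mutation.kind == "insertion":
        mutant = protein[:p] + mutation.alt_aa + protein[p:]
        altered = list(range(p + 1, p + len(mutation.alt_aa) + 1))
    else:  # deletion: flanks of the junction
        mutant = protein[: p - 1] + protein[p - 1 + len(mutation.ref_aa):]
        altered = [q for q in (p - 1, p) if 1 <= q <= len(mutant)]
    return mutant, altered


@dataclass(frozen=True)
class WindowPair:
    """One mutant peptide window, with its wild-type partner when defined."""

    mutant_peptide: str
    wild_type_peptide: Optional[str]
    length: int
    start: int  # 1-based start in the mutant protein


def enumerate_windows(
    protein: str,
    mutation: ProteinMutation,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
) -> List[WindowPair]:
    """All peptide windows of the given lengths covering the mutated site.

    Substitution windows are paired with the corresponding wild-type window
    (same coordinates); insertion/deletion windows overlap any altered or
    junction position and carry no wild-type partner. Duplicate
    (mutant, wild-type) sequence pairs are removed.
    """
    protein = protein.upper()
    mutant, altered = apply_mutation(protein, mutation)
    out: List[WindowPair] = []
    seen = set()
    for length in sorted(set(lengths)):
        if length < 1 or length > len(mutant):
            continue
        lo = max(1, min(altered) - length + 1)
        hi = min(max(altered), len(mutant) - length + 1)
        for start in range(lo, hi + 1):
            window = mutant[start - 1: start - 1 + length]
            if mutation.kind == "substitution":
                wt: Optional[str] = protein[start - 1: start - 1 + length]
            else:
                wt = None
            key = (window, wt)
            if key in seen:
                continue
            seen.add(key)
            out.append(WindowPair(window, wt, length, start))
    return out


@dataclass(frozen=True)
class NeoantigenCandidate:
    """A scored mutant/wild-type peptide pair for one allele."""

    mutant_peptide: str
    wild_type_peptide: Optional[str]
    allele: str
    ic50_mut: Optional[float]
    ic50_wt: Optional[float]
    passed: bool
    reason: str  # pass | fail_binder | fail_wt_comparison | uncovered_length
    length: int = 0
    start: int = 0
    protein_id: str = ""


def call_neoantigens(
    pairs: Sequence[WindowPair],
    alleles: Sequence[str],
    predictor: Callable[[str, str], float],
    transform: Ic50Transform = Ic50Transform(),
    protein_id: str = "",
) -> List[NeoantigenCandidate]:
    """Score each window against each allele and apply the two filter rules.

    ``predictor(peptide, allele)`` returns a predicted IC50 in nM. A
    candidate passes iff ``ic50_mut < binder_cutoff`` and (no wild-type
    partner or ``ic50_mut < ic50_wt``). A window length the predictor
    cannot cover is reported as ``uncovered_length`` rather than raised;
    an allele with no coverage at any length raises.
    """
    out: List[NeoantigenCandidate] = []
    covered: Dict[str, bool] = {a: False for a in alleles}
    for allele in alleles:
        for pair in pairs:
            try:
                ic50_mut = predictor(pair.mutant_peptide, allele)
            except UncoverableAlleleError:
                ic50_mut = None
            except PssmBindError:
                ic50_mut = None
            if ic50_mut is None:
                out.append(
                    NeoantigenCandidate(
                        pair.mutant_peptide, pair.wild_type_peptide, allele,
                        None, None, False, "uncovered_length",
                        pair.length, pair.start, protein_id,
                    )
                )
                continue
            covered[allele] = True
            ic50_wt = (
                predictor(pair.wild_type_peptide, allele)
                if pair.wild_type_peptide is not None
                else None
            )
            if ic50_mut >= transform.binder_cutoff:
                passed, reason = False, "fail_binder"
            elif ic50_wt is not None and ic50_mut >= ic50_wt:
                passed, reason = False, "fail_wt_comparison"
            else:
                passed, reason = True, "pass"
            out.append(
                NeoantigenCandidate(
                    pair.mutant_peptide, pair.wild_type_peptide, allele,
                    ic50_mut, ic50_wt, passed, reason,
                    pair.length, pair.start, protein_id,
                )
            )
    uncovered = [a for a, ok in covered.items() if not ok and pairs]
    if uncovered:
        raise UncoverableAlleleError(
            f"no prediction coverage for allele(s) {uncovered}; "
            f"covered: {[a for a, ok in covered.items() if ok]}"
        )
    return out


def neoantigen_load(candidates: Iterable[NeoantigenCandidate]) -> int:
    """Per-sample neoantigen load: the count of passing (peptide, allele) calls."""
    return sum(1 for c in candidates if c.passed)


def consensus_call(
    ic50_by_predictor: Mapping[str, float],
    cutoff: float = 500.0,
    min_support: int = 2,
) -> Tuple[float, bool]:
    """Multi-predictor consensus: binder iff at least ``min_support``
    predictors report IC50 < cutoff; the final IC50 is the median of all
    supplied values. With a single predictor its own call stands."""
    values = list(ic50_by_predictor.values())
    if not values:
        raise ValueError("no predictor IC50 values supplied")
    median = float(statistics.median(values))
    if len(values) == 1:
        return median, values[0] < cutoff
    n_binder_calls = sum(1 for v in values if v < cutoff)
    return median, n_binder_calls >= min_support


def read_mutation_tsv(path) -> List[ProteinMutation]:
    """Mutation table: columns protein_id, position, kind, ref_aa, alt_aa."""
    mutations: List[ProteinMutation] = []
    with Path(path).open("rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_id", "position", "kind", "ref_aa", "alt_aa"]
        if [h.strip().lower() for h in header] != expected:
            raise ValueError(f"{path}: expected columns {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields")
            mutations.append(
                ProteinMutation(
                    protein_id=fields[0],
                    position=int(fields[1]),
                    kind=fields[2],
                    ref_aa=fields[3].upper(),
                    alt_aa=fields[4].upper(),
                )
            )
    return mutations


def write_mutation_tsv(path, mutations: Sequence[ProteinMutation]) -> None:
    with Path(path).open("wt", encoding="utf-8") as fh:
        fh.write("protein_id\tposition\tkind\tref_aa\talt_aa\n")
        for m in mutations:
            fh.write(f"{m.protein_id}\t{m.position}\t{m.kind}\t{m.ref_aa}\t{m.alt_aa}\n")


def read_protein_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_candidates_tsv(path, candidates: Sequence[NeoantigenCandidate]) -> None:
    def fmt(x: Optional[float]) -> str:
        return f"{x:.4g}" if x is not None else "NA"

    with Path(path).open("wt", encoding="utf-8") as fh:
        fh.write(
            "protein_id\tallele\tmutant_peptide\twild_type_peptide\tlength\t"
            "start\tic50_mut_nM\tic50_wt_nM\tpass\treason\n"
        )
        for c in candidates:
            wt = c.wild_type_peptide if c.wild_type_peptide is not None else "NA"
            fh.write(
                f"{c.protein_id}\t{c.allele}\t{c.mutant_peptide}\t{wt}\t"
                f"{c.length}\t{c.start}\t{fmt(c.ic50_mut)}\t{fmt(c.ic50_wt)}\t"
                f"{str(c.passed).lower()}\t{c.reason}\n"
            )
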