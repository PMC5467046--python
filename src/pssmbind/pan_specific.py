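"""Pan-allele prediction for uncharacterized HLA alleles.

An uncharacterized allele (one without a trained PSSM) is predicted through
its sequence neighbors: each characterized allele is paired with the query
allele and weighted by the raw local-alignment score of their protein
sequences (BLOSUM62, affine gaps, protein-BLAST-style defaults). The
pan-specific IC50 is the weight-normalized mean of the neighbors'
allele-specific IC50s.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .core_scoring import (
    Ic50Transform,
    PredictionResult,
    classify_affinity,
    score_peptide,
    score_to_ic50,
    validate_peptide,
)
from .exceptions import AlphabetError, UncoverableAlleleError
from .model_store import PssmLibrary, normalize_allele

_PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def alignment_weight(
    seq_a: str,
    seq_b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Raw optimal local-alignment score of two protein sequences.

    Symmetric in its arguments; a pair with no positively-scoring residue
    match scores 0 (the empty local alignment).
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq.upper()) - _PROTEIN_ALPHABET
        if bad:
            raise AlphabetError(
                f"{name} contains non-canonical residues {sorted(bad)}"
            )
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    return float(max(0.0, aligner.score(seq_a.upper(), seq_b.upper())))


@dataclass(frozen=True)
class SimilarityPair:
    """One (uncharacterized, characterized) allele pair with its weight."""

    uncharacterized: str
    characterized: str
    weight: float
    source: str  # "alignment" | "nearest_distance"

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight!r}")
        if self.source not in ("alignment", "nearest_distance"):
            raise ValueError(f"unknown source {self.source!r}")


class SimilarityLibrary:
    """Deduplicated similarity pairs; alignment entries win over nearest_distance."""

    def __init__(self, pairs: Iterable[SimilarityPair] = ()) -> None:
        self._pairs: Dict[Tuple[str, str], SimilarityPair] = {}
        self.uncoverable: List[str] = []
        for pair in pairs:
            self.add(pair)

    def add(self, pair: SimilarityPair) -> None:
        key = (pair.uncharacterized, pair.characterized)
        existing = self._pairs.get(key)
        if existing is not None and existing.source == "alignment":
            return
        self._pairs[key] = pair

    def pairs_for(self, allele: str) -> List[SimilarityPair]:
        norm = normalize_allele(allele)
        return sorted(
            (p for p in self._pairs.values() if p.uncharacterized == norm),
            key=lambda p: (-p.weight, p.characterized),
        )

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        return iter(sorted(self._pairs.values(),
                           key=lambda p: (p.uncharacterized, p.characterized)))


def read_hla_fasta(path) -> Dict[str, str]:
    """Read a multi-FASTA of HLA protein sequences keyed by normalized allele name."""
    sequences: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        sequences[normalize_allele(record.id)] = str(record.seq).upper()
    return sequences


def build_similarity_library(
    hla_sequences: Mapping[str, str],
    characterized: Set[str],
    nearest_pairs: Optional[Sequence[Tuple[str, str]]] = None,
    constant_weight: Optional[float] = None,
    uncharacterized: Optional[Set[str]] = None,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> SimilarityLibrary:
    """Build the similarity-weight library.

    Every uncharacterized allele with a sequence is paired against every
    characterized allele that also has a sequence, weighted by
    :func:`alignment_weight`. ``nearest_pairs`` rows (an externally supplied
    neighbor list) are added with ``constant_weight`` (default: the median
    alignment weight, keeping the two sources on one scale). Alleles with
    neither a sequence nor a nearest-pairs entry are recorded in
    ``lib.uncoverable`` rather than raising.
    """
    if not characterized:
        raise ValueError("characterized allele set is empty")
    sequences = {normalize_allele(a): s for a, s in hla_sequences.items()}
    characterized_norm = {normalize_allele(a) for a in characterized}
    if uncharacterized is None:
        uncharacterized_norm = set(sequences) - characterized_norm
    else:
        uncharacterized_norm = {normalize_allele(a) for a in uncharacterized}

    lib = SimilarityLibrary()
    align_weights: List[float] = []
    covered: Set[str] = set()
    for unchar in sorted(uncharacterized_norm):
        if unchar not in sequences:
            continue
        for char in sorted(characterized_norm):
            if char not in sequences:
                continue
            w = alignment_weight(
                sequences[unchar], sequences[char], matrix_name, gap_open, gap_extend
            )
            if w <= 0:
                continue
            lib.add(SimilarityPair(unchar, char, w, "alignment"))
            align_weights.append(w)
            covered.add(unchar)

    nearest_pairs = nearest_pairs or []
    if nearest_pairs:
        if constant_weight is None:
            if not align_weights:
                raise ValueError(
                    "constant_weight required when no alignment weights exist"
                )
            constant_weight = float(statistics.median(align_weights))
        for unchar_raw, char_raw in nearest_pairs:
            unchar = normalize_allele(unchar_raw)
            char = normalize_allele(char_raw)
            lib.add(SimilarityPair(unchar, char, constant_weight, "nearest_distance"))
            covered.add(unchar)

    lib.uncoverable = sorted(uncharacterized_norm - covered)
    return lib


def write_similarity_tsv(lib: SimilarityLibrary, path) -> None:
    with Path(path).open("wt", encoding="utf-8") as fh:
        fh.write("uncharacterized_allele\tcharacterized_allele\tweight\tsource\n")
        for pair in lib:
            fh.write(
                f"{pair.uncharacterized}\t{pair.characterized}\t"
                f"{pair.weight:.6g}\t{pair.source}\n"
            )


def read_similarity_tsv(path) -> SimilarityLibrary:
    lib = SimilarityLibrary()
    with Path(path).open("rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["uncharacterized_allele", "characterized_allele", "weight", "source"]
        if header != expected:
            raise ValueError(f"{path}: expected columns {expected}, got {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            unchar, char, weight, source = line.split("\t")
            lib.add(SimilarityPair(
                normalize_allele(unchar), normalize_allele(char),
                float(weight), source,
            ))
    return lib


def predict_pan(
    peptide: str,
    allele: str,
    lib: PssmLibrary,
    sim: SimilarityLibrary,
    transform: Ic50Transform = Ic50Transform(),
    top_k: Optional[int] = None,
) -> PredictionResult:
    """Weighted-mean pan-specific IC50 for an allele without its own PSSM.

    Usable neighbors are similarity pairs whose characterized allele holds a
    PSSM of the peptide's length; with ``top_k`` set, only the top-k by
    weight contribute. The predicted IC50 is ``sum(w_i * ic50_i) /
    sum(w_i)`` over the usable neighbors and classified with the same
    500/50 nM rules as allele-specific predictions.
    """
    seq = validate_peptide(peptide)
    norm = normalize_allele(allele)
    if (norm, len(seq)) in lib:
        raise ValueError(
            f"{norm} has a PSSM of length {len(seq)}; use the allele-specific path"
        )
    usable = [
        (p, lib.get(p.characterized, len(seq)))
        for p in sim.pairs_for(norm)
        if lib.get(p.characterized, len(seq)) is not None
    ]
    if not usable:
        raise UncoverableAlleleError(
            f"no usable similarity neighbor with a length-{len(seq)} PSSM "
            f"for allele {norm}"
        )
    if top_k is not None:
        usable = usable[: max(1, top_k)]

    ic50s = [score_to_ic50(score_peptide(pssm, seq), transform)
             for _, pssm in usable]
    if len(usable) == 1:  # exact passthrough, no FP round trip
        ic50_un = ic50s[0]
    else:
        weights = [pair.weight for pair, _ in usable]
        ic50_un = float(
            math.fsum(w * x for w, x in zip(weights, ic50s)) / math.fsum(weights)
        )
    return PredictionResult(
        peptide=seq,
        allele=norm,
        mode="pan-specific",
        ic50=ic50_un,
        affinity_class=classify_affinity(ic50_un, transform),
        n_neighbors=len(usable),
    )
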