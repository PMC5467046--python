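"""Seeded synthetic data generators.

These produce planted-motif binder sets, background peptides, and families
of near-identical synthetic HLA protein sequences, so that training,
evaluation, pan-allele prediction and the neoantigen pipeline can all be
exercised without any external database.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core_scoring import AMINO_ACIDS, BackgroundFrequencies

#: Typical HLA class I heavy-chain length used for synthetic sequences.
DEFAULT_HLA_LENGTH = 365


@dataclass(frozen=True)
class MotifProfile:
    """Per-position residue probabilities with designated anchor columns."""

    length: int
    columns: np.ndarray  # (length, 20), rows sum to 1
    anchor_positions: FrozenSet[int]  # 1-based column indices

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        if cols.shape != (self.length, 20):
            raise ValueError(f"columns must be ({self.length}, 20), got {cols.shape}")
        if np.any(np.abs(cols.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("every column must sum to 1")
        object.__setattr__(self, "columns", cols)


def make_motif_profile(
    length: int,
    anchors: Sequence[int],
    dominance: float,
    background: BackgroundFrequencies,
    seed: int = 0,
) -> MotifProfile:
    """A motif with ``dominance`` mass on one seeded-random residue at each
    anchor column (remainder proportional to background) and plain
    background everywhere else."""
    bg = background.as_array()
    if any(not (1 <= a <= length) for a in anchors):
        raise ValueError(f"anchor positions must lie in 1..{length}")
    if dominance <= bg.max():
        raise ValueError(
            f"dominance {dominance} would not exceed the background maximum "
            f"{bg.max():.4f}; the anchor would be ineffective"
        )
    rng = np.random.default_rng(seed)
    columns = np.tile(bg, (length, 1))
    for pos in anchors:
        residue = int(rng.integers(20))
        col = np.zeros(20)
        others = bg.copy()
        others[residue] = 0.0
        if dominance < 1.0:
            col = (1.0 - dominance) * others / others.sum()
        col[residue] = dominance
        columns[pos - 1] = col
    return MotifProfile(length=length, columns=columns,
                        anchor_positions=frozenset(anchors))


def sample_binders(profile: MotifProfile, n: int, seed: int = 0) -> List[str]:
    """Draw ``n`` peptides by independent per-column sampling from the profile."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    draws = np.empty((n, profile.length), dtype=np.intp)
    for i in range(profile.length):
        draws[:, i] = rng.choice(20, size=n, p=profile.columns[i])
    return ["".join(letters[row]) for row in draws]


def perturb_profile(
    profile: MotifProfile, scale: float, seed: int
) -> MotifProfile:
    """A nearby motif: each column mixed with a seeded Dirichlet draw at
    weight ``scale`` (used to simulate related alleles with similar motifs)."""
    if not (0 <= scale < 1):
        raise ValueError("scale must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cols = profile.columns.copy()
    for i in range(profile.length):
        noise = rng.dirichlet(np.ones(20))
        cols[i] = (1 - scale) * cols[i] + scale * noise
    cols /= cols.sum(axis=1, keepdims=True)
    return MotifProfile(profile.length, cols, profile.anchor_positions)


def make_synthetic_hla_set(
    n_characterized: int,
    n_uncharacterized: int,
    mutation_rate: float,
    seed: int = 0,
    length: int = DEFAULT_HLA_LENGTH,
    uncharacterized_copy_of: Optional[str] = None,
) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Families of near-identical synthetic HLA protein sequences.

    One seeded ancestor sequence is mutated independently per allele at
    ``mutation_rate`` substitutions per site. Characterized alleles are
    named ``HLA-A*xx:01``, uncharacterized ones ``HLA-B*xx:01``. With
    ``uncharacterized_copy_of`` set to a characterized name, the first
    uncharacterized allele is an exact sequence copy of that allele.
    """
    if not (0.0 <= mutation_rate <= 0.5):
        raise ValueError("mutation_rate must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    ancestor = rng.integers(20, size=length)

    def mutate() -> str:
        seq = ancestor.copy()
        if mutation_rate > 0:
            hits = np.flatnonzero(rng.random(length) < mutation_rate)
            for i in hits:
                seq[i] = (seq[i] + rng.integers(1, 20)) % 20
        return "".join(letters[seq])

    characterized = {
        f"HLA-A*{i + 1:02d}:01": mutate() for i in range(n_characterized)
    }
    uncharacterized = {
        f"HLA-B*{i + 1:02d}:01": mutate() for i in range(n_uncharacterized)
    }
    if uncharacterized_copy_of is not None and uncharacterized:
        first = next(iter(uncharacterized))
        uncharacterized[first] = characterized[uncharacterized_copy_of]
    return characterized, uncharacterized


def write_hla_fasta(path, sequences: Dict[str, str]) -> None:
    with Path(path).open("wt", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def make_training_rows(
    allele: str, peptides: Iterable[str], label: str = "binder"
) -> List[Tuple[str, str, str]]:
    return [(allele, p, label) for p in peptides]


def write_training_tsv(path, rows: Sequence[Tuple[str, str, str]]) -> None:
    """Write (allele, peptide, label) rows in the training-table dialect."""
    with Path(path).open("wt", encoding="utf-8") as fh:
        fh.write("allele\tpeptide\tlabel\n")
        for allele, peptide, label in rows:
            fh.write(f"{allele}\t{peptide}\t{label}\n")
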