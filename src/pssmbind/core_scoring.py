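"""Position-specific scoring matrices: construction, peptide scoring, and the
score-to-IC50 transform with qualitative binder classification.

A PSSM here is a 20 x N log-odds matrix for one (allele, peptide-length)
pair. Each cell is ``log((F_ai + omega) / BG_a)`` where ``F_ai`` is the
observed proportion of residue ``a`` at column ``i`` over a binder set,
``BG_a`` a background amino-acid frequency, and ``omega`` a pseudocount that
keeps unobserved residues finite. A peptide's binding score is the mean of
its per-position matrix lookups; the score maps onto the nanomolar IC50
scale through an exponential transform bounded by configurable score
extremes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .exceptions import AlphabetError, LengthError

#: The 20 canonical amino acids in fixed alphabetical order. All matrices and
#: frequency vectors in this package use this row order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Ambiguity / non-standard one-letter codes rejected from all peptide input.
ABNORMAL_RESIDUES = frozenset("BJOUXZ")

MIN_PEPTIDE_LENGTH = 8
MAX_PEPTIDE_LENGTH = 25

_BACKGROUND_RESOURCE = "background_frequencies.tsv"


def validate_peptide(
    sequence: str,
    *,
    min_length: int = MIN_PEPTIDE_LENGTH,
    max_length: int = MAX_PEPTIDE_LENGTH,
) -> str:
    """Validate and uppercase a peptide sequence.

    Raises
    ------
    AlphabetError
        If any character is not one of the 20 canonical amino acids.
    LengthError
        If the length falls outside ``[min_length, max_length]``.
    """
    if not isinstance(sequence, str) or not sequence:
        raise AlphabetError(f"peptide must be a non-empty string, got {sequence!r}")
    seq = sequence.upper()
    for ch in seq:
        if ch not in AA_INDEX:
            raise AlphabetError(
                f"non-canonical residue {ch!r} in peptide {sequence!r}"
            )
    if not (min_length <= len(seq) <= max_length):
        raise LengthError(
            f"peptide length {len(seq)} outside supported range "
            f"[{min_length}, {max_length}]: {sequence!r}"
        )
    return seq


def peptide_indices(sequence: str) -> np.ndarray:
    """Map a canonical peptide to its row indices in ``AMINO_ACIDS`` order."""
    try:
        return np.fromiter((AA_INDEX[c] for c in sequence), dtype=np.intp,
                           count=len(sequence))
    except KeyError as exc:
        raise AlphabetError(f"non-canonical residue {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Background proportions of the 20 amino acids.

    ``freq`` maps each canonical one-letter code to a proportion; the 20
    entries must be positive and sum to 1 within 1e-9.
    """

    freq: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.freq)
        if keys != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - keys)
            extra = sorted(keys - set(AMINO_ACIDS))
            raise ValueError(
                f"background must cover exactly the 20 canonical residues "
                f"(missing {missing}, unexpected {extra})"
            )
        vals = np.array([self.freq[a] for a in AMINO_ACIDS], dtype=float)
        if not np.all(vals > 0):
            raise ValueError("every background frequency must be > 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"background frequencies must sum to 1 (got {vals.sum()!r})"
            )

    def as_array(self) -> np.ndarray:
        """Frequencies as a length-20 vector in ``AMINO_ACIDS`` order."""
        return np.array([self.freq[a] for a in AMINO_ACIDS], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "BackgroundFrequencies":
        arr = np.asarray(values, dtype=float)
        if arr.shape != (20,):
            raise ValueError(f"expected 20 values, got shape {arr.shape}")
        return cls(dict(zip(AMINO_ACIDS, arr.tolist())))

    @classmethod
    def from_file(cls, path) -> "BackgroundFrequencies":
        """Read a two-column TSV of ``<residue>\\t<proportion>`` (20 rows)."""
        freq: dict[str, float] = {}
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected '<residue>\\t<freq>', got {line!r}"
                    )
                aa, value = parts[0].strip().upper(), float(parts[1])
                if aa in freq:
                    raise ValueError(f"{path}:{lineno}: duplicate residue {aa!r}")
                freq[aa] = value
        return cls(freq)

    @classmethod
    def default(cls) -> "BackgroundFrequencies":
        """The bundled UniProtKB/Swiss-Prot-derived composition table."""
        ref = resources.files("pssmbind.data").joinpath(_BACKGROUND_RESOURCE)
        with resources.as_file(ref) as path:
            return cls.from_file(path)


@dataclass(frozen=True)
class OmegaPolicy:
    """How the pseudocount ``omega`` is chosen for each PSSM cell.

    ``fixed`` mode uses ``fixed_value`` everywhere (the reproducible
    default). ``dirichlet`` mode draws, for every matrix column, one
    symmetric Dirichlet vector over the 20 residues (concentration
    ``concentration``) and uses each component as that cell's omega; the
    draw is fully determined by ``seed``.
    """

    mode: str = "fixed"
    fixed_value: float = 0.02
    concentration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "dirichlet"):
            raise ValueError(f"unknown omega mode {self.mode!r}")
        if self.fixed_value <= 0:
            raise ValueError("fixed_value must be > 0 (omega = 0 gives log 0)")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")

    def omega_matrix(self, length: int) -> np.ndarray:
        """Per-cell omegas as a (20, length) array, all values in (0, 1]."""
        if self.mode == "fixed":
            return np.full((20, length), self.fixed_value, dtype=float)
        rng = np.random.default_rng(self.seed)
        cols = [rng.dirichlet(np.full(20, self.concentration)) for _ in range(length)]
        omega = np.column_stack(cols)
        # guard against numerically-zero Dirichlet components
        return np.clip(omega, 1e-12, 1.0)

    def tag(self) -> str:
        value = self.fixed_value if self.mode == "fixed" else self.concentration
        return f"{self.mode}:{value:g}:{self.seed}"

    @classmethod
    def from_tag(cls, tag: str) -> "OmegaPolicy":
        mode, value, seed = tag.split(":")
        if mode == "fixed":
            return cls(mode=mode, fixed_value=float(value), seed=int(seed))
        return cls(mode=mode, concentration=float(value), seed=int(seed))


@dataclass(frozen=True)
class PSSM:
    """A trained 20 x N log-odds matrix for one (allele, length) pair."""

    allele: str
    length: int
    matrix: np.ndarray
    log_base: float = math.e
    n_training_binders: int = 0
    omega_policy: OmegaPolicy = field(default_factory=OmegaPolicy)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape != (20, self.length):
            raise ValueError(
                f"matrix must be 20 x {self.length}, got {mat.shape}"
            )
        if not np.all(np.isfinite(mat)):
            raise ValueError("PSSM contains non-finite entries")
        if self.n_training_binders < 1:
            raise ValueError("n_training_binders must be >= 1")
        if self.log_base <= 0 or self.log_base == 1.0:
            raise ValueError("log_base must be positive and != 1")
        object.__setattr__(self, "matrix", mat)


def build_pssm(
    binders: Iterable[str],
    background: BackgroundFrequencies,
    omega_policy: Optional[OmegaPolicy] = None,
    log_base: float = math.e,
    allele: str = "",
) -> PSSM:
    """Construct a PSSM from a set of equal-length binder peptides.

    Each cell is ``log_base((F_ai + omega_ai) / BG_a)`` where ``F_ai`` is
    the proportion of binders carrying residue ``a`` at column ``i``
    (duplicates counted with multiplicity). Construction is deterministic:
    fixed-omega mode is a pure function of its inputs and dirichlet mode is
    reproducible given the policy seed.
    """
    omega_policy = omega_policy or OmegaPolicy()
    peptides = [validate_peptide(p) for p in binders]
    if not peptides:
        raise ValueError("binder list is empty")
    length = len(peptides[0])
    for p in peptides:
        if len(p) != length:
            raise LengthError(
                f"mixed peptide lengths in binder set: {length} vs {len(p)} ({p!r})"
            )

    counts = np.zeros((20, length), dtype=float)
    for p in peptides:
        counts[peptide_indices(p), np.arange(length)] += 1.0
    freq = counts / len(peptides)
    colsums = freq.sum(axis=0)
    assert np.all(np.abs(colsums - 1.0) < 1e-9), "column frequencies must sum to 1"

    omega = omega_policy.omega_matrix(length)
    bg = background.as_array()[:, np.newaxis]
    matrix = np.log((freq + omega) / bg) / math.log(log_base)
    return PSSM(
        allele=allele,
        length=length,
        matrix=matrix,
        log_base=log_base,
        n_training_binders=len(peptides),
        omega_policy=omega_policy,
    )


def score_peptide(pssm: PSSM, peptide: str) -> float:
    """Length-normalized sum of the PSSM lookups for ``peptide``.

    Higher scores mean higher predicted affinity; a positive score is the
    qualitative motif-match flag (reported separately from the IC50-based
    binder class).
    """
    seq = validate_peptide(peptide)
    if len(seq) != pssm.length:
        raise LengthError(
            f"peptide length {len(seq)} does not match PSSM length "
            f"{pssm.length} (allele {pssm.allele or '<unnamed>'})"
        )
    idx = peptide_indices(seq)
    return float(pssm.matrix[idx, np.arange(pssm.length)].sum() / pssm.length)


@dataclass(frozen=True)
class Ic50Transform:
    """Parameters of the exponential score-to-IC50 mapping.

    ``score_to_ic50`` maps a binding score ``s`` (clamped into
    ``[score_min, score_max]``) to ``base ** ((score_max - s) /
    (score_max - score_min))`` nanomolar, so the IC50 range is
    ``[1, base]`` and higher scores give lower (tighter) IC50.
    """

    base: float = 50000.0
    score_max: float = 0.8
    score_min: float = -0.8
    binder_cutoff: float = 500.0
    strong_cutoff: float = 50.0

    def __post_init__(self) -> None:
        if self.score_max <= self.score_min:
            raise ValueError("score_max must exceed score_min")
        if self.base <= 1:
            raise ValueError("base must be > 1")
        if not (0 < self.strong_cutoff < self.binder_cutoff):
            raise ValueError("require 0 < strong_cutoff < binder_cutoff")


def score_to_ic50(binding_score: float, transform: Ic50Transform = Ic50Transform()) -> float:
    """Convert a binding score to a predicted IC50 in nM (monotone decreasing)."""
    s = min(max(binding_score, transform.score_min), transform.score_max)
    exponent = (transform.score_max - s) / (transform.score_max - transform.score_min)
    return float(transform.base ** exponent)


def ic50_to_score(ic50: float, transform: Ic50Transform = Ic50Transform()) -> float:
    """Analytic inverse of :func:`score_to_ic50` on the interior of its range."""
    if ic50 <= 0:
        raise ValueError(f"ic50 must be positive, got {ic50!r}")
    span = transform.score_max - transform.score_min
    return transform.score_max - span * math.log(ic50) / math.log(transform.base)


def classify_affinity(ic50: float, transform: Ic50Transform = Ic50Transform()) -> str:
    """Qualitative class from IC50: strict < 50 nM strong_binder, < 500 nM binder."""
    if ic50 <= 0:
        raise ValueError(f"ic50 must be positive, got {ic50!r}")
    if ic50 < transform.strong_cutoff:
        return "strong_binder"
    if ic50 < transform.binder_cutoff:
        return "binder"
    return "nonbinder"


@dataclass(frozen=True)
class PredictionResult:
    """One peptide-allele prediction, from either prediction mode."""

    peptide: str
    allele: str
    mode: str  # "allele-specific" | "pan-specific"
    ic50: float
    affinity_class: str
    binding_score: Optional[float] = None  # allele-specific only
    score_positive: Optional[bool] = None  # motif-match flag (score > 0)
    n_neighbors: Optional[int] = None  # pan-specific only


def predict_allele_specific(
    pssm: PSSM, peptide: str, transform: Ic50Transform = Ic50Transform()
) -> PredictionResult:
    """Score a peptide against one trained PSSM and package the result."""
    score = score_peptide(pssm, peptide)
    ic50 = score_to_ic50(score, transform)
    return PredictionResult(
        peptide=validate_peptide(peptide),
        allele=pssm.allele,
        mode="allele-specific",
        ic50=ic50,
        affinity_class=classify_affinity(ic50, transform),
        binding_score=score,
        score_positive=score > 0,
    )
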