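"""PSSM library management: allele-name normalization, plain-text PSSM
serialization, and directory-backed model stores keyed by (allele, length)."""

from __future__ import annotations

import logging
import math
import re
import warnings
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Set, Tuple

import numpy as np

from .core_scoring import AMINO_ACIDS, OmegaPolicy, PSSM
from .exceptions import AlleleFormatError, PssmParseError

logger = logging.getLogger(__name__)

_CLASS_I_LOCI = frozenset("ABCEFG")

_ALLELE_RE = re.compile(r"(?:HLA-?)?([A-Z])\s*\*?\s*([0-9:]+)")


def normalize_allele(raw: str) -> str:
    """Normalize an HLA class I allele name to ``HLA-<locus>*<gg>:<pp>``.

    Accepts the common spellings (``A*0201``, ``HLA-A*0201``,
    ``HLA-A02:01``, ``HLA-A*02:01:03``); fields past the second are
    truncated with a logged notice. Unrecognizable input raises rather
    than guessing.
    """
    if not isinstance(raw, str):
        raise AlleleFormatError(f"allele name must be a string, got {raw!r}")
    m = _ALLELE_RE.fullmatch(raw.strip().upper())
    if m is None:
        raise AlleleFormatError(f"unrecognized HLA allele name: {raw!r}")
    locus, digits = m.group(1), m.group(2)
    if locus not in _CLASS_I_LOCI:
        raise AlleleFormatError(
            f"unrecognized HLA class I locus {locus!r} in {raw!r}"
        )
    if ":" in digits:
        fields = [f for f in digits.split(":") if f]
        if len(fields) < 2:
            raise AlleleFormatError(f"incomplete allele fields in {raw!r}")
    else:
        if len(digits) != 4:
            raise AlleleFormatError(
                f"cannot split {digits!r} into two-digit fields in {raw!r}"
            )
        fields = [digits[:2], digits[2:]]
    if len(fields) > 2:
        logger.info("truncating allele %r to two-field resolution", raw)
        fields = fields[:2]
    group, protein = (f.zfill(2) for f in fields)
    return f"HLA-{locus}*{group}:{protein}"


def _pssm_filename(allele: str, length: int) -> str:
    return f"{allele.replace('*', '_')}.{length}.pssm"


def write_pssm(pssm: PSSM, path) -> None:
    """Write one PSSM in the plain-text exchange format (6 significant digits)."""
    path = Path(path)
    with path.open("wt", encoding="utf-8") as fh:
        fh.write(f"#allele={pssm.allele}\n")
        fh.write(f"#length={pssm.length}\n")
        fh.write(f"#log_base={pssm.log_base!r}\n")
        fh.write(f"#omega={pssm.omega_policy.tag()}\n")
        fh.write(f"#n_binders={pssm.n_training_binders}\n")
        for row, aa in enumerate(AMINO_ACIDS):
            vals = "\t".join(f"{v:.6g}" for v in pssm.matrix[row])
            fh.write(f"{aa}\t{vals}\n")


def read_pssm(path) -> PSSM:
    """Parse a PSSM file; malformed content raises :class:`PssmParseError`."""
    path = Path(path)
    headers: Dict[str, str] = {}
    rows: Dict[str, List[float]] = {}
    with path.open("rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise PssmParseError(f"{path}:{lineno}: malformed header {line!r}")
                key, _, value = line[1:].partition("=")
                headers[key] = value
                continue
            parts = line.split("\t")
            aa = parts[0]
            if aa not in AMINO_ACIDS:
                raise PssmParseError(
                    f"{path}:{lineno}: unexpected row label {aa!r}"
                )
            try:
                rows[aa] = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise PssmParseError(f"{path}:{lineno}: {exc}") from exc

    for key in ("allele", "length", "log_base", "omega", "n_binders"):
        if key not in headers:
            raise PssmParseError(f"{path}: missing required header #{key}=")
    length = int(headers["length"])
    if set(rows) != set(AMINO_ACIDS):
        raise PssmParseError(
            f"{path}: expected 20 amino-acid rows, found {len(rows)}"
        )
    matrix = np.empty((20, length), dtype=float)
    for i, aa in enumerate(AMINO_ACIDS):
        if len(rows[aa]) != length:
            raise PssmParseError(
                f"{path}: row {aa!r} has {len(rows[aa])} values, expected {length}"
            )
        matrix[i] = rows[aa]
    log_base = float(headers["log_base"])
    if log_base <= 0:
        log_base = math.e
    return PSSM(
        allele=headers["allele"],
        length=length,
        matrix=matrix,
        log_base=log_base,
        n_training_binders=int(headers["n_binders"]),
        omega_policy=OmegaPolicy.from_tag(headers["omega"]),
    )


class PssmLibrary:
    """A collection of PSSMs keyed by normalized (allele, length)."""

    def __init__(self) -> None:
        self._entries: Dict[Tuple[str, int], PSSM] = {}

    def add(self, pssm: PSSM) -> None:
        key = (normalize_allele(pssm.allele), pssm.length)
        if key in self._entries:
            raise ValueError(f"duplicate library key {key}")
        self._entries[key] = pssm

    def get(self, allele: str, length: int) -> Optional[PSSM]:
        """Look up a PSSM; the query allele is normalized first."""
        return self._entries.get((normalize_allele(allele), length))

    def __contains__(self, key: Tuple[str, int]) -> bool:
        allele, length = key
        return (normalize_allele(allele), length) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[PSSM]:
        return iter(self._entries.values())

    def keys(self) -> List[Tuple[str, int]]:
        return sorted(self._entries)

    @property
    def characterized_alleles(self) -> Set[str]:
        return {allele for allele, _ in self._entries}

    def lengths_for(self, allele: str) -> List[int]:
        norm = normalize_allele(allele)
        return sorted(l for a, l in self._entries if a == norm)


def save_library(lib: PssmLibrary, directory) -> List[Dict[str, object]]:
    """Write one ``.pssm`` file per entry plus a ``manifest.tsv``; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: List[Dict[str, object]] = []
    for allele, length in lib.keys():
        pssm = lib.get(allele, length)
        fname = _pssm_filename(allele, length)
        write_pssm(pssm, directory / fname)
        manifest.append(
            {
                "allele": allele,
                "length": length,
                "n_binders": pssm.n_training_binders,
                "file": fname,
            }
        )
    with (directory / "manifest.tsv").open("wt", encoding="utf-8") as fh:
        fh.write("allele\tlength\tn_binders\tfile\n")
        for row in manifest:
            fh.write(f"{row['allele']}\t{row['length']}\t{row['n_binders']}\t{row['file']}\n")
    return manifest


def load_library(directory) -> PssmLibrary:
    """Load every ``.pssm`` file under ``directory``. Empty directories warn."""
    directory = Path(directory)
    lib = PssmLibrary()
    files = sorted(directory.glob("*.pssm"))
    if not files:
        warnings.warn(f"no .pssm files found in {directory}", stacklevel=2)
        return lib
    for path in files:
        lib.add(read_pssm(path))
    return lib
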