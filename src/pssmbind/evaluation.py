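"""Cross-validated evaluation: fold assignment, random-nonbinder
construction, and the AUC / accuracy / sensitivity / specificity metrics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .core_scoring import (
    AMINO_ACIDS,
    BackgroundFrequencies,
    Ic50Transform,
    OmegaPolicy,
    build_pssm,
    score_peptide,
    score_to_ic50,
)
from .exceptions import RejectionBudgetError, UndefinedMetricError


@dataclass(frozen=True)
class FoldAssignment:
    """A seeded random partition of ``n`` items into ``k`` folds (ids 1..k)."""

    assignment: np.ndarray
    k: int
    seed: int

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


def kfold_split(n: int, k: int, seed: int) -> FoldAssignment:
    """Uniform random fold assignment; fold sizes differ by at most one."""
    if not (2 <= k <= n):
        raise ValueError(f"require 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    assignment[perm] = np.arange(n) % k + 1
    return FoldAssignment(assignment=assignment, k=k, seed=seed)


def generate_nonbinders(
    n: int,
    length: int,
    background: BackgroundFrequencies,
    screen: Optional[Callable[[str], float]] = None,
    seed: int = 0,
    cutoff: float = 500.0,
    max_attempts_factor: int = 50,
) -> List[str]:
    """Random peptides drawn i.i.d. per position from background frequencies.

    With ``screen`` (a peptide -> IC50 callable) supplied, candidates
    predicted as binders (IC50 < ``cutoff``) are rejected and resampled; the
    total attempt budget is ``max_attempts_factor * n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    probs = background.as_array()
    letters = np.array(list(AMINO_ACIDS))
    out: List[str] = []
    attempts = 0
    budget = max_attempts_factor * n
    while len(out) < n:
        batch = min(n - len(out), budget - attempts)
        if batch <= 0:
            rate = len(out) / max(attempts, 1)
            raise RejectionBudgetError(
                f"nonbinder rejection budget exhausted after {attempts} attempts "
                f"(acceptance rate {rate:.3f})"
            )
        draws = rng.choice(20, size=(batch, length), p=probs)
        for row in draws:
            attempts += 1
            pep = "".join(letters[row])
            if screen is not None and screen(pep) < cutoff:
                continue
            out.append(pep)
            if len(out) == n:
                break
    return out


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney pair-counting AUC: the fraction of (positive, negative)
    pairs where the positive scores strictly higher, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined: {n_pos} positives, {n_neg} negatives"
        )
    ranks = rankdata(scores)  # midranks implement the tie = 1/2 convention
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN at an IC50 cutoff, with the derived rate metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float = 500.0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")


def confusion_metrics(
    predictions: Sequence, truths: Sequence[int], cutoff: float = 500.0
) -> ConfusionCounts:
    """Confusion counts with a positive call iff predicted IC50 < cutoff.

    ``predictions`` may be IC50 values or objects with an ``ic50`` attribute.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    ic50s = np.array(
        [p.ic50 if hasattr(p, "ic50") else float(p) for p in predictions],
        dtype=float,
    )
    truths = np.asarray(truths, dtype=int)
    if ic50s.shape != truths.shape:
        raise ValueError(
            f"got {len(ic50s)} predictions but {len(truths)} labels"
        )
    called = ic50s < cutoff
    pos = truths == 1
    return ConfusionCounts(
        tp=int(np.sum(called & pos)),
        fp=int(np.sum(called & ~pos)),
        tn=int(np.sum(~called & ~pos)),
        fn=int(np.sum(~called & pos)),
        cutoff=cutoff,
    )


@dataclass(frozen=True)
class GroupEval:
    allele: str
    length: int
    n_binders: int
    n_nonbinders: int
    auc: float
    acc: float
    sensitivity: float
    specificity: float


@dataclass
class EvalSummary:
    """Per-(allele, length) cross-validation metrics plus macro-averages."""

    rows: List[GroupEval] = field(default_factory=list)
    skipped: List[Tuple[Tuple[str, int], str]] = field(default_factory=list)

    @property
    def macro_auc(self) -> float:
        return float(np.mean([r.auc for r in self.rows])) if self.rows else float("nan")

    @property
    def macro_acc(self) -> float:
        return float(np.mean([r.acc for r in self.rows])) if self.rows else float("nan")

    def write_tsv(self, path) -> None:
        with Path(path).open("wt", encoding="utf-8") as fh:
            fh.write(
                "allele\tlength\tn_binders\tn_nonbinders\tauc\tacc\t"
                "sensitivity\tspecificity\n"
            )
            for r in self.rows:
                fh.write(
                    f"{r.allele}\t{r.length}\t{r.n_binders}\t{r.n_nonbinders}\t"
                    f"{r.auc:.4f}\t{r.acc:.4f}\t{r.sensitivity:.4f}\t"
                    f"{r.specificity:.4f}\n"
                )


def cross_validate(
    groups: Mapping[Tuple[str, int], List[str]],
    background: BackgroundFrequencies,
    k: int = 10,
    seed: int = 0,
    omega_policy: Optional[OmegaPolicy] = None,
    transform: Ic50Transform = Ic50Transform(),
    nonbinders: Optional[Mapping[Tuple[str, int], List[str]]] = None,
    min_binders: int = 12,
    log_base: float = math.e,
    per_fold: bool = False,
) -> EvalSummary:
    """Seeded k-fold cross-validation over per-(allele, length) binder groups.

    For each group, binders are partitioned into ``k`` folds; each fold's
    PSSM is trained on the other folds and scores the held-out binders plus
    an equal-count (within one) nonbinder set — freshly generated from
    background frequencies by default, or the matching ``nonbinders`` group
    split alongside the binders when provided. Fold predictions are pooled
    per group before computing AUC (on binding scores) and the confusion
    metrics at the transform's binder cutoff; ``per_fold=True`` averages
    per-fold AUCs instead of pooling. Groups with fewer than
    ``max(min_binders, k)`` binders are skipped with a report entry.
    """
    omega_policy = omega_policy or OmegaPolicy()
    summary = EvalSummary()
    seed_seq = np.random.SeedSequence(seed)

    for key in sorted(groups):
        allele, length = key
        binders = list(groups[key])
        group_seed_seq, = seed_seq.spawn(1)
        group_seeds = group_seed_seq.generate_state(2 * k + 2)
        n = len(binders)
        if n < min_binders:
            summary.skipped.append((key, f"only {n} binders (< {min_binders})"))
            continue
        if n < k:
            summary.skipped.append((key, f"only {n} binders (< k={k})"))
            continue

        folds = kfold_split(n, k, int(group_seeds[0]))
        provided_neg = list(nonbinders[key]) if nonbinders and key in nonbinders else None
        neg_folds = None
        if provided_neg is not None and len(provided_neg) >= k:
            neg_folds = kfold_split(len(provided_neg), k, int(group_seeds[1]))

        pooled_scores: List[float] = []
        pooled_ic50: List[float] = []
        pooled_labels: List[int] = []
        fold_aucs: List[float] = []
        n_neg_total = 0
        for fold in range(1, k + 1):
            held = folds.indices(fold)
            train = [binders[i] for i in range(n) if folds.assignment[i] != fold]
            pssm = build_pssm(
                train, background, omega_policy=omega_policy,
                log_base=log_base, allele=allele,
            )
            if neg_folds is not None:
                negatives = [provided_neg[i] for i in neg_folds.indices(fold)]
            elif provided_neg is not None:
                negatives = provided_neg
            else:
                negatives = generate_nonbinders(
                    max(1, len(held)), length, background,
                    seed=int(group_seeds[1 + fold]),
                )
            n_neg_total += len(negatives)

            fold_scores: List[float] = []
            fold_labels: List[int] = []
            for i in held:
                s = score_peptide(pssm, binders[i])
                fold_scores.append(s)
                fold_labels.append(1)
            for pep in negatives:
                fold_scores.append(score_peptide(pssm, pep))
                fold_labels.append(0)
            pooled_scores.extend(fold_scores)
            pooled_labels.extend(fold_labels)
            pooled_ic50.extend(score_to_ic50(s, transform) for s in fold_scores)
            if per_fold:
                fold_aucs.append(auc(fold_scores, fold_labels))

        group_auc = float(np.mean(fold_aucs)) if per_fold else auc(pooled_scores, pooled_labels)
        counts = confusion_metrics(pooled_ic50, pooled_labels, transform.binder_cutoff)
        summary.rows.append(
            GroupEval(
                allele=allele,
                length=length,
                n_binders=n,
                n_nonbinders=n_neg_total,
                auc=group_auc,
                acc=counts.acc,
                sensitivity=counts.sensitivity,
                specificity=counts.specificity,
            )
        )
    return summary
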