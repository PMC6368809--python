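"""Prediction scoring (recall / precision / F-value) and the k-fold
cross-validation protocol.

Per protein *p*: ``C_p`` correctly predicted functions, ``N_p`` actual
functions, ``M_p`` predicted functions; recall = C_p/N_p, precision =
C_p/M_p, F = 2PR/(P+R).  Averages are macro (per-protein); proteins with
an undefined metric (N_p = 0 or M_p = 0) are skipped with a warning.
Correctness is exact category-id match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pipeline import AnnotationTable, PredictionRecord

__all__ = [
    "EvalCounts",
    "EvalSummary",
    "FoldAssignment",
    "MetricError",
    "recall",
    "precision",
    "f_value",
    "evaluate",
    "kfold_split",
]

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    """A metric denominator is zero for a protein."""


def recall(c_p: int, n_p: int) -> float:
    if n_p <= 0:
        raise MetricError("N_p must be positive for recall")
    return c_p / n_p


def precision(c_p: int, m_p: int) -> float:
    if m_p <= 0:
        raise MetricError("M_p must be positive for precision")
    return c_p / m_p


def f_value(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if p == 0.0 and r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


@dataclass(frozen=True)
class EvalCounts:
    protein: str
    c_p: int
    n_p: int
    m_p: int

    def __post_init__(self) -> None:
        if min(self.c_p, self.n_p, self.m_p) < 0:
            raise MetricError("counts must be non-negative")
        if self.c_p > min(self.n_p, self.m_p):
            raise MetricError("C_p cannot exceed min(N_p, M_p)")


@dataclass(frozen=True)
class EvalSummary:
    counts: tuple[EvalCounts, ...]
    macro_recall: float
    macro_precision: float
    macro_f: float
    skipped: tuple[str, ...]


def evaluate(
    predictions: Iterable[PredictionRecord],
    gold: AnnotationTable,
) -> EvalSummary:
    """Score predictions against a gold annotation table.

    Duplicate (protein, category) rows are deduplicated first; the
    result is invariant to prediction order.  Every predicted protein
    must be present in the gold table.
    """
    predicted: dict[str, set[str]] = {}
    for r in predictions:
        if r.protein not in gold:
            raise MetricError(f"protein {r.protein!r} missing from gold annotations")
        predicted.setdefault(r.protein, set()).add(r.category)

    counts: list[EvalCounts] = []
    skipped: list[str] = []
    recalls, precisions, fs = [], [], []
    for protein in sorted(predicted):
        gold_set = gold.categories(protein)
        pred_set = predicted[protein]
        c = len(pred_set & gold_set)
        n, m = len(gold_set), len(pred_set)
        counts.append(EvalCounts(protein, c, n, m))
        if n == 0 or m == 0:
            logger.warning("protein %s skipped: undefined metric (N=%d, M=%d)", protein, n, m)
            skipped.append(protein)
            continue
        r_, p_ = recall(c, n), precision(c, m)
        recalls.append(r_)
        precisions.append(p_)
        fs.append(f_value(p_, r_))

    def mean(xs: list[float]) -> float:
        return float(np.mean(xs)) if xs else float("nan")

    return EvalSummary(
        counts=tuple(counts),
        macro_recall=mean(recalls),
        macro_precision=mean(precisions),
        macro_f=mean(fs),
        skipped=tuple(skipped),
    )


@dataclass(frozen=True)
class FoldAssignment:
    """Seeded round-robin fold assignment; fold sizes differ by <= 1."""

    folds: Mapping[str, int]
    k: int
    seed: int

    def test_proteins(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.folds.items() if f == fold)

    def train_proteins(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.folds.items() if f != fold)


def kfold_split(protein_ids: Sequence[str], k: int, seed: int) -> FoldAssignment:
    """Shuffle proteins with a seeded RNG, then deal them round-robin
    into *k* folds (reproducible for a fixed seed)."""
    proteins = sorted(set(protein_ids))
    if k < 2:
        raise MetricError("k must be >= 2")
    if k > len(proteins):
        raise MetricError("k exceeds the number of proteins")
    rng = np.random.default_rng(seed)
    order = [proteins[i] for i in rng.permutation(len(proteins))]
    return FoldAssignment(
        folds={p: i % k for i, p in enumerate(order)}, k=k, seed=seed
    )
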