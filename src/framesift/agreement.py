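"""Consensus ground truth from two raters and inter-rater reliability.

A frame is *valid* when both raters assigned it a label; it enters the
consensus only when those labels agree. Disagreements are discarded rather
than adjudicated. Reliability is summarized by raw percent agreement and
Cohen's kappa over the valid frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .labels import CANONICAL_EMOTIONS, EmotionLabel
from .models import RaterAnnotation


@dataclass(frozen=True)
class ConsensusCounts:
    total: int  # distinct frames seen by either rater
    valid: int  # frames both raters labeled
    agreed: int  # valid frames with identical labels


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square rater-vs-rater count grid (rows = rater 1, columns = rater 2)."""

    labels: tuple[EmotionLabel, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.labels)
        if counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))


def _pair_table(
    annotations: Sequence[RaterAnnotation], raters: tuple[str, str]
) -> dict[str, list[Optional[EmotionLabel]]]:
    r1, r2 = raters
    present = {a.rater_id for a in annotations}
    for r in raters:
        if r not in present:
            raise ValueError(f"rater {r!r} does not appear in the annotations")
    table: dict[str, list[Optional[EmotionLabel]]] = {}
    for a in annotations:
        if a.rater_id not in raters:
            continue
        slot = table.setdefault(a.frame_id, [None, None])
        slot[0 if a.rater_id == r1 else 1] = a.label
    return table


def consensus_labels(
    annotations: Sequence[RaterAnnotation], raters: tuple[str, str]
) -> tuple[dict[str, EmotionLabel], ConsensusCounts]:
    """Consensus label per frame, plus total/valid/agreed frame counts.

    A frame enters the consensus map iff both raters labeled it and their
    labels are equal.
    """
    table = _pair_table(annotations, raters)
    consensus: dict[str, EmotionLabel] = {}
    valid = agreed = 0
    for frame_id, (l1, l2) in table.items():
        if l1 is None or l2 is None:
            continue
        valid += 1
        if l1 == l2:
            agreed += 1
            consensus[frame_id] = l1
    return consensus, ConsensusCounts(total=len(table), valid=valid, agreed=agreed)


def confusion_matrix(
    annotations: Sequence[RaterAnnotation],
    raters: tuple[str, str],
    labels: tuple[EmotionLabel, ...] = CANONICAL_EMOTIONS,
) -> ConfusionMatrix:
    """Rater-vs-rater confusion matrix over valid frames only."""
    table = _pair_table(annotations, raters)
    index = {label: i for i, label in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    n_valid = 0
    for l1, l2 in table.values():
        if l1 is None or l2 is None:
            continue
        counts[index[l1], index[l2]] += 1
        n_valid += 1
    if n_valid == 0:
        raise ValueError("no valid frames: every frame lacks a label from a rater")
    return ConfusionMatrix(labels=tuple(labels), counts=counts)


def percent_agreement(matrix: ConfusionMatrix) -> float:
    """Raw agreement: 100 x trace / total, over valid frames."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * matrix.trace / matrix.total


def cohens_kappa(matrix: ConfusionMatrix) -> float:
    """Chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement rate; p_e the agreement expected by
    chance from the raters' marginal label frequencies. When both raters
    used a single identical label (p_e = 1), kappa is 1 by convention.
    """
    total = matrix.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = matrix.trace / total
    row = matrix.counts.sum(axis=1) / total
    col = matrix.counts.sum(axis=0) / total
    p_e = float(np.dot(row, col))
    if abs(1.0 - p_e) < 1e-12:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def reliability_report(
    annotations: Sequence[RaterAnnotation], raters: tuple[str, str]
) -> dict[str, float]:
    """Summary of the rater pair: counts plus agreement and kappa."""
    _, counts = consensus_labels(annotations, raters)
    matrix = confusion_matrix(annotations, raters)
    return {
        "total": counts.total,
        "valid": counts.valid,
        "agreed": counts.agreed,
        "percent_agreement": percent_agreement(matrix),
        "kappa": cohens_kappa(matrix),
    }


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Display rounding with half-up ties, e.g. 91.15 -> 91.2."""
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
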