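"""Scoring predicted base pairs against a reference structure.

The negative universe is every unordered position pair, C(L,2) in total,
with no diagonal exclusion; base pairs are roughly fifty times rarer than
non-pairs in this universe, so the headline summary is the Matthews
correlation coefficient together with the precision-recall curve rather
than an ROC curve.  Noncanonical reference pairs count as positives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .structures import ReferenceStructure

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    predicted_pairs: Iterable[tuple[int, int]],
    reference: ReferenceStructure,
    length: int | None = None,
) -> ConfusionCounts:
    """Exact set comparison over the universe of all C(L,2) position pairs."""
    L = length or reference.length
    predicted = {(min(i, j), max(i, j)) for i, j in predicted_pairs}
    for i, j in predicted:
        if not (1 <= i < j <= L):
            raise ValueError(f"predicted pair ({i},{j}) outside [1,{L}]")
    ref = reference.pairs
    universe = L * (L - 1) // 2
    tp = len(predicted & ref)
    fp = len(predicted - ref)
    fn = len(ref - predicted)
    tn = universe - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a marginal is empty."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        logger.debug("MCC denominator zero; returning 0")
        return 0.0
    return (tp * tn - fp * fn) / denom


def sensitivity(counts: ConfusionCounts) -> float:
    """Recall: fraction of known base pairs recovered."""
    if counts.tp + counts.fn == 0:
        logger.debug("sensitivity denominator zero; returning 0")
        return 0.0
    return counts.tp / (counts.tp + counts.fn)


def precision(counts: ConfusionCounts) -> float:
    """Fraction of predicted base pairs that are correct."""
    if counts.tp + counts.fp == 0:
        logger.debug("precision denominator zero; returning 0")
        return 0.0
    return counts.tp / (counts.tp + counts.fp)


def _ranked(position_scores: Mapping[tuple[int, int], float]):
    keys = [(min(i, j), max(i, j)) for i, j in position_scores]
    scores = np.array([position_scores[k] for k in position_scores], dtype=float)
    order = np.argsort(-scores, kind="stable")
    return [keys[k] for k in order], scores[order]


def pr_curve(
    position_scores: Mapping[tuple[int, int], float],
    reference: ReferenceStructure,
    length: int | None = None,
) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall curve over ranked position pairs and its AUC.

    Pairs are ranked by score descending with ties grouped at a single
    threshold; pairs never scored rank below every scored pair (they are
    predicted unpaired at every cutoff).  The area is the trapezoid over the
    curve, anchored by extending the first threshold's precision back to
    recall zero.
    """
    L = length or reference.length
    if not reference.pairs:
        raise ValueError("reference structure has no pairs")
    if not position_scores:
        raise ValueError("no scored position pairs")
    keys, scores = _ranked(position_scores)
    ref = reference.pairs
    n_pos = len(ref)
    curve: list[tuple[float, float]] = []
    tp = fp = 0
    k = 0
    n = len(keys)
    while k < n:
        threshold = scores[k]
        while k < n and scores[k] == threshold:  # tie group
            if keys[k] in ref:
                tp += 1
            else:
                fp += 1
            k += 1
        curve.append((tp / n_pos, tp / (tp + fp)))
    recalls = np.array([r for r, _ in curve])
    precisions = np.array([p for _, p in curve])
    # anchor: constant precision from recall 0 to the first threshold
    r = np.concatenate([[0.0], recalls])
    p = np.concatenate([[precisions[0]], precisions])
    auc = float(np.trapezoid(p, r))
    return curve, auc


def max_mcc_threshold(
    position_scores: Mapping[tuple[int, int], float],
    reference: ReferenceStructure,
    length: int | None = None,
) -> tuple[float, ConfusionCounts]:
    """Cutoff (pair predicted iff score >= cutoff) maximizing MCC.

    All distinct score values are scanned; ties on MCC resolve to the
    larger cutoff, i.e. the sparser prediction.
    """
    L = length or reference.length
    if not reference.pairs:
        raise ValueError("reference structure has no pairs")
    if not position_scores:
        raise ValueError("no scored position pairs")
    keys, scores = _ranked(position_scores)
    ref = reference.pairs
    universe = L * (L - 1) // 2
    n_pos = len(ref)
    best: tuple[float, float, ConfusionCounts] | None = None
    tp = fp = 0
    k = 0
    n = len(keys)
    while k < n:
        threshold = scores[k]
        while k < n and scores[k] == threshold:
            if keys[k] in ref:
                tp += 1
            else:
                fp += 1
            k += 1
        fn = n_pos - tp
        tn = universe - tp - fp - fn
        counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        m = mcc(counts)
        if best is None or m > best[0]:
            best = (m, threshold, counts)
    assert best is not None
    return best[1], best[2]
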