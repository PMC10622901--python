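"""Conditional-folding classification from pLDDT and its performance metrics.

A disordered segment is called *conditionally folded* (CF) when it
contains a long enough run of consecutive residues with confident pLDDT
(default: >= 10 residues at pLDDT >= 70).  At the residue level, pLDDT
itself is scored as a binary classifier of conditional folding with a
ROC analysis: positives are residues of IDRs known to fold conditionally,
negatives residues of IDRs that stay disordered, and a residue is
predicted positive when its pLDDT is at or above a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .tracks import DisorderSegment, ResidueTrack, filter_segments_high_plddt

__all__ = [
    "ROCCurve",
    "OperatingPoint",
    "CorrelationResult",
    "roc_curve",
    "best_operating_point",
    "classify_idrs",
    "upper_bound_fraction",
    "pearson_correlation",
]


@dataclass
class ROCCurve:
    """ROC points at every unique score threshold, descending.

    ``thresholds[k]`` classifies positive where score >= thresholds[k];
    ``tpr``/``fpr`` include the leading (0, 0) point (threshold +inf) and
    end at (1, 1).  ``auc`` is the trapezoidal integral of TPR over FPR,
    equivalent to the tie-adjusted rank statistic U/(n_pos * n_neg).
    """

    thresholds: np.ndarray  # descending unique scores, len = n points - 1
    tpr: np.ndarray         # len = n points (leading 0.0)
    fpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve of a "score >= threshold -> positive" classifier.

    ``labels`` are booleans (True = positive class).  Tied scores are
    grouped into a single ROC point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group ties: indices where a threshold ends
    distinct = np.flatnonzero(np.diff(s) != 0)
    boundaries = np.append(distinct, len(s) - 1)
    tp = np.cumsum(y)[boundaries]
    fp = np.cumsum(~y)[boundaries]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        thresholds=s[boundaries],
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        n_positive=n_pos,
        n_negative=n_neg,
    )


@dataclass
class OperatingPoint:
    threshold: float
    tpr: float
    fpr: float
    ratio: float  # TPR/FPR; inf when degenerate
    degenerate: bool = False


def best_operating_point(roc: ROCCurve) -> OperatingPoint:
    """Threshold maximizing the TPR-to-FPR ratio.

    Points with FPR = 0 are excluded (infinite ratio); ties break toward
    higher TPR, then higher threshold.  A perfectly separating classifier
    (full TPR already reached at FPR = 0) has no meaningful interior
    optimum: the result is flagged degenerate and reports the smallest
    threshold reaching TPR = 1 at FPR = 0.
    """
    tpr, fpr = roc.tpr[1:], roc.fpr[1:]  # drop the (0, 0) origin
    thresholds = roc.thresholds
    valid = fpr > 0
    perfect = (fpr == 0) & (tpr >= 1.0)
    if perfect.any() or not valid.any():
        at_zero = fpr == 0
        best_tpr = tpr[at_zero].max()
        candidates = np.flatnonzero(at_zero & (tpr == best_tpr))
        k = int(candidates[-1])  # smallest threshold attaining that TPR
        return OperatingPoint(
            threshold=float(thresholds[k]), tpr=float(tpr[k]), fpr=0.0,
            ratio=float("inf"), degenerate=True,
        )
    best = None
    for k in np.flatnonzero(valid):
        cand = (tpr[k] / fpr[k], tpr[k], thresholds[k])
        if best is None or cand > best:
            best = cand
            best_k = k
    return OperatingPoint(
        threshold=float(thresholds[best_k]),
        tpr=float(tpr[best_k]),
        fpr=float(fpr[best_k]),
        ratio=float(best[0]),
    )


def classify_idrs(
    segments,
    tracks,
    plddt_threshold: float = 70.0,
    min_consecutive: int = 10,
) -> dict[DisorderSegment, bool]:
    """Per-segment conditional-folding call.

    A segment is CF iff it survives the confident-run filter
    (>= ``min_consecutive`` consecutive residues at pLDDT >=
    ``plddt_threshold``).
    """
    segments = list(segments)
    kept = set(
        id(s) for s in filter_segments_high_plddt(
            segments, tracks, min_plddt=plddt_threshold,
            min_consecutive=min_consecutive,
        )
    )
    return {seg: (id(seg) in kept) for seg in segments}


def upper_bound_fraction(observed_fraction: float, sensitivity: float) -> float:
    """Upper bound on the true CF fraction: observed / sensitivity, capped at 1.

    With ~15% of disordered residues confidently predicted and the
    classifier recovering ~60% of known conditional folders, the bound is
    0.15 / 0.60 = 25%.
    """
    if not 0.0 <= observed_fraction <= 1.0:
        raise ValueError("observed_fraction must lie in [0, 1]")
    if sensitivity <= 0.0 or sensitivity > 1.0:
        raise ValueError("sensitivity must lie in (0, 1]")
    quotient = observed_fraction / sensitivity
    if quotient > 1.0:
        warnings.warn(
            f"upper bound {quotient:.3f} exceeds 1; capping at 1.0", stacklevel=2
        )
        return 1.0
    return quotient


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    n: int


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with its square."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r = float(pearsonr(x, y).statistic)
    return CorrelationResult(r=r, r_squared=r * r, n=int(x.size))
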