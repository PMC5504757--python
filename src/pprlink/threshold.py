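"""Decision-threshold estimation from the full field-state space.

The tabulated combinations cover only patterns that occurred among
candidate pairs; threshold estimation needs the full 3^n space, so unseen
combinations are added with a count of zero and their recall_j / fpr_j
computed under the adopted parameter set. Each combination gets a weight
(sum of per-field agreement / disagreement weights, zero for missing) and
the estimated True Matches (from the final EM iteration) and False
Matches (total comparison space minus True Matches) are apportioned into
per-combination TP_j = TrueMatches * recall_j and FP_j = FalseMatches *
fpr_j. Sweeping a threshold over the combination weights then yields a
predicted precision / recall / F-measure curve, and the threshold with
the highest predicted F-measure is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import (
    FieldStateTable,
    ParameterSet,
    WeightSet,
    combination_recall_fpr,
)

__all__ = [
    "FullStateSpace",
    "QualityCurve",
    "CapacityError",
    "enumerate_full_space",
    "combination_weight",
    "estimate_match_totals",
    "quality_curve",
    "select_threshold",
    "estimate_threshold",
]

MAX_FIELDS = 12  # 3^12 ≈ 531k combinations; beyond that the sweep is refused


class CapacityError(ValueError):
    """Field count too large to enumerate the full 3^n state space."""


@dataclass
class FullStateSpace:
    """All 3^n field-state combinations with counts, rates and weights."""

    fields: list[str]
    states: np.ndarray  # uint8 (3^n, n)
    counts: np.ndarray  # int64 (3^n,)
    recall: np.ndarray  # float (3^n,), sums to 1
    fpr: np.ndarray  # float (3^n,), sums to 1
    weights: np.ndarray  # float (3^n,)


@dataclass
class QualityCurve:
    """Predicted linkage quality at every candidate threshold."""

    points: pd.DataFrame  # threshold, est_tp, est_fp, precision, recall, fmeasure
    chosen_threshold: float
    true_matches: float
    false_matches: float
    total_comparisons: int


def combination_weight(states: np.ndarray, weights: WeightSet) -> np.ndarray:
    """Weight of each combination: agree → w_agree, disagree → w_disagree,
    missing → 0, summed over fields."""
    states = np.atleast_2d(states)
    fields = weights.fields
    total = np.zeros(len(states))
    for k, f in enumerate(fields):
        lut = np.array([weights.agree[f], weights.disagree[f], 0.0])
        total += lut[states[:, k]]
    return total


def enumerate_full_space(
    table: FieldStateTable, params: ParameterSet, weights: WeightSet
) -> FullStateSpace:
    """Expand the observed table to the full 3^n combination space.

    Observed counts are carried over; unseen combinations enter with a
    count of zero but non-zero recall_j / fpr_j under ``params``.
    """
    n = len(table.fields)
    if n > MAX_FIELDS:
        raise CapacityError(f"{n} fields would enumerate 3^{n} combinations")
    size = 3**n
    radix = 3 ** np.arange(n, dtype=np.int64)
    codes = np.arange(size, dtype=np.int64)
    states = ((codes[:, None] // radix) % 3).astype(np.uint8)

    counts = np.zeros(size, dtype=np.int64)
    observed_codes = table.states.astype(np.int64) @ radix
    counts[observed_codes] = table.counts

    recall, fpr = combination_recall_fpr(states, params)
    w = combination_weight(states, weights)
    return FullStateSpace(list(table.fields), states, counts, recall, fpr, w)


def estimate_match_totals(
    table: FieldStateTable, pj: np.ndarray, n_records: int
) -> tuple[float, float, int]:
    """Estimated True Matches, False Matches and the comparison space.

    True Matches is the posterior match mass of the final EM iteration;
    False Matches is the full de-duplication comparison space
    N (N - 1) / 2 minus the True Matches.
    """
    if n_records < 2:
        raise ValueError("need at least two records")
    true_matches = float(pj @ table.counts)
    total = n_records * (n_records - 1) // 2
    if true_matches > total:
        raise ValueError("estimated true matches exceed the comparison space")
    return true_matches, float(total) - true_matches, total


def quality_curve(
    space: FullStateSpace,
    totals: tuple[float, float, int],
    thresholds: np.ndarray | None = None,
    integer_thresholds: bool = False,
) -> QualityCurve:
    """Predicted precision / recall / F-measure at each threshold.

    TP_j = TrueMatches * recall_j and FP_j = FalseMatches * fpr_j are
    accumulated over combinations whose weight is at or above each
    threshold. Candidate thresholds default to the distinct combination
    weights; ``integer_thresholds`` sweeps whole numbers instead. An
    empty selection (threshold above every weight) is reported as
    precision 1, recall 0, F-measure 0.
    """
    true_matches, false_matches, total = totals
    if true_matches <= 0:
        raise ValueError("estimated true matches is zero; curve undefined")

    order = np.argsort(space.weights)[::-1]
    w_sorted = space.weights[order]
    tp_cum = np.cumsum(true_matches * space.recall[order])
    fp_cum = np.cumsum(false_matches * space.fpr[order])

    if thresholds is None:
        if integer_thresholds:
            thresholds = np.arange(
                np.ceil(w_sorted[0]), np.floor(w_sorted[-1]) - 1, -1.0
            )
        else:
            thresholds = np.unique(space.weights)[::-1]
    thresholds = np.asarray(thresholds, dtype=float)

    # Number of combinations with weight >= t (w_sorted is descending).
    idx = np.searchsorted(-w_sorted, -thresholds, side="right")
    tp = np.where(idx > 0, tp_cum[idx - 1], 0.0)
    fp = np.where(idx > 0, fp_cum[idx - 1], 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 1.0)
        recall = tp / true_matches
        fmeasure = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    points = pd.DataFrame(
        {
            "threshold": thresholds,
            "est_tp": tp,
            "est_fp": fp,
            "precision": precision,
            "recall": recall,
            "fmeasure": fmeasure,
        }
    )
    curve = QualityCurve(points, float("nan"), true_matches, false_matches, total)
    curve.chosen_threshold = select_threshold(curve)
    return curve


def select_threshold(curve: QualityCurve) -> float:
    """Smallest threshold attaining the maximal predicted F-measure."""
    pts = curve.points
    if pts.empty:
        raise ValueError("empty quality curve")
    best = pts["fmeasure"].max()
    at_best = pts.loc[pts["fmeasure"] >= best - 1e-12, "threshold"]
    return float(at_best.min())


def estimate_threshold(
    table: FieldStateTable,
    params: ParameterSet,
    weights: WeightSet,
    pj: np.ndarray,
    n_records: int,
    integer_thresholds: bool = False,
) -> QualityCurve:
    """Full-space threshold estimation in one step."""
    space = enumerate_full_space(table, params, weights)
    totals = estimate_match_totals(table, pj, n_records)
    return quality_curve(space, totals, integer_thresholds=integer_thresholds)
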