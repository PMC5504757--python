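"""Linkage quality evaluation against a truth set, and dataset profiling.

The truth set maps every record to its ground-truth entity; the true-pair
set is *all* unordered same-entity pairs, so true pairs that never shared
a block count as false negatives. Quality is reported as precision,
recall and F-measure; estimate accuracy across repeated linkages is
summarised by root-mean-square error. Profiling reports, per field, the
number of distinct values, the missing percentage and the discriminating
power (Shannon entropy, base 2, of the non-missing value distribution).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import LINKAGE_FIELDS, PersonRecord

__all__ = [
    "EvaluationReport",
    "ProfileReport",
    "evaluate_linkage",
    "rmse",
    "discriminating_power",
    "profile_dataset",
    "sample_dataset",
    "actual_quality_by_threshold",
]


@dataclass
class EvaluationReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    fmeasure: float

    def to_dict(self) -> dict:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "precision": self.precision,
            "recall": self.recall,
            "fmeasure": self.fmeasure,
        }


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 1.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f


def _true_pair_total(truth: Mapping[str, str]) -> int:
    # Sum k(k-1)/2 per entity; never materialises the pair space.
    sizes = Counter(truth.values())
    return sum(k * (k - 1) // 2 for k in sizes.values())


def evaluate_linkage(
    matches: Iterable[tuple[str, str]] | pd.DataFrame,
    truth: Mapping[str, str],
) -> EvaluationReport:
    """Score declared matches against the ground-truth entity mapping."""
    if isinstance(matches, pd.DataFrame):
        matches = list(zip(matches["id_a"], matches["id_b"]))
    seen: set[tuple[str, str]] = set()
    tp = 0
    for a, b in matches:
        if a not in truth or b not in truth:
            raise ValueError(f"record id not in truth set: {a if a not in truth else b}")
        pair = (a, b) if a <= b else (b, a)
        if pair in seen:
            continue
        seen.add(pair)
        if truth[a] == truth[b]:
            tp += 1
    fp = len(seen) - tp
    fn = _true_pair_total(truth) - tp
    precision, recall, f = _prf(tp, fp, fn)
    return EvaluationReport(tp, fp, fn, precision, recall, f)


def rmse(estimated: Sequence[float], actual: Sequence[float]) -> float:
    """Root-mean-square error between two equal-length value lists."""
    est = np.asarray(estimated, dtype=float)
    act = np.asarray(actual, dtype=float)
    if est.shape != act.shape or est.size == 0:
        raise ValueError("inputs must be equal-length, non-empty")
    return float(np.sqrt(np.mean((est - act) ** 2)))


def discriminating_power(values: Iterable[str]) -> float:
    """Shannon entropy (bits) of the non-missing value distribution."""
    counts = np.asarray(
        [c for v, c in Counter(v for v in values if v != "").items()], dtype=float
    )
    if counts.size == 0:
        raise ValueError("all values missing; discriminating power undefined")
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass
class ProfileReport:
    """Per-field unique-value count, missing % and discriminating power."""

    fields: pd.DataFrame  # index: field; columns: unique_values, missing_pct, discriminating_power

    def to_dict(self) -> dict:
        return {
            f: {
                "unique_values": int(row["unique_values"]),
                "missing_pct": float(row["missing_pct"]),
                "discriminating_power": float(row["discriminating_power"]),
            }
            for f, row in self.fields.iterrows()
        }


def profile_dataset(records: Sequence[PersonRecord]) -> ProfileReport:
    rows = {}
    n = len(records)
    for f in LINKAGE_FIELDS:
        values = [rec.get(f) for rec in records]
        present = [v for v in values if v != ""]
        rows[f] = {
            "unique_values": len(set(present)),
            "missing_pct": 100.0 * (n - len(present)) / n if n else 0.0,
            "discriminating_power": (
                discriminating_power(present) if present else float("nan")
            ),
        }
    return ProfileReport(pd.DataFrame.from_dict(rows, orient="index"))


def sample_dataset(
    records: Sequence[PersonRecord], fraction: float, seed: int
) -> list[PersonRecord]:
    """Simple random sample of ⌊fraction·N⌋ records, input order kept."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n = len(records)
    size = int(np.floor(fraction * n))
    idx = np.sort(np.random.default_rng(seed).choice(n, size=size, replace=False))
    return [records[i] for i in idx]


def actual_quality_by_threshold(
    pair_ids: Sequence[tuple[str, str]],
    scores: np.ndarray,
    truth: Mapping[str, str],
) -> pd.DataFrame:
    """Actual precision / recall / F-measure at every distinct score.

    Sweeps the threshold over the observed pair scores (match rule:
    score >= threshold); recall is relative to all true pairs in the
    truth set, so blocking misses depress it. Used to find the best
    achievable quality for a given weight set.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.fromiter(
        (truth[a] == truth[b] for a, b in pair_ids), dtype=bool, count=len(scores)
    )
    order = np.argsort(scores)[::-1]
    s_sorted = scores[order]
    tp_cum = np.cumsum(labels[order])
    n_cum = np.arange(1, len(scores) + 1)

    # Last index of each distinct score run = everything with score >= t.
    last = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    total_true = _true_pair_total(truth)
    tp = tp_cum[last]
    fp = n_cum[last] - tp
    fn = total_true - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 1.0)
        recall = tp / total_true if total_true else np.zeros_like(tp, dtype=float)
        fmeasure = np.where(
            precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0
        )
    return pd.DataFrame(
        {
            "threshold": s_sorted[last],
            "true_positives": tp,
            "false_positives": fp,
            "false_negatives": fn,
            "precision": precision,
            "recall": recall,
            "fmeasure": fmeasure,
        }
    )
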