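"""Candidate-pair generation, encoded field comparison and pair scoring.

Record pairs are formed by the union of within-block pairs from each
blocking strategy. Each linkage field of a pair is compared on the
encoded values: Sørensen-Dice similarity for Bloom fields, token equality
for exact fields. Comparisons are discretised into the three states
agree / disagree / missing for parameter estimation, while scoring keeps
the continuous similarity and applies Winkler-style piecewise-linear
partial agreement weights. A pair's score is the sum of its field
weights (missing contributes zero) and pairs at or above the decision
threshold are declared matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import BloomFilter, EncodedDataset
from .records import LINKAGE_FIELDS

__all__ = [
    "AGREE",
    "DISAGREE",
    "MISSING",
    "FieldScheme",
    "PairComparisons",
    "PairComparison",
    "dice_coefficient",
    "field_state",
    "candidate_pairs",
    "compare_pairs",
    "partial_weight",
    "score_pair",
    "score_pairs",
    "run_linkage",
]

AGREE, DISAGREE, MISSING = 0, 1, 2
STATE_NAMES = ("agree", "disagree", "missing")

#: Blocks larger than this emit a warning (quadratic pair blow-up).
OVERSIZED_BLOCK = 10_000


@dataclass
class FieldScheme:
    """How fields are compared and how similarity maps to weight.

    agree_cutoff discretises Dice similarity into agree/disagree for the
    state tabulation that feeds the EM fit. partial_anchors are
    (similarity, weight-fraction) points of the Winkler-style curve used
    at scoring time: fraction 1 at similarity 1 gives the full agreement
    weight; below the lowest anchor the full disagreement weight applies.
    """

    comparators: dict[str, str] = field(
        default_factory=lambda: {
            f: ("dice" if f in ("first_name", "middle_name", "last_name",
                                "address", "suburb") else "exact")
            for f in LINKAGE_FIELDS
        }
    )
    agree_cutoff: float = 0.8
    partial_anchors: tuple[tuple[float, float], ...] = ((0.8, 0.0), (1.0, 1.0))

    def __post_init__(self):
        if not (0.0 < self.agree_cutoff <= 1.0):
            raise ValueError("agree_cutoff must lie in (0, 1]")
        sims = [a[0] for a in self.partial_anchors]
        fracs = [a[1] for a in self.partial_anchors]
        if sorted(sims) != list(sims) or sorted(fracs) != list(fracs):
            raise ValueError("partial_anchors must be monotone non-decreasing")

    @property
    def fields(self) -> list[str]:
        return [f for f in LINKAGE_FIELDS if f in self.comparators]

    def dice_fields(self) -> list[str]:
        return [f for f in self.fields if self.comparators[f] == "dice"]


def dice_coefficient(a: BloomFilter, b: BloomFilter) -> float:
    """Sørensen-Dice coefficient 2|a∧b| / (|a| + |b|) of two filters."""
    if a.length_bits != b.length_bits:
        raise ValueError("Bloom filters have different lengths")
    pa, pb = a.popcount, b.popcount
    if pa + pb == 0:
        raise ValueError("degenerate input: both filters have no set bits")
    inter = int(np.bitwise_count(a.bits & b.bits).sum())
    return 2.0 * inter / (pa + pb)


def field_state(
    encoding_a, encoding_b, comparator: str, agree_cutoff: float = 0.8
) -> tuple[int, float | None]:
    """Trinary comparison state of one field, plus the similarity when
    a Dice comparison was performed."""
    if encoding_a is None or encoding_b is None:
        return MISSING, None
    if comparator == "exact":
        return (AGREE if encoding_a == encoding_b else DISAGREE), None
    sim = dice_coefficient(encoding_a, encoding_b)
    return (AGREE if sim >= agree_cutoff else DISAGREE), sim


def candidate_pairs(ds: EncodedDataset) -> np.ndarray:
    """Union of within-block record pairs over all blocking strategies.

    Returns an (P, 2) array of record indices with i < j; each unordered
    pair appears once even when it shares several blocks.
    """
    n = len(ds)
    codes = []
    for strategy, tokens in ds.blocking.items():
        present = np.flatnonzero(tokens != "")
        if present.size == 0:
            continue
        order = present[np.argsort(tokens[present], kind="stable")]
        sorted_tokens = tokens[order]
        boundaries = np.flatnonzero(
            np.r_[True, sorted_tokens[1:] != sorted_tokens[:-1], True]
        )
        for s, e in zip(boundaries[:-1], boundaries[1:]):
            size = e - s
            if size < 2:
                continue
            if size > OVERSIZED_BLOCK:
                warnings.warn(
                    f"blocking strategy '{strategy}' has a block of {size} records"
                )
            block = np.sort(order[s:e])
            ii, jj = np.triu_indices(size, k=1)
            codes.append(block[ii].astype(np.int64) * n + block[jj])
    if not codes:
        return np.empty((0, 2), dtype=np.int64)
    uniq = np.unique(np.concatenate(codes))
    return np.column_stack([uniq // n, uniq % n])


@dataclass
class PairComparisons:
    """Vectorised comparison results for a batch of candidate pairs."""

    pairs: np.ndarray  # (P, 2) record indices
    fields: list[str]
    states: np.ndarray  # uint8 (P, n_fields), values AGREE/DISAGREE/MISSING
    similarities: np.ndarray  # float32 (P, n_fields); NaN where not a Dice field

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PairComparison:
    """Single-pair comparison detail."""

    id_a: str
    id_b: str
    states: dict[str, str]
    similarities: dict[str, float]
    score: float | None = None


def compare_pairs(
    ds: EncodedDataset,
    pairs: np.ndarray,
    scheme: FieldScheme | None = None,
    chunk: int = 200_000,
) -> PairComparisons:
    """Compare every candidate pair on every linkage field."""
    scheme = scheme or FieldScheme()
    fields = scheme.fields
    p = len(pairs)
    states = np.empty((p, len(fields)), dtype=np.uint8)
    sims = np.full((p, len(fields)), np.nan, dtype=np.float32)

    ia, ib = pairs[:, 0], pairs[:, 1]
    for k, f in enumerate(fields):
        if scheme.comparators[f] == "exact":
            ta, tb = ds.tokens[f][ia], ds.tokens[f][ib]
            miss = (ta == "") | (tb == "")
            agree = (ta == tb) & ~miss
            states[:, k] = np.where(miss, MISSING, np.where(agree, AGREE, DISAGREE))
        else:
            mat = ds.bloom[f]
            pops = np.bitwise_count(mat).sum(axis=1).astype(np.int64)
            miss_col = ds.bloom_missing[f]
            for s in range(0, p, chunk):
                e = min(s + chunk, p)
                a_idx, b_idx = ia[s:e], ib[s:e]
                inter = np.bitwise_count(mat[a_idx] & mat[b_idx]).sum(axis=1)
                denom = pops[a_idx] + pops[b_idx]
                miss = miss_col[a_idx] | miss_col[b_idx]
                with np.errstate(divide="ignore", invalid="ignore"):
                    sim = 2.0 * inter / denom
                sim = np.where(miss, np.nan, sim)
                sims[s:e, k] = sim
                states[s:e, k] = np.where(
                    miss, MISSING, np.where(sim >= scheme.agree_cutoff, AGREE, DISAGREE)
                )
    return PairComparisons(pairs, fields, states, sims)


def partial_weight(
    similarity: float | np.ndarray,
    w_agree: float,
    w_disagree: float,
    anchors: Sequence[tuple[float, float]] = ((0.8, 0.0), (1.0, 1.0)),
) -> float | np.ndarray:
    """Winkler-style partial agreement weight for a Dice similarity.

    Below the lowest anchor the full disagreement weight applies; between
    anchors the weight fraction interpolates linearly; fraction f maps to
    f * w_agree (anchor fraction 0 is a zero weight, 1 the full agreement
    weight).
    """
    xs = np.array([a[0] for a in anchors])
    fs = np.array([a[1] for a in anchors])
    sim = np.asarray(similarity, dtype=float)
    w = np.where(sim < xs[0], w_disagree, np.interp(sim, xs, fs) * w_agree)
    return float(w) if np.isscalar(similarity) else w


def score_pairs(
    comps: PairComparisons,
    weights,  # estimation.WeightSet
    scheme: FieldScheme | None = None,
) -> np.ndarray:
    """Fellegi-Sunter composite score of each compared pair.

    Exact fields contribute the agreement or disagreement weight, Dice
    fields the partial weight of their similarity, missing fields zero.
    """
    scheme = scheme or FieldScheme()
    total = np.zeros(len(comps), dtype=float)
    for k, f in enumerate(comps.fields):
        wa = weights.agree[f]
        wd = weights.disagree[f]
        st = comps.states[:, k]
        if scheme.comparators[f] == "exact":
            contrib = np.where(st == AGREE, wa, np.where(st == DISAGREE, wd, 0.0))
        else:
            sim = comps.similarities[:, k].astype(float)
            contrib = np.where(
                st == MISSING,
                0.0,
                partial_weight(np.nan_to_num(sim), wa, wd, scheme.partial_anchors),
            )
        total += contrib
    return total


def score_pair(comp: PairComparisons, index: int, weights,
               scheme: FieldScheme | None = None) -> float:
    """Score of a single compared pair (convenience over score_pairs)."""
    scores = score_pairs(
        PairComparisons(
            comp.pairs[index : index + 1],
            comp.fields,
            comp.states[index : index + 1],
            comp.similarities[index : index + 1],
        ),
        weights,
        scheme,
    )
    return float(scores[0])


def run_linkage(
    ds: EncodedDataset,
    weights,
    scheme: FieldScheme | None = None,
    threshold: float = 0.0,
    strict_gt: bool = False,
    comps: PairComparisons | None = None,
    scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Declare matches among candidate pairs at the given threshold.

    Returns a DataFrame (id_a, id_b, score) with ids lexicographically
    ordered within each pair; by default pairs scoring >= threshold match
    (``strict_gt`` switches to a strict inequality).
    """
    if comps is None:
        comps = compare_pairs(ds, candidate_pairs(ds), scheme)
    if scores is None:
        scores = score_pairs(comps, weights, scheme)
    keep = scores > threshold if strict_gt else scores >= threshold
    ids_a = ds.record_ids[comps.pairs[keep, 0]].astype(str)
    ids_b = ds.record_ids[comps.pairs[keep, 1]].astype(str)
    swap = ids_a > ids_b
    lo = np.where(swap, ids_b, ids_a)
    hi = np.where(swap, ids_a, ids_b)
    return pd.DataFrame({"id_a": lo, "id_b": hi, "score": scores[keep]})
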