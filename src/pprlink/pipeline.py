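"""End-to-end de-duplication pipeline on privacy-preserved data.

Chains the library stages: encode → block → compare → tabulate → EM fit →
frequency-based u → adopted parameters and weights → predicted quality
curve and threshold → linkage. The result object keeps every intermediate
artefact so callers can evaluate against a truth set or re-link at a
different threshold without recomputing comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import comparison, estimation, threshold as threshold_mod
from .comparison import FieldScheme, PairComparisons
from .encoding import BloomFilterParams, EncodedDataset, encode_dataset
from .estimation import FieldStateTable, ParameterSet, WeightSet
from .records import PersonRecord
from .threshold import QualityCurve


@dataclass
class LinkageResult:
    encoded: EncodedDataset
    pairs: np.ndarray
    comparisons: PairComparisons
    scores: np.ndarray
    table: FieldStateTable
    em_params: ParameterSet
    params: ParameterSet  # adopted: EM m/mm with frequency-based u/um
    weights: WeightSet
    curve: QualityCurve
    threshold: float
    matches: pd.DataFrame

    def pair_ids(self) -> list[tuple[str, str]]:
        ids = self.encoded.record_ids
        return [(str(ids[i]), str(ids[j])) for i, j in self.pairs]

    def relink(self, threshold: float, strict_gt: bool = False) -> pd.DataFrame:
        return comparison.run_linkage(
            self.encoded, self.weights, threshold=threshold, strict_gt=strict_gt,
            comps=self.comparisons, scores=self.scores,
        )


def deduplicate(
    records: list[PersonRecord],
    secret_key: bytes = b"pprlink",
    bloom_params: BloomFilterParams | None = None,
    scheme: FieldScheme | None = None,
    integer_thresholds: bool = False,
) -> LinkageResult:
    """Estimate parameters and run a de-duplication linkage in one pass."""
    scheme = scheme or FieldScheme()
    ds = encode_dataset(records, params=bloom_params, secret_key=secret_key)
    pairs = comparison.candidate_pairs(ds)
    comps = comparison.compare_pairs(ds, pairs, scheme)
    table = estimation.tabulate_states(comps)

    em_params = estimation.run_em(table)
    freq_u, freq_um = estimation.estimate_u_frequencies(ds)
    params = estimation.adopt_parameters(em_params, freq_u, freq_um)
    weights = estimation.weight_set(params)

    pj = estimation.em_expectation(table, em_params)
    curve = threshold_mod.estimate_threshold(
        table, params, weights, pj, n_records=len(ds),
        integer_thresholds=integer_thresholds,
    )
    scores = comparison.score_pairs(comps, weights, scheme)
    matches = comparison.run_linkage(
        ds, weights, scheme, threshold=curve.chosen_threshold,
        comps=comps, scores=scores,
    )
    return LinkageResult(
        ds, pairs, comps, scores, table, em_params, params, weights,
        curve, curve.chosen_threshold, matches,
    )
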