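"""Fellegi-Sunter parameter estimation with missing-value states.

Candidate-pair comparisons are tabulated into field-state combinations —
each pair contributes one pattern over {agree, disagree, missing}^n — and
an EM algorithm fits, per field, the m-probability (agreement among true
matches), u-probability (agreement among non-matches) and the missing
m-/u-probabilities m_m, u_m, together with the global match proportion p.
Because the tabulation runs on blocked pairs, the EM u estimates are
biased upwards; Jaro's frequency-based u estimate on the unblocked file
is computed separately and the adopted parameter set combines EM m/m_m
with the frequency-based u/u_m. Probabilities convert to log2 agreement
and disagreement weights for scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .comparison import AGREE, DISAGREE, MISSING, STATE_NAMES, PairComparisons
from .encoding import EncodedDataset

__all__ = [
    "FieldStateTable",
    "ParameterSet",
    "WeightSet",
    "EstimationError",
    "tabulate_states",
    "combination_recall_fpr",
    "em_expectation",
    "em_maximisation",
    "run_em",
    "log_likelihood",
    "estimate_u_frequencies",
    "weights_from_parameters",
    "adopt_parameters",
    "simulate_state_table",
]

_CLIP_LO, _CLIP_HI = 1e-6, 1.0 - 1e-6


class EstimationError(RuntimeError):
    """Estimation cannot proceed (no pairs, degenerate fit, ...)."""


@dataclass
class FieldStateTable:
    """Counts of observed field-state combinations over candidate pairs."""

    fields: list[str]
    states: np.ndarray  # uint8 (R, n_fields)
    counts: np.ndarray  # int64 (R,)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        data = {
            f: [STATE_NAMES[s] for s in self.states[:, k]]
            for k, f in enumerate(self.fields)
        }
        data["count"] = self.counts
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FieldStateTable":
        fields = [c for c in frame.columns if c != "count"]
        lut = {name: i for i, name in enumerate(STATE_NAMES)}
        states = np.array(
            [[lut[v] for v in frame[f]] for f in fields], dtype=np.uint8
        ).T.reshape(len(frame), len(fields))
        return cls(fields, states, frame["count"].to_numpy(dtype=np.int64))


def tabulate_states(comps: PairComparisons) -> FieldStateTable:
    """Aggregate pair comparisons into a field-state combination table."""
    if len(comps) == 0:
        raise EstimationError("no candidate pairs to tabulate")
    n = len(comps.fields)
    radix = 3 ** np.arange(n, dtype=np.int64)
    codes = comps.states.astype(np.int64) @ radix
    uniq, counts = np.unique(codes, return_counts=True)
    states = (uniq[:, None] // radix) % 3
    return FieldStateTable(list(comps.fields), states.astype(np.uint8), counts)


@dataclass
class ParameterSet:
    """Per-field match/non-match probabilities and the match proportion.

    For each field: m (agree | match), u (agree | non-match), mm and um
    (missing | match, missing | non-match). The three state probabilities
    of a field are [m, 1-m-mm, mm] among matches and [u, 1-u-um, um]
    among non-matches.
    """

    fields: list[str]
    m: np.ndarray
    u: np.ndarray
    mm: np.ndarray
    um: np.ndarray
    p: float
    iterations: int = 0
    converged: bool = False
    loglik_trace: list[float] = dc_field(default_factory=list)

    @classmethod
    def initial(cls, fields: list[str], m: float = 0.8, u: float = 0.1,
                mm: float = 0.1, um: float = 0.1, p: float = 0.01) -> "ParameterSet":
        n = len(fields)
        return cls(list(fields), np.full(n, m), np.full(n, u),
                   np.full(n, mm), np.full(n, um), p)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.m, self.u, self.mm, self.um, [self.p]])

    def to_dict(self) -> dict:
        per_field = {
            f: {"m": float(self.m[i]), "u": float(self.u[i]),
                "mm": float(self.mm[i]), "um": float(self.um[i])}
            for i, f in enumerate(self.fields)
        }
        return {"fields": per_field, "p": float(self.p),
                "iterations": self.iterations, "converged": self.converged}

    def save(self, path, weights: "WeightSet | None" = None) -> None:
        payload = self.to_dict()
        if weights is not None:
            for f in self.fields:
                payload["fields"][f]["w_agree"] = float(weights.agree[f])
                payload["fields"][f]["w_disagree"] = float(weights.disagree[f])
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path) -> "ParameterSet":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        fields = list(payload["fields"])
        get = lambda k: np.array([payload["fields"][f][k] for f in fields])
        return cls(fields, get("m"), get("u"), get("mm"), get("um"),
                   payload["p"], payload.get("iterations", 0),
                   payload.get("converged", False))


@dataclass
class WeightSet:
    """log2 agreement/disagreement weights per field."""

    agree: dict[str, float]
    disagree: dict[str, float]

    @property
    def fields(self) -> list[str]:
        return list(self.agree)


def combination_recall_fpr(
    states: np.ndarray, params: ParameterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-combination recall and false-positive rate under the product model.

    recall_j multiplies, over fields, m for agree, 1-m-mm for disagree and
    mm for missing; fpr_j does the same with u and um.
    """
    states = np.atleast_2d(states)
    recall = np.ones(len(states))
    fpr = np.ones(len(states))
    for k in range(states.shape[1]):
        m_probs = np.array(
            [params.m[k], 1.0 - params.m[k] - params.mm[k], params.mm[k]]
        ).clip(0.0, 1.0)
        u_probs = np.array(
            [params.u[k], 1.0 - params.u[k] - params.um[k], params.um[k]]
        ).clip(0.0, 1.0)
        st = states[:, k]
        recall *= m_probs[st]
        fpr *= u_probs[st]
    return recall, fpr


def em_expectation(table: FieldStateTable, params: ParameterSet) -> np.ndarray:
    """Posterior match probability p_j of each observed combination."""
    recall, fpr = combination_recall_fpr(table.states, params)
    num = params.p * recall
    den = num + (1.0 - params.p) * fpr
    bad = den <= 0.0
    if bad.any():
        warnings.warn("zero mixture density for some combinations; p_j set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        pj = np.where(bad, 0.0, num / np.where(bad, 1.0, den))
    return pj


def em_maximisation(table: FieldStateTable, pj: np.ndarray) -> ParameterSet:
    """Re-estimate all parameters from the posterior match probabilities.

    m is the share of posterior match mass on combinations where the field
    agrees; u the analogous share of non-match mass; mm/um use the missing
    state; p the posterior match mass over all tabulated pairs.
    """
    c = table.counts.astype(float)
    match_mass = float(pj @ c)
    nonmatch_mass = float((1.0 - pj) @ c)
    if match_mass <= 0.0 or nonmatch_mass <= 0.0:
        raise EstimationError("degenerate fit: all pairs classified one way")

    n = len(table.fields)
    m = np.empty(n)
    u = np.empty(n)
    mm = np.empty(n)
    um = np.empty(n)
    for k in range(n):
        st = table.states[:, k]
        m[k] = float(pj @ (c * (st == AGREE))) / match_mass
        u[k] = float((1.0 - pj) @ (c * (st == AGREE))) / nonmatch_mass
        mm[k] = float(pj @ (c * (st == MISSING))) / match_mass
        um[k] = float((1.0 - pj) @ (c * (st == MISSING))) / nonmatch_mass
    p = match_mass / float(c.sum())

    clip = lambda a: np.clip(a, _CLIP_LO, _CLIP_HI)
    return ParameterSet(table.fields, clip(m), clip(u), clip(mm), clip(um),
                        float(np.clip(p, _CLIP_LO, _CLIP_HI)))


def log_likelihood(table: FieldStateTable, params: ParameterSet) -> float:
    """Observed-data log-likelihood of the two-class mixture."""
    recall, fpr = combination_recall_fpr(table.states, params)
    dens = params.p * recall + (1.0 - params.p) * fpr
    dens = np.clip(dens, 1e-300, None)
    return float(table.counts @ np.log(dens))


def run_em(
    table: FieldStateTable,
    init: ParameterSet | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ParameterSet:
    """Fit the extended Fellegi-Sunter mixture by EM.

    Alternates the expectation and maximisation steps until the largest
    absolute parameter change falls below ``tol`` or ``max_iter`` is
    reached; the returned set carries the final posterior-based fit, its
    iteration count, convergence flag and the log-likelihood trace.
    """
    params = init or ParameterSet.initial(table.fields)
    trace = [log_likelihood(table, params)]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        pj = em_expectation(table, params)
        new = em_maximisation(table, pj)
        trace.append(log_likelihood(table, new))
        delta = float(np.max(np.abs(new.as_vector() - params.as_vector())))
        params = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge within {max_iter} iterations")
    params.iterations = iterations
    params.converged = converged
    params.loglik_trace = trace
    return params


def estimate_u_frequencies(ds: EncodedDataset) -> tuple[dict[str, float], dict[str, float]]:
    """Jaro's frequency-based u and missing-u estimates on unblocked data.

    For a field with value counts c_v over its N_f non-missing records,
    u = Σ c_v (c_v - 1) / (N_f (N_f - 1)) is the chance-agreement
    probability of a random pair given both values present, and
    um = 1 - N_f (N_f - 1) / (N (N - 1)) the probability that a random
    unordered pair has at least one value missing. Bloom fields use exact
    filter equality (identical plaintext gives identical filters), which
    understates near-match agreement.
    """
    n = len(ds)
    if n < 2:
        raise EstimationError("need at least two records")
    u: dict[str, float] = {}
    um: dict[str, float] = {}
    total_pairs = n * (n - 1)
    for f in ds.fields:
        if ds.field_kinds[f] == "bloom":
            miss = ds.bloom_missing[f]
            rows = ds.bloom[f][~miss]
            if len(rows):
                _, counts = np.unique(rows, axis=0, return_counts=True)
            else:
                counts = np.array([])
        else:
            tok = ds.tokens[f]
            present = tok[tok != ""]
            counts = pd.Series(present).value_counts().to_numpy()
        nf = int(counts.sum())
        um[f] = 1.0 - (nf * (nf - 1)) / total_pairs
        if nf < 2:
            warnings.warn(f"field '{f}' has < 2 observed values; u undefined")
            u[f] = float("nan")
        else:
            u[f] = float((counts * (counts - 1)).sum() / (nf * (nf - 1)))
    return u, um


def weights_from_parameters(m: float, u: float) -> tuple[float, float]:
    """log2 agreement and disagreement weights from m and u.

    Inputs are clipped away from 0 and 1 to keep the weights finite; a
    clipped (saturated) weight draws a warning.
    """
    mc = float(np.clip(m, _CLIP_LO, _CLIP_HI))
    uc = float(np.clip(u, _CLIP_LO, _CLIP_HI))
    if mc != m or uc != u:
        warnings.warn("m or u at clip boundary; weight saturated")
    return float(np.log2(mc / uc)), float(np.log2((1.0 - mc) / (1.0 - uc)))


def adopt_parameters(
    em_params: ParameterSet,
    freq_u: dict[str, float],
    freq_um: dict[str, float],
) -> ParameterSet:
    """Combine EM m/m_m with the frequency-based u/u_m.

    This is the adopted parameter set used for weights, scoring and
    threshold estimation; EM's blocked-pair u estimates are discarded as
    biased. u is capped at 1 - um so the trinary state probabilities of
    each field remain a valid distribution.
    """
    u = np.array([freq_u[f] for f in em_params.fields])
    um = np.array([freq_um[f] for f in em_params.fields])
    u = np.where(np.isnan(u), em_params.u, u)
    u = np.minimum(u, 1.0 - um)
    return ParameterSet(
        em_params.fields, em_params.m.copy(), u, em_params.mm.copy(), um,
        em_params.p, em_params.iterations, em_params.converged,
    )


def weight_set(params: ParameterSet) -> WeightSet:
    """Per-field log2 weights under a parameter set."""
    agree: dict[str, float] = {}
    disagree: dict[str, float] = {}
    for i, f in enumerate(params.fields):
        wa, wd = weights_from_parameters(float(params.m[i]), float(params.u[i]))
        agree[f] = wa
        disagree[f] = wd
    return WeightSet(agree, disagree)


def simulate_state_table(
    params: ParameterSet, n_pairs: int, rng: np.random.Generator
) -> FieldStateTable:
    """Draw a field-state table from the product mixture model.

    Independent oracle for validating the EM fitter: each pair is a match
    with probability p, and each field's state is drawn from the match or
    non-match trinary distribution accordingly.
    """
    n = len(params.fields)
    match = rng.random(n_pairs) < params.p
    states = np.empty((n_pairs, n), dtype=np.uint8)
    for k in range(n):
        m_cdf = np.cumsum([params.m[k], 1 - params.m[k] - params.mm[k], params.mm[k]])
        u_cdf = np.cumsum([params.u[k], 1 - params.u[k] - params.um[k], params.um[k]])
        r = rng.random(n_pairs)
        states[:, k] = np.where(
            match,
            np.searchsorted(m_cdf, r),
            np.searchsorted(u_cdf, r),
        ).clip(0, 2)
    radix = 3 ** np.arange(n, dtype=np.int64)
    codes = states.astype(np.int64) @ radix
    uniq, counts = np.unique(codes, return_counts=True)
    st = ((uniq[:, None] // radix) % 3).astype(np.uint8)
    return FieldStateTable(list(params.fields), st, counts)


__all__.append("weight_set")
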