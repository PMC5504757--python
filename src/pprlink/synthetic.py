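"""Synthetic person-record generation and controlled corruption.

The generator produces a "master" dataset with a known duplicate structure:
each individual (entity) appears in a configurable number of records, and
all records of one entity carry identical field values with no missing
data. Corruption then degrades a master dataset at a stated per-cell error
rate — a fraction of (record, field) values is set to missing and a further
disjoint fraction is corrupted by one of four operators (typographical
error, misspelling, truncation, replacement) — emulating the data-quality
spectrum of administrative collections while the record → entity truth is
retained for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .freqdata import default_frequency_tables
from .records import LINKAGE_FIELDS, PersonRecord

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "CorruptionConfig",
    "default_duplicate_distribution",
    "generate_master",
    "corrupt_dataset",
]


class ConfigError(ValueError):
    """Invalid generator or corruption configuration."""


CORRUPTION_OPERATORS = ("typo", "misspelling", "truncation", "replacement")

_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

# QWERTY neighbourhoods for the typo operator.
_KEYBOARD_ADJACENT = {
    "A": "QWSZ", "B": "VGHN", "C": "XDFV", "D": "SERFCX", "E": "WSDR",
    "F": "DRTGVC", "G": "FTYHBV", "H": "GYUJNB", "I": "UJKO", "J": "HUIKMN",
    "K": "JIOLM", "L": "KOP", "M": "NJK", "N": "BHJM", "O": "IKLP",
    "P": "OL", "Q": "WA", "R": "EDFT", "S": "AWEDXZ", "T": "RFGY",
    "U": "YHJI", "V": "CFGB", "W": "QASE", "X": "ZSDC", "Y": "TGHU",
    "Z": "ASX",
    "0": "19", "1": "02", "2": "13", "3": "24", "4": "35", "5": "46",
    "6": "57", "7": "68", "8": "79", "9": "80",
}

_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def default_duplicate_distribution(p: float = 0.4, k_max: int = 10) -> dict[int, float]:
    """Truncated-geometric duplicate-count distribution on 1..k_max.

    P(k) ∝ p (1-p)^(k-1); with the default p=0.4 an individual has on
    average ~2.4 records, emulating the multi-admission structure of
    hospital morbidity collections.
    """
    ks = np.arange(1, k_max + 1)
    w = p * (1.0 - p) ** (ks - 1)
    w = w / w.sum()
    return {int(k): float(v) for k, v in zip(ks, w)}


def _validate_distribution(dist: Mapping, what: str) -> None:
    if not dist:
        raise ConfigError(f"{what} is empty")
    vals = np.asarray(list(dist.values()), dtype=float)
    if (vals < 0).any():
        raise ConfigError(f"{what} has negative probabilities")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{what} probabilities sum to {vals.sum()}, not 1")


@dataclass
class GeneratorConfig:
    """Configuration of the master-dataset generator.

    n_records is a target: generation stops at the first individual whose
    records push the total to or past it, so the output size matches the
    target to within one individual's record count.
    """

    n_records: int = 10_000
    duplicate_distribution: dict[int, float] = field(
        default_factory=default_duplicate_distribution
    )
    frequency_tables: dict[str, dict[str, float]] = field(
        default_factory=default_frequency_tables
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 1:
            raise ConfigError("n_records must be positive")
        _validate_distribution(self.duplicate_distribution, "duplicate_distribution")
        if all(k < 1 for k in self.duplicate_distribution):
            raise ConfigError("duplicate_distribution has no mass on k >= 1")
        if any(k < 1 for k in self.duplicate_distribution if self.duplicate_distribution[k] > 0):
            raise ConfigError("duplicate counts must be >= 1")
        for name, table in self.frequency_tables.items():
            _validate_distribution(table, f"frequency table '{name}'")


@dataclass
class CorruptionConfig:
    """Per-cell error injection settings.

    error_rate is applied twice, independently, per (record, field) cell:
    once to select cells set to missing and once (on a disjoint set —
    missing takes precedence) to select cells degraded by an operator
    drawn from operator_mix.
    """

    error_rate: float = 0.01
    operator_mix: dict[str, float] = field(
        default_factory=lambda: {op: 0.25 for op in CORRUPTION_OPERATORS}
    )
    seed: int = 0
    frequency_tables: dict[str, dict[str, float]] | None = None

    def validate(self) -> None:
        if not (0.0 <= self.error_rate <= 0.5):
            raise ConfigError("error_rate must lie in [0, 0.5]")
        _validate_distribution(self.operator_mix, "operator_mix")
        unknown = set(self.operator_mix) - set(CORRUPTION_OPERATORS)
        if unknown:
            raise ConfigError(f"unknown corruption operators: {sorted(unknown)}")


def _choice(rng: np.random.Generator, table: Mapping[str, float], size: int) -> np.ndarray:
    values = np.asarray(list(table.keys()), dtype=object)
    probs = np.asarray(list(table.values()), dtype=float)
    return rng.choice(values, size=size, p=probs / probs.sum())


def generate_master(config: GeneratorConfig) -> tuple[list[PersonRecord], dict[str, str]]:
    """Generate an error-free master dataset with known duplicate structure.

    Returns the dataset and its record_id → entity_id truth mapping. Every
    field of every record is populated, and all records of one entity are
    exact field-level copies with distinct record ids. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tables = config.frequency_tables

    ks_vals = np.asarray(sorted(config.duplicate_distribution), dtype=np.int64)
    ks_prob = np.asarray(
        [config.duplicate_distribution[int(k)] for k in ks_vals], dtype=float
    )
    ks_prob = ks_prob / ks_prob.sum()

    # Draw duplicate counts until the running total reaches the target.
    counts = []
    total = 0
    while total < config.n_records:
        chunk = rng.choice(ks_vals, size=max(256, config.n_records // 4), p=ks_prob)
        stop = np.searchsorted(total + np.cumsum(chunk), config.n_records)
        take = chunk[: stop + 1] if stop < len(chunk) else chunk
        counts.append(take)
        total += int(take.sum())
    ks = np.concatenate(counts)
    n_entities = len(ks)

    first = _choice(rng, tables["first_name"], n_entities)
    middle = _choice(rng, tables["middle_name"], n_entities)
    last = _choice(rng, tables["last_name"], n_entities)
    sex = _choice(rng, tables["sex"], n_entities)
    year = _choice(rng, tables["dob_year"], n_entities)
    month = rng.integers(1, 13, size=n_entities)
    day = (rng.random(n_entities) * _DAYS_IN_MONTH[month - 1]).astype(int) + 1
    number = rng.integers(1, 1000, size=n_entities)
    street = _choice(rng, tables["street_name"], n_entities)
    stype = _choice(rng, tables["street_type"], n_entities)
    suburb = _choice(rng, tables["suburb"], n_entities)
    postcode = _choice(rng, tables["postcode"], n_entities)

    records: list[PersonRecord] = []
    rec_no = 0
    for e in range(n_entities):
        entity_id = f"e{e:07d}"
        base = dict(
            entity_id=entity_id,
            first_name=str(first[e]),
            middle_name=str(middle[e]),
            last_name=str(last[e]),
            sex=str(sex[e]),
            dob_year=str(year[e]),
            dob_month=str(month[e]),
            dob_day=str(day[e]),
            address=f"{number[e]} {street[e]} {stype[e]}",
            suburb=str(suburb[e]),
            postcode=str(postcode[e]),
        )
        for _ in range(int(ks[e])):
            records.append(PersonRecord(record_id=f"r{rec_no:08d}", **base))
            rec_no += 1

    truth = {rec.record_id: rec.entity_id for rec in records}
    return records, truth


# ---------------------------------------------------------------------------
# Corruption operators


def _typo(value: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(value)))
    ch = value[pos].upper()
    pool = _KEYBOARD_ADJACENT.get(ch)
    repl = pool[int(rng.integers(len(pool)))] if pool else _ALPHABET[int(rng.integers(26))]
    return value[:pos] + repl + value[pos + 1:]


def _misspelling(value: str, rng: np.random.Generator) -> str:
    kind = int(rng.integers(3)) if len(value) > 1 else int(rng.integers(2))
    pos = int(rng.integers(len(value)))
    letter = _ALPHABET[int(rng.integers(26))]
    if kind == 0:  # substitute
        return value[:pos] + letter + value[pos + 1:]
    if kind == 1:  # insert
        return value[:pos] + letter + value[pos:]
    return value[:pos] + value[pos + 1:]  # delete (len > 1 guaranteed)


def _truncation(value: str, rng: np.random.Generator) -> str:
    # Drop 1-3 trailing characters, always leaving a non-empty strict prefix.
    drop = int(rng.integers(1, min(3, len(value) - 1) + 1))
    return value[:-drop]


def _replacement(field_name: str, value: str, rng: np.random.Generator,
                 tables: Mapping[str, dict[str, float]]) -> str:
    if field_name == "address":
        number = int(rng.integers(1, 1000))
        street = str(_choice(rng, tables["street_name"], 1)[0])
        stype = str(_choice(rng, tables["street_type"], 1)[0])
        return f"{number} {street} {stype}"
    table = tables.get(field_name)
    if not table or len(table) < 2:
        return value
    for _ in range(8):
        new = str(_choice(rng, table, 1)[0])
        if new != value:
            return new
    return new


def _corrupt_numeric(value: str, rng: np.random.Generator, lo: int, hi: int) -> str:
    """Substitute one digit, keeping the value inside [lo, hi]."""
    for _ in range(8):
        pos = int(rng.integers(len(value)))
        digit = str(int(rng.integers(10)))
        cand = value[:pos] + digit + value[pos + 1:]
        if cand != value and cand.isdigit() and lo <= int(cand) <= hi:
            return cand
    # Fall back to a uniform redraw from the valid range.
    cand = int(rng.integers(lo, hi + 1))
    return str(cand if str(cand) != value else (lo if cand != lo else hi))


_NUMERIC_RANGES = {
    "dob_year": (1880, 2024),
    "dob_month": (1, 12),
    "dob_day": (1, 31),
    "postcode": (800, 9999),
}


def _corrupt_value(field_name: str, value: str, op: str, rng: np.random.Generator,
                   tables: Mapping[str, dict[str, float]]) -> str:
    if field_name == "sex":
        return {"M": "F", "F": "M"}.get(value) or _replacement(
            field_name, value, rng, tables
        )
    if field_name in _NUMERIC_RANGES and value.isdigit():
        if op == "replacement":
            lo, hi = _NUMERIC_RANGES[field_name]
            return str(int(rng.integers(lo, hi + 1)))
        lo, hi = _NUMERIC_RANGES[field_name]
        return _corrupt_numeric(value, rng, lo, hi)
    if op == "replacement":
        return _replacement(field_name, value, rng, tables)
    if op == "truncation" and len(value) < 2:
        op = "misspelling"  # a length-1 value has no strict non-empty prefix
    if op == "typo":
        return _typo(value, rng)
    if op == "truncation":
        return _truncation(value, rng)
    return _misspelling(value, rng)


def corrupt_dataset(dataset: list[PersonRecord],
                    config: CorruptionConfig) -> list[PersonRecord]:
    """Degrade a dataset at the configured per-cell error rate.

    Each (record, linkage-field) cell is independently set to missing with
    probability ``error_rate`` and, on a disjoint draw, corrupted by one
    operator with the same probability (missing takes precedence). Record
    and entity identifiers are never altered. Deterministic given
    ``config.seed``.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    config.validate()
    rng = np.random.default_rng(config.seed)
    tables = config.frequency_tables or default_frequency_tables()

    n, nf = len(dataset), len(LINKAGE_FIELDS)
    miss_mask = rng.random((n, nf)) < config.error_rate
    corr_mask = (rng.random((n, nf)) < config.error_rate) & ~miss_mask

    ops = np.asarray(list(config.operator_mix.keys()), dtype=object)
    op_p = np.asarray(list(config.operator_mix.values()), dtype=float)
    n_corr = int(corr_mask.sum())
    drawn_ops = rng.choice(ops, size=n_corr, p=op_p / op_p.sum()) if n_corr else []

    out = [rec.copy() for rec in dataset]
    op_idx = 0
    corr_cells = np.argwhere(corr_mask)
    for i, j in corr_cells:
        rec = out[i]
        name = LINKAGE_FIELDS[j]
        value = rec.get(name)
        if value:
            setattr(rec, name, _corrupt_value(name, value, str(drawn_ops[op_idx]),
                                              rng, tables))
        op_idx += 1
    for i, j in np.argwhere(miss_mask):
        setattr(out[i], LINKAGE_FIELDS[j], "")
    return out
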