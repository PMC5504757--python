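"""Plaintext person records and their delimited-text serialisation.

A dataset is a list of :class:`PersonRecord`; an empty string in any
identifying field means the value is missing. ``entity_id`` is the hidden
ground-truth individual behind a record and is only ever written to the
truth file or the synthetic master file — it never enters an encoded
(privacy-preserved) output.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Mapping

import pandas as pd

#: Identifying fields used for linkage, in canonical column order.
LINKAGE_FIELDS: tuple[str, ...] = (
    "first_name",
    "middle_name",
    "last_name",
    "sex",
    "dob_year",
    "dob_month",
    "dob_day",
    "address",
    "suburb",
    "postcode",
)

#: Full column order of a plaintext dataset file.
DATASET_COLUMNS: tuple[str, ...] = ("record_id", "entity_id") + LINKAGE_FIELDS


@dataclass
class PersonRecord:
    """One row of identifying fields plus its ground-truth entity.

    All fields are stored as text; ``""`` denotes a missing value.
    Date-of-birth components are integer-valued strings.
    """

    record_id: str
    entity_id: str
    first_name: str = ""
    middle_name: str = ""
    last_name: str = ""
    sex: str = ""
    dob_year: str = ""
    dob_month: str = ""
    dob_day: str = ""
    address: str = ""
    suburb: str = ""
    postcode: str = ""

    def get(self, field: str) -> str:
        return getattr(self, field)

    def copy(self) -> "PersonRecord":
        return PersonRecord(**{f.name: getattr(self, f.name) for f in dc_fields(self)})


def records_to_frame(records: Iterable[PersonRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame in canonical column order."""
    rows = [[rec.get(c) for c in DATASET_COLUMNS] for rec in records]
    return pd.DataFrame(rows, columns=list(DATASET_COLUMNS), dtype=str)


def frame_to_records(frame: pd.DataFrame) -> list[PersonRecord]:
    missing = set(DATASET_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"dataset is missing columns: {sorted(missing)}")
    out = []
    for row in frame[list(DATASET_COLUMNS)].itertuples(index=False):
        out.append(PersonRecord(*[("" if pd.isna(v) else str(v)) for v in row]))
    return out


def write_dataset(records: Iterable[PersonRecord], path) -> None:
    """Write a plaintext dataset as UTF-8 CSV with a header row."""
    records_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def read_dataset(path) -> list[PersonRecord]:
    """Read a plaintext dataset CSV; empty cells become missing values."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    return frame_to_records(frame)


def truth_mapping(records: Iterable[PersonRecord]) -> dict[str, str]:
    """Extract the record_id → entity_id ground-truth mapping."""
    return {rec.record_id: rec.entity_id for rec in records}


def write_truth(truth: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"record_id": list(truth.keys()), "entity_id": list(truth.values())}
    ).to_csv(path, index=False, encoding="utf-8")


def read_truth(path) -> dict[str, str]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    return dict(zip(frame["record_id"], frame["entity_id"]))
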