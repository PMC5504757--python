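"""Privacy-preserving field encodings: Bloom filters, keyed tokens, blocking.

Similarity fields (names, address, suburb) are encoded as per-field Bloom
filters: the value's character q-grams are inserted with keyed double
hashing, so two encodings can later be compared with the Sørensen-Dice
coefficient without access to plaintext. Exact-match fields (sex, date of
birth components, postcode) become keyed HMAC tokens. Blocking keys —
surname Soundex with first initial, and date of birth with sex — are also
emitted as keyed tokens so the encoded file leaks no phonetic codes. A
missing plaintext value stays missing in the encoded output; it is never
represented as an all-zero filter.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .records import LINKAGE_FIELDS, PersonRecord

__all__ = [
    "BloomFilterParams",
    "BloomFilter",
    "EncodedRecord",
    "EncodedDataset",
    "DEFAULT_FIELD_KINDS",
    "BLOOM_FIELDS",
    "TOKEN_FIELDS",
    "normalise",
    "qgram_set",
    "bloom_encode",
    "hash_token",
    "soundex",
    "make_blocking_keys",
    "encode_dataset",
    "write_encoded",
    "read_encoded",
]

#: Which comparator each linkage field is encoded for.
DEFAULT_FIELD_KINDS: dict[str, str] = {
    "first_name": "bloom",
    "middle_name": "bloom",
    "last_name": "bloom",
    "sex": "token",
    "dob_year": "token",
    "dob_month": "token",
    "dob_day": "token",
    "address": "bloom",
    "suburb": "bloom",
    "postcode": "token",
}
BLOOM_FIELDS = tuple(f for f in LINKAGE_FIELDS if DEFAULT_FIELD_KINDS[f] == "bloom")
TOKEN_FIELDS = tuple(f for f in LINKAGE_FIELDS if DEFAULT_FIELD_KINDS[f] == "token")

BLOCKING_STRATEGIES = ("name_soundex", "dob_sex")

_PUNCT_RE = re.compile(r"[^A-Z0-9 ]+")
_WS_RE = re.compile(r"\s+")


def normalise(value: str) -> str:
    """Canonical plaintext form: uppercase, punctuation stripped, single
    internal spaces; integer-valued strings lose leading zeros."""
    v = _WS_RE.sub(" ", _PUNCT_RE.sub("", value.upper())).strip()
    if v.isdigit():
        v = str(int(v))
    return v


@dataclass(frozen=True)
class BloomFilterParams:
    """Bloom filter construction settings.

    Each q-gram sets ``num_hashes`` bit positions through keyed double
    hashing: position_i = (g1 + i*g2) mod length_bits, with g1, g2 derived
    from two independent HMACs of the q-gram under ``secret_key``.
    """

    length_bits: int = 1000
    num_hashes: int = 30
    qgram_length: int = 2
    pad: bool = True
    secret_key: bytes = b""

    def __post_init__(self):
        if self.length_bits < 8:
            raise ValueError("length_bits must be >= 8")
        if self.num_hashes < 1:
            raise ValueError("num_hashes must be >= 1")
        if self.qgram_length < 1:
            raise ValueError("qgram_length must be >= 1")

    @property
    def length_bytes(self) -> int:
        return (self.length_bits + 7) // 8


@dataclass
class BloomFilter:
    """A fixed-length bit vector stored packed (big-endian bit order)."""

    bits: np.ndarray  # uint8, packed
    length_bits: int

    @property
    def popcount(self) -> int:
        return int(np.bitwise_count(self.bits).sum())

    def positions(self) -> np.ndarray:
        return np.flatnonzero(np.unpackbits(self.bits)[: self.length_bits])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BloomFilter)
            and self.length_bits == other.length_bits
            and np.array_equal(self.bits, other.bits)
        )


def qgram_set(value: str, q: int, pad: bool) -> frozenset[str]:
    """Set of character q-grams of the normalised value.

    With padding, the value is framed with q-1 sentinel characters ("_")
    on each side so leading/trailing characters contribute distinct grams.
    An empty result signals that the value must be treated as missing.
    """
    v = normalise(value)
    if not v:
        return frozenset()
    if pad:
        v = "_" * (q - 1) + v + "_" * (q - 1)
    return frozenset(v[i : i + q] for i in range(len(v) - q + 1))


@lru_cache(maxsize=200_000)
def _qgram_positions(gram: str, key: bytes, length_bits: int, num_hashes: int) -> np.ndarray:
    data = gram.encode("utf-8")
    g1 = int.from_bytes(hmac.new(key, b"g1|" + data, hashlib.sha1).digest()[:8], "big")
    g2 = int.from_bytes(hmac.new(key, b"g2|" + data, hashlib.sha1).digest()[:8], "big")
    i = np.arange(num_hashes, dtype=np.uint64)
    return ((g1 + i * g2) % np.uint64(length_bits)).astype(np.int64)


def bloom_encode(value: str, params: BloomFilterParams) -> BloomFilter | None:
    """Encode a value as a Bloom filter; ``None`` for a missing value."""
    grams = qgram_set(value, params.qgram_length, params.pad)
    if not grams:
        return None
    unpacked = np.zeros(params.length_bytes * 8, dtype=np.uint8)
    for gram in sorted(grams):
        pos = _qgram_positions(gram, params.secret_key, params.length_bits,
                               params.num_hashes)
        unpacked[pos] = 1
    return BloomFilter(bits=np.packbits(unpacked), length_bits=params.length_bits)


def hash_token(value: str, secret_key: bytes) -> str | None:
    """Keyed hash token of the normalised value; ``None`` for missing."""
    v = normalise(value)
    if not v:
        return None
    return _raw_token(v, secret_key)


def _raw_token(data: str, secret_key: bytes) -> str:
    """Keyed hash of an already-canonical string (no normalisation)."""
    return hmac.new(secret_key, b"tok|" + data.encode("utf-8"), hashlib.sha256).hexdigest()[:32]


_SOUNDEX_CODES = {
    **dict.fromkeys("BFPV", "1"),
    **dict.fromkeys("CGJKQSXZ", "2"),
    **dict.fromkeys("DT", "3"),
    "L": "4",
    **dict.fromkeys("MN", "5"),
    "R": "6",
}


def soundex(name: str) -> str | None:
    """American Soundex code (letter + 3 digits), ``None`` if no letters.

    Adjacent letters with the same code collapse, including across H/W;
    vowels (and Y) break such runs.
    """
    letters = [c for c in name.upper() if "A" <= c <= "Z"]
    if not letters:
        return None
    code = letters[0]
    prev = _SOUNDEX_CODES.get(letters[0], "")
    for c in letters[1:]:
        d = _SOUNDEX_CODES.get(c, "")
        if d and d != prev:
            code += d
            if len(code) == 4:
                break
        if c not in "HW":
            prev = d
    return (code + "000")[:4]


def make_blocking_keys(record: PersonRecord, secret_key: bytes) -> set[tuple[str, str]]:
    """Keyed blocking tokens for a record.

    Strategy ``name_soundex`` hashes surname Soundex + first-name initial;
    strategy ``dob_sex`` hashes the full date of birth + sex. A strategy
    contributes no key when any of its components is missing.
    """
    keys: set[tuple[str, str]] = set()
    sdx = soundex(record.last_name) if record.last_name else None
    first = normalise(record.first_name)
    if sdx and first:
        keys.add(("name_soundex", _raw_token(f"{sdx}|{first[0]}", secret_key)))
    dob = [normalise(v) for v in (record.dob_year, record.dob_month, record.dob_day)]
    sex = normalise(record.sex)
    if all(dob) and sex:
        keys.add(("dob_sex", _raw_token("|".join(dob) + "|" + sex, secret_key)))
    return keys


@dataclass
class EncodedRecord:
    """Per-record view of the privacy-preserved encodings."""

    record_id: str
    field_encodings: dict[str, BloomFilter | str | None]
    blocking_keys: set[tuple[str, str]]


@dataclass
class EncodedDataset:
    """Column-oriented container of encoded records.

    Bloom fields are stored as packed uint8 matrices (one row per record)
    with a parallel missing mask; token fields as string arrays with ""
    for missing; blocking keys as one string array per strategy ("" when
    the strategy did not fire for a record).
    """

    record_ids: np.ndarray  # object array of str
    bloom: dict[str, np.ndarray]  # field -> uint8 [N, length_bytes]
    bloom_missing: dict[str, np.ndarray]  # field -> bool [N]
    tokens: dict[str, np.ndarray]  # field -> object [N]
    blocking: dict[str, np.ndarray]  # strategy -> object [N]
    params: BloomFilterParams = field(default_factory=BloomFilterParams)
    field_kinds: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FIELD_KINDS))

    def __len__(self) -> int:
        return len(self.record_ids)

    @property
    def fields(self) -> list[str]:
        return [f for f in LINKAGE_FIELDS if f in self.field_kinds]

    def field_missing(self, name: str) -> np.ndarray:
        if self.field_kinds[name] == "bloom":
            return self.bloom_missing[name]
        return self.tokens[name] == ""

    def record(self, i: int) -> EncodedRecord:
        enc: dict[str, BloomFilter | str | None] = {}
        for f in self.fields:
            if self.field_kinds[f] == "bloom":
                enc[f] = (
                    None
                    if self.bloom_missing[f][i]
                    else BloomFilter(self.bloom[f][i], self.params.length_bits)
                )
            else:
                enc[f] = self.tokens[f][i] or None
        keys = {
            (s, tok)
            for s, arr in self.blocking.items()
            if (tok := arr[i])
        }
        return EncodedRecord(str(self.record_ids[i]), enc, keys)

    def __iter__(self) -> Iterator[EncodedRecord]:
        return (self.record(i) for i in range(len(self)))


def encode_dataset(
    dataset: Iterable[PersonRecord],
    params: BloomFilterParams | None = None,
    secret_key: bytes | None = None,
    field_kinds: Mapping[str, str] | None = None,
) -> EncodedDataset:
    """Encode a plaintext dataset into its privacy-preserved form.

    The entity identifier never enters the output. Identical plaintext
    values produce bit-identical encodings, so per-field value caches make
    this linear in the number of *distinct* values.
    """
    kinds = dict(field_kinds or DEFAULT_FIELD_KINDS)
    if params is None:
        params = BloomFilterParams(secret_key=secret_key or b"")
    elif secret_key is not None and params.secret_key != secret_key:
        params = BloomFilterParams(params.length_bits, params.num_hashes,
                                   params.qgram_length, params.pad, secret_key)
    key = params.secret_key

    records = list(dataset)
    n = len(records)
    ids = np.array([r.record_id for r in records], dtype=object)
    if len(set(ids.tolist())) != n:
        raise ValueError("duplicate record_id in dataset")

    bloom_fields = [f for f in LINKAGE_FIELDS if kinds.get(f) == "bloom"]
    token_fields = [f for f in LINKAGE_FIELDS if kinds.get(f) == "token"]

    bloom: dict[str, np.ndarray] = {}
    bloom_missing: dict[str, np.ndarray] = {}
    cache: dict[str, np.ndarray | None] = {}
    for f in bloom_fields:
        mat = np.zeros((n, params.length_bytes), dtype=np.uint8)
        miss = np.zeros(n, dtype=bool)
        for i, rec in enumerate(records):
            value = normalise(rec.get(f))
            got = cache.get(f + "|" + value, "unset")
            if isinstance(got, str):
                bf = bloom_encode(value, params)
                got = None if bf is None else bf.bits
                cache[f + "|" + value] = got
            if got is None:
                miss[i] = True
            else:
                mat[i] = got
        bloom[f] = mat
        bloom_missing[f] = miss

    tokens: dict[str, np.ndarray] = {}
    tok_cache: dict[str, str] = {}
    for f in token_fields:
        col = np.empty(n, dtype=object)
        for i, rec in enumerate(records):
            value = normalise(rec.get(f))
            if not value:
                col[i] = ""
                continue
            k = f + "|" + value
            if k not in tok_cache:
                tok_cache[k] = hash_token(value, key) or ""
            col[i] = tok_cache[k]
        tokens[f] = col

    blocking: dict[str, np.ndarray] = {
        s: np.full(n, "", dtype=object) for s in BLOCKING_STRATEGIES
    }
    for i, rec in enumerate(records):
        for strategy, tok in make_blocking_keys(rec, key):
            blocking[strategy][i] = tok

    return EncodedDataset(ids, bloom, bloom_missing, tokens, blocking, params, kinds)


# ---------------------------------------------------------------------------
# Serialisation: CSV (base64 Bloom columns, hex token columns) + JSON sidecar.


def write_encoded(ds: EncodedDataset, path: str, sidecar_path: str | None = None) -> None:
    """Write an encoded dataset as CSV with a JSON parameter sidecar.

    The sidecar records every Bloom parameter except the secret key.
    """
    cols: dict[str, list | np.ndarray] = {"record_id": ds.record_ids}
    for f in ds.fields:
        if ds.field_kinds[f] == "bloom":
            miss = ds.bloom_missing[f]
            cols[f] = [
                "" if miss[i] else base64.b64encode(ds.bloom[f][i].tobytes()).decode()
                for i in range(len(ds))
            ]
        else:
            cols[f] = ds.tokens[f]
    for s in ds.blocking:
        cols[f"block_{s}"] = ds.blocking[s]
    pd.DataFrame(cols).to_csv(path, index=False, encoding="utf-8")

    sidecar = sidecar_path or str(path) + ".json"
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "bloom_params": {
                    "length_bits": ds.params.length_bits,
                    "num_hashes": ds.params.num_hashes,
                    "qgram_length": ds.params.qgram_length,
                    "pad": ds.params.pad,
                },
                "field_kinds": ds.field_kinds,
            },
            fh,
            indent=2,
        )


def read_encoded(path: str, sidecar_path: str | None = None) -> EncodedDataset:
    sidecar = sidecar_path or str(path) + ".json"
    with open(sidecar, encoding="utf-8") as fh:
        meta = json.load(fh)
    params = BloomFilterParams(secret_key=b"", **meta["bloom_params"])
    kinds = meta["field_kinds"]
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")

    n = len(frame)
    bloom: dict[str, np.ndarray] = {}
    bloom_missing: dict[str, np.ndarray] = {}
    tokens: dict[str, np.ndarray] = {}
    for f, kind in kinds.items():
        if kind == "bloom":
            mat = np.zeros((n, params.length_bytes), dtype=np.uint8)
            miss = np.zeros(n, dtype=bool)
            for i, cell in enumerate(frame[f]):
                if cell:
                    mat[i] = np.frombuffer(base64.b64decode(cell), dtype=np.uint8)
                else:
                    miss[i] = True
            bloom[f] = mat
            bloom_missing[f] = miss
        else:
            tokens[f] = frame[f].to_numpy(dtype=object)
    blocking = {
        c[len("block_"):]: frame[c].to_numpy(dtype=object)
        for c in frame.columns
        if c.startswith("block_")
    }
    return EncodedDataset(
        frame["record_id"].to_numpy(dtype=object),
        bloom,
        bloom_missing,
        tokens,
        blocking,
        params,
        kinds,
    )
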