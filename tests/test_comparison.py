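"""Pair formation, Dice comparison, partial weights and scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pprlink.comparison import (
    AGREE,
    DISAGREE,
    MISSING,
    FieldScheme,
    PairComparisons,
    candidate_pairs,
    compare_pairs,
    dice_coefficient,
    field_state,
    partial_weight,
    run_linkage,
    score_pairs,
)
from pprlink.encoding import BloomFilter, encode_dataset
from pprlink.estimation import WeightSet
from pprlink.records import LINKAGE_FIELDS, PersonRecord


def _bf(positions, length=64):
    unpacked = np.zeros(length, dtype=np.uint8)
    unpacked[list(positions)] = 1
    return BloomFilter(np.packbits(unpacked), length)


def test_dice_identity_disjoint_and_formula():
    assert dice_coefficient(_bf({1, 5, 9}), _bf({1, 5, 9})) == 1.0
    assert dice_coefficient(_bf({1, 2}), _bf({3, 4})) == 0.0
    assert dice_coefficient(_bf({1, 2, 3, 4}), _bf({3, 4, 5, 6})) == 0.5


def test_dice_degenerate_and_mismatched_inputs():
    with pytest.raises(ValueError):
        dice_coefficient(_bf(set()), _bf(set()))
    with pytest.raises(ValueError):
        dice_coefficient(_bf({1}, 64), _bf({1}, 128))


def test_field_state_rules():
    assert field_state(None, "tok", "exact") == (MISSING, None)
    assert field_state("tok", "tok", "exact") == (AGREE, None)
    assert field_state("tok", "other", "exact") == (DISAGREE, None)
    a, b = _bf({1, 2, 3, 4}), _bf({1, 2, 3, 5})
    state, sim = field_state(a, b, "dice", agree_cutoff=0.8)
    assert state == DISAGREE and sim == pytest.approx(0.75)
    state, _ = field_state(a, a, "dice", agree_cutoff=0.8)
    assert state == AGREE


def _toy_dataset(n, secret_key, entity_of=None):
    """Records in a handful of shared blocks (same surname pool + dob)."""
    rng = np.random.default_rng(17)
    names = ["SMITH", "SMYTH", "JONES", "BROWN"]
    recs = []
    for i in range(n):
        e = entity_of(i) if entity_of else i
        recs.append(
            PersonRecord(
                record_id=f"r{i:03d}", entity_id=f"e{e:03d}",
                first_name="ANNA", middle_name="B",
                last_name=names[rng.integers(len(names))],
                sex="F", dob_year=str(1980 + int(rng.integers(3))),
                dob_month="1", dob_day="1",
                address=f"{i} HIGH ST", suburb="PERTH", postcode="6000",
            )
        )
    return encode_dataset(recs, secret_key=secret_key)


def test_candidate_pairs_unique_and_no_self(secret_key):
    ds = _toy_dataset(30, secret_key)
    pairs = candidate_pairs(ds)
    assert (pairs[:, 0] < pairs[:, 1]).all()
    codes = pairs[:, 0] * len(ds) + pairs[:, 1]
    assert len(np.unique(codes)) == len(codes)


def test_block_pair_combinatorics(secret_key):
    # All 12 records share one dob+sex block and one surname block: the
    # union of both strategies is exactly n(n-1)/2 distinct pairs.
    recs = [
        PersonRecord(
            record_id=f"r{i}", entity_id=f"e{i}", first_name="ANNA",
            middle_name="B", last_name="SMITH", sex="F", dob_year="1980",
            dob_month="1", dob_day="2", address=f"{i} HIGH ST",
            suburb="PERTH", postcode="6000",
        )
        for i in range(12)
    ]
    ds = encode_dataset(recs, secret_key=secret_key)
    assert len(candidate_pairs(ds)) == 12 * 11 // 2


def test_records_without_blocks_contribute_no_pairs(secret_key):
    recs = [
        PersonRecord(record_id=f"r{i}", entity_id=f"e{i}")
        for i in range(5)
    ]
    ds = encode_dataset(recs, secret_key=secret_key)
    assert len(candidate_pairs(ds)) == 0


@given(sim=st.floats(0.0, 1.0))
@settings(max_examples=60, deadline=None)
def test_partial_weight_bounds_and_saturation(sim):
    w = partial_weight(sim, 4.0, -3.0)
    assert -3.0 <= w <= 4.0
    if sim < 0.8:
        assert w == -3.0


def test_partial_weight_anchors():
    assert partial_weight(1.0, 4.0, -3.0) == pytest.approx(4.0)
    assert partial_weight(0.0, 4.0, -3.0) == pytest.approx(-3.0)
    assert partial_weight(0.9, 4.0, -3.0) == pytest.approx(2.0)


def test_partial_weight_monotone_in_similarity():
    sims = np.linspace(0, 1, 101)
    ws = partial_weight(sims, 4.0, -3.0)
    assert (np.diff(ws) >= -1e-12).all()


def _uniform_weights(value=3.0, disagree=-2.0):
    return WeightSet(
        {f: value for f in LINKAGE_FIELDS}, {f: disagree for f in LINKAGE_FIELDS}
    )


def test_score_all_missing_is_zero():
    comps = PairComparisons(
        pairs=np.array([[0, 1]]),
        fields=list(LINKAGE_FIELDS),
        states=np.full((1, 10), MISSING, dtype=np.uint8),
        similarities=np.full((1, 10), np.nan, dtype=np.float32),
    )
    assert score_pairs(comps, _uniform_weights())[0] == 0.0


def test_score_additivity_on_exact_fields():
    scheme = FieldScheme(comparators={f: "exact" for f in LINKAGE_FIELDS})
    states = np.full((2, 10), AGREE, dtype=np.uint8)
    states[1, 3] = DISAGREE
    comps = PairComparisons(
        np.array([[0, 1], [0, 2]]), list(LINKAGE_FIELDS), states,
        np.full((2, 10), np.nan, dtype=np.float32),
    )
    scores = score_pairs(comps, _uniform_weights(3.0, -2.0), scheme)
    assert scores[0] == pytest.approx(30.0)
    assert scores[0] - scores[1] == pytest.approx(3.0 - (-2.0))


def test_score_symmetry(secret_key):
    ds = _toy_dataset(10, secret_key)
    pairs = candidate_pairs(ds)
    fwd = compare_pairs(ds, pairs)
    rev = compare_pairs(ds, pairs[:, ::-1].copy())
    w = _uniform_weights()
    assert np.allclose(score_pairs(fwd, w), score_pairs(rev, w))


def test_run_linkage_threshold_extremes(secret_key):
    ds = _toy_dataset(20, secret_key)
    w = _uniform_weights()
    everything = run_linkage(ds, w, threshold=-1e9)
    nothing = run_linkage(ds, w, threshold=1e9)
    assert len(everything) == len(candidate_pairs(ds))
    assert len(nothing) == 0
    assert (everything["id_a"] < everything["id_b"]).all()


def test_distinct_blocks_yield_no_matches(secret_key):
    # 50 records with pairwise-distinct surnames and birth dates: no two
    # records share a block, so even a very low threshold finds nothing.
    surnames = ["".join(t) for t in itertools.permutations("BCDLMR", 4)][:50]
    recs = []
    for i, last in enumerate(surnames):
        recs.append(
            PersonRecord(
                record_id=f"r{i:02d}", entity_id=f"e{i:02d}",
                first_name="ANNA", middle_name="B",
                last_name=last,  # permutations of distinct-code consonants
                sex="F", dob_year=str(1900 + i), dob_month=str(1 + i % 12),
                dob_day=str(1 + i % 28), address=f"{i} HIGH ST",
                suburb="PERTH", postcode="6000",
            )
        )
    ds = encode_dataset(recs, secret_key=secret_key)
    assert len(run_linkage(ds, _uniform_weights(), threshold=-1e9)) == 0


def test_blocked_equals_exhaustive_when_blocks_cover(secret_key):
    # Every record shares the dob+sex block, so blocking loses nothing
    # relative to brute-force all-pairs comparison.
    rng = np.random.default_rng(23)
    names = ["SMITH", "SMYTH", "JONES", "BROWN"]
    recs = [
        PersonRecord(
            record_id=f"r{i:03d}", entity_id=f"e{i // 2:03d}",
            first_name="ANNA", middle_name="B",
            last_name=names[rng.integers(len(names))],
            sex="F", dob_year="1980", dob_month="1", dob_day="1",
            address=f"{i} HIGH ST", suburb="PERTH", postcode="6000",
        )
        for i in range(40)
    ]
    ds = encode_dataset(recs, secret_key=secret_key)
    pairs = candidate_pairs(ds)
    n = len(ds)
    all_pairs = np.array(list(itertools.combinations(range(n), 2)))
    w = _uniform_weights()
    scheme = FieldScheme()
    blocked = run_linkage(ds, w, scheme, threshold=5.0)
    exhaustive_scores = score_pairs(compare_pairs(ds, all_pairs, scheme), w, scheme)
    keep = exhaustive_scores >= 5.0
    assert len(pairs) == len(all_pairs)
    exhaustive = {
        (f"r{a:03d}", f"r{b:03d}") for (a, b) in all_pairs[keep]
    }
    assert set(zip(blocked["id_a"], blocked["id_b"])) == exhaustive
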