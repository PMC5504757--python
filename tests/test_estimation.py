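"""EM parameter estimation, frequency-based u, and weight conversion."""

import numpy as np
import pytest

from pprlink.comparison import candidate_pairs, compare_pairs
from pprlink.encoding import encode_dataset
from pprlink.estimation import (
    EstimationError,
    FieldStateTable,
    ParameterSet,
    combination_recall_fpr,
    em_expectation,
    em_maximisation,
    estimate_u_frequencies,
    log_likelihood,
    run_em,
    simulate_state_table,
    tabulate_states,
    weights_from_parameters,
)
from pprlink.records import PersonRecord

A, D, M = 0, 1, 2


def _table(fields, rows):
    states = np.array([r[0] for r in rows], dtype=np.uint8)
    counts = np.array([r[1] for r in rows], dtype=np.int64)
    return FieldStateTable(list(fields), states, counts)


def _params(fields, m, u, mm, um, p):
    n = len(fields)
    return ParameterSet(
        list(fields), np.full(n, m, dtype=float), np.full(n, u, dtype=float),
        np.full(n, mm, dtype=float), np.full(n, um, dtype=float), p,
    )


def test_tabulation_conserves_pairs(corrupted_small, secret_key):
    records, _ = corrupted_small
    ds = encode_dataset(records, secret_key=secret_key)
    comps = compare_pairs(ds, candidate_pairs(ds))
    table = tabulate_states(comps)
    assert table.n_pairs == len(comps)
    assert len(np.unique(table.states, axis=0)) == len(table.states)
    assert table.states.shape[1] == 10


def test_tabulation_single_pair():
    from pprlink.comparison import PairComparisons

    comps = PairComparisons(
        np.array([[0, 1]]), ["a", "b"],
        np.array([[A, A]], dtype=np.uint8),
        np.full((1, 2), np.nan, dtype=np.float32),
    )
    table = tabulate_states(comps)
    assert len(table.states) == 1 and table.counts[0] == 1


def test_tabulation_round_trips_through_frame():
    table = _table("ab", [((A, D), 5), ((M, A), 3)])
    back = FieldStateTable.from_frame(table.to_frame())
    assert np.array_equal(back.states, table.states)
    assert np.array_equal(back.counts, table.counts)


def test_recall_fpr_products():
    p2 = _params("ab", m=0.8, u=0.1, mm=0.1, um=0.1, p=0.5)
    recall, fpr = combination_recall_fpr(np.array([[A, M]]), p2)
    assert recall[0] == pytest.approx(0.8 * 0.1)
    p4 = _params("abcd", m=0.8, u=0.1, mm=0.1, um=0.1, p=0.5)
    recall, _ = combination_recall_fpr(np.array([[M, M, M, M]]), p4)
    assert recall[0] == pytest.approx(1e-4)
    p3 = _params("abc", m=0.8, u=0.1, mm=0.1, um=0.1, p=0.5)
    _, fpr = combination_recall_fpr(np.array([[A, A, A]]), p3)
    assert fpr[0] == pytest.approx(1e-3)


def test_recall_fpr_sum_to_one_over_full_space():
    rng = np.random.default_rng(5)
    fields = list("abcde")
    params = ParameterSet(
        fields, m=rng.uniform(0.6, 0.95, 5), u=rng.uniform(0.01, 0.2, 5),
        mm=rng.uniform(0.01, 0.1, 5), um=rng.uniform(0.01, 0.1, 5), p=0.1,
    )
    codes = np.arange(3**5)
    radix = 3 ** np.arange(5)
    states = ((codes[:, None] // radix) % 3).astype(np.uint8)
    recall, fpr = combination_recall_fpr(states, params)
    assert recall.sum() == pytest.approx(1.0, abs=1e-9)
    assert fpr.sum() == pytest.approx(1.0, abs=1e-9)


def test_expectation_posteriors():
    # recall == fpr at p=0.5 -> posterior 0.5; direct evaluation case.
    table = _table("ab", [((A, A), 1), ((A, M), 1)])
    params = _params("ab", m=0.8, u=0.8, mm=0.1, um=0.1, p=0.5)
    pj = em_expectation(table, params)
    assert pj == pytest.approx([0.5, 0.5])

    params = _params("a", m=0.8, u=0.1, mm=0.1, um=0.1, p=0.5)
    single = _table("a", [((A,), 1)])
    assert em_expectation(single, params)[0] == pytest.approx(8 / 9)


def test_expectation_zero_fpr_limit():
    table = _table("a", [((A,), 1)])
    params = ParameterSet(["a"], np.array([0.9]), np.array([0.0]),
                          np.array([0.05]), np.array([0.1]), 0.5)
    assert em_expectation(table, params)[0] == pytest.approx(1.0)


def test_maximisation_hand_oracle():
    # Two combinations over two fields with fixed posteriors: match mass
    # 0.9*10 + 0.1*10 = 10, so m_1 = 9/10 and m_2 = 1.
    table = _table("ab", [((A, A), 10), ((D, A), 10)])
    out = em_maximisation(table, np.array([0.9, 0.1]))
    assert out.m[0] == pytest.approx(0.9)
    assert out.m[1] == pytest.approx(1.0 - 1e-6)  # clipped from exactly 1
    assert out.p == pytest.approx(0.5)


def test_maximisation_reduces_to_raw_fractions_when_all_match():
    table = _table("ab", [((A, A), 30), ((D, M), 10)])
    out = em_maximisation(table, np.array([1.0 - 1e-9, 1.0 - 1e-9]))
    assert out.m[0] == pytest.approx(0.75, abs=1e-6)
    assert out.mm[1] == pytest.approx(0.25, abs=1e-6)


def test_maximisation_state_shares_conserved():
    rng = np.random.default_rng(9)
    truth = _params("abcd", m=0.85, u=0.08, mm=0.05, um=0.07, p=0.2)
    table = simulate_state_table(truth, 20_000, rng)
    out = em_maximisation(table, em_expectation(table, truth))
    for k in range(4):
        agree = out.m[k] + out.mm[k]
        assert agree <= 1.0 + 1e-9


def test_run_em_default_initialisation():
    init = ParameterSet.initial(["a", "b"])
    assert (init.m == 0.8).all() and (init.u == 0.1).all()
    assert (init.mm == 0.1).all() and (init.um == 0.1).all()


def test_run_em_converges_to_fixed_point(rng):
    truth = _params("abcde", m=0.9, u=0.05, mm=0.05, um=0.08, p=0.1)
    table = simulate_state_table(truth, 50_000, rng)
    fit = run_em(table, tol=1e-8)
    assert fit.converged
    # One further iteration moves every parameter by less than tol.
    again = em_maximisation(table, em_expectation(table, fit))
    assert np.max(np.abs(again.as_vector() - fit.as_vector())) < 1e-6


def test_run_em_recovers_known_parameters(rng):
    truth = ParameterSet(
        list("abcdef"),
        m=np.array([0.95, 0.9, 0.85, 0.92, 0.88, 0.8]),
        u=np.array([0.02, 0.05, 0.1, 0.03, 0.08, 0.15]),
        mm=np.array([0.03, 0.05, 0.08, 0.02, 0.06, 0.1]),
        um=np.array([0.04, 0.06, 0.09, 0.03, 0.07, 0.12]),
        p=0.05,
    )
    table = simulate_state_table(truth, 100_000, rng)
    fit = run_em(table)
    assert np.abs(fit.m - truth.m).max() < 0.02
    assert np.abs(fit.mm - truth.mm).max() < 0.02
    assert abs(fit.p - truth.p) < 0.01


def test_log_likelihood_nondecreasing(rng):
    truth = _params("abcd", m=0.9, u=0.1, mm=0.05, um=0.05, p=0.08)
    table = simulate_state_table(truth, 30_000, rng)
    fit = run_em(table)
    trace = np.asarray(fit.loglik_trace)
    assert (np.diff(trace) >= -1e-7).all()


def test_em_invariant_to_row_order_and_field_permutation(rng):
    truth = _params("abc", m=0.9, u=0.1, mm=0.05, um=0.05, p=0.1)
    table = simulate_state_table(truth, 20_000, rng)
    fit = run_em(table)

    perm = np.random.default_rng(0).permutation(len(table.states))
    shuffled = FieldStateTable(table.fields, table.states[perm], table.counts[perm])
    fit_shuffled = run_em(shuffled)
    assert np.allclose(fit.as_vector(), fit_shuffled.as_vector())

    swapped = FieldStateTable(
        [table.fields[1], table.fields[0], table.fields[2]],
        table.states[:, [1, 0, 2]], table.counts,
    )
    fit_swapped = run_em(swapped)
    assert np.allclose(fit_swapped.m[[1, 0, 2]], fit.m)
    assert np.allclose(fit_swapped.u[[1, 0, 2]], fit.u)


def _records_with_values(values, field="postcode"):
    recs = []
    for i, v in enumerate(values):
        recs.append(
            PersonRecord(
                record_id=f"r{i}", entity_id=f"e{i}", first_name="ANN",
                middle_name="B", last_name="SMITH", sex="M",
                dob_year="1980", dob_month="1", dob_day="1",
                address="1 HIGH ST", suburb="PERTH",
                postcode="6000",
            )
        )
        setattr(recs[-1], field, v)
    return recs


def test_frequency_u_constant_field(secret_key):
    ds = encode_dataset(_records_with_values(["6000"] * 6), secret_key=secret_key)
    u, um = estimate_u_frequencies(ds)
    assert u["postcode"] == pytest.approx(1.0)
    assert um["postcode"] == pytest.approx(0.0)


def test_frequency_u_two_value_split(secret_key):
    ds = encode_dataset(
        _records_with_values(["6000", "6000", "6100", "6100"]),
        secret_key=secret_key,
    )
    u, _ = estimate_u_frequencies(ds)
    assert u["postcode"] == pytest.approx(1 / 3)


def test_frequency_u_missing_adjustment(secret_key):
    ds = encode_dataset(
        _records_with_values(["6000", "6000", "", "6100"]), secret_key=secret_key
    )
    u, um = estimate_u_frequencies(ds)
    # 3 present of 4: P(at least one missing in a random pair) = 1 - 6/12.
    assert um["postcode"] == pytest.approx(0.5)
    assert u["postcode"] == pytest.approx(2 / 6)


def test_frequency_u_uniform_brute_force(secret_key, rng):
    values = [str(6000 + int(v)) for v in rng.integers(0, 10, size=300)]
    ds = encode_dataset(_records_with_values(values), secret_key=secret_key)
    u, _ = estimate_u_frequencies(ds)
    agree = sum(
        1
        for i in range(300)
        for j in range(i + 1, 300)
        if values[i] == values[j]
    )
    assert u["postcode"] == pytest.approx(agree / (300 * 299 / 2))
    assert u["postcode"] == pytest.approx(0.1, abs=0.02)


def test_weights_from_parameters():
    wa, wd = weights_from_parameters(0.8, 0.1)
    assert wa == pytest.approx(3.0)
    assert wd == pytest.approx(np.log2(0.2 / 0.9))
    assert wd == pytest.approx(-2.1699, abs=1e-4)
    wa_eq, wd_eq = weights_from_parameters(0.3, 0.3)
    assert wa_eq == 0.0 and wd_eq == 0.0


def test_weights_saturation_warns():
    with pytest.warns(UserWarning):
        weights_from_parameters(1.0, 0.1)


def test_tabulate_empty_raises():
    from pprlink.comparison import PairComparisons

    comps = PairComparisons(
        np.empty((0, 2), dtype=int), ["a"],
        np.empty((0, 1), dtype=np.uint8), np.empty((0, 1), dtype=np.float32),
    )
    with pytest.raises(EstimationError):
        tabulate_states(comps)
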