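from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirseq.diffexpr import (
    EXCLUSIVE_LIB1,
    EXCLUSIVE_LIB2,
    STATUS_FILTERED_CONFIDENCE,
    STATUS_FILTERED_FLOOR,
    STATUS_NS,
    STATUS_UP,
    UNDEFINED,
    DifferentialExpression,
    ac_point_prob,
    ac_point_prob_oracle,
    ac_pvalue,
    bh_adjust,
    call_dems,
    log2_fold_change,
)
from mirseq.quantify import tpm_normalize

N = 1_000_000


@pytest.mark.parametrize(
    "x,y,n1,n2,expected",
    [
        (0, 0, N, N, 0.5),
        (2, 1, N, N, 3 / 16),
        (1, 1, N, N, 0.25),
        (0, 1, 1e6, 2e6, 2 / 9),
    ],
)
def test_point_probability_closed_values(x, y, n1, n2, expected):
    assert ac_point_prob(x, y, n1, n2) == pytest.approx(expected, rel=1e-12)
    assert ac_point_prob_oracle(x, y, n1, n2) == pytest.approx(expected, rel=1e-12)


def test_point_probability_agrees_with_rational_oracle_on_grid():
    for ratio in (0.5, 1.0, 2.0, 5.0):
        n1, n2 = 1_000_000, int(ratio * 1_000_000)
        for x in range(0, 31, 3):
            for y in range(0, 31, 3):
                fast = ac_point_prob(x, y, n1, n2)
                exact = ac_point_prob_oracle(x, y, n1, n2)
                assert fast == pytest.approx(exact, rel=1e-10)


def test_equal_library_closed_form():
    for total in (0, 10, 37, 60):
        for x in range(total + 1):
            y = total - x
            expected = comb(total, x) / 2 ** (total + 1)
            assert ac_point_prob(x, y, N, N) == pytest.approx(expected, rel=1e-10)


def test_oracle_refuses_out_of_range_and_bad_counts():
    with pytest.raises(ValueError):
        ac_point_prob_oracle(150, 100, N, N)
    with pytest.raises(ValueError):
        ac_point_prob(-1, 2, N, N)
    with pytest.raises(ValueError):
        ac_point_prob(1.5, 2, N, N)


def test_point_prob_stays_finite_at_large_counts():
    p = ac_point_prob(5_000_000, 5_001_000, 10_000_000, 10_000_000)
    assert 0 < p <= 1


def test_two_sided_pvalue_is_one_at_symmetric_counts():
    # symmetry makes the doubled smaller tail >= 1 (machine precision at the cap)
    for x in (0, 3, 50, 1000):
        assert ac_pvalue(x, x, N, N) == pytest.approx(1.0, rel=1e-12)


def test_point_mode_returns_point_mass_and_is_bounded_by_two_sided():
    assert ac_pvalue(0, 0, N, N, mode="point") == pytest.approx(0.5)
    for x, y in [(0, 10), (5, 1), (100, 130)]:
        assert ac_pvalue(x, y, N, N) >= ac_pvalue(x, y, N, N, mode="point")


def _exact_point(x, y, n1, n2):
    q = Fraction(n2, n1)
    return q**y * comb(x + y, x) / (1 + q) ** (x + y + 1)


def test_two_sided_tail_matches_oracle_summation():
    """Doubled smaller tail, assembled from exact rational point masses."""
    n1, n2 = 1_000_000, 2_000_000
    for x, y in [(3, 10), (10, 3), (0, 7), (12, 12)]:
        lower = sum(_exact_point(k, y, n1, n2) for k in range(x + 1))
        lower_strict = lower - _exact_point(x, y, n1, n2)
        upper = max(Fraction(0), min(Fraction(1), 1 - lower_strict))
        expected = min(1.0, 2 * min(float(lower), float(upper)))
        assert ac_pvalue(x, y, n1, n2) == pytest.approx(expected, rel=1e-9)


def test_conditional_distribution_normalizes_over_x():
    for x in (0, 1, 5):
        for ratio in (0.5, 1, 2):
            ys = np.arange(0, 2000)
            total = ac_point_prob(np.full_like(ys, x), ys, N, ratio * N).sum()
            assert total == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize(
    "tpm1,tpm2,pseudo,expected",
    [
        (2.0, 8.0, 0.0, 2.0),
        (5.0, 5.0, 0.0, 0.0),
        (3.0, 12.0, 1.0, np.log2(13 / 4)),
    ],
)
def test_log2_fold_change_values(tpm1, tpm2, pseudo, expected):
    assert log2_fold_change(tpm1, tpm2, pseudo) == pytest.approx(expected)


def test_log2_fold_change_sentinels():
    assert log2_fold_change(0.0, 5.0) == EXCLUSIVE_LIB2
    assert log2_fold_change(5.0, 0.0) == EXCLUSIVE_LIB1
    assert log2_fold_change(0.0, 0.0) == UNDEFINED
    assert log2_fold_change(0.0, 5.0, pseudocount=1.0) == pytest.approx(np.log2(6))


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([0.001, 0.5], [0.002, 0.5]),
    ],
)
def test_bh_step_up_hand_computed(pvals, expected):
    assert bh_adjust(pvals) == pytest.approx(expected)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.randoms(use_true_random=False))
def test_bh_is_invariant_to_input_order(pvals, rnd):
    base = bh_adjust(pvals)
    perm = list(range(len(pvals)))
    rnd.shuffle(perm)
    shuffled = bh_adjust([pvals[i] for i in perm])
    for out_pos, in_pos in enumerate(perm):
        assert shuffled[out_pos] == pytest.approx(base[in_pos], rel=1e-12)


def _paired(rows):
    return pd.DataFrame(
        rows, columns=["mirna", "count_1", "count_2", "tpm_1", "tpm_2", "confidence"]
    )


def test_call_dems_three_row_toy():
    """Hand-built: an ER-exclusive miRNA above the floor, a null miRNA, a floored one."""
    table = _paired(
        [
            ("exclusive", 0, 200, 0.0, 200.0, 1.0),
            ("null", 100, 110, 100.0, 110.0, 1.0),
            ("floored", 0, 0, 0.5, 0.5, 1.0),
        ]
    )
    out = call_dems(table, N, N).set_index("mirna")
    assert out.loc["exclusive", "status"] == STATUS_UP
    assert np.isposinf(out.loc["exclusive", "log2fc"])
    assert out.loc["null", "status"] == STATUS_NS
    assert out.loc["floored", "status"] == STATUS_FILTERED_FLOOR
    assert np.isnan(out.loc["floored", "p_raw"])
    # p for the exclusive row is the doubled lower tail 2 * p(0|200)
    expected_p = 2 * ac_point_prob_oracle(0, 200, N, N)
    assert out.loc["exclusive", "p_raw"] == pytest.approx(expected_p, rel=1e-9)


def test_call_dems_identical_counts_never_significant():
    table = _paired([(f"m{i}", 50, 50, 50.0, 50.0, 1.0) for i in range(20)])
    out = call_dems(table, N, N)
    assert (out["status"] == STATUS_NS).all()


def test_call_dems_confidence_filter_overrides_counts():
    table = _paired([("novel", 0, 5000, 0.0, 5000.0, 0.5)])
    out = call_dems(table, N, N)
    assert out.loc[0, "status"] == STATUS_FILTERED_CONFIDENCE
    assert np.isnan(out.loc[0, "p_raw"])


def test_call_dems_nonsignificant_exclusive_keeps_exclusive_status():
    table = _paired([("rare", 0, 2, 0.0, 2.0, 1.0)])
    out = call_dems(table, N, N)
    assert out.loc[0, "status"] == EXCLUSIVE_LIB2


def test_call_dems_rejects_counts_exceeding_totals():
    table = _paired([("m", 10, 5, 1.0, 1.0, 1.0)])
    with pytest.raises(ValueError):
        call_dems(table, 8, N)


def test_model_results_surface():
    profile_1 = tpm_normalize({"m1": 100, "m2": 4000, "m3": 0}, N, "LL")
    profile_2 = tpm_normalize({"m1": 110, "m2": 400, "m3": 300}, N, "ER")
    model = DifferentialExpression.from_profiles(profile_1, profile_2)
    res = model.fit()
    assert set(res.table.columns) >= {"mirna", "log2fc", "p_raw", "p_adj", "status"}
    assert res.n_tested == 3
    assert res.n_down >= 1  # m2 drops tenfold
    text = res.summary()
    assert "N1 = 1,000,000" in text and "up" in text
    recs = {r.mirna: r for r in res.records()}
    assert recs["m2"].status == "down"


def test_from_dataframe_requires_consistent_totals():
    df = pd.DataFrame(
        {
            "mirna": ["a", "b"],
            "count_1": [1, 2],
            "count_2": [1, 2],
            "tpm_1": [1.0, 2.0],
            "tpm_2": [1.0, 2.0],
            "n_1": [100, 200],
            "n_2": [100, 100],
        }
    )
    with pytest.raises(ValueError):
        DifferentialExpression.from_dataframe(df)
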