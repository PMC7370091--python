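"""Percent change, typical error, responder flags, proportion tests."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import respfanova as rf
from respfanova.errors import DegenerateInputError
from respfanova.trialref import N_SUBJECTS, TABLE2
from respfanova.variables import Direction

from conftest import make_toy_dataset


GRID = [0.0, 5.0, 10.0]


def test_percent_change_arithmetic():
    ds = make_toy_dataset(
        GRID,
        {
            "S1": {"ONB": [1.0, 1.0, 1.0], "FB": [1.4, 1.4, 1.4]},
            "S2": {"ONB": [2.0, 2.0, 2.0], "FB": [2.0, 2.0, 2.0]},
        },
    )
    subjects, pct = rf.percent_change(ds, "HR")
    assert subjects == ["S1", "S2"]
    assert np.allclose(pct, [40.0, 0.0])


def test_percent_change_hand_computed_three_subjects():
    # hand arithmetic: mean_FB / mean_ONB per subject
    ds = make_toy_dataset(
        GRID,
        {
            "A": {"ONB": [10, 10, 10], "FB": [11, 12, 13]},  # (12-10)/10 = +20%
            "B": {"ONB": [20, 22, 24], "FB": [22, 22, 22]},  # (22-22)/22 = 0%
            "C": {"ONB": [8, 8, 8], "FB": [6, 6, 6]},  # -25%
        },
    )
    _, pct = rf.percent_change(ds, "HR")
    assert np.allclose(pct, [20.0, 0.0, -25.0])


def test_percent_change_zero_onb_mean_names_subject():
    ds = make_toy_dataset(
        GRID, {"S1": {"ONB": [1.0, -1.0, 0.0], "FB": [1.0, 1.0, 1.0]}}
    )
    with pytest.raises(DegenerateInputError, match="S1"):
        rf.percent_change(ds, "HR")


def test_typical_error_hand_computation():
    # sample SD of [-2, 4, 6, 8] is 4.3205; TE = SD / sqrt(2) = 3.055
    te = rf.typical_error(np.array([-2.0, 4.0, 6.0, 8.0]))
    assert np.isclose(te, 4.3205 / np.sqrt(2.0), atol=1e-4)
    assert np.isclose(te, 3.055, atol=1e-3)
    assert rf.typical_error(np.array([5.0, 5.0, 5.0])) == 0.0
    with pytest.raises(DegenerateInputError):
        rf.typical_error(np.array([1.0]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.1, 100.0),
    changes=st.lists(st.floats(-50, 50), min_size=2, max_size=10),
)
def test_typical_error_homogeneous_and_classify_scale_free(scale, changes):
    changes = np.asarray(changes)
    te = rf.typical_error(changes)
    assert np.isclose(rf.typical_error(scale * changes), scale * te, rtol=1e-9)
    flags = rf.classify(changes, te, Direction.FB_GT_ONB)
    flags_scaled = rf.classify(scale * changes, scale * te, Direction.FB_GT_ONB)
    assert np.array_equal(flags, flags_scaled)


def test_classify_threshold_logic():
    assert np.array_equal(
        rf.classify(np.array([4.0, 2.0, -5.0]), 3.0, Direction.FB_GT_ONB),
        [True, False, False],
    )
    assert np.array_equal(
        rf.classify(np.array([-4.0, -2.0, 5.0]), 3.0, Direction.ONB_GT_FB),
        [True, False, False],
    )
    # TE = 0: any strictly directional change responds
    assert np.array_equal(
        rf.classify(np.array([0.1, 0.0, -0.1]), 0.0, Direction.FB_GT_ONB),
        [True, False, False],
    )
    assert np.array_equal(
        rf.classify(np.array([4.0, -4.0, 1.0]), 3.0, Direction.ONB_GT_FB, two_sided=True),
        [True, True, False],
    )


def brute_force_binomial_tail(k, n, p0=0.5):
    return sum(comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1))


@pytest.mark.parametrize("k,n,expected", [(13, 18, 0.0481), (9, 18, 0.5927)])
def test_exact_proportion_test_against_brute_force(k, n, expected):
    p = rf.proportion_test(k, n)
    assert np.isclose(p, brute_force_binomial_tail(k, n), atol=1e-12)
    assert np.isclose(p, expected, atol=5e-5)


def test_proportion_test_closed_forms_and_monotonicity():
    n = 18
    assert np.isclose(rf.proportion_test(n, n), 0.5**n, atol=1e-15)
    ps = [rf.proportion_test(k, n) for k in range(n + 1)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    # normal approximation with continuity correction agrees roughly
    assert abs(rf.proportion_test(13, 18, method="normal_cc") - ps[13]) < 0.02
    with pytest.raises(ValueError):
        rf.proportion_test(19, 18)


def test_table_counts_yield_single_significant_variable():
    """Of the trial's printed responder counts (n=18), only k=13 is significant."""
    counts = sorted({row.responders for row in TABLE2.values()}, reverse=True)
    assert counts == [13, 12, 10, 9, 8, 7, 6, 5, 2]
    stars = {k: rf.proportion_test(k, N_SUBJECTS) < 0.05 for k in counts}
    assert stars[13]
    assert not any(v for k, v in stars.items() if k != 13)
    assert np.isclose(rf.proportion_test(12, N_SUBJECTS), 0.1189, atol=5e-5)


def test_build_table2_hand_computed_row():
    ds = make_toy_dataset(
        GRID,
        {
            "A": {"ONB": [10, 10, 10], "FB": [12, 12, 12]},  # +20%
            "B": {"ONB": [10, 10, 10], "FB": [11, 11, 11]},  # +10%
            "C": {"ONB": [10, 10, 10], "FB": [9, 9, 9]},  # -10%
        },
    )
    tables, df = rf.build_table2(ds, [rf.VARIABLES["HR"]])
    t = tables[0]
    # changes [20, 10, -10]: SD = 15.2753, TE = 10.8012
    assert np.isclose(t.te_pct, np.std([20, 10, -10], ddof=1) / np.sqrt(2))
    assert np.array_equal(t.responder, [True, False, False])
    assert t.k == 1 and t.n == 3
    assert np.isclose(t.fb_mean, (12 + 11 + 9) / 3)
    assert np.isclose(t.onb_mean, 10.0)
    row = df.iloc[0]
    assert row["proportion_pct"] == 33.3
    assert row["significant"] == ""
    assert np.isclose(row["p_value"], rf.proportion_test(1, 3), atol=5e-5)


def test_null_data_responder_counts_near_half():
    from conftest import make_single_var_config

    cfg = make_single_var_config(
        effect=rf.EffectCurve("zero"), sigma=0.1, grid_step_s=60.0, seed=21
    )
    ds = rf.generate_dataset(cfg)
    tables, _ = rf.build_table2(ds, [rf.VARIABLES["Tin"]])
    assert 3 <= tables[0].k <= 15  # near n/2, no extreme count under the null
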