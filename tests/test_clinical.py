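import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from nirsvft.clinical import (
    between_group_change,
    between_group_change_from_ci,
    chi_square_2x2,
    inflate_dropout,
    normality_gate,
    paired_change,
    power_two_sample_t,
    proportion_pct,
    sample_size_two_t,
    sd_from_ci,
)


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

def test_gaussian_sample_passes_the_gate():
    x = np.random.default_rng(1234).normal(0, 1, 500)
    assert normality_gate(x)[0] == "parametric"


def test_skewed_discrete_scores_fail_the_gate():
    rng = np.random.default_rng(1)
    x = np.clip(np.round(rng.exponential(0.5, 60)), 0, 3)
    assert normality_gate(x)[0] == "nonparametric"


def test_gate_input_validation():
    with pytest.raises(ValueError):
        normality_gate([1.0, 2.0])
    with pytest.raises(ValueError):
        normality_gate([3.0, 3.0, 3.0])


# ---------------------------------------------------------------------------
# paired change
# ---------------------------------------------------------------------------

def test_no_change_is_flagged_null():
    x = np.array([3.0, 5.0, 4.0, 6.0])
    res = paired_change(x, x)
    assert res.mean_change == 0.0
    assert res.statistic == 0.0 and res.p == 1.0
    assert res.ci[0] <= 0.0 <= res.ci[1]
    assert res.flagged == "all-zero differences"


def test_hand_computed_change_ci():
    pre = np.zeros(4)
    post = np.array([-5.0, -4.0, -6.0, -5.0])
    res = paired_change(pre, post, force="parametric")
    # sd(d) = sqrt(2/3), se = sd/2, t_{.975,3} = 3.1824:
    # CI = -5 -/+ 3.1824 * 0.40825 = (-6.299, -3.701)
    assert res.mean_change == pytest.approx(-5.0)
    assert res.ci[0] == pytest.approx(-6.299, abs=0.001)
    assert res.ci[1] == pytest.approx(-3.701, abs=0.001)
    assert res.test == "paired-t"


def test_printed_ci_inverts_to_change_sd():
    # published change -4.69 with CI (-6.04, -3.33) at n = 32
    assert sd_from_ci(-6.04, -3.33, 32) == pytest.approx(3.76, abs=0.02)


def test_ci_inversion_round_trip():
    rng = np.random.default_rng(2)
    for _ in range(20):
        d = rng.normal(0, 3, rng.integers(5, 40))
        res = paired_change(np.zeros_like(d), d, force="parametric")
        sd = sd_from_ci(res.ci[0], res.ci[1], d.size)
        assert sd == pytest.approx(d.std(ddof=1), abs=1e-9)


def test_wilcoxon_route_reports_rank_effect_size():
    rng = np.random.default_rng(3)
    pre = rng.normal(0, 1, 30)
    post = pre - np.abs(rng.normal(1, 0.5, 30))
    res = paired_change(pre, post, force="nonparametric")
    assert res.test == "wilcoxon"
    assert 0.0 <= res.p <= 1.0
    assert res.effect_size >= 0.0


# ---------------------------------------------------------------------------
# between-group change
# ---------------------------------------------------------------------------

def test_identical_groups_are_null():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = between_group_change(x, x.copy(), force="parametric")
    assert res.statistic == 0.0
    assert res.p == pytest.approx(1.0)
    assert res.effect_size == 0.0


def test_published_effect_sizes_reproduce_from_summary_tables():
    psqi = between_group_change_from_ci(-4.69, (-6.04, -3.33), 32,
                                        -2.13, (-2.83, -1.42), 32)
    assert psqi.effect_size == pytest.approx(-0.854, abs=0.003)
    assert psqi.effect_ci[0] == pytest.approx(-1.363, abs=0.01)
    assert psqi.effect_ci[1] == pytest.approx(-0.338, abs=0.01)

    sds = between_group_change_from_ci(-7.78, (-10.54, -5.02), 32,
                                       -3.31, (-6.22, -0.41), 32)
    assert sds.effect_size == pytest.approx(-0.569, abs=0.003)


def test_cohens_d_sign_convention():
    """d is negative when group 1 improves (decreases) more."""
    g1 = np.array([-5.0, -4.5, -5.5, -4.0])
    g2 = np.array([-2.0, -1.5, -2.5, -1.0])
    res = between_group_change(g1, g2, force="parametric")
    assert res.effect_size < 0


def test_mann_whitney_route():
    rng = np.random.default_rng(4)
    g1 = rng.exponential(1.0, 25)
    g2 = rng.exponential(2.0, 25)
    res = between_group_change(g1, g2, force="nonparametric")
    assert res.test == "mann-whitney"
    assert res.effect_size >= 0.0
    assert 0.0 <= res.p <= 1.0


def test_zero_pooled_variance_error():
    with pytest.raises(ValueError):
        between_group_change(np.array([1.0, 1.0]), np.array([2.0, 2.0]),
                             force="parametric")


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "table,chi2_expected,p_expected",
    [
        ([[15, 17], [14, 18]], 0.063, 0.802),
        ([[4, 28], [3, 29]], 0.160, 0.689),
        ([[11, 21], [13, 19]], 0.267, 0.606),
    ],
)
def test_chi_square_reproduces_published_tables(table, chi2_expected, p_expected):
    chi2, p, df = chi_square_2x2(table)
    assert round(chi2, 3) == chi2_expected
    assert round(p, 3) == p_expected
    assert df == 1


@given(st.tuples(*[st.integers(1, 50)] * 4))
def test_chi_square_matches_expected_count_oracle(cells):
    a, b, c, d = cells
    chi2, p, _ = chi_square_2x2([[a, b], [c, d]])
    ref_chi2, ref_p, _, _ = stats.chi2_contingency([[a, b], [c, d]],
                                                   correction=False)
    assert abs(chi2 - ref_chi2) < 1e-10
    assert abs(p - ref_p) < 1e-10


def test_chi_square_degenerate_tables():
    with pytest.raises(ValueError, match="marginal"):
        chi_square_2x2([[0, 0], [3, 5]])
    with pytest.raises(ValueError):
        chi_square_2x2([[-1, 2], [3, 4]])


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

def test_pilot_sample_size_is_31_per_group():
    assert sample_size_two_t(5.19, 2.37, 3.02, alpha=0.05, power=0.95) == 31


def test_sample_size_brackets_the_target_power():
    d = abs(5.19 - 2.37) / 3.02
    n = sample_size_two_t(5.19, 2.37, 3.02, power=0.95)
    assert power_two_sample_t(n, d) >= 0.95
    assert power_two_sample_t(n - 1, d) < 0.95


def test_sample_size_monotonicity():
    n95 = sample_size_two_t(5.19, 2.37, 3.02, power=0.95)
    n80 = sample_size_two_t(5.19, 2.37, 3.02, power=0.80)
    assert n80 < n95
    n_big_effect = sample_size_two_t(5.19 + 2.82, 2.37, 3.02, power=0.95)
    assert n_big_effect < n95


def test_sample_size_matches_statsmodels_solver():
    from statsmodels.stats.power import TTestIndPower

    d = abs(5.19 - 2.37) / 3.02
    n_ref = TTestIndPower().solve_power(effect_size=d, alpha=0.05, power=0.95)
    assert sample_size_two_t(5.19, 2.37, 3.02, power=0.95) == math.ceil(n_ref)


def test_sample_size_input_validation():
    with pytest.raises(ValueError):
        sample_size_two_t(1.0, 1.0, 3.0)
    with pytest.raises(ValueError):
        sample_size_two_t(1.0, 2.0, 0.0)


@pytest.mark.parametrize("n,rate,expected", [
    (31, 0.20, (38, 76)),
    (31, 0.0, (31, 62)),
    (10, 0.15, (12, 24)),
])
def test_dropout_inflation(n, rate, expected):
    assert inflate_dropout(n, rate) == expected


def test_dropout_rate_validation():
    with pytest.raises(ValueError):
        inflate_dropout(31, 1.0)


def test_blinding_guess_rate_reporting():
    assert proportion_pct(15, 32) == 46.9
    assert proportion_pct(14, 32) == 43.8
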