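"""Disproportionality statistics against independent oracles and frozen values.

The brute-force oracle below evaluates each published formula directly with
numpy on the raw cells, independently of the implementation's code path;
chi-square and the odds ratio are additionally cross-checked against scipy
and statsmodels.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

import pvsignals as pv
from pvsignals.signal_stats import SignalScores

# ---------------------------------------------------------------- oracles


def oracle_ror(a, b, c, d):
    ror = (a * d) / (b * c)
    half = 1.96 * np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, (np.exp(np.log(ror) - half), np.exp(np.log(ror) + half))


def oracle_prr(a, b, c, d):
    prr = (a / (a + b)) / (c / (c + d))
    half = 1.96 * np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return prr, (np.exp(np.log(prr) - half), np.exp(np.log(prr) + half))


def oracle_chi2(a, b, c, d, yates):
    n = a + b + c + d
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    return n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))


def oracle_bcpnn(a, b, c, d, a1=1.0, b1=1.0, g11=1.0, al=2.0, be=2.0):
    n = a + b + c + d
    ab, ac = a + b, a + c
    g = g11 * (n + al) * (n + be) / ((ab + a1) * (ac + b1))
    e_ic = np.log2((a + g11) * (n + al) * (n + be) / ((n + g) * (ab + a1) * (ac + b1)))
    v_ic = (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - ab + al - a1) / ((ab + a1) * (1 + n + al))
        + (n - ac + be - b1) / ((ac + b1) * (1 + n + be))
    ) / np.log(2) ** 2
    return e_ic, e_ic - 2 * np.sqrt(v_ic)


def oracle_ebgm(a, b, c, d):
    n = a + b + c + d
    ebgm = a * n / ((a + b) * (a + c))
    half = 1.96 * np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ebgm, np.exp(np.log(ebgm) - half)


def table(a, b, c, d, event="X"):
    return pv.ContingencyTable(event, "PT", a, b, c, d)


# ---------------------------------------------------------- frozen examples


class TestWorkedExamples:
    t = table(10, 90, 100, 9900)

    def test_ror_point_and_ci(self):
        ror, (lo, hi) = pv.ror_score(self.t, correction="none")
        assert ror == pytest.approx(11.0)
        assert (lo, hi) == pytest.approx((5.56, 21.76), rel=1e-3)

    def test_ror_matches_statsmodels(self):
        sm = Table2x2(np.array([[10, 90], [100, 9900]]))
        ror, ci = pv.ror_score(self.t, correction="none")
        assert ror == pytest.approx(sm.oddsratio, rel=1e-12)
        # statsmodels uses z=1.959964 where the conventional table prints 1.96
        assert ci == pytest.approx(sm.oddsratio_confint(0.05), rel=1e-4)

    def test_prr_point(self):
        prr, _ = pv.prr_score(self.t, correction="none")
        assert prr == pytest.approx(10.0)

    def test_chi2_with_and_without_yates(self):
        assert pv.chi2_score(self.t, yates=False) == pytest.approx(74.45, abs=0.01)
        assert pv.chi2_score(self.t, yates=True) == pytest.approx(66.33, abs=0.01)

    def test_chi2_matches_scipy(self):
        obs = np.array([[10, 90], [100, 9900]])
        for yates in (False, True):
            expected = chi2_contingency(obs, correction=yates)[0]
            assert pv.chi2_score(self.t, yates=yates) == pytest.approx(expected, rel=1e-12)

    def test_bcpnn_shrinks_sparse_signal(self):
        # expected count is ~1.1, so the posterior IC sits well below the
        # crude log2 observed/expected of 3.20 bits
        ic, ic025 = pv.bcpnn_score(self.t)
        assert ic == pytest.approx(2.3825, abs=1e-4)
        assert ic025 < ic

    def test_ebgm_point(self):
        ebgm, ebgm05 = pv.ebgm_score(self.t)
        assert ebgm == pytest.approx(9.1818, abs=1e-4)
        assert ebgm05 < ebgm


class TestIndependenceTables:
    t = table(10, 90, 90, 810)

    def test_all_ratios_are_one(self):
        assert pv.ror_score(self.t, "none")[0] == pytest.approx(1.0)
        assert pv.prr_score(self.t, "none")[0] == pytest.approx(1.0)
        assert pv.ebgm_score(self.t)[0] == pytest.approx(1.0)

    def test_ic_near_zero(self):
        ic, _ = pv.bcpnn_score(self.t)
        assert abs(ic) < 0.05

    def test_chi2_zero_without_yates(self):
        assert pv.chi2_score(self.t, yates=False) == 0.0


class TestZeroCells:
    def test_zero_cell_without_correction_names_the_cell(self):
        with pytest.raises(pv.UndefinedScoreError, match="cell b"):
            pv.ror_score(table(3, 0, 5, 100), correction="none")

    def test_haldane_correction_gives_finite_ror(self):
        ror, _ = pv.ror_score(table(3, 0, 5, 100), correction="haldane")
        assert ror == pytest.approx(3.5 * 100.5 / (0.5 * 5.5))

    def test_degenerate_table_has_finite_regularised_ic(self):
        ic, ic025 = pv.bcpnn_score(table(1, 0, 0, 0))
        assert math.isfinite(ic) and ic025 < ic

    def test_zero_a_gives_zero_ebgm(self):
        assert pv.ebgm_score(table(0, 10, 5, 100)) == (0.0, 0.0)

    def test_zero_margin_chi2_warns_and_is_zero(self):
        with pytest.warns(UserWarning):
            assert pv.chi2_score(table(0, 0, 5, 100)) == 0.0


# ----------------------------------------------------------- oracle sweep

cells = st.integers(min_value=1, max_value=10_000)


@settings(max_examples=1000, derandomize=True, deadline=None)
@given(a=cells, b=cells, c=cells, d=cells)
def test_all_statistics_match_bruteforce_oracle(a, b, c, d):
    t = table(a, b, c, d)
    ror, ror_ci = pv.ror_score(t, correction="none")
    o_ror, o_ci = oracle_ror(a, b, c, d)
    assert ror == pytest.approx(o_ror, rel=1e-9)
    assert ror_ci == pytest.approx(o_ci, rel=1e-9)

    prr, prr_ci = pv.prr_score(t, correction="none")
    o_prr, o_prr_ci = oracle_prr(a, b, c, d)
    assert prr == pytest.approx(o_prr, rel=1e-9)
    assert prr_ci == pytest.approx(o_prr_ci, rel=1e-9)

    for yates in (False, True):
        assert pv.chi2_score(t, yates=yates) == pytest.approx(oracle_chi2(a, b, c, d, yates), rel=1e-9, abs=1e-12)

    ic, ic025 = pv.bcpnn_score(t)
    o_ic, o_ic025 = oracle_bcpnn(a, b, c, d)
    assert ic == pytest.approx(o_ic, rel=1e-9, abs=1e-12)
    assert ic025 == pytest.approx(o_ic025, rel=1e-9, abs=1e-12)

    ebgm, ebgm05 = pv.ebgm_score(t)
    o_ebgm, o_ebgm05 = oracle_ebgm(a, b, c, d)
    assert ebgm == pytest.approx(o_ebgm, rel=1e-9)
    assert ebgm05 == pytest.approx(o_ebgm05, rel=1e-9)
    assert ebgm05 < ebgm


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    base=st.integers(min_value=5, max_value=200),
    shift=st.integers(min_value=1, max_value=50),
)
def test_statistics_increase_with_a_at_fixed_margins(base, shift):
    """Moving mass from the off-diagonal onto `a` (margins fixed) raises
    every statistic and never flips a signal flag from pass to fail."""
    a, b, c, d = base, base + 300, base + 300, base + 3000
    lo = table(a, b, c, d)
    hi = table(a + shift, b - shift, c - shift, d + shift)
    assert pv.ror_score(hi, "none")[0] > pv.ror_score(lo, "none")[0]
    assert pv.prr_score(hi, "none")[0] > pv.prr_score(lo, "none")[0]
    assert pv.bcpnn_score(hi)[0] > pv.bcpnn_score(lo)[0]
    assert pv.ebgm_score(hi)[0] > pv.ebgm_score(lo)[0]
    dec_lo = pv.decide(pv.compute_scores(lo))
    dec_hi = pv.decide(pv.compute_scores(hi))
    for flag in ("pass_ror", "pass_prr", "pass_bcpnn", "pass_ebgm"):
        assert getattr(dec_hi, flag) >= getattr(dec_lo, flag)


def test_ror_ci_covers_one_on_null_poisson_tables():
    """Under the reporting null the Woolf 95% interval should contain 1 in
    about 95% of replicates."""
    rng = np.random.default_rng(7)
    reps = 10_000
    mu = np.array([50.0, 450.0, 500.0, 4500.0])  # ad = bc in expectation
    cells_ = rng.poisson(mu, size=(reps, 4))
    covered = 0
    valid = 0
    for a, b, c, d in cells_:
        if min(a, b, c, d) == 0:
            continue
        valid += 1
        _, (lo, hi) = pv.ror_score(table(int(a), int(b), int(c), int(d)), "none")
        covered += lo <= 1.0 <= hi
    assert valid > reps * 0.99
    assert covered / valid == pytest.approx(0.95, abs=0.02)


# ------------------------------------------------------------- decisions


def scores(a=10, ror_low=2.0, prr_low=2.0, ic025=1.0, ebgm05=3.0):
    return SignalScores(
        a=a, ror=ror_low * 2, ror_ci95=(ror_low, ror_low * 4),
        prr=prr_low * 2, prr_ci95=(prr_low, prr_low * 4),
        chi2=10.0, ic=ic025 + 1, ic025=ic025, ebgm=ebgm05 * 2, ebgm05=ebgm05,
    )


class TestDecide:
    def test_min_count_gate_blocks_ror_and_prr(self):
        dec = pv.decide(scores(a=2))
        assert not dec.pass_ror and not dec.pass_prr
        assert pv.decide(scores(a=3)).pass_ror

    def test_ci_lower_limit_must_exceed_one(self):
        eps = 1e-9
        assert not pv.decide(scores(ror_low=1.0)).pass_ror
        assert pv.decide(scores(ror_low=1.0 + eps)).pass_ror
        assert not pv.decide(scores(prr_low=1.0 - eps)).pass_prr

    def test_ic025_strictly_positive(self):
        eps = 1e-9
        assert not pv.decide(scores(ic025=0.0)).pass_bcpnn
        assert not pv.decide(scores(ic025=-eps)).pass_bcpnn
        assert pv.decide(scores(ic025=eps)).pass_bcpnn

    def test_ebgm05_strictly_above_two(self):
        eps = 1e-9
        assert not pv.decide(scores(ebgm05=2.0)).pass_ebgm
        assert pv.decide(scores(ebgm05=2.0 + eps)).pass_ebgm

    def test_pass_all_is_conjunction(self):
        assert pv.decide(scores()).pass_all
        assert not pv.decide(scores(ic025=-1.0)).pass_all

    def test_independence_table_fails_everything(self):
        dec = pv.decide(pv.compute_scores(table(10, 90, 90, 810)))
        assert not (dec.pass_ror or dec.pass_prr or dec.pass_bcpnn or dec.pass_ebgm)


class TestScoreAll:
    def test_sorted_by_ebgm_descending(self):
        tables = [table(5, 100, 50, 1000, "low"), table(50, 55, 5, 1045, "high"), table(20, 85, 20, 1030, "mid")]
        rows = pv.score_all(tables)
        ebgms = [r.scores.ebgm for r in rows]
        assert ebgms == sorted(ebgms, reverse=True)
        assert [r.event_id for r in rows] == ["high", "mid", "low"]

    def test_equal_ebgm_ties_break_on_event_id(self):
        rows = pv.score_all([table(10, 90, 100, 9900, "zeta"), table(10, 90, 100, 9900, "alpha")])
        assert [r.event_id for r in rows] == ["alpha", "zeta"]

    def test_scores_frame_has_standard_columns(self):
        frame = pv.scores_frame(pv.score_all([table(10, 90, 100, 9900)]))
        expected = {
            "event_id", "level", "a", "b", "c", "d", "ror", "ror_low", "ror_high",
            "prr", "prr_low", "prr_high", "chi2", "ic", "ic025", "ebgm", "ebgm05",
            "pass_ror", "pass_prr", "pass_bcpnn", "pass_ebgm", "pass_all",
        }
        assert set(frame.columns) == expected


def test_priors_must_be_positive():
    with pytest.raises(ValueError):
        pv.BcpnnPriors(alpha1=0.0)


def test_thresholds_validate_min_a():
    with pytest.raises(ValueError):
        pv.Thresholds(min_a=0)
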