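"""Unit and property tests for the 2x2 disproportionality statistics."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, strategies as st

from pvsignal.stats import (
    ContingencyTable2x2,
    RorEstimate,
    bh_adjust,
    fisher_exact_2x2,
    ror_with_ci,
    signal_flag,
)


def brute_force_fisher(a: int, b: int, c: int, d: int) -> float:
    """Independent two-sided Fisher oracle: enumerate every table with the
    observed margins and sum multivariate-hypergeometric point probabilities
    not exceeding the observed one."""
    row1, col1, n = a + b, a + c, a + b + c + d
    if 0 in (row1, col1, n - row1, n - col1):
        return 1.0

    def prob(k: int) -> float:
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    return sum(
        p
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if (p := prob(k)) <= p_obs * (1 + 1e-7)
    )


class TestRorWithCI:
    @pytest.mark.parametrize(
        "table, ror, lo, hi",
        [
            # avelumab- and blinatumomab-scale tables, known to 2 dp
            ((25, 253, 1737, 95552), 5.44, 3.59, 8.22),
            ((59, 185, 1703, 95620), 17.91, 13.31, 24.10),
            # perfectly null table: a/b == c/d
            ((10, 90, 100, 900), 1.00, None, None),
        ],
    )
    def test_known_tables(self, table, ror, lo, hi):
        est = ror_with_ci(table)
        assert est.defined
        assert round(est.ror, 2) == ror
        if lo is not None:
            assert round(est.ci_low, 2) == lo
            assert round(est.ci_high, 2) == hi

    def test_zero_cell_is_undefined_unless_continuity(self):
        est = ror_with_ci((0, 10, 5, 100))
        assert not est.defined and math.isnan(est.ror)
        cc = ror_with_ci((0, 10, 5, 100), continuity=True)
        assert cc.defined and cc.ror > 0

    def test_rejects_negative_or_fractional_counts(self):
        with pytest.raises(ValueError):
            ror_with_ci((-1, 2, 3, 4))
        with pytest.raises(ValueError):
            ror_with_ci((1.5, 2, 3, 4))

    @given(
        st.tuples(*[st.integers(min_value=1, max_value=500)] * 4)
    )
    def test_symmetry(self, table):
        """Transposing the table preserves the ROR; swapping only the rows
        inverts it and swaps+inverts the CI bounds."""
        a, b, c, d = table
        est = ror_with_ci((a, b, c, d))
        transposed = ror_with_ci((a, c, b, d))
        assert transposed.ror == pytest.approx(est.ror, rel=1e-12)
        swapped = ror_with_ci((c, d, a, b))
        assert swapped.ror == pytest.approx(1 / est.ror, rel=1e-12)
        assert swapped.ci_low == pytest.approx(1 / est.ci_high, rel=1e-12)
        assert swapped.ci_high == pytest.approx(1 / est.ci_low, rel=1e-12)

    @given(st.tuples(*[st.integers(min_value=1, max_value=500)] * 4))
    def test_ci_brackets_estimate(self, table):
        est = ror_with_ci(table)
        assert est.ci_low <= est.ror <= est.ci_high


class TestSignalFlag:
    def test_fires_on_elevated_ci_with_enough_cases(self):
        t = ContingencyTable2x2(25, 253, 1737, 95552)
        assert signal_flag(t, ror_with_ci(t)) is True

    def test_single_case_never_signals(self):
        assert signal_flag((1, 0, 10, 100), RorEstimate(9.0, 2.0, 40.0)) is False

    def test_lower_bound_exactly_one_does_not_signal(self):
        assert signal_flag((5, 5, 5, 5), RorEstimate(2.0, 1.0, 4.0)) is False

    def test_undefined_ci_never_signals(self):
        est = ror_with_ci((0, 10, 5, 100))
        assert signal_flag((0, 10, 5, 100), est) is False


class TestFisherExact2x2:
    def test_detection_table_p_value(self):
        assert round(fisher_exact_2x2((9, 5, 1, 10)).p_value, 4) == 0.0119

    def test_zero_margin_gives_one(self):
        assert fisher_exact_2x2((0, 5, 0, 7)).p_value == 1.0

    def test_small_table_matches_enumeration(self):
        p = fisher_exact_2x2((2, 3, 4, 1)).p_value
        assert p == pytest.approx(brute_force_fisher(2, 3, 4, 1), abs=1e-12)

    @given(st.tuples(*[st.integers(min_value=0, max_value=15)] * 4))
    def test_matches_oracle_and_scipy(self, table):
        """Exact agreement with a brute-force enumeration oracle (margins
        <= 30) and with scipy's independent implementation."""
        res = fisher_exact_2x2(table)
        assert res.p_value == pytest.approx(brute_force_fisher(*table), abs=1e-12)
        a, b, c, d = table
        assert res.p_value == pytest.approx(
            scipy.stats.fisher_exact([[a, b], [c, d]])[1], abs=1e-9
        )

    def test_log10_survives_underflow(self):
        # cetuximab-scale counts: p underflows to 0.0 but log10 stays finite
        res = fisher_exact_2x2((591, 4208, 1171, 91597))
        assert res.p_value == 0.0
        assert np.isfinite(res.log10_p) and res.log10_p < -300


def bh_oracle(pvals):
    """Independent hand application of the step-up definition:
    q_(i) = min(1, min_{j>=i} p_(j) * m / j), returned in input order."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    stepped = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    return out


def bh_reject_set(pvals, alpha):
    """The raw BH procedure: reject the k smallest p-values where k is the
    largest rank with p_(k) <= alpha * k / m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    below = np.nonzero(p[order] <= alpha * np.arange(1, m + 1) / m)[0]
    if below.size == 0:
        return set()
    return set(order[: below[-1] + 1])


class TestBHAdjust:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([0.03], [0.03]),
            ([0.02, 0.02, 0.02], [0.02, 0.02, 0.02]),
            # hand application of the step-up rule
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([], []),
        ],
    )
    def test_known_adjustments(self, raw, expected):
        assert list(np.round(bh_adjust(raw), 10)) == expected

    def test_preserves_input_order(self):
        raw = [0.04, 0.001, 0.2]
        adj = bh_adjust(raw)
        assert adj[1] < adj[0] < adj[2]

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=40))
    def test_matches_stepup_oracle_and_monotone(self, pvals):
        adj = bh_adjust(pvals)
        assert np.allclose(adj, bh_oracle(pvals), atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)

    @given(
        st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=40),
        st.floats(min_value=0.01, max_value=0.2),
    )
    def test_thresholding_adjusted_values_reproduces_stepup_decisions(self, pvals, alpha):
        """Rejecting where the adjusted p <= alpha is exactly the BH
        procedure applied to the raw p-values at level alpha."""
        adj = bh_adjust(pvals)
        assert {i for i, q in enumerate(adj) if q <= alpha} == bh_reject_set(pvals, alpha)

    def test_tied_inputs_are_a_fixed_point(self):
        # constant vectors are fixed points of the step-up map
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)
        assert np.allclose(bh_adjust(adj), adj)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])
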