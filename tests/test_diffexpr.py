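from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnakit.diffexpr import (
    LibraryPair,
    ac_pvalue,
    array_significant,
    bh_fdr,
    call_differential,
    intersect_platforms,
    log2_fold_change,
    rpm,
    score_table,
    summarize_calls,
)

PAIR = LibraryPair(10_876_248, 11_194_928)


class TestRpm:
    def test_zero_count(self):
        assert rpm(0, 10**7) == 0.0

    def test_full_library(self):
        assert rpm(10**6, 10**6) == 10**6

    def test_direct_arithmetic(self):
        assert rpm(1011, 10_876_248) == pytest.approx(92.9549, abs=1e-4)

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            rpm(1, 0)


class TestFoldChange:
    def test_printed_value(self):
        assert round(log2_fold_change(41719, 85216, PAIR), 4) == 0.9888

    def test_symmetry_zero(self):
        pair = LibraryPair(10**6, 10**6)
        assert log2_fold_change(123, 123, pair) == 0.0

    def test_antisymmetry(self):
        fc = log2_fold_change(100, 400, PAIR)
        swapped = log2_fold_change(400, 100, LibraryPair(PAIR.n2, PAIR.n1))
        assert fc == pytest.approx(-swapped)

    def test_zero_substitution(self):
        pair = LibraryPair(10**6, 10**6)
        fc = log2_fold_change(0, 100, pair)
        assert fc == pytest.approx(np.log2(rpm(100, 10**6) / 0.01))

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            log2_fold_change(0, 0, PAIR)


def exact_pvalue(x, y, n1, n2):
    """Exact-rational oracle for the two-sided conditional count test.

    Twice the inclusive lower tail of the deficient side, computed with
    Fraction arithmetic: p(k | n) = r^k C(k+n, k) / (1+r)^(k+n+1).
    """
    def lower_tail(c, n, r):
        return sum(r**k * comb(k + n, k) / (1 + r)**(k + n + 1)
                   for k in range(c + 1))
    if Fraction(y, n2) > Fraction(x, n1):
        t = lower_tail(x, y, Fraction(n1, n2))
    else:
        t = lower_tail(y, x, Fraction(n2, n1))
    p = 2 * min(t, 1 - t)
    return min(p, Fraction(1))


class TestAcPvalue:
    def test_printed_value(self):
        assert f"{ac_pvalue(25, 84, PAIR):.3g}" == "1.86e-08"

    def test_near_null_bound(self):
        pair = LibraryPair(1000, 1000)
        assert ac_pvalue(10, 10, pair) >= 0.4

    @pytest.mark.parametrize("x,y,n1,n2", [
        (2, 8, 1000, 1000),
        (0, 5, 1000, 1000),
        (8, 2, 1000, 1000),
        (5, 5, 1000, 2000),
        (30, 70, 5000, 4000),
        (12, 0, 777, 1234),
    ])
    def test_matches_exact_rational_oracle(self, x, y, n1, n2):
        pair = LibraryPair(n1, n2)
        expected = float(exact_pvalue(x, y, n1, n2))
        assert ac_pvalue(x, y, pair) == pytest.approx(expected, rel=1e-12)

    def test_strict_upper_tail_identity(self):
        """2x inclusive deficient lower tail == 2x strict enriched upper tail."""
        n1 = n2 = 1000
        x, y = 2, 8
        r = Fraction(n2, n1)
        upper = 2 * sum(r**k * comb(k + x, k) / (1 + r)**(k + x + 1)
                        for k in range(y + 1, 400))
        assert ac_pvalue(x, y, LibraryPair(n1, n2)) == pytest.approx(
            float(upper), rel=1e-10)

    @given(st.integers(0, 40), st.integers(0, 40),
           st.integers(100, 10000), st.integers(100, 10000))
    @settings(max_examples=100, deadline=None)
    def test_reciprocity(self, x, y, n1, n2):
        a = ac_pvalue(x, y, LibraryPair(n1, n2))
        b = ac_pvalue(y, x, LibraryPair(n2, n1))
        assert a == pytest.approx(b, rel=1e-12)
        assert 0 < a <= 1

    def test_monotone_in_y_away_from_mode(self):
        pair = LibraryPair(10**6, 10**6)
        x = 50
        ps = [ac_pvalue(x, y, pair) for y in range(50, 200, 10)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            ac_pvalue(-1, 5, PAIR)

    def test_type_one_error_quick(self):
        """Null calibration at reduced scale (full 10k in acceptance suite)."""
        rng = np.random.default_rng(0)
        pair = LibraryPair(10**6, 10**6)
        x = rng.poisson(50, 1000)
        y = rng.poisson(50, 1000)
        ps = np.array([ac_pvalue(int(a), int(b), pair) for a, b in zip(x, y)])
        assert (ps < 0.05).mean() <= 0.07


class TestBhFdr:
    def test_hand_applied_formula(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.5])
        assert q == pytest.approx([0.004, 0.02, 0.02 * 4 / 3, 0.5])

    def test_single_p(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])

    def test_all_equal(self):
        assert bh_fdr([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_q_at_least_p_and_capped(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        assert np.all(q <= 1.0)


class TestCallDifferential:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["id", "x", "y"])
        return score_table(df, PAIR)

    def test_printed_row_called_up(self):
        # published-table convention: the columns labelled RPM carry the
        # raw counts, and the RPM>10 gate is applied to those printed
        # values while fc/p are computed from normalized counts
        scored = self._table([("miR-310-3p", 25, 84)])
        scored[["rpm_na", "rpm_da"]] = scored[["x", "y"]].astype(float)
        called = call_differential(scored)
        row = called.iloc[0]
        assert round(row["fc"], 2) == 1.71
        assert row["call"] == "up"

    def test_low_rpm_both_excluded(self):
        # ~0.5 and ~0.8 RPM
        called = call_differential(self._table([("t", 5, 9)]))
        assert called.iloc[0]["call"] == "excluded"

    def test_planted_gates(self):
        """10 rows: 3 pass all up-gates, 2 pass all down-gates, 5 fail one."""
        n1 = n2 = 10**6
        pair = LibraryPair(n1, n2)
        rows = [
            ("up1", 100, 500), ("up2", 200, 900), ("up3", 50, 400),
            ("down1", 500, 100), ("down2", 900, 200),
            ("low_fc", 300, 400),          # |fc| < 1
            ("low_rpm", 4, 9),             # rpm <= 10 both, also weak
            ("flat", 250, 250),            # fc = 0
            ("weak_p", 12, 20),            # fails FDR
            ("excl", 0, 0),                # dropped entirely
        ]
        df = pd.DataFrame([r for r in rows if r[1] + r[2] > 0],
                          columns=["id", "x", "y"])
        called = call_differential(score_table(df, pair))
        summary = summarize_calls(called)
        assert summary["up"] == 3
        assert summary["down"] == 2


ARRAY_COLS = ["id", "signal_na", "signal_da", "fc", "q"]


class TestIntersectPlatforms:
    def test_empty_array_table(self):
        seq = pd.DataFrame({"id": ["a"], "fc": [2.0], "call": ["up"]})
        arr = pd.DataFrame(columns=ARRAY_COLS)
        assert intersect_platforms(seq, arr) == []

    def test_opposite_signs_excluded(self):
        seq = pd.DataFrame({"id": ["a"], "fc": [2.0], "call": ["up"]})
        arr = pd.DataFrame([["a", 600, 900, -2.0, 0.001]], columns=ARRAY_COLS)
        assert intersect_platforms(seq, arr) == []

    def test_concordant_kept(self):
        seq = pd.DataFrame({"id": ["a", "b"], "fc": [2.0, -2.0],
                            "call": ["up", "down"]})
        arr = pd.DataFrame([["a", 600, 900, 1.5, 0.001],
                            ["b", 600, 900, -1.5, 0.001]], columns=ARRAY_COLS)
        assert intersect_platforms(seq, arr) == ["a", "b"]

    def test_array_criteria(self):
        arr = pd.DataFrame([
            ["low_signal", 100, 400, 2.0, 0.001],
            ["low_fc", 600, 900, 0.5, 0.001],
            ["high_fdr", 600, 900, 2.0, 0.02],
            ["ok", 600, 900, 2.0, 0.001],
        ], columns=ARRAY_COLS)
        assert list(arr[array_significant(arr)]["id"]) == ["ok"]

    def test_id_on_one_platform_only(self):
        seq = pd.DataFrame({"id": ["a"], "fc": [2.0], "call": ["up"]})
        arr = pd.DataFrame([["b", 600, 900, 2.0, 0.001]], columns=ARRAY_COLS)
        assert intersect_platforms(seq, arr) == []
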