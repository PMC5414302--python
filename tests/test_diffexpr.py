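"""Exact count test, NE rules, fold change, FDR, and DE status assembly."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ac_oracle_tails, ac_oracle_two_sided
from lactamir.diffexpr import (
    DEParams,
    STATUS_DOWN,
    STATUS_EXCLUDED,
    STATUS_UNCHANGED,
    STATUS_UP,
    ac_pvalue,
    ac_tails,
    apply_ne_rules,
    bh_fdr,
    fold_change,
    normalize,
    run_de,
)


class TestNormalize:
    @pytest.mark.parametrize(
        "x,total,expected",
        [(100, 1_000_000, 100.0), (0, 10_000_000, 0.0), (12, 12_000_000, 1.0)],
    )
    def test_reads_per_million(self, x, total, expected):
        assert normalize(x, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize(5, 0)


class TestNeRules:
    def test_zero_substituted(self):
        assert apply_ne_rules(0, 250) == (0.001, 250, True)

    def test_both_below_three_excluded(self):
        assert apply_ne_rules(2.5, 2.9)[2] is False

    def test_one_at_boundary_kept(self):
        assert apply_ne_rules(2.5, 3.0)[2] is True

    def test_exclusion_judged_before_substitution(self):
        # a (0, 0) pair must be excludable despite the zero substitution
        ne1, ne2, keep = apply_ne_rules(0.0, 0.0)
        assert keep is False and ne1 == ne2 == 0.001


class TestFoldChange:
    @pytest.mark.parametrize(
        "ne1,ne2,expected", [(8, 2, 2.0), (5, 5, 0.0), (1000, 0.001, math.log2(1e6))]
    )
    def test_log2_ratio(self, ne1, ne2, expected):
        assert fold_change(ne1, ne2) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0, 5)


class TestAcPvalue:
    def test_lower_tail_one_in_sixtyfour(self):
        lower, _upper, _p = ac_tails(5, 0, 1000, 1000)
        assert lower == pytest.approx(1 / 64, abs=1e-12)
        assert ac_pvalue(5, 0, 1000, 1000) == pytest.approx(1 / 32, abs=1e-12)

    def test_symmetric_case_exact_half(self):
        lower, _upper, _p = ac_tails(3, 3, 500, 500)
        assert lower == pytest.approx(0.5, abs=1e-12)
        assert ac_pvalue(3, 3, 500, 500) == 1.0

    def test_double_zero_closed_form(self):
        # single-term lower tail p(0|0) = N1/(N1+N2)
        n1, n2 = 300, 700
        lower, upper, p = ac_tails(0, 0, n1, n2)
        assert lower == pytest.approx(n1 / (n1 + n2), abs=1e-12)
        assert upper == pytest.approx(1.0, abs=1e-12)
        expected = min(1.0, 2 * min(n1 / (n1 + n2), 1.0))
        assert ac_pvalue(0, 0, n1, n2) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(1000, 500), (1000, 1000), (500, 1000)])
    def test_matches_exact_rational_oracle_small_grid(self, n1, n2):
        for x in range(0, 26, 5):
            for y in range(0, 26, 5):
                expected = float(ac_oracle_two_sided(x, y, n1, n2))
                assert ac_pvalue(x, y, n1, n2) == pytest.approx(expected, abs=1e-12)

    def test_one_sided_returns_smaller_tail(self):
        lower, upper, _p = ac_tails(5, 0, 1000, 1000)
        assert ac_pvalue(5, 0, 1000, 1000, sided="one") == pytest.approx(
            min(lower, upper), abs=1e-14
        )

    @pytest.mark.parametrize("bad", [(-1, 0), (0.5, 1), (2, -3)])
    def test_non_integer_or_negative_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            ac_pvalue(bad[0], bad[1], 100, 100)

    @settings(deadline=None, max_examples=150)
    @given(
        x=st.integers(0, 120),
        y=st.integers(0, 120),
        n1=st.integers(50, 5000),
        n2=st.integers(50, 5000),
    )
    def test_tails_partition_probability(self, x, y, n1, n2):
        """C + D = 1 + p(y|x): both tails include the observed point."""
        lower, upper, p = ac_tails(x, y, n1, n2)
        assert lower + upper == pytest.approx(1.0 + p, abs=1e-10)
        assert 0.0 <= ac_pvalue(x, y, n1, n2) <= 1.0

    @settings(deadline=None, max_examples=100)
    @given(x=st.integers(0, 80), y=st.integers(0, 80), pair=st.sampled_from(
        [(1000, 1000), (1000, 2000), (1500, 750)]))
    def test_swap_relationship(self, x, y, pair):
        """Swapping libraries shifts each tail by exactly one pmf term:
        D(x,y,N1,N2 swapped) = C(y|x) + p_swap, so the doubled-tail
        two-sided p differs by at most twice the larger pmf term."""
        n1, n2 = pair
        lower, upper, p = ac_tails(x, y, n1, n2)
        s_lower, s_upper, s_p = ac_tails(y, x, n2, n1)
        assert s_upper == pytest.approx(lower + s_p, abs=1e-10)
        diff = abs(ac_pvalue(x, y, n1, n2) - ac_pvalue(y, x, n2, n1))
        assert diff <= 2 * max(p, s_p) + 1e-10

    def test_p_decreases_with_imbalance_along_ray(self):
        """With x+y fixed, p falls monotonically as x*N2 - y*N1 grows."""
        n1 = n2 = 1_000_000
        total = 60
        ps = [ac_pvalue(x, total - x, n1, n2) for x in range(total // 2, total + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.01]).tolist() == [0.01]

    def test_hand_applied_step_up(self):
        # ranks 1..4: min_j>=i (p_(j) * 4 / j) = 0.04 for every rank
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_empty(self):
        assert bh_fdr([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_stable_under_permutation(self, ps, rnd):
        order = list(range(len(ps)))
        rnd.shuffle(order)
        direct = bh_fdr(ps)
        permuted = bh_fdr([ps[i] for i in order])
        for out_pos, in_pos in enumerate(order):
            assert permuted[out_pos] == pytest.approx(direct[in_pos], abs=1e-12)


def _table(rows, n1, n2):
    df = pd.DataFrame(rows, columns=["mirna_id", "count_1", "count_2"]).set_index(
        "mirna_id"
    )
    df.attrs["N1"], df.attrs["N2"] = n1, n2
    return df


class TestRunDe:
    def test_equal_counts_unchanged(self):
        de = run_de(_table([("m1", 500, 500)], 10_000, 10_000))
        assert de.at["m1", "status"] == STATUS_UNCHANGED

    def test_all_low_ne_excluded(self):
        de = run_de(_table([("m1", 1, 2), ("m2", 0, 1)], 10**6, 10**6))
        assert (de["status"] == STATUS_EXCLUDED).all()
        assert de["p_value"].isna().all()

    def test_status_partition_covers_table(self, small_run):
        _cfg, result, _truth = small_run
        statuses = result.de["status"].value_counts()
        assert statuses.sum() == len(result.de)
        assert set(statuses.index) <= {
            STATUS_UP, STATUS_DOWN, STATUS_UNCHANGED, STATUS_EXCLUDED
        }

    def test_every_branch_of_the_filters(self):
        """Zero substitution, low-NE exclusion, |log2fc|=1 boundary, both calls."""
        n = 10**6
        rows = [
            ("m_zero_down", 0, 250),     # 0 -> 0.001, huge negative fc: down
            ("m_excluded", 2, 2),        # NE < 3 in both: excluded
            ("m_boundary", 1000, 2000),  # log2fc exactly -1: not < -1
            ("m_up", 4000, 1000),        # log2fc = +2, tiny p: up
            ("m_null", 1000, 1000),      # unchanged
        ]
        de = run_de(_table(rows, n, n))
        assert de.at["m_zero_down", "NE1"] == 0.001
        assert de.at["m_zero_down", "status"] == STATUS_DOWN
        assert de.at["m_excluded", "status"] == STATUS_EXCLUDED
        assert de.at["m_boundary", "log2fc"] == pytest.approx(-1.0)
        assert de.at["m_boundary", "status"] == STATUS_UNCHANGED
        assert de.at["m_up", "status"] == STATUS_UP
        assert de.at["m_null", "status"] == STATUS_UNCHANGED

    def test_fdr_computed_over_kept_mirnas_only(self):
        n = 10**6
        rows = [("m_excl", 1, 1)] + [(f"m{i}", 100, 100) for i in range(4)]
        de = run_de(_table(rows, n, n))
        kept = de.dropna(subset=["p_value"])
        assert len(kept) == 4
        assert np.allclose(
            np.sort(kept["fdr"]), np.sort(bh_fdr(kept["p_value"].tolist()))
        )

    def test_sorted_by_p_then_effect(self, small_run):
        _cfg, result, _truth = small_run
        ps = result.de["p_value"].dropna()
        assert ps.is_monotonic_increasing

    def test_planted_effects_recovered(self, small_run):
        cfg, result, _truth = small_run
        # effects scale library 2, so a positive planted effect is a "down"
        # call on the library-1-over-library-2 fold change
        assert result.de.at["syn-mir-0005", "status"] == STATUS_DOWN
        assert result.de.at["syn-mir-0010", "status"] == STATUS_UP
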