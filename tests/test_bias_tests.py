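"""Exact binomial kernel and the four support/hemiplasy tests."""

import itertools
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from blindtree import (
    InsertionCount,
    RatioCount,
    UNOBSERVABLE,
    binomial_upper_tail,
    format_p,
    ils_symmetry,
    insertion_ratio_test,
    kksc_multi,
    kksc_onedir,
    max_introgressed_markers,
    round_p,
)
from blindtree.errors import (
    InvalidArgumentError,
    UndefinedTestError,
    WrongTestError,
)


def enumerate_upper_tail(n, k, p):
    """Independent oracle: weighted enumeration over all 2^n outcome sequences."""
    p = Fraction(p)
    total = Fraction(0)
    for seq in itertools.product((0, 1), repeat=n):
        if sum(seq) >= k:
            weight = Fraction(1)
            for s in seq:
                weight *= p if s else (1 - p)
            total += weight
    return total


class TestBinomialUpperTail:
    @pytest.mark.parametrize(
        "n, k, p, expected",
        [
            (3, 2, Fraction(1, 3), Fraction(7, 27)),  # ~0.2593
            (5, 0, Fraction(1, 2), Fraction(1)),
            (8, 6, Fraction(1, 5), Fraction(481, 390625)),  # 0.00123136 by enumeration
        ],
    )
    def test_reference_values(self, n, k, p, expected):
        assert binomial_upper_tail(n, k, p) == expected

    def test_matches_enumeration_oracle(self):
        for p in (Fraction(1, 5), Fraction(1, 3), Fraction(1, 2)):
            for n in range(0, 13):
                for k in range(0, n + 2):
                    exact = binomial_upper_tail(n, k, p)
                    oracle = enumerate_upper_tail(n, k, p)
                    assert exact == oracle  # rational arithmetic: identical

    def test_matches_scipy_survival_function(self):
        # independent float route: sf(k-1) = P(X >= k)
        for n, k, p in [(10, 4, 0.3), (25, 20, 0.5), (7, 7, 0.2)]:
            assert float(binomial_upper_tail(n, k, p)) == pytest.approx(
                stats.binom.sf(k - 1, n, p), rel=1e-12
            )

    @pytest.mark.parametrize(
        "n, k, p",
        [(-1, 0, 0.5), (3, -1, 0.5), (3, 5, 0.5), (2.5, 1, 0.5), (3, 1, 0.0), (3, 1, 1.0)],
    )
    def test_invalid_arguments(self, n, k, p):
        with pytest.raises(InvalidArgumentError):
            binomial_upper_tail(n, k, p)

    def test_float_probability_means_its_decimal_literal(self):
        assert binomial_upper_tail(2, 2, 0.2) == Fraction(1, 25)


class TestKksc:
    @pytest.mark.parametrize(
        "count, expected",
        [
            ((2, 1, 0), Fraction(7, 27)),     # 0.2593
            ((3, 0, 0), Fraction(1, 27)),     # 0.0370
            ((5, 2, 0), Fraction(99, 2187)),  # 0.0453, printed-table cell
        ],
    )
    def test_multi_directional(self, count, expected):
        result = kksc_multi(InsertionCount(*count))
        assert result.p_value == expected
        assert result.tail == "upper"

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (2, 1, Fraction(1, 2)),
            (6, 1, Fraction(1, 16)),   # 0.0625
            (1, 1, Fraction(3, 4)),    # 0.75
            (11, 2, Fraction(92, 8192)),  # 0.0112 with ambiguous markers added
        ],
    )
    def test_one_directional(self, a, b, expected):
        result = kksc_onedir(InsertionCount(a, b, UNOBSERVABLE))
        assert result.p_value == expected

    def test_wrong_test_errors_point_to_the_other_test(self):
        with pytest.raises(WrongTestError, match="kksc_onedir"):
            kksc_multi(InsertionCount(2, 1, UNOBSERVABLE))
        with pytest.raises(WrongTestError, match="kksc_multi"):
            kksc_onedir(InsertionCount(2, 1, 0))

    def test_unopposed_count_is_half_power(self):
        for a in range(1, 10):
            assert kksc_onedir(InsertionCount(a, 0)).p_value == Fraction(1, 2**a)


class TestIlsSymmetry:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (8, 1, Fraction(20, 512)),   # 0.0391
            (6, 6, Fraction(1)),
            (9, 1, Fraction(22, 1024)),  # 0.0215
            (8, 0, Fraction(2, 256)),    # 0.0078
            (4, 0, Fraction(2, 16)),     # 0.1250
        ],
    )
    def test_worked_examples(self, a, b, expected):
        result = ils_symmetry(a, b)
        assert result.p_value == expected
        assert result.tail == "two_tailed"

    def test_undefined_for_no_markers(self):
        with pytest.raises(UndefinedTestError):
            ils_symmetry(0, 0)

    @given(a=st.integers(0, 40), b=st.integers(0, 40))
    @settings(derandomize=True, max_examples=150)
    def test_symmetric_and_doubles_the_onedir_tail(self, a, b):
        if a + b == 0:
            return
        p_ab = ils_symmetry(a, b).p_value
        assert p_ab == ils_symmetry(b, a).p_value
        if a == b:
            assert p_ab == 1
        one_dir = kksc_onedir(InsertionCount(max(a, b), min(a, b))).p_value
        assert p_ab == min(Fraction(1), 2 * one_dir)


class TestInsertionRatio:
    @pytest.mark.parametrize(
        "d, e, gamma, p, n_bound",
        [
            (6, 2, "1/2", Fraction(37, 256), Fraction(4)),       # 0.1445
            (6, 2, "0.2", Fraction(481, 390625), Fraction(8, 5)),  # 0.0012, N = 1.6
            (8, 0, "1/2", Fraction(1, 256), Fraction(4)),        # 0.0039
            (4, 0, "0.2", Fraction(1, 625), Fraction(4, 5)),     # 0.0016
        ],
    )
    def test_worked_examples(self, d, e, gamma, p, n_bound):
        result = insertion_ratio_test(RatioCount(d, e), gamma)
        assert result.p_value == p
        assert result.n_bound == n_bound

    def test_unopposed_shared_count_is_gamma_power(self):
        for d in range(1, 8):
            assert insertion_ratio_test(RatioCount(d, 0), "0.2").p_value == Fraction(1, 5) ** d

    def test_bound_is_linear_in_total(self):
        assert max_introgressed_markers(RatioCount(0, 5), "0.3") == Fraction(3, 2)

    @pytest.mark.parametrize("gamma", [0, 1, -0.1, "5/4"])
    def test_gamma_outside_unit_interval(self, gamma):
        with pytest.raises(InvalidArgumentError):
            insertion_ratio_test(RatioCount(3, 1), gamma)


class TestMonotonicity:
    @given(a=st.integers(0, 25), b=st.integers(0, 25))
    @settings(derandomize=True, max_examples=100)
    def test_more_support_never_weakens_the_onedir_test(self, a, b):
        if a + b == 0:
            return
        p1 = kksc_onedir(InsertionCount(a, b)).p_value
        p2 = kksc_onedir(InsertionCount(a + 1, b)).p_value
        assert p2 <= p1

    @given(d=st.integers(0, 25), e=st.integers(0, 25))
    @settings(derandomize=True, max_examples=100)
    def test_more_shared_markers_never_weaken_the_ratio_test(self, d, e):
        if d + e == 0:
            return
        g = Fraction(1, 2)
        p1 = insertion_ratio_test(RatioCount(d, e), g).p_value
        p2 = insertion_ratio_test(RatioCount(d + 1, e), g).p_value
        assert p2 <= p1

    @given(d=st.integers(1, 20), e=st.integers(0, 20))
    @settings(derandomize=True, max_examples=100)
    def test_ratio_p_value_nondecreasing_in_gamma(self, d, e):
        gammas = [Fraction(1, 10), Fraction(1, 5), Fraction(1, 2), Fraction(4, 5)]
        ps = [insertion_ratio_test(RatioCount(d, e), g).p_value for g in gammas]
        assert ps == sorted(ps)


class TestFormatting:
    def test_four_decimal_rounding_is_half_up(self):
        assert round_p(Fraction(1, 32)) == 0.0313
        assert round_p(Fraction(22, 64)) == 0.3438
        assert round_p(Fraction(7, 27)) == 0.2593

    def test_tiny_values_print_as_a_bound(self):
        assert format_p(Fraction(481, 390625)) == "0.0012"
        assert format_p(Fraction(1, 62500)) == "<0.0001"
        assert format_p(Fraction(1, 625)) == "0.0016"
        assert format_p(Fraction(1, 2)) == "0.5000"


class TestCountContainers:
    def test_parse_accepts_brackets_commas_and_blind_synonyms(self):
        for text in ("[6 1 X]", "6,1,x", "6 1 ?"):
            c = InsertionCount.parse(text)
            assert (c.support_t1, c.support_t2, c.blind) == (6, 1, True)
        assert not InsertionCount.parse("3 0 0").blind
        assert RatioCount.parse("(6,2)") == RatioCount(6, 2)

    def test_canonicalize_reports_the_swap(self):
        swapped, was_swapped = InsertionCount(1, 5).canonicalized()
        assert was_swapped and swapped.support_t1 == 5
        same, was_swapped = InsertionCount(5, 1).canonicalized()
        assert not was_swapped and same.support_t1 == 5

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            InsertionCount(-1, 0)
        with pytest.raises(InvalidArgumentError):
            RatioCount(1, -2)
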