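"""Exact cumulative-binomial tests for retrotransposon insertion counts.

Four tests share one kernel, the exact upper tail of a binomial distribution,
computed in rational arithmetic so that the published 4-decimal tables are
reproduced without float summation error:

* ``kksc_multi``  — multi-directional KKSC test: all three resolutions of a
  trichotomy are observable, each marker falls on the tested topology with
  probability 1/3.
* ``kksc_onedir`` — one-directional KKSC test: markers for the topology that
  excludes the reference genome are unobservable ("blind" tree); testing is
  binary with success probability 1/2.
* ``ils_symmetry`` — two-tailed symmetry test of the hypothesis that the blind
  tree is the species tree and the observable markers are hemiplasy from
  incomplete lineage sorting, which distributes discordant markers roughly
  symmetrically between the two non-species trees.
* ``insertion_ratio_test`` — upper-tail test of the hypothesis that the blind
  tree is the species tree and the observable markers were donated by
  introgression sharing a fraction ``gamma`` of the genome; the number of
  shared markers ``d`` among ``d + e`` candidates is binomial with success
  probability at most ``gamma``, giving the conservative bound
  ``N = gamma * (d + e)`` on the expected introgressed markers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction

from .counts import InsertionCount, RatioCount, UNOBSERVABLE
from .errors import InvalidArgumentError, UndefinedTestError, WrongTestError

log = logging.getLogger("blindtree.tests")

KKSC_MULTI = "KKSC_MULTI"
KKSC_ONEDIR = "KKSC_ONEDIR"
ILS_SYMMETRY = "ILS_SYMMETRY"
INSERTION_RATIO = "INSERTION_RATIO"

UPPER = "upper"
TWO_TAILED = "two_tailed"


def as_fraction(p) -> Fraction:
    """Convert a probability to an exact Fraction.

    Floats are interpreted through their shortest decimal repr (so 0.2 means
    exactly 1/5, not the nearest binary double); strings like ``"1/3"`` or
    ``"0.2"`` are accepted directly.
    """
    if isinstance(p, Fraction):
        return p
    if isinstance(p, int):
        return Fraction(p)
    if isinstance(p, float):
        return Fraction(repr(p))
    if isinstance(p, str):
        return Fraction(p)
    raise InvalidArgumentError(f"cannot interpret probability {p!r}")


def binomial_upper_tail(n: int, k: int, p) -> Fraction:
    """Exact P(X >= k) for X ~ Binomial(n, p).

    ``k = 0`` returns 1 and ``k = n + 1`` returns 0.  The result is an exact
    rational; callers round only for display.
    """
    if not isinstance(n, int) or isinstance(n, bool) or n < 0:
        raise InvalidArgumentError(f"n must be a non-negative integer, got {n!r}")
    if not isinstance(k, int) or isinstance(k, bool) or k < 0 or k > n + 1:
        raise InvalidArgumentError(f"k must be an integer in [0, n+1], got {k!r}")
    pf = as_fraction(p)
    if not (0 < pf < 1):
        raise InvalidArgumentError(f"p must lie strictly in (0, 1), got {p!r}")
    if k == 0:
        return Fraction(1)
    q = 1 - pf
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * pf**i * q ** (n - i)
    return total


def round_p(p: Fraction, decimals: int = 4) -> float:
    """Round an exact probability half-up to the given decimals (report scale)."""
    d = Decimal(p.numerator) / Decimal(p.denominator * 1)
    quantum = Decimal(1).scaleb(-decimals)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def format_p(p: Fraction, decimals: int = 4) -> str:
    """Format a p-value the way the report tables print it.

    Values that round to zero at the requested precision are printed as a
    bound, e.g. ``<0.0001``; everything else with fixed decimals.
    """
    floor = Fraction(1, 2 * 10**decimals)  # rounds to 0.0000
    if p < floor:
        return "<" + f"{10**-decimals:.{decimals}f}"
    return f"{round_p(p, decimals):.{decimals}f}"


@dataclass(frozen=True)
class TestResult:
    """Outcome of one named test on one count."""

    test_id: str
    input_count: InsertionCount | RatioCount
    p_value: Fraction
    tail: str
    gamma: Fraction | None = None
    n_bound: Fraction | None = None

    @property
    def p_float(self) -> float:
        return float(self.p_value)

    def formatted(self, decimals: int = 4) -> str:
        return format_p(self.p_value, decimals)

    def __post_init__(self):
        if not (0 <= self.p_value <= 1):
            raise InvalidArgumentError(f"p_value {self.p_value} outside [0, 1]")


def _log_result(result: TestResult):
    log.info(
        "test=%s count=%s gamma=%s p=%s (%s)",
        result.test_id,
        result.input_count,
        result.gamma,
        result.p_value,
        result.tail,
    )


def kksc_multi(count: InsertionCount) -> TestResult:
    """Multi-directional KKSC test: P(X >= a) with X ~ Binomial(a+b+c, 1/3).

    Requires all three slots observed; the tested topology is slot 1.
    """
    if count.blind:
        raise WrongTestError(
            "third slot is unobservable; use kksc_onedir for one-directional counts"
        )
    if count.total < 1:
        raise UndefinedTestError("at least one marker is required")
    p = binomial_upper_tail(count.total, count.support_t1, Fraction(1, 3))
    result = TestResult(KKSC_MULTI, count, p, UPPER)
    _log_result(result)
    return result


def kksc_onedir(count: InsertionCount) -> TestResult:
    """One-directional KKSC test: P(X >= a) with X ~ Binomial(a+b, 1/2).

    Requires the blind third slot (single-reference regime).
    """
    if not count.blind:
        raise WrongTestError(
            "all three slots are observed; use kksc_multi for multi-directional counts"
        )
    n = count.support_t1 + count.support_t2
    if n < 1:
        raise UndefinedTestError("at least one observable marker is required")
    p = binomial_upper_tail(n, count.support_t1, Fraction(1, 2))
    result = TestResult(KKSC_ONEDIR, count, p, UPPER)
    _log_result(result)
    return result


def ils_symmetry(count_t1: int, count_t2: int) -> TestResult:
    """Two-tailed ILS symmetry test on the two observable-topology counts.

    Under the null (blind tree true, observable markers are ILS hemiplasy) the
    split of a+b markers between the two observable trees is Binomial(a+b, 1/2);
    the p-value doubles the upper tail at max(a, b), capped at 1.  The result
    is independent of the unobservable blind-slot count.
    """
    for name, v in (("count_t1", count_t1), ("count_t2", count_t2)):
        if not isinstance(v, int) or isinstance(v, bool) or v < 0:
            raise InvalidArgumentError(f"{name} must be a non-negative integer, got {v!r}")
    n = count_t1 + count_t2
    if n < 1:
        raise UndefinedTestError("ILS symmetry test undefined for (0, 0)")
    tail = binomial_upper_tail(n, max(count_t1, count_t2), Fraction(1, 2))
    p = min(Fraction(1), 2 * tail)
    result = TestResult(
        ILS_SYMMETRY, InsertionCount(count_t1, count_t2, UNOBSERVABLE), p, TWO_TAILED
    )
    _log_result(result)
    return result


def max_introgressed_markers(count: RatioCount, gamma) -> Fraction:
    """Upper bound N = gamma * (d + e) on expected introgression-shared markers.

    The true expectation is beta*gamma with beta the donor-stem insertions
    before the gene-flow event; N maximises it over the unobservable beta and
    pre/post-event split, which makes the ratio test conservative.
    """
    g = as_fraction(gamma)
    if not (0 < g < 1):
        raise InvalidArgumentError(f"gamma must lie strictly in (0, 1), got {gamma!r}")
    return g * count.total


def insertion_ratio_test(count: RatioCount, gamma) -> TestResult:
    """Insertion ratio test: P(X >= d) with X ~ Binomial(d+e, gamma).

    Rejects the hypothesis that introgression sharing a genome fraction
    ``gamma`` contributed the markers supporting the observed reference-sister
    clade, when the shared count d is improbably high.
    """
    g = as_fraction(gamma)
    if not (0 < g < 1):
        raise InvalidArgumentError(f"gamma must lie strictly in (0, 1), got {gamma!r}")
    if count.total < 1:
        raise UndefinedTestError("insertion ratio test needs d + e >= 1")
    p = binomial_upper_tail(count.total, count.shared, g)
    result = TestResult(
        INSERTION_RATIO,
        count,
        p,
        UPPER,
        gamma=g,
        n_bound=max_introgressed_markers(count, g),
    )
    _log_result(result)
    return result
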