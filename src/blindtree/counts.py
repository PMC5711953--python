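"""Insertion-count containers for trichotomy tests.

A trichotomy (three competing resolutions of a 3-way split) is summarised by
the number of unambiguous markers supporting each resolution, written
``[a b c]``.  When markers were ascertained in a single reference genome, the
resolution that excludes the reference taxon is *unobservable* ("blind") and
its slot is written ``X``: the count becomes ``[a b X]``.

The insertion ratio test instead uses a ``(d, e)`` pair: *d* markers support
the clade joining the reference lineage with its hypothesised sister, and *e*
markers sit on the next shallower branch that contains only the reference
side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import FormatError, InvalidArgumentError


class _Unobservable:
    """Sentinel for the blind (unobservable) slot of an insertion count."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):  # pragma: no cover - cosmetic
        return "X"


#: Sentinel marking the blind slot, printed ``X``.
UNOBSERVABLE = _Unobservable()


def _check_count(value, name):
    if not isinstance(value, int) or isinstance(value, bool) or value < 0:
        raise InvalidArgumentError(f"{name} must be a non-negative integer, got {value!r}")
    return value


@dataclass(frozen=True)
class InsertionCount:
    """Marker tallies ``[a b c]`` (or ``[a b X]``) for a trichotomy.

    ``support_t1`` is the count for the topology under test; the library never
    silently reorders slots (the caller decides which hypothesis is T1 — see
    :meth:`canonicalized`).
    """

    support_t1: int
    support_t2: int
    support_t3: int | _Unobservable = UNOBSERVABLE

    def __post_init__(self):
        _check_count(self.support_t1, "support_t1")
        _check_count(self.support_t2, "support_t2")
        if self.support_t3 is not UNOBSERVABLE:
            _check_count(self.support_t3, "support_t3")
        # an all-zero count is representable (empty tallies occur); the tests
        # themselves refuse it

    # -- properties ---------------------------------------------------------
    @property
    def blind(self) -> bool:
        """True when the third resolution is unobservable."""
        return self.support_t3 is UNOBSERVABLE

    @property
    def total(self) -> int:
        return self.support_t1 + self.support_t2 + (0 if self.blind else self.support_t3)

    def canonicalized(self) -> tuple["InsertionCount", bool]:
        """Return (count with t1 >= t2, whether slots were swapped).

        The swap is reported, never applied silently: Table-style reports test
        a specific prior hypothesis, which need not be the best supported one.
        """
        if self.support_t2 > self.support_t1:
            return (
                InsertionCount(self.support_t2, self.support_t1, self.support_t3),
                True,
            )
        return self, False

    def __str__(self) -> str:
        third = "X" if self.blind else str(self.support_t3)
        return f"[{self.support_t1} {self.support_t2} {third}]"

    @classmethod
    def parse(cls, text: str) -> "InsertionCount":
        """Parse ``"[6 1 X]"``, ``"6 1 X"``, ``"6,1,x"`` or ``"6 1 ?"``."""
        raw = text.strip().strip("[]")
        parts = [p for p in re.split(r"[,\s]+", raw) if p]
        if len(parts) != 3:
            raise FormatError(f"count string needs three slots, got {text!r}")
        vals = []
        for i, p in enumerate(parts):
            if i == 2 and p.lower() in {"x", "?"}:
                vals.append(UNOBSERVABLE)
                continue
            try:
                vals.append(int(p))
            except ValueError as exc:
                raise FormatError(f"bad count slot {p!r} in {text!r}") from exc
        return cls(*vals)


@dataclass(frozen=True)
class RatioCount:
    """The ``(d, e)`` pattern on successive reference-lineage branches.

    ``shared`` (*d*): markers supporting the clade joining the reference
    lineage and its hypothesised sister.  ``exclusive`` (*e*): markers on the
    next shallower branch containing only the reference side.
    """

    shared: int
    exclusive: int

    def __post_init__(self):
        _check_count(self.shared, "shared (d)")
        _check_count(self.exclusive, "exclusive (e)")

    @property
    def total(self) -> int:
        return self.shared + self.exclusive

    def __str__(self) -> str:
        return f"({self.shared},{self.exclusive})"

    @classmethod
    def parse(cls, text: str) -> "RatioCount":
        """Parse ``"(6,2)"`` or ``"6 2"``."""
        raw = text.strip().strip("()")
        parts = [p for p in re.split(r"[,\s]+", raw) if p]
        if len(parts) != 2:
            raise FormatError(f"ratio string needs two slots, got {text!r}")
        try:
            d, e = (int(p) for p in parts)
        except ValueError as exc:
            raise FormatError(f"bad ratio slot in {text!r}") from exc
        return cls(d, e)
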