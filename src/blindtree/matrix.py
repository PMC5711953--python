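"""Presence/absence marker matrices.

Rows are taxa, columns are marker loci; each cell is PRESENT, ABSENT or
MISSING.  On disk the matrix is a delimited table with the taxon label in the
first column and locus identifiers in the header; cells use ``+ - ?`` (or the
``1 0 NA`` synonyms).  Polymorphic/heterozygous calls (``p``) are coded
PRESENT for counting, with a warning, since the insertion is demonstrably in
the lineage.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, MappingError

log = logging.getLogger("blindtree.matrix")

PRESENT = "+"
ABSENT = "-"
MISSING = "?"

#: Accepted cell spellings -> canonical state.
STATE_SYNONYMS = {
    "+": PRESENT,
    "1": PRESENT,
    "present": PRESENT,
    "-": ABSENT,
    "0": ABSENT,
    "absent": ABSENT,
    "?": MISSING,
    "": MISSING,
    "na": MISSING,
    "nan": MISSING,
    "missing": MISSING,
    # polymorphic: the insertion exists in the lineage but is not fixed
    "p": PRESENT,
}


@dataclass
class MarkerMatrix:
    """Taxa x loci presence/absence calls.

    ``calls`` maps ``(taxon, locus)`` implicitly through a DataFrame of the
    canonical one-character states.  Taxon labels and locus ids are unique and
    ordered.
    """

    data: pd.DataFrame  # index: taxa, columns: loci, values in {+,-,?}
    polymorphic: set = field(default_factory=set)  # (taxon, locus) coded + with warning

    def __post_init__(self):
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate taxon labels: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate locus identifiers: {dups}")
        bad = set(self.data.values.ravel()) - {PRESENT, ABSENT, MISSING}
        if bad:
            raise FormatError(f"unknown state symbols {sorted(bad)}")

    # -- basic accessors ----------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(self.data.columns)

    def call(self, taxon: str, locus: str) -> str:
        return self.data.at[taxon, locus]

    def column(self, locus: str) -> dict[str, str]:
        if locus not in self.data.columns:
            raise KeyError(f"locus {locus!r} not in matrix")
        return self.data[locus].to_dict()

    def state_sets(self, locus: str) -> tuple[frozenset, frozenset, frozenset]:
        """(present, absent, missing) taxon sets for one locus."""
        col = self.column(locus)
        present = frozenset(t for t, s in col.items() if s == PRESENT)
        absent = frozenset(t for t, s in col.items() if s == ABSENT)
        missing = frozenset(t for t, s in col.items() if s == MISSING)
        return present, absent, missing

    def state_counts(self) -> dict[str, int]:
        flat = pd.Series(self.data.values.ravel())
        return {
            "present": int((flat == PRESENT).sum()),
            "absent": int((flat == ABSENT).sum()),
            "missing": int((flat == MISSING).sum()),
        }

    def require_taxa(self, taxa) -> None:
        missing = sorted(set(taxa) - set(self.taxa))
        if missing:
            raise MappingError(f"taxa absent from matrix: {missing}")

    # -- construction -------------------------------------------------------
    @classmethod
    def from_dict(cls, calls: dict[str, dict[str, str]], taxa=None, loci=None) -> "MarkerMatrix":
        """Build from {locus: {taxon: state}}; omitted cells are MISSING."""
        taxa = list(taxa) if taxa is not None else sorted({t for c in calls.values() for t in c})
        loci = list(loci) if loci is not None else list(calls)
        frame = pd.DataFrame(MISSING, index=taxa, columns=loci, dtype=object)
        for locus, col in calls.items():
            for taxon, state in col.items():
                frame.at[taxon, locus] = state
        return cls(frame)


def _canonical_state(raw, taxon: str, locus: str) -> tuple[str, bool]:
    text = str(raw).strip().lower() if raw is not None else ""
    if text in STATE_SYNONYMS:
        return STATE_SYNONYMS[text], text == "p"
    raise FormatError(f"unknown state symbol {raw!r} at taxon {taxon!r}, locus {locus!r}")


def read_matrix(source, sep: str | None = None) -> MarkerMatrix:
    """Read a delimited presence/absence table (path, file object or string).

    The first column holds taxon labels and the header row holds locus ids.
    ``sep=None`` auto-detects tab vs comma from the header line.
    """
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        handle = io.StringIO(source)
    elif hasattr(source, "read"):
        handle = source
    else:
        handle = open(source)
    try:
        text = handle.read()
    finally:
        if handle is not source and not isinstance(source, io.StringIO):
            handle.close()
    if not text.strip():
        raise FormatError("empty marker table")
    if sep is None:
        header = text.splitlines()[0]
        sep = "\t" if "\t" in header else ","
    # pandas silently mangles duplicate column names; check the raw header
    header_cells = [c.strip() for c in text.splitlines()[0].split(sep)][1:]
    dup_loci = sorted({c for c in header_cells if header_cells.count(c) > 1})
    if dup_loci:
        raise FormatError(f"duplicate locus identifiers: {dup_loci}")
    try:
        frame = pd.read_csv(
            io.StringIO(text), sep=sep, index_col=0, dtype=str, keep_default_na=False
        )
    except Exception as exc:  # malformed table
        raise FormatError(f"cannot parse marker table: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError("marker table has no locus columns")
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    polymorphic = set()
    out = frame.copy()
    for locus in frame.columns:
        for taxon in frame.index:
            state, poly = _canonical_state(frame.at[taxon, locus], taxon, locus)
            out.at[taxon, locus] = state
            if poly:
                polymorphic.add((taxon, locus))
    if polymorphic:
        log.warning(
            "%d polymorphic call(s) coded PRESENT: %s", len(polymorphic), sorted(polymorphic)
        )
    matrix = MarkerMatrix(out, polymorphic=polymorphic)
    log.info("read matrix %d taxa x %d loci: %s", len(matrix.taxa), len(matrix.loci),
             matrix.state_counts())
    return matrix


def write_matrix(matrix: MarkerMatrix, path, sep: str = "\t") -> None:
    """Round-trip writer for :func:`read_matrix`."""
    matrix.data.to_csv(path, sep=sep, index_label="taxon")
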