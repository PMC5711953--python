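"""Marker polarization and trichotomy counting on a rooted species tree.

Markers obey Dollo logic: a retrotransposon inserts once and is never
precisely excised, so the set of taxa carrying it defines the branch on which
the insertion occurred — up to hemiplasy (incomplete lineage sorting or
introgression), which produces patterns that conflict with the species tree.

``polarize_marker`` assigns each locus a branch and a status on the species
tree; ``count_trifurcation`` tallies markers for the resolutions of one
trichotomy (where a marker can be unambiguous even if it conflicts with the
overall species tree, as long as it fits one of the three local resolutions);
``ratio_count_for_clade`` extracts the (d, e) pattern on successive
reference-lineage branches for the insertion ratio test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy

from .counts import InsertionCount, RatioCount, UNOBSERVABLE
from .errors import FormatError, MappingError, SpecError
from .matrix import MarkerMatrix

log = logging.getLogger("blindtree.polarity")

CLEAN = "CLEAN"
AMBIGUOUS = "AMBIGUOUS"
UNINFORMATIVE = "UNINFORMATIVE"
INSUFFICIENT_OUTGROUP = "INSUFFICIENT_OUTGROUP"

STATUSES = (CLEAN, AMBIGUOUS, UNINFORMATIVE, INSUFFICIENT_OUTGROUP)


class SpeciesTree:
    """A rooted species tree with set-based clade queries.

    Thin wrapper over a dendropy tree; every query works on frozensets of
    taxon labels so that results are independent of node identity and leaf
    ordering.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._leafset = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                if node.taxon is None:
                    raise FormatError("tree contains an unlabeled leaf")
                self._leafset[node] = frozenset({node.taxon.label})
            else:
                self._leafset[node] = frozenset().union(
                    *(self._leafset[c] for c in node.child_nodes())
                )
        self.leaves = frozenset(self._leafset[tree.seed_node])

    # -- construction -------------------------------------------------------
    @classmethod
    def read_newick(cls, source, outgroup: str | None = None) -> "SpeciesTree":
        """Read a Newick tree; polarity needs a root.

        A tree with a basal polytomy (>2 children at the seed node) is treated
        as unrooted and refused unless ``outgroup`` names a leaf to root with.
        """
        kwargs = dict(schema="newick", preserve_underscores=True)
        if hasattr(source, "read") or (isinstance(source, str) and "(" in source):
            data = source.read() if hasattr(source, "read") else source
            tree = dendropy.Tree.get(data=data, **kwargs)
        else:
            tree = dendropy.Tree.get(path=source, **kwargs)
        basal = len(tree.seed_node.child_nodes())
        if basal > 2:
            if outgroup is None:
                raise FormatError(
                    "tree has a basal polytomy (unrooted); supply an outgroup to root it"
                )
            taxon = tree.taxon_namespace.get_taxon(outgroup)
            if taxon is None:
                raise MappingError(f"outgroup {outgroup!r} not a leaf of the tree")
            node = tree.find_node_with_taxon_label(outgroup)
            tree.reroot_at_edge(node.edge, update_bipartitions=False)
        tree.is_rooted = True
        return cls(tree)

    # -- queries (all restricted to a working taxon set) --------------------
    def restricted(self, taxa) -> frozenset:
        missing = set(taxa) - self.leaves
        if missing:
            raise MappingError(f"taxa absent from tree: {sorted(missing)}")
        return frozenset(taxa)

    def _mrca_node(self, taxa: frozenset):
        taxa = frozenset(taxa)
        if not taxa:
            raise SpecError("cannot take MRCA of an empty taxon set")
        node = self._tree.find_node_with_taxon_label(next(iter(taxa)))
        while not taxa <= self._leafset[node]:
            node = node.parent_node
            if node is None:  # pragma: no cover - root covers everything
                raise MappingError(f"taxa not on tree: {sorted(taxa - self.leaves)}")
        return node

    def mrca_clade(self, taxa, within=None) -> frozenset:
        """Smallest clade containing ``taxa``, optionally restricted to a working taxon set."""
        clade = self._leafset[self._mrca_node(frozenset(taxa))]
        return clade & frozenset(within) if within is not None else clade

    def deeper_lineages(self, taxa, within=None) -> list[frozenset]:
        """Sister subtrees branching below the clade spanning ``taxa``.

        Ordered from the shallowest (immediately below the clade) to the
        deepest (adjacent to the root); empty lineages after restriction are
        dropped.
        """
        node = self._mrca_node(frozenset(taxa))
        within = frozenset(within) if within is not None else self.leaves
        lineages = []
        child = node
        parent = node.parent_node
        while parent is not None:
            for sib in parent.child_nodes():
                if sib is not child:
                    restricted = self._leafset[sib] & within
                    if restricted:
                        lineages.append(restricted)
            child, parent = parent, parent.parent_node
        return lineages

    def child_clade_containing(self, taxa, member, within=None) -> frozenset | None:
        """The child clade of span(taxa) that contains ``member`` (None at a leaf)."""
        node = self._mrca_node(frozenset(taxa))
        for child in node.child_nodes():
            if member in self._leafset[child]:
                clade = self._leafset[child]
                return clade & frozenset(within) if within is not None else clade
        return None

    def is_clade(self, taxa, within=None) -> bool:
        taxa = frozenset(taxa)
        return self.mrca_clade(taxa, within=within) == taxa

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass(frozen=True)
class PolarizedMarker:
    """One locus placed on the species tree.

    CLEAN markers carry the branch (as the clade below it); AMBIGUOUS markers
    list the minimal conflicting taxa; INSUFFICIENT_OUTGROUP means the
    presence set matches a clade but absence could not be verified on enough
    deeper lineages.  The raw pattern travels along because trichotomy
    counting is pattern-based (a globally conflicting marker can still fit one
    resolution of a particular trichotomy).
    """

    locus: str
    status: str
    branch: frozenset | None
    conflict_note: str
    present: frozenset
    absent: frozenset
    missing: frozenset
    depends_on_missing: bool = False


def polarize_marker(
    matrix: MarkerMatrix,
    tree: SpeciesTree,
    locus: str,
    stringency: int = 2,
    strict_successive: bool = False,
) -> PolarizedMarker:
    """Place one marker on the species tree under Dollo logic.

    CLEAN requires (i) the present taxa (MISSING is compatible either way) to
    be exactly the sampled members of one clade and (ii) verified absence on
    at least ``stringency`` lineages branching below that clade — or on all
    such lineages when the tree offers fewer (markers near the root cannot
    have two outgroup lineages).  ``strict_successive`` demands that the
    verified lineages be the immediately successive ones below the clade.
    """
    if stringency < 0:
        raise SpecError("stringency must be >= 0")
    present, absent, missing = matrix.state_sets(locus)  # KeyError if unknown locus
    taxa = frozenset(matrix.taxa)
    extra = taxa - tree.leaves
    if extra:
        raise MappingError(f"matrix taxa absent from tree: {sorted(extra)}")

    def result(status, branch=None, note="", depends=False):
        marker = PolarizedMarker(
            locus, status, branch, note, present, absent, missing, depends
        )
        log.debug("polarize %s -> %s %s %s", locus, status, branch, note)
        return marker

    if not present:
        return result(UNINFORMATIVE, note="absent in every sampled taxon")
    if len(present) == 1:
        return result(UNINFORMATIVE, note="autapomorphy (present in one taxon)")
    if not absent:
        return result(UNINFORMATIVE, note="present in every sampled taxon")

    clade = tree.mrca_clade(present, within=taxa)
    conflicts = sorted(clade & absent)
    depends = bool(clade & missing)
    if conflicts:
        return result(
            AMBIGUOUS,
            note="absent within the supported clade: " + ", ".join(conflicts),
            depends=depends,
        )
    lineages = tree.deeper_lineages(clade, within=taxa)
    required = min(stringency, len(lineages))
    verified = [bool(lin & absent) for lin in lineages]
    ok = all(verified[:required]) if strict_successive else sum(verified) >= required
    depends = depends or any(
        not v and (lin <= missing) for v, lin in zip(verified, lineages)
    )
    if ok:
        return result(CLEAN, branch=clade, depends=depends)
    return result(
        INSUFFICIENT_OUTGROUP,
        branch=clade,
        note=(
            f"absence verified on {sum(verified)} deeper lineage(s), "
            f"{required} required"
        ),
        depends=depends,
    )


def polarize_all(matrix, tree, stringency=2, strict_successive=False) -> list[PolarizedMarker]:
    return [
        polarize_marker(matrix, tree, locus, stringency, strict_successive)
        for locus in matrix.loci
    ]


def polarization_table(markers: list[PolarizedMarker]) -> str:
    """TSV report: locus, status, branch, conflicts, depends_on_missing."""
    lines = ["locus\tstatus\tbranch\tnote\tdepends_on_missing"]
    for m in markers:
        branch = ",".join(sorted(m.branch)) if m.branch else ""
        lines.append(
            f"{m.locus}\t{m.status}\t{branch}\t{m.conflict_note}\t"
            f"{'yes' if m.depends_on_missing else 'no'}"
        )
    return "\n".join(lines) + "\n"


def ascertainment_report(markers, reference_taxon: str) -> list[str]:
    """Loci whose CLEAN branch does not contain the reference taxon.

    A matrix ascertained from a single reference genome cannot contain such
    markers; on real matrices deviations are reported, not rejected.
    """
    return [
        m.locus
        for m in markers
        if m.status == CLEAN and m.branch is not None and reference_taxon not in m.branch
    ]


# ---------------------------------------------------------------------------
# Trichotomy specifications and counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grouping:
    """A clade hypothesis as a taxon set.

    ``required`` members must be present (or missing); every taxon outside
    ``required | optional`` must be absent (or missing).  ``optional`` taxa
    are "don't care" — used when a node is tested regardless of the position
    of some lineage (e.g. a trichotomy among Macropus subgenera regardless of
    Wallabia).
    """

    required: frozenset
    optional: frozenset = frozenset()

    def matches(self, present, absent, missing, within) -> bool:
        dont_care = self.required | self.optional
        p = present & within
        if not p & self.required:
            return False
        if not self.required <= (present | missing):
            return False
        return p <= dont_care


_PAIRING_KEYS = ("ab", "ac", "bc")


@dataclass(frozen=True)
class TrifurcationSpec:
    """Three disjoint clade hypotheses for one trichotomy.

    ``reference_taxon`` determines the blind resolution: the pairing of the
    two clades that exclude it cannot be observed when markers were
    ascertained in the reference genome.  ``tested`` names the pairing taken
    as T1 (the prior hypothesis under test); the remaining observable pairing
    is T2.  Set ``reference_taxon=None`` for the fully observed regime (all
    three slots counted).  ``ignore`` lists taxa whose state is irrelevant to
    this trichotomy.
    """

    clade_a: frozenset
    clade_b: frozenset
    clade_c: frozenset
    reference_taxon: str | None
    tested: str = "ab"
    ignore: frozenset = frozenset()
    label: str = ""

    def __post_init__(self):
        clades = [self.clade_a, self.clade_b, self.clade_c]
        if any(not c for c in clades):
            raise SpecError("all three clades must be non-empty")
        for i in range(3):
            for j in range(i + 1, 3):
                if clades[i] & clades[j]:
                    raise SpecError("trifurcation clades must be disjoint")
        if self.ignore & (self.clade_a | self.clade_b | self.clade_c):
            raise SpecError("ignored taxa cannot belong to a clade")
        if self.tested not in _PAIRING_KEYS:
            raise SpecError(f"tested must be one of {_PAIRING_KEYS}")
        if self.reference_taxon is not None and len(self.reference_clade_key()) != 1:
            raise SpecError("reference taxon must belong to exactly one clade")

    # -- helpers ------------------------------------------------------------
    def clades(self) -> dict[str, frozenset]:
        return {"a": self.clade_a, "b": self.clade_b, "c": self.clade_c}

    def union(self) -> frozenset:
        return self.clade_a | self.clade_b | self.clade_c

    def pairing(self, key: str) -> frozenset:
        return self.clades()[key[0]] | self.clades()[key[1]]

    def reference_clade_key(self) -> str:
        return "".join(
            k for k, c in self.clades().items() if self.reference_taxon in c
        )

    def reference_clade(self) -> frozenset:
        return self.clades()[self.reference_clade_key()]

    def blind_pair(self) -> str | None:
        """The pairing of the two clades that do not contain the reference."""
        if self.reference_taxon is None:
            return None
        ref = self.reference_clade_key()
        return next(k for k in _PAIRING_KEYS if ref not in k)

    def slot_keys(self) -> tuple[str, str, str | None]:
        """(t1 pairing, t2 pairing, blind pairing or the remaining one)."""
        blind = self.blind_pair()
        if blind is None:
            rest = [k for k in _PAIRING_KEYS if k != self.tested]
            return self.tested, rest[0], rest[1]
        if self.tested == blind:
            raise SpecError("the tested pairing cannot be the blind pairing")
        t2 = next(k for k in _PAIRING_KEYS if k not in (self.tested, blind))
        return self.tested, t2, blind


@dataclass(frozen=True)
class NodeSpec:
    """One row of a node scan: a trichotomy plus what to test there.

    Either wraps a :class:`TrifurcationSpec` directly, or — for composite
    nodes whose printed counts aggregate successive branches — gives explicit
    grouping lists per observable slot.  ``ratio`` requests the (d, e)
    insertion-ratio pattern, with ``reference_grouping`` defining the branch
    whose markers are exclusive to the reference side (defaults to the
    trifurcation's reference clade).
    """

    label: str
    trifurcation: TrifurcationSpec | None = None
    t1_groupings: tuple[Grouping, ...] = ()
    t2_groupings: tuple[Grouping, ...] = ()
    reference_grouping: Grouping | None = None
    topology_t1: str = ""
    topology_t2: str = ""
    topology_blind: str = ""
    ratio: bool = False
    apriori: str | None = None

    def __post_init__(self):
        if self.trifurcation is None and not self.t1_groupings:
            raise SpecError(f"node {self.label!r}: needs a trifurcation or groupings")
        if self.trifurcation is not None and self.t1_groupings:
            raise SpecError(f"node {self.label!r}: trifurcation and groupings are exclusive")
        if self.trifurcation is None and self.ratio and self.reference_grouping is None:
            raise SpecError(f"node {self.label!r}: ratio needs a reference grouping")

    def effective_reference_grouping(self) -> Grouping | None:
        if self.reference_grouping is not None:
            return self.reference_grouping
        if self.trifurcation is not None and self.trifurcation.reference_taxon is not None:
            return Grouping(self.trifurcation.reference_clade(), self.trifurcation.ignore)
        return None


@dataclass
class TrifurcationTally:
    """Per-locus dispositions and the resulting insertion count for one node."""

    spec: NodeSpec
    count: InsertionCount                       # unambiguous markers only
    assignments: dict = field(default_factory=dict)   # locus -> disposition string
    supporting: dict = field(default_factory=dict)    # slot -> [locus]
    ambiguous_resolved: dict = field(default_factory=dict)  # slot -> [locus]
    insufficient: list = field(default_factory=list)
    ratio: RatioCount | None = None
    exclusive_loci: list = field(default_factory=list)

    def combined_count(self) -> InsertionCount:
        """Unambiguous plus resolvable-ambiguous markers (reported separately)."""
        add1 = len(self.ambiguous_resolved.get("t1", []))
        add2 = len(self.ambiguous_resolved.get("t2", []))
        return InsertionCount(
            self.count.support_t1 + add1, self.count.support_t2 + add2,
            self.count.support_t3,
        )


def _working_taxa(polarized, tree):
    if not polarized:
        return tree.leaves
    return frozenset().union(*(m.present | m.absent | m.missing for m in polarized))


def _passes_stringency(tree, taxa_span, absent, ignore, within, stringency, strict=False):
    lineages = tree.deeper_lineages(taxa_span, within=within - ignore)
    required = min(stringency, len(lineages))
    verified = [bool(lin & absent) for lin in lineages]
    if strict:
        return all(verified[:required])
    return sum(verified) >= required


def count_trifurcation(
    polarized,
    spec: NodeSpec | TrifurcationSpec,
    tree: SpeciesTree,
    include_ambiguous: bool = False,
    stringency: int = 2,
) -> TrifurcationTally:
    """Tally markers for the resolutions of one trichotomy.

    A marker counts for a pairing when its pattern is unambiguous *for this
    trichotomy*: every taxon of the pairing present (or missing), every other
    taxon absent (or missing, or ignored), presence touching both clades of
    the pairing, and absence verified on deeper lineages per ``stringency``.
    Markers violating this but whose presence touches exactly two clades are
    recorded as resolvable-ambiguous; ``include_ambiguous`` adds them to the
    combined count, always reported separately.
    """
    if isinstance(spec, TrifurcationSpec):
        spec = NodeSpec(label=spec.label or "trifurcation", trifurcation=spec)
    if spec.trifurcation is not None:
        return _count_standard(polarized, spec, tree, include_ambiguous, stringency)
    return _count_groupings(polarized, spec, tree, stringency)


def _count_standard(polarized, node, tree, include_ambiguous, stringency):
    tri = node.trifurcation
    within = _working_taxa(polarized, tree)
    extra = tri.union() - within
    if extra:
        raise SpecError(f"trifurcation taxa not in the marker set: {sorted(extra)}")
    t1_key, t2_key, blind_key = tri.slot_keys()
    union = tri.union()
    tally = {t1_key: [], t2_key: []}
    if blind_key is not None and tri.reference_taxon is None:
        tally[blind_key] = []
    resolved = {"t1": [], "t2": []}
    assignments, insufficient = {}, []

    for m in polarized:
        p = m.present - tri.ignore
        a = m.absent - tri.ignore
        mi = m.missing - tri.ignore
        disposition = None
        if not p & union:
            disposition = "uninformative (absent across the trichotomy)"
        elif union <= (p | mi) and all(p & c for c in tri.clades().values()):
            disposition = "uninformative (predates the trichotomy)"
        else:
            matches = []
            for key in _PAIRING_KEYS:
                pair = tri.pairing(key)
                x, y = tri.clades()[key[0]], tri.clades()[key[1]]
                if (
                    p <= pair
                    and pair <= (p | mi)
                    and p & x
                    and p & y
                ):
                    matches.append(key)
            if len(matches) == 1:
                key = matches[0]
                if not _passes_stringency(
                    tree, tri.pairing(key), a, tri.ignore, within, stringency
                ):
                    disposition = "insufficient outgroup verification"
                    insufficient.append(m.locus)
                elif key in tally:
                    tally[key].append(m.locus)
                    disposition = f"supports {key}"
                else:
                    disposition = "matches the blind pairing (unexpected under ascertainment)"
            elif len(matches) > 1:
                disposition = "undecidable (missing data spans several pairings)"
            else:
                touched = [k for k, c in tri.clades().items() if p & c]
                if len(touched) == 2:
                    key = "".join(touched)
                    slot = "t1" if key == t1_key else ("t2" if key == t2_key else None)
                    if slot is not None:
                        resolved[slot].append(m.locus)
                        disposition = f"ambiguous, resolvable toward {key}"
                    else:
                        disposition = "ambiguous, resolvable only toward the blind pairing"
                else:
                    disposition = "ambiguous (multilevel conflict)"
        assignments[m.locus] = disposition

    t3 = UNOBSERVABLE if tri.reference_taxon is not None else len(tally.get(blind_key, []))
    count = InsertionCount(len(tally[t1_key]), len(tally[t2_key]), t3)
    result = TrifurcationTally(
        spec=node,
        count=count,
        assignments=assignments,
        supporting={"t1": tally[t1_key], "t2": tally[t2_key]},
        ambiguous_resolved=resolved,
        insufficient=insufficient,
    )
    _attach_ratio(result, polarized, node, tree, within, stringency)
    log.info("node %s: count=%s ratio=%s", node.label, count, result.ratio)
    return result


def _count_groupings(polarized, node, tree, stringency):
    within = _working_taxa(polarized, tree)
    assignments, insufficient = {}, []
    supporting = {"t1": [], "t2": []}
    slots = {"t1": node.t1_groupings, "t2": node.t2_groupings}
    for m in polarized:
        disposition = "uninformative for this node"
        for slot, groupings in slots.items():
            matched = [
                g for g in groupings if g.matches(m.present, m.absent, m.missing, within)
            ]
            if matched:
                g = matched[0]
                if _passes_stringency(
                    tree, g.required, m.absent, g.optional, within, stringency
                ):
                    supporting[slot].append(m.locus)
                    disposition = f"supports {slot}"
                else:
                    disposition = "insufficient outgroup verification"
                    insufficient.append(m.locus)
                break
        assignments[m.locus] = disposition
    count = InsertionCount(len(supporting["t1"]), len(supporting["t2"]), UNOBSERVABLE)
    result = TrifurcationTally(
        spec=node, count=count, assignments=assignments, supporting=supporting,
        insufficient=insufficient,
    )
    _attach_ratio(result, polarized, node, tree, within, stringency)
    log.info("node %s: count=%s ratio=%s", node.label, count, result.ratio)
    return result


def _attach_ratio(result, polarized, node, tree, within, stringency):
    if not node.ratio:
        return
    ref = node.effective_reference_grouping()
    if ref is None:
        return
    exclusive = []
    for m in polarized:
        if m.locus in result.supporting["t1"] or m.locus in result.supporting["t2"]:
            continue
        # the shallower exclusive branch is a branch of the accepted species
        # tree, so only globally CLEAN markers can sit on it
        if m.status != CLEAN:
            continue
        if ref.matches(m.present, m.absent, m.missing, within) and _passes_stringency(
            tree, ref.required, m.absent, ref.optional, within, stringency
        ):
            exclusive.append(m.locus)
    result.exclusive_loci = exclusive
    result.ratio = RatioCount(result.count.support_t1, len(exclusive))


def ratio_count_for_clade(
    polarized,
    clade,
    tree: SpeciesTree,
    reference_taxon: str,
    ignore=frozenset(),
    stringency: int = 2,
) -> RatioCount:
    """(d, e) on successive reference-lineage branches.

    ``d`` counts markers whose pattern (with ``ignore`` masked out) is exactly
    the clade joining the reference lineage and its hypothesised sister;
    ``e`` counts markers on the immediately shallower branch containing only
    the reference side.  A (0, 0) result is untestable and is returned as-is.
    """
    within = _working_taxa(polarized, tree)
    clade = frozenset(clade) - frozenset(ignore)
    ignore = frozenset(ignore)
    if reference_taxon not in clade:
        raise SpecError("the clade must contain the reference taxon")
    target_d = Grouping(clade, ignore)
    # next shallower reference-containing branch: descend from the clade's span
    span = clade
    child = tree.child_clade_containing(span, reference_taxon, within=within)
    while child is not None and (child - ignore) == clade:
        span = child
        child = tree.child_clade_containing(span, reference_taxon, within=within)
    if child is None:
        raise SpecError("no shallower reference-containing branch below the clade")
    target_e = Grouping(child - ignore, ignore)

    d = e = 0
    for m in polarized:
        if m.status != CLEAN:
            continue
        if target_d.matches(m.present, m.absent, m.missing, within) and _passes_stringency(
            tree, target_d.required, m.absent, ignore, within, stringency
        ):
            d += 1
        elif target_e.matches(m.present, m.absent, m.missing, within) and _passes_stringency(
            tree, target_e.required, m.absent, ignore, within, stringency
        ):
            e += 1
    return RatioCount(d, e)
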