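"""Synthetic kangaroo/wallaby marker fixture.

Encodes the published solo-LTR presence/absence counts for the Macropus +
Wallabia radiation as a 16-taxon x 29-locus matrix on the retrotransposon
species tree, with Macropus eugenii as the single reference genome.  The
matrix is a synthetic stand-in constructed so that polarization and node
counting reproduce the published per-node insertion patterns ([2 1 X],
[6 1 X], [8 0 X], [9 1 X], [3 1 X], [3 0 X], [1 0 X], [4 0 X]), the ratio
patterns ((6,2), (8,0), (9,2), (4,0)), the eight conflicting loci C1-C8, one
less-stringent locus (K136) excluded from testing, and the documented
untested cells for M. parma.  Locus identifiers are synthetic.

Everything is generated programmatically and deterministically — no data
files ship with the package.
"""

from __future__ import annotations

from .matrix import MarkerMatrix, PRESENT, ABSENT, MISSING
from .polarity import Grouping, NodeSpec, SpeciesTree, TrifurcationSpec

REFERENCE = "M_eugenii"

CORE_NOTA = ("M_eugenii", "M_parma", "M_agilis", "M_rufogriseus")
NOTA = CORE_NOTA + ("M_irma",)
WALLABIA = ("Wallabia_bicolor",)
OSPH = ("M_robustus", "M_rufus", "M_antilopinus", "M_bernardus")
MAC = ("M_giganteus", "M_fuliginosus")
MACROPUS = NOTA + OSPH + MAC
MW = MACROPUS + WALLABIA  # Macropus + Wallabia
ONY = ("Onychogalea_unguifera",)
LAGORCHESTES = ("Lagorchestes_hirsutus",)
THY = ("Thylogale_thetis",)
LAGOSTROPHUS = ("Lagostrophus_fasciatus",)
MACROPODINES = MW + ONY + LAGORCHESTES + THY

TAXA = MW + ONY + LAGORCHESTES + THY + LAGOSTROPHUS  # 16 taxa

NEWICK = (
    "(Lagostrophus_fasciatus,(Thylogale_thetis,(Lagorchestes_hirsutus,"
    "(Onychogalea_unguifera,((M_giganteus,M_fuliginosus),"
    "((M_robustus,(M_rufus,(M_antilopinus,M_bernardus))),"
    "(Wallabia_bicolor,(M_irma,(M_rufogriseus,(M_agilis,"
    "(M_eugenii,M_parma)))))))))));"
)

# Loci: (id, present taxa, missing taxa).  Everything else is absent.
_LOCI = [
    # Notamacropus stem (incl. M. irma): the e = 2 of the (6,2) ratio pattern
    ("K101", NOTA, ()),
    ("K102", NOTA, ()),
    # Wallabia + Notamacropus stem: the six markers nesting Wallabia
    ("K103", NOTA + WALLABIA, ()),
    ("K104", NOTA + WALLABIA, ("M_parma",)),  # M. parma untested
    ("K105", NOTA + WALLABIA, ()),
    ("K106", NOTA + WALLABIA, ()),
    ("K108", NOTA + WALLABIA, ()),
    ("K109", NOTA + WALLABIA, ()),
    # Wallabia + Notamacropus + Osphranter stem
    ("K110", NOTA + WALLABIA + OSPH, ()),
    ("K111", NOTA + WALLABIA + OSPH, ("M_parma",)),  # M. parma untested
    ("K112", NOTA + WALLABIA + OSPH, ()),
    # Macropus + Wallabia stem (monophyly of the genus incl. Wallabia)
    ("K113", MW, ()),
    ("K114", MW, ()),
    ("K115", MW, ()),
    # Onychogalea + Macropus/Wallabia stem
    ("K116", ONY + MW, ()),
    # macropodine stem (absent only in Lagostrophus, the sole deeper lineage)
    ("K117", MACROPODINES, ()),
    ("K118", MACROPODINES, ()),
    ("K119", MACROPODINES, ()),
    ("K107", MACROPODINES, ()),  # "absent only in the deepest" exception
    # M. eugenii + M. parma cherry
    ("K120", ("M_eugenii", "M_parma"), ()),
    # Conflicting loci C1-C8 (hemiplasy within the radiation)
    ("C1", WALLABIA + CORE_NOTA, ()),                     # excludes M. irma
    ("C2", MACROPUS, ()),                                  # Macropus monophyly
    ("C3", NOTA + OSPH, ()),                               # excludes Wallabia
    ("C4", MAC + NOTA, ()),                                # excludes Osph and Wallabia
    ("C5", MAC + NOTA + WALLABIA, ()),                     # excludes Osphranter
    ("C6", WALLABIA + ("M_irma", "M_agilis", "M_eugenii", "M_parma"), ()),
    ("C7", WALLABIA + ("M_irma", "M_rufogriseus", "M_eugenii", "M_parma"), ()),
    ("C8", WALLABIA + ("M_eugenii", "M_parma"), ()),
    # Less-stringent locus: pattern fits Ony+Macropus/Wallabia but absence is
    # verifiable on only one deeper lineage (the two deepest are untested)
    ("K136", ONY + MW, ("Thylogale_thetis", "Lagostrophus_fasciatus")),
]


def fixture_tree() -> SpeciesTree:
    return SpeciesTree.read_newick(NEWICK)


def fixture_matrix() -> MarkerMatrix:
    calls = {}
    for locus, present, missing in _LOCI:
        col = {}
        for taxon in TAXA:
            if taxon in missing:
                col[taxon] = MISSING
            elif taxon in present:
                col[taxon] = PRESENT
            else:
                col[taxon] = ABSENT
        calls[locus] = col
    return MarkerMatrix.from_dict(calls, taxa=TAXA, loci=[l for l, _, _ in _LOCI])


def _g(required, optional=()) -> Grouping:
    return Grouping(frozenset(required), frozenset(optional))


def fixture_nodes() -> list[NodeSpec]:
    """The eight published trichotomies, shallowest to deepest.

    Nodes (iii) and (iv) are composite: their printed counts aggregate
    markers across successive reference-path branches ("regardless of" the
    position of Wallabia, respectively Osphranter), so they are expressed as
    explicit grouping lists rather than three disjoint clades.
    """
    fs = frozenset
    nodes = [
        NodeSpec(
            label="(i)",
            trifurcation=TrifurcationSpec(
                clade_a=fs(("M_irma",)), clade_b=fs(CORE_NOTA), clade_c=fs(WALLABIA),
                reference_taxon=REFERENCE, tested="ab", label="(i)",
            ),
            topology_t1="(M.irma, Nota), Wall",
            topology_t2="(Nota, Wall), M.irma",
            topology_blind="(M.irma, Wall), Nota",
        ),
        NodeSpec(
            label="(ii)",
            trifurcation=TrifurcationSpec(
                clade_a=fs(WALLABIA), clade_b=fs(NOTA), clade_c=fs(OSPH),
                reference_taxon=REFERENCE, tested="ab", label="(ii)",
            ),
            topology_t1="(Wall, Nota), Osph",
            topology_t2="(Osph, Nota), Wall",
            topology_blind="(Wall, Osph), Nota",
            ratio=True,
        ),
        NodeSpec(
            label="(iii)",
            t1_groupings=(_g(NOTA, WALLABIA),),
            t2_groupings=(_g(CORE_NOTA + OSPH, WALLABIA),),
            reference_grouping=_g(CORE_NOTA, WALLABIA),
            topology_t1="(M.irma, Nota), Osph",
            topology_t2="(Nota, Osph), M.irma",
            topology_blind="(M.irma, Osph), Nota",
            ratio=True,
        ),
        NodeSpec(
            label="(iv)",
            t1_groupings=(_g(WALLABIA + NOTA, OSPH),),
            t2_groupings=(_g(MACROPUS),),
            reference_grouping=_g(NOTA, OSPH),
            topology_t1="Macropus paraphyly",
            topology_t2="Macropus monophyly",
            topology_blind="(Wall, Osph/Mac), Nota",
            ratio=True,
        ),
        NodeSpec(
            label="(v)",
            trifurcation=TrifurcationSpec(
                clade_a=fs(NOTA + WALLABIA), clade_b=fs(OSPH), clade_c=fs(MAC),
                reference_taxon=REFERENCE, tested="ab", label="(v)",
            ),
            topology_t1="((Nota+Wall), Osph), Mac",
            topology_t2="((Nota+Wall), Mac), Osph",
            topology_blind="(Mac, Osph), (Nota+Wall)",
        ),
        NodeSpec(
            label="(vi)",
            trifurcation=TrifurcationSpec(
                clade_a=fs(NOTA + OSPH + WALLABIA), clade_b=fs(MAC), clade_c=fs(ONY),
                reference_taxon=REFERENCE, tested="ab", label="(vi)",
            ),
            topology_t1="((Nota+Osph+Wall)+Mac), Ony",
            topology_t2="((Nota+Osph+Wall)+Ony), Mac",
            topology_blind="(Mac, Ony), (Nota+Osph+Wall)",
        ),
        NodeSpec(
            label="(vii)",
            trifurcation=TrifurcationSpec(
                clade_a=fs(ONY), clade_b=fs(LAGORCHESTES), clade_c=fs(MW),
                reference_taxon=REFERENCE, tested="ac", label="(vii)",
            ),
            topology_t1="((Wall+M), Ony), Lag",
            topology_t2="((Wall+M), Lag), Ony",
            topology_blind="(Ony, Lag), (Wall+M)",
        ),
        NodeSpec(
            label="(viii)",
            trifurcation=TrifurcationSpec(
                clade_a=fs(LAGOSTROPHUS), clade_b=fs(THY),
                clade_c=fs(MW + ONY + LAGORCHESTES),
                reference_taxon=REFERENCE, tested="bc", label="(viii)",
            ),
            topology_t1="((Ony+Lag+Wall+M), Thy), Lagost",
            topology_t2="((Ony+Lag+Wall+M), Lagost), Thy",
            topology_blind="(Thy, Lagost), (Ony+Lag+Wall+M)",
            ratio=True,
        ),
    ]
    return nodes


def make_fixture(outdir) -> dict:
    """Write matrix TSV, tree Newick and node-spec YAML into ``outdir``.

    Deterministic: re-running produces byte-identical files.  Returns the
    paths written.
    """
    from pathlib import Path
    from .matrix import write_matrix
    from .nodespec_io import nodes_to_yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "markers.tsv",
        "tree": out / "tree.nwk",
        "nodes": out / "nodes.yaml",
    }
    write_matrix(fixture_matrix(), paths["matrix"])
    paths["tree"].write_text(NEWICK + "\n")
    paths["nodes"].write_text(nodes_to_yaml(fixture_nodes(), REFERENCE))
    return {k: str(v) for k, v in paths.items()}
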