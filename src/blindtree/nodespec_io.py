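"""YAML serialization of node specifications.

The file format:

.. code-block:: yaml

    reference: M_eugenii
    clades:                       # optional named clades, may nest by name
      coreNota: [M_eugenii, M_parma, M_agilis, M_rufogriseus]
      Nota: [coreNota, M_irma]
    nodes:
      - label: "(ii)"
        clade_a: [Wallabia_bicolor]
        clade_b: [Nota]
        clade_c: [M_robustus, M_rufus]
        tested: ab
        ratio: true
      - label: "(iii)"            # composite node: explicit groupings
        t1: [{required: [Nota], optional: [Wallabia_bicolor]}]
        t2: [{required: [coreNota, M_robustus], optional: [Wallabia_bicolor]}]
        reference_grouping: {required: [coreNota], optional: [Wallabia_bicolor]}
        ratio: true
"""

from __future__ import annotations

import yaml

from .errors import SpecError
from .polarity import Grouping, NodeSpec, TrifurcationSpec


def _resolve(tokens, clades, seen=()):
    """Expand a taxon/clade-name list into a frozenset of taxon labels."""
    if isinstance(tokens, str):
        tokens = [tokens]
    out = set()
    for token in tokens:
        if token in clades:
            if token in seen:
                raise SpecError(f"cyclic clade definition through {token!r}")
            out |= _resolve(clades[token], clades, seen + (token,))
        else:
            out.add(token)
    return frozenset(out)


def _parse_grouping(raw, clades) -> Grouping:
    if isinstance(raw, dict):
        return Grouping(
            _resolve(raw.get("required", []), clades),
            _resolve(raw.get("optional", []), clades),
        )
    return Grouping(_resolve(raw, clades))


def nodes_from_yaml(text_or_path) -> tuple[list[NodeSpec], str]:
    """Parse node specs; returns (nodes, reference taxon)."""
    if hasattr(text_or_path, "read"):
        doc = yaml.safe_load(text_or_path.read())
    elif isinstance(text_or_path, str) and "\n" in text_or_path:
        doc = yaml.safe_load(text_or_path)
    else:
        with open(text_or_path) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "nodes" not in doc:
        raise SpecError("node spec file needs a top-level 'nodes' list")
    reference = doc.get("reference")
    clades = doc.get("clades", {}) or {}
    nodes = []
    for i, raw in enumerate(doc["nodes"]):
        label = str(raw.get("label", f"node{i + 1}"))
        common = dict(
            label=label,
            topology_t1=raw.get("topology_t1", ""),
            topology_t2=raw.get("topology_t2", ""),
            topology_blind=raw.get("topology_blind", ""),
            ratio=bool(raw.get("ratio", False)),
            apriori=raw.get("apriori"),
        )
        if "t1" in raw:
            nodes.append(
                NodeSpec(
                    t1_groupings=tuple(_parse_grouping(g, clades) for g in raw["t1"]),
                    t2_groupings=tuple(_parse_grouping(g, clades) for g in raw.get("t2", [])),
                    reference_grouping=(
                        _parse_grouping(raw["reference_grouping"], clades)
                        if "reference_grouping" in raw
                        else None
                    ),
                    **common,
                )
            )
        else:
            try:
                tri = TrifurcationSpec(
                    clade_a=_resolve(raw["clade_a"], clades),
                    clade_b=_resolve(raw["clade_b"], clades),
                    clade_c=_resolve(raw["clade_c"], clades),
                    reference_taxon=raw.get("reference", reference),
                    tested=raw.get("tested", "ab"),
                    ignore=_resolve(raw.get("ignore", []), clades),
                    label=label,
                )
            except KeyError as exc:
                raise SpecError(f"node {label!r}: missing {exc}") from exc
            nodes.append(NodeSpec(trifurcation=tri, **common))
    return nodes, reference


def _grouping_dict(g: Grouping) -> dict:
    out = {"required": sorted(g.required)}
    if g.optional:
        out["optional"] = sorted(g.optional)
    return out


def nodes_to_yaml(nodes: list[NodeSpec], reference: str | None = None) -> str:
    doc: dict = {}
    if reference is not None:
        doc["reference"] = reference
    items = []
    for node in nodes:
        raw: dict = {"label": node.label}
        if node.trifurcation is not None:
            tri = node.trifurcation
            raw.update(
                clade_a=sorted(tri.clade_a),
                clade_b=sorted(tri.clade_b),
                clade_c=sorted(tri.clade_c),
                tested=tri.tested,
            )
            if tri.ignore:
                raw["ignore"] = sorted(tri.ignore)
            if tri.reference_taxon != reference:
                raw["reference"] = tri.reference_taxon
        else:
            raw["t1"] = [_grouping_dict(g) for g in node.t1_groupings]
            raw["t2"] = [_grouping_dict(g) for g in node.t2_groupings]
            if node.reference_grouping is not None:
                raw["reference_grouping"] = _grouping_dict(node.reference_grouping)
        for key in ("topology_t1", "topology_t2", "topology_blind"):
            if getattr(node, key):
                raw[key] = getattr(node, key)
        if node.ratio:
            raw["ratio"] = True
        if node.apriori:
            raw["apriori"] = node.apriori
        items.append(raw)
    doc["nodes"] = items
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)
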