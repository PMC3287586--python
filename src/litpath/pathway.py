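"""Regulatory pathway graphs and their KGML serialization.

Manual curation is codified as a declarative rule set: which interaction
types are accepted (default: type 1 only), how interaction-word polarity
maps to a KGML relation subtype, and optional allow/deny symbol lists.
Edge direction is the textual order (A acts on B); re-assertions of the
same (source, target, subtype) merge their evidence PMIDs.

The KGML writer emits a byte-stable document valid against the packaged
KGML v0.7.2 DTD.  Two annotations ride on standard KGML slots so that
write -> read -> write is the identity: the gene-age label is encoded in
the graphics ``bgcolor`` (lilac = ancient, green = recent, grey =
unassigned, white = unannotated) and a fly ortholog is marked by a
trailing ``*`` on the graphics display name; evidence PMIDs live in an
optional ``evidence`` attribute on ``relation``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence
from xml.sax.saxutils import escape

from lxml import etree

from .errors import CurationError, FormatError, SerializationError
from .extract import Biointeraction
from .resources import kgml_dtd_path

__all__ = ["SUBTYPES", "PathwayNode", "PathwayEdge", "PathwayGraph",
           "CurationRules", "curate", "write_kgml", "read_kgml",
           "validate_kgml", "annotate_ancestry", "to_networkx"]

SUBTYPES = ("activation", "inhibition", "expression", "repression",
            "binding/association", "phosphorylation", "indirect")

_SUBTYPE_VALUE = {
    "activation": "-->",
    "inhibition": "--|",
    "expression": "-->",
    "repression": "--|",
    "binding/association": "---",
    "phosphorylation": "+p",
    "indirect": "..>",
}
_RELATION_TYPE = {"expression": "GErel", "repression": "GErel"}

_AGE_BGCOLOR = {"ancient": "#C8A2C8", "recent": "#90EE90",
                "unassigned": "#BFBFBF", None: "#FFFFFF"}
_BGCOLOR_AGE = {v: k for k, v in _AGE_BGCOLOR.items()}

# Neutral-polarity words whose mechanism the lexicon itself names.
DEFAULT_WORD_SUBTYPES = {
    "binds": "binding/association", "bind": "binding/association",
    "bound": "binding/association", "associates": "binding/association",
    "interacts": "binding/association", "interact": "binding/association",
    "phosphorylates": "phosphorylation", "phosphorylate": "phosphorylation",
    "phosphorylated": "phosphorylation", "dephosphorylates": "phosphorylation",
}


@dataclass(frozen=True)
class PathwayNode:
    symbol: str
    age_label: Optional[str] = None  # ancient | recent | unassigned | None
    fly_ortholog: bool = False


@dataclass(frozen=True)
class PathwayEdge:
    source: str
    target: str
    subtype: str
    evidence: tuple[str, ...]


class PathwayGraph:
    """Genes as nodes; directed, typed, evidence-carrying edges."""

    def __init__(self):
        self._nodes: dict[str, PathwayNode] = {}
        self._edges: dict[tuple[str, str, str], list[str]] = {}

    # -- construction -------------------------------------------------
    def add_node(self, symbol: str, *, age_label: Optional[str] = None,
                 fly_ortholog: bool = False) -> None:
        existing = self._nodes.get(symbol)
        if existing is None:
            self._nodes[symbol] = PathwayNode(symbol, age_label, fly_ortholog)
        elif age_label is not None or fly_ortholog:
            self._nodes[symbol] = PathwayNode(symbol,
                                              age_label or existing.age_label,
                                              fly_ortholog or existing.fly_ortholog)

    def add_edge(self, source: str, target: str, subtype: str,
                 evidence: Iterable[str] = ()) -> None:
        if subtype not in SUBTYPES:
            raise SerializationError(f"unknown relation subtype {subtype!r}")
        self.add_node(source)
        self.add_node(target)
        bucket = self._edges.setdefault((source, target, subtype), [])
        for pmid in evidence:
            if pmid not in bucket:
                bucket.append(pmid)

    # -- access -------------------------------------------------------
    @property
    def nodes(self) -> dict[str, PathwayNode]:
        return dict(self._nodes)

    def edges(self) -> list[PathwayEdge]:
        return [PathwayEdge(s, t, st, tuple(sorted(ev)))
                for (s, t, st), ev in sorted(self._edges.items())]

    def evidence(self, source: str, target: str, subtype: str) -> tuple[str, ...]:
        return tuple(sorted(self._edges.get((source, target, subtype), [])))

    def copy(self) -> "PathwayGraph":
        g = PathwayGraph()
        g._nodes = dict(self._nodes)
        g._edges = {k: list(v) for k, v in self._edges.items()}
        return g

    def __len__(self):
        return len(self._nodes)

    def __eq__(self, other):
        if not isinstance(other, PathwayGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()


@dataclass(frozen=True)
class CurationRules:
    """Declarative stand-in for the human curation step."""

    accepted_types: frozenset[int] = frozenset({1})
    word_subtypes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_WORD_SUBTYPES))
    allow: Optional[frozenset[str]] = None
    deny: frozenset[str] = frozenset()
    strict: bool = False

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CurationRules":
        word_subtypes = dict(DEFAULT_WORD_SUBTYPES)
        word_subtypes.update(payload.get("word_subtypes", {}))
        allow = payload.get("allow")
        return cls(
            accepted_types=frozenset(payload.get("accepted_types", [1])),
            word_subtypes=word_subtypes,
            allow=frozenset(allow) if allow is not None else None,
            deny=frozenset(payload.get("deny", [])),
            strict=bool(payload.get("strict", False)),
        )


def _subtype_for(bi: Biointeraction, rules: CurationRules) -> str:
    if bi.word is not None and bi.word in rules.word_subtypes:
        return rules.word_subtypes[bi.word]
    if bi.polarity == "activation":
        return "activation"
    if bi.polarity == "repression":
        return "inhibition"
    if rules.strict:
        raise CurationError(
            f"cannot map interaction word {bi.word!r} (polarity {bi.polarity}) to a subtype")
    return "indirect"


def curate(interactions: Sequence[Biointeraction],
           rules: CurationRules = CurationRules()) -> PathwayGraph:
    """Apply curation rules to extracted interactions, producing a graph."""
    graph = PathwayGraph()
    for bi in interactions:
        if bi.type_code not in rules.accepted_types:
            continue
        if bi.gene_a in rules.deny or bi.gene_b in rules.deny:
            continue
        if rules.allow is not None and not {bi.gene_a, bi.gene_b} <= rules.allow:
            continue
        subtype = _subtype_for(bi, rules)
        evidence = [bi.pmid] if bi.pmid else []
        graph.add_edge(bi.gene_a, bi.gene_b, subtype, evidence)
    return graph


# ---------------------------------------------------------------------------
# KGML


def _attr(value: str) -> str:
    return escape(value, {'"': "&quot;"})


def write_kgml(graph: PathwayGraph, name: str = "path:litpath00001",
               org: str = "hsa", title: Optional[str] = None) -> bytes:
    """Serialize to a byte-stable KGML document.

    Entry ids are assigned in lexicographic symbol order starting at 1;
    graphics get deterministic grid coordinates.  Raises
    :class:`SerializationError` when an edge carries no evidence or a
    dangling endpoint is found.
    """
    symbols = sorted(graph.nodes)
    ids = {sym: i + 1 for i, sym in enumerate(symbols)}
    lines = ['<?xml version="1.0" encoding="UTF-8"?>',
             '<!DOCTYPE pathway SYSTEM "KGML_v0.7.2.dtd">']
    attrs = f'name="{_attr(name)}" org="{_attr(org)}"'
    if title:
        attrs += f' title="{_attr(title)}"'
    lines.append(f"<pathway {attrs}>")
    for i, sym in enumerate(symbols):
        node = graph.nodes[sym]
        if node.age_label not in _AGE_BGCOLOR:
            raise SerializationError(f"node {sym}: unknown age label {node.age_label!r}")
        x, y = 100 + 140 * (i % 8), 50 + 70 * (i // 8)
        display = sym + ("*" if node.fly_ortholog else "")
        lines.append(f'  <entry id="{ids[sym]}" name="{_attr(sym)}" type="gene">')
        lines.append(
            f'    <graphics name="{_attr(display)}" type="rectangle" '
            f'x="{x}" y="{y}" width="46" height="17" '
            f'fgcolor="#000000" bgcolor="{_AGE_BGCOLOR[node.age_label]}"/>')
        lines.append("  </entry>")
    for edge in graph.edges():
        for endpoint in (edge.source, edge.target):
            if endpoint not in ids:
                raise SerializationError(f"edge endpoint {endpoint!r} is not a node")
        if not edge.evidence:
            raise SerializationError(
                f"edge {edge.source}->{edge.target} ({edge.subtype}) has no evidence")
        rel_type = _RELATION_TYPE.get(edge.subtype, "PPrel")
        ev = " ".join(edge.evidence)
        lines.append(
            f'  <relation entry1="{ids[edge.source]}" entry2="{ids[edge.target]}" '
            f'type="{rel_type}" evidence="{_attr(ev)}">')
        lines.append(
            f'    <subtype name="{_attr(edge.subtype)}" value="{_attr(_SUBTYPE_VALUE[edge.subtype])}"/>')
        lines.append("  </relation>")
    lines.append("</pathway>")
    return ("\n".join(lines) + "\n").encode("utf-8")


def validate_kgml(document: bytes) -> bool:
    """Validate a KGML document against the packaged DTD."""
    parser = etree.XMLParser(load_dtd=False, no_network=True)
    root = etree.fromstring(document, parser)
    with open(kgml_dtd_path(), "rb") as fh:
        dtd = etree.DTD(fh)
    return bool(dtd.validate(root))


def read_kgml(document: bytes | str | Path) -> PathwayGraph:
    """Parse KGML back into a :class:`PathwayGraph`.

    Inverse of :func:`write_kgml` on its image.  Unknown relation subtypes
    are preserved as ``indirect`` with a warning; a relation referencing a
    missing entry id is a parse error naming the element path.
    """
    if isinstance(document, (str, Path)) and Path(str(document)).exists():
        document = Path(document).read_bytes()
    if isinstance(document, str):
        document = document.encode("utf-8")
    parser = etree.XMLParser(load_dtd=False, no_network=True)
    try:
        root = etree.fromstring(document, parser)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed KGML: {exc}") from exc
    graph = PathwayGraph()
    by_id: dict[str, str] = {}
    for entry in root.findall("entry"):
        symbol = entry.get("name")
        by_id[entry.get("id")] = symbol
        age, fly = None, False
        graphics = entry.find("graphics")
        if graphics is not None:
            display = graphics.get("name") or symbol
            fly = display.endswith("*")
            age = _BGCOLOR_AGE.get(graphics.get("bgcolor", "#FFFFFF"))
        graph.add_node(symbol, age_label=age, fly_ortholog=fly)
    for relation in root.findall("relation"):
        tree = relation.getroottree()
        for key in ("entry1", "entry2"):
            if relation.get(key) not in by_id:
                raise FormatError(
                    f"{tree.getpath(relation)}: relation references missing entry id "
                    f"{relation.get(key)!r}")
        sub = relation.find("subtype")
        subtype = sub.get("name") if sub is not None else "indirect"
        if subtype not in SUBTYPES:
            warnings.warn(f"unknown relation subtype {subtype!r}; preserving as 'indirect'")
            subtype = "indirect"
        evidence = (relation.get("evidence") or "").split()
        graph.add_edge(by_id[relation.get("entry1")], by_id[relation.get("entry2")],
                       subtype, evidence)
    return graph


def annotate_ancestry(graph: PathwayGraph, lca_results: Mapping[str, object]) -> PathwayGraph:
    """Label nodes ancient/recent/unassigned and set the fly-ortholog flag.

    ``lca_results`` maps gene symbol to any object exposing ``age_label``
    and ``fly_ortholog`` (an :class:`~litpath.ancestry.LCAResult`).  Symbols
    absent from the results become ``unassigned`` — the no-seed case.
    Never adds or removes nodes or edges.
    """
    out = graph.copy()
    for symbol, node in graph.nodes.items():
        res = lca_results.get(symbol)
        if res is None:
            out._nodes[symbol] = replace(node, age_label="unassigned", fly_ortholog=False)
        else:
            out._nodes[symbol] = replace(node, age_label=res.age_label,
                                         fly_ortholog=bool(res.fly_ortholog))
    return out


def to_networkx(graph: PathwayGraph):
    """Export as a networkx MultiDiGraph (e.g. for GraphML viewers)."""
    import networkx as nx

    g = nx.MultiDiGraph()
    for sym, node in sorted(graph.nodes.items()):
        g.add_node(sym, age_label=node.age_label or "",
                   fly_ortholog=node.fly_ortholog)
    for edge in graph.edges():
        g.add_edge(edge.source, edge.target, key=edge.subtype,
                   subtype=edge.subtype, evidence=" ".join(edge.evidence))
    return g
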