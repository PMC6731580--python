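"""RDF triples with Turtle and RDF/XML readers/writers.

The codec is intentionally small: it covers the constructs the annotation
documents use (IRIs, blank nodes, plain/typed/language literals, prefixed
names, comments, ``;``/``,`` continuations) rather than the full grammars.
Serialization is deterministic — subjects sorted, blank nodes renumbered in
traversal order — so a document double-serializes byte-stably.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .errors import ParseError

__all__ = [
    "IRI",
    "BNode",
    "Literal",
    "Triple",
    "RDF_NS",
    "XSD_NS",
    "parse_turtle",
    "serialize_turtle",
    "parse_rdfxml",
    "serialize_rdfxml",
    "merge_graphs",
    "canonical_triples",
]

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"


@dataclass(frozen=True)
class IRI:
    value: str

    def __str__(self):
        return self.value


@dataclass(frozen=True)
class BNode:
    id: str

    def __str__(self):
        return f"_:{self.id}"


@dataclass(frozen=True)
class Literal:
    """A literal compares by (lexical form, datatype, language); no value-space
    coercion — "1" typed as integer and "1.0" typed as decimal never compare equal."""

    lexical: str
    datatype: Optional[str] = None
    lang: Optional[str] = None

    def __str__(self):
        return self.lexical


Node = Union[IRI, BNode, Literal]


@dataclass(frozen=True)
class Triple:
    subject: Union[IRI, BNode]
    predicate: IRI
    object: Node

    def __post_init__(self):
        if isinstance(self.subject, Literal):
            raise ValueError("literals may not be triple subjects")
        if not isinstance(self.predicate, IRI):
            raise ValueError("predicates must be IRIs")


# --------------------------------------------------------------------------
# ordering / canonicalization helpers

_KIND_ORDER = {IRI: 0, BNode: 1, Literal: 2}


def _node_key(node: Node) -> tuple:
    if isinstance(node, Literal):
        return (2, node.lexical, node.datatype or "", node.lang or "")
    if isinstance(node, BNode):
        return (1, node.id)
    return (0, node.value)


def triple_key(t: Triple) -> tuple:
    return (_node_key(t.subject), _node_key(t.predicate), _node_key(t.object))


def _bnode_signature(triples: Sequence[Triple], bid: str, depth: int = 2) -> tuple:
    """Label-independent signature of a blank node from its neighborhood."""

    def node_sig(node: Node, d: int) -> tuple:
        if isinstance(node, BNode):
            if d <= 0:
                return ("~",)
            return ("~",) + _bnode_signature(triples, node.id, d - 1)
        return _node_key(node)

    out, inc = [], []
    for t in triples:
        if isinstance(t.subject, BNode) and t.subject.id == bid:
            out.append((t.predicate.value, node_sig(t.object, depth)))
        if isinstance(t.object, BNode) and t.object.id == bid:
            inc.append((t.predicate.value, node_sig(t.subject, depth)))
    return (tuple(sorted(out)), tuple(sorted(inc)))


def canonical_triples(triples: Iterable[Triple]) -> list[Triple]:
    """Triples with blank nodes relabelled ``b0, b1, ...`` by a neighborhood
    signature, sorted.  Two isomorphic graphs (whose blank nodes are
    distinguishable by their neighborhoods, as annotation graphs are)
    canonicalize to the same list."""
    ts = list(set(triples))
    bids = sorted(
        {n.id for t in ts for n in (t.subject, t.object) if isinstance(n, BNode)}
    )
    sigs = {bid: _bnode_signature(ts, bid) for bid in bids}
    ordered = sorted(bids, key=lambda b: (sigs[b], b))
    mapping = {old: f"b{i}" for i, old in enumerate(ordered)}

    def remap(node: Node) -> Node:
        if isinstance(node, BNode):
            return BNode(mapping[node.id])
        return node

    out = [Triple(remap(t.subject), t.predicate, remap(t.object)) for t in ts]
    return sorted(set(out), key=triple_key)


def merge_graphs(graphs: Sequence[Iterable[Triple]]) -> set[Triple]:
    """Set-union of several documents' triples with blank nodes renamed apart,
    per standard RDF merge semantics (a shared ``_:x`` label in two documents
    denotes two distinct nodes)."""
    merged: set[Triple] = set()
    for i, graph in enumerate(graphs):
        def remap(node: Node, i=i) -> Node:
            if isinstance(node, BNode):
                return BNode(f"d{i}-{node.id}")
            return node

        for t in graph:
            merged.add(Triple(remap(t.subject), t.predicate, remap(t.object)))
    return merged


def _resolve(ref: str, base: Optional[str]) -> str:
    """Resolve a same-document or sibling reference against a base name.

    Entity URIs are workspace-relative (``weinstein_1995.cellml#NHE3.x``), so
    resolution is string-level: ``#frag`` attaches to the base document name.
    """
    if base and ref.startswith("#"):
        return base + ref
    return ref


# --------------------------------------------------------------------------
# Turtle

_TOKEN = re.compile(
    r"""
    (?P<comment>\#[^\n]*)
  | (?P<iri><[^<>"{}|^`\\\s]*>)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<bnode>_:[A-Za-z0-9][A-Za-z0-9_.-]*)
  | (?P<langtag>@[A-Za-z]+(?:-[A-Za-z0-9]+)*)
  | (?P<dtype>\^\^)
  | (?P<punct>[;,.\[\]])
  | (?P<pname>[A-Za-z][\w.-]*)?:(?P<local>[\w.%-]*)
  | (?P<kw>@?[A-Za-z]+)
  | (?P<num>[+-]?\d+(?:\.\d+)?)
    """,
    re.VERBOSE,
)

_STR_ESCAPES = {
    "\\n": "\n", "\\t": "\t", "\\r": "\r",
    '\\"': '"', "\\\\": "\\",
}


def _unescape(s: str) -> str:
    return re.sub(
        r"\\.", lambda m: _STR_ESCAPES.get(m.group(0), m.group(0)[1]), s
    )


def _escape(s: str) -> str:
    return (
        s.replace("\\", "\\\\").replace('"', '\\"')
        .replace("\n", "\\n").replace("\r", "\\r").replace("\t", "\\t")
    )


def parse_turtle(
    text: str, base: Optional[str] = None, source: str = "<string>"
) -> list[Triple]:
    """Parse a Turtle document into triples.

    Supports ``@prefix``/``PREFIX``, IRIs, prefixed names, the ``a`` keyword,
    blank-node labels and ``[]``, plain/typed/language literals, numeric
    shorthand, and ``;``/``,`` continuations.
    """
    tokens: list[tuple[str, str, int]] = []  # (kind, text, pos)
    pos = 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN.match(text, pos)
        if not m:
            line = text.count("\n", 0, pos) + 1
            raise ParseError(f"{source}:{line}: unexpected character {text[pos]!r}")
        kind = m.lastgroup if m.lastgroup != "local" else "pname"
        if m.group("pname") is not None or m.group("local") is not None:
            kind = "pname"
        if m.group(0) in ("@prefix", "@base"):  # langtag pattern shadows these
            kind = "kw"
        if kind != "comment":
            tokens.append((kind, m.group(0), m.start()))
        pos = m.end()

    prefixes: dict[str, str] = {}
    triples: list[Triple] = []
    bnode_counter = [0]
    i = 0

    def err(msg: str, at: int) -> ParseError:
        line = text.count("\n", 0, at) + 1
        return ParseError(f"{source}:{line}: {msg}")

    def expand_pname(tok: str, at: int) -> str:
        pfx, _, local = tok.partition(":")
        if pfx not in prefixes:
            raise err(f"undeclared prefix {pfx!r}", at)
        return prefixes[pfx] + local

    def parse_node(allow_literal: bool):
        nonlocal i
        kind, tok, at = tokens[i]
        if kind == "iri":
            i += 1
            return IRI(_resolve(tok[1:-1], base))
        if kind == "pname":
            i += 1
            return IRI(expand_pname(tok, at))
        if kind == "bnode":
            i += 1
            return BNode(tok[2:])
        if kind == "punct" and tok == "[":
            i += 1
            if tokens[i][1] != "]":
                raise err("non-empty [...] blank nodes are not supported", at)
            i += 1
            bnode_counter[0] += 1
            return BNode(f"anon{bnode_counter[0]}")
        if kind == "kw" and tok == "a":
            i += 1
            return IRI(RDF_NS + "type")
        if not allow_literal:
            raise err(f"expected IRI or blank node, got {tok!r}", at)
        if kind == "string":
            i += 1
            lex = _unescape(tok[1:-1])
            if i < len(tokens) and tokens[i][0] == "langtag":
                lang = tokens[i][1][1:]
                i += 1
                return Literal(lex, lang=lang)
            if i < len(tokens) and tokens[i][0] == "dtype":
                i += 1
                dt = parse_node(allow_literal=False)
                if not isinstance(dt, IRI):
                    raise err("literal datatype must be an IRI", at)
                return Literal(lex, datatype=dt.value)
            return Literal(lex)
        if kind == "num":
            i += 1
            dt = XSD_NS + ("decimal" if "." in tok else "integer")
            return Literal(tok, datatype=dt)
        raise err(f"unexpected token {tok!r}", at)

    while i < len(tokens):
        kind, tok, at = tokens[i]
        if (kind == "kw" and tok in ("@prefix", "@base")) or (
            kind == "pname" and tok.upper().startswith("PREFIX")
        ) or (kind == "kw" and tok.upper() in ("PREFIX", "BASE")):
            directive = tok.lstrip("@").upper()
            i += 1
            if directive == "BASE":
                k2, t2, _ = tokens[i]
                if k2 != "iri":
                    raise err("@base expects an IRI", at)
                base = t2[1:-1]
                i += 1
            else:
                k2, t2, a2 = tokens[i]
                if k2 != "pname" or not t2.endswith(":"):
                    raise err("@prefix expects 'pfx:'", a2)
                pfx = t2[:-1]
                i += 1
                k3, t3, a3 = tokens[i]
                if k3 != "iri":
                    raise err("@prefix expects an IRI", a3)
                prefixes[pfx] = t3[1:-1]
                i += 1
            if i < len(tokens) and tokens[i][1] == ".":
                i += 1
            continue

        subject = parse_node(allow_literal=False)
        while True:  # predicate-object list
            predicate = parse_node(allow_literal=False)
            if not isinstance(predicate, IRI):
                raise err("predicate must be an IRI", at)
            while True:  # object list
                obj = parse_node(allow_literal=True)
                triples.append(Triple(subject, predicate, obj))
                if i < len(tokens) and tokens[i][1] == ",":
                    i += 1
                    continue
                break
            if i < len(tokens) and tokens[i][1] == ";":
                i += 1
                if i < len(tokens) and tokens[i][1] == ".":
                    i += 1
                    break
                continue
            if i < len(tokens) and tokens[i][1] == ".":
                i += 1
                break
            raise err("expected '.', ';' or ',' after object", at)
    return triples


def _turtle_term(node: Node, prefixes: dict[str, str]) -> str:
    if isinstance(node, IRI):
        for pfx, stem in prefixes.items():
            if node.value.startswith(stem):
                local = node.value[len(stem):]
                if re.fullmatch(r"[\w.%-]*", local):
                    return f"{pfx}:{local}"
        return f"<{node.value}>"
    if isinstance(node, BNode):
        return f"_:{node.id}"
    lit = f'"{_escape(node.lexical)}"'
    if node.lang:
        return f"{lit}@{node.lang}"
    if node.datatype:
        return f"{lit}^^{_turtle_term(IRI(node.datatype), prefixes)}"
    return lit


def serialize_turtle(
    triples: Iterable[Triple], prefixes: Optional[dict[str, str]] = None
) -> str:
    """Deterministic Turtle text: prefixes sorted, triples canonicalized
    (subjects sorted by IRI, blank nodes renumbered in traversal order)."""
    prefixes = dict(prefixes or {})
    lines = [f"@prefix {p}: <{u}> ." for p, u in sorted(prefixes.items())]
    if lines:
        lines.append("")
    for t in canonical_triples(triples):
        lines.append(
            f"{_turtle_term(t.subject, prefixes)} "
            f"{_turtle_term(t.predicate, prefixes)} "
            f"{_turtle_term(t.object, prefixes)} ."
        )
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# RDF/XML

def _split_iri(iri: str) -> tuple[str, str]:
    m = re.search(r"[#/](?=[^#/]+$)", iri)
    if not m:
        raise ValueError(f"cannot derive a QName from predicate IRI {iri!r}")
    return iri[: m.end()], iri[m.end():]


def parse_rdfxml_element(
    rdf_elem: ET.Element, base: Optional[str] = None, source: str = "<xml>"
) -> list[Triple]:
    """Extract triples from an ``rdf:RDF`` element (standalone or embedded in
    a CellML document)."""
    triples: list[Triple] = []
    counter = [0]

    def fresh_bnode() -> BNode:
        counter[0] += 1
        return BNode(f"genid{counter[0]}")

    def node_id(elem: ET.Element) -> Union[IRI, BNode]:
        about = elem.get(f"{{{RDF_NS}}}about")
        if about is not None:
            return IRI(_resolve(about, base))
        nid = elem.get(f"{{{RDF_NS}}}nodeID")
        if nid is not None:
            return BNode(nid)
        rid = elem.get(f"{{{RDF_NS}}}ID")
        if rid is not None:
            return IRI(_resolve("#" + rid, base))
        return fresh_bnode()

    def elem_iri(elem: ET.Element) -> str:
        tag = elem.tag
        if not tag.startswith("{"):
            raise ParseError(f"{source}: unqualified element {tag!r} in RDF")
        ns, local = tag[1:].split("}", 1)
        joiner = "" if ns.endswith(("#", "/")) else "#"
        return f"{ns}{joiner}{local}"

    def walk_node(elem: ET.Element) -> Union[IRI, BNode]:
        subj = node_id(elem)
        if elem_iri(elem) != RDF_NS + "Description":
            triples.append(Triple(subj, IRI(RDF_NS + "type"), IRI(elem_iri(elem))))
        for prop in elem:
            pred = IRI(elem_iri(prop))
            res = prop.get(f"{{{RDF_NS}}}resource")
            nid = prop.get(f"{{{RDF_NS}}}nodeID")
            dtype = prop.get(f"{{{RDF_NS}}}datatype")
            lang = prop.get("{http://www.w3.org/XML/1998/namespace}lang")
            children = list(prop)
            if res is not None:
                triples.append(Triple(subj, pred, IRI(_resolve(res, base))))
            elif nid is not None:
                triples.append(Triple(subj, pred, BNode(nid)))
            elif children:
                obj = walk_node(children[0])
                triples.append(Triple(subj, pred, obj))
            else:
                text = prop.text or ""
                triples.append(Triple(subj, pred, Literal(text, dtype, lang)))
        return subj

    for child in rdf_elem:
        walk_node(child)
    return triples


def parse_rdfxml(
    text: str, base: Optional[str] = None, source: str = "<xml>"
) -> list[Triple]:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"{source}: {exc}") from exc
    if root.tag == f"{{{RDF_NS}}}RDF":
        return parse_rdfxml_element(root, base=base, source=source)
    blocks = root.findall(f".//{{{RDF_NS}}}RDF")
    triples: list[Triple] = []
    for block in blocks:
        triples.extend(parse_rdfxml_element(block, base=base, source=source))
    return triples


def serialize_rdfxml(
    triples: Iterable[Triple], prefixes: Optional[dict[str, str]] = None
) -> str:
    """Deterministic RDF/XML: one ``rdf:Description`` per subject, subjects
    and predicates sorted; namespace prefixes assigned deterministically."""
    canon = canonical_triples(triples)
    ns_map: dict[str, str] = {RDF_NS: "rdf"}
    for pfx, stem in sorted((prefixes or {}).items()):
        if stem.endswith(("#", "/")) and stem not in ns_map:
            ns_map[stem] = pfx
    for t in canon:
        ns, _ = _split_iri(t.predicate.value)
        if ns not in ns_map:
            ns_map[ns] = f"ns{len(ns_map)}"

    by_subject: dict[tuple, list[Triple]] = {}
    for t in canon:
        by_subject.setdefault(_node_key(t.subject), []).append(t)

    out = ['<?xml version="1.0" encoding="UTF-8"?>']
    decls = " ".join(
        f'xmlns:{p}="{ns}"' for ns, p in sorted(ns_map.items(), key=lambda kv: kv[1])
    )
    out.append(f"<rdf:RDF {decls}>")
    for key in sorted(by_subject):
        group = by_subject[key]
        subj = group[0].subject
        attr = (
            f'rdf:about="{subj.value}"'
            if isinstance(subj, IRI)
            else f'rdf:nodeID="{subj.id}"'
        )
        out.append(f"  <rdf:Description {attr}>")
        for t in group:
            ns, local = _split_iri(t.predicate.value)
            q = f"{ns_map[ns]}:{local}"
            o = t.object
            if isinstance(o, IRI):
                out.append(f'    <{q} rdf:resource="{o.value}"/>')
            elif isinstance(o, BNode):
                out.append(f'    <{q} rdf:nodeID="{o.id}"/>')
            else:
                extra = ""
                if o.datatype:
                    extra = f' rdf:datatype="{o.datatype}"'
                elif o.lang:
                    extra = f' xml:lang="{o.lang}"'
                text = (
                    o.lexical.replace("&", "&amp;").replace("<", "&lt;")
                    .replace(">", "&gt;")
                )
                out.append(f"    <{q}{extra}>{text}</{q}>")
        out.append("  </rdf:Description>")
    out.append("</rdf:RDF>")
    return "\n".join(out) + "\n"


def read_rdf_file(path: str | Path, base: Optional[str] = None) -> list[Triple]:
    """Read an RDF document, dispatching on extension (.ttl/.turtle vs .rdf/.xml)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".ttl", ".turtle"):
        return parse_turtle(text, base=base, source=str(path))
    return parse_rdfxml(text, base=base, source=str(path))
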