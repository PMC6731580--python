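"""CellML document parsing: components, variables and metadata identifiers.

Only the structural skeleton of a model is read — components, the variables
they declare, units attributes and ``cmeta:id`` anchors.  MathML content is
deliberately skipped: annotation never touches the mathematics.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import ParseError, UnsupportedDialectError
from .rdfio import RDF_NS, Triple, parse_rdfxml_element

CELLML_1_0 = "http://www.cellml.org/cellml/1.0#"
CELLML_1_1 = "http://www.cellml.org/cellml/1.1#"
CELLML_2_0 = "http://www.cellml.org/cellml/2.0#"
CMETA_NS = "http://www.cellml.org/metadata/1.0#"

SUPPORTED_NS = (CELLML_1_0, CELLML_1_1)


@dataclass(frozen=True)
class CellmlVariable:
    component: str
    name: str
    units: Optional[str] = None
    metadata_id: Optional[str] = None


@dataclass(frozen=True)
class CellmlComponent:
    name: str
    metadata_id: Optional[str] = None


@dataclass
class CellmlModel:
    file: str
    name: str
    components: list[CellmlComponent] = field(default_factory=list)
    variables: list[CellmlVariable] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_variables(self) -> int:
        return len(self.variables)


def _cmeta_id(elem: ET.Element) -> Optional[str]:
    return elem.get(f"{{{CMETA_NS}}}id")


def parse_cellml(path: str | Path) -> CellmlModel:
    """Parse a CellML 1.0/1.1 file into its component/variable skeleton.

    Raises :class:`ParseError` for malformed XML (message carries the line
    number) and :class:`UnsupportedDialectError` for non-CellML or CellML 2.0
    documents.
    """
    path = Path(path)
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    root = tree.getroot()
    if not root.tag.startswith("{"):
        raise UnsupportedDialectError(f"{path}: element {root.tag!r} has no namespace")
    ns = root.tag[1:].split("}", 1)[0]
    if not ns.endswith("#"):
        ns += "#"
    if ns == CELLML_2_0:
        raise UnsupportedDialectError(
            f"{path}: CellML 2.0 uses a different metadata mechanism and is not supported"
        )
    if ns not in SUPPORTED_NS:
        raise UnsupportedDialectError(f"{path}: unsupported XML namespace {ns!r}")

    model = CellmlModel(file=path.name, name=root.get("name", path.stem))
    seen_components: set[str] = set()
    seen_ids: set[str] = set()

    def check_id(mid: Optional[str], what: str) -> Optional[str]:
        if mid is not None:
            if mid in seen_ids:
                raise ParseError(f"{path}: duplicate metadata id {mid!r} on {what}")
            seen_ids.add(mid)
        return mid

    root_id = _cmeta_id(root)
    if root_id is not None:
        seen_ids.add(root_id)

    comp_tag = f"{{{ns}}}component"
    var_tag = f"{{{ns}}}variable"
    for comp in root.iter(comp_tag):
        cname = comp.get("name")
        if not cname:
            raise ParseError(f"{path}: component without a name attribute")
        if cname in seen_components:
            raise ParseError(f"{path}: duplicate component name {cname!r}")
        seen_components.add(cname)
        model.components.append(
            CellmlComponent(name=cname, metadata_id=check_id(_cmeta_id(comp), cname))
        )
        seen_vars: set[str] = set()
        for var in comp.iter(var_tag):
            vname = var.get("name")
            if not vname:
                raise ParseError(f"{path}: variable without a name in {cname!r}")
            if vname in seen_vars:
                raise ParseError(
                    f"{path}: duplicate variable {vname!r} in component {cname!r}"
                )
            seen_vars.add(vname)
            model.variables.append(
                CellmlVariable(
                    component=cname,
                    name=vname,
                    units=var.get("units"),
                    metadata_id=check_id(_cmeta_id(var), f"{cname}.{vname}"),
                )
            )
    return model


def embedded_rdf(path: str | Path) -> list[Triple]:
    """Triples from ``rdf:RDF`` blocks embedded inside a CellML document.

    Same-document references (``#id``) resolve against the file *name*, per
    the workspace-relative entity URI scheme.
    """
    path = Path(path)
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    triples: list[Triple] = []
    for block in tree.getroot().iter(f"{{{RDF_NS}}}RDF"):
        triples.extend(parse_rdfxml_element(block, base=path.name, source=str(path)))
    return triples
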