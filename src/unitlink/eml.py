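"""Annotate EML metadata documents with QUDT unit URIs.

EML (Ecological Metadata Language) 2.2 added ``<annotation>`` elements that
carry RDF-style property/value URI pairs.  This module reads the unit
declarations of attribute-level ``<unit>`` elements (``standardUnit`` or
``customUnit``), resolves each through the lookup table, and emits an
edited copy of the document in which every resolvable attribute gains an
annotation whose value URI is the QUDT unit URI::

    <annotation>
      <propertyURI label="has unit">http://qudt.org/schema/qudt/hasUnit</propertyURI>
      <valueURI label="micromole per litre">http://qudt.org/vocab/unit/MicroMOL-PER-L</valueURI>
    </annotation>

The source document is never modified in place; annotation is idempotent
(an identical existing annotation is not duplicated).  Optionally the
package revision number is bumped and deterministic ``id`` attributes are
added to attributes that lack them.  Only EML 2.2+ documents are accepted —
annotation support entered the schema at 2.2, so older documents produce a
clear error rather than a silent upgrade.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass
from pathlib import Path

from lxml import etree

__all__ = [
    "DEFAULT_PROPERTY_URI",
    "DEFAULT_PROPERTY_LABEL",
    "EmlError",
    "UnitOccurrence",
    "AnnotationTriple",
    "parse_eml",
    "extract_units",
    "annotate_document",
    "validate_eml",
]

DEFAULT_PROPERTY_URI = "http://qudt.org/schema/qudt/hasUnit"
DEFAULT_PROPERTY_LABEL = "has unit"

_EML_NS_RE = re.compile(r"eml-(\d+)\.(\d+)")


class EmlError(ValueError):
    """Raised for malformed, non-EML or pre-2.2 documents."""


@dataclass(frozen=True)
class UnitOccurrence:
    """One attribute-level unit declaration."""

    attribute_id: str
    path: str  # XPath of the standardUnit/customUnit element
    raw_unit: str
    kind: str  # standardUnit | customUnit


@dataclass(frozen=True)
class AnnotationTriple:
    subject: str
    property_uri: str
    property_label: str
    value_uri: str
    value_label: str

    def __post_init__(self) -> None:
        for uri in (self.property_uri, self.value_uri):
            if "://" not in uri:
                raise EmlError(f"annotation URI must be absolute: {uri!r}")
        if not self.property_label or not self.value_label:
            raise EmlError("annotation labels must be nonempty")


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def parse_eml(source) -> etree._ElementTree:
    """Parse an EML document from a path, bytes or an existing tree.

    Requires well-formed XML whose root namespace is EML 2.2 or later.
    """
    if isinstance(source, etree._ElementTree):
        tree = source
    elif isinstance(source, (str, Path)):
        try:
            tree = etree.parse(str(source))
        except (OSError, etree.XMLSyntaxError) as exc:
            raise EmlError(f"cannot parse EML document: {exc}") from None
    elif isinstance(source, bytes):
        try:
            tree = etree.ElementTree(etree.fromstring(source))
        except etree.XMLSyntaxError as exc:
            raise EmlError(f"cannot parse EML document: {exc}") from None
    else:
        raise EmlError(f"unsupported EML source type {type(source)!r}")
    root = tree.getroot()
    ns = root.tag[1:].split("}", 1)[0] if root.tag.startswith("{") else ""
    m = _EML_NS_RE.search(ns)
    if _local(root.tag) != "eml" or not m:
        raise EmlError(f"root element is not in an EML namespace: {root.tag!r}")
    if (int(m.group(1)), int(m.group(2))) < (2, 2):
        raise EmlError(
            f"EML {m.group(1)}.{m.group(2)} predates annotation support; "
            "only EML 2.2+ documents can be annotated"
        )
    return tree


def _iter_attributes(tree):
    """Attribute elements in document order, with generated fallback ids."""
    for i, elem in enumerate(tree.getroot().iter(), start=0):
        if _local(elem.tag) == "attribute":
            yield elem


def _attribute_id(elem, index: int, prefix: str = "attr") -> str:
    existing = elem.get("id")
    if existing:
        return existing
    return f"{prefix}.{index}"


def _unit_element(attribute_elem):
    for elem in attribute_elem.iter():
        if _local(elem.tag) == "unit":
            for child in elem:
                if _local(child.tag) in ("standardUnit", "customUnit"):
                    return child
    return None


def extract_units(source) -> list[UnitOccurrence]:
    """One occurrence per attribute-level unit element, in document order."""
    tree = parse_eml(source)
    occurrences = []
    for i, attr in enumerate(_iter_attributes(tree), start=1):
        unit_elem = _unit_element(attr)
        if unit_elem is None:
            continue
        occurrences.append(
            UnitOccurrence(
                attribute_id=_attribute_id(attr, i),
                path=tree.getpath(unit_elem),
                raw_unit=(unit_elem.text or "").strip(),
                kind=_local(unit_elem.tag),
            )
        )
    return occurrences


def _has_annotation(attr_elem, property_uri: str, value_uri: str) -> bool:
    for elem in attr_elem:
        if _local(elem.tag) != "annotation":
            continue
        prop = value = None
        for child in elem:
            if _local(child.tag) == "propertyURI":
                prop = (child.text or "").strip()
            elif _local(child.tag) == "valueURI":
                value = (child.text or "").strip()
        if prop == property_uri and value == value_uri:
            return True
    return False


def annotate_document(
    source,
    resolver,
    *,
    bump_revision: bool = False,
    add_ids: bool = False,
    property_uri: str = DEFAULT_PROPERTY_URI,
    property_label: str = DEFAULT_PROPERTY_LABEL,
    id_prefix: str = "attr",
) -> tuple[etree._ElementTree, dict]:
    """Return an annotated copy of the document and a match report.

    ``resolver`` is any object with a one-argument ``resolve(raw)`` method
    returning a match result (:class:`unitlink.lookup.Resolver` fits).
    """
    tree = copy.deepcopy(parse_eml(source))
    root = tree.getroot()

    if bump_revision:
        package_id = root.get("packageId") or ""
        m = re.search(r"^(.*?)(\d+)$", package_id)
        if not m:
            raise EmlError(
                f"packageId {package_id!r} has no trailing revision integer to bump"
            )
        root.set("packageId", m.group(1) + str(int(m.group(2)) + 1))

    report = {"matched": [], "unmatched": [], "annotations_added": 0}
    for i, attr in enumerate(_iter_attributes(tree), start=1):
        unit_elem = _unit_element(attr)
        if unit_elem is None:
            continue
        if add_ids and not attr.get("id"):
            attr.set("id", f"{id_prefix}.{i}")
        attr_id = _attribute_id(attr, i, id_prefix)
        raw = (unit_elem.text or "").strip()
        result = resolver.resolve(raw)
        if not result.matched:
            report["unmatched"].append(
                {
                    "attribute_id": attr_id,
                    "raw_unit": raw,
                    "candidate": result.candidate.finalized if result.candidate else None,
                }
            )
            continue
        unit = result.matched_unit
        report["matched"].append(
            {
                "attribute_id": attr_id,
                "raw_unit": raw,
                "qudt_code": unit.code,
                "uri": unit.uri,
                "match_path": result.match_path,
            }
        )
        if _has_annotation(attr, property_uri, unit.uri):
            continue
        annotation = etree.SubElement(attr, "annotation")
        prop = etree.SubElement(annotation, "propertyURI", label=property_label)
        prop.text = property_uri
        value = etree.SubElement(annotation, "valueURI", label=unit.label)
        value.text = unit.uri
        report["annotations_added"] += 1
    return tree, report


def annotation_fragment(unit, property_uri: str = DEFAULT_PROPERTY_URI,
                        property_label: str = DEFAULT_PROPERTY_LABEL) -> str:
    """The EML-ready ``<annotation>`` element for one matched unit, as text."""
    annotation = etree.Element("annotation")
    prop = etree.SubElement(annotation, "propertyURI", label=property_label)
    prop.text = property_uri
    value = etree.SubElement(annotation, "valueURI", label=unit.label)
    value.text = unit.uri
    return etree.tostring(annotation, pretty_print=True, encoding="unicode").strip()


def validate_eml(tree_or_source, schema_path=None) -> None:
    """Validate a document against the bundled reduced EML 2.2 schema.

    The bundled schema is a synthetic subset of EML 2.2 covering the
    document structures this package reads and writes; it is not the
    official multi-file EML distribution.  Raises :class:`EmlError` with
    the validator's message on failure.
    """
    if schema_path is None:
        from .resources import data_path

        schema_path = data_path("eml_2_2_synthetic_subset.xsd")
    schema = etree.XMLSchema(etree.parse(str(schema_path)))
    tree = tree_or_source if isinstance(tree_or_source, etree._ElementTree) else parse_eml(tree_or_source)
    if not schema.validate(tree):
        raise EmlError(f"document is not schema-valid: {schema.error_log}")
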