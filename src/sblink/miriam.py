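"""MIRIAM annotation extraction.

BioModels-style SBML elements carry an ``<annotation>`` block whose RDF
payload links the element to external resources through qualifier elements
(``bqbiol:is``, ``bqmodel:isDescribedBy``, ...), each wrapping an
``rdf:Bag`` of ``rdf:li`` items with ``urn:miriam:namespace:id`` resources.
This module turns those blocks into flat :class:`AnnotationLink` tuples.

Extraction is deliberately forgiving: a record whose annotation does not
parse is skipped with a warning, non-MIRIAM resources are skipped with a
warning, and unrecognized qualifier names are mapped to ``unknown`` — an
ingest over thousands of curated-by-hand documents must never die on one
messy annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from urllib.parse import unquote

from lxml import etree

from .errors import MalformedUrnError
from .records import SbaseRecord

logger = logging.getLogger(__name__)

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"


class Qualifier(str, Enum):
    """Relation between a model component and an annotation resource."""

    IS = "is"
    IS_DESCRIBED_BY = "isDescribedBy"
    IS_DERIVED_FROM = "isDerivedFrom"
    ENCODES = "encodes"
    HAS_PART = "hasPart"
    HAS_PROPERTY = "hasProperty"
    HAS_TAXON = "hasTaxon"
    HAS_VERSION = "hasVersion"
    IS_ENCODED_BY = "isEncodedBy"
    IS_HOMOLOG_TO = "isHomologTo"
    IS_PART_OF = "isPartOf"
    IS_PROPERTY_OF = "isPropertyOf"
    IS_VERSION_OF = "isVersionOf"
    OCCURS_IN = "occursIn"
    UNKNOWN = "unknown"


#: Names pre-filled in the persisted qualifier dimension; the remaining enum
#: members are accepted and inserted into the dimension on first use.
PREFILLED_QUALIFIERS: tuple[str, ...] = (
    "is", "isDescribedBy", "encodes", "hasPart", "hasVersion", "isEncodedBy",
    "isHomologTo", "isPartOf", "isVersionOf", "occursIn", "unknown",
)


class QualifierFamily(str, Enum):
    MODEL = "model"
    BIOLOGY = "biology"


@dataclass(frozen=True)
class AnnotationLink:
    """One (subject, qualifier, namespace, external id) annotation tuple."""

    subject_sbase_id: str
    qualifier: Qualifier
    family: QualifierFamily
    namespace: str  # stored lowercase, e.g. "kegg.compound"
    external_id: str  # percent-decoded, case preserved
    raw_urn: str

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.qualifier.value, self.namespace, self.external_id)


def parse_miriam_urn(urn: str) -> tuple[str, str]:
    """Split ``urn:miriam:<namespace>:<id>`` into (namespace, external id).

    The namespace segment never contains a colon, so the first ``:`` after
    the scheme separates namespace from id; percent-escapes in the id (the
    encoded colon of GO/ChEBI accessions) are decoded exactly once.
    Namespaces compare case-insensitively and are returned lowercase; ids
    keep their case.

    >>> parse_miriam_urn("urn:miriam:obo.go:GO%3A0006096")
    ('obo.go', 'GO:0006096')
    """
    prefix = "urn:miriam:"
    if not urn.lower().startswith(prefix):
        raise MalformedUrnError(f"not a MIRIAM URN: {urn!r}")
    rest = urn[len(prefix):]
    namespace, sep, external_id = rest.partition(":")
    if not sep or not namespace or not external_id:
        raise MalformedUrnError(f"MIRIAM URN missing namespace or id: {urn!r}")
    return namespace.lower(), unquote(external_id)


def classify_qualifier(element_name: str) -> tuple[Qualifier, QualifierFamily]:
    """Map a prefixed qualifier element name to (qualifier, family).

    ``bqmodel:`` prefixes belong to the model family, every other prefix
    (normally ``bqbiol:``) to the biology family.  Local names are matched
    case-sensitively against the known qualifiers; anything else becomes
    ``unknown`` in the prefix's family.
    """
    prefix, _, local = element_name.rpartition(":")
    family = (
        QualifierFamily.MODEL if prefix == "bqmodel" else QualifierFamily.BIOLOGY
    )
    try:
        qualifier = Qualifier(local)
    except ValueError:
        qualifier = Qualifier.UNKNOWN
    return qualifier, family


def _family_of_ns(ns: str) -> QualifierFamily | None:
    if ns == BQMODEL_NS:
        return QualifierFamily.MODEL
    if ns == BQBIOL_NS:
        return QualifierFamily.BIOLOGY
    return None


def extract_annotation_links(record: SbaseRecord) -> list[AnnotationLink]:
    """Extract all MIRIAM links from a record's raw annotation block.

    One link per ``rdf:li`` inside each qualifier element's ``rdf:Bag``;
    duplicates on (qualifier, namespace, id) collapse to one.  Unparseable
    annotations and non-MIRIAM resources are skipped with a warning.
    """
    if not record.annotation:
        return []
    try:
        root = etree.fromstring(record.annotation.encode())
    except etree.XMLSyntaxError as exc:
        logger.warning(
            "skipping unparseable annotation on %s: %s", record.id, exc
        )
        return []

    links: list[AnnotationLink] = []
    seen: set[tuple[str, str, str]] = set()
    for el in root.iter():
        if not isinstance(el.tag, str):
            continue
        qname = etree.QName(el)
        family = _family_of_ns(qname.namespace)
        if family is None:
            continue
        try:
            qualifier = Qualifier(qname.localname)
        except ValueError:
            qualifier = Qualifier.UNKNOWN
        for li in el.iter(f"{{{RDF_NS}}}li"):
            resource = li.get(f"{{{RDF_NS}}}resource")
            if resource is None:
                continue
            try:
                namespace, external_id = parse_miriam_urn(resource)
            except MalformedUrnError:
                logger.warning(
                    "skipping non-MIRIAM resource %r on %s", resource, record.id
                )
                continue
            link = AnnotationLink(
                subject_sbase_id=record.id,
                qualifier=qualifier,
                family=family,
                namespace=namespace,
                external_id=external_id,
                raw_urn=resource,
            )
            if link.key in seen:
                continue
            seen.add(link.key)
            links.append(link)
    return links


def extract_links_from_bundle(bundle) -> list[AnnotationLink]:
    """Extract links from every Sbase-bearing record of a model bundle."""
    links: list[AnnotationLink] = []
    for record in bundle.all_sbase_records():
        links.extend(extract_annotation_links(record))
    return links
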