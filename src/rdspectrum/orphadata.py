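"""Adapter for Orphadata-style product XML.

Orphadata publishes the content of the Orphanet knowledge base as several
"product" XML files (epidemiology, associated genes, HPO phenotypes, natural
history, linearisation).  This adapter targets the 2020-era element
vocabulary (``JDBOR``/``DisorderList``/``Disorder`` with facet-specific
sub-lists), detects the dialect of each file from its content, and merges all
facets into one :class:`~rdspectrum.registry.DisorderRegistry` keyed by
orphacode.  Unknown elements are ignorable by design: the files drift between
releases, so the parser extracts what it recognizes and counts what it
skipped.

Annotations are mapped verbatim; notably, HPO annotations with occurrence
"Excluded (0%)" are *kept* at parse time — downstream analytics decide what
to omit.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

from lxml import etree

from .registry import (
    AssociationType,
    DisorderGroup,
    DisorderRecord,
    DisorderRegistry,
    DisorderType,
    GeneAssociation,
    GeographicScope,
    HPOAnnotation,
    Inheritance,
    Occurrence,
    PrevalenceClass,
    PrevalenceKind,
    PrevalenceRecord,
    Provenance,
)

__all__ = ["OrphadataParseError", "parse_orphadata_products", "detect_dialect"]

logger = logging.getLogger(__name__)


class OrphadataParseError(Exception):
    pass


SUPPORTED_DIALECTS = (
    "epidemiology",
    "genes",
    "phenotypes",
    "natural_history",
    "linearisation",
)

_DIALECT_MARKERS = {
    "epidemiology": "PrevalenceList",
    "genes": "DisorderGeneAssociationList",
    "phenotypes": "HPODisorderAssociationList",
    "natural_history": "AverageAgeOfOnsetList",
    "linearisation": "LinearisationParent",
}

_PREVALENCE_KIND_MAP = {
    "point prevalence": PrevalenceKind.POINT,
    "prevalence at birth": PrevalenceKind.BIRTH,
    "annual incidence": PrevalenceKind.ANNUAL_INCIDENCE,
}

# Orphadata writes classes like "1-9 / 100 000"; normalize spacing and
# thousand grouping to the canonical interval labels.
_PREVALENCE_CLASS_MAP = {
    ">1/1000": PrevalenceClass.MORE_THAN_1_IN_1000,
    "6-9/10000": PrevalenceClass.SIX_NINE_IN_10000,
    "1-5/10000": PrevalenceClass.ONE_FIVE_IN_10000,
    "1-9/100000": PrevalenceClass.ONE_NINE_IN_100000,
    "1-9/1000000": PrevalenceClass.ONE_NINE_IN_1000000,
    "<1/1000000": PrevalenceClass.LESS_THAN_1_IN_1000000,
    "unknown": PrevalenceClass.UNKNOWN,
    "notdocumented": PrevalenceClass.UNKNOWN,
}

_SCOPE_MAP = {
    "worldwide": GeographicScope.WORLDWIDE,
    "continent": GeographicScope.CONTINENT,
    "country": GeographicScope.COUNTRY,
    "region": GeographicScope.REGION,
    # Orphadata labels continent-level records with the continent name
    "europe": GeographicScope.CONTINENT,
    "north america": GeographicScope.CONTINENT,
    "south america": GeographicScope.CONTINENT,
    "asia": GeographicScope.CONTINENT,
    "africa": GeographicScope.CONTINENT,
    "oceania": GeographicScope.CONTINENT,
}

_OCCURRENCE_MAP = {
    "obligate": Occurrence.OBLIGATE,
    "very frequent": Occurrence.VERY_FREQUENT,
    "frequent": Occurrence.FREQUENT,
    "occasional": Occurrence.OCCASIONAL,
    "very rare": Occurrence.VERY_RARE,
    "excluded": Occurrence.EXCLUDED,
}

_INHERITANCE_MAP = {
    "autosomal recessive": Inheritance.AUTOSOMAL_RECESSIVE,
    "autosomal dominant": Inheritance.AUTOSOMAL_DOMINANT,
    "x-linked recessive": Inheritance.X_LINKED_RECESSIVE,
    "x-linked dominant": Inheritance.X_LINKED_DOMINANT,
    "mitochondrial inheritance": Inheritance.MITOCHONDRIAL,
    "mitochondrial": Inheritance.MITOCHONDRIAL,
    "semi-dominant": Inheritance.SEMI_DOMINANT,
    "y-linked": Inheritance.Y_LINKED,
    "oligogenic": Inheritance.OLIGOGENIC,
    "multigenic/multifactorial": Inheritance.MULTIGENIC_MULTIFACTORIAL,
}

_GROUP_MAP = {
    "disorder": DisorderGroup.DISORDER,
    "group of disorders": DisorderGroup.GROUP_OF_DISORDERS,
    "subtype of disorder": DisorderGroup.SUBTYPE_OF_DISORDER,
    "subtype of a disorder": DisorderGroup.SUBTYPE_OF_DISORDER,
}

_TYPE_MAP = {
    "disease": DisorderType.DISEASE,
    "malformation syndrome": DisorderType.MALFORMATION_SYNDROME,
    "morphological anomaly": DisorderType.MORPHOLOGICAL_ANOMALY,
    "particular clinical situation in a disease or syndrome": (
        DisorderType.PARTICULAR_CLINICAL_SITUATION
    ),
    "clinical syndrome": DisorderType.CLINICAL_SYNDROME,
    "biological anomaly": DisorderType.BIOLOGICAL_ANOMALY,
}


def _norm(text: str | None) -> str:
    return (text or "").strip()


def _norm_class(label: str) -> PrevalenceClass | None:
    key = re.sub(r"[\s,]", "", label).lower()
    return _PREVALENCE_CLASS_MAP.get(key)


def detect_dialect(root: etree._Element) -> str:
    """Identify which Orphadata product a parsed document is."""
    for dialect, marker in _DIALECT_MARKERS.items():
        if root.find(f".//{marker}") is not None:
            return dialect
    if root.find(".//DisorderGroup") is not None:
        return "linearisation"
    raise OrphadataParseError(
        "unrecognized Orphadata dialect; supported products: "
        + ", ".join(SUPPORTED_DIALECTS)
    )


def _orphacode(disorder: etree._Element) -> int:
    for tag in ("OrphaCode", "OrphaNumber"):
        node = disorder.find(tag)
        if node is not None and _norm(node.text):
            return int(_norm(node.text))
    raise OrphadataParseError("Disorder element without OrphaCode/OrphaNumber")


def _name_text(parent: etree._Element | None, tag: str = "Name") -> str:
    if parent is None:
        return ""
    node = parent.find(tag)
    return _norm(node.text) if node is not None else ""


class _Merger:
    """Accumulates facets per orphacode across product files."""

    def __init__(self) -> None:
        self.partial: dict[int, dict] = {}
        self.skipped = 0

    def entry(self, disorder: etree._Element) -> dict:
        code = _orphacode(disorder)
        if code not in self.partial:
            self.partial[code] = {
                "orphacode": code,
                "name": "",
                "synonyms": [],
                "disorder_group": DisorderGroup.DISORDER,
                "disorder_type": DisorderType.DISEASE,
                "linearisation_parent": "",
                "inheritance_types": set(),
                "onset_intervals": set(),
                "death_intervals": set(),
                "prevalence_records": [],
                "hpo_annotations": [],
                "gene_associations": [],
            }
        entry = self.partial[code]
        name = _name_text(disorder)
        if name and not entry["name"]:
            entry["name"] = name
        for syn in disorder.findall(".//Synonym"):
            text = _norm(syn.text)
            if text and text not in entry["synonyms"]:
                entry["synonyms"].append(text)
        return entry


def _parse_epidemiology(root: etree._Element, merger: _Merger) -> None:
    for disorder in root.iter("Disorder"):
        entry = merger.entry(disorder)
        for prev in disorder.findall(".//Prevalence"):
            kind_label = _name_text(prev.find("PrevalenceType"), "Name")
            kind = _PREVALENCE_KIND_MAP.get(kind_label.lower())
            cls_node = prev.find("PrevalenceClass")
            cls = _norm_class(_name_text(cls_node)) if cls_node is not None else None
            geo_label = _name_text(prev.find("PrevalenceGeographic"), "Name")
            scope = _SCOPE_MAP.get(geo_label.lower())
            if kind is None or cls is None or scope is None:
                merger.skipped += 1
                continue
            entry["prevalence_records"].append(
                PrevalenceRecord(kind, cls, scope, geo_label)
            )


def _parse_genes(root: etree._Element, merger: _Merger) -> None:
    for disorder in root.iter("Disorder"):
        entry = merger.entry(disorder)
        for assoc in disorder.findall(".//DisorderGeneAssociation"):
            gene = assoc.find("Gene")
            symbol = _name_text(gene, "Symbol") if gene is not None else ""
            if not symbol:
                merger.skipped += 1
                continue
            type_label = _name_text(
                assoc.find("DisorderGeneAssociationType"), "Name"
            ).lower()
            if "modif" in type_label:
                a_type = AssociationType.MODIFIER
            elif "susceptib" in type_label:
                a_type = AssociationType.SUSCEPTIBILITY
            elif "caus" in type_label or not type_label:
                a_type = AssociationType.DISEASE_CAUSING
            else:
                a_type = AssociationType.OTHER
            ga = GeneAssociation(symbol, a_type)
            if ga not in entry["gene_associations"]:
                entry["gene_associations"].append(ga)


def _parse_phenotypes(root: etree._Element, merger: _Merger) -> None:
    for disorder in root.iter("Disorder"):
        entry = merger.entry(disorder)
        for assoc in disorder.findall(".//HPODisorderAssociation"):
            hpo = assoc.find("HPO")
            if hpo is None:
                merger.skipped += 1
                continue
            hpo_id = _name_text(hpo, "HPOId")
            term = _name_text(hpo, "HPOTerm")
            freq_label = _name_text(assoc.find("HPOFrequency"), "Name")
            key = freq_label.split("(")[0].strip().lower()
            occurrence = _OCCURRENCE_MAP.get(key)
            if not hpo_id or occurrence is None:
                merger.skipped += 1
                continue
            if any(a.hpo_id == hpo_id for a in entry["hpo_annotations"]):
                merger.skipped += 1
                continue
            entry["hpo_annotations"].append(HPOAnnotation(hpo_id, term, occurrence))


def _parse_natural_history(root: etree._Element, merger: _Merger) -> None:
    for disorder in root.iter("Disorder"):
        entry = merger.entry(disorder)
        for node in disorder.findall(".//AverageAgeOfOnset"):
            label = _name_text(node)
            if label:
                entry["onset_intervals"].add(label.lower())
        for node in disorder.findall(".//AverageAgeOfDeath"):
            label = _name_text(node)
            if label:
                entry["death_intervals"].add(label.lower())
        for node in disorder.findall(".//TypeOfInheritance"):
            label = _name_text(node).lower()
            inh = _INHERITANCE_MAP.get(label)
            if inh is not None:
                entry["inheritance_types"].add(inh)
            elif label:
                merger.skipped += 1


def _parse_linearisation(root: etree._Element, merger: _Merger) -> None:
    for disorder in root.iter("Disorder"):
        entry = merger.entry(disorder)
        group_node = disorder.find("DisorderGroup")
        if group_node is not None:
            label = _name_text(group_node).lower()
            if label in _GROUP_MAP:
                entry["disorder_group"] = _GROUP_MAP[label]
            else:
                merger.skipped += 1
        type_node = disorder.find("DisorderType")
        if type_node is not None:
            label = _name_text(type_node).lower()
            if label in _TYPE_MAP:
                entry["disorder_type"] = _TYPE_MAP[label]
            else:
                merger.skipped += 1
        parent = disorder.find("LinearisationParent")
        if parent is not None and _norm(parent.text):
            entry["linearisation_parent"] = _norm(parent.text).lower()


_PARSERS = {
    "epidemiology": _parse_epidemiology,
    "genes": _parse_genes,
    "phenotypes": _parse_phenotypes,
    "natural_history": _parse_natural_history,
    "linearisation": _parse_linearisation,
}


def parse_orphadata_products(
    xml_paths: list[str | Path], snapshot_date: str = ""
) -> DisorderRegistry:
    """Parse one or more Orphadata product XML files into a registry.

    Dialect is detected per file from its content; records are merged across
    products by orphacode.  Unparseable optional fields are skipped and
    counted (logged as a warning total).
    """
    merger = _Merger()
    for path in xml_paths:
        path = Path(path)
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise OrphadataParseError(f"{path.name}: not well-formed XML: {exc}")
        root = tree.getroot()
        dialect = detect_dialect(root)
        logger.info("parsing %s as %s product", path.name, dialect)
        _PARSERS[dialect](root, merger)
    if merger.skipped:
        logger.warning(
            "skipped %d unparseable optional elements across products",
            merger.skipped,
        )
    records = [DisorderRecord(**merger.partial[c]) for c in sorted(merger.partial)]
    return DisorderRegistry(
        records, provenance=Provenance("orphadata-xml", snapshot_date)
    )
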