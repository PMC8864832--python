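"""Domain model for a rare-disorder registry.

A registry holds one :class:`DisorderRecord` per Orphacode (Orphanet's stable
integer identifier).  Each record carries the facets relevant to
characterizing the rare-disorder spectrum: classification labels (disorder
group, disorder type, linearisation parent), point/birth/incidence prevalence
records expressed as interval classes, inheritance types, natural-history
interval labels (average age of onset and of death), HPO phenotype
annotations with their occurrence category, and gene associations.

The module also implements the spectrum inclusion filter: keep disorders (not
groups or subtypes) outside the excluded linearisation branches that have a
known worldwide or continent point prevalence.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "PrevalenceKind",
    "PrevalenceClass",
    "GeographicScope",
    "Occurrence",
    "AssociationType",
    "DisorderGroup",
    "DisorderType",
    "Inheritance",
    "PrevalenceRecord",
    "HPOAnnotation",
    "GeneAssociation",
    "DisorderRecord",
    "Provenance",
    "DisorderRegistry",
    "FilterReport",
    "filter_spectrum",
    "DEFAULT_EXCLUDED_PARENTS",
    "RARITY_ORDER",
]

_HPO_ID_RE = re.compile(r"^HP:\d{7}$")


class PrevalenceKind(str, enum.Enum):
    """Type of disease-frequency measure reported for a disorder."""

    POINT = "point"
    BIRTH = "birth"
    ANNUAL_INCIDENCE = "annual_incidence"


class PrevalenceClass(str, enum.Enum):
    """Interval prevalence classes as reported in Orphadata.

    The enum values are the exact display labels used in the tabular bundle
    format; rarity increases from ``MORE_THAN_1_IN_1000`` down to
    ``LESS_THAN_1_IN_1000000``.
    """

    MORE_THAN_1_IN_1000 = ">1/1,000"
    SIX_NINE_IN_10000 = "6-9/10,000"
    ONE_FIVE_IN_10000 = "1-5/10,000"
    ONE_NINE_IN_100000 = "1-9/100,000"
    ONE_NINE_IN_1000000 = "1-9/1,000,000"
    LESS_THAN_1_IN_1000000 = "<1/1,000,000"
    UNKNOWN = "unknown"


#: Prevalence classes ordered from most common to rarest (``unknown`` last).
RARITY_ORDER: tuple[PrevalenceClass, ...] = (
    PrevalenceClass.MORE_THAN_1_IN_1000,
    PrevalenceClass.SIX_NINE_IN_10000,
    PrevalenceClass.ONE_FIVE_IN_10000,
    PrevalenceClass.ONE_NINE_IN_100000,
    PrevalenceClass.ONE_NINE_IN_1000000,
    PrevalenceClass.LESS_THAN_1_IN_1000000,
    PrevalenceClass.UNKNOWN,
)


class GeographicScope(str, enum.Enum):
    WORLDWIDE = "worldwide"
    CONTINENT = "continent"
    COUNTRY = "country"
    REGION = "region"


class Occurrence(str, enum.Enum):
    """HPO term occurrence category within a disorder.

    Orphanet reports how often patients with a disorder exhibit a phenotype:
    obligate (100%), very frequent (99-80%), frequent (79-30%), occasional
    (29-5%), very rare (<4-1%) and excluded (0%).
    """

    OBLIGATE = "obligate"
    VERY_FREQUENT = "very_frequent"
    FREQUENT = "frequent"
    OCCASIONAL = "occasional"
    VERY_RARE = "very_rare"
    EXCLUDED = "excluded"


class AssociationType(str, enum.Enum):
    DISEASE_CAUSING = "disease_causing"
    MODIFIER = "modifier"
    SUSCEPTIBILITY = "susceptibility"
    OTHER = "other"


class DisorderGroup(str, enum.Enum):
    DISORDER = "disorder"
    GROUP_OF_DISORDERS = "group_of_disorders"
    SUBTYPE_OF_DISORDER = "subtype_of_disorder"


class DisorderType(str, enum.Enum):
    DISEASE = "disease"
    MALFORMATION_SYNDROME = "malformation_syndrome"
    MORPHOLOGICAL_ANOMALY = "morphological_anomaly"
    PARTICULAR_CLINICAL_SITUATION = "particular_clinical_situation"
    CLINICAL_SYNDROME = "clinical_syndrome"
    BIOLOGICAL_ANOMALY = "biological_anomaly"


class Inheritance(str, enum.Enum):
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    X_LINKED_RECESSIVE = "x_linked_recessive"
    X_LINKED_DOMINANT = "x_linked_dominant"
    MITOCHONDRIAL = "mitochondrial"
    SEMI_DOMINANT = "semi_dominant"
    Y_LINKED = "y_linked"
    OLIGOGENIC = "oligogenic"
    MULTIGENIC_MULTIFACTORIAL = "multigenic_multifactorial"


#: Linearisation parents excluded from the spectrum by default.
DEFAULT_EXCLUDED_PARENTS: frozenset[str] = frozenset(
    {
        "rare disorder due to toxic effects",
        "rare infectious disease",
        "rare neoplastic disease",
    }
)


@dataclass(frozen=True)
class PrevalenceRecord:
    """One prevalence report for a disorder."""

    kind: PrevalenceKind
    prevalence_class: PrevalenceClass
    geographic_scope: GeographicScope
    scope_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", PrevalenceKind(self.kind))
        object.__setattr__(
            self, "prevalence_class", PrevalenceClass(self.prevalence_class)
        )
        object.__setattr__(
            self, "geographic_scope", GeographicScope(self.geographic_scope)
        )


@dataclass(frozen=True)
class HPOAnnotation:
    """An HPO phenotype annotation with its occurrence category."""

    hpo_id: str
    term_label: str
    occurrence: Occurrence

    def __post_init__(self) -> None:
        if not _HPO_ID_RE.match(self.hpo_id):
            raise ValueError(f"invalid HPO identifier: {self.hpo_id!r}")
        object.__setattr__(self, "occurrence", Occurrence(self.occurrence))


@dataclass(frozen=True)
class GeneAssociation:
    """A gene associated with a disorder (causing, modifying, ...)."""

    gene_symbol: str
    association_type: AssociationType = AssociationType.DISEASE_CAUSING

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        object.__setattr__(
            self, "association_type", AssociationType(self.association_type)
        )


@dataclass
class DisorderRecord:
    """One rare disorder with all facets used by the pipeline.

    Collections are normalized at construction (annotations sorted by HPO id,
    genes by symbol, prevalence records by a fixed key) so that two records
    built from the same facts compare equal regardless of input order.
    """

    orphacode: int
    name: str
    synonyms: list[str] = field(default_factory=list)
    disorder_group: DisorderGroup = DisorderGroup.DISORDER
    disorder_type: DisorderType = DisorderType.DISEASE
    linearisation_parent: str = ""
    inheritance_types: set[Inheritance] = field(default_factory=set)
    onset_intervals: set[str] = field(default_factory=set)
    death_intervals: set[str] = field(default_factory=set)
    prevalence_records: list[PrevalenceRecord] = field(default_factory=list)
    hpo_annotations: list[HPOAnnotation] = field(default_factory=list)
    gene_associations: list[GeneAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if int(self.orphacode) <= 0:
            raise ValueError(f"orphacode must be positive, got {self.orphacode}")
        self.orphacode = int(self.orphacode)
        self.disorder_group = DisorderGroup(self.disorder_group)
        self.disorder_type = DisorderType(self.disorder_type)
        self.inheritance_types = {Inheritance(i) for i in self.inheritance_types}
        self.onset_intervals = set(self.onset_intervals)
        self.death_intervals = set(self.death_intervals)
        self.prevalence_records = sorted(
            self.prevalence_records,
            key=lambda p: (
                p.kind.value,
                p.geographic_scope.value,
                p.prevalence_class.value,
                p.scope_label,
            ),
        )
        self.hpo_annotations = sorted(
            self.hpo_annotations, key=lambda a: a.hpo_id
        )
        seen: set[str] = set()
        for ann in self.hpo_annotations:
            if ann.hpo_id in seen:
                raise ValueError(
                    f"duplicate HPO annotation {ann.hpo_id} on "
                    f"orphacode {self.orphacode}"
                )
            seen.add(ann.hpo_id)
        self.gene_associations = sorted(
            set(self.gene_associations),
            key=lambda g: (g.gene_symbol, g.association_type.value),
        )


@dataclass(frozen=True)
class Provenance:
    source: str = "synthetic"
    snapshot_date: str = ""


class DisorderRegistry:
    """Collection of :class:`DisorderRecord` keyed by orphacode.

    Equality compares the record collections only; provenance is descriptive
    metadata and does not participate.
    """

    def __init__(
        self,
        records: Iterable[DisorderRecord] = (),
        provenance: Provenance | None = None,
    ) -> None:
        self.provenance = provenance or Provenance()
        self._records: dict[int, DisorderRecord] = {}
        for record in records:
            self.add(record)

    def add(self, record: DisorderRecord) -> None:
        if record.orphacode in self._records:
            raise ValueError(f"duplicate orphacode {record.orphacode}")
        self._records[record.orphacode] = record

    @property
    def records(self) -> Mapping[int, DisorderRecord]:
        return dict(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[DisorderRecord]:
        for code in sorted(self._records):
            yield self._records[code]

    def __contains__(self, orphacode: int) -> bool:
        return orphacode in self._records

    def __getitem__(self, orphacode: int) -> DisorderRecord:
        return self._records[orphacode]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DisorderRegistry):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:  # pragma: no cover
        return f"DisorderRegistry({len(self)} records, {self.provenance})"


# ---------------------------------------------------------------------------
# Spectrum filter
# ---------------------------------------------------------------------------

#: Filter rules in attribution order; each removed record is counted once
#: under the first rule it violates.
FILTER_RULES: tuple[str, ...] = (
    "no_known_prevalence",
    "group_or_subtype",
    "excluded_parent",
    "no_point_prevalence_in_scope",
)


@dataclass
class FilterReport:
    """Per-rule removal counts for a spectrum filter run."""

    n_input: int
    n_survivors: int
    removed: dict[str, int]

    def __post_init__(self) -> None:
        assert self.n_input == self.n_survivors + sum(self.removed.values())


def _has_known_prevalence(record: DisorderRecord) -> bool:
    return any(
        p.prevalence_class is not PrevalenceClass.UNKNOWN
        for p in record.prevalence_records
    )


def _has_point_prevalence_in_scope(record: DisorderRecord) -> bool:
    return any(
        p.kind is PrevalenceKind.POINT
        and p.prevalence_class is not PrevalenceClass.UNKNOWN
        and p.geographic_scope
        in (GeographicScope.WORLDWIDE, GeographicScope.CONTINENT)
        for p in record.prevalence_records
    )


def filter_spectrum(
    registry: DisorderRegistry,
    excluded_parents: Iterable[str] = DEFAULT_EXCLUDED_PARENTS,
) -> tuple[DisorderRegistry, FilterReport]:
    """Apply the spectrum inclusion criteria.

    Records survive when (in attribution order) they have at least one known
    prevalence record, are true disorders (not groups or subtypes), do not
    belong to an excluded linearisation parent, and carry at least one point
    prevalence of known class at worldwide or continent scope.

    Returns the filtered registry together with a :class:`FilterReport` whose
    per-rule counts plus survivors sum to the input size.
    """
    excluded = {p.lower() for p in excluded_parents}
    removed = Counter({rule: 0 for rule in FILTER_RULES})
    survivors: list[DisorderRecord] = []
    for record in registry:
        if not _has_known_prevalence(record):
            removed["no_known_prevalence"] += 1
        elif record.disorder_group is not DisorderGroup.DISORDER:
            removed["group_or_subtype"] += 1
        elif record.linearisation_parent.lower() in excluded:
            removed["excluded_parent"] += 1
        elif not _has_point_prevalence_in_scope(record):
            removed["no_point_prevalence_in_scope"] += 1
        else:
            survivors.append(record)
    out = DisorderRegistry(survivors, provenance=registry.provenance)
    report = FilterReport(
        n_input=len(registry), n_survivors=len(out), removed=dict(removed)
    )
    return out, report
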