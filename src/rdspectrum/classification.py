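"""Spectrum category assignment and the fictive-cohort burden model.

Each disorder's point-prevalence class is resolved by prioritizing worldwide
records over continent records; among continent records the modal class wins,
with a configurable deterministic tie-break.  Classes map onto three spectrum
categories:

* borderline-common — 6-9/10,000 and 1-5/10,000
* rare             — 1-9/100,000 and 1-9/1,000,000
* ultra-rare       — <1/1,000,000

``>1/1,000`` falls outside the rare-disorder spectrum and maps to
``excluded_common``.

The fictive-cohort model translates per-class disorder counts into the
expected share of a randomly selected population living with a disorder of
each category: ``percent = representative_prevalence(class) x n_disorders x
100`` summed over the category's classes, and ``expected patients = percent /
100 x population size`` (default population 500).  The representative
prevalence is the class midpoint, except for the open-ended rarest class
where the upper bound 1e-6 is used.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .registry import (
    DisorderRecord,
    DisorderRegistry,
    GeographicScope,
    PrevalenceClass,
    PrevalenceKind,
    RARITY_ORDER,
)

__all__ = [
    "Category",
    "ClassProvenance",
    "CategoryAssignment",
    "ClassificationResult",
    "CohortEstimate",
    "REPRESENTATIVE_PREVALENCE",
    "CATEGORY_OF_CLASS",
    "SPECTRUM_CATEGORIES",
    "round_half_up",
    "resolve_prevalence_class",
    "assign_category",
    "classify_registry",
    "category_shares",
    "cohort_expectation",
    "expected_patients",
    "one_in_n_from_percents",
]


class Category(str, enum.Enum):
    BORDERLINE_COMMON = "borderline_common"
    RARE = "rare"
    ULTRA_RARE = "ultra_rare"
    EXCLUDED_COMMON = "excluded_common"


#: The three categories forming the rare-disorder spectrum (ordered from the
#: common end to the rare end).
SPECTRUM_CATEGORIES: tuple[Category, ...] = (
    Category.BORDERLINE_COMMON,
    Category.RARE,
    Category.ULTRA_RARE,
)


class ClassProvenance(str, enum.Enum):
    WORLDWIDE = "worldwide"
    CONTINENT_MODE = "continent_mode"
    CONTINENT_TIEBREAK = "continent_tiebreak"


CATEGORY_OF_CLASS: dict[PrevalenceClass, Category] = {
    PrevalenceClass.MORE_THAN_1_IN_1000: Category.EXCLUDED_COMMON,
    PrevalenceClass.SIX_NINE_IN_10000: Category.BORDERLINE_COMMON,
    PrevalenceClass.ONE_FIVE_IN_10000: Category.BORDERLINE_COMMON,
    PrevalenceClass.ONE_NINE_IN_100000: Category.RARE,
    PrevalenceClass.ONE_NINE_IN_1000000: Category.RARE,
    PrevalenceClass.LESS_THAN_1_IN_1000000: Category.ULTRA_RARE,
}

#: Representative per-person point prevalence of each interval class: the
#: interval midpoint, except the open-ended rarest class where the upper
#: bound is used.  User-overridable wherever it is consumed.
REPRESENTATIVE_PREVALENCE: dict[PrevalenceClass, float] = {
    PrevalenceClass.SIX_NINE_IN_10000: 7.5e-4,
    PrevalenceClass.ONE_FIVE_IN_10000: 3e-4,
    PrevalenceClass.ONE_NINE_IN_100000: 5e-5,
    PrevalenceClass.ONE_NINE_IN_1000000: 5e-6,
    PrevalenceClass.LESS_THAN_1_IN_1000000: 1e-6,
}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    value = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return value


@dataclass(frozen=True)
class CategoryAssignment:
    """Resolved prevalence class and spectrum category for one disorder."""

    orphacode: int
    resolved_class: PrevalenceClass
    provenance: ClassProvenance
    category: Category
    tie_flag: bool = False

    def __post_init__(self) -> None:
        assert self.category is CATEGORY_OF_CLASS[self.resolved_class]
        assert self.tie_flag == (
            self.provenance is ClassProvenance.CONTINENT_TIEBREAK
        )


def resolve_prevalence_class(
    record: DisorderRecord, tie_break: str = "rarer"
) -> CategoryAssignment:
    """Resolve the point-prevalence class for a spectrum-filtered record.

    Worldwide point prevalence takes priority; otherwise the modal class among
    continent point records is used.  ``tie_break`` governs modal ties:
    ``"rarer"`` (default) keeps the rarest tied class, ``"commoner"`` the most
    common one, ``"error"`` raises.  Ties are flagged on the assignment.
    """
    if tie_break not in ("rarer", "commoner", "error"):
        raise ValueError(f"unknown tie_break policy {tie_break!r}")
    eligible = [
        p
        for p in record.prevalence_records
        if p.kind is PrevalenceKind.POINT
        and p.prevalence_class is not PrevalenceClass.UNKNOWN
        and p.geographic_scope
        in (GeographicScope.WORLDWIDE, GeographicScope.CONTINENT)
    ]
    if not eligible:
        raise ValueError(
            f"orphacode {record.orphacode}: no worldwide/continent point "
            "prevalence record (record must pass the spectrum filter first)"
        )

    worldwide = [
        p for p in eligible if p.geographic_scope is GeographicScope.WORLDWIDE
    ]
    pool = worldwide if worldwide else eligible
    counts = Counter(p.prevalence_class for p in pool)
    top = max(counts.values())
    modal = [cls for cls, n in counts.items() if n == top]
    modal.sort(key=RARITY_ORDER.index)

    if len(modal) == 1 or worldwide:
        # Multiple worldwide classes are vanishingly rare; prefer the rarer
        # one deterministically without flagging a continent tie.
        resolved = modal[-1] if tie_break != "commoner" else modal[0]
        provenance = (
            ClassProvenance.WORLDWIDE
            if worldwide
            else ClassProvenance.CONTINENT_MODE
        )
        tie = False
    else:
        if tie_break == "error":
            raise ValueError(
                f"orphacode {record.orphacode}: modal tie between "
                + ", ".join(c.value for c in modal)
            )
        resolved = modal[-1] if tie_break == "rarer" else modal[0]
        provenance = ClassProvenance.CONTINENT_TIEBREAK
        tie = True

    return CategoryAssignment(
        orphacode=record.orphacode,
        resolved_class=resolved,
        provenance=provenance,
        category=CATEGORY_OF_CLASS[resolved],
        tie_flag=tie,
    )


def assign_category(resolved_class: PrevalenceClass) -> Category:
    """Map a resolved prevalence class to its spectrum category."""
    cls = PrevalenceClass(resolved_class)
    if cls is PrevalenceClass.UNKNOWN:
        raise ValueError("cannot assign a category to an unknown prevalence class")
    return CATEGORY_OF_CLASS[cls]


@dataclass
class ClassificationResult:
    assignments: list[CategoryAssignment]
    category_counts: dict[Category, int]
    class_counts: dict[PrevalenceClass, int]
    n_excluded_common: int

    @property
    def by_orphacode(self) -> dict[int, CategoryAssignment]:
        return {a.orphacode: a for a in self.assignments}

    def shares_percent(self) -> dict[Category, float]:
        return category_shares(self.category_counts)


def classify_registry(
    registry: DisorderRegistry, tie_break: str = "rarer"
) -> ClassificationResult:
    """Assign every record of a filtered registry to a spectrum category."""
    assignments = [
        resolve_prevalence_class(record, tie_break=tie_break)
        for record in registry
    ]
    category_counts = {c: 0 for c in SPECTRUM_CATEGORIES}
    class_counts: dict[PrevalenceClass, int] = {}
    n_excluded = 0
    for a in assignments:
        class_counts[a.resolved_class] = class_counts.get(a.resolved_class, 0) + 1
        if a.category is Category.EXCLUDED_COMMON:
            n_excluded += 1
        else:
            category_counts[a.category] += 1
    return ClassificationResult(
        assignments=assignments,
        category_counts=category_counts,
        class_counts=class_counts,
        n_excluded_common=n_excluded,
    )


def category_shares(
    category_counts: Mapping[Category, int]
) -> dict[Category, float]:
    """Percentage share of each spectrum category among classified disorders.

    ``excluded_common`` disorders are outside the spectrum and are not part
    of the denominator.
    """
    total = sum(
        category_counts.get(c, 0) for c in SPECTRUM_CATEGORIES
    )
    if total == 0:
        return {c: 0.0 for c in SPECTRUM_CATEGORIES}
    return {
        c: 100.0 * category_counts.get(c, 0) / total for c in SPECTRUM_CATEGORIES
    }


# ---------------------------------------------------------------------------
# Fictive cohort
# ---------------------------------------------------------------------------


@dataclass
class CategoryBurden:
    disorder_count: int
    population_prevalence_percent: float
    expected_patients_real: float
    expected_patients: int


@dataclass
class CohortEstimate:
    """Expected patient burden of each spectrum category in a fictive cohort."""

    population_size: int
    per_category: dict[Category, CategoryBurden]
    total_expected: int
    one_in_n: int | None = field(default=None)


def expected_patients(percent: float, population_size: int) -> int:
    """Expected patient count (half-up rounded) for a population prevalence
    expressed in percent."""
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    return int(round_half_up(percent / 100.0 * population_size))


def one_in_n_from_percents(
    percents: Iterable[float], population_size: int = 500
) -> int | None:
    """"1 in N" burden summary from per-category population prevalences.

    The total expected patient count is the sum of the per-category half-up
    rounded counts; N is the population divided by that total, half-up
    rounded.  Returns None when no patients are expected.
    """
    total = sum(expected_patients(p, population_size) for p in percents)
    if total == 0:
        return None
    return int(round_half_up(population_size / total))


def cohort_expectation(
    class_counts: Mapping[PrevalenceClass, int],
    population_size: int = 500,
    rep_map: Mapping[PrevalenceClass, float] | None = None,
) -> CohortEstimate:
    """Fictive-cohort burden from per-class disorder counts.

    For each spectrum category: population prevalence percent = sum over the
    category's classes of representative prevalence x disorder count x 100;
    expected patients = percent/100 x population, half-up rounded.  The
    ``one_in_n`` summary divides the population by the total of the rounded
    per-category counts.
    """
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    reps = dict(REPRESENTATIVE_PREVALENCE)
    if rep_map:
        reps.update({PrevalenceClass(k): float(v) for k, v in rep_map.items()})

    percent: dict[Category, float] = {c: 0.0 for c in SPECTRUM_CATEGORIES}
    counts: dict[Category, int] = {c: 0 for c in SPECTRUM_CATEGORIES}
    for cls, n in class_counts.items():
        cls = PrevalenceClass(cls)
        if n < 0:
            raise ValueError(f"negative count for {cls.value}")
        if n == 0:
            continue
        category = CATEGORY_OF_CLASS.get(cls)
        if category is None or category is Category.EXCLUDED_COMMON:
            raise ValueError(
                f"class {cls.value} has no representative prevalence; "
                "it lies outside the rare-disorder spectrum"
            )
        if cls not in reps:
            raise ValueError(f"no representative prevalence for {cls.value}")
        percent[category] += reps[cls] * n * 100.0
        counts[category] += n

    per_category: dict[Category, CategoryBurden] = {}
    total = 0
    for c in SPECTRUM_CATEGORIES:
        real = percent[c] / 100.0 * population_size
        rounded = expected_patients(percent[c], population_size)
        per_category[c] = CategoryBurden(
            disorder_count=counts[c],
            population_prevalence_percent=percent[c],
            expected_patients_real=real,
            expected_patients=rounded,
        )
        total += rounded
    one_in_n = (
        int(round_half_up(population_size / total)) if total > 0 else None
    )
    return CohortEstimate(
        population_size=population_size,
        per_category=per_category,
        total_expected=total,
        one_in_n=one_in_n,
    )
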