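"""Phenotypic expressivity measures and HPO term analytics.

Orphanet annotates each disorder's HPO terms with an occurrence category
(obligate, very frequent, frequent, occasional, very rare, excluded).  Two
per-disorder ratios proxy how variable the clinical presentation is:

* ``ratio_obligate_vf``  = (obligate + very frequent terms) / all terms —
  lower values indicate more variable expressivity;
* ``ratio_occasional_vr`` = (occasional + very rare terms) / all terms —
  higher values indicate more variable expressivity.

"Excluded (0%)" annotations are omitted from every count.  A disorder holds
phenotypic information iff it has at least one non-excluded annotation;
excluded-only disorders are treated as unphenotyped and get no profile.

The module also ranks terms within a category (proportions over phenotyped
disorders), builds symmetric term-by-term co-occurrence matrices (entry
(i, j) = number of disorders annotated with both terms), extracts top
co-occurrence edges for chord-diagram tooling, and computes category
term-overlap Venn regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import Category, CategoryAssignment, SPECTRUM_CATEGORIES
from .registry import DisorderRecord, DisorderRegistry, Occurrence
from .setops import venn_regions

__all__ = [
    "OccurrenceCounts",
    "ExpressivityProfile",
    "CooccurrenceMatrix",
    "occurrence_counts",
    "expressivity_ratios",
    "expressivity_table",
    "phenotyped_orphacodes",
    "phenotyped_fraction_percent",
    "top_terms",
    "cooccurrence_matrix",
    "top_cooccurrent",
    "term_overlap_sets",
    "SPECTRUM_SCOPE",
]

#: Scope label addressing the whole spectrum rather than one category.
SPECTRUM_SCOPE = "spectrum"

_OBLIGATE_VF = frozenset({Occurrence.OBLIGATE, Occurrence.VERY_FREQUENT})
_OCCASIONAL_VR = frozenset({Occurrence.OCCASIONAL, Occurrence.VERY_RARE})


@dataclass(frozen=True)
class OccurrenceCounts:
    """Non-excluded HPO annotation counts for one disorder."""

    orphacode: int
    n_total: int
    n_obligate_vf: int
    n_frequent: int
    n_occasional_vr: int

    def __post_init__(self) -> None:
        assert self.n_total == (
            self.n_obligate_vf + self.n_frequent + self.n_occasional_vr
        )


@dataclass(frozen=True)
class ExpressivityProfile:
    orphacode: int
    ratio_obligate_vf: float
    ratio_occasional_vr: float


def occurrence_counts(record: DisorderRecord) -> OccurrenceCounts:
    """Count a disorder's HPO annotations by occurrence group, omitting
    'excluded (0%)' annotations entirely."""
    n_ob = n_fr = n_oc = 0
    for ann in record.hpo_annotations:
        if ann.occurrence is Occurrence.EXCLUDED:
            continue
        if ann.occurrence in _OBLIGATE_VF:
            n_ob += 1
        elif ann.occurrence is Occurrence.FREQUENT:
            n_fr += 1
        else:
            n_oc += 1
    return OccurrenceCounts(
        orphacode=record.orphacode,
        n_total=n_ob + n_fr + n_oc,
        n_obligate_vf=n_ob,
        n_frequent=n_fr,
        n_occasional_vr=n_oc,
    )


def expressivity_ratios(counts: OccurrenceCounts) -> ExpressivityProfile:
    """The two expressivity ratios; undefined (raises) when the disorder has
    no non-excluded annotations."""
    if counts.n_total == 0:
        raise ValueError(
            f"orphacode {counts.orphacode}: expressivity undefined for a "
            "disorder without phenotypic information"
        )
    return ExpressivityProfile(
        orphacode=counts.orphacode,
        ratio_obligate_vf=counts.n_obligate_vf / counts.n_total,
        ratio_occasional_vr=counts.n_occasional_vr / counts.n_total,
    )


def expressivity_table(
    registry: DisorderRegistry,
    assignments: Mapping[int, CategoryAssignment] | None = None,
) -> pd.DataFrame:
    """Per-disorder occurrence counts and expressivity ratios.

    Unphenotyped disorders (no non-excluded annotations) are excluded, not
    zero-filled.  When ``assignments`` is given a ``category`` column is
    attached.
    """
    rows = []
    for record in registry:
        c = occurrence_counts(record)
        if c.n_total == 0:
            continue
        profile = expressivity_ratios(c)
        row = {
            "orphacode": c.orphacode,
            "n_total": c.n_total,
            "n_obligate_vf": c.n_obligate_vf,
            "n_frequent": c.n_frequent,
            "n_occasional_vr": c.n_occasional_vr,
            "ratio_obligate_vf": profile.ratio_obligate_vf,
            "ratio_occasional_vr": profile.ratio_occasional_vr,
        }
        if assignments is not None:
            a = assignments.get(record.orphacode)
            row["category"] = a.category.value if a else ""
        rows.append(row)
    return pd.DataFrame(rows)


def _non_excluded_terms(record: DisorderRecord) -> set[str]:
    return {
        a.hpo_id
        for a in record.hpo_annotations
        if a.occurrence is not Occurrence.EXCLUDED
    }


def phenotyped_orphacodes(registry: DisorderRegistry) -> set[int]:
    """Orphacodes of disorders holding phenotypic information (>=1
    non-excluded annotation)."""
    return {r.orphacode for r in registry if _non_excluded_terms(r)}


def phenotyped_fraction_percent(n_phenotyped: int, n_total: int) -> float:
    """Share of disorders with phenotypic information, in percent (1 d.p.
    rounding is left to the caller; full precision returned)."""
    if n_total == 0:
        raise ValueError("no disorders in denominator")
    if not 0 <= n_phenotyped <= n_total:
        raise ValueError("phenotyped count outside [0, total]")
    return 100.0 * n_phenotyped / n_total


def _scope_records(
    registry: DisorderRegistry,
    assignments: Mapping[int, CategoryAssignment],
    scope: Category | str,
) -> list[DisorderRecord]:
    if scope == SPECTRUM_SCOPE:
        wanted = {
            code
            for code, a in assignments.items()
            if a.category in SPECTRUM_CATEGORIES
        }
    else:
        scope = Category(scope)
        wanted = {
            code for code, a in assignments.items() if a.category is scope
        }
    return [registry[code] for code in sorted(wanted) if code in registry]


def top_terms(
    registry: DisorderRegistry,
    assignments: Mapping[int, CategoryAssignment],
    scope: Category | str = SPECTRUM_SCOPE,
    k: int = 15,
) -> pd.DataFrame:
    """Ranked HPO term table for a category (or the whole spectrum).

    A term counts once per disorder regardless of occurrence class (excluded
    annotations never count).  The proportion denominator is the number of
    phenotyped disorders within the scope.  Ranking is by proportion
    descending with lexicographic hpo_id tie-break.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    records = _scope_records(registry, assignments, scope)
    term_disorders: dict[str, int] = {}
    labels: dict[str, str] = {}
    n_phenotyped = 0
    for record in records:
        terms = _non_excluded_terms(record)
        if not terms:
            continue
        n_phenotyped += 1
        for ann in record.hpo_annotations:
            if ann.occurrence is Occurrence.EXCLUDED:
                continue
            term_disorders[ann.hpo_id] = term_disorders.get(ann.hpo_id, 0) + 1
            labels.setdefault(ann.hpo_id, ann.term_label)
    if n_phenotyped == 0:
        return pd.DataFrame(
            columns=["hpo_id", "term_label", "n_disorders", "proportion_percent"]
        ).assign(denominator=0)
    df = pd.DataFrame(
        {
            "hpo_id": list(term_disorders),
            "term_label": [labels[t] for t in term_disorders],
            "n_disorders": list(term_disorders.values()),
        }
    )
    df["proportion_percent"] = 100.0 * df["n_disorders"] / n_phenotyped
    df["denominator"] = n_phenotyped
    df = df.sort_values(
        ["proportion_percent", "hpo_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return df.head(k)


@dataclass
class CooccurrenceMatrix:
    """Symmetric term-by-term disorder co-annotation counts.

    ``counts[i, j]`` is the number of scope disorders annotated (non-excluded)
    with both ``terms[i]`` and ``terms[j]``; the diagonal holds per-term
    disorder counts.
    """

    terms: list[str]
    counts: np.ndarray
    scope: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        assert self.counts.shape == (len(self.terms), len(self.terms))

    def pair(self, term_i: str, term_j: str) -> int:
        return int(
            self.counts[self.terms.index(term_i), self.terms.index(term_j)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.terms, columns=self.terms)


def cooccurrence_matrix(
    registry: DisorderRegistry,
    assignments: Mapping[int, CategoryAssignment],
    scope: Category | str = SPECTRUM_SCOPE,
) -> CooccurrenceMatrix:
    """Build the co-occurrence matrix for all non-excluded terms in scope."""
    records = _scope_records(registry, assignments, scope)
    term_sets = [_non_excluded_terms(r) for r in records]
    vocab = sorted(set().union(*term_sets)) if term_sets else []
    index = {t: i for i, t in enumerate(vocab)}
    indicator = np.zeros((len(term_sets), len(vocab)), dtype=np.int64)
    for row, terms in enumerate(term_sets):
        for t in terms:
            indicator[row, index[t]] = 1
    counts = indicator.T @ indicator
    scope_label = scope.value if isinstance(scope, Category) else str(scope)
    return CooccurrenceMatrix(terms=vocab, counts=counts, scope=scope_label)


def top_cooccurrent(
    matrix: CooccurrenceMatrix, seed_terms: Sequence[str], k: int = 10
) -> pd.DataFrame:
    """For each seed term, its ``k`` most co-occurring partner terms.

    Returns an edge list (term_i, term_j, n_disorders) sorted per seed by
    count descending then partner id; suitable for chord-diagram tooling.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    unknown = [t for t in seed_terms if t not in matrix.terms]
    if unknown:
        raise KeyError(f"seed terms not in matrix: {', '.join(unknown)}")
    edges = []
    for seed in seed_terms:
        i = matrix.terms.index(seed)
        partners = [
            (int(matrix.counts[i, j]), matrix.terms[j])
            for j in range(len(matrix.terms))
            if j != i
        ]
        partners.sort(key=lambda e: (-e[0], e[1]))
        for count, partner in partners[:k]:
            edges.append(
                {"term_i": seed, "term_j": partner, "n_disorders": count}
            )
    return pd.DataFrame(edges, columns=["term_i", "term_j", "n_disorders"])


def term_overlap_sets(
    registry: DisorderRegistry,
    assignments: Mapping[int, CategoryAssignment],
    top_k: int | None = None,
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Per-category HPO term sets and their Venn region cardinalities.

    With ``top_k`` set, each category contributes only its top-k terms (by
    proportion, as in :func:`top_terms`); otherwise the full vocabularies are
    compared.  Returns ``(sets_by_category, region_cardinalities)``; the
    seven region counts partition the union.
    """
    sets_by_category: dict[str, set[str]] = {}
    for category in SPECTRUM_CATEGORIES:
        if top_k is None:
            terms: set[str] = set()
            for record in _scope_records(registry, assignments, category):
                terms |= _non_excluded_terms(record)
        else:
            terms = set(
                top_terms(registry, assignments, category, k=top_k)["hpo_id"]
            )
        sets_by_category[category.value] = terms
    return sets_by_category, venn_regions(sets_by_category)
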