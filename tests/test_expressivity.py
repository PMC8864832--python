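"""Occurrence accounting, expressivity ratios, term rankings and
co-occurrence structures."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from rdspectrum.classification import Category, classify_registry
from rdspectrum.expressivity import (
    SPECTRUM_SCOPE,
    cooccurrence_matrix,
    expressivity_ratios,
    expressivity_table,
    occurrence_counts,
    phenotyped_fraction_percent,
    term_overlap_sets,
    top_cooccurrent,
    top_terms,
)
from rdspectrum.registry import (
    DisorderRecord,
    DisorderRegistry,
    GeographicScope,
    HPOAnnotation,
    Occurrence,
    PrevalenceClass,
    PrevalenceKind,
    PrevalenceRecord,
)
from rdspectrum.simulate import default_config, generate

O = Occurrence


def _disorder(code, terms, cls=PrevalenceClass.LESS_THAN_1_IN_1000000):
    return DisorderRecord(
        orphacode=code,
        name=f"d{code}",
        prevalence_records=[
            PrevalenceRecord(
                PrevalenceKind.POINT, cls, GeographicScope.WORLDWIDE, "Worldwide"
            )
        ],
        hpo_annotations=[
            HPOAnnotation(f"HP:00000{i:02d}", f"term {i}", occ)
            for i, occ in terms
        ],
    )


class TestOccurrenceCounts:
    def test_excluded_omitted_from_every_counter(self):
        record = _disorder(
            1,
            [
                (1, O.OBLIGATE),
                (2, O.OBLIGATE),
                (3, O.FREQUENT),
                (4, O.FREQUENT),
                (5, O.FREQUENT),
                (6, O.VERY_RARE),
                (7, O.EXCLUDED),
            ],
        )
        c = occurrence_counts(record)
        assert (c.n_total, c.n_obligate_vf, c.n_frequent, c.n_occasional_vr) == (
            6,
            2,
            3,
            1,
        )

    def test_no_annotations_all_zero(self):
        c = occurrence_counts(_disorder(1, []))
        assert c.n_total == 0

    def test_all_obligate(self):
        c = occurrence_counts(_disorder(1, [(i, O.OBLIGATE) for i in range(5)]))
        assert (c.n_total, c.n_obligate_vf, c.n_occasional_vr) == (5, 5, 0)


class TestExpressivityRatios:
    def test_exact_division(self):
        record = _disorder(
            1,
            [(i, O.OBLIGATE) for i in range(4)]
            + [(i, O.FREQUENT) for i in range(4, 8)]
            + [(i, O.OCCASIONAL) for i in range(8, 10)],
        )
        profile = expressivity_ratios(occurrence_counts(record))
        assert profile.ratio_obligate_vf == pytest.approx(0.4)
        assert profile.ratio_occasional_vr == pytest.approx(0.2)

    def test_all_obligate_boundary(self):
        record = _disorder(1, [(i, O.OBLIGATE) for i in range(3)])
        profile = expressivity_ratios(occurrence_counts(record))
        assert (profile.ratio_obligate_vf, profile.ratio_occasional_vr) == (1.0, 0.0)

    def test_undefined_for_unphenotyped(self):
        with pytest.raises(ValueError, match="undefined"):
            expressivity_ratios(occurrence_counts(_disorder(1, [])))

    def test_ratio_conservation_on_synthetic_cohort(self):
        registry, _ = generate(default_config(seed=11, scale=0.1))
        table = expressivity_table(registry)
        total = (
            table["ratio_obligate_vf"]
            + table["n_frequent"] / table["n_total"]
            + table["ratio_occasional_vr"]
        )
        assert np.allclose(total, 1.0)

    def test_brute_force_recount_oracle(self):
        registry, _ = generate(default_config(seed=11, scale=0.05))
        table = expressivity_table(registry).set_index("orphacode")
        for record in registry:
            raw = [
                a.occurrence
                for a in record.hpo_annotations
                if a.occurrence is not O.EXCLUDED
            ]
            if not raw:
                assert record.orphacode not in table.index
                continue
            row = table.loc[record.orphacode]
            n_ob = sum(o in (O.OBLIGATE, O.VERY_FREQUENT) for o in raw)
            n_oc = sum(o in (O.OCCASIONAL, O.VERY_RARE) for o in raw)
            assert row["ratio_obligate_vf"] == pytest.approx(n_ob / len(raw))
            assert row["ratio_occasional_vr"] == pytest.approx(n_oc / len(raw))

    def test_phenotyped_fraction_percent(self):
        assert phenotyped_fraction_percent(131, 145) == pytest.approx(
            90.3448, abs=1e-3
        )
        with pytest.raises(ValueError):
            phenotyped_fraction_percent(1, 0)


def _three_disorder_setup():
    registry = DisorderRegistry(
        [
            _disorder(1, [(1, O.OBLIGATE), (2, O.FREQUENT)]),
            _disorder(2, [(1, O.OCCASIONAL)]),
            _disorder(3, [(1, O.VERY_RARE), (2, O.OBLIGATE)]),
        ]
    )
    assignments = classify_registry(registry).by_orphacode
    return registry, assignments


class TestTopTerms:
    def test_proportion_and_ranking(self):
        registry, assignments = _three_disorder_setup()
        table = top_terms(registry, assignments, SPECTRUM_SCOPE, k=10)
        assert list(table["hpo_id"]) == ["HP:0000001", "HP:0000002"]
        assert table.iloc[0]["n_disorders"] == 3
        assert table.iloc[1]["proportion_percent"] == pytest.approx(66.6667, abs=1e-3)
        assert (table["denominator"] == 3).all()

    def test_k_larger_than_vocabulary_returns_full_table(self):
        registry, assignments = _three_disorder_setup()
        assert len(top_terms(registry, assignments, SPECTRUM_SCOPE, k=999)) == 2

    def test_empty_category_has_zero_denominator(self):
        registry, assignments = _three_disorder_setup()
        table = top_terms(registry, assignments, Category.BORDERLINE_COMMON, k=5)
        assert len(table) == 0
        assert list(table["denominator"]) == []

    def test_known_fraction_recovered(self):
        # term HP:0000001 annotated in exactly 2 of 4 phenotyped disorders
        registry = DisorderRegistry(
            [
                _disorder(1, [(1, O.FREQUENT), (2, O.FREQUENT)]),
                _disorder(2, [(1, O.OBLIGATE)]),
                _disorder(3, [(2, O.FREQUENT)]),
                _disorder(4, [(3, O.FREQUENT)]),
            ]
        )
        assignments = classify_registry(registry).by_orphacode
        table = top_terms(registry, assignments, SPECTRUM_SCOPE, k=10)
        row = table[table["hpo_id"] == "HP:0000001"].iloc[0]
        assert row["proportion_percent"] == pytest.approx(50.0)


class TestCooccurrence:
    def test_worked_example(self):
        registry = DisorderRegistry(
            [
                _disorder(1, [(1, O.OBLIGATE), (2, O.FREQUENT)]),  # {A,B}
                _disorder(2, [(1, O.FREQUENT)]),  # {A}
                _disorder(3, [(1, O.OCCASIONAL), (2, O.VERY_RARE)]),  # {A,B}
            ]
        )
        assignments = classify_registry(registry).by_orphacode
        m = cooccurrence_matrix(registry, assignments)
        A, B = "HP:0000001", "HP:0000002"
        assert m.pair(A, B) == 2
        assert m.pair(A, A) == 3
        assert m.pair(B, B) == 2

    def test_never_coannotated_is_zero(self):
        registry = DisorderRegistry(
            [_disorder(1, [(1, O.FREQUENT)]), _disorder(2, [(2, O.FREQUENT)])]
        )
        assignments = classify_registry(registry).by_orphacode
        m = cooccurrence_matrix(registry, assignments)
        assert m.pair("HP:0000001", "HP:0000002") == 0

    def test_brute_force_oracle_on_200_disorders(self):
        config = default_config(seed=13, scale=0.057)  # ~200 disorders
        registry, _ = generate(config)
        assignments = classify_registry(registry).by_orphacode
        m = cooccurrence_matrix(registry, assignments)
        # independent recount: double loop over disorders and term pairs
        expected = {}
        for record in registry:
            terms = sorted(
                a.hpo_id
                for a in record.hpo_annotations
                if a.occurrence is not O.EXCLUDED
            )
            for ti, tj in itertools.combinations_with_replacement(terms, 2):
                expected[(ti, tj)] = expected.get((ti, tj), 0) + 1
        assert np.array_equal(m.counts, m.counts.T)
        diag = np.diag(m.counts)
        assert (m.counts <= np.minimum.outer(diag, diag)).all()
        for (ti, tj), count in expected.items():
            assert m.pair(ti, tj) == count
        assert m.counts.sum() == sum(
            (2 if ti != tj else 1) * c for (ti, tj), c in expected.items()
        )


class TestTopCooccurrent:
    def test_seed_example(self):
        registry = DisorderRegistry(
            [
                _disorder(1, [(1, O.OBLIGATE), (2, O.FREQUENT)]),
                _disorder(2, [(1, O.FREQUENT)]),
                _disorder(3, [(1, O.OCCASIONAL), (2, O.VERY_RARE)]),
            ]
        )
        assignments = classify_registry(registry).by_orphacode
        m = cooccurrence_matrix(registry, assignments)
        edges = top_cooccurrent(m, ["HP:0000001"], k=1)
        assert edges.iloc[0].tolist() == ["HP:0000001", "HP:0000002", 2]

    def test_k_zero_empty(self):
        registry, assignments = _three_disorder_setup()
        m = cooccurrence_matrix(registry, assignments)
        assert len(top_cooccurrent(m, ["HP:0000001"], k=0)) == 0

    def test_unknown_seed_named_in_error(self):
        registry, assignments = _three_disorder_setup()
        m = cooccurrence_matrix(registry, assignments)
        with pytest.raises(KeyError, match="HP:7777777"):
            top_cooccurrent(m, ["HP:7777777"], k=1)

    def test_matches_full_row_sort_on_synthetic_data(self):
        registry, _ = generate(default_config(seed=5, scale=0.05))
        assignments = classify_registry(registry).by_orphacode
        m = cooccurrence_matrix(registry, assignments)
        seed = m.terms[0]
        edges = top_cooccurrent(m, [seed], k=5)
        i = m.terms.index(seed)
        row = [
            (int(m.counts[i, j]), m.terms[j])
            for j in range(len(m.terms))
            if j != i
        ]
        row.sort(key=lambda e: (-e[0], e[1]))
        assert [
            (r["term_j"], r["n_disorders"]) for _, r in edges.iterrows()
        ] == [(t, c) for c, t in row[:5]]


class TestTermOverlap:
    def test_identical_vocabularies_all_shared(self):
        registry = DisorderRegistry(
            [
                _disorder(1, [(1, O.FREQUENT)], PrevalenceClass.ONE_FIVE_IN_10000),
                _disorder(2, [(1, O.FREQUENT)], PrevalenceClass.ONE_NINE_IN_100000),
                _disorder(3, [(1, O.FREQUENT)]),
            ]
        )
        assignments = classify_registry(registry).by_orphacode
        _, regions = term_overlap_sets(registry, assignments)
        triple = "borderline_common&rare&ultra_rare"
        assert regions[triple] == 1
        assert sum(v for k, v in regions.items() if k != triple) == 0

    def test_disjoint_vocabularies(self):
        registry = DisorderRegistry(
            [
                _disorder(1, [(1, O.FREQUENT)], PrevalenceClass.ONE_FIVE_IN_10000),
                _disorder(2, [(2, O.FREQUENT)], PrevalenceClass.ONE_NINE_IN_100000),
                _disorder(3, [(3, O.FREQUENT)]),
            ]
        )
        assignments = classify_registry(registry).by_orphacode
        _, regions = term_overlap_sets(registry, assignments)
        assert regions["borderline_common"] == 1
        assert regions["rare"] == 1
        assert regions["ultra_rare"] == 1
        assert all("&" not in k or v == 0 for k, v in regions.items())

    def test_regions_partition_union_on_synthetic_data(self):
        registry, _ = generate(default_config(seed=9, scale=0.1))
        assignments = classify_registry(registry).by_orphacode
        sets, regions = term_overlap_sets(registry, assignments, top_k=50)
        union = set().union(*sets.values())
        assert sum(regions.values()) == len(union)
        # independent set algebra for the triple intersection
        bc, ra, ur = (
            sets["borderline_common"],
            sets["rare"],
            sets["ultra_rare"],
        )
        assert regions["borderline_common&rare&ultra_rare"] == len(bc & ra & ur)
        assert regions["borderline_common"] == len(bc - ra - ur)
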