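"""Statistical kernel: Fisher exact, BH-FDR, rank tests and the
category-comparison builders, cross-checked against scipy/statsmodels."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from rdspectrum.classification import Category, classify_registry
from rdspectrum.registry import (
    DisorderRecord,
    DisorderRegistry,
    GeographicScope,
    PrevalenceClass,
    PrevalenceKind,
    PrevalenceRecord,
)
from rdspectrum.stats import (
    ContingencyTable2x2,
    Direction,
    bh_fdr,
    compare_proportions,
    fisher_exact_two_sided,
    hypergeom_pmf,
    kruskal_wallis,
    midranks,
    proportion_se,
    rank_compare,
    summarize_natural_history,
    wilcoxon_rank_sum,
)


class TestFisherExact:
    def test_worked_examples(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(2, 0, 0, 2)) == (
            pytest.approx(1 / 3)
        )
        assert fisher_exact_two_sided(ContingencyTable2x2(3, 1, 1, 3)) == (
            pytest.approx(34 / 70)
        )

    def test_all_zero_column_gives_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(3, 0, 2, 0)) == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ContingencyTable2x2(0, 0, 0, 0)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 40, size=4)
            if a + b + c + d == 0:
                continue
            ours = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            _, theirs = scipy.stats.fisher_exact(
                [[a, b], [c, d]], alternative="two-sided"
            )
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    def test_hypergeometric_pmf_sums_to_one(self):
        for N, K, n in [(10, 4, 3), (30, 15, 12), (100, 5, 50)]:
            total = sum(
                hypergeom_pmf(k, N, K, n)
                for k in range(max(0, n + K - N), min(n, K) + 1)
            )
            assert total == pytest.approx(1.0)


class TestBHFDR:
    def test_worked_examples(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_fdr([0.04, 0.01]) == pytest.approx([0.04, 0.02])
        assert bh_fdr([0.7]) == [0.7]

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40)).tolist()
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_fdr(p) == pytest.approx(expected.tolist())

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, p, rnd):
        adjusted = bh_fdr(p)
        indices = list(range(len(p)))
        rnd.shuffle(indices)
        shuffled = bh_fdr([p[i] for i in indices])
        assert shuffled == pytest.approx([adjusted[i] for i in indices])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=0.9), min_size=1, max_size=15),
        st.integers(min_value=0, max_value=14),
    )
    def test_monotonicity_raising_raw_never_lowers_adjusted(self, p, idx):
        idx = idx % len(p)
        bumped = list(p)
        bumped[idx] = min(1.0, bumped[idx] + 0.1)
        before = bh_fdr(p)
        after = bh_fdr(bumped)
        assert all(a >= b - 1e-12 for a, b in zip(after, before))


class TestProportionSE:
    @pytest.mark.parametrize(
        "p,n,expected",
        [(0.5, 100, 0.05), (0.0, 50, 0.0), (0.1448, 145, 0.0292)],
    )
    def test_formula(self, p, n, expected):
        assert proportion_se(p, n) == pytest.approx(expected, abs=1e-4)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            proportion_se(0.5, 0)


class TestRankTests:
    def test_kruskal_wallis_worked_example(self):
        H, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert H == pytest.approx(7.2)
        assert p == pytest.approx(scipy.stats.chi2.sf(7.2, 2))

    def test_kruskal_wallis_identical_groups(self):
        H, p = kruskal_wallis([[5, 5, 5], [5, 5], [5, 5, 5, 5]])
        assert H == 0.0
        assert p == 1.0

    def test_kruskal_wallis_matches_scipy_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            groups = [
                rng.integers(0, 8, size=rng.integers(5, 20)).tolist()
                for _ in range(3)
            ]
            H, p = kruskal_wallis(groups)
            ref = scipy.stats.kruskal(*groups)
            assert H == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_wilcoxon_exact_worked_example(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_wilcoxon_exact_matches_scipy(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.permutation(100)[: rng.integers(3, 10)].tolist()
            y = [v + 0.5 for v in rng.permutation(100)[: rng.integers(3, 10)]]
            ours = wilcoxon_rank_sum(x, y, mode="exact")
            ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours == pytest.approx(ref.pvalue)

    def test_wilcoxon_approx_close_to_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 30, size=60).tolist()
        y = (rng.integers(0, 30, size=55) + 4).tolist()
        ours = wilcoxon_rank_sum(x, y, mode="approx")
        ref = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        )
        assert ours == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_mode_with_ties_rejected(self):
        with pytest.raises(ValueError, match="ties"):
            wilcoxon_rank_sum([1, 2, 2], [2, 3, 4], mode="exact")

    def test_midranks_handle_ties(self):
        assert midranks([10, 20, 20, 30]).tolist() == [1.0, 2.5, 2.5, 4.0]

    def test_two_group_relation_to_wilcoxon(self):
        # for two groups, KW significance tracks the rank-sum distance
        x, y = [1, 2, 3, 4, 5], [6, 7, 8, 9, 10]
        H_far, _ = kruskal_wallis([x, y])
        H_near, _ = kruskal_wallis([[1, 3, 5, 7, 9], [2, 4, 6, 8, 10]])
        assert H_far > H_near


class TestCompareProportions:
    def test_reconstructed_inheritance_row(self):
        # multigenic/multifactorial: 21/145 (14.48%) vs 9/2967 (0.30%)
        rows = compare_proportions(
            {"multigenic": {Category.BORDERLINE_COMMON: 21, Category.ULTRA_RARE: 9}},
            {Category.BORDERLINE_COMMON: 145, Category.ULTRA_RARE: 2967},
            family="inheritance",
            compared=(Category.BORDERLINE_COMMON,),
        )
        [row] = rows
        assert row.prop_category_percent == pytest.approx(14.48, abs=0.01)
        assert row.prop_reference_percent == pytest.approx(0.30, abs=0.01)
        assert row.p_raw < 1e-15
        assert row.significant
        assert row.direction is Direction.DOWN

    def test_identical_proportions_not_significant(self):
        rows = compare_proportions(
            {"f": {Category.BORDERLINE_COMMON: 10, Category.ULTRA_RARE: 10}},
            {Category.BORDERLINE_COMMON: 100, Category.ULTRA_RARE: 100},
            family="x",
            compared=(Category.BORDERLINE_COMMON,),
        )
        [row] = rows
        assert row.p_raw == pytest.approx(1.0)
        assert row.direction is Direction.NONE

    def test_single_feature_family_adjustment_is_identity(self):
        rows = compare_proportions(
            {"f": {Category.BORDERLINE_COMMON: 3, Category.ULTRA_RARE: 30}},
            {Category.BORDERLINE_COMMON: 50, Category.ULTRA_RARE: 500},
            family="x",
            compared=(Category.BORDERLINE_COMMON,),
        )
        assert rows[0].p_adj == rows[0].p_raw


class TestRankCompare:
    def test_pairwise_only_when_omnibus_significant(self):
        same = {"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5], "c": [2, 3, 4, 5, 6]}
        result = rank_compare(same, feature="null-ish")
        assert result.p_kw >= 0.05
        assert len(result.pairwise) == 0

        rng = np.random.default_rng(4)
        shifted = {
            "a": rng.normal(0, 1, 40).tolist(),
            "b": rng.normal(2, 1, 40).tolist(),
            "c": rng.normal(4, 1, 40).tolist(),
        }
        result = rank_compare(shifted, feature="shifted")
        assert result.p_kw < 0.05
        assert len(result.pairwise) == 3
        assert result.pairwise["significant"].all()

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            rank_compare({"a": [1, 2], "b": []}, feature="x")

    def test_medians_and_iqrs_reported(self):
        result = rank_compare(
            {"a": [1, 2, 3, 4, 100], "b": [5, 6, 7, 8, 9]}, feature="x"
        )
        assert result.medians["a"] == 3
        assert result.group_sizes == {"a": 5, "b": 5}


def _nh_registry():
    """10 ultra-rare disorders, 4 with onset=infancy, 1 lacking death info."""
    records = []
    for i in range(1, 11):
        records.append(
            DisorderRecord(
                orphacode=i,
                name=f"d{i}",
                onset_intervals={"infancy"} if i <= 4 else {"adulthood"},
                death_intervals=(
                    set() if i == 10 else {"normal_life_expectancy"}
                ),
                prevalence_records=[
                    PrevalenceRecord(
                        PrevalenceKind.POINT,
                        PrevalenceClass.LESS_THAN_1_IN_1000000,
                        GeographicScope.WORLDWIDE,
                        "Worldwide",
                    )
                ],
            )
        )
    # a small comparison category so Fisher rows exist
    for i in range(11, 16):
        records.append(
            DisorderRecord(
                orphacode=i,
                name=f"d{i}",
                onset_intervals={"adulthood"},
                prevalence_records=[
                    PrevalenceRecord(
                        PrevalenceKind.POINT,
                        PrevalenceClass.ONE_FIVE_IN_10000,
                        GeographicScope.WORLDWIDE,
                        "Worldwide",
                    )
                ],
            )
        )
    return DisorderRegistry(records)


class TestNaturalHistory:
    def test_proportion_and_se_with_full_denominator(self):
        registry = _nh_registry()
        assignments = classify_registry(registry).by_orphacode
        table = summarize_natural_history(registry, assignments)
        row = table[
            (table["axis"] == "onset")
            & (table["level"] == "infancy")
            & (table["category"] == "ultra_rare")
        ].iloc[0]
        assert row["proportion_percent"] == pytest.approx(40.0)
        assert row["se_percent"] == pytest.approx(
            100 * np.sqrt(0.4 * 0.6 / 10)
        )

    def test_missing_death_info_still_in_denominator(self):
        registry = _nh_registry()
        assignments = classify_registry(registry).by_orphacode
        table = summarize_natural_history(registry, assignments)
        row = table[
            (table["axis"] == "death")
            & (table["level"] == "normal_life_expectancy")
            & (table["category"] == "ultra_rare")
        ].iloc[0]
        assert row["denominator"] == 10  # disorder without death info included
        assert row["n_disorders"] == 9
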