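"""Statistical kernel for category comparisons.

Everything the spectrum tables need is implemented here from first
principles so the analysis is reproducible across platforms:

* two-sided Fisher's exact test on 2x2 tables (sum of hypergeometric
  probabilities no larger than the observed table's, the convention used by
  R's ``fisher.test``);
* Benjamini–Hochberg step-up FDR adjustment;
* tie-corrected Kruskal–Wallis rank-sum test (chi-square reference);
* two-sided Wilcoxon rank-sum test, exact for small untied samples via the
  full null rank-sum distribution, otherwise a normal approximation with
  continuity and tie corrections;
* the binomial standard error of a proportion.

Only distribution tail functions (chi-square, normal) come from scipy.

On top of the kernel sit the category-comparison builders: proportion tables
comparing the borderline-common and rare categories against the ultra-rare
reference (Fisher + BH within a declared family), rank tests for count/ratio
distributions, and the natural-history (age of onset / age of death)
proportion summary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm

from .classification import Category, CategoryAssignment, SPECTRUM_CATEGORIES
from .registry import DisorderRegistry

__all__ = [
    "ContingencyTable2x2",
    "Direction",
    "ComparisonRow",
    "RankTestResult",
    "hypergeom_pmf",
    "fisher_exact_two_sided",
    "bh_fdr",
    "proportion_se",
    "midranks",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "rank_compare",
    "compare_proportions",
    "summarize_natural_history",
    "ALPHA",
]

#: Significance level used throughout the comparison tables (on BH-adjusted p).
ALPHA = 0.05

# Relative tolerance when comparing hypergeometric probabilities against the
# observed table's probability (guards against floating-point noise deciding
# whether an equal-probability table enters the two-sided sum).
_REL_EPS = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = feature yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")


def _log_comb(n: int, k: int) -> float:
    return (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    )


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("invalid hypergeometric parameters")
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    return math.exp(
        _log_comb(K, k) + _log_comb(N - K, n - k) - _log_comb(N, n)
    )


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (up to a
    small relative tolerance).  Returns a p-value in (0, 1].
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - N)
    hi = min(row1, col1)
    log_probs = [
        _log_comb(col1, k)
        + _log_comb(N - col1, row1 - k)
        - _log_comb(N, row1)
        for k in range(lo, hi + 1)
    ]
    log_obs = log_probs[a - lo]
    threshold = log_obs + math.log1p(_REL_EPS)
    p = sum(math.exp(lp) for lp in log_probs if lp <= threshold)
    return min(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = list(p_values)
    m = len(p)
    for v in p:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {v}")
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def proportion_se(p: float, n: int) -> float:
    """Binomial standard error sqrt(p(1-p)/n) of a proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return math.sqrt(p * (1.0 - p) / n)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties replaced by their midrank."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _tie_sizes(values: np.ndarray) -> list[int]:
    _, counts = np.unique(values, return_counts=True)
    return [int(c) for c in counts if c > 1]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    Degrees of freedom are (number of groups - 1).  With every pooled value
    identical the statistic is 0 and p is 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = midranks(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    ties = _tie_sizes(pooled)
    correction = 1.0 - sum(t**3 - t for t in ties) / (N**3 - N)
    if correction <= 0.0:  # all pooled values identical
        return 0.0, 1.0
    H /= correction
    H = max(H, 0.0)
    p = float(_chi2.sf(H, df=len(groups) - 1))
    return float(H), p


def _exact_rank_sum_distribution(n1: int, N: int) -> dict[int, int]:
    """Number of n1-subsets of ranks 1..N attaining each rank sum."""
    # DP over ranks; ways[k][s] = subsets of size k with sum s
    ways = [dict() for _ in range(n1 + 1)]
    ways[0][0] = 1
    for rank in range(1, N + 1):
        for k in range(min(rank, n1), 0, -1):
            for s, count in list(ways[k - 1].items()):
                ways[k][s + rank] = ways[k].get(s + rank, 0) + count
    return ways[n1]


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
) -> float:
    """Two-sided Wilcoxon (Mann–Whitney) rank-sum p-value.

    ``mode`` is ``"exact"``, ``"approx"`` or ``"auto"`` (exact when both
    samples have <= 25 observations and the pooled data has no ties).  The
    exact two-sided p doubles the smaller tail of the null rank-sum
    distribution (capped at 1); the approximation applies continuity and tie
    corrections.
    """
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = mode == "exact" or (
        mode == "auto" and n1 <= 25 and n2 <= 25 and not has_ties
    )
    if use_exact and has_ties:
        raise ValueError("exact Wilcoxon p is unavailable with ties")

    ranks = midranks(pooled)
    w = float(ranks[:n1].sum())

    if use_exact:
        N = n1 + n2
        dist = _exact_rank_sum_distribution(n1, N)
        total = math.comb(N, n1)
        w_int = int(round(w))
        lower = sum(c for s, c in dist.items() if s <= w_int)
        upper = sum(c for s, c in dist.items() if s >= w_int)
        p = 2.0 * min(lower, upper) / total
        return min(p, 1.0)

    N = n1 + n2
    mu = n1 * (N + 1) / 2.0
    ties = _tie_sizes(pooled)
    tie_term = sum(t**3 - t for t in ties) / ((N) * (N - 1))
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    diff = w - mu
    # continuity correction toward the mean
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * _norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Category comparison builders
# ---------------------------------------------------------------------------


class Direction(str, enum.Enum):
    """Change of a proportion from borderline-common toward ultra-rare."""

    UP = "up"
    DOWN = "down"
    NONE = "none"


@dataclass
class ComparisonRow:
    feature: str
    family: str
    category: Category
    prop_category_percent: float
    prop_reference_percent: float
    p_raw: float
    p_adj: float = float("nan")
    significant: bool = False
    direction: Direction = Direction.NONE


@dataclass
class RankTestResult:
    feature: str
    H: float
    p_kw: float
    medians: dict[str, float]
    iqrs: dict[str, float]
    group_sizes: dict[str, int]
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def compare_proportions(
    feature_counts: Mapping[str, Mapping[Category, int]],
    denominators: Mapping[Category, int],
    family: str,
    reference: Category = Category.ULTRA_RARE,
    compared: Sequence[Category] = (Category.BORDERLINE_COMMON, Category.RARE),
    alpha: float = ALPHA,
) -> list[ComparisonRow]:
    """Fisher comparisons of per-category feature proportions vs a reference.

    For every feature, each compared category's count/denominator is tested
    against the reference category's with the two-sided Fisher exact test;
    BH adjustment is applied across all tests in the declared ``family``.
    Features with a zero denominator on either side are skipped.  The
    direction column is the sign of (reference prop - borderline-common
    prop), reported only when at least one of the feature's comparisons is
    significant.
    """
    rows: list[ComparisonRow] = []
    n_ref = denominators.get(reference, 0)
    for feature, counts in feature_counts.items():
        k_ref = counts.get(reference, 0)
        for category in compared:
            n_cat = denominators.get(category, 0)
            if n_cat == 0 or n_ref == 0:
                continue
            k_cat = counts.get(category, 0)
            table = ContingencyTable2x2(
                a=k_cat, b=n_cat - k_cat, c=k_ref, d=n_ref - k_ref
            )
            rows.append(
                ComparisonRow(
                    feature=feature,
                    family=family,
                    category=category,
                    prop_category_percent=100.0 * k_cat / n_cat,
                    prop_reference_percent=100.0 * k_ref / n_ref,
                    p_raw=fisher_exact_two_sided(table),
                )
            )
    adjusted = bh_fdr([r.p_raw for r in rows])
    for row, p_adj in zip(rows, adjusted):
        row.p_adj = p_adj
        row.significant = p_adj < alpha

    by_feature: dict[str, list[ComparisonRow]] = {}
    for row in rows:
        by_feature.setdefault(row.feature, []).append(row)
    for feature, feature_rows in by_feature.items():
        if not any(r.significant for r in feature_rows):
            continue
        bc = next(
            (r for r in feature_rows if r.category is Category.BORDERLINE_COMMON),
            feature_rows[0],
        )
        diff = bc.prop_reference_percent - bc.prop_category_percent
        direction = (
            Direction.UP if diff > 0 else Direction.DOWN if diff < 0 else Direction.NONE
        )
        for r in feature_rows:
            r.direction = direction
    return rows


def comparison_frame(rows: Iterable[ComparisonRow]) -> pd.DataFrame:
    """Flatten comparison rows into a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "family": r.family,
                "category": r.category.value,
                "prop_category_percent": r.prop_category_percent,
                "prop_reference_percent": r.prop_reference_percent,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
                "direction": r.direction.value,
            }
            for r in rows
        ]
    )


def rank_compare(
    values_by_category: Mapping[str, Sequence[float]],
    feature: str,
    alpha: float = ALPHA,
    pairwise_mode: str = "auto",
) -> RankTestResult:
    """Kruskal–Wallis across categories with conditional pairwise Wilcoxon.

    Pairwise two-sided Wilcoxon rank-sum tests (BH-adjusted within the
    pairwise family) are run only when the Kruskal–Wallis p-value is below
    ``alpha``, mirroring the usual omnibus-then-posthoc workflow.
    """
    labels = [k for k, v in values_by_category.items() if len(v) > 0]
    if len(labels) < 2:
        raise ValueError("rank_compare needs >= 2 non-empty groups")
    groups = [np.asarray(values_by_category[k], dtype=float) for k in labels]
    H, p_kw = kruskal_wallis(groups)
    medians = {k: float(np.median(g)) for k, g in zip(labels, groups)}
    iqrs = {
        k: float(np.percentile(g, 75) - np.percentile(g, 25))
        for k, g in zip(labels, groups)
    }
    sizes = {k: int(len(g)) for k, g in zip(labels, groups)}

    pairwise = pd.DataFrame(
        columns=["group_a", "group_b", "p_raw", "p_adj", "significant"]
    )
    if p_kw < alpha:
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        p_raw = [
            wilcoxon_rank_sum(
                values_by_category[a], values_by_category[b], mode=pairwise_mode
            )
            for a, b in pairs
        ]
        p_adj = bh_fdr(p_raw)
        pairwise = pd.DataFrame(
            {
                "group_a": [a for a, _ in pairs],
                "group_b": [b for _, b in pairs],
                "p_raw": p_raw,
                "p_adj": p_adj,
                "significant": [p < alpha for p in p_adj],
            }
        )
    return RankTestResult(
        feature=feature,
        H=H,
        p_kw=p_kw,
        medians=medians,
        iqrs=iqrs,
        group_sizes=sizes,
        pairwise=pairwise,
    )


def summarize_natural_history(
    registry: DisorderRegistry,
    assignments: Mapping[int, CategoryAssignment],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-level onset/death proportions with SEs and Fisher comparisons.

    Denominators are *all* category disorders, including those without
    natural-history information (which is why onset and death percentage
    magnitudes differ).  A disorder with several levels on an axis counts
    once per level.  Comparisons against the ultra-rare category are
    BH-adjusted within each axis family.
    """
    sizes = {c: 0 for c in SPECTRUM_CATEGORIES}
    level_counts: dict[str, dict[str, dict[Category, int]]] = {
        "onset": {},
        "death": {},
    }
    for record in registry:
        a = assignments.get(record.orphacode)
        if a is None or a.category not in SPECTRUM_CATEGORIES:
            continue
        sizes[a.category] += 1
        for axis, levels in (
            ("onset", record.onset_intervals),
            ("death", record.death_intervals),
        ):
            for level in levels:
                per_level = level_counts[axis].setdefault(
                    level, {c: 0 for c in SPECTRUM_CATEGORIES}
                )
                per_level[a.category] += 1

    frames = []
    for axis, features in level_counts.items():
        rows = compare_proportions(
            features, sizes, family=f"natural_history_{axis}", alpha=alpha
        )
        comparison = comparison_frame(rows)
        records = []
        for level, counts in sorted(features.items()):
            for category in SPECTRUM_CATEGORIES:
                n = sizes[category]
                if n == 0:
                    continue
                p = counts[category] / n
                if category is not Category.ULTRA_RARE and len(comparison):
                    sub = comparison[
                        (comparison["feature"] == level)
                        & (comparison["category"] == category.value)
                    ]
                else:
                    sub = pd.DataFrame()
                records.append(
                    {
                        "axis": axis,
                        "level": level,
                        "category": category.value,
                        "n_disorders": counts[category],
                        "denominator": n,
                        "proportion_percent": 100.0 * p,
                        "se_percent": 100.0 * proportion_se(p, n),
                        "p_raw": float(sub["p_raw"].iloc[0]) if len(sub) else float("nan"),
                        "p_adj": float(sub["p_adj"].iloc[0]) if len(sub) else float("nan"),
                        "significant": bool(sub["significant"].iloc[0]) if len(sub) else False,
                    }
                )
        frames.append(pd.DataFrame(records))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
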