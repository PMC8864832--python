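"""Pathway over-representation analysis for category gene universes.

For each spectrum category, the deduplicated union of its disorders' gene
associations forms a query gene set.  Each pathway from a GMT annotation is
tested with Fisher's exact test against a background universe (default: all
genes appearing in the annotation), p-values are BH-adjusted within the run,
and a pathway counts as *enriched* only when the adjusted p is below 0.05
AND at least 10 query genes are annotated to it — the minimum-gene rule
guards against tiny-overlap artifacts.

The default test is two-sided; a one-sided (over-representation only,
hypergeometric upper tail) mode is available since ORA tools commonly use
it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classification import Category, CategoryAssignment
from .registry import AssociationType, DisorderRegistry
from .setops import venn_regions
from .stats import (
    ALPHA,
    ContingencyTable2x2,
    bh_fdr,
    fisher_exact_two_sided,
    hypergeom_pmf,
    proportion_se,
)

__all__ = [
    "PathwayAnnotation",
    "read_gmt",
    "write_gmt",
    "category_gene_universe",
    "enrich",
    "enrichment_overlap",
    "annotated_fraction_comparison",
    "MIN_QUERY_GENES",
]

logger = logging.getLogger(__name__)

#: Minimum number of query genes annotated to a pathway for it to count as
#: truly enriched.
MIN_QUERY_GENES = 10


@dataclass(frozen=True)
class PathwayAnnotation:
    pathway_id: str
    pathway_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id}: empty gene set")
        object.__setattr__(self, "genes", frozenset(self.genes))


def read_gmt(path) -> list[PathwayAnnotation]:
    """Parse a GMT file: id, description, then member genes, tab-separated.

    Duplicate genes within a line are deduplicated with a warning; duplicate
    pathway ids raise.
    """
    pathways: list[PathwayAnnotation] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs id, description and "
                    "at least one gene"
                )
            pathway_id, name, *genes = fields
            genes = [g for g in genes if g]
            if pathway_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pathway_id}")
            seen.add(pathway_id)
            if len(set(genes)) < len(genes):
                logger.warning(
                    "%s:%d: duplicate genes within pathway %s deduplicated",
                    path,
                    lineno,
                    pathway_id,
                )
            pathways.append(PathwayAnnotation(pathway_id, name, frozenset(genes)))
    return pathways


def write_gmt(pathways: Sequence[PathwayAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(pathways, key=lambda p: p.pathway_id):
            fh.write(
                "\t".join([p.pathway_id, p.pathway_name, *sorted(p.genes)]) + "\n"
            )


def category_gene_universe(
    registry: DisorderRegistry,
    assignments: Mapping[int, CategoryAssignment],
    category: Category,
    association_filter: Iterable[AssociationType] | None = None,
) -> set[str]:
    """Deduplicated union of gene symbols over a category's disorders.

    By default all association types contribute (causing, modifier,
    susceptibility, other); restrict with ``association_filter``.
    """
    allowed = (
        {AssociationType(a) for a in association_filter}
        if association_filter is not None
        else None
    )
    universe: set[str] = set()
    for record in registry:
        a = assignments.get(record.orphacode)
        if a is None or a.category is not Category(category):
            continue
        for ga in record.gene_associations:
            if allowed is None or ga.association_type in allowed:
                universe.add(ga.gene_symbol)
    logger.info(
        "gene universe for %s: %d genes", Category(category).value, len(universe)
    )
    return universe


def _hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    return min(
        1.0, sum(hypergeom_pmf(j, N, K, n) for j in range(k, min(n, K) + 1))
    )


def enrich(
    query: set[str],
    annotation: Sequence[PathwayAnnotation],
    background: set[str] | None = None,
    alpha: float = ALPHA,
    min_query_genes: int = MIN_QUERY_GENES,
    one_sided: bool = False,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-pathway over-representation table for a query gene set.

    ``background`` defaults to all genes in the annotation.  Query genes
    missing from the background raise in strict mode and are dropped with a
    warning otherwise.  Pathway gene sets are intersected with the
    background.  Rows are sorted by (p_adj, pathway_id); the ``enriched``
    flag requires both p_adj < alpha and k >= min_query_genes.
    """
    if background is None:
        background = set().union(*(p.genes for p in annotation)) if annotation else set()
    if not background:
        raise ValueError("empty background universe")
    stray = set(query) - background
    if stray:
        if strict:
            raise ValueError(
                f"{len(stray)} query genes absent from background "
                f"(e.g. {sorted(stray)[:3]}); pass strict=False to drop them"
            )
        logger.warning(
            "dropping %d query genes absent from background", len(stray)
        )
    query = set(query) & background

    N = len(background)
    n = len(query)
    rows = []
    for pathway in annotation:
        genes = pathway.genes & background
        K = len(genes)
        k = len(query & genes)
        if one_sided:
            p = _hypergeom_upper_tail(k, N, K, n)
        else:
            p = fisher_exact_two_sided(
                ContingencyTable2x2(a=k, b=n - k, c=K - k, d=N - K - (n - k))
            )
        fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        rows.append(
            {
                "pathway_id": pathway.pathway_id,
                "pathway_name": pathway.pathway_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fold": fold,
                "p_raw": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_fdr(df["p_raw"].tolist())
        df["enriched"] = (df["p_adj"] < alpha) & (df["k"] >= min_query_genes)
        df = df.sort_values(["p_adj", "pathway_id"]).reset_index(drop=True)
    else:
        df["p_adj"] = []
        df["enriched"] = []
    return df


def enrichment_overlap(
    rows_by_category: Mapping[str, pd.DataFrame]
) -> dict[str, int]:
    """Venn region cardinalities over enriched pathway ids per category."""
    if len(rows_by_category) < 2:
        raise ValueError("need >= 2 categories to compute overlaps")
    sets = {
        label: set(df.loc[df["enriched"], "pathway_id"])
        for label, df in rows_by_category.items()
    }
    return venn_regions(sets)


def annotated_fraction_comparison(
    shared_pathways: Sequence[str],
    universes_by_category: Mapping[Category, set[str]],
    annotation: Sequence[PathwayAnnotation],
    reference: Category = Category.ULTRA_RARE,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-pathway annotated gene fractions with SEs and Fisher comparisons.

    For every shared pathway and category: fraction = |universe ∩ pathway| /
    |universe|.  Non-reference categories are compared against the reference
    with the two-sided Fisher exact test, BH-adjusted within the
    shared-pathway family.
    """
    by_id = {p.pathway_id: p for p in annotation}
    missing = [p for p in shared_pathways if p not in by_id]
    if missing:
        raise KeyError(f"pathways not in annotation: {', '.join(missing)}")
    for category, universe in universes_by_category.items():
        if not universe:
            raise ValueError(f"empty gene universe for {Category(category).value}")

    reference = Category(reference)
    ref_universe = universes_by_category[reference]
    records = []
    tests = []
    for pathway_id in shared_pathways:
        genes = by_id[pathway_id].genes
        k_ref = len(ref_universe & genes)
        n_ref = len(ref_universe)
        for category, universe in universes_by_category.items():
            category = Category(category)
            k = len(universe & genes)
            n = len(universe)
            fraction = k / n
            entry = {
                "pathway_id": pathway_id,
                "category": category.value,
                "k": k,
                "n": n,
                "fraction": fraction,
                "se": proportion_se(fraction, n),
                "p_raw": float("nan"),
                "p_adj": float("nan"),
                "significant": False,
            }
            if category is not reference:
                p = fisher_exact_two_sided(
                    ContingencyTable2x2(a=k, b=n - k, c=k_ref, d=n_ref - k_ref)
                )
                entry["p_raw"] = p
                tests.append(entry)
            records.append(entry)
    adjusted = bh_fdr([t["p_raw"] for t in tests])
    for entry, p_adj in zip(tests, adjusted):
        entry["p_adj"] = p_adj
        entry["significant"] = p_adj < alpha
    return pd.DataFrame(records)
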