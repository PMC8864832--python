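"""Small set-algebra helpers shared by the phenotype and pathway modules."""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

__all__ = ["venn_regions"]


def venn_regions(sets_by_label: Mapping[str, set]) -> dict[str, int]:
    """Cardinalities of all exclusive Venn regions of the given sets.

    Region keys join the member labels with ``&`` in sorted order; for three
    sets this yields the familiar seven regions.  Regions partition the
    union, so the cardinalities sum to ``len(union of all sets)``.
    """
    labels = sorted(sets_by_label)
    regions: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(set(sets_by_label[l]) for l in combo))
            for other in labels:
                if other not in combo:
                    inside -= set(sets_by_label[other])
            regions["&".join(combo)] = len(inside)
    return regions
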