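"""Split genes into lowly and highly translated groups of equal footprint mass.

Genes are ranked by windowed mean footprint coverage; the boundary is placed
where the cumulative footprint count first reaches half the grand total, so
the two groups hold (nearly) the same number of footprints rather than the
same number of genes — the highly-translated group is small and strongly
translated.  A fraction of genes on either side of the boundary (default 5%
of each group) is then excluded to sharpen the contrast between the groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .footprints import GeneCoverage

LOW, HIGH, EXCLUDED = "low", "high", "excluded_boundary"


@dataclass
class GroupAssignment:
    #: gene_id → "low" | "high" | "excluded_boundary"
    labels: dict[str, str]
    #: rank (0-based, ascending coverage) of the first high-group gene
    split_index: int
    #: footprint totals per label
    totals: dict[str, int]
    #: gene ids in ascending coverage order
    ranking: list[str]

    def genes(self, label: str) -> list[str]:
        return [g for g in self.ranking if self.labels[g] == label]

    def to_frame(self, coverages: Mapping[str, GeneCoverage]) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g,
                    "n_footprints": coverages[g].n_footprints,
                    "mean_coverage": coverages[g].mean_coverage,
                    "rank": i,
                    "label": self.labels[g],
                }
                for i, g in enumerate(self.ranking)
            ]
        )


def rank_and_split(
    coverages: Mapping[str, GeneCoverage],
    exclusion_fraction: float = 0.05,
) -> GroupAssignment:
    """Rank by mean coverage and split at half the total footprint mass.

    The low group is the smallest coverage-ascending prefix whose cumulative
    footprint count reaches half the total (the boundary gene goes low); the
    high group is the remainder.  Then ``ceil(exclusion_fraction * |group|)``
    genes adjacent to the boundary on each side are relabelled
    ``excluded_boundary``.  Ties in coverage are broken by gene id, so the
    assignment is independent of input order.
    """
    if len(coverages) < 4:
        raise ValueError("need at least 4 genes to form two groups after exclusion")
    ranking = sorted(coverages, key=lambda g: (coverages[g].mean_coverage, g))
    total = sum(coverages[g].n_footprints for g in ranking)
    cum = 0
    split = len(ranking)
    for i, g in enumerate(ranking):
        cum += coverages[g].n_footprints
        if cum >= total / 2:
            split = i + 1
            break

    labels = {g: (LOW if i < split else HIGH) for i, g in enumerate(ranking)}
    n_low, n_high = split, len(ranking) - split
    for g in ranking[split - math.ceil(exclusion_fraction * n_low) : split]:
        labels[g] = EXCLUDED
    for g in ranking[split : split + math.ceil(exclusion_fraction * n_high)]:
        labels[g] = EXCLUDED

    totals = {LOW: 0, HIGH: 0, EXCLUDED: 0}
    for g in ranking:
        totals[labels[g]] += coverages[g].n_footprints
    return GroupAssignment(labels, split, totals, ranking)
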