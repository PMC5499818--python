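"""End-to-end convenience: footprints + ORFs → per-group RSCU and bias stats."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from . import footprints as fp
from .grouping import HIGH, LOW, GroupAssignment, rank_and_split
from .orfs import SelectedORF
from .rscu import (
    CodonCountTable,
    CodonWindow,
    PreferredCall,
    RSCUVector,
    compute_rscu,
    count_codons,
    euclidean_distance,
    preferred_codons,
)


@dataclass
class RSCUAnalysis:
    """Result of one ribosome-profiling codon-usage run."""

    offset: fp.PSiteOffset
    coverages: dict[str, fp.GeneCoverage]
    assignment: GroupAssignment
    counts: dict[str, CodonCountTable]     # per group label
    rscu: dict[str, RSCUVector]            # per group label
    preferred: dict[str, dict[str, PreferredCall]]  # per group label

    @property
    def htg_ltg_distance(self) -> float:
        """Euclidean distance between high- and low-group RSCU vectors —
        the intensity of codon usage bias in this experiment."""
        return euclidean_distance(self.rscu[HIGH], self.rscu[LOW])


def run_rscu_analysis(
    orfs: Mapping[str, SelectedORF],
    records: Iterable[fp.FootprintRecord],
    window: CodonWindow | tuple[int, int] = CodonWindow(),
    stop_margin: int = 20,
    offset: int | None = None,
    f_min: int = 10,
    exclusion_fraction: float = 0.05,
) -> RSCUAnalysis:
    """Run the full method: P-site assignment, coverage ranking, group split,
    windowed codon counting and RSCU per group.

    `offset` fixes the P-site shift in nt; None detects it from the metagene
    profile.
    """
    records = list(records)
    if offset is None:
        shift = fp.detect_offset(fp.build_metagene(records))
    else:
        shift = fp.PSiteOffset(offset)
    psites = fp.assign_psites(records, shift, orfs)
    coverages = fp.compute_coverage(psites.psites, orfs, window, stop_margin)
    kept = fp.filter_low_coverage(coverages, f_min)
    assignment = rank_and_split(kept, exclusion_fraction)

    counts: dict[str, CodonCountTable] = {}
    rscu: dict[str, RSCUVector] = {}
    preferred: dict[str, dict[str, PreferredCall]] = {}
    for label in (LOW, HIGH):
        group_orfs = [orfs[g] for g in assignment.genes(label)]
        table = count_codons(group_orfs, window, stop_margin)
        counts[label] = table
        rscu[label] = compute_rscu(table)
        preferred[label] = preferred_codons(table)
    return RSCUAnalysis(shift, coverages, assignment, counts, rscu, preferred)
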