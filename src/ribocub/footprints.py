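"""Ribosome-footprint processing: 5' ends → P-sites → per-gene coverage.

A ribosome protects ~28–30 nt of mRNA; the P-site of the ribosome sits at a
fixed distance downstream of the protected fragment's 5' end.  Aggregating
footprint 5' ends around the start codons of all genes (a metagene profile)
shows a majority peak at a fixed negative offset — the initiating ribosome
whose P-site holds codon 1.  The detected offset (canonically 12 nt) is then
added to every 5' end to place each footprint on the codon its ribosome was
translating.

Alignments must be in transcript space over the selected ORFs: reference names
are gene ids and position 0 is the first base of the start codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .orfs import SelectedORF
from .rscu import DEFAULT_STOP_MARGIN, CodonWindow

logger = logging.getLogger(__name__)

DEFAULT_SHIFT = 12
DEFAULT_METAGENE_RANGE = (-50, 50)
DEFAULT_OFFSET_SEARCH = (-18, -6)


@dataclass(frozen=True)
class FootprintRecord:
    gene_id: str
    #: 0-based transcript coordinate of the read's 5' end, relative to the
    #: first base of the start codon; negative values lie in the 5' UTR.
    five_prime_pos: int
    read_length: int

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


@dataclass
class AlignmentInput:
    records: list[FootprintRecord]
    n_dropped_unknown_gene: int = 0
    n_dropped_not_primary: int = 0


@dataclass
class MetageneProfile:
    """Histogram of footprint 5' ends relative to the start codon."""

    offsets: np.ndarray  # consecutive integers, min..max
    counts: np.ndarray

    def count_at(self, offset: int) -> int:
        lo = int(self.offsets[0])
        if not lo <= offset <= int(self.offsets[-1]):
            return 0
        return int(self.counts[offset - lo])


@dataclass(frozen=True)
class PSiteOffset:
    """The shift (nt) added to a 5' end to reach the ribosome's P-site."""

    shift: int

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("shift must be non-negative")


@dataclass(frozen=True)
class GeneCoverage:
    gene_id: str
    n_footprints: int
    mean_coverage: float  # footprints per codon of effective window


@dataclass
class PSiteAssignment:
    #: per gene, 1-based codon indices of assigned P-sites
    psites: dict[str, list[int]]
    n_assigned: int = 0
    n_dropped: int = 0


def read_footprint_tsv(path, orfs: Mapping[str, SelectedORF] | None = None) -> AlignmentInput:
    """Read a 3-column TSV (gene_id, five_prime_pos, read_length)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["gene_id", "five_prime_pos", "read_length"],
    )
    return _filter_records(
        (FootprintRecord(str(g), int(p), int(l))
         for g, p, l in df.itertuples(index=False)),
        orfs,
    )


def read_bam(path, orfs: Mapping[str, SelectedORF] | None = None) -> AlignmentInput:
    """Read primary alignments from a transcript-space BAM/SAM."""
    out = AlignmentInput([])
    known = set(orfs) if orfs is not None else None
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                out.n_dropped_not_primary += 1
                continue
            gene = aln.reference_name
            if known is not None and gene not in known:
                out.n_dropped_unknown_gene += 1
                continue
            five_prime = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            out.records.append(
                FootprintRecord(gene, int(five_prime), aln.query_length or len(aln.query_sequence or "x"))
            )
    return out


def _filter_records(records: Iterable[FootprintRecord],
                    orfs: Mapping[str, SelectedORF] | None) -> AlignmentInput:
    out = AlignmentInput([])
    if orfs is None:
        out.records = list(records)
        return out
    for rec in records:
        if rec.gene_id in orfs:
            out.records.append(rec)
        else:
            out.n_dropped_unknown_gene += 1
    return out


def read_alignments(source, orfs: Mapping[str, SelectedORF] | None = None) -> AlignmentInput:
    """Dispatch on file type: .bam/.sam via pysam, anything else as TSV."""
    s = str(source)
    if s.endswith((".bam", ".sam")):
        return read_bam(source, orfs)
    return read_footprint_tsv(source, orfs)


def build_metagene(
    records: Iterable[FootprintRecord],
    profile_range: tuple[int, int] = DEFAULT_METAGENE_RANGE,
) -> MetageneProfile:
    """Aggregate footprint 5' ends within `profile_range` over all genes."""
    lo, hi = profile_range
    counts = np.zeros(hi - lo + 1, dtype=int)
    for rec in records:
        if lo <= rec.five_prime_pos <= hi:
            counts[rec.five_prime_pos - lo] += 1
    return MetageneProfile(np.arange(lo, hi + 1), counts)


def detect_offset(
    profile: MetageneProfile,
    search: tuple[int, int] = DEFAULT_OFFSET_SEARCH,
) -> PSiteOffset:
    """P-site shift = −(position of the metagene majority peak).

    The argmax is taken within `search` (default [−18, −6] nt upstream of the
    start codon); ties are broken toward −12.  An all-zero profile falls back
    to the canonical shift of 12 with a warning.
    """
    lo, hi = search
    window = [(off, profile.count_at(off)) for off in range(lo, hi + 1)]
    best = max(c for _, c in window)
    if best == 0:
        logger.warning("metagene profile empty in search window; using default shift %d",
                       DEFAULT_SHIFT)
        return PSiteOffset(DEFAULT_SHIFT)
    peak = min((off for off, c in window if c == best),
               key=lambda off: (abs(off + DEFAULT_SHIFT), off))
    return PSiteOffset(-peak)


def assign_psites(
    records: Iterable[FootprintRecord],
    offset: PSiteOffset,
    orfs: Mapping[str, SelectedORF] | None = None,
) -> PSiteAssignment:
    """Shift each 5' end to its P-site and convert to a 1-based codon index.

    P-site nucleotide p = five_prime_pos + shift; codon = floor(p/3) + 1.
    Records with p < 0, or (when `orfs` is given) past the end of the CDS,
    are dropped and counted.
    """
    out = PSiteAssignment({})
    for rec in records:
        p = rec.five_prime_pos + offset.shift
        codon = p // 3 + 1
        if p < 0 or (orfs is not None and rec.gene_id in orfs
                     and codon > orfs[rec.gene_id].length_codons):
            out.n_dropped += 1
            continue
        out.psites.setdefault(rec.gene_id, []).append(codon)
        out.n_assigned += 1
    return out


def compute_coverage(
    psites: Mapping[str, Sequence[int]],
    orfs: Mapping[str, SelectedORF],
    window: CodonWindow | tuple[int, int] = CodonWindow(),
    stop_margin: int = DEFAULT_STOP_MARGIN,
) -> dict[str, GeneCoverage]:
    """Windowed footprint coverage per gene.

    The effective window of a gene with L codons is
    [window.start, min(window.end, L − stop_margin)]; genes whose effective
    window is empty are excluded.  Mean coverage is footprints per codon of
    the effective window.
    """
    window = CodonWindow(*window)
    out: dict[str, GeneCoverage] = {}
    for gene_id, orf in orfs.items():
        end = min(window.end, orf.length_codons - stop_margin)
        if end < window.start:
            continue
        length = end - window.start + 1
        n = sum(1 for c in psites.get(gene_id, ()) if window.start <= c <= end)
        out[gene_id] = GeneCoverage(gene_id, n, n / length)
    return out


def filter_low_coverage(
    coverages: Mapping[str, GeneCoverage], f_min: int = 10
) -> dict[str, GeneCoverage]:
    """Drop genes with fewer than `f_min` footprints in their window."""
    return {g: c for g, c in coverages.items() if c.n_footprints >= f_min}


def write_metagene_tsv(profile: MetageneProfile, path) -> None:
    pd.DataFrame({"offset": profile.offsets, "count": profile.counts}).to_csv(
        path, sep="\t", index=False
    )


def write_coverage_tsv(coverages: Mapping[str, GeneCoverage], path) -> None:
    pd.DataFrame(
        [
            {"gene_id": c.gene_id, "n_footprints": c.n_footprints,
             "mean_coverage": c.mean_coverage}
            for c in coverages.values()
        ]
    ).to_csv(path, sep="\t", index=False)
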