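"""Windowed codon counting and relative synonymous codon usage (RSCU).

RSCU (Sharp) for codon j of amino acid i is

    RSCU_ij = n_i * x_ij / sum_j x_ij

where n_i is the number of synonymous codons of amino acid i and x_ij the
number of occurrences of codon j in a set of coding sequences.  A value of 1
means unbiased usage; n_i means exclusive use of that codon.

Counting is windowed: codons are tallied from a fixed codon range of each ORF
(default the 20th through 200th codons), clipped to stay at least a margin of
codons away from the stop codon.  The lower bound avoids the footprint pile-up
caused by translation initiation; the window matches the region used to rank
genes by ribosome coverage, so the bias is measured exactly where translation
was quantified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .genetic_code import BASES, STANDARD_CODE, GeneticCode

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_START = 20
DEFAULT_WINDOW_END = 200
DEFAULT_STOP_MARGIN = 20


class CodonWindow(NamedTuple):
    """1-based inclusive codon range; the start codon is codon 1."""

    start: int = DEFAULT_WINDOW_START
    end: int = DEFAULT_WINDOW_END


@dataclass
class CodonCountTable:
    """Occurrence counts x_ij for the 59 analysis codons within a window."""

    counts: dict[str, int]
    window: CodonWindow
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    def __post_init__(self) -> None:
        for codon, n in self.counts.items():
            if codon not in self.code.analysis_codons:
                raise ValueError(f"{codon!r} is not an analysis codon")
            if n < 0 or n != int(n):
                raise ValueError(f"count for {codon} must be a non-negative integer")
        for codon in self.code.analysis_codons:
            self.counts.setdefault(codon, 0)

    def aa_total(self, aa: str) -> int:
        return sum(self.counts[c] for c in self.code.synonyms(aa))


@dataclass
class RSCUVector:
    """RSCU values per analysis codon.

    Amino acids with zero total count in the underlying table carry no value
    and are listed in ``undefined_aas``.
    """

    values: dict[str, float]
    undefined_aas: frozenset[str] = frozenset()
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    def defined_codons(self) -> tuple[str, ...]:
        return tuple(c for c in self.code.analysis_codons if c in self.values)

    def as_array(self, codons: Iterable[str]) -> np.ndarray:
        return np.array([self.values[c] for c in codons], dtype=float)


class PreferredCall(NamedTuple):
    """A preferred-codon call; `tied` marks a lexicographically broken tie."""

    codon: str
    tied: bool


def _cds_of(orf) -> str:
    return getattr(orf, "cds_sequence", orf)


def count_codons(
    orfs: Iterable,
    window: CodonWindow | tuple[int, int] = CodonWindow(),
    stop_margin: int = DEFAULT_STOP_MARGIN,
    code: GeneticCode = STANDARD_CODE,
) -> CodonCountTable:
    """Tally analysis codons of each ORF within the effective window.

    For an ORF of L codons (stop included) the effective window is
    ``[window.start, min(window.end, L - stop_margin)]``; ORFs for which that
    range is empty contribute nothing.  Codons containing characters outside
    ACGT are skipped with a warning.

    Parameters
    ----------
    orfs
        Iterable of coding sequences — `SelectedORF` objects or plain strings,
        each in frame from the start codon.
    window
        1-based inclusive codon range, default [20, 200].
    stop_margin
        Minimum number of codons to keep clear of the stop codon, default 20.
    """
    window = CodonWindow(*window)
    if window.start < 1:
        raise ValueError("window start must be >= 1 (the start codon is codon 1)")
    counts: dict[str, int] = {c: 0 for c in code.analysis_codons}
    valid = set(code.analysis_codons)
    n_skipped = 0
    for orf in orfs:
        seq = _cds_of(orf).upper()
        total_codons = len(seq) // 3
        end = min(window.end, total_codons - stop_margin)
        if end < window.start:
            continue
        for idx in range(window.start, end + 1):
            codon = seq[3 * (idx - 1) : 3 * idx]
            if codon in valid:
                counts[codon] += 1
            elif any(b not in BASES for b in codon):
                n_skipped += 1
    if n_skipped:
        logger.warning("skipped %d codons containing non-ACGT characters", n_skipped)
    return CodonCountTable(counts, window, code)


def compute_rscu(table: CodonCountTable) -> RSCUVector:
    """Sharp's RSCU_ij = n_i * x_ij / sum_j x_ij for each analysis codon."""
    code = table.code
    values: dict[str, float] = {}
    undefined = set()
    for aa in code.degenerate_aas:
        synonyms = code.synonyms(aa)
        total = sum(table.counts[c] for c in synonyms)
        if total == 0:
            undefined.add(aa)
            continue
        n_i = len(synonyms)
        for c in synonyms:
            values[c] = n_i * table.counts[c] / total
    return RSCUVector(values, frozenset(undefined), code)


def rscu_to_frequency(rscu: RSCUVector) -> dict[str, float]:
    """Relative synonym frequency in [0, 1]: RSCU / n_i.

    Per amino acid the frequencies sum to 1; undefined amino acids are absent
    from the result.
    """
    code = rscu.code
    return {
        c: v / code.n_synonyms(code.aa_of(c)) for c, v in rscu.values.items()
    }


def preferred_codons(table: CodonCountTable) -> dict[str, PreferredCall]:
    """The most-used codon per degenerate amino acid.

    Amino acids with zero total count are omitted.  Ties are broken
    lexicographically (A<C<G<T) and flagged via ``PreferredCall.tied``.
    """
    code = table.code
    out: dict[str, PreferredCall] = {}
    for aa in code.degenerate_aas:
        synonyms = code.synonyms(aa)
        best = max(table.counts[c] for c in synonyms)
        if best == 0 and all(table.counts[c] == 0 for c in synonyms):
            continue
        winners = [c for c in synonyms if table.counts[c] == best]
        out[aa] = PreferredCall(min(winners), tied=len(winners) > 1)
    return out


def preferred_codon_map(calls: Mapping[str, PreferredCall | str]) -> dict[str, str]:
    """Flatten preferred-codon calls to a plain aa→codon mapping."""
    return {aa: getattr(c, "codon", c) for aa, c in calls.items()}


def euclidean_distance(a: RSCUVector, b: RSCUVector) -> float:
    """Euclidean distance between two RSCU vectors over shared defined codons.

    Codons undefined in either vector (their amino acid had zero counts) are
    dropped from the sum; the number dropped is logged.  Raises if no codon is
    defined in both.
    """
    shared = [c for c in a.code.analysis_codons if c in a.values and c in b.values]
    if not shared:
        raise ValueError("no codon is defined in both RSCU vectors")
    dropped = len(a.code.analysis_codons) - len(shared)
    if dropped:
        logger.warning("dropped %d codons undefined in one of the vectors", dropped)
    return math.sqrt(sum((a.values[c] - b.values[c]) ** 2 for c in shared))


def rscu_to_frame(
    table: CodonCountTable,
    rscu: RSCUVector | None = None,
    group: str = "",
) -> pd.DataFrame:
    """Tabulate counts, RSCU and frequency as a tidy DataFrame.

    Columns: codon, amino_acid, count, rscu, frequency, group.  Codons of
    undefined amino acids carry NaN in rscu/frequency.
    """
    if rscu is None:
        rscu = compute_rscu(table)
    freq = rscu_to_frequency(rscu)
    code = table.code
    rows = [
        {
            "codon": c,
            "amino_acid": code.aa_of(c),
            "count": table.counts[c],
            "rscu": rscu.values.get(c, float("nan")),
            "frequency": freq.get(c, float("nan")),
            "group": group,
        }
        for c in code.analysis_codons
    ]
    return pd.DataFrame(rows)


def write_rscu_tsv(path, table: CodonCountTable, rscu=None, group: str = "") -> None:
    rscu_to_frame(table, rscu, group).to_csv(path, sep="\t", index=False)


def read_rscu_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
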