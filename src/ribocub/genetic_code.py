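"""The standard genetic code, restricted to the codons informative for codon
usage bias.

Codon usage bias is only defined for amino acids with a synonymous choice, so
the analysis alphabet drops the three stop codons and the two amino acids
encoded by a single codon, ATG (Met) and TGG (Trp).  That leaves 59 "analysis"
codons spread over 18 degenerate amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

BASES = "ACGT"
STOP = "*"

#: Codons excluded from bias analysis because their amino acid admits no
#: synonymous alternative.
NON_DEGENERATE_CODONS = frozenset({"ATG", "TGG"})


@dataclass(frozen=True)
class GeneticCode:
    """A codon→amino-acid map plus the derived analysis alphabet.

    Attributes
    ----------
    codon_to_aa
        Maps each of the 64 DNA triplets to a one-letter amino acid, with
        ``"*"`` for stops.
    analysis_codons
        The codons retained for codon-usage analysis, in lexicographic order.
    degenerate_aas
        Amino acids with at least two synonymous codons after exclusions,
        in alphabetical order.
    """

    codon_to_aa: dict[str, str]
    analysis_codons: tuple[str, ...] = field(init=False)
    degenerate_aas: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        stops = {c for c, aa in self.codon_to_aa.items() if aa == STOP}
        kept = sorted(
            c for c in self.codon_to_aa
            if c not in stops and c not in NON_DEGENERATE_CODONS
        )
        aas = sorted({self.codon_to_aa[c] for c in kept})
        object.__setattr__(self, "analysis_codons", tuple(kept))
        object.__setattr__(self, "degenerate_aas", tuple(aas))

    def synonyms(self, aa: str) -> tuple[str, ...]:
        """Analysis codons encoding amino acid `aa`, lexicographic order."""
        return tuple(c for c in self.analysis_codons if self.codon_to_aa[c] == aa)

    def n_synonyms(self, aa: str) -> int:
        """Degeneracy n_i of amino acid `aa` within the analysis alphabet."""
        return len(self.synonyms(aa))

    def aa_of(self, codon: str) -> str:
        return self.codon_to_aa[codon]


def _standard_code() -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = {}
    for codon in ("".join(p) for p in product(BASES, repeat=3)):
        mapping[codon] = STOP if codon in table.stop_codons else table.forward_table[codon]
    return GeneticCode(mapping)


#: The standard nuclear genetic code (NCBI translation table 1).
STANDARD_CODE = _standard_code()
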