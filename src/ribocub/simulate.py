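"""Synthetic transcriptomes and ribosome footprints with known ground truth.

The generator emulates the data a codon-usage study consumes, with every
latent quantity recorded so each pipeline stage can be checked against truth:

* coding sequences whose interior codons follow a two-regime bias model —
  each degenerate amino acid has a designated preferred codon used with
  probability π_h in high-expression genes and π_l in low-expression genes,
  remaining mass uniform over the other synonyms;
* a heavy-tailed (log-normal) per-gene expression law;
* footprints whose P-sites are uniform over the coding region except for an
  initiation peak on the first five codons — sharpest at the start codon
  itself, as in real profiles — and whose 5' ends sit a fixed offset upstream
  of the P-site (default 12 nt, the canonical geometry).

A π below the uniform rate 1/n_i of an amino acid is clamped to 1/n_i (a
codon cannot be "preferred" less often than chance), so a single scalar π
applies across amino acids of different degeneracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .comparative import TRNAPool, cognate_codon
from .footprints import FootprintRecord
from .genetic_code import STANDARD_CODE, GeneticCode
from .orfs import SelectedORF

STOP_CODON = "TAA"
LOW, HIGH = "low", "high"


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a realistic mid-size experiment."""

    n_genes: int = 300
    #: uniform CDS length range in sense codons (start included, stop excluded)
    cds_length_codons: tuple[int, int] = (100, 500)
    #: log-normal expression law: exp(sigma * N(0,1)) * scale
    expression_sigma: float = 1.5
    expression_scale: float = 1.0
    #: preferred-codon usage probability in high/low expression genes;
    #: None means unbiased (1/n_i)
    pi_high: float | None = 0.8
    pi_low: float | None = None
    #: nt between a footprint 5' end and its ribosome's P-site
    offset: int = 12
    read_length_range: tuple[int, int] = (27, 31)
    #: fraction of footprints concentrated on codons 1–5 by initiation
    init_peak_weight: float = 0.1
    n_footprints: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be non-negative")
        ph = 1.0 if self.pi_high is None else self.pi_high
        pl = 0.0 if self.pi_low is None else self.pi_low
        if not 0.0 <= pl <= 1.0 or not 0.0 <= ph <= 1.0:
            raise ValueError("pi_high and pi_low must lie in [0, 1]")
        if self.pi_low is not None and self.pi_high is not None and pl > ph:
            raise ValueError("pi_low must not exceed pi_high")
        if not 0.0 <= self.init_peak_weight <= 1.0:
            raise ValueError("init_peak_weight must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Latent state of one simulated experiment."""

    expression: dict[str, float]
    group: dict[str, str]  # gene_id → "low" | "high" (by expression half)
    #: designated preferred codon per degenerate amino acid
    preferred: dict[str, str]
    #: per group, per amino acid, codon → generator probability
    codon_freqs: dict[str, dict[str, dict[str, float]]]
    offset: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _group_probs(
    code: GeneticCode, preferred: Mapping[str, str], pi: float | None
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for aa in code.degenerate_aas:
        synonyms = code.synonyms(aa)
        n = len(synonyms)
        p = 1.0 / n if pi is None else max(pi, 1.0 / n)
        rest = (1.0 - p) / (n - 1)
        out[aa] = {c: (p if c == preferred[aa] else rest) for c in synonyms}
    return out


def simulate_transcriptome(
    config: SimulationConfig, code: GeneticCode = STANDARD_CODE
) -> tuple[dict[str, SelectedORF], GroundTruth]:
    """Draw a transcriptome under the two-regime codon-bias model.

    Every gene starts with ATG and ends with a stop codon; interior codons
    are drawn amino acid first (uniform over the 18 degenerate amino acids),
    then codon according to the gene's expression half.  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    lo, hi = config.cds_length_codons
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    expr = config.expression_scale * rng.lognormal(0.0, config.expression_sigma,
                                                   size=config.n_genes)
    order = np.argsort(np.argsort(-expr))  # rank 0 = most expressed
    group = {g: (HIGH if order[i] < config.n_genes // 2 else LOW)
             for i, g in enumerate(gene_ids)}

    preferred = {
        aa: code.synonyms(aa)[rng.integers(len(code.synonyms(aa)))]
        for aa in code.degenerate_aas
    }
    freqs = {
        LOW: _group_probs(code, preferred, config.pi_low),
        HIGH: _group_probs(code, preferred, config.pi_high),
    }

    aas = code.degenerate_aas
    orfs: dict[str, SelectedORF] = {}
    for i, g in enumerate(gene_ids):
        n_interior = int(lengths[i]) - 1
        aa_idx = rng.integers(len(aas), size=n_interior)
        probs = freqs[group[g]]
        codons = np.empty(n_interior, dtype=object)
        for a, aa in enumerate(aas):
            mask = aa_idx == a
            k = int(mask.sum())
            if not k:
                continue
            synonyms = code.synonyms(aa)
            p = np.array([probs[aa][c] for c in synonyms])
            codons[mask] = rng.choice(synonyms, size=k, p=p)
        seq = "ATG" + "".join(codons) + STOP_CODON
        orfs[g] = SelectedORF(g, seq)

    truth = GroundTruth(
        expression={g: float(expr[i]) for i, g in enumerate(gene_ids)},
        group=group,
        preferred=preferred,
        codon_freqs=freqs,
        offset=config.offset,
    )
    return orfs, truth


def simulate_footprints(
    orfs: Mapping[str, SelectedORF],
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[FootprintRecord]:
    """Draw footprints: genes multinomially by expression, P-sites uniform
    over sense codons except the initiation-peak mass on codons 1–5, 5' end
    = P-site nucleotide − offset."""
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = list(orfs)
    expr = np.array([truth.expression[g] for g in gene_ids])
    total = expr.sum()
    if total == 0:
        raise ValueError("all expression levels are zero")
    counts = rng.multinomial(config.n_footprints, expr / total)

    records: list[FootprintRecord] = []
    rl_lo, rl_hi = config.read_length_range
    # initiation mass decays from the start codon so the metagene keeps a
    # single majority peak at codon 1
    init_codons = np.arange(1, 6)
    init_probs = np.array([0.5, 0.125, 0.125, 0.125, 0.125])
    for g, n in zip(gene_ids, counts):
        if n == 0:
            continue
        n_sense = orfs[g].length_codons - 1  # exclude the stop codon
        n_init = rng.binomial(n, config.init_peak_weight)
        codons = np.concatenate([
            np.minimum(rng.choice(init_codons, size=n_init, p=init_probs), n_sense),
            rng.integers(1, n_sense + 1, size=n - n_init),
        ])
        five_primes = (codons - 1) * 3 - config.offset
        read_lengths = rng.integers(rl_lo, rl_hi + 1, size=n)
        records.extend(
            FootprintRecord(g, int(fp), int(rl))
            for fp, rl in zip(five_primes, read_lengths)
        )
    return records


def simulate_trna_pool(
    truth: GroundTruth,
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> TRNAPool:
    """A tRNA pool broadly concordant with the generator's preferred codons:
    preferred codons get high cognate copy numbers, other synonyms low ones
    (possibly zero, yielding codons lacking tRNA)."""
    rng = np.random.default_rng(seed)
    copies: dict[str, int] = {}
    for aa in code.degenerate_aas:
        for c in code.synonyms(aa):
            high = c == truth.preferred[aa]
            copies[cognate_codon(c)] = int(
                rng.integers(5, 15) if high else rng.integers(0, 4)
            )
    return TRNAPool(copies)


# ---------------------------------------------------------------------------
# on-disk fixtures


def write_footprint_tsv(records: Sequence[FootprintRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.gene_id}\t{r.five_prime_pos}\t{r.read_length}\n")


def write_fasta_gff(
    orfs: Mapping[str, SelectedORF],
    fasta_path,
    gff_path,
    utr: int = 30,
    spacer: int = 20,
    intron: int = 50,
) -> None:
    """Lay the ORFs on a synthetic chromosome and write genome FASTA + GFF3.

    Genes alternate strand; every third gene is split into two CDS exons by
    an intron, exercising spliced extraction.  UTRs are poly-N pads so any
    frame error is caught immediately by the downstream ATG check.
    """
    chrom_parts: list[str] = []
    rows: list[str] = []
    pos = 0
    chrom = "chr_sim"
    for k, (gene_id, orf) in enumerate(sorted(orfs.items())):
        strand = "+" if k % 2 == 0 else "-"
        seq = orf.cds_sequence if strand == "+" else _revcomp(orf.cds_sequence)
        split = k % 3 == 2 and len(seq) > 6
        chrom_parts.append("N" * utr)
        pos += utr
        if split:
            cut = (len(seq) // 6) * 3
            if strand == "-":
                cut = len(seq) - cut
            pieces = [seq[:cut], seq[cut:]]
        else:
            pieces = [seq]
        segs = []
        for i, piece in enumerate(pieces):
            if i:
                chrom_parts.append("N" * intron)
                pos += intron
            segs.append((pos, pos + len(piece)))
            chrom_parts.append(piece)
            pos += len(piece)
        chrom_parts.append("N" * (utr + spacer))
        pos += utr + spacer
        gene_start = min(s for s, _ in segs) + 1
        gene_end = max(e for _, e in segs)
        tx = f"{gene_id}.t1"
        rows.append(f"{chrom}\tsim\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\tID={gene_id}")
        rows.append(
            f"{chrom}\tsim\tmRNA\t{gene_start}\t{gene_end}\t.\t{strand}\t.\tID={tx};Parent={gene_id}"
        )
        for s, e in segs:
            rows.append(f"{chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\tParent={tx}")
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        full = "".join(chrom_parts)
        for i in range(0, len(full), 80):
            fh.write(full[i : i + 80] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\n".join(rows) + "\n")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
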