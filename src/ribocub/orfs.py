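"""ORF selection: choose one unambiguous coding sequence per gene.

Codon indices relative to the start codon are the backbone of the whole
analysis, so only genes whose start codon is certain are admitted:

* genes with a unique isoform are kept whole;
* genes whose isoforms start at different genomic positions are rejected;
* genes whose isoforms share the start codon are truncated to the longest
  common codon prefix of their spliced CDS sequences (the shared start anchors
  the reading frame, so the prefix has identical codon indices in every
  isoform);
* mitochondrial genes are excluded.

Coordinates: annotation files (GFF3/GTF) are 1-based inclusive; internally
everything is 0-based half-open.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Sequence names treated as the mitochondrial genome (case-insensitive).
DEFAULT_MITO_NAMES = ("MT", "chrM", "chrMT", "mito")


@dataclass(frozen=True)
class Isoform:
    transcript_id: str
    #: CDS segments as 0-based half-open genomic intervals, in transcript
    #: (5'→3') order.
    segments: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    isoforms: tuple[Isoform, ...]
    is_mitochondrial: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class SelectedORF:
    """A gene's admitted coding sequence, in frame from the start codon."""

    gene_id: str
    cds_sequence: str

    @property
    def length_codons(self) -> int:
        return len(self.cds_sequence) // 3


@dataclass
class SelectionResult:
    orfs: dict[str, SelectedORF]
    decisions: pd.DataFrame  # columns: gene_id, decision, reason
    counts: Counter = field(default_factory=Counter)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_spliced_cds(
    model: GeneModel,
    genome: Mapping[str, str],
    transcript_id: str | None = None,
) -> str:
    """Spliced CDS of one isoform, reverse-complemented on the minus strand.

    Segments are concatenated in transcript order; on the minus strand each
    genomic segment is reverse-complemented.
    """
    if transcript_id is None:
        if len(model.isoforms) != 1:
            raise ValueError(f"{model.gene_id}: transcript_id required for multi-isoform gene")
        isoform = model.isoforms[0]
    else:
        isoform = next(i for i in model.isoforms if i.transcript_id == transcript_id)
    chrom = genome[model.chromosome]
    parts = []
    for start, end in isoform.segments:
        if start < 0 or end > len(chrom) or start >= end:
            raise ValueError(
                f"transcript {isoform.transcript_id}: segment [{start},{end}) "
                f"outside chromosome {model.chromosome} (length {len(chrom)})"
            )
        piece = chrom[start:end].upper()
        parts.append(_revcomp(piece) if model.strand == "-" else piece)
    return "".join(parts)


def _start_codon_position(model: GeneModel, isoform: Isoform) -> int:
    """Genomic coordinate of the first transcribed CDS base (strand-aware)."""
    first = isoform.segments[0]
    return first[0] if model.strand == "+" else first[1] - 1


def _common_codon_prefix(seqs: Sequence[str]) -> str:
    n_codons = min(len(s) // 3 for s in seqs)
    keep = 0
    for i in range(n_codons):
        codon = seqs[0][3 * i : 3 * i + 3]
        if all(s[3 * i : 3 * i + 3] == codon for s in seqs[1:]):
            keep = i + 1
        else:
            break
    return seqs[0][: 3 * keep]


def select_orfs(
    models: Iterable[GeneModel],
    genome: Mapping[str, str],
) -> SelectionResult:
    """Apply the isoform and mitochondrial filters and extract each kept CDS."""
    orfs: dict[str, SelectedORF] = {}
    rows = []
    counts: Counter = Counter()

    def record(gene_id, decision, reason):
        counts[decision] += 1
        rows.append({"gene_id": gene_id, "decision": decision, "reason": reason})

    for model in models:
        if not model.isoforms:
            logger.warning("%s has no isoforms; dropped", model.gene_id)
            record(model.gene_id, "dropped_no_isoform", "gene has zero isoforms")
            continue
        if model.is_mitochondrial:
            record(model.gene_id, "dropped_mitochondrial", f"on {model.chromosome}")
            continue
        if len(model.isoforms) == 1:
            seq = extract_spliced_cds(model, genome, model.isoforms[0].transcript_id)
            decision, reason = "kept_unique_isoform", "single isoform"
        else:
            starts = {_start_codon_position(model, iso) for iso in model.isoforms}
            if len(starts) > 1:
                record(model.gene_id, "rejected_start_mismatch",
                       f"{len(starts)} distinct start positions")
                continue
            seqs = [extract_spliced_cds(model, genome, iso.transcript_id)
                    for iso in model.isoforms]
            seq = _common_codon_prefix(seqs)
            if all(s == seqs[0] for s in seqs):
                decision, reason = "kept_identical_isoforms", "isoform CDSs identical"
            else:
                decision, reason = (
                    "kept_common_prefix",
                    f"truncated to {len(seq) // 3} common codons of {len(model.isoforms)} isoforms",
                )
        if not seq:
            record(model.gene_id, "dropped_empty_cds", "no common coding sequence")
            continue
        if not seq.startswith("ATG"):
            logger.warning("%s: CDS starts with %s, not ATG", model.gene_id, seq[:3])
        orfs[model.gene_id] = SelectedORF(model.gene_id, seq)
        record(model.gene_id, decision, reason)

    decisions = pd.DataFrame(rows, columns=["gene_id", "decision", "reason"])
    return SelectionResult(orfs, decisions, counts)


# ---------------------------------------------------------------------------
# annotation / sequence I/O


def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_models(
    gff_path,
    mito_names: Iterable[str] = DEFAULT_MITO_NAMES,
) -> list[GeneModel]:
    """Read GFF3 or GTF into gene models (CDS features grouped by transcript).

    Transcript linkage uses ``Parent`` (GFF3) or ``transcript_id`` (GTF);
    gene linkage uses the parent gene feature or the ``gene_id`` attribute.
    """
    mito = {m.lower() for m in mito_names}
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    # transcript_id -> (gene_id, chrom, strand, [segments])
    by_tx: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        attrs = cds.attributes
        if "Parent" in attrs:
            tx_ids = list(attrs["Parent"])
        elif "transcript_id" in attrs:
            tx_ids = [attrs["transcript_id"][0]]
        else:
            raise ValueError(f"CDS at {cds.seqid}:{cds.start} lacks Parent/transcript_id")
        if "gene_id" in attrs:
            gene_id = attrs["gene_id"][0]
        else:
            parents = list(db.parents(cds, featuretype="gene"))
            if not parents:  # fall back to the transcript's Parent attribute
                tx = db[tx_ids[0]]
                gene_id = tx.attributes.get("Parent", [tx_ids[0]])[0]
            else:
                gene_id = parents[0].id
        seg = (cds.start - 1, cds.end)  # to 0-based half-open
        for tx_id in tx_ids:
            entry = by_tx.setdefault(
                tx_id, {"gene": gene_id, "chrom": cds.seqid, "strand": cds.strand, "segs": []}
            )
            entry["segs"].append(seg)

    by_gene: dict[str, dict] = {}
    for tx_id, entry in by_tx.items():
        segs = sorted(entry["segs"], reverse=(entry["strand"] == "-"))
        iso = Isoform(tx_id, tuple(segs))
        g = by_gene.setdefault(
            entry["gene"], {"chrom": entry["chrom"], "strand": entry["strand"], "isos": []}
        )
        g["isos"].append(iso)

    return [
        GeneModel(
            gene_id,
            g["chrom"],
            g["strand"],
            tuple(sorted(g["isos"], key=lambda i: i.transcript_id)),
            is_mitochondrial=g["chrom"].lower() in mito,
        )
        for gene_id, g in sorted(by_gene.items())
    ]


def write_orf_fasta(orfs: Mapping[str, SelectedORF] | Iterable[SelectedORF], path) -> None:
    if isinstance(orfs, Mapping):
        orfs = orfs.values()
    records = [
        SeqRecord(Seq(o.cds_sequence), id=o.gene_id, description="") for o in orfs
    ]
    SeqIO.write(records, str(path), "fasta")


def write_decision_log(result: SelectionResult, path) -> None:
    result.decisions.to_csv(path, sep="\t", index=False)
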