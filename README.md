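# ribocub

Codon usage bias (CUB) measured directly from ribosome profiling.

Synonymous codons are not used equally: in most genomes, highly expressed
genes favour a subset of "preferred" codons, largely those matching the most
abundant tRNAs. The classical way to quantify this — Sharp's relative
synonymous codon usage (RSCU) computed on a curated set of highly expressed
genes — needs functional annotation or statistical clustering, which limits it
to well-studied species. `ribocub` instead ranks genes by how heavily they are
translated, observed directly as ribosome-footprint (Ribo-seq) coverage, and
computes RSCU within translation-defined gene groups. This works for any
species with a Ribo-seq dataset, including mammals.

## Method

For each amino acid *i* with *n<sub>i</sub>* synonymous codons and codon
counts *x<sub>ij</sub>*,

&nbsp;&nbsp;&nbsp;&nbsp;RSCU<sub>ij</sub> = *n<sub>i</sub>* · *x<sub>ij</sub>* / Σ<sub>j</sub> *x<sub>ij</sub>*

so RSCU = 1 means unbiased usage and RSCU = *n<sub>i</sub>* exclusive use.
Only the 59 codons of the 18 amino acids with a synonymous choice are used
(ATG, TGG and the stop codons are excluded). The pipeline:

1. **ORF selection** — keep genes with an unambiguous start codon
   (single-isoform genes; multi-isoform genes sharing a start are truncated to
   the longest common codon prefix; mitochondrial genes excluded).
2. **P-site assignment** — aggregate footprint 5' ends around start codons;
   the majority peak (canonically −12 nt) gives the shift from 5' end to the
   ribosomal P-site.
3. **Coverage and grouping** — count P-sites per gene in codons 20–200 (at
   least 20 codons clear of the stop), drop genes with < 10 footprints, rank
   by mean coverage, and split into lowly (ltg) and highly (htg) translated
   groups holding equal total footprint mass; 5% of genes on each side of the
   boundary are excluded to sharpen the contrast.
4. **RSCU per group** — count codons in the same window within each group;
   the Euclidean distance between the two 59-codon RSCU vectors measures the
   intensity of CUB, and the most-used codon per amino acid in the htg group
   is the species' preferred codon.

A comparative layer relates preferred codons to tRNA gene copy numbers
(strict Watson–Crick cognates), regresses counts of codons lacking tRNA on
tRNA pool size, clusters species by UPGMA on Canberra distances, and computes
GC statistics. A synthetic-data module generates transcriptomes, footprints
and tRNA pools with known ground truth.

## Worked example

```python
import ribocub as rc

config = rc.SimulationConfig(n_genes=300, n_footprints=200_000, seed=1)
orfs, truth = rc.simulate_transcriptome(config)
records = rc.simulate_footprints(orfs, truth, config)

analysis = rc.run_rscu_analysis(orfs, records)
print("P-site shift:", analysis.offset.shift, "nt")
print("genes in low/high group:",
      len(analysis.assignment.genes("low")), len(analysis.assignment.genes("high")))
print("htg-ltg RSCU distance:", round(analysis.htg_ltg_distance, 2))
```

prints

```
P-site shift: 12 nt
genes in low/high group: 259 16
htg-ltg RSCU distance: 5.28
```

The detected shift equals the simulated footprint geometry (12 nt). The
equal-footprint-mass split makes the highly translated group small (16 genes
carry as many footprints as the other 259) — exactly the strongly translated
minority in which codon bias is sharpest. The distance of 5.28 between the
group RSCU vectors reflects the simulated bias (preferred-codon probability
0.8 in high-expression genes vs uniform in low ones); an unbiased simulation
gives ≈ 1.1, pure sampling noise. Asking for the preferred codons,

```python
called = rc.preferred_codon_map(analysis.preferred["high"])
agree = sum(called[aa] == c for aa, c in truth.preferred.items())
print("preferred codons recovered:", agree, "of 18")   # → 18 of 18
print("GCG RSCU high:", round(analysis.rscu["high"].values["GCG"], 2),
      "low:", round(analysis.rscu["low"].values["GCG"], 2))  # → 2.97 / 2.05
```

recovers every designated preferred codon; the generator's preferred alanine
codon GCG has RSCU 2.97 in the htg group (3.2 would be exclusive-use 0.8 of a
4-fold amino acid) versus 2.05 in the ltg group, which still contains
mid-expression genes.

The same stages are available from the shell:

```sh
ribocub simulate --out-dir sim --seed 1
ribocub select-orfs --fasta sim/genome.fasta --gff sim/annotation.gff3 \
    --out-fasta orfs.fasta --out-log decisions.tsv
ribocub psite --aln sim/footprints.tsv --orfs orfs.fasta --out run
ribocub rscu  --aln sim/footprints.tsv --orfs orfs.fasta --out rscu.tsv
ribocub compare --rscu-tsv rscu.tsv --trna sim/trna.tsv --species sim --out summary.tsv
```

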