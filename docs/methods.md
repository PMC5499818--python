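# Methods

## The measure

Relative synonymous codon usage for codon *j* of amino acid *i* is
RSCU<sub>ij</sub> = n<sub>i</sub> · x<sub>ij</sub> / Σ<sub>j</sub> x<sub>ij</sub>,
where n<sub>i</sub> is the degeneracy of the amino acid and x<sub>ij</sub> the
codon count in a set of coding sequences. The analysis alphabet is the 59
codons of the 18 degenerate amino acids: stop codons, ATG and TGG carry no
synonymous choice and are excluded. Amino acids with zero total count in a
table yield no RSCU values and are reported as undefined; distances between
RSCU vectors are taken over the codons defined in both.

The package's premise is that ribosome footprint density identifies the
highly translated genes that classical RSCU studies had to curate by hand.
Codon counting and coverage ranking use the same codon window, so the bias is
measured exactly on the sequence region whose translation was quantified.

Codon frequency used in heat-map-style outputs is RSCU / n<sub>i</sub>, the
relative synonym frequency in [0, 1] (per amino acid these sum to 1). This is
the only normalization consistent with a bounded range.

## Pipeline parameters

| parameter | default | unit | why |
|---|---|---|---|
| codon window | [20, 200] | codons, 1-based inclusive | the lower bound skips the initiation pile-up; the upper bound keeps shorter mRNAs comparable while providing enough counts |
| stop margin | 20 | codons | keeps the window clear of termination effects; the effective window of a gene with L codons (stop included) is [20, min(200, L−20)] |
| minimum footprints | 10 | footprints per gene window | genes below this cannot be ranked reliably |
| P-site shift | detected, fallback 12 | nt | argmax of the metagene profile within [−18, −6], ties broken toward −12, the canonical elongating-ribosome geometry |
| boundary exclusion | 5% | of each group's gene count, ceil-rounded | removes genes adjacent to the mass split whose group membership is least certain |

The group split equalizes total footprint mass, not gene count: genes are
sorted by mean windowed coverage and the lowly translated group is the
smallest prefix whose cumulative footprint count reaches half the total (the
boundary gene goes to the low group; the subsequent exclusion removes it in
typical sizes). With heavy-tailed expression this leaves a small, strongly
translated high group — the population in which selection on codon choice is
concentrated. Mean coverage is footprints per codon of the effective window;
any fixed positive rescaling would leave the ranking, and hence the result,
unchanged.

Preferred codons are per-amino-acid count argmaxes in the highly translated
group; ties are broken lexicographically and flagged, so calls are
deterministic.

## ORF selection

Only genes whose start codon is unambiguous enter the analysis: unique-isoform
genes whole; multi-isoform genes rejected when isoform start positions differ
(compared as strand-aware genomic coordinates); otherwise truncated to the
longest common codon prefix of the spliced CDS sequences — the shared start
anchors the frame, and a prefix is the only reading that preserves codon
indices across isoforms. Mitochondrial genes are excluded by chromosome name
(default MT/chrM/chrMT/mito, case-insensitive), since the organellar code and
tRNA pool differ. GFF3/GTF coordinates are 1-based inclusive and converted to
0-based half-open internally.

## Comparative layer

tRNA gene copy number is used as the proxy for tRNA abundance. Cognate
pairing is strict Watson–Crick (the cognate anticodon is the codon's reverse
complement); wobble decoding is deliberately not modelled, which is what makes
"codons lacking tRNA" well defined. A preferred codon is concordant with the
pool when its cognate copy count ties or exceeds every synonym's; under an
empty pool all counts tie at zero, so all 18 amino acids count as concordant
and as lacking — a documented degenerate case rather than an error.

Species clustering uses Canberra distance (scale-sensitive, 0/0 terms
contribute 0; delegated to scipy) and a hand-implemented UPGMA: node height is
half the merge distance, distances to a merged cluster are size-weighted
means, and distance ties are broken by the smallest pair of cluster labels
(a cluster is labelled by its smallest leaf). The hand implementation exists
because the tie rule and exact node heights are part of the contract; scipy's
average-linkage serves as an independent cross-check in the tests. Trees are
ultrametric by construction and serialized as Newick with 12-significant-digit
branch lengths so round-trips are lossless at double precision.

Regressions of codon-lacking counts on pool size are ordinary least squares
(scipy); the conventional outlier species (a mammal-adapted pathogen whose
CUB does not track its own tRNA pool) is excluded by name. On the bundled
nine-species reference table the slope for all codons lacking tRNA is
−0.026642 and for preferred codons lacking tRNA −0.0020; both are recomputed,
never stored. GC statistics are genome GC% over A/C/G/T and the percentage of
the 18 preferred codons ending in G or C.

## Synthetic data

The generator emulates the data structures the pipeline consumes, with every
latent variable recorded:

* **Expression** — log-normal (σ = 1.5), a realistic heavy tail: the top half
  of genes by expression receives most footprints.
* **Codon bias** — each degenerate amino acid has a designated preferred
  codon drawn at random; high-expression genes use it with probability
  π<sub>h</sub> (default 0.8), low-expression genes with π<sub>l</sub>
  (default uniform, 1/n<sub>i</sub>); remaining mass is uniform over the other
  synonyms. A π below 1/n<sub>i</sub> is clamped to 1/n<sub>i</sub> so one
  scalar applies across degeneracies. Bias is attached to expression halves
  rather than a continuum, which keeps the ground-truth group RSCU analytic.
* **Footprints** — genes draw footprint counts multinomially in proportion to
  expression (200 000 total by default, a mid-size experiment); P-sites are
  uniform over sense codons except an initiation peak (10% of mass) on codons
  1–5, decaying from codon 1 so the metagene keeps a single majority peak;
  5' end = P-site − offset (default 12 nt); read lengths uniform on 27–31 nt.
* **Layout** — ORFs of 100–500 codons starting with ATG and ending with a
  stop; for annotation-level tests the genes are laid on a synthetic
  chromosome with alternating strands and a third of genes split by an
  intron.

What the generator does **not** model: codon-specific dwell times and pausing,
sequencing error, rRNA contamination, nucleotide composition gradients along
genes, and isoform-level expression mixtures. Passing tests therefore show
that the pipeline recovers a bias of the assumed two-regime form from
realistic coverage levels — not that any particular real genome satisfies
those assumptions.

## Numerical and design choices

* RSCU is computed from each group's sequences with each gene counted once,
  not footprint-weighted: the footprints decide membership, the sequences
  decide usage.
* Codons containing non-ACGT characters are skipped with a warning rather
  than failing a whole gene.
* Secondary and supplementary alignments are ignored to avoid double
  counting; read length is not filtered by default (a configurable filter is
  available at the TSV level by preprocessing).
* All stochastic tests and the acceptance script derive their generators from
  explicit seeds; simulation sizes (300 genes × 200 000 footprints, five
  seeds) were chosen as the smallest scale at which group contamination and
  sampling noise are clearly dominated by the simulated effect.
* Grouping requires ≥ 4 genes; regression requires ≥ 3 points and non-zero
  x-variance; empty metagene profiles fall back to the canonical shift of 12
  with a warning instead of failing.

## Known limitations

* The equal-mass split leaves the lowly translated group containing
  mid-expression genes; its RSCU is therefore a mixture and the htg–ltg
  distance is a conservative estimate of the extreme-group contrast.
* Strict-cognate accounting overstates "codons lacking tRNA" for species
  relying heavily on wobble; this is intentional and documented above.
* Footprint alignment itself (adapter trimming, mapping, rRNA filtering) is
  out of scope: inputs are transcript-space alignments or position tables.
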