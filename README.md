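# itrscan

Genome analysis of *Hsmar1* inverted terminal repeats (ITRs) and their
recognition by the human SETMAR (Metnase) fusion protein.

SETMAR arose from the fusion of a SET histone-methyltransferase domain to an
*Hsmar1* mariner transposase, and its DNA-binding domain still recognises the
19-nt ITR core motif `5'-GGTGCAAAAGTAATTGCGG-3'` scattered in thousands of
copies across the human genome — as miniature inverted-repeat transposable
elements (MITEs, two ITRs a short distance apart) and as solo ITRs.  Because
these relics drift neutrally, the genome contains a natural mutagenesis
experiment: ITR copies at 0, 1, 2 or 3 substitutions from the consensus can
be compared for SETMAR binding (ChIP signal) and for the expression of the
genes they sit in.

`itrscan` implements that analysis end to end as a tested Python library
with a CLI, a set of numbered analysis drivers, and a synthetic-data
generator with planted ground truth so the whole pipeline runs and is
validated without any downloads.

## What it computes

- **Degenerate motif scan** (`genome_scan`): both strands of a FASTA genome
  are scanned for every window *w* with Hamming distance
  *d(w, m) ≤ k* to the motif *m* (default *k* = 3).  Windows containing `N`
  are skipped; overlapping raw matches are resolved greedily (lowest
  mismatch count, then `+` strand, then leftmost).  Hits carry a per-position
  mismatch profile in 1-based motif coordinates (e.g. `17:C>T`).  The
  vectorized scanner is verified against a naive all-window oracle.
- **Element classification** (`element_annotation`): two hits with inner gap
  ≤ 500 bp form a MITE; everything else is a solo ITR (sITR); lengths and
  per-group solo counts are summarised.
- **Peak analysis** (`peak_analysis`): ChIP peaks extended ±500 bp are
  intersected with ITRs (Venn counts); summits are annotated with a fixed
  priority TSS > TTS > exon > intron > intergenic; enrichment per category is
  tested against seeded, blacklist-excluding randomized peak sets with the
  pooled two-proportion z test

  z = (p̂₁ − p̂₂) / √( p̂(1−p̂)(1/n₁ + 1/n₂) ),  p̂ = (x₁+x₂)/(n₁+n₂),

  whose square equals the 2×2 χ² statistic without continuity correction.
  Per-chromosome ITR and peak counts are correlated with chromosome length
  (Spearman ρ).
- **Affinity analysis** (`affinity_analysis`): binding affinity per locus is
  the length-weighted mean bedGraph signal over the 19-bp hit; groups
  0MM–3MM are compared to each other and to a random genomic background
  ("Total") with a Wilcoxon rank-sum test (exact enumeration for n₁+n₂ ≤ 12,
  tie- and continuity-corrected normal approximation otherwise).  The
  single-substitution analysis groups 1MM solo ITRs by (position, change),
  drops groups below 2% frequency, and reports median score, fold change
  versus the 0MM solo median, and rank-sum p.
- **Expression analysis** (`expression_analysis`): genes are associated with
  ITRs over TSS-window ∪ exons ∪ introns ∪ TTS-window, stratified by their
  minimum ITR mismatch count, and each group's FPKM distribution is compared
  to a seeded random group of non-associated genes.
- **Synthetic data** (`synthetic_data`): a seeded generator plants solo ITRs
  with exact mismatch counts, inverted-repeat pairs, a blacklist, peaks
  preferentially on high-fidelity ITRs, a signal of amplitude S₀·f^mm plus
  Gaussian noise, and log-normal FPKM with a per-group repression shift —
  all recorded in a truth table.

## Worked example

```
python analysis/01_simulate.py            # default conditions, seed 0
python analysis/02_scan_itrs.py
python analysis/03_classify_elements.py
```

prints

```
planted ITR loci: 500 (solo groups (20, 30, 25, 25), 200 MITE pairs)
accidental background motif matches: 0
...
hits: 500 -> {'0MM': 420, '1MM': 30, '2MM': 25, '3MM': 25}
truth recovery: exact
...
500 hits -> 200 MITEs + 100 solo ITRs
median MITE length: 91.5 bp
solo ITRs by group: {'0MM': 20, '1MM': 30, '2MM': 25, '3MM': 25}
```

i.e. the scanner recovers every planted locus (the 420 perfect copies are
the 20 planted 0MM solos plus 2×200 MITE arms), pairing reconstructs exactly
the 200 planted MITEs, and the median element length follows the planted
inner-gap distribution.  `analysis/04–06` then run the enrichment, affinity
and expression stages; on the same dataset the ITR category is enriched
4.4-fold over the randomized null (z = 36.8), group 0MM has a median ChIP
score of 101.2 against a genomic background of 0.5, and the high-fidelity
gene group MM0 is repressed relative to random genes (median FPKM 1.5 vs
3.1, rank-sum p = 0.02 at n = 15).

The same operations run from the CLI on your own files:

```
itrscan scan --genome hg38.fa --max-mismatch 3 --out itrs.bed
itrscan classify --itrs itrs.bed --out elements.bed
itrscan enrich --peaks peaks.narrowPeak --itrs itrs.bed --genes genes.gtf \
    --blacklist blacklist.bed --chrom-sizes chrom.sizes --seed 11 --out enrich.json
itrscan affinity --signal chip.bedgraph --itrs itrs.bed \
    --chrom-sizes chrom.sizes --seed 5 --out affinity.json
itrscan expression --genes genes.gtf --fpkm fpkm.tsv --itrs itrs.bed \
    --random-n 304 --seed 21 --out expression.json
```

`analysis/07_hg38_reproduction.py --genome <path to hg38.fa>` recomputes the
genome-only statistics (total and per-group hit counts, MITE count and
median length, solo counts, 1MM substitution spectrum) on a locally
available human assembly, both with and without alt/unplaced scaffolds.

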