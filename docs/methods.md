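# Methods

## Motif scanning

The query is the 19-nt *Hsmar1* ITR core `GGTGCAAAAGTAATTGCGG`; a hit is any
genomic window on either strand within `max_mismatch` (default 3)
substitutions of it.  Coordinates are 0-based half-open everywhere except
mismatch positions inside the motif, which are 1-based in motif 5'→3'
orientation so a change at the 17th base of the consensus reads `17:C>T`
regardless of genomic strand.

Numerical/algorithmic choices:

- The production scanner is vectorized (one numpy comparison per motif
  position per strand, ~40 array operations per chromosome).  A naive
  all-window scanner with early-exit Hamming counting ships in the package
  (`scan_motif_naive`) and is the ground-truth oracle in the tests; the two
  paths share only the overlap-resolution step, which is a declared rule,
  not a search.
- Windows containing `N` are never hits: an ambiguous base can be claimed
  neither identical nor mismatched.  Soft-masked lowercase bases are
  uppercased and scanned normally — degenerate relic copies are exactly what
  repeat maskers hide.
- Overlapping raw matches are resolved greedily so each locus is annotated
  once: lowest mismatch count first, then `+` strand over `−` (a palindromic
  window matching both strands keeps the lower-mismatch orientation), then
  the leftmost start.  Resolution is per chromosome and deterministic, so
  identical inputs give byte-identical output.
- Indels, PWM scoring and repeat masking are out of scope.

## Element classification

Two hits on one chromosome with inner gap (downstream start − upstream end)
≤ `max_gap` = 500 bp form a MITE; the element length is the outer span.
Everything unpaired is a solo ITR.  The gap is measured on the *inner*
sequence because the elements are miniature (median well under 100 bp);
bounding the outer span instead would make the threshold depend on motif
length.  Pairing is greedy left-to-right — each unpaired hit takes its
nearest eligible downstream neighbour — which is deterministic and
order-independent for a fixed hit set; chains of ≥3 nearby hits therefore
resolve first-come.  Inverted (+/−) orientation is *not* required by
default, since the operational definition of a MITE here is purely
distance-based; `require_inverted=True` (CLI `--require-inverted`) enables
the stricter rule.

## Peak analysis

- Peaks are extended ±500 bp (clipped at chromosome ends) before
  intersection; overlap means ≥1 bp of half-open intersection.
- Summit annotation uses a fixed priority TSS > TTS > exon > intron >
  intergenic with strand-aware windows TSS = [TSS−1000, TSS+100] and
  TTS = [TTS−100, TTS+1000] (configurable).  Priorities make the category
  total and independent of gene input order.
- The null model re-places each peak uniformly over the blacklist
  complement, preserving per-chromosome counts and exact lengths.  Placement
  is rejection-free: for every (chromosome, length) the allowed starts form
  a cumulative table over blacklist-complement gaps, and one uniform integer
  indexes into it.  A peak longer than every gap raises an error naming the
  length.  The RNG is numpy's default PCG64 generator seeded explicitly;
  the generator name and seed are recorded in the CLI report.
- Enrichment per category: observed proportion vs the pooled proportion over
  all `n_sets` (default 100) randomized sets, pooled two-proportion z test,
  two-sided normal p.  Identical proportions give z = 0, p = 1; z² equals
  the 2×2 χ² without continuity correction (asserted in tests).  Categories
  are tested independently and no multiple-testing correction is applied —
  raw p values are reported with α = 0.05 left to the reader.
- Whether one or many randomized sets form the expectation is configurable
  (`n_sets`); the expected count reported is the per-set mean.

## Affinity analysis

"Affinity" is operationalized as the length-weighted mean of the
piecewise-constant coverage track over the 19-bp hit itself (not the
extended peak), with uncovered bases contributing zero.  Means come from a
cumulative integral over the sorted intervals, so each query is O(log n) and
matches a per-base summation oracle to 1e-9.

The genomic background ("Total") is 10,000 seeded random motif-length
intervals excluding hit loci and the blacklist (size configurable).

The rank-sum test enumerates all C(n₁+n₂, n₁) rank assignments (average
ranks for ties) when n₁+n₂ ≤ 12 and counts assignments at least as far from
the null mean as observed; above that it uses the normal approximation with
the standard tie correction and a 0.5 continuity correction, which matches
scipy's asymptotic Mann-Whitney p to ~1e-9 (scipy is the independent
cross-check in the tests, never the implementation).  The two branches agree
within |Δp| ≤ 0.05 at the boundary.

Single-substitution analysis: 1MM solo ITRs are grouped by (position,
from-base, to-base); group frequency is a percentage of all 1MM solos and
groups strictly below 2% are excluded; the effect size is the fold change
(0MM solo median)/(group median) — medians because the score distributions
are heavy-tailed — with a rank-sum p against the 0MM solo scores.  With no
0MM solos there is no reference group and the analysis raises.

## Expression analysis

A gene is associated with an ITR when the hit interval intersects the union
of its TSS window, exons, introns and TTS window (one contiguous span);
association by peak summit is available as an alternative
(`associate_genes_by_peaks`) since binding evidence can be framed either
way — the default and documented mode is by hit position.  Genes take the
*minimum* mismatch count among their ITRs.  The comparison group is a seeded
sample of non-associated genes, size defaulting to the total of the MM
groups, drawn either from all genes or from expressed (FPKM > 0) genes —
both modes exist because which pool a "random gene group" should come from
is a genuine free choice.  Genes missing from the expression table are
dropped and counted.  Duplicate gene ids in the expression table keep the
maximum FPKM.

## Synthetic data

The generator's defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| chrom_lengths | 1.0 / 0.8 / 0.6 Mb | three-chromosome uniform-random genome |
| solo_counts | (20, 30, 25, 25) | planted solo ITRs per mismatch group |
| mite_pairs | 200 | planted exact inverted-repeat pairs |
| mite_gap_range | 20–80 bp | inner gap, uniform |
| element_spacing | 2500 bp | min distance between planted elements |
| blacklist_fraction | 0.05 | of each chromosome, in 2-kb chunks |
| peak_fraction | (0.9, 0.6, 0.4, 0.2) | chance an ITR of each group is peaked |
| s0, decay, noise_sigma | 100, 0.5, 5 | signal amplitude S₀·f^mm + N(0, σ) |
| gene_fraction | 0.7 | chance a planted solo carries a gene |
| log_mu, log_sigma | 1, 1 | log-normal FPKM of null genes |
| expression_shift | (−1, −0.5, −0.25, 0) | log-mean shift per gene group |

A solo of group k is the motif with exactly k substitutions at distinct
random positions, inserted on a random strand; a MITE is motif + random gap
+ reverse-complemented motif (both arms exact).  The 2.5-kb element spacing
guarantees planted solos stay solo, MITE arms pair only with each other, and
gene-association windows (±1.1 kb) never reach a neighbouring element.  One
master seed drives three derived child streams (genome, ChIP, expression) so
each artifact can be regenerated independently.

Uniform background sequence can still contain accidental matches (expected
≈ 2 · L · 2.8e-11 · 4³ per strand; about 0.1 per 2.4-Mb genome).  These are
not suppressed: after assembly the genome is rescanned and any non-planted
hit is appended to the truth table with `source="background"`, so truth is
defined by enumeration rather than assumption.  Scanner correctness itself
is established against the naive oracle on independent random genomes, so
using the vectorized scanner for this enumeration at full scale does not
close a loop the tests rely on.

With `noise_sigma = 0` the signal track is exact (mean over a peaked k-MM
ITR is precisely S₀·f^k), which the tests assert.

What the generator does *not* emulate: non-uniform base composition and
repeat structure of real genomes, read-level noise, GC/chromatin-matched
nulls, fragment-size smoothing of real coverage, multi-transcript gene
models, and the spatial clustering of real ITRs inside larger repeats.
Passing tests therefore demonstrate that the *inference machinery* recovers
planted structure and is calibrated under its null — not that real-genome
estimates are unbiased under mapping artifacts.

## Test and reproduction problem sizes

Oracle-equivalence checks run on twenty 50-kb random genomes plus
property-based small genomes; the fidelity-affinity monotonicity check uses
100 signal replicates over 100 ITRs per group on a 1.6-Mb genome; the null
calibration uses 200 seeds with 300 observed peaks × 10 randomized sets per
seed and a 120-gene random expression group, with p-value uniformity
assessed by a Kolmogorov-Smirnov test.  These sizes keep the full suite
under a minute while leaving the statistical assertions well-powered.

## Known limitations

- The greedy overlap resolution and greedy pairing are declared conventions;
  other conventions (e.g. keeping the `−` orientation on ties) would shift
  counts by a handful of loci on real genomes.
- The two-proportion z test treats randomized peaks as independent draws;
  for very small peak sets an exact binomial comparison would be preferable.
- Absolute affinity values depend on the upstream coverage normalization
  (bin size, smoothing); only relative and ordinal statements are
  meaningful, which is why group comparisons use ranks and medians.
- The hg38 reproduction driver requires a user-supplied local assembly and
  reports counts with and without alt/unplaced scaffolds, because degenerate
  match totals depend on that choice.
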