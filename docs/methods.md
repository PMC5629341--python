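# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open intervals. File I/O speaks
each format's native convention (SAM and GFF3 1-based inclusive,
BED/bedGraph 0-based half-open); conversion is `internal = external − 1`
for starts, and interval length is `end − start` in both systems.

## Detection model

The detector targets a single LTR retrotransposon family described by a
consensus sequence whose first and last `ltr_len` bases are identical (the
defining property of an LTR element). It assumes paired-end reads aligned
to a reference in which every resident copy of the element has been
hard-masked to `N`. Masking is what converts element-derived reads into
evidence: a mate sampled from inside any element copy — old or new — cannot
map, and is either recovered as a discordant partner (its mate maps
uniquely nearby) or as a junction read (it straddles the host/element
boundary).

Junction resolution relies on the geometry of integration. With an
insertion point *p* and TSD length *t*, the mutated chromosome is
`ref[0:p+t] + element + ref[p:]`: the upstream flank ends at reference
coordinate *p + t*, the downstream flank begins at *p*. Remapped junction
fragments from the two sides therefore disagree by exactly *t*, and the
call interval `[p, p+t)` *is* the TSD, whose sequence is lifted from the
reference. TSD length is never assumed; the configurable simulator default
(5 bp) reflects the canonical Ty1/copia integrase footprint.

Element orientation follows from which LTR extremity faces each genomic
side (element 5′ end facing the upstream flank means a forward insertion),
voted across junction reads.

### LTR matching

`match_to_ltr` is an ungapped seed-and-extend local aligner: exact 14-mers
sampled every 7 bp from the read are looked up in an index of the LTR and
its reverse complement, and each candidate diagonal is scanned by 1-D
Smith–Waterman (match +1, mismatch −3). A match qualifies at ≥ 25 bp and
≥ 0.9 identity. Because the two LTRs are byte-identical, matching is
against a single LTR sequence. For junction trimming the match must reach
the element's outer end (2 bp slack for terminal sequencing errors);
internal LTR matches are not junctions. The seed design guarantees
detection of any error-free qualifying match; a match fragmented by
mismatches into runs all shorter than 21 bp can be missed, which at the
error rates the pipeline targets (≲ 0.5%) loses only a small fraction of
junction reads — support counting absorbs this.

### Fragment remapping and ambiguity

Trimmed genomic fragments (≥ 20 bp) are placed by exact substring search on
both strands of the unmasked reference; only unique placements become
evidence, and fragments with zero (sequencing error) or multiple
(repetitive origin) hits are discarded and counted. A one-mismatch-tolerant
mode (pigeonhole split search) is available via
`DetectionParams.remap_max_mismatches`. Exact search was chosen over scored
local alignment because at desk scale it is deterministic and sufficient;
it is the one component that would need replacing for error-rich real data.

### Clustering and calling

Evidence positions (junction points, or the insertion-facing end of a
discordant anchor) are single-linkage clustered within `cluster_window`
(default 500 bp ≈ insert mean + 3 SD). Within a cluster, junction points
are sub-clustered at `max_tsd` (20 bp) linkage so that two insertions close
enough for their read evidence to chain — anything nearer than about one
insert size — still resolve into separate calls; each discordant pair
supports its nearest sub-cluster. Consensus junction points are medians,
which makes calls robust to a single mis-remapped fragment. Status
assignment order: `preexisting` (within `cluster_window` of a resident-copy
interval or a masked N-run), `control_shared` (within `cluster_window` of a
control-genotype call), `low_support` (fewer than 2 discordant pairs or no
junction read), else `novel`.

All numeric thresholds in `DetectionParams` are declared package defaults —
the decisions they stand in for were made by manual curation in the
original analytical setting and are not recoverable — and all are exposed
on the CLI. Defaults were chosen so that the synthetic recall/precision
guarantees hold with margin at 30× coverage.

## Synthetic data: what it emulates, and what not

The generator reproduces the *signatures* the detector and statistics
consume: a multi-chromosome genome with one central heterochromatin block
per chromosome, stranded multi-exon gene models with UTRs tiling
euchromatin, resident element copies (two-thirds heterochromatic, written
into the reference), planted insertions with canonical TSDs and a
configurable genic bias (default 0.9, matching the observed ~90% genic
targeting), 75-bp paired-end fragments at configurable coverage
(default 30×) with substitution errors (default 0.002), an H3K9me2-like
two-level tile track (high 3.0 / low 0.5, SD 0.3), and negative-binomial
count tables in which insertion-linked genes gain a heat-condition fold
change (default 8).

Mates are reported mapped only when their fragment lies wholly inside a
reference-derived segment clear of masked intervals; reads touching a
junction, the inserted element, or a masked region are emitted unmapped
with their sequence. This is the contract a single-best-alignment mapper
produces on these data, generated constructively instead of by re-aligning.
Consequences to keep in mind when extrapolating to real data: no indels, no
base-quality structure, no PCR duplicates, no soft-clipped partial
mappings, uniform coverage, and a random (repeat-free) genomic background —
uniqueness of 20-bp fragments is near-certain here but not in a real
genome. Passing tests demonstrate the algorithmic logic is correct under
the stated read model, not that the pipeline is robust to every real-data
artifact.

A FASTQ emitter (`write_fastq`) lets users push simulated reads through a
real aligner instead.

## Chromatin partition

Per-tile enrichment (60-bp tiles) is smoothed with a centered moving
average over 100 tiles (window truncated at chromosome ends; centering
avoids a systematic boundary shift, and the alignment is configurable).
Runs of smoothed values above 1.5 become heterochromatin; boundaries are
rounded half-up to the nearest 100 kb, collapsed intervals dropped, and the
complement is euchromatin — the two classes always form an exact disjoint
cover. "Above 1.5" is read as an absolute threshold on the smoothed signal;
the alternative reading (raw > 1.5 × local trend) is implemented as
`mode="ratio"` but is not the default, because the absolute reading is the
one consistent with a two-level enrichment track. Note the 100-kb rounding
floor means blocks much smaller than 100 kb can legitimately round away;
the simulation used for recovery checks uses ≥ 400-kb blocks.

## Permutation variance test

For each observed insertion, a random locus of the same length is drawn
uniformly in the euchromatin of the same chromosome (never crossing a class
boundary); 1-Mbp windows slide across each euchromatin segment at a 100-kb
step (the step is a package choice — it is not recoverable from the
analysis being reproduced — and `step = window` gives disjoint windows;
segments shorter than 1 Mbp count as single windows). The statistic is the
population variance of per-window counts; observed and permuted variances
use the same estimator, so the population-vs-sample choice cancels. Gamma
moment matching on the 1000 permuted variances (shape k = m²/v, scale
θ = v/m) yields the upper-tail p-value; the empirical tail proportion is
reported alongside, and is the fallback when the null degenerates. The
gamma tail is slightly conservative in the far tail but calibrated at
conventional levels: on uniform-insertion replicates the false-positive
rate at α = 0.05 sits within 0.02–0.08.

One geometry caveat: sliding windows are truncated at segment ends, so
loci near chromosome ends are covered by fewer windows. Clustering
*at a segment edge* is therefore partially invisible to the variance
statistic; the power guarantee is stated for clustering in the interior of
euchromatin.

## Positional classification

Precedence for a point with overlapping annotations: TE feature > gene body
(exon > 5′UTR > 3′UTR > intron, by containment) > promoter (distance
upstream of the nearest TSS on that gene's strand, <500 bp before
500–1000 bp) > intergenic. The order is a package decision; it is
configurable in the sense that each predicate is a separate function.
Category counts always sum to the number of insertions (the classification
is total and single-valued).

The gene-length-corrected χ² compares observed functional-class counts
among insertion-target genes with an expectation proportional to the summed
gene length per class — long genes present a larger target, and this is
one defensible operationalization of "correcting for gene length"; the
exact construction in the original analysis is not recoverable.

## Expression impact

Presence calling: strictly more than 5 CPM in at least 2 samples
(CPM = 1e6·count/column-sum). Activation: log2FC ≥ 1 at BH FDR < 0.05 from
a supplied DE table. The built-in fallback DE (used only when no table is
given, and by the synthetic end-to-end tests) is a pooled-replicate
two-sided binomial test with median-of-ratios size factors and BH
correction. Median-of-ratios normalization matters at desk scale: with only
~100 simulated genes, total-count scaling lets a minority of strongly
activated genes inflate the heat library and bias every fold change
downward. The fallback ignores biological dispersion and is
anti-conservative relative to a negative-binomial DE model — it closes the
synthetic loop, nothing more.

Target gene: span from 500 bp upstream of the TSS through the gene end
contains the insertion point (at most one target per insertion; nearest
promoter wins upstream ties). Adjacent genes: within 12 kb, the maximum
distance at which regulatory influence of a new insertion has been
observed. All summary fractions are reported with numerator and
denominator; empty denominators yield NaN, never a silent zero.

## Problem sizes and determinism

Test and acceptance simulations use 3 × 200-kb chromosomes, 30 planted
insertions, 30× coverage (10 + 10 seeds for recall/precision), 200
calibration and 100 power replicates at 1000 permutations each, and
2 × 1-Mb chromosomes for partition recovery — sizes chosen so the full
statistical battery runs on a laptop while keeping every guarantee a
property of the method rather than of one lucky seed. All randomness flows
through explicitly passed `numpy.random.Generator` objects; fixed seeds
give byte-identical genomes, reads and results.

## Known limitations

- Single element family per run; no genotyping of zygosity.
- Exact-match remapping limits junction recovery in error-rich or
  repeat-rich contexts (one-mismatch mode available).
- The chromatin partition consumes a precomputed enrichment track; it does
  not compute enrichment from ChIP reads.
- The fallback DE test is not a substitute for a dispersion-aware model.
- Text SAM only; BAM/CRAM and VCF emission are out of scope.
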