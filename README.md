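# ltrcall

Detection and chromosomal-landscape statistics of **new LTR retrotransposon
insertions** from paired-end whole-genome sequencing.

Heat stress can mobilize Ty1/copia-family LTR retrotransposons such as
*Onsen* (ATCOPIA78) in *Arabidopsis thaliana*, planting new element copies
across the genome of the progeny. `ltrcall` is for researchers who need to
(i) call those neo-insertions from short-read data, (ii) characterize where
they land — euchromatin vs heterochromatin, genes vs intergenic space — and
(iii) relate them to transcriptional changes in flanking genes. A
first-class synthetic-data generator makes every stage testable without any
sequencing download.

## Method

**Detection** combines two evidence classes against a *TE-masked* reference
(all resident element copies hard-masked to `N` so element-derived reads
cannot map to old copies):

1. *Discordant pairs* — one mate maps uniquely to a chromosome, the other is
   unmapped but matches the element's long terminal repeat (LTR).
2. *Junction reads* — unmapped reads whose prefix or suffix matches an LTR
   **extremity**; the element part is trimmed and the remaining genomic
   fragment is remapped exactly, placing the insertion breakpoint at base
   resolution.

Because integration duplicates a few bases of host sequence (the
target-site duplication, TSD), the 5′-side junction lies downstream of the
3′-side junction by exactly the TSD length; `ltrcall` infers the TSD from
this offset rather than assuming it. Evidence is clustered, and clusters are
labeled `novel`, `preexisting` (at a resident copy), `control_shared`
(recurring in a control genotype — background subtraction), or
`low_support`.

**Landscape statistics** mirror the analyses a population-genomic study of
insertion preference runs:

- insertions/Mbp per chromosome,
- euchromatin enrichment: Fisher's exact test on insertion counts vs class
  sizes in Mbp, where the chromatin classes come from H3K9me2 tile
  enrichment (moving average over 100 × 60-bp tiles, threshold 1.5,
  boundaries rounded to 100 kb),
- an eight-way positional classification (promoter 500–1000 bp,
  promoter <500 bp, 5′UTR, exon, intron, 3′UTR, intergenic >1000 bp, TE)
  with hypergeometric gene-space enrichment,
- a permutation test of window-count variance: *n* random loci matched to
  the observed insertions in chromosome and length are drawn uniformly in
  euchromatin, 1000 times; a gamma distribution is fitted to the permuted
  variances by moment matching (k = m²/v, θ = v/m) and the p-value is the
  upper gamma tail at the observed variance,
- a Kolmogorov–Smirnov comparison of insertion-to-gene distances and a
  gene-length-corrected χ² for functional-class enrichment.

**Expression impact** applies a presence-call filter (> 5 counts-per-million
in ≥ 2 replicates), classifies genes from a differential-expression table
(|log2FC| ≥ 1, BH FDR < 0.05), maps each insertion to its target gene and to
adjacent genes within 12 kb with sense/antisense orientation, and reports
activation fractions with explicit numerators and denominators.

## Worked example

Simulate a three-chromosome genome (200 kb each, central heterochromatin
blocks, nine resident element copies) with 12 planted insertions at 30×
coverage, then detect and characterize them:

```bash
ltrcall simulate --outdir sim --seed 7 --chromosomes 3 --chrom-length 200000 \
    --insertions 12 --coverage 30
ltrcall detect --sam sim/reads.sam --reference sim/reference.fa \
    --te sim/te.fa --te-gff sim/annotation.gff3 --out calls.tsv
ltrcall partition --track sim/h3k9me2.bedgraph --round 10000 \
    --chrom-sizes sim/chrom_sizes.tsv --out partition.bed
ltrcall stats --calls calls.tsv --annotation sim/annotation.gff3 \
    --partition partition.bed --chrom-sizes sim/chrom_sizes.tsv \
    --nperm 500 --seed 1 --out report.tsv
```

which prints

```
wrote synthetic dataset (12 planted insertions) to sim
30 calls (12 novel) -> calls.tsv
euchromatin 0.48 Mbp, heterochromatin 0.12 Mbp -> partition.bed
stats written to report.tsv
```

All 12 planted insertions come back as `novel` calls with the 5-bp TSD
resolved exactly, e.g.

```
chrom  start  end    orientation  tsd_len  n_discordant  n_junction5  n_junction3  status
chr1   31348  31353  -            5        93            7            14           novel
chr1   38513  38513  +            0        40            12           0            preexisting
...
```

The `preexisting` rows sit at the boundaries of the nine resident copies
(evidence accumulates there because element-derived reads cannot map to the
masked copies); only genuinely new sites are `novel`. The report ends with
the test block, here (12 genic insertions of 12, as planted with a 0.9
genic bias):

```
cumulative_genic  91.7  100.0  100.0
permutation_observed_variance  2.6667
permutation_gamma_shape  2.6040
permutation_gamma_scale  0.4398
permutation_p  0.03769
```

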