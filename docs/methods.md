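# Methods

This note documents the models and procedures implemented in `ermotifs`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Motif model and scanning

A motif is a letter probability matrix (LPM): L rows of per-position
nucleotide probabilities in A, C, G, T order, each row summing to 1. Before
scoring, an additive pseudocount (default 1e-4 per cell, rows renormalised)
removes zeros, and the matrix is converted to log-odds in bits against a
background distribution (default uniform 0.25; configurable — the original
scan's background model is not known, and uniform is the reproducible
choice). Scores of a sequence window are sums of per-position entries.

**Exact score distribution.** Per-position scores are rounded to a grid
(default granularity 0.001 bits) and the per-position (score, mass) pairs
convolved across positions — equivalent to enumerating all 4^L sequences
and accumulating their background probabilities, at O(L * support) cost.
The survival function is evaluated with half-grid tolerance so exact and
grid-rounded scores agree on which atoms they dominate. Unit and
acceptance tests verify the DP against full enumeration for L <= 8.

**The one-wobble threshold.** The scan cutoff is the score of the weakest
single-substitution variant of the consensus, where the substitution at
each position is the second-most-probable base ("wobble" base). Ties for
second place are broken toward the lower substituted score, which admits
every tied base. The pipeline scans at the exact (ungridded) wobble score
and reports its tail probability from the exact distribution; using the
exact score rather than a grid quantile removes any ambiguity (up to
L*granularity/2 bits) about whether one-wobble sequences themselves clear
the cutoff. `threshold_for_pvalue` maps an arbitrary tail probability to
the smallest grid score whose survival probability does not exceed it; if
even the top score's mass exceeds the request, the top score is returned
and flagged.

**Scanning.** Every window on both strands is scored (minus strand via the
reverse-complemented score matrix) and reported in plus-strand coordinates;
overlapping matches are kept; windows containing non-ACGT characters are
skipped on both strands. Coordinates are 0-based half-open; motif positions
are 1-based on the motif's own strand.

**Shipped matrices.** The four LPMs in `ermotifs.simulate.default_motifs`
are synthetic stand-ins constructed from the published consensus layouts
(ERSEI CCAAT-N9-CCACG with spacer positions 6–14; ERSEII ATTGG-N-CCACG with
spacer 6; UPRE (C/A)CACGTCA; ATF4 (A/C)TGA(T/C)GCAA(T/C)). Strong positions
put 0.88 on the consensus base and 0.08 on its transition partner — so the
wobble base of a consensus C is T, matching CpG deamination; degenerate
positions are 0.48/0.44; spacers are uniform. They are not the
experimentally derived reference matrices, and the wobble tail
probabilities they produce (order 1e-6 to 3e-5) are properties of these
synthetic matrices.

## Interval arithmetic

All operations use half-open BED semantics: overlap requires at least one
shared base, so touching intervals do not overlap. Gene-proximity filtering
keeps a hit iff it overlaps any gene body expanded by the window (default
2,000 bp: within the gene, or up to 2 kb up/downstream). Overlap summaries
report both pair counts and distinct-query counts, since "number of
overlaps" admits both readings; distinct-query is the default elsewhere.
Random regions are drawn uniformly over all valid start positions (so
chromosomes are weighted by length), fully inside a chromosome, and may
overlap each other; the generator is deterministic given its seed. Tests
cross-check intersect/window semantics against bedtools on random inputs.

The ERSE half-site mask restricts SNV counting to the non-spacer positions
(the first and last five bases); it is strand-aware, though the ERSEI/II
layouts are symmetric so the genomic sub-intervals coincide for both
strands. Indels count anywhere in the motif, spacer included, because they
change the spacing between the two half sites. Whether the half-site mask
also applies to eQTL-variant overlap (stated in the source method only for
clinical-variant counting and for random-set lengths) is an open reading;
the pipeline applies it uniformly behind a `half_site` switch (default on).

## Conservation

Tracks are per-base values loaded from bedGraph into dense per-chromosome
arrays with NaN for uncovered bases (uncovered is always "missing", never
0). PhastCons-like tracks live in [0,1]; PhyloP-like tracks are signed with
0 = neutral. The conservation filter keeps a hit iff every base is covered
and the mean is **>= 0.5** — the source text uses both "cutoff of 0.5" and
"> 0.5"; `>=` was chosen once and is configurable. Positional profiles
average PhyloP values at each motif position across hits (strand-aware
projection); a missing value reduces that position's n rather than
dropping the hit (the full-coverage rule is a PhastCons-filter rule).
Position effects are tested with one-way ANOVA and, when significant at
0.05, Tukey's HSD; the hotspot-vs-rest comparison pools all non-focal
positions into one group and applies the same studentized-range procedure
to the two-group layout (the method prescribes Tukey rather than a t-test
for this contrast).

## Enrichment statistics

**Permutation.** The observed count is the number of distinct variants
overlapping any predicted site. Each of N draws (default 9,999) regenerates
random regions matched per motif in length (half-site length for ERSEs) and
number, and recounts;
`p = (#{n* >= n_real} + 1)/(N + 1)`, which is bounded below by 1/(N+1).
Draw i uses a Philox stream keyed on (seed, i), so results do not depend on
execution order. Bonferroni correction is applied within the family of
tests run together (e.g. motifs, or tissues x motifs).

**Positional chi-squared.** For a motif with k analysed positions and
total count T, position p is tested with observed (c_p, T − c_p) against
expected (T/k, T(k−1)/k), df = 1, no continuity correction, Bonferroni
multiplier k. For ERSE motifs the analysed positions are the half-site
positions; spacer indels are tallied separately and never assigned a
position. Pooled tissues deduplicate by variant by default.

**Benign binomial.** With motif-wide totals B benign and P pathogenic
({pathogenic, likely pathogenic} → PATH, {benign, likely benign} → BENIGN,
everything else excluded), `p_benign = B/(B+P)`; a position with b benign
of n variants gets the exact one-sided tail `P(X >= b | Binomial(n,
p_benign))`, Bonferroni over positions, flagged at adjusted p < 0.05.
Being exact, the test is conservative under the null (realized type-I
error below nominal), which the calibration checks assert as an upper
bound rather than a two-sided band.

## cis-eQTL scan

Candidate pairs are all (gene, variant) with |pos − TSS| <= 1 Mb on the
same chromosome (closed bound; strand-aware TSS). Per pair, over
complete-case samples (no imputation; n >= 3, non-constant dosage and
expression required): Pearson r between dosage and expression,
`t = r sqrt((n−2)/(1−r^2))`, two-sided t tail with n−2 df,
`slope = r sd(y)/sd(g)`, `se = |slope|/|t|`. No covariates, and expression
values are used as provided (log2 intensities). Perfect fits (|r| = 1) are
kept with se = 0 and flagged; they are excluded from effect-size testing.
BH-FDR is applied over all tested pairs within a condition; significance is
p_adj < 0.001. The nominal+BH design (rather than a beta-approximation
permutation pass) matches an analysis whose significant-pair counts span
all variant–gene pairs.

**Effect-size comparison.** For one pair in two conditions,
d = slope_a − slope_b, se_d = sqrt(se_a² + se_b²), degrees of freedom by
Welch–Satterthwaite on (se², n−2) per condition, CI = d ± t_{df,0.95} se_d
at 90% confidence (normal quantile when df > 200; difference < 1e-3),
significant iff the CI excludes 0. This summary-statistic Welch form is one
concrete reading of a Welch comparison on regression slopes; the null flag
rate calibrates to ~10% at 90% confidence in simulation, which is the
behaviour the construction is meant to have. Genotype-stratified summaries
report per-dosage-class mean log2 intensity per condition and fold change
`2^(mean_TM − mean_control)`.

## Synthetic-data generator

The generator defines the desk-scale study conditions. All randomness uses
Philox counter-based streams keyed on (seed, stream id), one stream per
output, so every file is independently and byte-identically reproducible.

* **Genome** — i.i.d. bases at GC 0.41 (human-like); default two 500 kb
  chromosomes, 60 evenly spaced 2 kb genes. Planted instances (default 30
  per motif) are consensus or, with probability 0.3, one-wobble sequences,
  random strand, placed within 1.5 kb of their gene (inside the 2 kb
  proximity window) without overlapping each other; spacer bases are drawn
  uniformly. The truth table records coordinates, strand, gene and wobble
  position.
* **Conservation** — PhastCons-like baseline Beta(1,4) (mean 0.2) with
  Beta(19,1) (mean 0.95) over planted half-sites, so a fully covered
  planted ERSEI averages ≈0.60 (≈3.5 SD above the 0.5 cutoff) while decoys
  average ≈0.2; PhyloP-like baseline N(0,1) with N(2,0.5) over half-sites.
  Coverage gaps at rate 0.01 per base.
* **Variants** — SNVs are placed at informative motif positions with a 10x
  weight at the CpG hotspot positions (ERSEI 18/19, ERSEII 10/11, UPRE 4/5,
  ATF4 5/6); hotspot alternates follow CpG deamination (C→T / G→A).
  Clinical labels are benign with probability 0.95 at hotspots and 0.5
  elsewhere; 1–2 bp deletions are planted in ERSE spacers; background SNVs
  are uniform over the genome. In power simulations the clinical set is
  sized by a design calculation: ~40 variants per analysed position give
  >99% power for the 0.95-vs-0.5 benign contrast under the
  Bonferroni-corrected exact binomial.
* **Cohort** — 110 samples; per-variant MAF ~ U(0.05, 0.5) with
  Hardy–Weinberg dosages Binomial(2, MAF); expression
  `y = mu_g + delta_g·[TM] + beta·dosage·[condition in class] + N(0, 0.5²)`
  with mu_g ~ N(10,1), condition main effect delta_g ~ N(0,0.5), planted
  |beta| = 1 per class (shared / control-only / TM-only), plus null
  variants near the remaining genes.

**What the generator does not emulate:** linkage disequilibrium and
population structure (dosages are independent across variants), realistic
motif co-occurrence or clustering, array-specific noise, sequence-context
mutation rates beyond the hotspot multiplier, and genome assembly gaps.
Passing tests therefore demonstrate correctness of the statistical
machinery and adequate power under idealised independence, not performance
on correlated real genotypes or real ChIP-defined binding sites.

## Numerical choices and degenerate inputs

Score-grid granularity 0.001 bits; survival-function lookups use half-grid
tolerance. Non-stochastic LPM rows, negative probabilities and
out-of-range spacer positions are rejected with the offending row named.
Zero-coverage conservation intervals return missing, flagged. ANOVA with
all-equal constant groups returns F = 0, p = 1; unequal constants with zero
within-group variance return NaN with a warning. Tukey groups with fewer
than two observations are excluded with a warning. Chi-squared requires a
positive total count; binomial positions with zero variants are skipped.
Pairs with constant dosage/expression are skipped with a reason code;
permutation draws are reproducible per (seed, draw index).

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the whole
suite completes in a few minutes: fuzzed scanner checks on 300 bp
sequences (100+ cases), permutation calibration with N = 999 over 500 runs
on a 100 kb genome, positional calibration/power over 200 simulated
variant sets on an 80 kb genome with 20 planted motifs, eQTL recovery on
1 Mb genomes with 180 genes and 150 planted effects at n = 110, and the
full pipeline funnel on a 160 kb genome. These sizes are the package's
own validation design; the library itself is vectorised and handles
genome-scale inputs streamed per chromosome.
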