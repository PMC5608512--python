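# Methods

This note documents the models, conventions, and numerical choices behind
`greekislands`, and what the synthetic-data results do and do not show.

## Coordinates and interval logic

All coordinates are 0-based half-open `[start, end)` (BED convention);
1-based inputs must be converted at the I/O boundary. Two intervals
overlap when they share at least one base — no minimum overlap fraction is
imposed anywhere, matching the default of standard interval tools.
Replicate consensus takes every cross-replicate overlapping pair and emits
the union span `min(starts)..max(ends)`; chains (A1–B1–A2) collapse into a
single span via connected components of the cross-set overlap graph, and
peaks private to one replicate are dropped. The same construction builds
co-bound spans across the two factors, with provenance back to the
component peak ids.

Point-to-interval distances are 0 inside a target, `start − p` to the left
edge and `p − end` past the right edge, and infinite when the chromosome
carries no target.

## H3K9me3 region calling

The caller tiles each chromosome with 2 kb windows at 1 kb step, normalises
chip and input window counts to 10 million reads, keeps windows with
fold ≥ 2.5 (inclusive), and merges kept windows separated by < 4 kb.
The fold of a merged region is total normalised chip over total normalised
input. The input pseudocount (0.5 normalised reads) acts as a *floor* on
the denominator rather than an additive offset: an additive pseudocount
would silently shift every fold (a window at exactly 2.5 would be rejected),
whereas a floor only intervenes where the input is effectively zero, which
is its sole purpose. No local-background filter is applied — only the
global chip/input fold. These comparisons are inclusive for determinism.

## Co-binding enrichment

The in-cluster co-binding rate `k/n` is compared to the genome-wide rate
`p₀ = k_bg/n_bg` with the exact binomial upper tail (scipy's `binomtest`).
Degenerate backgrounds (p₀ of 0 or 1) are rejected with a message, since
the test is undefined there. P-values are held at full double precision
and displayed at 4 significant figures. Note the two background-count
conventions in circulation for the Ebf test (total 8850 vs 8959 peaks);
both are accepted as inputs — the package takes counts, not a side.

## Motif model

Scores are natural-log log-odds against a configurable background (uniform
0.25 default) with pseudocount 0.01:
`w(b,i) = ln((p(b,i) + c·bg(b)) / ((1+c)·bg(b)))`. A perfectly uniform
column scores 0; a zero-probability cell with no pseudocount scores −inf,
as do positions containing N. Both strands are scanned (the minus-strand
score is the reverse-complement matrix applied to the forward window);
hits are ordered by offset with plus strand first on ties. The composite
motif concatenates the Lhx2 matrix, a background spacer (0 bp by default,
matching the juxtaposed geometry of the island composite element), and the
Ebf matrix; spacer columns contribute exactly zero. Score thresholds 10
(stringent) and 5 (permissive) are configuration, not constants, because
they are only meaningful relative to a concrete matrix; "scoring over 10"
is a strict inequality. The published composite matrix itself is not
available numerically (only as a logo), so the package ships synthetic
default matrices (below) and accepts real ones in MEME minimal format.

Motif proximity: for each Ebf hit in a region, the edge-to-edge gap to the
nearest Lhx2 hit (overlap → 0); the region's value is the minimum over its
Ebf hits, and regions with no Ebf hit are excluded rather than scored.

## One-sided two-sample KS test

For "sample1 stochastically smaller", D⁺ = sup_x(F₁ − F₂) over the pooled
support, with p = exp(−2mD⁺²), m = n₁n₂/(n₁+n₂). For n₁+n₂ ≤ 12 the exact
conditional permutation null is enumerated instead (all C(n₁+n₂, n₁)
assignments of the pooled values). The asymptotic tail is mildly
conservative at moderate sample sizes — measured null rejection at
α = 0.05 is ≈ 0.042 at n = 100/150 and ≈ 0.050 at n = 500/750 — so the
package's own null-calibration study uses n₁ = 500, n₂ = 750, squarely in
the asymptotic regime, and uses unequal sizes to avoid the coarse-lattice
conservatism of equal-n D⁺. These sizes are the calibration study's
conditions, not tunable analysis parameters.

## Accessibility signal

Fragment ends are shifted 4 bp toward the fragment interior
(start+4, end−4) to the transposase insertion sites; both ends are treated
identically. The common asymmetric +4/−5 convention is deliberately not
used. Fragments shorter than 9 bp cannot hold two shifted ends; both
sites clamp to the midpoint and the fragment is flagged. Tracks are
per-bp counts × 1e7/library_size ("reads per 10 million"), either
full-fragment extension or 1 bp insertion sites. Footprint profiles bin
insertion sites in 5 bp windows over a symmetric flank around motif
centers and report the across-center mean and standard error (SEM defined
as 0 for a single center). Input subtraction of display tracks clips at
zero and is a plotting convenience only. Region count matrices count a
fragment in every peak it overlaps by ≥ 1 bp, normalised per 10 million —
a deliberate simplification of effective-library (TMM-style)
normalisation, which is out of scope. Heatmap rows are center±flank or
linearly body-scaled windows, reversed for minus-strand regions, ordered
by descending row mean with stable ties.

## Expression analysis

Size factors follow the median-of-ratios definition: per sample, the
median over all-nonzero genes of count/geometric-mean. When a large known
fraction of the transcriptome changes (the synthetic study knocks down
30% of genes 4-fold), the all-gene median absorbs ~0.5 log2 of the shift;
the pipeline therefore estimates factors on the non-OR genes
(`control_genes=`), the standard control-gene idiom. In real data, where
ORs are a few percent of genes, the two choices coincide closely.

Fold changes are `log2((mean_B + 1)/(mean_A + 1))` on normalised counts
(pseudocount 1 stabilises low counts); base mean is the mean normalised
count over all samples and genes below 5 are flagged for exclusion from
density/scatter views. Differential-expression *inference* (dispersion
shrinkage, Wald tests, FDR) is intentionally replaced by effect-size
ranking: the downstream analyses (distance stratification, promoter
grouping, top-k enrichment) consume ranks and fold changes only. FPKM is
`(count/factor) × 1e9 / (L_s × length)` with L_s the factor-normalised
library size.

Island distance is measured gene-span edge to island edge, with two
sentinels: 1 for a gene overlapping an island and 1e8 for a gene on a
chromosome with no island; non-sentinel distances are floored at 1 so the
overlap sentinel stays unambiguous (the function never returns 0).
Promoter groups assign each gene {both, A-only, B-only, none} by which
factors have a peak within 1 kb of the TSS (a 500 bp window reproduces the
tighter variant). Top-k category enrichment is the exact hypergeometric
upper tail of the category overlap among the k most extreme genes.

## Synthetic-data generator

The generator emulates the statistical structure of the study, not its
sequences. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| chromosomes | 10 / 8 / 4 Mb | chr3 carries a cluster but no island (1e8 sentinel) |
| clusters | 10, 200–400 kb | non-overlapping, margin from chromosome ends |
| islands | 63 | ≥ 5 kb apart inside clusters, peak-sized (150–300 bp) |
| background peaks | 5000 | outside clusters, on a 1 kb grid (no accidental overlap) |
| background labels | 0.2315 / 0.5614 / 0.2071 | co-bound / Lhx2-only / Ebf-only, the published genome-wide tallies |
| in-cluster singles | 51 Lhx2-only + 2 Ebf-only | published in-cluster composition; non-island in-cluster peaks are singly bound |
| replicate jitter | ±30 bp | per peak edge, per replicate |
| window counts | Poisson, input mean 50 | 2 kb windows, 1 kb step |
| cluster fold | 4 | *library-normalised* chip/input fold over clusters |
| island dip | ×0.25 | chip mean over windows touching an island |
| regions | 100 composite + 100 dispersed (gap 40–120 bp) + 20 single-site, 200 bp | planted sites sampled from the matrices, random strand |
| footprint | 500 sites, 20 fragments each, depletion 0.5 within ±10 bp | insertion ends rejected inside the footprint |
| counts | 1000 genes (300 OR), NB dispersion 0.1, means lognormal(ln 200, 1), knockdown ×0.25, 3 vs 3, depth 0.8–1.2 | variance = μ + 0.1 μ² |

Each stage draws from `default_rng([seed, crc32(stage)])`, so stages can be
regenerated independently and reruns are byte-identical.

Two generator choices deserve explanation. First, `cluster_fold` is
defined as the fold the *caller observes after library normalisation*:
because enriched windows inflate the chip library total, a raw per-window
fold f over an enriched fraction φ appears as f/(1 + (f−1)φ); the
generator inverts this so that "domains at 4× background" means what it
says (at the defaults, raw ≈ 7.8 yields observed ≈ 4). Second, the default
motif matrices (Lhx2 6-mer `CTAATT`-like, Ebf 10-mer palindromic
`TCCCTAGGGA`-like) combine 10 near-deterministic columns (p = 0.997) with
6 near-uniform ones, giving a composite consensus score ≈ 14.4 so the
stringent/permissive thresholds 10/5 are meaningful, while sites sampled
from the matrices still score above 10 with ≈ 97% probability. Note the
Ebf default is genuinely palindromic, so its consensus matches both
strands — intended, and a property real Ebf half-sites share.

What the generator does *not* model: sequencing error, mappability, GC
bias, fragment-length distributions, peak-width/signal correlation,
between-replicate efficiency differences, dispersion trends (a single NB
dispersion for all genes), and any real genome sequence. Passing tests
demonstrate the statistical machinery is correct on data with the study's
structure; they do not certify performance on real libraries.

## Problem sizes and determinism

The default synthetic study (22 Mb genome, ~22k windows, ~13k peak
intervals, 220 sequence regions, 10k fragments, 1000 genes, 2000 KS null
replicates) was chosen so every stage, the full test suite, and the
acceptance script each complete in seconds while keeping empirical rates
(co-occurrence, type-I error, medians) within tight bands of their
configured values. All orderings are deterministic (coordinate sort,
stable tie-breaks), and pipeline reruns with the same config are
byte-identical — `manifest.json` records the config hash, seed, stages and
outputs.

## Known limitations

- The region caller is a tiling-window reimplementation of broad-mark
  "region mode" calling: window-quantised edges (±1 kb) and no local
  background model.
- The published composite-motif matrix is unavailable numerically, so
  score thresholds transfer to real data only after recalibrating against
  a real matrix.
- The KS asymptotic tail is conservative below n ≈ a few hundred; use the
  exact mode (automatic for n₁+n₂ ≤ 12) or larger samples where the exact
  level matters.
- `region_count_matrix` double-counts fragments spanning adjacent peaks by
  design (the stated counting rule) — columns need not sum to fragment
  totals.
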