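# Methods

`methylmark` implements the quantitative core of an epigenetic marker-region
study on murine innate lymphoid cells (ILCs): pairwise detection of
differentially methylated regions (DMRs) from unicate whole-genome bisulfite
sequencing (WGBS) methylomes, genomic annotation of DMRs, selection of
lineage marker regions, sample clustering on region methylation,
integration with gene expression, a between-lineage contrast ledger
(ILC vs. T-helper groups), hypergeometric pathway overrepresentation, and
de novo motif discovery in DMR sequences. All stages are exercised
end-to-end on synthetic methylomes with planted ground truth.

## Methylome representation and coverage filter

Per-CpG methylation calls enter as bedGraph-dialect tables (chrom, start,
end, fraction, optionally methylated/total read counts), with CpGs
strand-merged and keyed by the plus-strand C position. Internally all
coordinates are 0-based half-open; GTF input is converted on read. The
matrix keeps one level and one coverage per sample and CpG; a CpG missing
from a sample carries coverage 0 and an undefined level, and every
operation that averages over CpGs skips undefined values rather than
imputing them. Detection operates on CpGs with read coverage >= 5 in at
least one sample (`filter_by_coverage(min_cov=5, min_samples=1)`).

Gene models come from GTF/GFF3 via `gffutils`. Each gene is represented by
its longest transcript (exonic length, ties broken by transcript id); that
transcript's 5' end in transcript orientation defines the gene TSS, the
same length convention used for RPKM.

## DMR calling

A DMR between two samples is a contiguous run of >= 3 CpGs whose mean
methylation difference is >= 25% in absolute value. Because the
published workflows delegate detection to an external segmenter whose
internals are not restated here, `methylmark` uses a deterministic
recursive segmentation with an explicit contract:

1. CpGs with a defined difference are split into blocks wherever adjacent
   CpGs are more than `max_cpg_gap` (default 500 bp) apart, preventing
   regions from spanning CpG deserts. Blocks larger than 5,000 CpGs are
   split at their widest internal gap before exact scanning.
2. Within a block, a prefix-sum scan finds the contiguous window of
   >= `min_cpgs` CpGs maximising |mean difference| (ties resolved toward
   the longer, then the leftmost window).
3. The window is accepted if |mean| >= `min_diff` **and** it contains at
   least `min_cpgs` CpGs whose own same-sign |difference| reaches
   `min_diff`. The second clause keeps a window that is dragged over the
   threshold by one or two extreme CpGs from becoming a region.
4. An accepted window greedily absorbs flanking CpGs whose own same-sign
   |difference| is >= `min_diff` (this makes regions maximal: no reported
   region can be extended by an adjacent qualifying CpG), and segmentation
   recurses on both remainders. Rejected windows are skipped, with
   recursion continuing on their flanks.

Each region is scored with a two-sided exact Kolmogorov–Smirnov test
between the two samples' per-CpG level vectors, the natural 1-vs-1
analogue of distribution-level DMR testing in the absence of replicates.
`pairwise_dmr_tables` applies a region significance threshold of p <= 0.01
by default — the threshold at which downstream stages consume DMRs — which
also suppresses short noise windows (the exact KS test cannot reach 0.01
below five paired CpGs). Passing `max_p=None` disables it.

## Genomic annotation

A DMR is *promoter* if it overlaps TSS +/- `promoter_halfwidth`
(default 1,000 bp, i.e. "1 kb around the TSS" read as a symmetric radius;
+/- 500 bp is selectable) of any gene; otherwise *intragenic* if it
overlaps any gene body; otherwise *intergenic*. TSS distances are measured
from the nearest TSS to the nearest DMR edge, signed in transcript
orientation (downstream positive, upstream negative, zero when the region
spans the TSS). Nearest-gene ties break on the lexicographically smaller
gene id so reruns are reproducible. The distance histogram uses symmetric
bins centred on zero.

## Marker regions

Marker candidates for a target population are DMRs hypomethylated in that
population with |mean difference| strictly above 0.40 in at least one
pairwise comparison. Each candidate is extended with flanking same-sign
CpGs of |difference| >= 0.25 (the only differential threshold the study
states; configurable), merged with overlapping candidates from other
comparisons, and associated with a gene (gene body or promoter overlap,
else nearest TSS within 5 kb; candidates with no association are dropped
by default). Ranking uses the composite key

  (exclusivity, number of member CpGs, maximum |pairwise difference|),

descending, where *exclusivity* = min over other populations of
(region mean there − region mean in the target). This is one formalisation
of a selection that in practice also involved judgment; the exclusivity
term makes "demethylated exclusively in one population" quantitative. The
default list length is 12 per population (the study chose 7–14).

Region means are unweighted means over member CpGs with defined levels; a
region with no defined CpG in a sample is reported as not determined.
Locus profiles are smoothed with a coverage-weighted Gaussian kernel
(sd = bandwidth/2, truncated at the bandwidth, default 500 bp). This is a
visualisation smoother standing in for a local-likelihood fit; it is a
convex combination of nearby raw values, hence bounded by them, and leaves
constant profiles unchanged.

## Sample distances and clustering

Region-mean methylation over the pooled unique DMR spans gives a
samples x regions matrix; duplicate spans are merged. Regions are ranked
by across-sample variance and the top 1,000 retained ("most variable
DMRs" read as variance of region means). Euclidean distances between
sample rows (missing entries imputed with the region's across-sample
mean) feed agglomerative clustering; complete linkage is the default
because it is deterministic and standard for sample-level heatmaps
(single/average/ward selectable). Dendrograms export to Newick.

## Expression integration

Counts are normalised with median-of-ratios size factors; log2
fold-changes use group means with pseudocount 1 so zero counts stay
bounded; RPKM = count / (maximum-transcript length in kb x library size in
millions). Internal differential-expression p-values come from Welch's
t-test on log2(normalised + 1) with Benjamini–Hochberg correction
(implemented directly as the standard step-up transform and checked in the
tests against an independent reference implementation); externally
computed DE tables can be substituted. The DE filter keeps
|log2FC| >= 2 and adjusted p <= 0.05.

For a comparison of two populations, each marker gene contributes the pair
(region-mean methylation difference, log2 fold-change); the Pearson R with
its two-sided p and the fitted regression line are reported. Strength
labels follow half-open |R| bins: negligible (<= 0.3), low (<= 0.5),
moderate (<= 0.7), high (<= 0.9), very high (<= 1); boundary values fall
in the weaker bin, and the same bins apply to positive R. Both R and R²
are reported.

## Lineage contrast ledger

DMRs from all cross-group pairwise tables are merged into unique entries
(overlapping spans pooled, union span, constituent of largest |mean
difference| kept). An entry survives when (a) recomputed region-mean
differences are >= 0.5 in the same direction for *every* cross-group
sample pair — the universal quantifier is checked on region means rather
than trusting each pairwise caller to have emitted the region — (b) its
nearest TSS lies within 5 kb of a region edge, and (c) the nearest gene
has a canonical name (non-empty and not matching `^(Gm\d+|.*Rik)$`, the
mouse placeholder conventions; pattern configurable). The top 75 entries
per direction, ordered by |group-mean difference|, form the hyper- and
hypomethylated ledgers; the plot table carries one row per (DMR, sample),
so a gene with k surviving DMRs contributes k x n_samples points.

## Pathway enrichment

DMRs with |mean difference| >= 0.25 and p <= 0.01 map to their nearest
genes (each gene once). Overrepresentation of a gene set is the upper-tail
hypergeometric probability P(X >= k); the odds ratio comes from the 2x2
table with a Haldane 0.5 correction when a cell is zero. The default
universe is the genes with at least one assayed CpG in gene body or
promoter window (avoids trivial enrichment of long genes; "all annotated
genes" selectable). No multiple-testing correction is applied at this
stage — the consensus panel thresholds raw p <= 0.01 in *every* pairwise
comparison — but a BH column is emitted for information. The consensus is
ranked by the minimum odds ratio across comparisons (a conservative,
deterministic scalarisation of "highest odds ratios ... in all
comparisons") and truncated to 40.

## Motif discovery

DMR sequences (spans +/- 10 nt, clipped at chromosome edges) are searched
with an expectation–maximisation mixture model in the "any number of
repetitions" mode: every width-w window of every sequence is independently
a motif site with prior λ (split equally between strands) or background
(0th-order model from the input composition). EM runs from the most
frequent strand-canonical w-mers (3 starts, up to 40 iterations, stopping
when the penalised objective improves by < 0.01); the update is exact EM
for the Dirichlet-regularised mixture, so the objective is non-decreasing
— a property the tests assert. Discovered sites (posterior > 0.5) are
masked before the next motif is sought; widths 6–12 are scanned and up to
20 motifs reported.

Significance is empirical: for each width the same fitting procedure is
run on composition-preserving per-sequence shuffles (30 by default), a
Gumbel (extreme-value) distribution is moment-fitted to the null LLRs —
the standard model for maxima of fitted log-likelihood ratios — and the
motif's tail probability is multiplied by the size of the search
(widths x motifs sought) to give an E-value, i.e. the expected number of
equally strong motifs in the whole search under the null. A rank-based
empirical p was rejected at design time: with any affordable number of
shuffles its resolution floor (1/(M+1)) times the search-size multiplier
can never reach the E < 0.05 reporting threshold, so it cannot separate a
planted motif from noise at all.

Low-complexity motifs are removed when one base dominates > 70% of
consensus columns or a period-2 pattern covers > 80% of them; surviving
motifs with E < 0.05 are matched against a JASPAR-style PWM database by
the best mean column Pearson correlation over ungapped offset alignments
and both orientations, with an empirical p from column-shuffled queries.

## Synthetic data

The generator emulates the data structure the pipeline assumes, not any
particular genome:

- **Genome**: 2 chromosomes x 2 Mb. CpGs are placed in islands (5–30 CpGs,
  15–45 bp spacing, ~560 islands per chromosome, ~20,000 CpGs total)
  rather than uniformly: clustered CpGs are where regulatory DMRs live,
  and uniform placement at the same overall density would scatter planted
  blocks across gaps larger than the caller's 500 bp limit, making
  recovery ill-posed by construction. Each of 120 genes per chromosome
  gets a promoter island at its TSS and a gene-body island 2 kb
  downstream; a reserved pool of islands sits > 5 kb from every TSS.
  Accidental CpGs are removed from the sequence so the island catalog is
  exhaustive. About 10% of genes carry placeholder names (Gm…, …Rik).
- **Methylomes**: one unicate per population (five ILC-like populations by
  default; replicate mode available). Each CpG has a shared background
  level ~ Beta(8, 2) plus small per-population jitter (sd 0.02). CpGs
  inside planted blocks draw their shared base level from Beta(25, 3):
  a hypomethylation block of depth Δ presupposes a methylated baseline,
  otherwise the planted difference is not realisable. Each population
  receives 25 exclusive hypomethylated blocks (5–20 CpGs, depth
  Δ ~ U[0.4, 0.8]) — hence 50 planted blocks per pairwise comparison — of
  which 8 are *marker blocks* in promoters of distinct canonical genes
  with Δ ~ U[0.5, 0.8]; the remainder sit on the far-from-genes island
  pool so the set of gene-associable planted candidates per population is
  exactly its marker set. Optional shared blocks (hypomethylated in two
  designated populations) create the close-pair structure used in the
  clustering tests; optional lineage blocks (hypomethylated in a whole
  super-group) feed the contrast ledger in the 8-sample ILC+Th
  configuration. Observed levels are Binomial(coverage, level)/coverage at
  coverage ~ Poisson(20); coverage 0 yields a missing value.
- **Expression**: negative-binomial counts (dispersion 0.1, log-normal
  baseline means around 200) in triplicate for the four RNA-profiled
  populations. A marker gene of population P is up-regulated in P by
  log2FC = 4Δ + N(0, 0.35); with Δ ~ U[0.4, 0.8] this plants a latent
  methylation–expression correlation of −0.80, the coupling strength the
  marker-gene analysis is designed to detect. A pair-level generator
  (`simulate_methylation_expression_pairs`) exposes the same coupling
  without the count layer for calibration experiments.
- **Motifs**: the 8-mer TGACTCAG (an AP-1-like site) or its reverse
  complement is written into 80% of one population's exclusive blocks, at
  offsets between member CpGs so no catalogued CpG is destroyed. A toy
  PWM database (50 random PWMs plus a synthetic planted-motif model and
  no real transcription-factor matrices) supports matching tests.

What passing on these data does **not** show: real WGBS carries
bisulfite-conversion errors, strand-coverage asymmetry, copy-number and
mappability artefacts, spatially correlated methylation beyond the planted
blocks, and DMRs of graded rather than uniform depth; the expression model
has no batch structure or length bias. Recovery rates measured here are
upper bounds for field performance.

## Pipeline, determinism and problem sizes

`run_pipeline` executes simulate → coverage filter → pairwise DMRs →
annotation → markers → distances → expression integration → contrast →
enrichment → motifs from a single config with a single seed; every
threshold is a config key with the defaults above. All reports and tables
are byte-identical across reruns with the same seed; wall-clock timings go
to a separate `run.log` so the deterministic outputs can be compared
bitwise. The default simulated run (8 populations, ~19,000 retained CpGs,
28 pairwise comparisons) completes in a few minutes on one CPU; the test
suite and the acceptance script use these same scales, with motif null
calibration at 30 shuffles per width and 20 seeded null runs. These sizes
were chosen to make every ground-truth comparison cheap to re-run while
keeping all estimated rates (sensitivity ≈ 0.93, FDR ≈ 0.08 at the default
conditions) stable across seeds.

## Numerical choices and degenerate inputs

- Window-scan ties: longer window, then leftmost; all downstream ties
  (nearest gene, marker ordering, ledger ordering, consensus ranking)
  break lexicographically.
- Exact KS is used up to 100 paired CpGs, scipy's automatic policy above.
- Identical level vectors short-circuit to p = 1.
- Empty results are legal everywhere (empty DMR table, empty consensus);
  errors are reserved for malformed input (negative counts, asymmetric
  distance matrices, queries outside the universe, empty annotation).
- The EM evaluates window likelihoods in linear space, which is exact for
  motif widths up to ~20 at the pseudocount floor used (0.01).

## Known limitations

- Group-mode DMR statistics (n > 1 per condition) are out of scope; the
  KS score is a 1-vs-1 test.
- The segmentation is contract-equivalent to the exhaustive-window oracle
  but makes no claim of bit-compatibility with any external DMR caller.
- The motif E-value is calibrated against shuffles of the *input*; for
  later motifs (after masking) it is conservative.
- Conditional (nested-set-decorrelated) pathway testing is not
  implemented; gene sets are user-supplied.
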