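# Methods

`promoshift` re-creates, as a tested pipeline, the analysis chain that
links temporal gene-expression clusters in a differentiating tissue to
the motif content of each transcript's promoter: a differential-
expression gate, k-means temporal clustering, calibrated PSSM scanning
of two promoter windows, permutation-null enrichment z-scores,
hypergeometric gene-set tests, and an alternative-TSS core-promoter
"switch" analysis. Every stage is exercised end to end on synthetic
data with known ground truth.

## Data model and coordinates

The unit of analysis is the **transcript** (one TSS of one gene); genes
with alternative TSSs contribute one record per TSS. All internal
coordinates are 1-based inclusive with the TSS at +1 and **no position
0**: −1 abuts +1, so the core window −60..+40 spans exactly 100 bases
and the extended window −1000..−1 exactly 1000 bases. BED input is
converted on read (TSS = `start` for +, `end − 1` for − records,
0-based). For − strand records the contig is reverse-complemented and
the TSS re-anchored before window extraction, so windows always read in
the transcript's sense direction.

Expression is a transcripts × (time point, replicate) matrix of log2
ratios against a common reference sample (defaults: 5 post-reference
time points — 2, 6, 18, 24, 36 h labels — × 4 biological replicates).
The reference sits implicitly at log2 ratio 0 and is not a group of its
own.

## Differential-expression gate

Two independently switchable gates, both on by default:

* one-way ANOVA across time-point groups on each transcript's log2
  ratios, Benjamini–Hochberg adjusted, `alpha = 0.05`. BH is the
  array-era default; Bonferroni is available. Transcripts with zero
  total variance are degenerate (p = 1); zero within-group variance
  with real between-group spread gives F = ∞, p = 0.
* a fold gate: max over time points of |replicate-mean log2 ratio|
  must exceed log2(`fc_threshold`), default 1.5-fold. The mean (rather
  than any single replicate) is used for robustness.

Selection is monotone in both knobs (tightening either never adds a
transcript).

## Temporal clustering

k-means with Euclidean distance on **raw** replicate-mean profiles
(display normalisation — per-transcript division by max |log2 ratio| —
is presentational only; raw values preserve the amplitude information
that separates strong from weak responses). Defaults: k = 30,
k-means++ initialisation, 20 restarts, fixed seed; best-inertia
solution; labels 1..k; scikit-learn's Lloyd iterations relocate empty
clusters, so none is returned empty. A mean-silhouette sweep
(`estimate_k`, default k = 26..40) reports a recommended k but never
applies it. Cluster rows for heat maps are ordered by average-linkage
Euclidean clustering of cluster mean profiles.

## PSSM scanning with exact p-value calibration

The scanner is written from scratch because its calibration is the
load-bearing property. Per-position log2-odds
`score(i,b) = log2((p_ib + c·bg_b) / ((1+c)·bg_b))` with pseudocount
`c = 0.001` against a 0-order background; −∞ entries (at c = 0) are
capped at −100 bits. Scores are discretised to 1/1000 bit and the null
distribution of a single random background word is computed exactly by
convolving per-position score PMFs (dynamic programming). The hit
threshold is the smallest lattice score whose upper-tail mass is ≤
`p_threshold` (default 1e-4). Scanning compares the *same* discretised
scores against that threshold, so on i.i.d. background the per-offset
hit rate equals the DP tail mass exactly in expectation — verified on
10 Mb within 3 binomial standard errors. Short motifs whose best word
already exceeds `p_threshold` get threshold +∞ with an explicit
"no hit possible" warning, never an error.

Conventions: overlapping hits are all reported (no greedy masking —
this inflates counts for low-complexity motifs and is documented
deliberately); offsets where the motif covers an N are skipped;
p-values are per-offset single-word tails with no correction across
offsets. Default strand policy differs by window: sense-only in the
core window (core elements are position/orientation-specific), both
strands in the enhancer window (TF sites are orientation-agnostic);
both are configurable.

## Permutation-null motif enrichment

For each cluster of size n, 1000 random clusters of n transcripts are
drawn **without replacement** from the analysis universe (default: the
clustered DE set; the full platform is configurable). One shared draw
set per cluster is scored against all motifs and windows, which makes
z-scores comparable across motifs. z = (observed − μ)/σ with the
sample (n−1) denominator for σ; |z| > 3 called enriched/depleted;
σ = 0 cells are degenerate and reported with z = 0. The closed-form
finite-population moments (mean n·m̄; variance n·(N−n)/(N−1)·σ²_pop)
serve as the independent oracle; permutation estimates converge to
them at the 1/√n_perm rate.

## Hypergeometric tests

GO enrichment per (cluster, term) uses the hypergeometric upper tail
P(X ≥ b) with N = genes carrying ≥ 1 annotation, B = genes with the
term, n = annotated cluster genes, b = their overlap; the headline
term per cluster is the minimum-p term, reported only below 1e-5. No
multiple-testing correction is applied beyond that display rule
(documented as anti-conservative). Overlap validation against a
published target set uses N = platform genes, B = published genes on
the platform, n = cluster genes with data in the comparison, b = the
validated overlap, significant below 0.05. Both tests collapse
transcripts to genes; motif enrichment stays transcript-level.

## Promoter-switch concordance

A transcript's promoter type is the set of core motifs with ≥ 1 hit in
its core window. A switch gene has ≥ 2 TSSs with fundamentally
different complements — default rule: DRE at one TSS, no DRE but ≥ 1
other core motif at another; a strict DRE-vs-DPE pairing is available.
A transcript is **concordant** when ≥ 1 of its present motifs is
called enriched in its assigned cluster's core-window row (OR rule,
the weakest defensible reading of "the complement predicts the
cluster"; an AND rule over all present motifs is available). An empty
complement is concordant only in clusters with no enriched core motif.
Depleted calls never count against concordance. Transcripts that fail
the DE gate are excluded and listed. The analysis also reports, per
gene, whether differing-type TSSs landed in different clusters.

## Synthetic-data generator

The generator emulates the emulated study's design and is the ground
truth for every test:

* 2,000 genes by default; exactly round(0.14 × n) genes carry a second
  TSS; each transcript owns a 1,100-nt promoter contig (1 kb upstream
  + the 100-nt core window), strand random.
* 30 template profiles over 5 time points at amplitude 2 log2 units:
  10 declining, 10 rising, 10 peak/dip/transient shapes (minimum
  pairwise Euclidean distance 1.41, an order of magnitude above the
  0.15 replicate-mean noise per coordinate, so planted partitions are
  recoverable). Replicate noise is i.i.d. Gaussian, sd 0.3 log2 units.
  The shapes are an artifact choice; amplitude, noise and counts are
  the study-design values.
* promoter background is i.i.d. per-base (0-order), matching the
  scanner's null so calibration tests are exact. Motif instances are
  planted at template-class-dependent Bernoulli rates (declining:
  DRE/CP-class core motifs + growth TF motifs; rising: INR/DPE/MTE +
  differentiation TF motifs; background rate 0.03; TATA only weakly
  planted anywhere), non-overlapping, with enhancer instances on a
  random strand. Planted instances are sampled from the PSSM by
  default; `clean_planting` writes exact consensus instances, which
  the p<1e-4 scan recovers with certainty — concordance experiments
  use it so they measure the promoter/cluster association rather than
  instance-sampling noise.
* 25% of multi-TSS genes are designated **switch genes**: a DRE
  consensus planted at TSS-A and a DPE consensus at TSS-B; with
  probability `association_strength` TSS-A draws a declining and
  TSS-B a rising template, otherwise templates are uniform. This makes
  concordance a tunable truth: ≈ chance at strength 0, exactly 1 on
  designated genes at strength 1.
* ten synthetic core-promoter PSSMs and eight synthetic TF PSSMs are
  built as sharp (0.97) matrices around 8-mer consensi inspired by the
  canonical Drosophila elements (DRE TATCGATA, TATA, INR, DPE, MTE,
  CP-x; E2F, Myc, etc.). They are *not* any published matrix
  collection. Widths ≥ 8 keep the p<1e-4 threshold reachable;
  consensi are mutually ≥ 3 mismatches apart in any orientation that
  the scan can see, so cross-detection is negligible.
* GO truth: one term per template annotated over its member genes at
  purity 0.9 plus 20 uniform decoy terms; three "published" target
  sets are noisy copies (80% members + 2% extras) of template
  memberships with sign tags.

A fixed seed gives byte-identical output files. Per-stage seeds are
derived from the root seed by stable hashing of stage names, so adding
a stage never perturbs another stage's randomness.

What the generator does **not** emulate: array-level artifacts
(normalisation residue, probe effects, missing values), correlated
replicate noise, higher-order sequence composition, overlapping
promoters on a shared contig, and realistic GO term hierarchies.
Passing tests therefore demonstrate the correctness and calibration of
the machinery, not performance on real microarray data.

## Problem sizes and numerical choices

Experiments are sized to finish in seconds to a couple of minutes on
one CPU while keeping wide statistical margins: scanner/brute-force
panels of ~1,200 cases (lengths ≤ 50, widths ≤ 8) plus exhaustive 4^w
enumeration; 10 Mb for hit-rate calibration; 10,000 permutations
against the 15-subset exact enumeration; 2,500 cells for null z
calibration; 20 seeds × 2,000-transcript universes for planted power;
30 templates × 60 transcripts for clustering recovery; 1,000-gene
studies (≈ 35 designated switch genes) for the concordance guarantee
and 400-gene studies × 10 seeds × 5 strengths for its monotonicity;
2,000-gene studies for end-to-end determinism.

Tie-breaks and degenerate inputs: equidistant k-means assignment
resolves to the lowest label (scikit-learn's deterministic argmin);
all-identical profiles make the silhouette undefined — flagged, no
recommendation; truncated promoter windows (TSS near a contig end)
warn with the achieved length and are scanned as-is; empty restricted
clusters in overlap validation give NaN with an `undefined` flag.

## Known limitations

* The permutation universe (DE set vs. whole platform) changes z-score
  magnitudes; the DE-set default is the standard reading of
  equal-size resampling but is not the only one.
* GO p-values are uncorrected across terms and clusters by design.
* The scanner's null is 0-order; CpG-like composition or repeats in
  real promoters would mis-calibrate p-values relative to this null.
* Genome-scale summary fractions (share of multi-TSS genes with
  identifiable DPE/DRE promoters, absolute switch-gene counts) are
  only meaningful with a real genome annotation and are reported only
  when such input is supplied.
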