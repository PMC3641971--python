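# promoshift

Temporal gene-expression clustering meets promoter-motif content:
`promoshift` is a tested pipeline for developmental time-course
studies that asks whether the motifs in a transcript's promoter —
core-promoter elements around the TSS and transcription-factor sites
in the kilobase upstream — predict its temporal expression behaviour.
It was built for regulatory-genomics analyses of the kind done on the
differentiating *Drosophila* wing, where genes fall into ~30 temporal
clusters and core-promoter types (DRE vs. INR/DPE/MTE) track declining
vs. rising expression, down to genes whose alternative TSSs use
different core promoters and land in different clusters.

## What it computes

Given a TSS table (BED6), promoter sequences (FASTA), PSSMs
(MEME-minimal), a log2-ratio expression matrix (TSV; time points ×
replicates vs. a common reference) and optional GO/target gene sets
(GMT):

1. **DE gate** — per-transcript one-way ANOVA across time points
   (BH-adjusted p < 0.05) and a >1.5-fold gate at ≥ 1 time point.
2. **Temporal clusters** — k-means (Euclidean, k = 30, 20 restarts) on
   replicate-mean profiles; silhouette sweep over k = 26..40;
   average-linkage ordering of cluster profiles.
3. **Motif scan** — from-scratch PSSM scanner over the core window
   (−60..+40, 100 bp) and the extended window (−1 kb..−1). Hits are
   called at p < 1e-4 under an *exact* null: per-position log-odds
   scores are discretised (1/1000 bit) and convolved by dynamic
   programming, so the threshold's tail mass is exact rather than
   approximated.
4. **Enrichment z-scores** — for each cluster of n transcripts, motif
   occurrence sums are compared with 1000 random clusters of n drawn
   without replacement; z = (obs − μ)/σ, |z| > 3 called
   enriched/depleted.
5. **Gene-set tests** — hypergeometric GO enrichment per cluster
   (headline term only below p < 1e-5) and overlap validation against
   published target sets (p < 0.05).
6. **Promoter-switch analysis** — every TSS typed by its core-motif
   complement; genes whose alternative TSSs use fundamentally
   different core promoters (e.g. DRE at one, DPE at another) are
   flagged, and each transcript is scored *concordant* when its
   complement matches its cluster's enriched core motifs.

A synthetic-study generator (`promoshift.synthetic_data`) produces all
of these inputs with known ground truth — planted templates, planted
motif instances, designated switch genes with tunable
promoter/cluster association — so the whole chain is testable without
any downloads. See `docs/methods.md` for the model details.

## Worked example

The numbered drivers under `analysis/` run the default in-silico study
(2,000 genes, 2,280 transcripts) end to end, writing tables under
`results/`:

```sh
python analysis/01_simulate.py
python analysis/02_expression_filtering.py
python analysis/03_temporal_clusters.py
python analysis/04_promoter_scan.py
python analysis/05_motif_enrichment.py
python analysis/06_promoter_switch.py
```

which prints, step by step:

```
  genes:            2000
  transcripts:      2280
  multi-TSS genes:  280 (14%)
  switch genes:     70
...
clustered 2280 DE transcripts into k=30
  cluster sizes: 66..86
  silhouette sweep 26..40 recommends k=30 (report only)
...
scanned 2280 promoters with 10 core + 8 enhancer motifs at p<1e-4
  hits: 2912 core / 2885 enhancer
...
540 cluster x motif x window cells (30 clusters, 1000 permutations, |z|>3):
  enriched 130, depleted 140, ns 270
GO: 30/30 clusters have a headline term at p<1e-5
...
switch genes (DRE vs other core motif at alternate TSSs): 126
  concordant transcripts: 243/252 (96%)
  genes with differing-type TSSs in different clusters: 126/126
  designated (planted) switch genes: 140/140 transcripts concordant
```

Reading: every planted signal is recovered — all transcripts pass the
DE gate (all templates have amplitude 2 > the 1.5-fold cutoff), the 30
planted templates come back as 30 clusters, planted core/enhancer
motifs light up as enrichment cells, and every *designated* switch
gene's transcripts sit in clusters whose enriched core motifs match
their promoter type. The remaining discordant transcripts belong to
genes flagged as switch-like through chance background hits, for which
no association was planted. `analysis/07_benchmarks.py` adds the
calibration numbers (scanner vs. brute force, p-value calibration on
10 Mb, null |z|>3 rate ≈ 0.003, planted-enrichment power 1.0) and
`analysis/08_figures.py` renders the heat map and enrichment dot
matrices.

The same pipeline is scriptable via a single YAML config:

```sh
promoshift simulate --outdir study --seed 1
promoshift run --config cfg.yaml
promoshift report outdir
```

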