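#!/usr/bin/env python
"""Permutation-null motif enrichment per cluster (1000 random equal-size
clusters; |z|>3 called), hypergeometric GO headlines (p<1e-5), and
overlap validation against the synthetic published target sets (p<0.05).

Reads results/analysis/{clusters,occurrences}.tsv; writes
enrichment.tsv, go_enrichment.tsv, go_headlines.tsv, overlap_validation.tsv.
"""

from pathlib import Path

import pandas as pd

from promoshift.enrichment_stats import (
    _gene_of,
    go_enrichment,
    overlap_validation,
    permutation_enrichment,
)
from promoshift.io_formats import read_gene_sets, read_tss_table
from promoshift.motif_scan import OccurrenceMatrix
from promoshift.pipeline import stage_seed
from promoshift.temporal_clustering import ClusterAssignment

ROOT = Path(__file__).resolve().parent.parent
SEED = 1


def main() -> None:
    out = ROOT / "results/analysis"
    labels = pd.read_csv(out / "clusters.tsv", sep="\t", index_col=0)["cluster"]
    assignment = ClusterAssignment(labels, int(labels.max()), float("nan"))
    occ = OccurrenceMatrix(
        pd.read_csv(out / "occurrences.tsv", sep="\t", header=[0, 1], index_col=0),
        1e-4,
    )

    enr = permutation_enrichment(
        occ, assignment, n_perm=1000, seed=stage_seed(SEED, "enrichment")
    )
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    by_call = enr.call.value_counts()
    print(f"{len(enr)} cluster x motif x window cells "
          f"({assignment.k} clusters, 1000 permutations, |z|>3):")
    print(f"  enriched {by_call.get('enriched', 0)}, "
          f"depleted {by_call.get('depleted', 0)}, ns {by_call.get('ns', 0)}")

    annotations = read_gene_sets(ROOT / "results/study/go_annotations.gmt")
    go_table, headlines = go_enrichment(assignment, annotations)
    go_table.to_csv(out / "go_enrichment.tsv", sep="\t", index=False,
                    float_format="%.6g")
    pd.DataFrame(
        [(c, h or "") for c, h in sorted(headlines.items())],
        columns=["cluster", "headline_term"],
    ).to_csv(out / "go_headlines.tsv", sep="\t", index=False)
    n_head = sum(1 for h in headlines.values() if h)
    print(f"GO: {n_head}/{assignment.k} clusters have a headline term at p<1e-5")

    targets = read_gene_sets(ROOT / "results/study/target_sets.gmt")
    transcripts = read_tss_table(ROOT / "results/study/tss.bed")
    platform = {_gene_of(t.transcript_id) for t in transcripts}
    rows = []
    for name in targets:
        for label in range(1, assignment.k + 1):
            genes = {_gene_of(t) for t in assignment.members(label)}
            r = overlap_validation(genes, targets[name], platform)
            rows.append((name, label, r["n"], r["b"], r["p"], r["significant"]))
    overlap = pd.DataFrame(
        rows, columns=["set", "cluster", "n", "b", "p", "significant"]
    )
    overlap.to_csv(out / "overlap_validation.tsv", sep="\t", index=False,
                   float_format="%.6g")
    print(f"overlap validation: {int(overlap.significant.sum())} significant "
          f"(set, cluster) pairs at p<0.05 out of {len(overlap)}")


if __name__ == "__main__":
    main()
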