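"""Promoter typing, switch-gene detection, and concordance rules."""

import numpy as np
import pandas as pd
import pytest

from promoshift.experiments import _assignment_from_labels
from promoshift.io_formats import TranscriptRecord
from promoshift.motif_scan import OccurrenceMatrix
from promoshift.promoter_switch import (
    classify_tss,
    concordance,
    concordance_summary,
    find_switch_genes,
)


def _occ(counts: dict[str, dict[str, int]], motifs=("DRE", "DPE", "INR")):
    tids = list(counts)
    cols = pd.MultiIndex.from_tuples(
        [("core", m) for m in motifs], names=["window", "motif"]
    )
    df = pd.DataFrame(0, index=tids, columns=cols, dtype=int)
    for tid, row in counts.items():
        for m, c in row.items():
            df.loc[tid, ("core", m)] = c
    return OccurrenceMatrix(df, 1e-4)


def _enrichment(rows):
    """rows: (cluster, motif, call)"""
    return pd.DataFrame(
        [(c, "core", m, 10, 5, 1.0, 0.5, 4.0 if call == "enriched" else 0.0, call)
         for c, m, call in rows],
        columns=["cluster", "window", "motif", "n", "observed",
                 "perm_mean", "perm_sd", "z", "call"],
    )


def _records(genes: dict[str, list[str]]):
    return [
        TranscriptRecord(g, t, f"{t}_prom", 1001, "+")
        for g, ts in genes.items()
        for t in ts
    ]


class TestClassifyTSS:
    def test_zero_counts_empty_complement_non_labels(self):
        calls = classify_tss(_occ({"t1": {}}))
        assert calls["t1"].present_motifs == frozenset()
        assert calls["t1"].label("DRE") == "Non-DRE"

    def test_presence_threshold_is_one_hit(self):
        calls = classify_tss(_occ({"t1": {"DRE": 2, "DPE": 0}}))
        assert calls["t1"].present_motifs == {"DRE"}
        assert calls["t1"].label("DRE") == "DRE"
        assert calls["t1"].label("DPE") == "Non-DPE"

    def test_pure_function_of_counts(self):
        occ = _occ({"t1": {"INR": 1}})
        assert classify_tss(occ) == classify_tss(occ)


class TestFindSwitchGenes:
    def test_single_tss_gene_never_reported(self):
        recs = _records({"g1": ["g1-RA"]})
        calls = classify_tss(_occ({"g1-RA": {"DRE": 1}}))
        assert find_switch_genes(recs, calls) == []

    def test_dre_vs_dpe_gene_reported(self):
        recs = _records({"g1": ["g1-RA", "g1-RB"]})
        calls = classify_tss(_occ({"g1-RA": {"DRE": 1}, "g1-RB": {"DPE": 1}}))
        reports = find_switch_genes(recs, calls)
        assert [r.gene_id for r in reports] == ["g1"]

    def test_both_tss_dre_not_reported(self):
        recs = _records({"g1": ["g1-RA", "g1-RB"]})
        calls = classify_tss(_occ({"g1-RA": {"DRE": 1}, "g1-RB": {"DRE": 2}}))
        assert find_switch_genes(recs, calls) == []

    def test_strict_pair_rule_requires_partner(self):
        recs = _records({"g1": ["g1-RA", "g1-RB"]})
        calls = classify_tss(_occ({"g1-RA": {"DRE": 1}, "g1-RB": {"INR": 1}}))
        assert len(find_switch_genes(recs, calls, rule="dre_vs_other")) == 1
        assert find_switch_genes(recs, calls, rule="strict_pair") == []


class TestConcordance:
    def _setup(self):
        recs = _records({"g1": ["g1-RA", "g1-RB"]})
        calls = classify_tss(_occ({"g1-RA": {"DRE": 1}, "g1-RB": {"DPE": 1}}))
        reports = find_switch_genes(recs, calls)
        assign = _assignment_from_labels(np.array([1, 2]), ["g1-RA", "g1-RB"])
        return reports, assign

    def test_transcript_concordant_when_motif_enriched_in_its_cluster(self):
        reports, assign = self._setup()
        enr = _enrichment([(1, "DRE", "enriched"), (2, "DPE", "enriched")])
        detail = concordance(reports, assign, enr)
        assert detail.concordant.all()
        summary = concordance_summary(detail)
        assert summary["fraction"] == 1.0
        assert summary["genes_separated"] == 1

    def test_discordant_when_cluster_enriches_other_motif_only(self):
        reports, assign = self._setup()
        enr = _enrichment([(1, "INR", "enriched"), (2, "DPE", "enriched")])
        detail = concordance(reports, assign, enr)
        assert not detail.set_index("transcript_id").loc["g1-RA", "concordant"]

    def test_depleted_calls_do_not_count_for_concordance(self):
        reports, assign = self._setup()
        enr = _enrichment([(1, "DRE", "depleted"), (2, "DPE", "enriched")])
        detail = concordance(reports, assign, enr)
        assert not detail.set_index("transcript_id").loc["g1-RA", "concordant"]

    def test_empty_complement_concordant_only_without_enrichment(self):
        recs = _records({"g1": ["g1-RA", "g1-RB"]})
        calls = classify_tss(
            _occ({"g1-RA": {"DRE": 1}, "g1-RB": {"DPE": 1}, "g1-RC": {}})
        )
        # force an empty-complement transcript through a hand-built report
        reports = find_switch_genes(recs, calls)
        reports[0].transcripts.append("g1-RC")
        reports[0].calls["g1-RC"] = classify_tss(_occ({"g1-RC": {}}))["g1-RC"]
        assign = _assignment_from_labels(
            np.array([1, 2, 3]), ["g1-RA", "g1-RB", "g1-RC"]
        )
        enr = _enrichment(
            [(1, "DRE", "enriched"), (2, "DPE", "enriched"), (3, "DRE", "ns")]
        )
        detail = concordance(reports, assign, enr).set_index("transcript_id")
        assert detail.loc["g1-RC", "concordant"]

    def test_unassigned_transcripts_excluded_and_logged(self):
        reports, _ = self._setup()
        assign = _assignment_from_labels(np.array([1]), ["g1-RA"])
        enr = _enrichment([(1, "DRE", "enriched")])
        detail = concordance(reports, assign, enr)
        assert list(detail.transcript_id) == ["g1-RA"]
        assert reports[0].excluded == ["g1-RB"]

    def test_all_rule_requires_every_present_motif(self):
        recs = _records({"g1": ["g1-RA", "g1-RB"]})
        calls = classify_tss(
            _occ({"g1-RA": {"DRE": 1, "INR": 1}, "g1-RB": {"DPE": 1}})
        )
        reports = find_switch_genes(recs, calls)
        assign = _assignment_from_labels(np.array([1, 2]), ["g1-RA", "g1-RB"])
        enr = _enrichment([(1, "DRE", "enriched"), (2, "DPE", "enriched")])
        any_detail = concordance(reports, assign, enr, rule="any")
        all_detail = concordance(reports, assign, enr, rule="all")
        a = any_detail.set_index("transcript_id")
        b = all_detail.set_index("transcript_id")
        assert a.loc["g1-RA", "concordant"]
        assert not b.loc["g1-RA", "concordant"]
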