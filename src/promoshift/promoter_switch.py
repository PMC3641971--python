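"""Per-TSS core-promoter typing, switch genes, and cluster concordance.

Each transcript is typed by the set of core-promoter motifs with at
least one hit in its -60..+40 window.  A "switch" gene has >= 2 TSSs
with fundamentally different core-promoter complements (default: DRE
at one TSS, no DRE but >= 1 other core motif at another; a strict
DRE-vs-DPE pairing is available).  Concordance asks whether a
transcript's promoter complement predicts its cluster: the transcript
is concordant when >= 1 of its present core motifs is called enriched
in its assigned cluster's core-window enrichment row (OR rule; an AND
rule over all present motifs is available), or — for an empty
complement — when no core motif is enriched there.  Depleted calls
never count against concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import TranscriptRecord
from .motif_scan import OccurrenceMatrix
from .temporal_clustering import ClusterAssignment

__all__ = [
    "PromoterTypeCall",
    "SwitchGeneReport",
    "classify_tss",
    "find_switch_genes",
    "concordance",
]


@dataclass(frozen=True)
class PromoterTypeCall:
    transcript_id: str
    present_motifs: frozenset[str]

    def label(self, focal_motif: str) -> str:
        return focal_motif if focal_motif in self.present_motifs else f"Non-{focal_motif}"


@dataclass
class SwitchGeneReport:
    gene_id: str
    transcripts: list[str]
    calls: dict[str, PromoterTypeCall]
    clusters: dict[str, int] = field(default_factory=dict)
    concordant: dict[str, bool] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)  # failed the DE gate

    @property
    def total_transcripts(self) -> int:
        return len(self.concordant)

    @property
    def concordant_transcripts(self) -> int:
        return sum(self.concordant.values())


def classify_tss(
    occ: OccurrenceMatrix, core_motif_ids: list[str] | None = None
) -> dict[str, PromoterTypeCall]:
    """Presence = count >= 1 in the core window; pure function of `occ`."""
    core = occ.window("core")
    if core_motif_ids is not None:
        core = core[core_motif_ids]
    calls = {}
    for tid, row in core.iterrows():
        calls[tid] = PromoterTypeCall(tid, frozenset(row.index[row >= 1]))
    return calls


def find_switch_genes(
    transcripts: list[TranscriptRecord],
    calls: dict[str, PromoterTypeCall],
    rule: str = "dre_vs_other",
    focal: str = "DRE",
    partner: str = "DPE",
) -> list[SwitchGeneReport]:
    """Genes whose alternative TSSs use fundamentally different promoters.

    rule='dre_vs_other': one TSS has the focal motif (DRE), another
    lacks it but has >= 1 other core motif.  rule='strict_pair': the
    other TSS must carry the named partner motif (DPE).
    """
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for tr in transcripts:
        by_gene.setdefault(tr.gene_id, []).append(tr)
    reports = []
    for gene_id in sorted(by_gene):
        group = by_gene[gene_id]
        if len(group) < 2:
            continue
        tids = [t.transcript_id for t in group]
        gcalls = {t: calls[t] for t in tids if t in calls}
        has_focal = [t for t in gcalls if focal in gcalls[t].present_motifs]
        if rule == "dre_vs_other":
            alt = [
                t for t in gcalls
                if focal not in gcalls[t].present_motifs and gcalls[t].present_motifs
            ]
        elif rule == "strict_pair":
            alt = [
                t for t in gcalls
                if focal not in gcalls[t].present_motifs
                and partner in gcalls[t].present_motifs
            ]
        else:
            raise ValueError(f"unknown switch rule {rule!r}")
        if has_focal and alt:
            reports.append(SwitchGeneReport(gene_id, tids, gcalls))
    return reports


def concordance(
    reports: list[SwitchGeneReport],
    assignment: ClusterAssignment,
    enrichment: pd.DataFrame,
    rule: str = "any",
) -> pd.DataFrame:
    """Fill in clusters + concordance flags; return the per-transcript table.

    A transcript whose cluster's core-window enrichment row contains
    >= 1 ('any') / all ('all') of its present motifs is concordant;
    empty complements are concordant only in clusters with no enriched
    core motif.  Transcripts filtered out by the DE gate are excluded
    and listed on their gene's report.  Also reports, per gene, whether
    differing-type TSSs landed in different clusters.
    """
    if rule not in ("any", "all"):
        raise ValueError(f"unknown concordance rule {rule!r}")
    core = enrichment[enrichment["window"] == "core"]
    enriched_by_cluster: dict[int, set[str]] = {
        int(c): set(g.loc[g["call"] == "enriched", "motif"])
        for c, g in core.groupby("cluster")
    }
    rows = []
    for rep in reports:
        for tid in rep.transcripts:
            if tid not in assignment.labels.index or tid not in rep.calls:
                rep.excluded.append(tid)
                continue
            cluster = int(assignment.labels[tid])
            rep.clusters[tid] = cluster
            present = rep.calls[tid].present_motifs
            enriched = enriched_by_cluster.get(cluster, set())
            if present:
                hit = present & enriched
                ok = bool(hit) if rule == "any" else present <= enriched
            else:
                ok = not enriched
            rep.concordant[tid] = ok
        # cluster separation between differing-type TSS pairs
        typed = [t for t in rep.clusters if rep.calls[t].present_motifs]
        separated = None
        pairs = [
            (a, b)
            for i, a in enumerate(typed)
            for b in typed[i + 1 :]
            if rep.calls[a].present_motifs != rep.calls[b].present_motifs
        ]
        if pairs:
            separated = all(rep.clusters[a] != rep.clusters[b] for a, b in pairs)
        for tid in rep.clusters:
            rows.append(
                (
                    rep.gene_id,
                    tid,
                    "+".join(sorted(rep.calls[tid].present_motifs)) or "none",
                    rep.clusters[tid],
                    rep.concordant[tid],
                    separated,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "transcript_id", "promoter_type",
            "cluster", "concordant", "gene_tss_separated",
        ],
    )


def concordance_summary(detail: pd.DataFrame) -> dict:
    """Concordant/total transcripts and the per-gene separation fraction."""
    total = len(detail)
    conc = int(detail["concordant"].sum())
    by_gene = detail.dropna(subset=["gene_tss_separated"]).groupby("gene_id")[
        "gene_tss_separated"
    ].first()
    return {
        "concordant": conc,
        "total": total,
        "fraction": conc / total if total else float("nan"),
        "genes_separated": int(by_gene.sum()) if len(by_gene) else 0,
        "genes_with_pairs": int(len(by_gene)),
    }
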