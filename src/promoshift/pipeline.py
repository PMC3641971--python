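"""End-to-end orchestration: DE gate -> clustering -> motif scan ->
permutation enrichment -> GO / overlap validation -> promoter-switch
concordance, under one declarative YAML config with per-stage seeds
derived from a single root seed and a machine-readable run report.

Identical config + inputs reproduce byte-identical outputs (content
hashes are recorded in the report).  The expensive scan and enrichment
stages can be resumed from cached outputs; the cache is keyed on a
hash of the parameter set and is never reused across configs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrichment_stats, motif_scan, promoter_switch, temporal_clustering
from .io_formats import (
    MotifClass,
    read_expression,
    read_fasta,
    read_gene_sets,
    read_pssm_set,
    read_tss_table,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_figures", "stage_seed"]

log = logging.getLogger("promoshift")


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed; adding a stage never perturbs the others."""
    digest = hashlib.blake2s(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Schema-checked pipeline configuration (mirrors the YAML layout)."""

    tss: str
    sequences: str
    core_motifs: str
    enhancer_motifs: str
    expression: str
    outdir: str
    go: str | None = None
    targets: str | None = None
    seed: int = 0
    de: dict[str, Any] = field(
        default_factory=lambda: {"alpha": 0.05, "fc_threshold": 1.5, "adjust_method": "BH"}
    )
    cluster: dict[str, Any] = field(
        default_factory=lambda: {"k": 30, "n_restarts": 20, "estimate_k": False}
    )
    scan: dict[str, Any] = field(
        default_factory=lambda: {
            "p_threshold": 1e-4,
            "pseudocount": 0.001,
            "strands": {"core": "sense_only", "enhancer": "both"},
            "background": [0.25, 0.25, 0.25, 0.25],
        }
    )
    enrich: dict[str, Any] = field(
        default_factory=lambda: {"n_perm": 1000, "z_threshold": 3.0}
    )
    go_opts: dict[str, Any] = field(
        default_factory=lambda: {"report_threshold": 1e-5}
    )
    switch: dict[str, Any] = field(
        default_factory=lambda: {"rule": "dre_vs_other", "concordance_rule": "any"}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("tss", "sequences", "core_motifs", "enhancer_motifs", "expression"):
            if not Path(getattr(cfg, key)).exists():
                raise FileNotFoundError(f"{key}: {getattr(cfg, key)}")
        return cfg

    def params(self) -> dict:
        return {
            "seed": self.seed, "de": self.de, "cluster": self.cluster,
            "scan": self.scan, "enrich": self.enrich, "go": self.go_opts,
            "switch": self.switch,
        }

    def param_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.params(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunReport:
    params: dict
    stages: dict[str, dict]
    hashes: dict[str, str]
    warnings: list[str]
    wall_clock_s: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "params": self.params,
                    "stages": self.stages,
                    "output_sha256": self.hashes,
                    "warnings": self.warnings,
                    "wall_clock_s": round(self.wall_clock_s, 2),
                },
                indent=1,
                sort_keys=True,
            )
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: RunConfig, resume: bool = False) -> RunReport:
    t0 = time.time()
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    warnings_log: list[str] = []
    cache_key = outdir / "param_hash.txt"
    cache_valid = (
        resume and cache_key.exists() and cache_key.read_text() == cfg.param_hash()
    )

    # ---- inputs -----------------------------------------------------------
    core_pssms = read_pssm_set(cfg.core_motifs, MotifClass.CORE_PROMOTER)
    enh_pssms = read_pssm_set(cfg.enhancer_motifs, MotifClass.ENHANCER)
    transcripts = read_tss_table(cfg.tss)
    sequences = read_fasta(cfg.sequences)
    expr = read_expression(cfg.expression)
    log.info(
        "inputs: %d transcripts, %d core + %d enhancer motifs, %d expression rows",
        len(transcripts), len(core_pssms), len(enh_pssms), expr.n_transcripts,
    )
    stages["inputs"] = {
        "transcripts": len(transcripts),
        "core_motifs": len(core_pssms),
        "enhancer_motifs": len(enh_pssms),
        "expression_rows": expr.n_transcripts,
    }

    # ---- differential expression -----------------------------------------
    de = diffexpr.select_de(
        expr,
        alpha=cfg.de.get("alpha", 0.05),
        fc_threshold=cfg.de.get("fc_threshold", 1.5),
        adjust_method=cfg.de.get("adjust_method", "BH"),
    )
    _write_tsv(de.table.rename_axis("transcript_id"), outdir / "de_table.tsv", index=True)
    log.info("DE gate: %d of %d transcripts selected", len(de), expr.n_transcripts)
    stages["diffexpr"] = {"selected": len(de), "tested": expr.n_transcripts}

    # ---- clustering -------------------------------------------------------
    profiles = expr.subset(de.selected).replicate_means()
    k = int(cfg.cluster.get("k", 30))
    assignment = temporal_clustering.kmeans_cluster(
        profiles, k=k,
        seed=stage_seed(cfg.seed, "cluster"),
        n_restarts=int(cfg.cluster.get("n_restarts", 20)),
    )
    if cfg.cluster.get("estimate_k"):
        lo, hi = cfg.cluster.get("k_range", [26, 40])
        ktable, krec = temporal_clustering.estimate_k(
            profiles, range(int(lo), int(hi) + 1), seed=stage_seed(cfg.seed, "estimate_k")
        )
        _write_tsv(ktable, outdir / "k_estimate.tsv")
        stages["estimate_k"] = {"recommended": krec}
    cprofiles = temporal_clustering.cluster_profiles(assignment, expr.subset(de.selected))
    order = (
        temporal_clustering.hierarchical_order(cprofiles) if assignment.k >= 2 else [1]
    )
    _write_tsv(
        assignment.labels.rename_axis("transcript_id").to_frame(),
        outdir / "clusters.tsv", index=True,
    )
    prof_df = pd.DataFrame(
        {p.label: p.mean_profile for p in cprofiles}
    ).T.rename_axis("cluster")
    prof_df["n"] = [p.n for p in cprofiles]
    _write_tsv(prof_df, outdir / "cluster_profiles.tsv", index=True)
    stages["clustering"] = {
        "k": assignment.k,
        "inertia": round(assignment.inertia, 4),
        "hierarchical_order": order,
    }

    # ---- motif scan -------------------------------------------------------
    occ_path = outdir / "occurrences.tsv"
    hits_path = outdir / "hits.tsv"
    if cache_valid and occ_path.exists() and hits_path.exists():
        occ_df = pd.read_csv(occ_path, sep="\t", header=[0, 1], index_col=0)
        occ = motif_scan.OccurrenceMatrix(occ_df, cfg.scan.get("p_threshold", 1e-4))
        n_hits = max(len(pd.read_csv(hits_path, sep="\t")), 0)
        stages["scan"] = {"hits": n_hits, "cached": True}
        log.info("scan: reloaded %d hits from cache", n_hits)
    else:
        occ, hits = motif_scan.scan_promoters(
            sequences, transcripts,
            {"core": core_pssms, "enhancer": enh_pssms},
            background=cfg.scan.get("background", [0.25] * 4),
            p_threshold=cfg.scan.get("p_threshold", 1e-4),
            pseudocount=cfg.scan.get("pseudocount", 0.001),
            strand_policies=cfg.scan.get("strands"),
        )
        occ.counts.to_csv(occ_path, sep="\t")
        _write_tsv(motif_scan.hits_to_frame(hits), hits_path)
        stages["scan"] = {"hits": len(hits), "cached": False}
        log.info("scan: %d hits at p<%g", len(hits), occ.threshold_p)

    # ---- permutation enrichment ------------------------------------------
    enrichment = enrichment_stats.permutation_enrichment(
        occ, assignment,
        n_perm=int(cfg.enrich.get("n_perm", 1000)),
        seed=stage_seed(cfg.seed, "enrichment"),
        z_threshold=float(cfg.enrich.get("z_threshold", 3.0)),
    )
    _write_tsv(enrichment, outdir / "enrichment.tsv")
    n_enriched = int((enrichment["call"] == "enriched").sum())
    n_depleted = int((enrichment["call"] == "depleted").sum())
    stages["enrichment"] = {
        "cells": len(enrichment), "enriched": n_enriched, "depleted": n_depleted,
    }
    log.info("enrichment: %d enriched / %d depleted cells", n_enriched, n_depleted)

    # ---- GO enrichment ----------------------------------------------------
    if cfg.go:
        annotations = read_gene_sets(cfg.go)
        go_table, headlines = enrichment_stats.go_enrichment(
            assignment, annotations,
            report_threshold=float(cfg.go_opts.get("report_threshold", 1e-5)),
        )
        _write_tsv(go_table, outdir / "go_enrichment.tsv")
        _write_tsv(
            pd.DataFrame(
                [(c, h if h else "") for c, h in sorted(headlines.items())],
                columns=["cluster", "headline_term"],
            ),
            outdir / "go_headlines.tsv",
        )
        stages["go"] = {
            "terms": len(annotations),
            "headlines": sum(1 for h in headlines.values() if h),
        }

    # ---- overlap validation ----------------------------------------------
    if cfg.targets:
        targets = read_gene_sets(cfg.targets)
        platform = {enrichment_stats._gene_of(t.transcript_id) for t in transcripts}
        rows = []
        for name in targets:
            for label in range(1, assignment.k + 1):
                genes = {
                    enrichment_stats._gene_of(t) for t in assignment.members(label)
                }
                res = enrichment_stats.overlap_validation(
                    genes, targets[name], platform
                )
                rows.append((name, label, res["N"], res["B"], res["n"], res["b"],
                             res["p"], res["significant"]))
        overlap = pd.DataFrame(
            rows, columns=["set", "cluster", "N", "B", "n", "b", "p", "significant"]
        )
        _write_tsv(overlap, outdir / "overlap_validation.tsv")
        stages["overlap"] = {
            "sets": len(targets),
            "significant": int(overlap["significant"].sum()),
        }

    # ---- promoter switch / concordance ------------------------------------
    calls = promoter_switch.classify_tss(occ)
    reports = promoter_switch.find_switch_genes(
        transcripts, calls, rule=cfg.switch.get("rule", "dre_vs_other")
    )
    detail = promoter_switch.concordance(
        reports, assignment, enrichment,
        rule=cfg.switch.get("concordance_rule", "any"),
    )
    _write_tsv(detail, outdir / "switch_report.tsv")
    summary = promoter_switch.concordance_summary(detail)
    stages["switch"] = {"genes": len(reports), **summary}
    log.info(
        "switch: %d genes, %d/%d concordant transcripts",
        len(reports), summary["concordant"], summary["total"],
    )

    cache_key.write_text(cfg.param_hash())
    hashes = {
        p.name: _sha256(p)
        for p in sorted(outdir.glob("*.tsv"))
    }
    report = RunReport(cfg.params(), stages, hashes, warnings_log, time.time() - t0)
    report.to_json(outdir / "run_report.json")
    return report


# ---------------------------------------------------------------------------
# Figures (presentational only)


def make_figures(outdir: str | Path) -> list[Path]:
    """Cluster-profile heat map + enrichment dot matrix from pipeline outputs.

    Enriched cells are red, depleted green, degenerate cells a grey 'x'.
    Purely presentational; idempotent.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    made = []

    prof = pd.read_csv(outdir / "cluster_profiles.tsv", sep="\t", index_col=0)
    profile_cols = [c for c in prof.columns if c != "n"]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(prof))))
    im = ax.imshow(prof[profile_cols].to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(profile_cols)), profile_cols)
    ax.set_yticks(range(len(prof)), prof.index)
    ax.set_xlabel("time point")
    ax.set_ylabel("cluster")
    fig.colorbar(im, label="mean log2 ratio")
    p = outdir / "cluster_profiles.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    made.append(p)

    enr = pd.read_csv(outdir / "enrichment.tsv", sep="\t")
    for window, sub in enr.groupby("window"):
        piv = sub.pivot_table(index="cluster", columns="motif", values="z")
        calls = sub.pivot_table(
            index="cluster", columns="motif", values="call", aggfunc="first"
        )
        fig, ax = plt.subplots(
            figsize=(max(3, 0.45 * piv.shape[1]), max(2, 0.25 * piv.shape[0]))
        )
        for i, cl in enumerate(piv.index):
            for j, m in enumerate(piv.columns):
                call = calls.loc[cl, m]
                if call == "enriched":
                    ax.scatter(j, i, c="red", s=40)
                elif call == "depleted":
                    ax.scatter(j, i, c="green", s=40)
                elif call == "degenerate":
                    ax.scatter(j, i, c="grey", marker="x", s=30)
        ax.set_xticks(range(piv.shape[1]), piv.columns, rotation=90)
        ax.set_yticks(range(piv.shape[0]), piv.index)
        ax.set_title(f"{window} window: enrichment (red) / depletion (green), |z|>3")
        ax.invert_yaxis()
        p = outdir / f"enrichment_{window}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        made.append(p)
    return made
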