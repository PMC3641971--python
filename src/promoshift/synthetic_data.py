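"""In-silico study generator with known ground truth.

Emulates the data model of a developmental time-course promoter study:

* ~2,000 genes, 14% with two alternative TSSs, each TSS a separate
  transcript with its own 1,100-nt promoter contig (1 kb upstream +
  100-nt core window around the TSS at internal position +1);
* temporal log2-ratio expression (5 post-reference time points x 4
  biological replicates) built from 30 template profiles (amplitude
  2 log2 units) plus i.i.d. Gaussian noise (sd 0.3);
* promoter sequences with motif instances planted at template-dependent
  rates on an i.i.d. background: declining templates carry DRE-class
  core elements and growth-associated enhancer motifs, rising templates
  carry INR/DPE/MTE and differentiation-associated enhancer motifs;
* "switch" genes: multi-TSS genes with a DRE consensus planted at one
  TSS (assigned a declining template) and a DPE consensus at the other
  (assigned a rising template), with a configurable association
  strength so promoter-type/cluster concordance has a tunable truth;
* GO annotations (one true term per template at configurable purity
  plus uniform decoys) and "published" target sets for overlap tests.

The PSSMs are synthetic: sharp matrices built around consensus 8-mers
inspired by the canonical Drosophila core-promoter elements and a few
well-known TF sites; they are not any published matrix collection.

Fixed seed => byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    BASES,
    ExpressionMatrix,
    GeneSetCollection,
    MotifClass,
    PSSM,
    TranscriptRecord,
    write_expression,
    write_fasta,
    write_gene_sets,
    write_pssm_set,
    write_tss_table,
)
from .motif_scan import reverse_complement

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_core_motifs",
    "default_enhancer_motifs",
    "default_templates",
    "default_planting_table",
    "sample_motif_instance",
    "simulate_expression",
    "plant_motifs",
    "generate_dataset",
]

DEFAULT_TIME_POINTS = ("02h", "06h", "18h", "24h", "36h")

# template family layout: 10 declining, 10 rising, 10 other
DECLINING = tuple(range(0, 10))
RISING = tuple(range(10, 20))
OTHER = tuple(range(20, 30))


def _consensus_pssm(
    motif_id: str,
    consensus: str,
    motif_class: MotifClass,
    sharpness: float = 0.97,
) -> PSSM:
    off = (1.0 - sharpness) / 3.0
    probs = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        probs[i, BASES.index(b)] = sharpness
    return PSSM(motif_id, motif_class, probs)


def default_core_motifs() -> list[PSSM]:
    """Ten synthetic core-promoter PSSMs (DRE/DPE/INR/MTE/TATA/CP-x)."""
    consensi = {
        "DRE": "TATCGATA",
        "DPE": "AGACGTGC",
        "INR": "TCAGTTCG",
        "MTE": "CGAACGGA",
        "TATA": "TATAAAAG",
        "CP1": "GGTCACAC",
        "CP2": "ACGGATGT",
        "CP3": "CTGCGGTT",
        "CP6": "GTGGCCAA",
        "CP7": "AACCGGCA",
    }
    return [
        _consensus_pssm(mid, cons, MotifClass.CORE_PROMOTER)
        for mid, cons in consensi.items()
    ]


def default_enhancer_motifs() -> list[PSSM]:
    """Eight synthetic transcription-factor PSSMs for the 1-kb upstream window."""
    consensi = {
        "E2F": "TTTCGCGC",
        "Myc": "CACGTGAC",
        "Dref_TF": "TATCGCGT",
        "Mad": "GGCGCCAT",
        "Cad": "TTTATGGC",
        "Croc": "ATTGTTTG",
        "En": "TAATTAGC",
        "Ubx": "TTAATGGC",
    }
    return [
        _consensus_pssm(mid, cons, MotifClass.ENHANCER) for mid, cons in consensi.items()
    ]


_UNIT_SHAPES: list[list[float]] = [
    # declining
    [1, 0.5, 0, -0.5, -1],
    [1, 1, 0.5, -0.5, -1],
    [1, 0.5, -0.5, -1, -1],
    [1, 1, 0, 0, -1],
    [1, 0, 0, -1, -1],
    [1, 1, 1, 0, -1],
    [1, 0, -1, -1, -1],
    [1, 1, -1, -1, -1],
    [1, 0.5, 0.5, -1, -1],
    [0.5, 1, 0, -1, -0.5],
    # rising (mirror of declining)
    [-1, -0.5, 0, 0.5, 1],
    [-1, -1, -0.5, 0.5, 1],
    [-1, -0.5, 0.5, 1, 1],
    [-1, -1, 0, 0, 1],
    [-1, 0, 0, 1, 1],
    [-1, -1, -1, 0, 1],
    [-1, 0, 1, 1, 1],
    [-1, -1, 1, 1, 1],
    [-1, -0.5, -0.5, 1, 1],
    [-0.5, -1, 0, 1, 0.5],
    # peaks, dips, transients
    [-1, 1, -0.5, -1, -1],
    [-1, -0.5, 1, -0.5, -1],
    [-1, -1, -0.5, 1, -0.5],
    [1, -1, 0.5, 1, 1],
    [1, 0.5, -1, 0.5, 1],
    [1, 1, -1, 1, 1],
    [-1, -1, 1, 1, -1],
    [-1, 1, 1, -1, -1],
    [0, 1, -1, 1, 0],
    [-0.5, -1, -1, 1, 1],
]


def default_templates(
    n_templates: int = 30, amplitude: float = 2.0
) -> np.ndarray:
    """Template profile library: (n_templates, 5) log2 ratios, amplitude-scaled."""
    if n_templates > len(_UNIT_SHAPES):
        raise ValueError(f"at most {len(_UNIT_SHAPES)} templates available")
    return amplitude * np.array(_UNIT_SHAPES[:n_templates], dtype=float)


def default_planting_table(
    n_templates: int = 30,
    core_ids: Sequence[str] | None = None,
    enhancer_ids: Sequence[str] | None = None,
    background_rate: float = 0.03,
) -> pd.DataFrame:
    """Per (template, motif) insertion probability, (n_templates x motifs).

    Declining templates carry DRE-class core elements and growth TF
    motifs at high rates; rising templates carry INR/DPE/MTE and
    differentiation TF motifs; TATA is only weakly planted anywhere.
    """
    if core_ids is None:
        core_ids = [p.motif_id for p in default_core_motifs()]
    if enhancer_ids is None:
        enhancer_ids = [p.motif_id for p in default_enhancer_motifs()]
    table = pd.DataFrame(
        background_rate,
        index=range(n_templates),
        columns=list(core_ids) + list(enhancer_ids),
        dtype=float,
    )
    high = {
        "DRE": 0.7, "CP1": 0.4, "CP6": 0.4, "CP7": 0.4,
        "E2F": 0.6, "Myc": 0.6, "Dref_TF": 0.5,
    }
    for t in DECLINING:
        if t < n_templates:
            for m, p in high.items():
                if m in table.columns:
                    table.loc[t, m] = p
    high = {
        "INR": 0.7, "DPE": 0.7, "MTE": 0.4,
        "Cad": 0.6, "En": 0.4, "Ubx": 0.4,
    }
    for t in RISING:
        if t < n_templates:
            for m, p in high.items():
                if m in table.columns:
                    table.loc[t, m] = p
    for t in OTHER[:5]:
        if t < n_templates and "TATA" in table.columns:
            table.loc[t, "TATA"] = 0.2
    return table


@dataclass
class SyntheticConfig:
    """Study-design knobs for the in-silico dataset.

    Defaults mirror the emulated study: 14% multi-TSS genes, 30
    temporal templates at amplitude 2 log2 units, 5 post-reference time
    points x 4 replicates, replicate noise sd 0.3 log2 units.
    """

    seed: int
    n_genes: int = 2000
    frac_multi_tss: float = 0.14
    n_templates: int = 30
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    replicates: int = 4
    noise_sd: float = 0.3
    template_amplitude: float = 2.0
    planting_table: pd.DataFrame | None = None
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    enhancer_len: int = 1000
    core_len: int = 100
    switch_fraction: float = 0.25  # of multi-TSS genes
    association_strength: float = 1.0
    # clean planting writes exact consensus instances (always recoverable
    # by the scan) instead of PSSM-sampled ones
    clean_planting: bool = False
    go_purity: float = 0.9
    n_go_decoys: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.frac_multi_tss, self.switch_fraction,
                  self.association_strength, self.go_purity):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if abs(sum(self.background_freqs) - 1.0) > 1e-6:
            raise ValueError("background_freqs must sum to 1")


@dataclass
class GroundTruth:
    """What the generator actually wrote: the oracle for every stage."""

    template_of: dict[str, int]  # transcript -> template index
    planted_counts: pd.DataFrame  # transcripts x (window, motif)
    switch_genes: set[str]
    tss_complement: dict[str, list[str]]  # transcript -> definitional core motifs
    templates: np.ndarray  # (n_templates, n_time_points)
    template_classes: dict[int, str]  # template -> declining/rising/other
    multi_tss_genes: set[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "template_of": self.template_of,
            "planted_counts": {
                f"{w}::{m}": {
                    t: int(c)
                    for t, c in self.planted_counts[(w, m)].items()
                    if c
                }
                for w, m in self.planted_counts.columns
            },
            "switch_genes": sorted(self.switch_genes),
            "tss_complement": self.tss_complement,
            "templates": self.templates.tolist(),
            "template_classes": {str(k): v for k, v in self.template_classes.items()},
            "multi_tss_genes": sorted(self.multi_tss_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Primitive generators


def sample_motif_instance(pssm: PSSM, rng: np.random.Generator) -> str:
    """Draw one instance, each position from its column distribution."""
    cum = np.cumsum(pssm.probs, axis=1)
    u = rng.random(pssm.width)
    idx = (u[:, None] > cum).sum(axis=1)
    return "".join(BASES[i] for i in idx)


def random_background(
    length: int, rng: np.random.Generator,
    freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> str:
    codes = rng.choice(4, size=length, p=np.asarray(freqs, dtype=float))
    return "".join(BASES[c] for c in codes)


def plant_motifs(
    window_seq: str,
    pssm: PSSM,
    count: int,
    rng: np.random.Generator,
    positions: Sequence[int] | None = None,
    max_tries: int = 1000,
) -> tuple[str, list[int]]:
    """Write `count` sampled non-overlapping instances into the window.

    Returns the modified sequence and the 1-based offsets used.  Raises
    if non-overlapping placement fails after bounded retries.
    """
    w = pssm.width
    L = len(window_seq)
    if count * w > L:
        raise ValueError(
            f"cannot plant {count} x width-{w} instances in a {L}-nt window"
        )
    seq = list(window_seq)
    occupied: list[tuple[int, int]] = []
    chosen: list[int] = []
    if positions is not None:
        if len(positions) != count:
            raise ValueError("positions length must equal count")
        chosen = [int(p) for p in positions]
        for p in chosen:
            if p < 1 or p + w - 1 > L:
                raise ValueError(f"position {p} out of range for width {w}")
    else:
        for _ in range(count):
            for _try in range(max_tries):
                p = int(rng.integers(1, L - w + 2))
                if all(p + w - 1 < s or p > e for s, e in occupied):
                    occupied.append((p, p + w - 1))
                    chosen.append(p)
                    break
            else:
                raise RuntimeError(
                    f"could not place instance {len(chosen) + 1}/{count} "
                    f"without overlap after {max_tries} tries"
                )
    for p in chosen:
        inst = sample_motif_instance(pssm, rng)
        seq[p - 1 : p + w - 1] = inst
    return "".join(seq), chosen


def simulate_expression(
    templates: np.ndarray,
    assignment: Mapping[str, int],
    noise_sd: float,
    replicates: int,
    rng: np.random.Generator,
    time_points: Sequence[str] = DEFAULT_TIME_POINTS,
) -> ExpressionMatrix:
    """value(t, tp, rep) = template[assignment[t], tp] + N(0, noise_sd)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    templates = np.asarray(templates, dtype=float)
    tids = list(assignment)
    base = templates[[assignment[t] for t in tids]]  # (n, ntp)
    n, ntp = base.shape
    if ntp != len(time_points):
        raise ValueError("template length != number of time points")
    noise = rng.normal(0.0, noise_sd, size=(n, ntp, replicates)) if noise_sd else (
        np.zeros((n, ntp, replicates))
    )
    values = base[:, :, None] + noise
    cols = pd.MultiIndex.from_tuples(
        [(tp, r + 1) for tp in time_points for r in range(replicates)],
        names=["time_point", "replicate"],
    )
    df = pd.DataFrame(
        values.reshape(n, ntp * replicates), index=tids, columns=cols
    )
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# Full dataset


def _check_planting_feasible(cfg: SyntheticConfig, table: pd.DataFrame,
                             core_w: Mapping[str, int],
                             enh_w: Mapping[str, int]) -> None:
    for t in table.index:
        core_load = sum(table.loc[t, m] * core_w[m] for m in core_w)
        enh_load = sum(table.loc[t, m] * enh_w[m] for m in enh_w)
        if core_load > cfg.core_len or enh_load > cfg.enhancer_len - cfg.core_len // 2:
            raise ValueError(
                f"template {t}: expected planted bases exceed window capacity"
            )


def generate_dataset(
    config: SyntheticConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Write the complete synthetic study to `outdir`; return paths + truth.

    Files: tss.bed, promoters.fa, expression.tsv, core_motifs.meme,
    enhancer_motifs.meme, go_annotations.gmt, target_sets.gmt,
    ground_truth.json.
    """
    cfg = config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    core_motifs = default_core_motifs()
    enhancer_motifs = default_enhancer_motifs()
    core_by_id = {p.motif_id: p for p in core_motifs}
    enh_by_id = {p.motif_id: p for p in enhancer_motifs}
    templates = default_templates(cfg.n_templates, cfg.template_amplitude)
    table = (
        cfg.planting_table
        if cfg.planting_table is not None
        else default_planting_table(cfg.n_templates)
    )
    _check_planting_feasible(
        cfg, table,
        {m: core_by_id[m].width for m in core_by_id if m in table.columns},
        {m: enh_by_id[m].width for m in enh_by_id if m in table.columns},
    )

    classes = {t: "declining" for t in DECLINING if t < cfg.n_templates}
    classes |= {t: "rising" for t in RISING if t < cfg.n_templates}
    classes |= {t: "other" for t in OTHER if t < cfg.n_templates}
    dre_templates = [t for t in DECLINING if t < cfg.n_templates]
    dpe_templates = [t for t in RISING if t < cfg.n_templates]

    # gene inventory: first round(frac*n) genes of a shuffled order are multi-TSS
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    order = rng.permutation(cfg.n_genes)
    n_multi = round(cfg.frac_multi_tss * cfg.n_genes)
    multi = {genes[i] for i in order[:n_multi]}
    n_switch = round(cfg.switch_fraction * n_multi)
    switch = {genes[i] for i in order[:n_switch]}

    transcripts: list[TranscriptRecord] = []
    template_of: dict[str, int] = {}
    tss_complement: dict[str, list[str]] = {}
    # template assignment: round-robin over genes for balance
    gene_template = {g: i % cfg.n_templates for i, g in enumerate(genes)}

    contig_len = cfg.enhancer_len + cfg.core_len
    tss_sense = cfg.enhancer_len + 1  # TSS at +1 right after the 1-kb window

    all_template_ids = list(range(cfg.n_templates))
    for g in genes:
        tids = [f"{g}-RA"] + ([f"{g}-RB"] if g in multi else [])
        for j, tid in enumerate(tids):
            strand = "+" if rng.random() < 0.5 else "-"
            if g in switch:
                # TSS-A carries a DRE, TSS-B a DPE; templates follow the
                # association with probability `association_strength`
                concordant = rng.random() < cfg.association_strength
                if j == 0:
                    tss_complement[tid] = ["DRE"]
                    pool = dre_templates if concordant else all_template_ids
                else:
                    tss_complement[tid] = ["DPE"]
                    pool = dpe_templates if concordant else all_template_ids
                tpl = int(pool[rng.integers(len(pool))])
            else:
                tss_complement[tid] = []
                tpl = (
                    gene_template[g]
                    if j == 0
                    else int(rng.integers(cfg.n_templates))
                )
            template_of[tid] = tpl
            transcripts.append(
                TranscriptRecord(
                    g, tid, f"{tid}_prom",
                    tss_sense if strand == "+" else contig_len - tss_sense + 1,
                    strand,
                )
            )

    # promoter sequences with planted instances
    motif_cols = pd.MultiIndex.from_tuples(
        [("core", m) for m in core_by_id] + [("enhancer", m) for m in enh_by_id],
        names=["window", "motif"],
    )
    planted = pd.DataFrame(
        0, index=[t.transcript_id for t in transcripts], columns=motif_cols, dtype=int
    )
    seqs: dict[str, str] = {}
    core_abs_start = tss_sense - 60  # -60 in 1-based sense coordinates
    core_abs_end = tss_sense + 39  # +40
    for tr in transcripts:
        tid = tr.transcript_id
        tpl = template_of[tid]
        sense = list(random_background(contig_len, rng, cfg.background_freqs))
        occupied: list[tuple[int, int]] = []

        def _place(pssm: PSSM, lo: int, hi: int, seq_str: str | None,
                   rc_allowed: bool) -> bool:
            w = pssm.width
            for _try in range(200):
                p = int(rng.integers(lo, hi - w + 2))
                if all(p + w - 1 < s or p > e for s, e in occupied):
                    inst = seq_str if seq_str is not None else sample_motif_instance(pssm, rng)
                    if rc_allowed and rng.random() < 0.5:
                        inst = reverse_complement(inst)
                    sense[p - 1 : p + w - 1] = inst
                    occupied.append((p, p + w - 1))
                    return True
            return False

        # definitional switch-gene plantings: exact consensus in the core window
        for m in tss_complement[tid]:
            pssm = core_by_id[m]
            if _place(pssm, core_abs_start, core_abs_end, pssm.consensus, False):
                planted.loc[tid, ("core", m)] += 1
        # rate-based plantings: core motifs inside -60..+40, enhancer motifs
        # upstream of the core window so the two never collide
        for m, pssm in core_by_id.items():
            if m in table.columns and rng.random() < table.loc[tpl, m]:
                inst = pssm.consensus if cfg.clean_planting else None
                if _place(pssm, core_abs_start, core_abs_end, inst, False):
                    planted.loc[tid, ("core", m)] += 1
        for m, pssm in enh_by_id.items():
            if m in table.columns and rng.random() < table.loc[tpl, m]:
                inst = pssm.consensus if cfg.clean_planting else None
                if _place(pssm, 1, core_abs_start - 1, inst, True):
                    planted.loc[tid, ("enhancer", m)] += 1

        sense_str = "".join(sense)
        seqs[tr.seq_id] = sense_str if tr.strand == "+" else reverse_complement(sense_str)

    expr = simulate_expression(
        templates, template_of, cfg.noise_sd, cfg.replicates, rng, cfg.time_points
    )

    # gene-level GO annotations: one true term per template + uniform decoys
    gene_tpl = {g: template_of[f"{g}-RA"] for g in genes}
    go_sets: dict[str, set[str]] = {}
    go_desc: dict[str, str] = {}
    for t in range(cfg.n_templates):
        members = {
            g for g in genes
            if gene_tpl[g] == t and rng.random() < cfg.go_purity
        }
        if members:
            name = f"GO:TPL{t:02d}"
            go_sets[name] = members
            go_desc[name] = f"true term for template {t}"
    for d in range(cfg.n_go_decoys):
        members = {g for g in genes if rng.random() < 0.05}
        if members:
            name = f"GO:DEC{d:02d}"
            go_sets[name] = members
            go_desc[name] = "decoy term"
    go = GeneSetCollection(go_sets, go_desc)

    # "published" target sets: noisy copies of three template memberships
    target_sets: dict[str, set[str]] = {}
    target_desc: dict[str, str] = {}
    target_signs: dict[str, dict[str, int]] = {}
    for t, sign in ((0, -1), (10, 1), (20, 1)):
        if t >= cfg.n_templates:
            continue
        members = {g for g in genes if gene_tpl[g] == t and rng.random() < 0.8}
        extras = {g for g in genes if gene_tpl[g] != t and rng.random() < 0.02}
        name = f"target_TPL{t:02d}"
        target_sets[name] = members | extras
        target_desc[name] = f"synthetic published target set around template {t}"
        target_signs[name] = {g: sign for g in members | extras}
    targets = GeneSetCollection(target_sets, target_desc, target_signs)

    truth = GroundTruth(
        template_of, planted, switch, tss_complement, templates, classes, multi
    )

    paths = {
        "tss": outdir / "tss.bed",
        "sequences": outdir / "promoters.fa",
        "expression": outdir / "expression.tsv",
        "core_motifs": outdir / "core_motifs.meme",
        "enhancer_motifs": outdir / "enhancer_motifs.meme",
        "go": outdir / "go_annotations.gmt",
        "targets": outdir / "target_sets.gmt",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_tss_table(transcripts, paths["tss"])
    write_fasta(seqs, paths["sequences"])
    write_expression(expr, paths["expression"])
    write_pssm_set(core_motifs, paths["core_motifs"], cfg.background_freqs)
    write_pssm_set(enhancer_motifs, paths["enhancer_motifs"], cfg.background_freqs)
    write_gene_sets(go, paths["go"])
    write_gene_sets(targets, paths["targets"])
    truth.to_json(paths["ground_truth"])
    return paths, truth
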