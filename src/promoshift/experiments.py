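"""Pre-wired synthetic-study experiments.

Each function runs one self-contained study on generated data with
known ground truth and returns the measured quantities: scanner/oracle
agreement, p-value calibration, permutation-statistic accuracy, null
z-score calibration, planted-enrichment power, clustering recovery,
DE-gate calibration, and promoter-switch concordance.  The analysis
drivers and the acceptance machinery are thin wrappers over these.

Problem sizes are chosen so each experiment finishes in seconds to a
couple of minutes on one CPU while leaving comfortable statistical
margins; see docs/methods.md.
"""

from __future__ import annotations

import itertools
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import diffexpr, enrichment_stats, motif_scan, promoter_switch, temporal_clustering
from .io_formats import (
    MotifClass,
    PSSM,
    read_expression,
    read_fasta,
    read_pssm_set,
    read_tss_table,
)
from .motif_scan import MotifScorer, encode
from .pipeline import RunConfig, run_pipeline, stage_seed
from .synthetic_data import (
    SyntheticConfig,
    default_templates,
    generate_dataset,
    random_background,
    simulate_expression,
)
from .temporal_clustering import ClusterAssignment

__all__ = [
    "bruteforce_scan",
    "enumerate_null_tail",
    "scanner_oracle_agreement",
    "pvalue_calibration",
    "permutation_oracle_errors",
    "null_zscore_calibration",
    "planted_enrichment_power",
    "clustering_recovery",
    "de_gate_calibration",
    "switch_concordance_experiment",
    "end_to_end_hashes",
]


# ---------------------------------------------------------------------------
# Independent oracles (plain-python paths, deliberately naive)


def bruteforce_scan(seq: str, scorer: MotifScorer, strand_policy: str = "sense_only"):
    """Naive per-offset scorer: python loops, no vectorisation.

    Independent of MotifScorer.scan's sliding-window path; used only as
    a test oracle.  Returns (offset, strand, score_int) tuples.
    """
    w = scorer.width
    codes = list(encode(seq))
    out = []
    if scorer.threshold_int is None:
        return out
    mats = [("+", scorer._s_int)]
    if strand_policy == "both":
        mats.append(("-", scorer._s_int_rc))
    for off in range(len(codes) - w + 1):
        window = codes[off : off + w]
        if 4 in window:
            continue
        for strand, mat in mats:
            s = sum(int(mat[i, window[i]]) for i in range(w))
            if s >= scorer.threshold_int:
                out.append((off + 1, strand, s))
    out.sort()
    return out


def enumerate_null_tail(scorer: MotifScorer) -> dict[int, float]:
    """Exhaustive 4^w word enumeration of the null score distribution.

    Returns the exact PMF over integer lattice scores; feasible for
    width <= 8.  Independent of the DP convolution.
    """
    w = scorer.width
    bg = scorer.background
    pmf: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(scorer._s_int[i, b] for i, b in enumerate(word)))
        p = float(np.prod([bg[b] for b in word]))
        pmf[s] = pmf.get(s, 0.0) + p
    return pmf


# ---------------------------------------------------------------------------
# Scanner experiments


def _random_pssm(rng: np.random.Generator, width: int, concentration: float = 0.5) -> PSSM:
    probs = rng.dirichlet([concentration] * 4, size=width)
    return PSSM(f"rand_w{width}", MotifClass.ENHANCER, probs)


def scanner_oracle_agreement(
    seed: int, n_random_seqs: int = 200, exhaustive_len: int = 5
) -> dict:
    """Scanner vs. brute force and DP null vs. word enumeration.

    Random panel: sequences of length 1..50 (with occasional N) scanned
    by random motifs of width 2..8 on one or both strands.  Exhaustive
    panel: every sequence of length `exhaustive_len` against a width-3
    motif.  Also compares the DP null PMF with exhaustive enumeration
    for widths 2..8 (total-variation distance).
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    cases = 0
    scorers = {}
    for width in range(2, 9):
        pssm = _random_pssm(rng, width)
        bg = rng.dirichlet([10.0] * 4)
        scorers[width] = MotifScorer(pssm, bg, p_threshold=1e-2)
    for _ in range(n_random_seqs):
        width = int(rng.integers(2, 9))
        scorer = scorers[width]
        L = int(rng.integers(1, 51))
        seq = random_background(L, rng)
        if rng.random() < 0.3 and L > 2:
            pos = rng.integers(0, L, size=max(1, L // 10))
            seq = "".join("N" if i in set(pos.tolist()) else c for i, c in enumerate(seq))
        policy = "both" if rng.random() < 0.5 else "sense_only"
        got = [(h.offset, h.strand, int(round(h.score / scorer.granularity)))
               for h in scorer.scan(seq, policy)]
        want = bruteforce_scan(seq, scorer, policy)
        cases += 1
        if sorted(got) != sorted(want):
            mismatches += 1
    scorer3 = scorers[3]
    for word in itertools.product("ACGT", repeat=exhaustive_len):
        seq = "".join(word)
        got = [(h.offset, h.strand, int(round(h.score / scorer3.granularity)))
               for h in scorer3.scan(seq, "both")]
        want = bruteforce_scan(seq, scorer3, "both")
        cases += 1
        if sorted(got) != sorted(want):
            mismatches += 1

    max_tv = 0.0
    for width, scorer in scorers.items():
        exact = enumerate_null_tail(scorer)
        dp = scorer.null
        support = set(exact) | {dp.base + i for i in range(len(dp.pmf)) if dp.pmf[i] > 0}
        tv = 0.5 * sum(
            abs(exact.get(s, 0.0) - (dp.pmf[s - dp.base] if 0 <= s - dp.base < len(dp.pmf) else 0.0))
            for s in support
        )
        max_tv = max(max_tv, tv)
    return {"cases": cases, "mismatches": mismatches, "max_tv": max_tv}


def pvalue_calibration(seed: int, length: int = 10_000_000) -> dict:
    """Empirical per-offset hit rate on i.i.d. background vs. DP tail mass."""
    from .synthetic_data import default_core_motifs

    rng = np.random.default_rng(seed)
    scorer = MotifScorer(default_core_motifs()[0])  # DRE, p<1e-4
    seq = random_background(length, rng)
    hits = scorer.scan(seq, "sense_only")
    n_offsets = length - scorer.width + 1
    rate = len(hits) / n_offsets
    expected = scorer.tail_mass
    se = float(np.sqrt(expected * (1 - expected) / n_offsets))
    return {
        "n_offsets": n_offsets, "hits": len(hits), "rate": rate,
        "expected": expected, "se": se,
        "deviation_se": (rate - expected) / se,
    }


# ---------------------------------------------------------------------------
# Permutation-statistic experiments


def _occ_from_array(counts: np.ndarray, window: str = "core") -> motif_scan.OccurrenceMatrix:
    counts = np.atleast_2d(counts)
    if counts.shape[0] == 1:
        counts = counts.T
    tids = [f"t{i:05d}" for i in range(counts.shape[0])]
    cols = pd.MultiIndex.from_tuples(
        [(window, f"m{j:03d}") for j in range(counts.shape[1])],
        names=["window", "motif"],
    )
    return motif_scan.OccurrenceMatrix(
        pd.DataFrame(counts, index=tids, columns=cols, dtype=int), 1e-4
    )


def _assignment_from_labels(labels: np.ndarray, tids: list[str]) -> ClusterAssignment:
    s = pd.Series(labels, index=tids)
    return ClusterAssignment(s, int(labels.max()), float("nan"))


def permutation_oracle_errors(seed: int, n_perm: int = 10_000) -> dict:
    """Permutation mean/sd vs. exact enumeration (tiny universe) and the
    closed-form finite-population formulas (larger fixture)."""
    # 6-transcript universe, cluster = the two 5-count transcripts
    counts = np.array([0, 0, 0, 0, 5, 5])
    occ = _occ_from_array(counts)
    labels = np.array([2, 2, 2, 2, 1, 1])
    assign = _assignment_from_labels(labels, list(occ.counts.index))
    table = enrichment_stats.permutation_enrichment(
        occ, assign, n_perm=n_perm, seed=seed
    )
    cell = table[(table.cluster == 1)].iloc[0]
    # exact null over all C(6,2)=15 pairs
    sums = [counts[i] + counts[j] for i, j in itertools.combinations(range(6), 2)]
    exact_mu = float(np.mean(sums))
    exact_sd = float(np.std(sums, ddof=0))
    mu_err_se = abs(cell.perm_mean - exact_mu) / (exact_sd / np.sqrt(n_perm))
    closed_mu, closed_var = enrichment_stats.exact_enrichment(counts, 2)

    # larger fixture: Poisson counts, closed form
    rng = np.random.default_rng(seed + 1)
    big = rng.poisson(1.0, size=500)
    occ2 = _occ_from_array(big)
    lab2 = np.full(500, 2)
    lab2[:50] = 1
    assign2 = _assignment_from_labels(lab2, list(occ2.counts.index))
    t2 = enrichment_stats.permutation_enrichment(occ2, assign2, n_perm=n_perm, seed=seed)
    c2 = t2[t2.cluster == 1].iloc[0]
    mu2, var2 = enrichment_stats.exact_enrichment(big, 50)
    return {
        "exact_mu": exact_mu, "exact_sd": exact_sd,
        "perm_mu": float(cell.perm_mean), "perm_sd": float(cell.perm_sd),
        "closed_mu": closed_mu, "closed_sd": float(np.sqrt(closed_var)),
        "mu_error_se": float(mu_err_se),
        "observed_is_max": bool(cell.observed == max(sums)),
        "big_perm_mu": float(c2.perm_mean), "big_closed_mu": mu2,
        "big_perm_sd": float(c2.perm_sd), "big_closed_sd": float(np.sqrt(var2)),
        "n_perm": n_perm,
    }


def null_zscore_calibration(
    seed: int,
    n_universe: int = 2000,
    n_clusters: int = 100,
    cluster_size: int = 20,
    n_motifs: int = 25,
    n_perm: int = 1000,
) -> dict:
    """Fraction of |z|>3 calls with i.i.d. counts and random clusters."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(1.0, size=(n_universe, n_motifs))
    occ = _occ_from_array(counts)
    labels = np.full(n_universe, n_clusters + 1)
    perm = rng.permutation(n_universe)
    for c in range(n_clusters):
        labels[perm[c * cluster_size : (c + 1) * cluster_size]] = c + 1
    # transcripts beyond the clustered ones form one remainder cluster
    assign = _assignment_from_labels(labels, list(occ.counts.index))
    table = enrichment_stats.permutation_enrichment(
        occ, assign, n_perm=n_perm, seed=seed + 1
    )
    table = table[table.cluster <= n_clusters]
    n_cells = len(table)
    n_calls = int((table.call != "ns").sum() - (table.call == "degenerate").sum())
    return {"cells": n_cells, "calls": n_calls, "fraction": n_calls / n_cells}


def planted_enrichment_power(
    seeds: range = range(20),
    n_universe: int = 2000,
    cluster_size: int = 200,
    n_motifs: int = 10,
    p_background: float = 0.1,
    odds_ratio: float = 3.0,
    n_perm: int = 1000,
) -> dict:
    """Power to call a motif planted at `odds_ratio` x insertion odds in
    one cluster, and the false-call rate on unplanted motifs."""
    odds = p_background / (1 - p_background) * odds_ratio
    p_planted = odds / (1 + odds)
    n_clusters = n_universe // cluster_size
    detected = 0
    false_calls = 0
    false_cells = 0
    for seed in seeds:
        rng = np.random.default_rng(1000 + seed)
        counts = (rng.random((n_universe, n_motifs)) < p_background).astype(int)
        counts[:cluster_size, 0] = (
            rng.random(cluster_size) < p_planted
        ).astype(int)
        occ = _occ_from_array(counts)
        labels = np.repeat(np.arange(1, n_clusters + 1), cluster_size)
        assign = _assignment_from_labels(labels, list(occ.counts.index))
        table = enrichment_stats.permutation_enrichment(
            occ, assign, n_perm=n_perm, seed=2000 + seed
        )
        planted = table[(table.cluster == 1) & (table.motif == "m000")]
        if (planted.call == "enriched").all():
            detected += 1
        unplanted = table[table.motif != "m000"]
        false_cells += len(unplanted)
        false_calls += int((unplanted.call != "ns").sum())
    return {
        "seeds": len(list(seeds)),
        "power": detected / len(list(seeds)),
        "false_call_rate": false_calls / false_cells,
        "p_planted": p_planted,
    }


# ---------------------------------------------------------------------------
# Clustering / DE experiments


def clustering_recovery(
    seed: int,
    n_templates: int = 30,
    per_template: int = 60,
    noise_sd: float = 0.3,
    amplitude: float = 2.0,
) -> dict:
    """ARI of k-means vs. planted templates + estimate_k on a 5-template toy."""
    rng = np.random.default_rng(seed)
    templates = default_templates(n_templates, amplitude)
    assignment = {
        f"t{i:05d}": i % n_templates for i in range(n_templates * per_template)
    }
    expr = simulate_expression(templates, assignment, noise_sd, 4, rng)
    profiles = expr.replicate_means()
    result = temporal_clustering.kmeans_cluster(profiles, k=n_templates, seed=seed)
    truth_labels = [assignment[t] for t in profiles.index]
    ari = adjusted_rand_score(truth_labels, result.labels.to_numpy())

    toy_templates = templates[[0, 12, 20, 24, 27]]
    toy_assign = {f"s{i:04d}": i % 5 for i in range(400)}
    toy = simulate_expression(toy_templates, toy_assign, noise_sd, 4, rng)
    _, recommended = temporal_clustering.estimate_k(
        toy.replicate_means(), range(2, 11), seed=seed
    )
    return {"ari": float(ari), "k_true_toy": 5, "k_recommended_toy": recommended}


def de_gate_calibration(seed: int, n_transcripts: int = 2000) -> dict:
    """Null selection rate on pure noise and recall on zero-noise signal."""
    rng = np.random.default_rng(seed)
    flat = np.zeros((1, 5))
    null_assign = {f"n{i:05d}": 0 for i in range(n_transcripts)}
    null_expr = simulate_expression(flat, null_assign, 0.3, 4, rng)
    null_rate = len(diffexpr.select_de(null_expr)) / n_transcripts

    templates = default_templates(30, 2.0)
    assign = {f"s{i:05d}": i % 30 for i in range(600)}
    clean = simulate_expression(templates, assign, 0.0, 4, rng)
    recall = len(diffexpr.select_de(clean)) / 600
    return {"null_selected_fraction": null_rate, "zero_noise_recall": recall}


# ---------------------------------------------------------------------------
# Promoter-switch concordance


def switch_concordance_experiment(
    seed: int,
    n_genes: int = 1000,
    association_strength: float = 1.0,
    workdir: str | Path | None = None,
    n_perm: int = 1000,
    k: int = 30,
    n_restarts: int = 10,
) -> dict:
    """Generate a study, run DE -> clustering -> core scan -> enrichment ->
    concordance, and score it against the designated switch genes.

    Planting is clean (consensus instances, always recoverable by the
    scan), so the promoter-type/cluster association itself — not
    instance-sampling noise — is what the experiment measures.  Only the
    core window is scanned (the enhancer window does not enter the
    promoter-type analysis), which keeps the experiment fast.
    """
    tmp = None
    if workdir is None:
        tmp = tempfile.TemporaryDirectory()
        workdir = tmp.name
    try:
        cfg = SyntheticConfig(
            seed=seed, n_genes=n_genes, association_strength=association_strength,
            clean_planting=True,
        )
        paths, truth = generate_dataset(cfg, workdir)
        transcripts = read_tss_table(paths["tss"])
        sequences = read_fasta(paths["sequences"])
        core = read_pssm_set(paths["core_motifs"], MotifClass.CORE_PROMOTER)
        expr = read_expression(paths["expression"])

        de = diffexpr.select_de(expr)
        profiles = expr.subset(de.selected).replicate_means()
        assign = temporal_clustering.kmeans_cluster(
            profiles, k=k, seed=stage_seed(seed, "cluster"), n_restarts=n_restarts
        )
        occ, _hits = motif_scan.scan_promoters(
            sequences, transcripts, {"core": core}
        )
        enrichment = enrichment_stats.permutation_enrichment(
            occ, assign, n_perm=n_perm, seed=stage_seed(seed, "enrichment")
        )
        calls = promoter_switch.classify_tss(occ)
        reports = promoter_switch.find_switch_genes(transcripts, calls)
        detail = promoter_switch.concordance(reports, assign, enrichment)

        designated = detail[detail.gene_id.isin(truth.switch_genes)]
        sep = designated.dropna(subset=["gene_tss_separated"]).groupby("gene_id")[
            "gene_tss_separated"
        ].first()
        all_summary = promoter_switch.concordance_summary(detail)
        return {
            "association_strength": association_strength,
            "n_designated_genes": int(designated.gene_id.nunique()),
            "designated_transcripts": int(len(designated)),
            "designated_concordance": (
                float(designated.concordant.mean()) if len(designated) else float("nan")
            ),
            "designated_separated_fraction": (
                float(sep.mean()) if len(sep) else float("nan")
            ),
            "all_concordance": all_summary["fraction"],
        }
    finally:
        if tmp is not None:
            tmp.cleanup()


# ---------------------------------------------------------------------------
# End-to-end determinism


def end_to_end_hashes(
    seed: int, outdir: str | Path, n_genes: int = 2000
) -> dict[str, str]:
    """Generate the default study and run the full pipeline; return the
    content hashes of every output file (inputs and results)."""
    import hashlib

    outdir = Path(outdir)
    datadir = outdir / "data"
    cfg = SyntheticConfig(seed=seed, n_genes=n_genes)
    paths, _truth = generate_dataset(cfg, datadir)
    rc = RunConfig(
        tss=str(paths["tss"]),
        sequences=str(paths["sequences"]),
        core_motifs=str(paths["core_motifs"]),
        enhancer_motifs=str(paths["enhancer_motifs"]),
        expression=str(paths["expression"]),
        go=str(paths["go"]),
        targets=str(paths["targets"]),
        outdir=str(outdir / "run"),
        seed=seed,
    )
    report = run_pipeline(rc)
    hashes = dict(report.hashes)
    for name, p in paths.items():
        hashes[f"input:{name}"] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    return hashes
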