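"""Cluster-level enrichment statistics.

Two machineries:

* the permutation-null motif enrichment z-score — for each cluster of
  size n, 1000 random clusters of n transcripts are drawn without
  replacement from the analysis universe; each motif's occurrence sum
  over the random cluster forms the null, and
  z = (observed - mean) / sd  with |z| > 3 called enriched/depleted.
  One shared set of random clusters per real cluster is scored against
  all motifs, so z-scores are comparable across motifs.

* hypergeometric upper-tail tests — GO-term enrichment per cluster
  (headline term reported only below p < 1e-5) and overlap validation
  against published target-gene sets (significant below p < 0.05).

`exact_enrichment` gives the closed-form finite-population mean and
variance of the without-replacement sum, the independent oracle for
the permutation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection
from .motif_scan import OccurrenceMatrix
from .temporal_clustering import ClusterAssignment

__all__ = [
    "EnrichmentCell",
    "HypergeomInput",
    "permutation_enrichment",
    "exact_enrichment",
    "hypergeom_upper_tail",
    "go_enrichment",
    "overlap_validation",
]


@dataclass(frozen=True)
class HypergeomInput:
    """N genes in the population, B annotated; n drawn, b annotated in the draw."""

    N: int
    B: int
    n: int
    b: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.b <= min(self.B, self.n)
            and self.n <= self.N
            and self.B <= self.N
        )
        if not ok:
            raise ValueError(f"invalid hypergeometric input {self}")


def hypergeom_upper_tail(h: HypergeomInput) -> float:
    """P(X >= b) for X ~ Hypergeometric(N, B, n)."""
    if h.b == 0:
        return 1.0
    return float(stats.hypergeom.sf(h.b - 1, h.N, h.B, h.n))


# ---------------------------------------------------------------------------
# Permutation-null motif enrichment


def exact_enrichment(
    counts: np.ndarray | pd.Series, n: int
) -> tuple[float, float]:
    """Closed-form mean and variance of an n-sample without-replacement sum.

    mean = n * mbar;  var = n * (N-n)/(N-1) * population variance.
    """
    x = np.asarray(counts, dtype=float)
    N = len(x)
    if not 1 <= n <= N:
        raise ValueError(f"cluster size {n} outside universe of {N}")
    mean = n * x.mean()
    if N == 1:
        return mean, 0.0
    pop_var = x.var(ddof=0)
    var = n * (N - n) / (N - 1) * pop_var
    return float(mean), float(var)


def permutation_enrichment(
    occ: OccurrenceMatrix,
    assignment: ClusterAssignment,
    universe: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Permutation z-score per (cluster, window, motif).

    Universe defaults to the clustered transcript set.  For each real
    cluster of size n, `n_perm` random size-n clusters are drawn without
    replacement from the universe; their occurrence sums give the null
    mean and sd (sample sd, n_perm-1 denominator).  sd = 0 cells are
    degenerate and reported with z = 0.

    Columns: cluster, window, motif, n, observed, perm_mean, perm_sd,
    z, call (enriched / depleted / ns / degenerate).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if universe is None:
        universe = list(assignment.labels.index)
    universe = list(universe)
    missing = set(assignment.labels.index) - set(universe)
    if missing:
        raise ValueError(
            f"{len(missing)} cluster members outside the permutation universe"
        )
    counts = occ.counts.loc[universe]
    mat = counts.to_numpy(dtype=np.int64)  # (|U|, n_features)
    n_universe = len(universe)
    rng = np.random.default_rng(seed)

    rows = []
    feature_cols = list(counts.columns)
    pos = {t: i for i, t in enumerate(universe)}
    for label in range(1, assignment.k + 1):
        members = assignment.members(label)
        n = len(members)
        if n > n_universe:
            raise ValueError(f"cluster {label} larger than the universe")
        observed = mat[[pos[t] for t in members]].sum(axis=0)
        # one shared draw set across all motifs/windows for this cluster
        perm_sums = np.empty((n_perm, mat.shape[1]), dtype=np.int64)
        for p in range(n_perm):
            idx = rng.choice(n_universe, size=n, replace=False)
            perm_sums[p] = mat[idx].sum(axis=0)
        mu = perm_sums.mean(axis=0)
        sd = perm_sums.std(axis=0, ddof=1)
        for f, (window, motif) in enumerate(feature_cols):
            if sd[f] == 0:
                z, call = 0.0, "degenerate"
            else:
                z = (observed[f] - mu[f]) / sd[f]
                call = (
                    "enriched"
                    if z > z_threshold
                    else "depleted" if z < -z_threshold else "ns"
                )
            rows.append(
                (label, window, motif, n, int(observed[f]), mu[f], sd[f], z, call)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "window", "motif", "n",
            "observed", "perm_mean", "perm_sd", "z", "call",
        ],
    )


def enriched_motifs(
    enrichment: pd.DataFrame, cluster: int, window: str = "core"
) -> set[str]:
    """Motifs called enriched for one cluster in one window."""
    sel = (
        (enrichment["cluster"] == cluster)
        & (enrichment["window"] == window)
        & (enrichment["call"] == "enriched")
    )
    return set(enrichment.loc[sel, "motif"])


# ---------------------------------------------------------------------------
# Gene-set tests (gene-level: transcript ids are collapsed on their gene)


def _gene_of(transcript_id: str) -> str:
    return transcript_id.rsplit("-", 1)[0] if "-" in transcript_id else transcript_id


def go_enrichment(
    assignment: ClusterAssignment,
    annotations: GeneSetCollection,
    report_threshold: float = 1e-5,
    gene_of: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[int, str | None]]:
    """Hypergeometric GO enrichment per (cluster, term) at gene level.

    The universe is every gene carrying >= 1 annotation in the GMT.
    Returns the full table and, per cluster, the minimum-p headline
    term — reported only when its p is below `report_threshold`
    (no multiple-testing correction beyond that display rule).
    """
    to_gene = (
        (lambda t: gene_of[t]) if gene_of is not None else _gene_of
    )
    universe: set[str] = set()
    for name in annotations:
        universe |= annotations[name]
    N = len(universe)

    cluster_genes = {
        label: {to_gene(t) for t in assignment.members(label)} & universe
        for label in range(1, assignment.k + 1)
    }
    rows = []
    headlines: dict[int, str | None] = {}
    for label in range(1, assignment.k + 1):
        genes = cluster_genes[label]
        n = len(genes)
        best_p, best_term = np.inf, None
        for term in annotations:
            members = annotations[term] & universe
            B = len(members)
            b = len(genes & members)
            p = hypergeom_upper_tail(HypergeomInput(N, B, n, b)) if n else np.nan
            rows.append((label, term, N, B, n, b, p))
            if n and b and p < best_p:
                best_p, best_term = p, term
        headlines[label] = best_term if best_p < report_threshold else None
    table = pd.DataFrame(
        rows, columns=["cluster", "term", "N", "B", "n", "b", "p"]
    )
    return table, headlines


def overlap_validation(
    cluster_genes: set[str],
    published: set[str],
    platform_universe: set[str],
    dataset_genes: set[str] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Hypergeometric overlap with a published target set.

    N = platform size; B = published genes also on the platform (and in
    the dataset when given); n = cluster genes with data in the
    published comparison; b = their overlap with the validated set.
    An empty restricted cluster leaves p undefined (NaN, flagged).
    """
    shared = published & platform_universe
    if dataset_genes is not None:
        shared &= dataset_genes
    restricted = cluster_genes & platform_universe
    b = len(restricted & shared)
    n = len(restricted)
    N = len(platform_universe)
    B = len(shared)
    if n == 0:
        return {
            "N": N, "B": B, "n": 0, "b": 0,
            "p": float("nan"), "significant": False, "undefined": True,
        }
    p = hypergeom_upper_tail(HypergeomInput(N, B, n, b))
    return {
        "N": N, "B": B, "n": n, "b": b,
        "p": p, "significant": bool(p < alpha), "undefined": False,
    }
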