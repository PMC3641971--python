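"""k-means temporal clustering of DE transcripts and cluster reporting.

Clustering operates on per-transcript replicate-mean log2 ratios per
time point (raw amplitude, not display-normalised) with Euclidean
distance, k-means++ initialisation and multiple restarts; the default
k=30 can be sanity-checked against a silhouette sweep over k=26..40.
Cluster labels are 1..k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io_formats import ExpressionMatrix

__all__ = [
    "ClusterAssignment",
    "ClusterProfile",
    "kmeans_cluster",
    "estimate_k",
    "cluster_profiles",
    "normalize_for_display",
    "hierarchical_order",
]


@dataclass
class ClusterAssignment:
    labels: pd.Series  # transcript_id -> label in 1..k
    k: int
    inertia: float

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class ClusterProfile:
    label: int
    mean_profile: pd.Series  # per-time-point mean log2 ratio
    n: int  # member count; the permutation test's 'n'


def kmeans_cluster(
    profiles: pd.DataFrame,
    k: int = 30,
    seed: int = 0,
    n_restarts: int = 20,
) -> ClusterAssignment:
    """Best-inertia k-means over `n_restarts` k-means++ starts; labels 1..k.

    scikit-learn's k-means relocates empty clusters during Lloyd
    iterations, so no returned cluster is ever empty.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds {len(profiles)} transcripts")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(profiles.to_numpy())
    labels = pd.Series(raw + 1, index=profiles.index, name="cluster")
    return ClusterAssignment(labels, k, float(km.inertia_))


def estimate_k(
    profiles: pd.DataFrame,
    k_range: range = range(26, 41),
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[pd.DataFrame, int | None]:
    """Mean-silhouette sweep over k; the argmax is recommended, never applied.

    Returns (table with columns k/silhouette/inertia, recommended k).
    All-identical profiles make the silhouette undefined: the table is
    returned with NaNs and no recommendation.
    """
    X = profiles.to_numpy()
    if np.allclose(X, X[0]):
        table = pd.DataFrame(
            {"k": list(k_range), "silhouette": np.nan, "inertia": np.nan}
        )
        return table, None
    rows = []
    for k in k_range:
        if k < 2 or k > len(profiles) - 1:
            rows.append((k, np.nan, np.nan))
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(X)
        sil = silhouette_score(X, lab, metric="euclidean")
        rows.append((k, sil, float(km.inertia_)))
    table = pd.DataFrame(rows, columns=["k", "silhouette", "inertia"])
    if table["silhouette"].notna().any():
        best = int(table.loc[table["silhouette"].idxmax(), "k"])
    else:
        best = None
    return table, best


def cluster_profiles(
    assignment: ClusterAssignment, expr: ExpressionMatrix
) -> list[ClusterProfile]:
    """Per-cluster per-time-point mean log2 ratios over member transcripts."""
    means = expr.replicate_means().loc[assignment.labels.index]
    out = []
    for label in range(1, assignment.k + 1):
        members = assignment.labels == label
        out.append(
            ClusterProfile(label, means[members.to_numpy()].mean(axis=0), int(members.sum()))
        )
    return out


def normalize_for_display(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript division by max |log2 ratio|, bounding rows to [-1, 1].

    Display only; all statistics use raw values.  All-zero rows stay zero.
    """
    scale = profiles.abs().max(axis=1).replace(0.0, 1.0)
    return profiles.div(scale, axis=0)


def hierarchical_order(profiles: list[ClusterProfile]) -> list[int]:
    """Average-linkage Euclidean dendrogram leaf order over cluster means."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 clusters to order")
    X = np.stack([p.mean_profile.to_numpy() for p in profiles])
    Z = linkage(X, method="average", metric="euclidean")
    return [profiles[i].label for i in leaves_list(Z)]
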