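"""Differential-expression gate feeding the temporal clustering.

A transcript enters the clustered set when (1) a one-way ANOVA across
time-point groups on its log2 ratios is significant after multiple-
testing adjustment (default Benjamini-Hochberg, alpha 0.05) and (2) its
replicate-mean log2 ratio exceeds the fold-change gate (default
1.5-fold, i.e. |log2| > log2(1.5)) at one or more time points relative
to the common reference sample.  The reference sits implicitly at log2
ratio 0 and is not itself an ANOVA group.  Either gate can be switched
off independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = ["DEResult", "anova_per_transcript", "adjust_pvalues", "select_de"]

_EPS = 1e-12


@dataclass
class DEResult:
    """Full per-transcript DE table plus the selected transcript list."""

    table: pd.DataFrame  # F, p_value, adjusted_p, max_abs_log2fc, de_flag, degenerate
    selected: list[str]

    def __len__(self) -> int:
        return len(self.selected)


def anova_per_transcript(expr: ExpressionMatrix) -> pd.DataFrame:
    """Vectorised one-way ANOVA across time points for every transcript.

    Degenerate transcripts (zero variance everywhere) get p=1 with a
    flag; zero within-group variance with real between-group spread
    gives F=inf, p=0.
    """
    groups = expr.groups()  # list of (n_transcripts, reps)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 time-point groups")
    if any(g.shape[1] < 2 for g in groups):
        raise ValueError("ANOVA needs at least 2 replicates per group")
    k = len(groups)
    all_vals = np.concatenate(groups, axis=1)  # (n, k*reps)
    n_total = all_vals.shape[1]
    grand = all_vals.mean(axis=1)
    ss_total = ((all_vals - grand[:, None]) ** 2).sum(axis=1)
    group_means = np.stack([g.mean(axis=1) for g in groups], axis=1)
    group_ns = np.array([g.shape[1] for g in groups])
    ss_between = (group_ns[None, :] * (group_means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = ss_total - ss_between
    df_between = k - 1
    df_within = n_total - k
    msb = ss_between / df_between
    msw = ss_within / df_within

    degenerate = ss_total < _EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    p = np.empty(len(F))
    finite = msw > _EPS
    p[finite] = stats.f.sf(F[finite], df_between, df_within)
    # zero within-group variance: F -> inf unless between is zero too
    p[~finite] = 0.0
    F[~finite & ~degenerate] = np.inf
    p[degenerate] = 1.0
    F[degenerate] = 0.0
    return pd.DataFrame(
        {"F": F, "p_value": p, "degenerate": degenerate},
        index=expr.transcript_ids,
    )


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment; BH step-up by default, Bonferroni optional."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def select_de(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    adjust_method: str = "BH",
    use_anova_gate: bool = True,
    use_fold_gate: bool = True,
) -> DEResult:
    """Apply the ANOVA and fold-change gates; both must pass by default."""
    anova = anova_per_transcript(expr)
    adjusted = adjust_pvalues(anova["p_value"].to_numpy(), adjust_method)
    means = expr.replicate_means()
    max_abs = means.abs().max(axis=1).to_numpy()

    pass_anova = (adjusted < alpha) if use_anova_gate else np.ones(len(anova), bool)
    log_fc = np.log2(fc_threshold)
    pass_fold = (max_abs > log_fc) if use_fold_gate else np.ones(len(anova), bool)
    de_flag = pass_anova & pass_fold

    table = anova.assign(
        adjusted_p=adjusted, max_abs_log2fc=max_abs, de_flag=de_flag
    )
    selected = list(table.index[de_flag])
    return DEResult(table, selected)
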