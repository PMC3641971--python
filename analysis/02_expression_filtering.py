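#!/usr/bin/env python
"""Differential-expression gate: one-way ANOVA across time points
(BH-adjusted p < 0.05) combined with the >1.5-fold change gate at one
or more time points vs. the reference.

Reads results/study/expression.tsv; writes results/analysis/de_table.tsv.
"""

from pathlib import Path

import numpy as np

from promoshift.diffexpr import select_de
from promoshift.io_formats import read_expression

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    expr = read_expression(ROOT / "results/study/expression.tsv")
    res = select_de(expr, alpha=0.05, fc_threshold=1.5)
    out = ROOT / "results/analysis"
    out.mkdir(parents=True, exist_ok=True)
    res.table.rename_axis("transcript_id").to_csv(
        out / "de_table.tsv", sep="\t", float_format="%.6g"
    )
    n = expr.n_transcripts
    print(f"tested {n} transcripts across {len(expr.time_points)} time points")
    print(f"  ANOVA gate (BH p<0.05):    {(res.table.adjusted_p < 0.05).sum()}")
    print(f"  fold gate (>1.5x, log2>{np.log2(1.5):.3f}): "
          f"{(res.table.max_abs_log2fc > np.log2(1.5)).sum()}")
    print(f"  selected (both gates):     {len(res)} ({len(res) / n:.0%})")


if __name__ == "__main__":
    main()
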