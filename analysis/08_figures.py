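#!/usr/bin/env python
"""Render the cluster-profile heat map and the per-window enrichment
dot matrices (red = enriched, green = depleted, grey x = degenerate)
from the tables written by the earlier steps.
"""

from pathlib import Path

from promoshift.pipeline import make_figures

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    for p in make_figures(ROOT / "results/analysis"):
        print(f"wrote {p}")


if __name__ == "__main__":
    main()
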