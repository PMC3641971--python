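#!/usr/bin/env python
"""Calibration and recovery benchmarks on data with known truth:
scanner vs. brute force, DP p-value calibration on 10 Mb, permutation
statistics vs. exact enumeration, null |z|>3 rate, planted-enrichment
power, clustering recovery, DE-gate calibration, and switch-concordance
behaviour as a function of association strength.

Writes results/analysis/benchmarks.json.
"""

import json
from pathlib import Path

import numpy as np

from promoshift import experiments as ex

ROOT = Path(__file__).resolve().parent.parent
SEED = 1


def main() -> None:
    out = ROOT / "results/analysis"
    out.mkdir(parents=True, exist_ok=True)
    bench: dict = {}

    sc = ex.scanner_oracle_agreement(SEED)
    print(f"scanner vs brute force: {sc['mismatches']}/{sc['cases']} mismatches; "
          f"DP-vs-enumeration TV {sc['max_tv']:.2e}")
    bench["scanner"] = sc

    cal = ex.pvalue_calibration(SEED)
    print(f"p-value calibration (10 Mb): rate {cal['rate']:.3e} vs "
          f"expected {cal['expected']:.3e} ({cal['deviation_se']:+.2f} SE)")
    bench["calibration"] = cal

    po = ex.permutation_oracle_errors(SEED)
    print(f"permutation vs exact: mu {po['perm_mu']:.3f} (exact {po['exact_mu']:.3f}), "
          f"sd {po['perm_sd']:.3f} (exact {po['exact_sd']:.3f})")
    bench["permutation_oracle"] = po

    nz = ex.null_zscore_calibration(SEED)
    print(f"null |z|>3 rate: {nz['fraction']:.4f} over {nz['cells']} cells "
          f"(nominal ~0.0027)")
    bench["null_z"] = nz

    pw = ex.planted_enrichment_power(range(20))
    print(f"planted 3x-odds power: {pw['power']:.2f}; "
          f"false-call rate {pw['false_call_rate']:.4f}")
    bench["power"] = pw

    cl = ex.clustering_recovery(SEED)
    print(f"clustering ARI (30 templates, noise 0.3): {cl['ari']:.3f}; "
          f"estimate_k toy: {cl['k_recommended_toy']} (true 5)")
    bench["clustering"] = cl

    de = ex.de_gate_calibration(SEED)
    print(f"DE gate: null rate {de['null_selected_fraction']:.4f}, "
          f"zero-noise recall {de['zero_noise_recall']:.2f}")
    bench["de"] = de

    sweep = []
    for s in (0.0, 0.5, 1.0):
        vals = [
            ex.switch_concordance_experiment(
                seed=100 + i, n_genes=400, association_strength=s
            )["designated_concordance"]
            for i in range(5)
        ]
        sweep.append({"strength": s, "mean_concordance": float(np.nanmean(vals))})
        print(f"switch concordance @ strength {s}: {sweep[-1]['mean_concordance']:.3f}")
    bench["switch_sweep"] = sweep

    (out / "benchmarks.json").write_text(json.dumps(bench, indent=1, default=float))
    print(f"written {out / 'benchmarks.json'}")


if __name__ == "__main__":
    main()
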