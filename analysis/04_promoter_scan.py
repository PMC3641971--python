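#!/usr/bin/env python
"""Calibrated PSSM scan (p < 1e-4) of the two promoter windows: the ten
core motifs across -60..+40 (sense strand) and the enhancer motifs
across -1000..-1 (both strands).

Reads results/study/; writes occurrences.tsv and hits.tsv.
"""

from pathlib import Path

from promoshift.io_formats import (
    MotifClass,
    read_fasta,
    read_pssm_set,
    read_tss_table,
)
from promoshift.motif_scan import hits_to_frame, scan_promoters

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    study = ROOT / "results/study"
    out = ROOT / "results/analysis"
    core = read_pssm_set(study / "core_motifs.meme", MotifClass.CORE_PROMOTER)
    enh = read_pssm_set(study / "enhancer_motifs.meme", MotifClass.ENHANCER)
    transcripts = read_tss_table(study / "tss.bed")
    sequences = read_fasta(study / "promoters.fa")

    occ, hits = scan_promoters(
        sequences, transcripts, {"core": core, "enhancer": enh}
    )
    occ.counts.to_csv(out / "occurrences.tsv", sep="\t")
    hits_to_frame(hits).to_csv(out / "hits.tsv", sep="\t", index=False,
                               float_format="%.6g")

    core_hits = sum(1 for h in hits if h.window == "core")
    print(f"scanned {len(transcripts)} promoters with "
          f"{len(core)} core + {len(enh)} enhancer motifs at p<1e-4")
    print(f"  hits: {core_hits} core / {len(hits) - core_hits} enhancer")
    print(f"  transcripts with >=1 core-motif hit: "
          f"{(occ.window('core').sum(axis=1) > 0).sum()}")


if __name__ == "__main__":
    main()
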