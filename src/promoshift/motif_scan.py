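"""PSSM scanning with exact null-distribution p-value calibration.

A motif match is reported wherever the log-odds score of the window
against a 0-order background meets a threshold chosen so that the
probability of a random background word scoring at least as high is
below ``p_threshold`` (FIMO-style semantics, default p < 1e-4).

The null distribution of the score of a single random background word
is computed exactly by dynamic programming: per-position scores are
discretized to a fixed granularity (default 1/1000 bit) and the
per-position score PMFs are convolved under the background.  Scanning
uses the *same* discretized scores, so the empirical per-offset hit
rate on i.i.d. background sequence equals the DP tail mass at the
threshold exactly, in expectation.

Scores are log2 odds; -inf entries (zero probability at pseudocount 0)
are capped at -100 bits so the DP stays finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import BASES, PSSM, TranscriptRecord

__all__ = [
    "ScanWindow",
    "CORE_WINDOW",
    "ENHANCER_WINDOW",
    "MotifHit",
    "OccurrenceMatrix",
    "MotifScorer",
    "log_odds_matrix",
    "null_distribution",
    "score_threshold",
    "extract_window",
    "scan_sequence",
    "count_occurrences",
    "scan_promoters",
    "TruncatedWindowWarning",
    "UnreachableThresholdWarning",
]

NEG_INF_CAP = -100.0  # bits
_N_CODE = 4

_CODE = np.full(256, _N_CODE, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class TruncatedWindowWarning(UserWarning):
    pass


class UnreachableThresholdWarning(UserWarning):
    pass


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0 C=1 G=2 T=3, anything else -> N."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanWindow:
    """A promoter window relative to the TSS (+1; no position 0 exists).

    core = -60..+40 (100 bases), enhancer = -1000..-1 (1000 bases).
    """

    kind: str
    rel_start: int = -60
    rel_end: int = 40
    strand_policy: str = "sense_only"

    def __post_init__(self) -> None:
        if self.rel_start == 0 or self.rel_end == 0:
            raise ValueError("position 0 does not exist in promoter coordinates")
        if self.rel_start >= self.rel_end:
            raise ValueError("rel_start must precede rel_end")
        if self.strand_policy not in ("sense_only", "both"):
            raise ValueError(f"unknown strand policy {self.strand_policy!r}")

    @property
    def length(self) -> int:
        span = self.rel_end - self.rel_start + 1
        if self.rel_start < 0 < self.rel_end:
            span -= 1  # the nonexistent position 0
        return span


CORE_WINDOW = ScanWindow("core", -60, 40, "sense_only")
ENHANCER_WINDOW = ScanWindow("enhancer", -1000, -1, "both")


@dataclass(frozen=True)
class MotifHit:
    transcript_id: str
    window: str
    motif_id: str
    offset: int  # 1-based within the window, leftmost base on the scanned strand
    strand: str  # '+' sense match, '-' reverse-complement match
    score: float  # log2 odds, discretized lattice
    p_value: float


@dataclass
class OccurrenceMatrix:
    """Per-transcript motif occurrence counts: transcripts x (window, motif)."""

    counts: pd.DataFrame  # index transcript_id, columns MultiIndex (window, motif)
    threshold_p: float

    def window(self, kind: str) -> pd.DataFrame:
        """Counts for one window kind: transcripts x motifs."""
        return self.counts.xs(kind, axis=1, level=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


# ---------------------------------------------------------------------------
# Scoring


def log_odds_matrix(
    pssm: PSSM,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.001,
) -> np.ndarray:
    """Log2-odds score matrix: score(i,b) = log2((p_ib + c*bg_b)/((1+c)*bg_b)).

    Zero-probability entries at pseudocount 0 would be -inf; they are
    capped at -100 bits.
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 strictly positive frequencies")
    if abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    with np.errstate(divide="ignore"):
        scores = np.log2(
            (pssm.probs + pseudocount * bg) / ((1.0 + pseudocount) * bg)
        )
    return np.maximum(scores, NEG_INF_CAP)


def _discretize(score_matrix: np.ndarray, granularity: float) -> np.ndarray:
    return np.rint(np.asarray(score_matrix, dtype=float) / granularity).astype(np.int64)


@dataclass
class NullDistribution:
    """Exact PMF of the discretized score of one random background word."""

    base: int  # integer score of pmf[0]
    pmf: np.ndarray
    granularity: float
    _tail: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # P(score >= s) for s on the integer lattice
        self._tail = np.cumsum(self.pmf[::-1])[::-1]

    def tail_int(self, score_int: int) -> float:
        """P(score >= score_int) over a single random background word."""
        idx = score_int - self.base
        if idx <= 0:
            return 1.0
        if idx >= len(self.pmf):
            return 0.0
        return float(self._tail[idx])

    def tail(self, score: float) -> float:
        return self.tail_int(int(np.rint(score / self.granularity)))

    @property
    def max_score_int(self) -> int:
        return self.base + len(self.pmf) - 1


def null_distribution(
    score_matrix: np.ndarray,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    granularity: float = 1e-3,
) -> NullDistribution:
    """Convolve per-position score PMFs under the background (exact DP)."""
    bg = np.asarray(background, dtype=float)
    s_int = _discretize(score_matrix, granularity)
    pmf = np.ones(1)
    base = 0
    for row in s_int:
        lo, hi = int(row.min()), int(row.max())
        new = np.zeros(len(pmf) + hi - lo)
        for b in range(4):
            shift = int(row[b]) - lo
            new[shift : shift + len(pmf)] += bg[b] * pmf
        pmf = new
        base += lo
    return NullDistribution(base, pmf, granularity)


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float  # in bits on the lattice; +inf when no word can pass
    threshold_int: int | None
    tail_mass: float  # P(score >= threshold) under the null; 0 when unreachable
    null: NullDistribution


def score_threshold(
    score_matrix: np.ndarray,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    p_threshold: float = 1e-4,
    granularity: float = 1e-3,
) -> ThresholdResult:
    """Smallest score s with P(score >= s) <= p_threshold under the null.

    When even the single best word exceeds p_threshold (short motifs),
    no hit is possible: threshold is +inf and a warning is issued.
    """
    null = null_distribution(score_matrix, background, granularity)
    tails = null._tail
    passing = np.nonzero(tails <= p_threshold)[0]
    if len(passing) == 0:
        warnings.warn(
            f"p_threshold={p_threshold:g} unreachable for this motif "
            f"(best word tail mass {tails[-1]:.3g}); no hit possible",
            UnreachableThresholdWarning,
            stacklevel=2,
        )
        return ThresholdResult(np.inf, None, 0.0, null)
    idx = int(passing[0])
    threshold_int = null.base + idx
    return ThresholdResult(
        threshold_int * granularity, threshold_int, float(tails[idx]), null
    )


class MotifScorer:
    """Bundles log-odds matrix, exact null, and calibrated threshold for one PSSM."""

    def __init__(
        self,
        pssm: PSSM,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        p_threshold: float = 1e-4,
        pseudocount: float = 0.001,
        granularity: float = 1e-3,
    ):
        self.pssm = pssm
        self.background = np.asarray(background, dtype=float)
        self.p_threshold = p_threshold
        self.granularity = granularity
        self.score_matrix = log_odds_matrix(pssm, background, pseudocount)
        self._s_int = _discretize(self.score_matrix, granularity)
        thr = score_threshold(self.score_matrix, background, p_threshold, granularity)
        self.threshold = thr.threshold
        self.threshold_int = thr.threshold_int
        self.tail_mass = thr.tail_mass
        self.null = thr.null
        # reverse-complement read: reversed positions, complemented bases
        self._s_int_rc = self._s_int[::-1, ::-1].copy()

    @property
    def width(self) -> int:
        return self.pssm.width

    def _offset_scores(self, codes: np.ndarray, s_int: np.ndarray) -> np.ndarray:
        """Integer score at every offset; offsets covering an N get -2^62."""
        w = self.width
        n_off = len(codes) - w + 1
        if n_off <= 0:
            return np.empty(0, dtype=np.int64)
        win = np.lib.stride_tricks.sliding_window_view(codes, w)
        has_n = (win == _N_CODE).any(axis=1)
        safe = np.where(win == _N_CODE, 0, win)
        scores = s_int[np.arange(w)[None, :], safe].sum(axis=1)
        scores[has_n] = np.int64(-(2**62))
        return scores

    def scan(
        self,
        seq: str,
        strand_policy: str = "sense_only",
        transcript_id: str = "",
        window: str = "",
    ) -> list[MotifHit]:
        """All offsets whose (discretized) score meets the threshold.

        Under ``both``, the reverse-complement read at each offset is
        scored too and reported with strand '-' at the same (leftmost
        forward-coordinate) offset.  Overlapping hits are all reported;
        offsets where the motif covers an N are skipped.
        """
        if self.threshold_int is None:
            return []
        codes = encode(seq)
        hits: list[MotifHit] = []
        strands = [("+", self._s_int)]
        if strand_policy == "both":
            strands.append(("-", self._s_int_rc))
        elif strand_policy != "sense_only":
            raise ValueError(f"unknown strand policy {strand_policy!r}")
        for strand, s_int in strands:
            scores = self._offset_scores(codes, s_int)
            for off in np.nonzero(scores >= self.threshold_int)[0]:
                s = int(scores[off])
                hits.append(
                    MotifHit(
                        transcript_id,
                        window,
                        self.pssm.motif_id,
                        int(off) + 1,
                        strand,
                        s * self.granularity,
                        self.null.tail_int(s),
                    )
                )
        hits.sort(key=lambda h: (h.offset, h.strand))
        return hits


def scan_sequence(
    seq: str,
    scorer: MotifScorer,
    strand_policy: str = "sense_only",
    transcript_id: str = "",
    window: str = "",
) -> list[MotifHit]:
    """Functional wrapper around :meth:`MotifScorer.scan`."""
    return scorer.scan(seq, strand_policy, transcript_id, window)


# ---------------------------------------------------------------------------
# Window extraction


def _rel_to_abs(tss: int, rel: int) -> int:
    # 1-based, no position 0: -1 abuts +1
    return tss + rel - (1 if rel > 0 else 0)


def extract_window(
    sequences: Mapping[str, str],
    transcript: TranscriptRecord,
    window: ScanWindow,
) -> str:
    """Cut the promoter window for one TSS out of its contig.

    For '-' strand records the contig is reverse-complemented and the
    TSS re-anchored first, so the returned string always reads in the
    transcript's sense direction.  Windows running off the contig end
    are truncated with a TruncatedWindowWarning, never silently.
    """
    contig = sequences[transcript.seq_id]
    if transcript.strand == "+":
        seq, tss = contig, transcript.tss_position
    else:
        seq = reverse_complement(contig)
        tss = len(contig) - transcript.tss_position + 1
    start = _rel_to_abs(tss, window.rel_start)
    end = _rel_to_abs(tss, window.rel_end)
    clipped_start = max(start, 1)
    clipped_end = min(end, len(seq))
    out = seq[clipped_start - 1 : clipped_end]
    if len(out) < window.length:
        warnings.warn(
            f"{transcript.transcript_id}: {window.kind} window truncated to "
            f"{len(out)} nt (wanted {window.length})",
            TruncatedWindowWarning,
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# Aggregation


def count_occurrences(
    hits: Iterable[MotifHit],
    transcript_ids: Sequence[str],
    motif_ids_by_window: Mapping[str, Sequence[str]],
    threshold_p: float,
) -> OccurrenceMatrix:
    """Aggregate hits into the transcripts x (window, motif) count matrix."""
    cols = pd.MultiIndex.from_tuples(
        [(w, m) for w, motifs in motif_ids_by_window.items() for m in motifs],
        names=["window", "motif"],
    )
    counts = pd.DataFrame(0, index=list(transcript_ids), columns=cols, dtype=int)
    for h in hits:
        counts.loc[h.transcript_id, (h.window, h.motif_id)] += 1
    return OccurrenceMatrix(counts, threshold_p)


def scan_promoters(
    sequences: Mapping[str, str],
    transcripts: Sequence[TranscriptRecord],
    pssms_by_window: Mapping[str, Sequence[PSSM]],
    windows: Mapping[str, ScanWindow] | None = None,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    p_threshold: float = 1e-4,
    pseudocount: float = 0.001,
    strand_policies: Mapping[str, str] | None = None,
) -> tuple[OccurrenceMatrix, list[MotifHit]]:
    """Scan every transcript's windows with every motif of the matching class.

    ``pssms_by_window`` maps window kind ('core'/'enhancer') to the PSSMs
    scanned there.  Default strand policy: sense_only in the core window
    (core elements are orientation-specific), both strands in the
    enhancer window (TF sites are orientation-agnostic).
    """
    if windows is None:
        windows = {"core": CORE_WINDOW, "enhancer": ENHANCER_WINDOW}
    scorers = {
        kind: [MotifScorer(p, background, p_threshold, pseudocount) for p in pssms]
        for kind, pssms in pssms_by_window.items()
    }
    all_hits: list[MotifHit] = []
    for tr in transcripts:
        for kind, win in windows.items():
            if kind not in scorers:
                continue
            policy = (
                strand_policies[kind]
                if strand_policies and kind in strand_policies
                else win.strand_policy
            )
            wseq = extract_window(sequences, tr, win)
            for scorer in scorers[kind]:
                all_hits.extend(scorer.scan(wseq, policy, tr.transcript_id, kind))
    motif_ids = {
        kind: [p.motif_id for p in pssms] for kind, pssms in pssms_by_window.items()
    }
    occ = count_occurrences(
        all_hits, [t.transcript_id for t in transcripts], motif_ids, p_threshold
    )
    return occ, all_hits


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.transcript_id, h.window, h.motif_id, h.offset, h.strand, h.score, h.p_value)
            for h in hits
        ],
        columns=["transcript_id", "window", "motif", "offset", "strand", "score", "p_value"],
    )
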