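"""Scanner correctness: log-odds algebra, exact null DP, window arithmetic,
and equivalence with a brute-force per-offset scorer."""

import numpy as np
import pytest

from promoshift.experiments import bruteforce_scan, enumerate_null_tail
from promoshift.io_formats import MotifClass, PSSM, TranscriptRecord
from promoshift.motif_scan import (
    CORE_WINDOW,
    ENHANCER_WINDOW,
    MotifScorer,
    ScanWindow,
    TruncatedWindowWarning,
    UnreachableThresholdWarning,
    count_occurrences,
    extract_window,
    log_odds_matrix,
    null_distribution,
    reverse_complement,
    score_threshold,
)
from conftest import one_hot_pssm

UNIFORM = (0.25, 0.25, 0.25, 0.25)


class TestLogOdds:
    def test_background_column_scores_zero(self):
        pssm = PSSM("bg", MotifClass.ENHANCER, np.array([[0.1, 0.2, 0.3, 0.4]]))
        S = log_odds_matrix(pssm, (0.1, 0.2, 0.3, 0.4), pseudocount=0.0)
        assert np.allclose(S, 0.0)

    def test_one_hot_column_two_bits_and_cap(self):
        pssm = one_hot_pssm("A")
        S = log_odds_matrix(pssm, UNIFORM, pseudocount=0.0)
        assert S[0, 0] == pytest.approx(2.0)
        assert (S[0, 1:] == -100.0).all()

    def test_odds_identity_sum_bg_weighted(self, rng):
        # for any column: sum_b bg_b * 2^score_b == 1 at pseudocount 0
        probs = rng.dirichlet([2, 2, 2, 2], size=6)
        bg = rng.dirichlet([5, 5, 5, 5])
        pssm = PSSM("r", MotifClass.ENHANCER, probs)
        S = log_odds_matrix(pssm, bg, pseudocount=0.0)
        ident = (bg[None, :] * 2.0**S).sum(axis=1)
        assert np.allclose(ident, 1.0, atol=1e-9)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            log_odds_matrix(one_hot_pssm("A"), (0.0, 0.5, 0.25, 0.25))


class TestScoreThreshold:
    def test_width4_motif_cannot_reach_1e4(self):
        # best-word null mass 1/256 > 1e-4: no hit possible
        pssm = one_hot_pssm("ACGT")
        S = log_odds_matrix(pssm, UNIFORM)
        with pytest.warns(UnreachableThresholdWarning):
            res = score_threshold(S, UNIFORM, p_threshold=1e-4)
        assert np.isinf(res.threshold)
        scorer = MotifScorer(pssm, p_threshold=1e-4)
        assert scorer.scan("ACGT" * 10) == []

    def test_width7_one_hot_only_consensus_passes(self):
        pssm = one_hot_pssm("ACGTACG")
        scorer = MotifScorer(pssm, p_threshold=1e-4, pseudocount=0.0)
        # null mass of the consensus word is 4^-7 ~ 6.1e-5 <= 1e-4
        assert scorer.tail_mass == pytest.approx(0.25**7)
        assert {h.offset for h in scorer.scan("ACGTACG")} == {1}
        assert scorer.scan("ACGTACC") == []

    def test_p_threshold_one_admits_every_offset(self, rng):
        pssm = PSSM("r", MotifClass.ENHANCER, rng.dirichlet([1] * 4, size=5))
        scorer = MotifScorer(pssm, p_threshold=1.0)
        seq = "ACGTACGTACGT"
        assert len(scorer.scan(seq)) == len(seq) - 4

    def test_dp_matches_word_enumeration(self, rng):
        # exact PMF identity for widths 2..8, non-uniform background
        for width in (2, 4, 6, 8):
            pssm = PSSM("r", MotifClass.ENHANCER, rng.dirichlet([0.7] * 4, size=width))
            bg = rng.dirichlet([8] * 4)
            scorer = MotifScorer(pssm, bg, p_threshold=1e-3)
            exact = enumerate_null_tail(scorer)
            dp = scorer.null
            tv = 0.5 * sum(
                abs(
                    exact.get(s, 0.0)
                    - (dp.pmf[s - dp.base] if 0 <= s - dp.base < len(dp.pmf) else 0.0)
                )
                for s in set(exact)
                | {dp.base + i for i in range(len(dp.pmf)) if dp.pmf[i] > 0}
            )
            assert tv < 1e-9


class TestExtractWindow:
    SEQ = {"c": "".join("ACGT"[(i // 7) % 4] for i in range(1060))}

    def _record(self, tss, strand="+"):
        return TranscriptRecord("g", "g-RA", "c", tss, strand)

    def test_core_window_is_941_to_1040(self):
        out = extract_window(self.SEQ, self._record(1001), CORE_WINDOW)
        assert out == self.SEQ["c"][940:1040]
        assert len(out) == 100

    def test_enhancer_window_is_1_to_1000(self):
        out = extract_window(self.SEQ, self._record(1001), ENHANCER_WINDOW)
        assert out == self.SEQ["c"][0:1000]
        assert len(out) == 1000

    def test_truncation_warns_with_achieved_length(self):
        with pytest.warns(TruncatedWindowWarning, match="49"):
            out = extract_window(self.SEQ, self._record(50), ENHANCER_WINDOW)
        assert len(out) == 49

    def test_minus_strand_reanchors_on_reverse_complement(self):
        L = len(self.SEQ["c"])
        tss_minus = L - 1001 + 1
        out = extract_window(self.SEQ, self._record(tss_minus, "-"), CORE_WINDOW)
        rc = reverse_complement(self.SEQ["c"])
        assert out == rc[940:1040]

    def test_no_position_zero_in_window_spans(self):
        with pytest.raises(ValueError):
            ScanWindow("bad", 0, 40)
        assert CORE_WINDOW.length == 100
        assert ENHANCER_WINDOW.length == 1000


class TestScanSequence:
    def test_sequence_shorter_than_motif_empty(self):
        scorer = MotifScorer(one_hot_pssm("ACGTACG"), p_threshold=1.0)
        assert scorer.scan("ACG") == []

    def test_planted_consensus_found_at_offset(self, rng):
        scorer = MotifScorer(one_hot_pssm("TTACGCA"), p_threshold=1e-4)
        seq = "G" * 16 + "TTACGCA" + "G" * 30
        assert [h.offset for h in scorer.scan(seq)] == [17]

    def test_equivalence_with_bruteforce_on_random_panel(self, rng):
        for _ in range(60):
            width = int(rng.integers(2, 9))
            pssm = PSSM("r", MotifClass.ENHANCER, rng.dirichlet([0.5] * 4, size=width))
            scorer = MotifScorer(pssm, p_threshold=1e-2)
            L = int(rng.integers(1, 51))
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=L))
            for policy in ("sense_only", "both"):
                got = sorted(
                    (h.offset, h.strand, int(round(h.score / scorer.granularity)))
                    for h in scorer.scan(seq, policy)
                )
                assert got == bruteforce_scan(seq, scorer, policy)

    def test_n_positions_skipped(self):
        scorer = MotifScorer(one_hot_pssm("ACGTACG"), p_threshold=1.0)
        hits = scorer.scan("ACGNACGTACG")
        assert all(h.offset > 4 for h in hits)

    def test_palindromic_motif_hit_count_invariant_under_rc(self, rng):
        pssm = one_hot_pssm("TATCGATA")  # its own reverse complement
        scorer = MotifScorer(pssm, p_threshold=1e-4)
        seq = "".join(rng.choice(list("ACGT"), size=400)) + "TATCGATA"
        fwd = scorer.scan(seq, "both")
        rev = scorer.scan(reverse_complement(seq), "both")
        assert len(fwd) == len(rev) > 0


class TestCountOccurrences:
    def test_no_hits_all_zero(self):
        occ = count_occurrences([], ["t1"], {"core": ["m"]}, 1e-4)
        assert occ.total == 0

    def test_counts_and_conservation(self):
        from promoshift.motif_scan import MotifHit

        hits = [
            MotifHit("t1", "enhancer", "mA", o, "+", 5.0, 1e-5) for o in (3, 9, 40)
        ] + [MotifHit("t2", "core", "mB", 1, "+", 4.0, 1e-5)]
        occ = count_occurrences(
            hits, ["t1", "t2"], {"core": ["mB"], "enhancer": ["mA"]}, 1e-4
        )
        assert occ.counts.loc["t1", ("enhancer", "mA")] == 3
        assert occ.counts.loc["t2", ("core", "mB")] == 1
        assert occ.total == len(hits)
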