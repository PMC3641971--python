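"""Permutation z-scores vs. exact finite-population oracles, and the
hypergeometric gene-set tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from promoshift.enrichment_stats import (
    HypergeomInput,
    exact_enrichment,
    go_enrichment,
    hypergeom_upper_tail,
    overlap_validation,
    permutation_enrichment,
)
from promoshift.experiments import _assignment_from_labels, _occ_from_array
from promoshift.io_formats import GeneSetCollection


class TestPermutationEnrichment:
    def test_constant_counts_degenerate_z_zero(self):
        occ = _occ_from_array(np.full(10, 3))
        assign = _assignment_from_labels(
            np.array([1] * 4 + [2] * 6), list(occ.counts.index)
        )
        table = permutation_enrichment(occ, assign, n_perm=100, seed=0)
        assert (table.call == "degenerate").all()
        assert (table.z == 0.0).all()

    def test_matches_exact_enumeration_on_15_pair_universe(self):
        counts = np.array([0, 0, 0, 0, 5, 5])
        occ = _occ_from_array(counts)
        assign = _assignment_from_labels(
            np.array([2, 2, 2, 2, 1, 1]), list(occ.counts.index)
        )
        table = permutation_enrichment(occ, assign, n_perm=10_000, seed=1)
        cell = table[table.cluster == 1].iloc[0]
        sums = [counts[i] + counts[j] for i, j in itertools.combinations(range(6), 2)]
        mu, sd = np.mean(sums), np.std(sums)
        assert cell.observed == 10 == max(sums)
        assert cell.perm_mean == pytest.approx(mu, abs=3 * sd / np.sqrt(10_000))
        assert cell.perm_sd == pytest.approx(sd, rel=0.05)

    def test_cluster_equal_to_universe_degenerate(self):
        occ = _occ_from_array(np.array([1, 2, 3]))
        assign = _assignment_from_labels(np.array([1, 1, 1]), list(occ.counts.index))
        table = permutation_enrichment(occ, assign, n_perm=50, seed=0)
        assert (table.call == "degenerate").all()

    def test_planted_high_and_low_counts_called(self, rng):
        # cluster 1 carries systematically higher counts, cluster 2 lower
        counts = rng.poisson(2.0, size=300)
        counts[:40] += 4
        counts[40:80] = 0
        labels = np.full(300, 3)
        labels[:40] = 1
        labels[40:80] = 2
        occ = _occ_from_array(counts)
        assign = _assignment_from_labels(labels, list(occ.counts.index))
        table = permutation_enrichment(occ, assign, n_perm=1000, seed=0)
        assert table[table.cluster == 1].iloc[0].call == "enriched"
        assert table[table.cluster == 2].iloc[0].call == "depleted"

    def test_calls_invariant_under_transcript_relabeling(self, rng):
        counts = rng.poisson(1.0, size=(60, 3))
        occ = _occ_from_array(counts)
        labels = np.array([1, 2, 3] * 20)
        assign = _assignment_from_labels(labels, list(occ.counts.index))
        t1 = permutation_enrichment(occ, assign, n_perm=500, seed=3)
        renamed = occ.counts.copy()
        renamed.index = [f"x{i}" for i in range(60)]
        occ2 = _occ_from_array(renamed.to_numpy())
        assign2 = _assignment_from_labels(labels, list(occ2.counts.index))
        t2 = permutation_enrichment(occ2, assign2, n_perm=500, seed=3)
        assert (t1.call.to_numpy() == t2.call.to_numpy()).all()

    def test_invalid_inputs_rejected(self):
        occ = _occ_from_array(np.array([1, 2, 3]))
        assign = _assignment_from_labels(np.array([1, 1, 2]), list(occ.counts.index))
        with pytest.raises(ValueError):
            permutation_enrichment(occ, assign, n_perm=1, seed=0)
        with pytest.raises(ValueError):
            permutation_enrichment(occ, assign, universe=["t00000"], n_perm=10, seed=0)


class TestExactEnrichment:
    def test_equal_counts_zero_variance(self):
        mu, var = exact_enrichment(np.full(8, 2.0), 3)
        assert mu == pytest.approx(6.0) and var == pytest.approx(0.0)

    def test_matches_subset_enumeration(self):
        counts = np.array([0, 0, 0, 0, 5, 5])
        mu, var = exact_enrichment(counts, 2)
        sums = [counts[i] + counts[j] for i, j in itertools.combinations(range(6), 2)]
        assert mu == pytest.approx(np.mean(sums))
        assert var == pytest.approx(np.var(sums))
        assert mu == pytest.approx(10 / 3)

    def test_single_draw_is_population_moments(self, rng):
        counts = rng.poisson(3.0, size=20)
        mu, var = exact_enrichment(counts, 1)
        assert mu == pytest.approx(counts.mean())
        assert var == pytest.approx(counts.var(ddof=0))


class TestHypergeom:
    def test_b_zero_tail_is_one(self):
        assert hypergeom_upper_tail(HypergeomInput(10, 4, 5, 0)) == 1.0

    def test_enumeration_example_66_over_252(self):
        # all C(10,5)=252 draws; 66 contain >= 3 of the 4 annotated
        count = sum(
            1
            for s in itertools.combinations(range(10), 5)
            if len(set(s) & {0, 1, 2, 3}) >= 3
        )
        assert count == 66
        p = hypergeom_upper_tail(HypergeomInput(10, 4, 5, 3))
        assert p == pytest.approx(66 / 252)

    def test_forced_draw_tail_one(self):
        assert hypergeom_upper_tail(HypergeomInput(7, 7, 7, 7)) == pytest.approx(1.0)

    def test_tail_complement_identity(self, rng):
        from scipy import stats

        for _ in range(300):
            N = int(rng.integers(1, 200))
            B = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            b = int(rng.integers(0, min(B, n) + 1))
            upper = hypergeom_upper_tail(HypergeomInput(N, B, n, b))
            lower = stats.hypergeom.cdf(b - 1, N, B, n)
            assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            HypergeomInput(10, 11, 5, 3)
        with pytest.raises(ValueError):
            HypergeomInput(10, 4, 5, 5)


class TestGeneSetTests:
    def test_no_annotated_members_no_headline(self):
        assign = _assignment_from_labels(
            np.array([1, 1, 2, 2]), ["a-RA", "b-RA", "c-RA", "d-RA"]
        )
        annotations = GeneSetCollection({"term1": {"zzz"}})
        table, headlines = go_enrichment(assign, annotations)
        assert headlines == {1: None, 2: None}

    def test_planted_term_becomes_headline(self):
        members = [f"g{i:03d}" for i in range(200)]
        labels = np.array([1] * 20 + [2] * 180)
        assign = _assignment_from_labels(labels, [f"{g}-RA" for g in members])
        planted = set(members[:18])  # 90% of cluster 1
        decoy = set(members[::7])
        annotations = GeneSetCollection({"planted": planted, "decoy": decoy})
        table, headlines = go_enrichment(assign, annotations)
        assert headlines[1] == "planted"
        row = table[(table.cluster == 1) & (table.term == "planted")].iloc[0]
        assert row.p < 1e-5

    def test_headline_suppressed_above_report_threshold(self):
        members = [f"g{i:03d}" for i in range(200)]
        labels = np.array([1] * 20 + [2] * 180)
        assign = _assignment_from_labels(labels, [f"{g}-RA" for g in members])
        planted = set(members[:18])
        annotations = GeneSetCollection({"planted": planted, "rest": set(members[18:])})
        _, strict = go_enrichment(assign, annotations, report_threshold=1e-30)
        assert strict[1] is None

    def test_overlap_identical_sets_significant(self):
        universe = {f"g{i}" for i in range(1000)}
        cluster = {f"g{i}" for i in range(10)}
        res = overlap_validation(cluster, cluster, universe)
        assert res["significant"] and res["p"] < 1e-10
        # p is exactly 1/C(1000,10)
        assert res["p"] == pytest.approx(1 / math.comb(1000, 10), rel=1e-6)

    def test_overlap_zero_is_p_one_and_empty_cluster_undefined(self):
        universe = {f"g{i}" for i in range(100)}
        res = overlap_validation({"g1"}, {"g50"}, universe)
        assert res["p"] == pytest.approx(1.0)
        empty = overlap_validation(set(), {"g50"}, universe)
        assert empty["undefined"] and np.isnan(empty["p"])

    def test_random_cluster_overlap_calibrated(self, rng):
        # ~5% of random clusters significant at p<0.05
        universe = [f"g{i}" for i in range(400)]
        published = set(universe[:100])
        n_sig = 0
        trials = 1000
        for _ in range(trials):
            cluster = set(rng.choice(universe, size=40, replace=False))
            if overlap_validation(cluster, published, set(universe))["significant"]:
                n_sig += 1
        # discrete test is conservative; allow [0.5%, 8%]
        assert 0.005 <= n_sig / trials <= 0.08
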