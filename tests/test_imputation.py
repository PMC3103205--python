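"""Haplotype-pair imputation: pre-selection, the three filtering steps,
fallback calls, full-individual pipeline and accuracy metric."""

import numpy as np
import pytest

from _oracles import reference_select_pair
from salhi.genmap import GeneticMap
from salhi.imputation import (PROV_FALLBACK_GPI, PROV_GENEPROB, PROV_OBSERVED,
                              PROV_PAIR, CandidateSet, ImputationConfig,
                              ImputationResult, SALHIImputer, fallback_calls,
                              impute_individual, imputation_accuracy,
                              preselect_genotypes, step1_filter, step2_filter,
                              step3_select)
from salhi.phasing import HaplotypeLibrary
from salhi.segregation import Geneprobs
from salhi.simulate import MISSING


def onehot(geno, L=None):
    geno = np.asarray(geno)
    p = np.zeros((len(geno), 3))
    p[np.arange(len(geno)), geno] = 1.0
    return p


class TestPreselect:
    def test_argmax_and_zygosity(self):
        probs = np.array([[0.1, 0.2, 0.7]])
        mpg = preselect_genotypes(probs, np.array([95.0]), 90.0)
        assert mpg.genotype[0] == 2 and not mpg.is_het[0]
        assert not mpg.excluded[0]

    def test_uniform_tie_defaults_to_heterozygote(self):
        probs = np.full((1, 3), 1 / 3)
        mpg = preselect_genotypes(probs, np.array([95.0]), 90.0)
        assert mpg.genotype[0] == 1 and mpg.is_het[0]

    def test_low_gpi_excluded(self):
        probs = np.array([[0.8, 0.1, 0.1]])
        mpg = preselect_genotypes(probs, np.array([50.0]), 90.0)
        assert mpg.excluded[0]


class TestStep1:
    def test_one_opposing_over_zero_threshold_excludes(self):
        probs = onehot([0])
        mpg = preselect_genotypes(probs, np.array([100.0]), 90.0)
        haps = np.array([[1], [0]], dtype=np.int8)
        cfg = ImputationConfig(error_threshold_step1=0)
        out = step1_filter(mpg, haps, cfg)
        assert list(out.ids) == [1]

    def test_agreeing_haplotype_retained_with_zero_count(self):
        probs = onehot([0, 2, 1])
        mpg = preselect_genotypes(probs, np.full(3, 100.0), 90.0)
        haps = np.array([[0, 1, 0]], dtype=np.int8)
        out = step1_filter(mpg, haps, ImputationConfig())
        assert list(out.ids) == [0] and out.mismatches[0] == 0

    def test_all_het_mpg_retains_everything(self):
        probs = onehot([1, 1, 1])
        mpg = preselect_genotypes(probs, np.full(3, 100.0), 90.0)
        haps = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
        out = step1_filter(mpg, haps, ImputationConfig(error_threshold_step1=0))
        assert len(out.ids) == 2

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        probs = onehot(rng.integers(0, 3, 30))
        mpg = preselect_genotypes(probs, np.full(30, 100.0), 90.0)
        haps = rng.integers(0, 2, (12, 30)).astype(np.int8)
        prev = set()
        for thr in (0, 1, 2, 4, 30):
            cfg = ImputationConfig(error_threshold_step1=thr)
            cur = set(step1_filter(mpg, haps, cfg).ids)
            assert prev <= cur
            prev = cur


class TestStep2:
    def test_single_survivor_forces_self_pair(self):
        probs = onehot([0, 0])
        mpg = preselect_genotypes(probs, np.full(2, 100.0), 0.0)
        singles = CandidateSet("single", np.array([3]), np.array([0]))
        haps = np.zeros((4, 2), dtype=np.int8)
        pairs = step2_filter(singles, mpg, ImputationConfig(), haps)
        assert pairs.ids.tolist() == [[3, 3]]

    def test_mismatching_pair_excluded_at_first_pass(self):
        probs = onehot([0])
        mpg = preselect_genotypes(probs, np.array([99.5]), 0.0)
        haps = np.array([[1], [0]], dtype=np.int8)
        singles = CandidateSet("single", np.array([0, 1]), np.zeros(2))
        cfg = ImputationConfig(error_threshold_step2=0, max_relax=1.0)
        pairs = step2_filter(singles, mpg, cfg, haps)
        # only (1,1) implies genotype 0 at the GPI-99.5 locus
        assert pairs.ids.tolist() == [[1, 1]]

    def test_descending_schedule_adds_loci(self):
        # three loci with GPI 99, 95, 70: candidate pairs tie at g=99 and
        # are separated by the locus that enters at g=94
        probs = onehot([0, 2, 1])
        gpi = np.array([99.0, 95.0, 70.0])
        mpg = preselect_genotypes(probs, gpi, 0.0)
        haps = np.array([[0, 1, 0], [0, 0, 0]], dtype=np.int8)
        singles = CandidateSet("single", np.array([0, 1]), np.zeros(2))
        cfg = ImputationConfig(error_threshold_step2=0)
        pairs = step2_filter(singles, mpg, cfg, haps)
        # at 99: all pairs imply 0 at locus 0 -> all survive; at 94 the
        # locus with mpg 2 kills any pair without two alt alleles there
        assert pairs.ids.tolist() == [[0, 0]]

    def test_empty_refilter_reverts_to_last_nonempty(self):
        # locus 0 (GPI 99) separates nothing; locus 1 (GPI 95) would kill
        # every pair -> the survivors at 99 must be kept
        probs = onehot([0, 2])
        gpi = np.array([99.0, 95.0])
        mpg = preselect_genotypes(probs, gpi, 0.0)
        haps = np.array([[0, 0], [0, 0]], dtype=np.int8)
        singles = CandidateSet("single", np.array([0, 1]), np.zeros(2))
        cfg = ImputationConfig(error_threshold_step2=0)
        pairs = step2_filter(singles, mpg, cfg, haps)
        assert len(pairs.ids) == 3  # all unordered pairs of two haplotypes

    def test_gpi_schedule_monotonicity(self):
        """Lowering the step-2 GPI floor never enlarges the survivor set."""
        rng = np.random.default_rng(1)
        L = 20
        probs = onehot(rng.integers(0, 3, L))
        gpi = rng.uniform(60, 100, L)
        mpg = preselect_genotypes(probs, gpi, 0.0)
        haps = rng.integers(0, 2, (6, L)).astype(np.int8)
        singles = CandidateSet("single", np.arange(6), np.zeros(6))
        prev = None
        for floor in (99, 90, 80, 70, 60):
            cfg = ImputationConfig(gpi_min_step2_floor=floor,
                                   error_threshold_step2=2, max_relax=1.0)
            ids = {tuple(p) for p in
                   step2_filter(singles, mpg, cfg, haps).ids.tolist()}
            if prev is not None and ids:
                assert ids <= prev
            if ids:
                prev = ids


class TestStep3:
    def test_sum_score_arithmetic(self):
        probs = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]])
        # pair A implies (0, 1); pair B implies (1, 2)
        haps = np.array([[0, 0], [0, 1], [1, 1]], dtype=np.int8)
        pairs = CandidateSet("pair", np.array([[0, 1], [1, 2]]), np.zeros(2))
        assert step3_select(pairs, probs, haps) == (0, 1)

    def test_single_pair_identity(self):
        probs = np.full((2, 3), 1 / 3)
        haps = np.array([[0, 0], [1, 1]], dtype=np.int8)
        pairs = CandidateSet("pair", np.array([[0, 1]]), np.zeros(1))
        assert step3_select(pairs, probs, haps) == (0, 1)

    def test_tie_breaks_lexicographically(self):
        probs = np.full((1, 3), 1 / 3)
        haps = np.array([[0], [0], [0]], dtype=np.int8)
        pairs = CandidateSet("pair", np.array([[1, 2], [0, 2]]), np.zeros(2))
        assert step3_select(pairs, probs, haps) == (0, 2)


class TestFallback:
    def test_unanimous_pair_frequency_calls(self):
        probs = np.full((1, 3), 1 / 3)
        gpi = np.array([50.0])
        haps = np.array([[0], [1]], dtype=np.int8)
        pairs = CandidateSet("pair", np.array([[0, 1], [0, 1]]), np.zeros(2))
        geno, prov = fallback_calls(pairs, probs, gpi, ImputationConfig(), haps)
        assert geno[0] == 1

    def test_below_threshold_stays_uncalled(self):
        probs = np.full((1, 3), 1 / 3)
        gpi = np.array([50.0])
        haps = np.array([[0], [1]], dtype=np.int8)
        pairs = CandidateSet(
            "pair", np.array([[0, 0], [0, 0], [0, 0], [0, 1], [1, 1]]),
            np.zeros(5))
        # 3/5 imply 0: fraction 0.6 < 0.9 -> uncalled
        geno, prov = fallback_calls(pairs, probs, gpi, ImputationConfig(), haps)
        assert geno[0] == MISSING

    def test_gpi_100_called_regardless_of_pairs(self):
        probs = np.array([[0.0, 0.0, 1.0]])
        gpi = np.array([100.0])
        haps = np.array([[0]], dtype=np.int8)
        pairs = CandidateSet("pair", np.array([[0, 0]]), np.zeros(1))
        geno, prov = fallback_calls(pairs, probs, gpi, ImputationConfig(), haps)
        assert geno[0] == 2 and prov[0] == PROV_FALLBACK_GPI


def tiny_map(L=6, chrom_mb=10.0):
    return GeneticMap(np.ones(L), np.linspace(1, chrom_mb * 1e6, L).astype(int))


def library_of(haps):
    lib = HaplotypeLibrary()
    lib.haplotypes[1] = np.asarray(haps, dtype=np.int8)
    lib.counts[1] = np.ones(len(haps), dtype=np.int64)
    return lib


class TestImputeIndividual:
    def test_observed_passthrough(self):
        gmap = tiny_map(4)
        obs = np.array([0, 1, 2, 1], dtype=np.int8)
        probs = onehot(obs)
        geno, prov, _ = impute_individual(probs, np.full(4, 100.0), obs,
                                          library_of([[0, 0, 1, 1]]), gmap,
                                          ImputationConfig())
        assert np.array_equal(geno, obs)
        assert np.all(prov == PROV_OBSERVED)

    def test_true_pair_in_library_reproduces_genotypes(self):
        gmap = tiny_map(8)
        rng = np.random.default_rng(5)
        h1 = rng.integers(0, 2, 8).astype(np.int8)
        h2 = rng.integers(0, 2, 8).astype(np.int8)
        truth = h1 + h2
        probs = onehot(truth)
        lib = library_of([h1, h2, 1 - h1])
        geno, prov, sel = impute_individual(
            probs, np.full(8, 99.0), np.full(8, MISSING, dtype=np.int8),
            lib, gmap, ImputationConfig())
        assert np.array_equal(geno, truth)

    def test_empty_library_geneprob_fill(self):
        gmap = tiny_map(3)
        probs = np.tile([0.25, 0.5, 0.25], (3, 1))
        geno, prov, sel = impute_individual(
            probs, np.zeros(3), np.full(3, MISSING, dtype=np.int8),
            HaplotypeLibrary(), gmap, ImputationConfig())
        assert np.all(geno == 1)
        assert np.all(prov == PROV_GENEPROB)
        assert sel == {}

    def test_output_always_complete(self):
        gmap = tiny_map(10)
        rng = np.random.default_rng(6)
        probs = rng.dirichlet(np.ones(3), size=10)
        gpi = rng.uniform(0, 100, 10)
        obs = np.where(rng.random(10) < 0.3, rng.integers(0, 3, 10),
                       MISSING).astype(np.int8)
        lib = library_of(rng.integers(0, 2, (5, 10)))
        geno, prov, _ = impute_individual(probs, gpi, obs, lib, gmap,
                                          ImputationConfig())
        assert np.all((geno >= 0) & (geno <= 2))


class TestOracleEquivalence:
    def test_pipeline_matches_reference_on_random_instances(self):
        """Step 1-2-3 composition agrees with a direct reimplementation of
        the rules on >= 50 random instances."""
        rng = np.random.default_rng(7)
        cfg = ImputationConfig()
        n_checked = 0
        for rep in range(60):
            L = int(rng.integers(5, 21))
            n_hap = int(rng.integers(2, 13))
            haps = rng.integers(0, 2, (n_hap, L)).astype(np.int8)
            i, j = rng.integers(0, n_hap, 2)
            truth = haps[i] + haps[j]
            # geneprobs: noisy point masses
            probs = np.zeros((L, 3))
            for l in range(L):
                if rng.random() < 0.8:
                    probs[l, truth[l]] = 1.0
                else:
                    probs[l] = rng.dirichlet(np.ones(3))
            gpi = rng.uniform(55, 100, L)
            gmap = tiny_map(L)
            geno, prov, sel = impute_individual(
                probs, gpi, np.full(L, MISSING, dtype=np.int8),
                library_of(haps), gmap, cfg)
            expected = reference_select_pair(probs, gpi, haps, cfg)
            got = sel.get(1)
            assert got == expected
            n_checked += 1
        assert n_checked >= 50


class TestAccuracy:
    def make_result(self, dosages, prov):
        return ImputationResult(np.asarray(dosages, dtype=np.int8),
                                np.asarray(prov, dtype=np.int8))

    def test_perfect_and_zero(self):
        truth = np.array([[0, 1, 2]])
        mask = np.ones((1, 3), dtype=bool)
        res = self.make_result([[0, 1, 2]], [[PROV_PAIR] * 3])
        assert imputation_accuracy(res, truth, mask)["overall"] == 100.0
        res = self.make_result([[1, 0, 0]], [[PROV_PAIR] * 3])
        assert imputation_accuracy(res, truth, mask)["overall"] == 0.0

    def test_three_of_four(self):
        truth = np.array([[0, 1, 2, 0]])
        res = self.make_result([[0, 1, 2, 1]], [[PROV_PAIR] * 4])
        out = imputation_accuracy(res, truth, np.ones((1, 4), dtype=bool))
        assert out["overall"] == 75.0

    def test_no_masked_entries_is_nan(self):
        truth = np.array([[0]])
        res = self.make_result([[0]], [[PROV_OBSERVED]])
        out = imputation_accuracy(res, truth, np.zeros((1, 1), dtype=bool))
        assert np.isnan(out["overall"])

    def test_per_provenance_breakdown(self):
        truth = np.array([[0, 1, 2, 0]])
        res = self.make_result([[0, 1, 0, 0]],
                               [[PROV_PAIR, PROV_PAIR, PROV_GENEPROB,
                                 PROV_GENEPROB]])
        out = imputation_accuracy(res, truth, np.ones((1, 4), dtype=bool))
        assert out["pair"] == 100.0
        assert out["geneprob_fill"] == 50.0
        assert out["called_only"] == 100.0
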