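"""Long-range phasing: core partition, opposing homozygotes, surrogates,
voting, library assembly and truth recovery on simulated half-sib data."""

import numpy as np
import pytest

from salhi.genmap import GeneticMap
from salhi.pedigree import Pedigree
from salhi.phasing import (UNPHASED, LongRangePhaser, build_library,
                           count_opposing_homozygotes, find_surrogates,
                           mosaic_switches, partition_cores, phase_core)
from salhi.simulate import (MISSING, PedigreeConfig, default_map, gene_drop,
                            simulate_founders, simulate_pedigree)


def evenly_spaced_map(n=100, chrom_mb=100.0):
    pos = np.linspace(1, chrom_mb * 1e6, n).astype(np.int64)
    return GeneticMap(np.ones(n), pos)


class TestPartitionCores:
    def test_cover_disjoint_and_complete(self):
        gmap = default_map(2, 137)
        part = partition_cores(gmap, 10.0)
        for c in gmap.chromosomes:
            s = gmap.chrom_slice(c)
            cores = part.chrom_cores(c)
            assert cores[0][0] == s.start and cores[-1][1] == s.stop
            for (a, b), (a2, b2) in zip(cores, cores[1:]):
                assert b == a2 and a < b

    def test_default_core_count_on_100mb(self):
        gmap = evenly_spaced_map(200)
        part = partition_cores(gmap, 10.0)
        assert 10 <= len(part.chrom_cores(1)) <= 12

    def test_core_longer_than_chromosome_gives_one_core(self):
        gmap = evenly_spaced_map(50, chrom_mb=20.0)
        part = partition_cores(gmap, 100.0)
        assert part.chrom_cores(1) == [(0, 50)]

    def test_cutting_rule_snp_at_every_mb(self):
        # SNPs at 1..100 Mb; boundary = first SNP at/after each 10 Mb
        pos = np.arange(1, 101) * 1_000_000
        gmap = GeneticMap(np.ones(100), pos)
        part = partition_cores(gmap, 10.0)
        starts = [a for a, _ in part.chrom_cores(1)]
        assert starts == [0, 9, 19, 29, 39, 49, 59, 69, 79, 89]


class TestOpposingHomozygotes:
    @pytest.mark.parametrize("g1,g2,expected", [
        ((0, 2, 1), (2, 2, 0), 1),
        ((0, 1, 2), (0, 1, 2), 0),
        ((0, 0, 0), (2, 2, 2), 3),
        ((0, 9, 2), (2, 2, 9), 1),
    ])
    def test_counts(self, g1, g2, expected):
        assert count_opposing_homozygotes(np.array(g1), np.array(g2)) == expected

    def test_interval_restriction(self):
        g1 = np.array([0, 0, 0, 0])
        g2 = np.array([2, 2, 2, 2])
        assert count_opposing_homozygotes(g1, g2, (1, 3)) == 2

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            count_opposing_homozygotes(np.zeros(3), np.zeros(4))


class TestSurrogates:
    @pytest.fixture
    def halfsib_family(self):
        # sire 1 with two dams (2, 3); offspring 4, 5 (dam 2), 6 (dam 3)
        ped = Pedigree(np.array([1, 2, 3, 4, 5, 6]),
                       np.array([0, 0, 0, 1, 1, 1]),
                       np.array([0, 0, 0, 2, 2, 3]),
                       np.array(["M", "F", "F", "M", "M", "M"]),
                       np.array([0, 0, 0, 1, 1, 1]))
        return ped

    def test_genotyped_sire_is_first(self, halfsib_family):
        G = np.array([[0, 0], [1, 1], [1, 1], [0, 1], [0, 1], [0, 1]],
                     dtype=np.int8)
        surr = find_surrogates(3, "paternal", G, halfsib_family, (0, 2))
        assert surr[0][0] == 0  # the sire's row

    def test_excludes_candidates_over_max_opposing(self, halfsib_family):
        G = np.array([[0, 0], [1, 1], [1, 1], [0, 0], [2, 2], [0, 9]],
                     dtype=np.int8)
        surr = find_surrogates(3, "paternal", G, halfsib_family, (0, 2),
                               max_opposing=0)
        rows = [r for r, _, _ in surr]
        assert 4 not in rows  # two opposing homozygotes with row 3
        assert 5 in rows      # half-sib with none

    def test_ordering_by_rank_then_opposing(self, halfsib_family):
        # sire genotyped (rank 0) must precede the half-sib (rank 2) even
        # when both have zero opposing homozygotes
        G = np.array([[1, 1], [1, 1], [1, 1], [1, 0], [0, 0], [2, 1]],
                     dtype=np.int8)
        surr = find_surrogates(3, "paternal", G, halfsib_family, (0, 2),
                               max_opposing=2)
        rows = [r for r, _, _ in surr]
        assert rows[0] == 0
        assert 5 in rows

    def test_full_sibs_are_not_surrogates(self, halfsib_family):
        G = np.zeros((6, 2), dtype=np.int8)
        surr = find_surrogates(3, "paternal", G, halfsib_family, (0, 2))
        rows = [r for r, _, _ in surr]
        assert 4 not in rows  # row 4 shares both parents with row 3


class TestPhaseCore:
    def test_homozygous_loci_trivially_phased(self):
        G = np.array([[0, 2, 1]], dtype=np.int8)
        pat, mat, conf = phase_core(0, G, [], [], (0, 3))
        assert pat[0] == mat[0] == 0
        assert pat[1] == mat[1] == 1
        assert pat[2] == UNPHASED and mat[2] == UNPHASED

    def test_homozygous_sire_forces_paternal_allele(self):
        # individual het, sire dosage 2 -> paternal 1, maternal 0
        G = np.array([[1], [2]], dtype=np.int8)
        pat, mat, conf = phase_core(0, G, [], [], (0, 1), sire_row=1)
        assert pat[0] == 1 and mat[0] == 0 and conf[0]

    def test_surrogate_agreement_assigns_allele(self):
        # five homozygous-alt paternal surrogates at a het locus
        G = np.array([[1], [2], [2], [2], [2], [2]], dtype=np.int8)
        surr = [(r, -1, "P") for r in range(1, 6)]
        pat, mat, conf = phase_core(0, G, surr, [], (0, 1))
        assert pat[0] == 1 and mat[0] == 0 and conf[0]

    def test_split_votes_stay_unphased(self):
        G = np.array([[1], [2], [0]], dtype=np.int8)
        surr = [(1, -1, "P"), (2, -1, "P")]
        pat, mat, conf = phase_core(0, G, surr, [], (0, 1),
                                    agreement_threshold=0.9)
        assert pat[0] == UNPHASED and mat[0] == UNPHASED

    def test_phase_consistency_pat_plus_mat_equals_dosage(self):
        rng = np.random.default_rng(4)
        G = rng.integers(0, 3, size=(6, 20)).astype(np.int8)
        surr = [(r, -1, "P") for r in range(1, 6)]
        pat, mat, _ = phase_core(0, G, surr, [], (0, 20))
        both = (pat != UNPHASED) & (mat != UNPHASED)
        assert np.array_equal((pat + mat)[both], G[0][both])


class TestLibrary:
    def test_concatenation_dedup_and_counts(self):
        gmap = evenly_spaced_map(6, chrom_mb=30.0)
        part = partition_cores(gmap, 10.0)
        h1 = np.array([0, 1], dtype=np.int8)
        h2 = np.array([1, 0], dtype=np.int8)
        h3 = np.array([1, 1], dtype=np.int8)
        conf = np.ones(2, dtype=bool)
        cores_a = [(h1, h2, conf), (h2, h1, conf), (h3, h3, conf)]
        cores_b = [(h1, h2, conf), (h2, h1, conf), (h3, h3, conf)]
        G = np.vstack([(cores_a[k][0] + cores_a[k][1] for k in range(3))])
        G = np.concatenate([h1 + h2, h2 + h1, h3 + h3])[None, :].astype(np.int8)
        G = np.vstack([G, G])
        phased = {0: {1: cores_a}, 1: {1: cores_b}}
        lib, long_haps = build_library(phased, part, gmap, G)
        # paternal = h1|h2|h3, maternal = h2|h1|h3 for both individuals
        assert lib.n_haplotypes(1) == 2
        assert np.array_equal(np.sort(lib.counts[1]), [2, 2])
        assert np.array_equal(long_haps[0][1][0],
                              np.concatenate([h1, h2, h3]))

    def test_incomplete_gamete_excluded(self):
        gmap = evenly_spaced_map(4, chrom_mb=10.0)
        part = partition_cores(gmap, 10.0)
        hap = np.array([0, 1, UNPHASED, 1], dtype=np.int8)
        other = np.array([1, 0, UNPHASED, 0], dtype=np.int8)
        conf = np.array([True, True, False, True])
        G = (np.array([1, 1, 1, 1], dtype=np.int8))[None, :]
        phased = {0: {1: [(hap, other, conf)]}}
        lib, _ = build_library(phased, part, gmap, G, completeness_min=0.99)
        assert lib.n_haplotypes(1) == 0

    def test_complement_filling(self):
        gmap = evenly_spaced_map(3, chrom_mb=10.0)
        part = partition_cores(gmap, 10.0)
        hap = np.array([0, UNPHASED, 1], dtype=np.int8)
        other = np.array([1, 1, 0], dtype=np.int8)
        conf = np.ones(3, dtype=bool)
        G = np.array([[1, 2, 1]], dtype=np.int8)
        phased = {0: {1: [(other, hap, conf)]}}
        lib, _ = build_library(phased, part, gmap, G, completeness_min=0.6)
        assert lib.n_haplotypes(1) == 2
        seqs = {h.tobytes() for h in lib.haplotypes[1]}
        assert np.array([0, 1, 1], dtype=np.int8).tobytes() in seqs

    def test_empty_input_empty_library(self):
        gmap = evenly_spaced_map(3)
        part = partition_cores(gmap, 10.0)
        lib, long_haps = build_library({}, part, gmap,
                                       np.zeros((0, 3), dtype=np.int8))
        assert lib.chromosomes == []


class TestMosaicSwitches:
    def test_intact_gamete_zero_switches(self):
        p = np.array([0, 1, 0, 1], dtype=np.int8)
        m = np.array([1, 0, 1, 0], dtype=np.int8)
        assert mosaic_switches(p.copy(), p, m) == 0

    def test_single_crossover_one_switch(self):
        p = np.array([0, 0, 0, 0], dtype=np.int8)
        m = np.array([1, 1, 1, 1], dtype=np.int8)
        g = np.array([0, 0, 1, 1], dtype=np.int8)
        assert mosaic_switches(g, p, m) == 1

    def test_isolated_error_costs_two_switches(self):
        p = np.array([0, 0, 0, 0, 0], dtype=np.int8)
        m = np.array([1, 1, 1, 1, 1], dtype=np.int8)
        g = np.array([0, 0, 1, 0, 0], dtype=np.int8)
        assert mosaic_switches(g, p, m) == 2

    def test_impossible_allele_returns_none(self):
        p = np.array([0, 0], dtype=np.int8)
        m = np.array([0, 0], dtype=np.int8)
        g = np.array([0, 1], dtype=np.int8)
        assert mosaic_switches(g, p, m) is None


@pytest.fixture(scope="module")
def phased_population():
    """Half-sib design: 10 genotyped sires, 30 offspring each."""
    cfg = PedigreeConfig(n_generations=2, n_sires=10, n_dams=30,
                         offspring_per_dam=10)
    ped = simulate_pedigree(cfg, seed=21)
    gmap = default_map(5, 200)
    founders = simulate_founders(int(ped.is_founder.sum()), gmap, seed=22)
    genome = gene_drop(ped, founders, gmap, seed=23)
    phaser = LongRangePhaser()
    lib, long_haps, _ = phaser.run(genome.genotypes, ped, gmap)
    return ped, gmap, genome, lib, long_haps


class TestTruthRecovery:

    def test_truth_recovery_95_percent(self, phased_population):
        ped, gmap, genome, lib, long_haps = phased_population
        correct = total = 0
        for i, per in long_haps.items():
            for c, (pat, mat) in per.items():
                s = gmap.chrom_slice(c)
                tp, tm = genome.paternal[i, s], genome.maternal[i, s]
                mp, mm = pat != UNPHASED, mat != UNPHASED
                direct = (np.sum(pat[mp] == tp[mp])
                          + np.sum(mat[mm] == tm[mm]))
                swapped = (np.sum(pat[mp] == tm[mp])
                           + np.sum(mat[mm] == tp[mm]))
                correct += max(direct, swapped)
                total += int(mp.sum() + mm.sum())
        assert total > 0
        assert correct / total >= 0.95

    def test_phase_consistency_after_concatenation(self, phased_population):
        ped, gmap, genome, lib, long_haps = phased_population
        G = genome.genotypes
        for i, per in long_haps.items():
            for c, (pat, mat) in per.items():
                s = gmap.chrom_slice(c)
                both = (pat != UNPHASED) & (mat != UNPHASED)
                assert np.array_equal((pat + mat)[both], G[i, s][both])

    def test_library_counts_conserve_gametes(self, phased_population):
        ped, gmap, genome, lib, long_haps = phased_population
        # counts sum to the number of complete confident gametes admitted;
        # every library haplotype must be some individual's filled gamete
        for c in lib.chromosomes:
            assert lib.counts[c].min() >= 1
            assert lib.n_haplotypes(c) <= lib.counts[c].sum()
            assert len({h.tobytes() for h in lib.haplotypes[c]}) == \
                lib.n_haplotypes(c)

    def test_determinism(self):
        cfg = PedigreeConfig(n_generations=2, n_sires=4, n_dams=8,
                             offspring_per_dam=6)
        ped = simulate_pedigree(cfg, seed=31)
        gmap = default_map(2, 60)
        founders = simulate_founders(int(ped.is_founder.sum()), gmap, seed=32)
        genome = gene_drop(ped, founders, gmap, seed=33)
        r1 = LongRangePhaser().run(genome.genotypes, ped, gmap)
        r2 = LongRangePhaser().run(genome.genotypes, ped, gmap)
        for c in r1[0].chromosomes:
            assert np.array_equal(r1[0].haplotypes[c], r2[0].haplotypes[c])
            assert np.array_equal(r1[0].counts[c], r2[0].counts[c])
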