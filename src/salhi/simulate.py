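"""Gene-drop simulator with the structure of a multi-generation livestock
nucleus: a few sires and prolific dams per generation (~30 offspring each),
five ~100 Mb chromosomes, a quantitative trait with optional paternally
imprinted QTL, and masking scenarios that turn a fully genotyped population
into a sparsely genotyped one (ungenotyped training females, low-density
prediction candidates).

Everything is seeded and deterministic; truth (haplotypes, TBV) is retained
so phasing, imputation and GEBV accuracy can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap
from .pedigree import Pedigree

__all__ = [
    "PedigreeConfig", "TrueGenome", "TraitArchitecture", "ScenarioSpec",
    "MISSING", "simulate_pedigree", "default_map", "simulate_founders",
    "gene_drop", "simulate_trait", "panel_loci", "apply_scenario",
]

MISSING = 9  # missing-genotype code in dosage matrices


class ConfigurationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class PedigreeConfig:
    """Breeding design: generation 0 holds exactly the founder breeders;
    each later generation is produced by ``n_dams`` dams (each mated to one
    randomly assigned sire of the same breeding pool) with a fixed number
    of offspring per dam."""

    n_generations: int = 5
    n_sires: int = 5
    n_dams: int = 13
    offspring_per_dam: int = 30

    def __post_init__(self):
        if self.n_generations < 1:
            raise ConfigurationError("need at least one generation")
        if self.offspring_per_dam < 1 and self.n_generations > 1:
            raise ConfigurationError("offspring_per_dam must be >= 1")
        if self.n_generations > 1 and (self.n_sires < 1 or self.n_dams < 1):
            raise ConfigurationError("need at least 1 sire and 1 dam")


@dataclass
class TrueGenome:
    """Phase-known genomes: one paternal and one maternal haplotype per
    individual; genotypes are allele-1 dosages (paternal + maternal)."""

    paternal: np.ndarray  # (n, L) alleles 0/1
    maternal: np.ndarray  # (n, L) alleles 0/1

    @property
    def genotypes(self) -> np.ndarray:
        return (self.paternal + self.maternal).astype(np.int8)


@dataclass
class TraitArchitecture:
    qtl_loci: np.ndarray
    additive_effects: np.ndarray
    imprinting: np.ndarray        # 'none' or 'paternal' per QTL
    h2: float
    tbv: np.ndarray
    phenotypes: np.ndarray        # NaN = unphenotyped


@dataclass
class ScenarioSpec:
    """Masking plan.

    BASE: everything observed.  S1: training females fully ungenotyped and
    prediction individuals reduced to the low-density panel (or nothing).
    S2: training fully observed, prediction reduced to the panel.
    """

    name: str
    panel_spacing_mb: float | None = None
    training_generations: frozenset = field(default_factory=frozenset)
    prediction_generations: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.name not in ("BASE", "S1", "S2"):
            raise ConfigurationError(f"unknown scenario {self.name!r}")
        self.training_generations = frozenset(self.training_generations)
        self.prediction_generations = frozenset(self.prediction_generations)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: PedigreeConfig, seed: int = 0) -> Pedigree:
    """Simulate a multi-generation pedigree.

    Generation 0 contains the founder breeders (``n_sires`` males then
    ``n_dams`` females); each subsequent generation is bred from sires and
    dams sampled from the previous generation, each dam producing
    ``offspring_per_dam`` offspring with sex assigned at random.  The final
    generation is the prediction set by convention.
    """
    rng = np.random.default_rng(seed)
    ids, sires, dams, sexes, gens = [], [], [], [], []
    next_id = 1

    def add(sire, dam, sex, gen):
        nonlocal next_id
        ids.append(next_id)
        sires.append(sire)
        dams.append(dam)
        sexes.append(sex)
        gens.append(gen)
        next_id += 1

    for _ in range(config.n_sires):
        add(0, 0, "M", 0)
    for _ in range(config.n_dams):
        add(0, 0, "F", 0)

    prev_ids = np.array(ids)
    prev_sex = np.array(sexes)
    for g in range(1, config.n_generations):
        males = prev_ids[prev_sex == "M"]
        females = prev_ids[prev_sex == "F"]
        if len(males) < config.n_sires:
            raise ConfigurationError(
                f"generation {g - 1} has {len(males)} males; "
                f"{config.n_sires} sires requested")
        if len(females) < config.n_dams:
            raise ConfigurationError(
                f"generation {g - 1} has {len(females)} females; "
                f"{config.n_dams} dams requested")
        gen_sires = rng.choice(males, size=config.n_sires, replace=False)
        gen_dams = rng.choice(females, size=config.n_dams, replace=False)
        start = len(ids)
        for dam in gen_dams:
            sire = int(rng.choice(gen_sires))
            for _ in range(config.offspring_per_dam):
                sex = "M" if rng.random() < 0.5 else "F"
                add(sire, int(dam), sex, g)
        prev_ids = np.array(ids[start:])
        prev_sex = np.array(sexes[start:])

    return Pedigree(np.array(ids), np.array(sires), np.array(dams),
                    np.array(sexes), np.array(gens))


def default_map(n_chromosomes: int = 5, snps_per_chrom: int = 150,
                chrom_length_mb: float = 100.0) -> GeneticMap:
    """Evenly spaced SNP map: ``snps_per_chrom`` loci per chromosome from
    1 bp to the chromosome end."""
    chroms, positions = [], []
    length_bp = int(chrom_length_mb * 1e6)
    for c in range(1, n_chromosomes + 1):
        pos = np.linspace(1, length_bp, snps_per_chrom).astype(np.int64)
        chroms.append(np.full(snps_per_chrom, c))
        positions.append(pos)
    return GeneticMap(np.concatenate(chroms), np.concatenate(positions))


# ---------------------------------------------------------------------------
# founders and gene drop
# ---------------------------------------------------------------------------

def simulate_founders(n_founders: int, gmap: GeneticMap,
                      maf_low: float = 0.1, maf_high: float = 0.5,
                      ld_block_loci: int = 25, pool_size: int = 8,
                      seed: int = 0) -> np.ndarray:
    """Founder haplotypes with block-copy linkage disequilibrium.

    A small pool of ancestral haplotypes is drawn with per-locus allele
    frequencies targeted uniformly in [maf_low, maf_high]; each founder
    haplotype is a mosaic of blocks (``ld_block_loci`` loci each) copied
    from the pool, giving strong positive LD within blocks.

    Returns a (2 * n_founders, L) array of 0/1 alleles, two consecutive
    rows per founder.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ConfigurationError("need 0 < maf_low <= maf_high <= 0.5")
    if gmap.n_loci == 0:
        raise ConfigurationError("empty map")
    rng = np.random.default_rng(seed)
    L = gmap.n_loci
    target = rng.uniform(maf_low, maf_high, size=L)
    # pool with per-locus allele-1 count as close as possible to pool*target
    pool = np.zeros((pool_size, L), dtype=np.int8)
    for locus in range(L):
        k = int(round(pool_size * target[locus]))
        k = min(max(k, 1), pool_size - 1)  # keep every locus segregating in pool
        carriers = rng.choice(pool_size, size=k, replace=False)
        pool[carriers, locus] = 1
    haps = np.empty((2 * n_founders, L), dtype=np.int8)
    for c in gmap.chromosomes:
        s = gmap.chrom_slice(c)
        n_blocks = int(np.ceil((s.stop - s.start) / ld_block_loci))
        for b in range(n_blocks):
            lo = s.start + b * ld_block_loci
            hi = min(lo + ld_block_loci, s.stop)
            src = rng.integers(0, pool_size, size=2 * n_founders)
            haps[:, lo:hi] = pool[src, lo:hi]
    return haps


def _meiosis(pat: np.ndarray, mat: np.ndarray, gmap: GeneticMap,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete: per chromosome, Poisson(#Morgans) crossovers at uniform
    positions between the parent's two haplotypes (Haldane)."""
    gamete = np.empty_like(pat)
    for c in gmap.chromosomes:
        s = gmap.chrom_slice(c)
        pos = gmap.pos[s]
        morgans = gmap.chrom_morgans(c)
        n_x = rng.poisson(morgans)
        cuts = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
        # current strand flips at each crossover position
        strand = int(rng.integers(0, 2))
        flips = np.searchsorted(cuts, pos, side="right")
        use_pat = ((strand + flips) % 2) == 0
        gamete[s] = np.where(use_pat, pat[s], mat[s])
    return gamete


def gene_drop(pedigree: Pedigree, founders: np.ndarray, gmap: GeneticMap,
              seed: int = 0) -> TrueGenome:
    """Drop founder haplotypes through the pedigree with Haldane
    recombination.  Requires both-or-neither known parents."""
    rng = np.random.default_rng(seed)
    n, L = pedigree.n, gmap.n_loci
    founder_rows = np.flatnonzero(pedigree.is_founder)
    if founders.shape[0] < 2 * len(founder_rows):
        raise ConfigurationError(
            f"{len(founder_rows)} founders need {2 * len(founder_rows)} "
            f"haplotypes; got {founders.shape[0]}")
    pat = np.zeros((n, L), dtype=np.int8)
    mat = np.zeros((n, L), dtype=np.int8)
    sidx, didx = pedigree.sire_index, pedigree.dam_index
    f = 0
    for i in range(n):
        if sidx[i] < 0 and didx[i] < 0:
            pat[i] = founders[2 * f]
            mat[i] = founders[2 * f + 1]
            f += 1
        elif sidx[i] >= 0 and didx[i] >= 0:
            pat[i] = _meiosis(pat[sidx[i]], mat[sidx[i]], gmap, rng)
            mat[i] = _meiosis(pat[didx[i]], mat[didx[i]], gmap, rng)
        else:
            raise ConfigurationError(
                f"individual {int(pedigree.ids[i])} has exactly one known "
                "parent; the simulator requires both or neither")
    return TrueGenome(pat, mat)


# ---------------------------------------------------------------------------
# trait
# ---------------------------------------------------------------------------

def simulate_trait(genome: TrueGenome, pedigree: Pedigree, n_qtl: int,
                   h2: float, n_imprinted: int = 0,
                   imprinting: np.ndarray | None = None,
                   seed: int = 0) -> TraitArchitecture:
    """Quantitative trait from ``n_qtl`` mapped SNPs with standard-normal
    additive effects; paternally imprinted QTL contribute only through the
    paternally inherited allele (doubled so expected variance matches an
    additive QTL of the same effect size).

    Phenotype = TBV + N(0, var_e) with var_e solved from ``h2`` on the
    realized TBV variance; only training generations (all but the last)
    receive phenotypes.
    """
    if not (0 < h2 <= 1):
        raise ConfigurationError("h2 must be in (0, 1]")
    L = genome.paternal.shape[1]
    if n_qtl > L:
        raise ConfigurationError("more QTL than loci")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(L, size=n_qtl, replace=False))
    effects = rng.normal(0.0, 1.0, size=n_qtl)
    if imprinting is None:
        imprinting = np.array(["none"] * n_qtl, dtype=object)
        if n_imprinted:
            imprinting[rng.choice(n_qtl, size=min(n_imprinted, n_qtl),
                                  replace=False)] = "paternal"
    imprinting = np.asarray(imprinting, dtype=object)

    pat_q = genome.paternal[:, qtl].astype(float)
    dose_q = pat_q + genome.maternal[:, qtl]
    imprint = imprinting == "paternal"
    contrib = np.where(imprint[None, :], 2.0 * pat_q, dose_q)
    tbv = contrib @ effects

    var_tbv = float(np.var(tbv))
    if h2 == 1.0:
        noise = np.zeros(pedigree.n)
    else:
        var_e = var_tbv * (1.0 - h2) / h2
        noise = rng.normal(0.0, np.sqrt(var_e), size=pedigree.n)
    phen = tbv + noise
    last_gen = int(pedigree.generation.max())
    phen = np.where(pedigree.generation < last_gen, phen, np.nan)
    return TraitArchitecture(qtl, effects, imprinting, h2, tbv, phen)


# ---------------------------------------------------------------------------
# masking scenarios
# ---------------------------------------------------------------------------

def panel_loci(gmap: GeneticMap, spacing_mb: float) -> np.ndarray:
    """Low-density panel: per chromosome, the SNP nearest each multiple of
    ``spacing_mb`` measured from position 0 (inclusive), ties to the lower
    position, deduplicated."""
    spacing = spacing_mb * 1e6
    keep: list[int] = []
    for c in gmap.chromosomes:
        s = gmap.chrom_slice(c)
        pos = gmap.pos[s].astype(float)
        if spacing > pos[-1]:
            warnings.warn(
                f"panel spacing {spacing_mb} Mb exceeds chromosome {c} "
                "length; keeping its first SNP")
        targets = np.arange(0.0, pos[-1] + 0.5, spacing)
        for t in targets:
            j = int(np.argmin(np.abs(pos - t)))  # argmin ties -> lower index
            keep.append(s.start + j)
    return np.unique(np.array(keep, dtype=np.int64))


def apply_scenario(genotypes: np.ndarray, pedigree: Pedigree,
                   spec: ScenarioSpec, gmap: GeneticMap) -> np.ndarray:
    """Mask a complete genotype matrix per the scenario. Returns a copy;
    unmasked entries are never altered."""
    out = np.array(genotypes, dtype=np.int8, copy=True)
    if spec.name == "BASE":
        return out
    gen = pedigree.generation
    is_pred = np.isin(gen, list(spec.prediction_generations))
    if spec.name == "S1":
        is_train = np.isin(gen, list(spec.training_generations))
        female_train = is_train & (pedigree.sex == "F")
        out[female_train, :] = MISSING
    if spec.panel_spacing_mb is None:
        out[is_pred, :] = MISSING
    else:
        panel = panel_loci(gmap, spec.panel_spacing_mb)
        off_panel = np.setdiff1d(np.arange(gmap.n_loci), panel)
        rows = np.flatnonzero(is_pred)
        out[np.ix_(rows, off_panel)] = MISSING
    return out
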