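"""Haplotype-pair imputation from geneprobs and a long-haplotype library.

For each non-genotyped or low-density genotyped individual, the most
probable genotype is inferred per locus from its geneprobs (pre-selection,
gated by the GPI information index), single library haplotypes are screened
against the putative homozygous loci (step 1), surviving haplotypes are
paired in all combinations and screened against all confident genotypes
under a descending GPI schedule (step 2), and any remaining ambiguity is
resolved by the geneprob-mass score of each pair (step 3).  When no pair
can be identified, fallback functions call individual genotypes from the
frequency of a genotype among surviving pairs, or directly where the GPI
shows no ambiguity; everything still missing is filled from the geneprob
argmax so the output matrix is complete for downstream genomic prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
from sklearn.base import BaseEstimator

from .genmap import GeneticMap
from .phasing import HaplotypeLibrary
from .segregation import Geneprobs
from .simulate import MISSING

__all__ = [
    "ImputationConfig", "MostProbableGenotypes", "CandidateSet",
    "ImputationResult", "preselect_genotypes", "step1_filter", "step2_filter",
    "step3_select", "fallback_calls", "impute_individual", "SALHIImputer",
    "imputation_accuracy",
    "PROV_OBSERVED", "PROV_PAIR", "PROV_FALLBACK_FREQ", "PROV_FALLBACK_GPI",
    "PROV_GENEPROB", "PROV_UNCALLED",
]

logger = logging.getLogger(__name__)

# call provenance codes
PROV_OBSERVED = 0       # genotype was observed (high-density or panel)
PROV_PAIR = 1           # from the selected haplotype pair
PROV_FALLBACK_FREQ = 2  # frequency of the genotype among surviving pairs
PROV_FALLBACK_GPI = 3   # GPI showed no ambiguity
PROV_GENEPROB = 4       # geneprob argmax fill
PROV_UNCALLED = 5       # transient; never present in final output

_TIE_EPS = 1e-9


@dataclass
class ImputationConfig:
    """Thresholds of the haplotype-matching algorithm, all in GPI units
    [0, 100] except the error thresholds (mismatch counts; ``None`` means
    the proportional default max(1, 1% of compared loci))."""

    gpi_min_step1: float = 90.0
    gpi_min_step2_start: float = 99.0
    gpi_min_step2_floor: float = 60.0
    gpi_step2_decrement: float = 5.0
    error_threshold_step1: int | None = None
    error_threshold_step2: int | None = None
    fallback_freq_threshold: float = 0.9
    use_step3: bool = True
    step3_score: str = "sum"  # or "product"
    # when no haplotype pair survives, the error thresholds are relaxed
    # geometrically (the thresholds are data-fit parameters: a library
    # rarely contains the exact recombinant gametes of fresh candidates)
    adaptive_relax: float = 2.0
    max_relax: float = 32.0
    threshold_scale: float = 1.0

    def __post_init__(self):
        for name in ("gpi_min_step1", "gpi_min_step2_start",
                     "gpi_min_step2_floor"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.gpi_min_step2_floor > self.gpi_min_step2_start:
            raise ValueError("step-2 GPI floor exceeds its start")
        if self.gpi_step2_decrement <= 0:
            raise ValueError("step-2 GPI decrement must be positive")
        if self.step3_score not in ("sum", "product"):
            raise ValueError("step3_score must be 'sum' or 'product'")

    def error_threshold(self, which: int, n_compared: int) -> int:
        explicit = (self.error_threshold_step1 if which == 1
                    else self.error_threshold_step2)
        if explicit is not None:
            return int(self.threshold_scale * int(explicit))
        return max(1, int(self.threshold_scale
                          * max(1, int(0.01 * n_compared))))


@dataclass
class MostProbableGenotypes:
    """Per-locus argmax genotype (heterozygote on ties), zygosity and the
    GPI-based exclusion mask used by the filtering steps."""

    genotype: np.ndarray   # (L,) in {0,1,2}
    is_het: np.ndarray     # (L,) bool
    excluded: np.ndarray   # (L,) bool: GPI below the active threshold
    gpi: np.ndarray        # (L,)


@dataclass
class CandidateSet:
    """Surviving haplotypes (stage 'single') or unordered haplotype-id
    pairs (stage 'pair') with mismatch counts."""

    stage: str
    ids: np.ndarray        # (k,) haplotype ids, or (k, 2) with i <= j
    mismatches: np.ndarray


@dataclass
class ImputationResult:
    """Complete imputed dosage matrix with per-entry call provenance and
    the selected haplotype pair per individual and chromosome."""

    dosages: np.ndarray     # (n, L) 0/1/2, no missing
    provenance: np.ndarray  # (n, L) PROV_* codes
    selected_pairs: dict = field(default_factory=dict)  # (row, chrom) -> (i, j)
    imputed_rows: np.ndarray | None = None


def preselect_genotypes(probs: np.ndarray, gpi: np.ndarray,
                        gpi_min: float) -> MostProbableGenotypes:
    """Most probable genotype per locus from the geneprob triple; the
    heterozygote is the default when no class is strictly most probable;
    loci with GPI < ``gpi_min`` are excluded from haplotype comparison."""
    probs = np.asarray(probs, dtype=float)
    top = probs.max(axis=1)
    tied = (np.abs(probs - top[:, None]) < _TIE_EPS).sum(axis=1) > 1
    geno = np.argmax(probs, axis=1).astype(np.int8)
    geno[tied] = 1
    return MostProbableGenotypes(
        genotype=geno,
        is_het=geno == 1,
        excluded=np.asarray(gpi) < gpi_min,
        gpi=np.asarray(gpi, dtype=float),
    )


def step1_filter(mpg: MostProbableGenotypes, haplotypes: np.ndarray,
                 config: ImputationConfig) -> CandidateSet:
    """Screen single haplotypes against the putative homozygous loci.

    A haplotype is excluded when the number of qualifying loci (not
    excluded, putatively homozygous) where its allele cannot produce the
    homozygote exceeds the step-1 error threshold.  Heterozygous loci
    never contribute.
    """
    H = np.asarray(haplotypes)
    use = ~mpg.excluded & ~mpg.is_het
    idx0 = np.flatnonzero(use & (mpg.genotype == 0))
    idx2 = np.flatnonzero(use & (mpg.genotype == 2))
    opposing = (H[:, idx0] == 1).sum(axis=1) + (H[:, idx2] == 0).sum(axis=1)
    thr = config.error_threshold(1, len(idx0) + len(idx2))
    keep = np.flatnonzero(opposing <= thr)
    return CandidateSet("single", keep, opposing[keep])


def _pair_mismatch_matrix(H: np.ndarray, geno: np.ndarray,
                          loci: np.ndarray) -> np.ndarray:
    """(k, k) mismatch counts over ``loci`` between every haplotype pair's
    implied genotype (allele sum) and the target genotypes."""
    k = H.shape[0]
    M = np.zeros((k, k), dtype=np.int64)
    if len(loci) == 0:
        return M
    A = H[:, loci].astype(np.float64)
    B = 1.0 - A
    t = geno[loci]
    l0 = t == 0
    l2 = t == 2
    l1 = t == 1
    # matches per target class, via matrix products
    m = (B[:, l0] @ B[:, l0].T) + (A[:, l2] @ A[:, l2].T)
    m += A[:, l1] @ B[:, l1].T + B[:, l1] @ A[:, l1].T
    M = len(loci) - np.rint(m).astype(np.int64)
    return M


def step2_filter(candidates: CandidateSet, mpg: MostProbableGenotypes,
                 config: ImputationConfig,
                 haplotypes: np.ndarray) -> CandidateSet:
    """Pair surviving haplotypes in all combinations (self-pairs included)
    and screen their implied genotypes against the most probable genotypes
    at every locus with GPI above the schedule's minimum; the minimum
    descends from ``gpi_min_step2_start`` by ``gpi_step2_decrement`` until
    one pair remains or the floor is reached.  A re-filter that would
    eliminate every pair is undone and the schedule stops.
    """
    singles = np.asarray(candidates.ids, dtype=np.int64)
    k = len(singles)
    if k == 0:
        return CandidateSet("pair", np.zeros((0, 2), dtype=np.int64),
                            np.zeros(0, dtype=np.int64))
    H = np.asarray(haplotypes)[singles]
    iu = np.triu_indices(k)

    g = config.gpi_min_step2_start
    used = np.zeros(len(mpg.genotype), dtype=bool)
    M = np.zeros((k, k), dtype=np.int64)
    n_compared = 0
    alive: np.ndarray | None = None
    while True:
        new = (mpg.gpi >= g) & ~used
        loci = np.flatnonzero(new)
        used |= new
        n_compared += len(loci)
        M = M + _pair_mismatch_matrix(H, mpg.genotype, loci)
        thr = config.error_threshold(2, n_compared)
        ok = M[iu] <= thr
        if alive is None:
            alive = ok
            if not alive.any():
                return CandidateSet("pair", np.zeros((0, 2), dtype=np.int64),
                                    np.zeros(0, dtype=np.int64))
        else:
            nxt = alive & ok
            if not nxt.any():
                break  # keep the last non-empty surviving set
            alive = nxt
        if alive.sum() <= 1 or g <= config.gpi_min_step2_floor:
            break
        g -= config.gpi_step2_decrement
        if g < config.gpi_min_step2_floor:
            g = config.gpi_min_step2_floor
    sel = np.flatnonzero(alive)
    pairs = np.stack([singles[iu[0][sel]], singles[iu[1][sel]]], axis=1)
    return CandidateSet("pair", pairs, M[iu][sel])


def _implied_genotypes(pairs: np.ndarray, haplotypes: np.ndarray) -> np.ndarray:
    """(P, L) genotypes implied by each unordered haplotype pair."""
    H = np.asarray(haplotypes)
    return (H[pairs[:, 0]] + H[pairs[:, 1]]).astype(np.int8)


def step3_select(pairs: CandidateSet, probs: np.ndarray,
                 haplotypes: np.ndarray,
                 score: str = "sum") -> tuple[int, int]:
    """Retain the pair with the highest geneprob score: the sum over all
    loci of the geneprob mass assigned to the genotype the pair implies
    (or the product of those masses with ``score='product'``).  Ties break
    to the lexicographically smallest id pair and are logged."""
    pid = np.asarray(pairs.ids, dtype=np.int64)
    G = _implied_genotypes(pid, haplotypes)
    L = probs.shape[0]
    mass = probs[np.arange(L)[None, :], G]
    if score == "product":
        with np.errstate(divide="ignore"):
            scores = np.where(mass > 0, np.log(np.where(mass > 0, mass, 1.0)),
                              -np.inf).sum(axis=1)
    else:
        scores = mass.sum(axis=1)
    best = scores.max()
    tied = np.flatnonzero(scores >= best - _TIE_EPS)
    if len(tied) > 1:
        logger.debug("step3 tie among %d pairs; lexicographic tie-break",
                     len(tied))
    order = np.lexsort((pid[tied, 1], pid[tied, 0]))
    i, j = pid[tied[order[0]]]
    return int(i), int(j)


def fallback_calls(pairs: CandidateSet, probs: np.ndarray, gpi: np.ndarray,
                   config: ImputationConfig,
                   haplotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partial genotype calls when no unique pair was identified.

    A locus is called when a fraction >= ``fallback_freq_threshold`` of
    surviving pairs imply the same genotype, and, independently, whenever
    GPI = 100 leaves no ambiguity (geneprob argmax).  Returns (genotypes
    with MISSING where uncalled, provenance with PROV_UNCALLED there).
    """
    L = probs.shape[0]
    geno = np.full(L, MISSING, dtype=np.int8)
    prov = np.full(L, PROV_UNCALLED, dtype=np.int8)
    pid = np.asarray(pairs.ids, dtype=np.int64)
    if len(pid) > 0:
        G = _implied_genotypes(pid, haplotypes)
        for t in range(3):
            frac = (G == t).mean(axis=0)
            sel = frac >= config.fallback_freq_threshold
            geno[sel] = t
            prov[sel] = PROV_FALLBACK_FREQ
    sure = np.asarray(gpi) >= 100.0 - _TIE_EPS
    geno[sure] = np.argmax(probs[sure], axis=1).astype(np.int8)
    prov[sure] = PROV_FALLBACK_GPI
    return geno, prov


def impute_individual(probs: np.ndarray, gpi: np.ndarray,
                      observed: np.ndarray, library: HaplotypeLibrary,
                      gmap: GeneticMap,
                      config: ImputationConfig) -> tuple[np.ndarray, np.ndarray, dict]:
    """Full pipeline for one individual: preselect, step 1-3 per
    chromosome, fallbacks, geneprob fill; observed entries pass through.

    Returns (dosages, provenance, selected pair per chromosome).
    """
    L = gmap.n_loci
    geno = np.full(L, MISSING, dtype=np.int8)
    prov = np.full(L, PROV_UNCALLED, dtype=np.int8)
    sel_pairs: dict[int, tuple[int, int]] = {}
    for c in gmap.chromosomes:
        s = gmap.chrom_slice(c)
        p, q = probs[s], gpi[s]
        haps = library.haplotypes.get(int(c))
        if haps is None or len(haps) == 0:
            fg, fp = fallback_calls(
                CandidateSet("pair", np.zeros((0, 2), np.int64),
                             np.zeros(0, np.int64)), p, q, config,
                np.zeros((0, s.stop - s.start), np.int8))
            geno[s], prov[s] = fg, fp
            continue
        mpg1 = preselect_genotypes(p, q, config.gpi_min_step1)
        mpg2 = preselect_genotypes(p, q, 0.0)  # step-2 gating is by schedule
        scale = 1.0
        while True:
            cfg_s = replace(config, threshold_scale=scale)
            singles = step1_filter(mpg1, haps, cfg_s)
            pairs = step2_filter(singles, mpg2, cfg_s, haps)
            if len(pairs.ids) > 0 or scale >= config.max_relax:
                break
            scale *= config.adaptive_relax
        if len(pairs.ids) == 1 or (len(pairs.ids) > 1 and config.use_step3):
            if len(pairs.ids) == 1:
                i, j = int(pairs.ids[0, 0]), int(pairs.ids[0, 1])
            else:
                i, j = step3_select(pairs, p, haps, config.step3_score)
            cg = haps[i] + haps[j]
            cp = np.full(s.stop - s.start, PROV_PAIR, dtype=np.int8)
            # a GPI of 100 leaves no ambiguity: never let the pair
            # overrule a certain genotype
            sure = q >= 100.0 - _TIE_EPS
            cg[sure] = np.argmax(p[sure], axis=1).astype(np.int8)
            cp[sure] = PROV_FALLBACK_GPI
            geno[s], prov[s] = cg, cp
            sel_pairs[int(c)] = (i, j)
        else:
            fg, fp = fallback_calls(pairs, p, q, config, haps)
            geno[s], prov[s] = fg, fp
    # geneprob fill for anything still missing
    miss = geno == MISSING
    geno[miss] = np.argmax(probs[miss], axis=1).astype(np.int8)
    prov[miss] = PROV_GENEPROB
    # observed passthrough
    obs = observed != MISSING
    geno[obs] = observed[obs]
    prov[obs] = PROV_OBSERVED
    return geno, prov, sel_pairs


class SALHIImputer(BaseEstimator):
    """Imputes complete genotypes for sparsely genotyped individuals from
    a haplotype library and segregation-analysis geneprobs.

    ``fit`` stores the library; ``impute`` runs the matching pipeline for
    every row with missing genotypes.  Configuration mirrors
    :class:`ImputationConfig`.
    """

    def __init__(self, gpi_min_step1: float = 90.0,
                 gpi_min_step2_start: float = 99.0,
                 gpi_min_step2_floor: float = 60.0,
                 gpi_step2_decrement: float = 5.0,
                 error_threshold_step1: int | None = None,
                 error_threshold_step2: int | None = None,
                 fallback_freq_threshold: float = 0.9,
                 use_step3: bool = True, step3_score: str = "sum",
                 adaptive_relax: float = 2.0, max_relax: float = 32.0,
                 threshold_scale: float = 1.0):
        self.gpi_min_step1 = gpi_min_step1
        self.gpi_min_step2_start = gpi_min_step2_start
        self.gpi_min_step2_floor = gpi_min_step2_floor
        self.gpi_step2_decrement = gpi_step2_decrement
        self.error_threshold_step1 = error_threshold_step1
        self.error_threshold_step2 = error_threshold_step2
        self.fallback_freq_threshold = fallback_freq_threshold
        self.use_step3 = use_step3
        self.step3_score = step3_score
        self.adaptive_relax = adaptive_relax
        self.max_relax = max_relax
        self.threshold_scale = threshold_scale

    def _config(self) -> ImputationConfig:
        return ImputationConfig(**{f.name: getattr(self, f.name)
                                   for f in fields(ImputationConfig)})

    def fit(self, library: HaplotypeLibrary, gmap: GeneticMap | None = None):
        self.library_ = library
        self.gmap_ = gmap
        return self

    def impute(self, geneprobs: Geneprobs, observed: np.ndarray,
               gmap: GeneticMap | None = None) -> ImputationResult:
        """Impute every row of ``observed`` that has missing entries.
        Fully observed rows pass through untouched."""
        if not hasattr(self, "library_"):
            raise RuntimeError("imputer is not fitted; call fit(library)")
        gmap = gmap if gmap is not None else self.gmap_
        cfg = self._config()
        n, L = observed.shape
        dosages = np.array(observed, dtype=np.int8, copy=True)
        prov = np.full((n, L), PROV_OBSERVED, dtype=np.int8)
        pairs: dict[tuple[int, int], tuple[int, int]] = {}
        rows = np.flatnonzero(np.any(observed == MISSING, axis=1))
        for i in rows:
            g, p, sel = impute_individual(geneprobs.probs[i],
                                          geneprobs.gpi[i], observed[i],
                                          self.library_, gmap, cfg)
            dosages[i], prov[i] = g, p
            for c, pr in sel.items():
                pairs[(int(i), c)] = pr
        return ImputationResult(dosages, prov, pairs, rows)


def imputation_accuracy(result: ImputationResult, truth: np.ndarray,
                        mask: np.ndarray) -> dict:
    """Percent of masked entries whose imputed dosage equals the truth,
    overall and per provenance class (NaN when nothing was masked)."""
    mask = np.asarray(mask, dtype=bool)
    n_masked = int(mask.sum())
    out: dict[str, float] = {}
    if n_masked == 0:
        out["overall"] = float("nan")
        return out
    good = (result.dosages == truth) & mask
    out["overall"] = 100.0 * good.sum() / n_masked
    names = {PROV_PAIR: "pair", PROV_FALLBACK_FREQ: "fallback_freq",
             PROV_FALLBACK_GPI: "fallback_gpi", PROV_GENEPROB: "geneprob_fill"}
    called = mask & (result.provenance != PROV_GENEPROB)
    out["called_only"] = (100.0 * (good & called).sum() / called.sum()
                          if called.any() else float("nan"))
    for code, name in names.items():
        sel = mask & (result.provenance == code)
        out[name] = (100.0 * (good & sel).sum() / sel.sum()
                     if sel.any() else float("nan"))
        out[f"n_{name}"] = int(sel.sum())
    return out
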