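"""Long-range phasing of densely genotyped individuals and assembly of a
chromosome-length haplotype library.

Each chromosome is split into ~10 Mb cores.  Within a core an individual's
heterozygous loci are resolved by "surrogate parents": pedigree relatives
(the parent itself, its parents, and half/full sibs through that parent)
that show no opposing homozygotes with the individual inside the core and
therefore plausibly share the corresponding gamete identical by descent.
Homozygous surrogates vote on the allele carried by the shared gamete;
a locus is phased when a large majority agrees.  Core haplotypes of the
same gamete are concatenated into one long haplotype per chromosome, and
complete haplotypes are collected, deduplicated, into the library.

Phasing is fully deterministic: no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap
from .pedigree import Pedigree
from .simulate import MISSING

__all__ = [
    "CorePartition", "HaplotypeLibrary", "partition_cores",
    "count_opposing_homozygotes", "find_surrogates", "phase_core",
    "build_library", "LongRangePhaser",
]

UNPHASED = -1  # missing allele in phased haplotypes


@dataclass
class CorePartition:
    """Per chromosome, half-open global locus-index intervals covering all
    loci exactly once."""

    cores: dict  # chrom -> list of (start, stop)
    core_length_mb: float

    def chrom_cores(self, c: int) -> list[tuple[int, int]]:
        return self.cores[int(c)]


@dataclass
class HaplotypeLibrary:
    """Distinct complete haplotypes per chromosome with occurrence counts."""

    haplotypes: dict = field(default_factory=dict)  # chrom -> (H, Lc) 0/1
    counts: dict = field(default_factory=dict)      # chrom -> (H,) int

    def n_haplotypes(self, c: int) -> int:
        return 0 if c not in self.haplotypes else len(self.haplotypes[c])

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.haplotypes)


def partition_cores(gmap: GeneticMap, core_length_mb: float = 10.0) -> CorePartition:
    """Cut each chromosome at the first SNP at/after each multiple of the
    core length; a final remainder shorter than half a core is absorbed
    into the previous core."""
    if core_length_mb <= 0:
        raise ValueError("core_length_mb must be positive")
    core_bp = core_length_mb * 1e6
    cores: dict[int, list[tuple[int, int]]] = {}
    for c in gmap.chromosomes:
        s = gmap.chrom_slice(c)
        pos = gmap.pos[s]
        bounds = [s.start]
        m = core_bp
        while m <= pos[-1]:
            j = int(np.searchsorted(pos, m, side="left"))
            if s.start + j > bounds[-1] and s.start + j < s.stop:
                bounds.append(s.start + j)
            m += core_bp
        bounds.append(s.stop)
        # absorb a short tail into the previous core
        if len(bounds) > 2:
            tail_span = pos[-1] - gmap.pos[bounds[-2]]
            if tail_span < core_bp / 2:
                bounds.pop(-2)
        cores[int(c)] = [(bounds[i], bounds[i + 1])
                         for i in range(len(bounds) - 1)]
    return CorePartition(cores, core_length_mb)


def count_opposing_homozygotes(g1: np.ndarray, g2: np.ndarray,
                               interval: tuple[int, int] | None = None) -> int:
    """Loci where one vector is homozygous 0 and the other homozygous 2 —
    proof the two individuals share neither gamete there.  Missing and
    heterozygous loci never contribute."""
    if len(g1) != len(g2):
        raise ValueError("genotype vectors differ in length")
    if interval is not None:
        g1 = g1[interval[0]:interval[1]]
        g2 = g2[interval[0]:interval[1]]
    return int(np.count_nonzero(((g1 == 0) & (g2 == 2))
                                | ((g1 == 2) & (g2 == 0))))


def _candidate_relatives(i: int, side: str, pedigree: Pedigree) -> list[tuple[int, int, int, str]]:
    """(proximity_rank, row, other_parent_row, shared_side) candidates
    sharing individual i's paternal or maternal gamete path: the parent,
    the parent's parents, and half-sibs through that parent.

    For sib candidates, ``other_parent_row`` is the sib's parent on the
    non-shared side: when that parent is homozygous, the allele the sib
    carries on the shared gamete is deducible even at the sib's
    heterozygous loci (-1 where no such deduction applies).
    ``shared_side`` says which of the surrogate's own gametes is the
    shared one: 'P' (its paternal), 'M' (its maternal) or '?' (unknown,
    e.g. the parent itself or a grandparent).
    """
    sidx, didx = pedigree.sire_index, pedigree.dam_index
    parent = sidx[i] if side == "paternal" else didx[i]
    if parent < 0:
        return []
    out = [(0, int(parent), -1, "?")]
    for gp in (sidx[parent], didx[parent]):
        if gp >= 0:
            out.append((1, int(gp), -1, "?"))
    pid = int(pedigree.ids[parent])
    own_other = didx[i] if side == "paternal" else sidx[i]
    for o in pedigree.offspring_of(pid):
        if o == i:
            continue
        if int(pedigree.sire[o]) == pid:
            other, schar = int(didx[o]), "P"
        else:
            other, schar = int(sidx[o]), "M"
        # full sibs share both parents, so a zero-opposing match cannot be
        # attributed to one side; only half-sibs through this parent vote
        if other == own_other:
            continue
        out.append((2, int(o), other, schar))
    return out


def find_surrogates(i: int, side: str, genotypes: np.ndarray,
                    pedigree: Pedigree, core: tuple[int, int],
                    max_opposing: int = 0) -> list[tuple[int, int]]:
    """Ordered surrogates for one side of individual ``i`` in a core:
    genotyped candidate relatives with at most ``max_opposing`` opposing
    homozygotes to ``i`` inside the core, ordered by pedigree proximity
    then opposing count (then row for determinism).

    Returns (row, other_parent_row, shared_side) triples; see
    :func:`_candidate_relatives`.
    """
    lo, hi = core
    gi = genotypes[i, lo:hi]
    scored = []
    for rank, r, other, schar in _candidate_relatives(i, side, pedigree):
        gr = genotypes[r, lo:hi]
        if np.all(gr == MISSING):
            continue
        opp = count_opposing_homozygotes(gi, gr)
        if opp <= max_opposing:
            scored.append((rank, opp, r, other, schar))
    scored.sort()
    return [(r, other, schar) for _, _, r, other, schar in scored]


def phase_core(i: int, genotypes: np.ndarray, pat_surrogates: list,
               mat_surrogates: list, core: tuple[int, int],
               agreement_threshold: float = 0.9, sire_row: int = -1,
               dam_row: int = -1, phased_prev: dict | None = None,
               min_confident_votes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Phase one individual in one core.

    Homozygous loci are phased trivially.  At heterozygous loci the parent
    genotype is applied first (a homozygous parent forces its side: sire
    dosage 2 forces paternal allele 1), then surrogate voting: each
    side-surrogate that can reveal the allele it carries on the shared
    gamete votes, and if a fraction >= ``agreement_threshold`` (at least
    one informative surrogate) agrees, that allele is assigned to the side
    and its complement to the other.  A surrogate's shared-gamete allele
    is known when the surrogate is homozygous, when its other parent is
    homozygous, or — on re-phasing passes — when its shared-side haplotype
    was already resolved (``phased_prev``: row -> (pat, mat) full-length
    vectors).  Unresolved or conflicting loci stay unphased on both sides.

    Surrogate entries are (row, other_parent_row, shared_side) triples as
    produced by :func:`find_surrogates`; bare rows are accepted too.

    Returns (paternal, maternal, confident): allele vectors with -1 =
    unphased, plus a per-locus flag marking calls backed by strong
    evidence (homozygous, parent-forced, or a unanimous vote of at least
    two informative surrogates).  Only confident gametes enter the
    haplotype library; weakly resolved alleles still appear in the long
    haplotypes.
    """
    lo, hi = core
    g = genotypes[i, lo:hi]
    w = hi - lo
    pat = np.full(w, UNPHASED, dtype=np.int8)
    mat = np.full(w, UNPHASED, dtype=np.int8)
    conf = np.zeros(w, dtype=bool)
    homo = (g == 0) | (g == 2)
    pat[homo] = (g[homo] // 2).astype(np.int8)
    mat[homo] = (g[homo] // 2).astype(np.int8)
    conf[homo] = True

    het = np.flatnonzero(g == 1)
    if len(het) == 0:
        return pat, mat, conf

    def parent_force(row: int, j: int) -> int:
        if row < 0:
            return UNPHASED
        gp = genotypes[row, lo + j]
        if gp == 0:
            return 0
        if gp == 2:
            return 1
        return UNPHASED

    def side_vote(surrogates: list, j: int) -> int:
        votes = [0, 0]
        for entry in surrogates:
            if isinstance(entry, tuple):
                r, other, schar = entry
            else:
                r, other, schar = entry, -1, "?"
            if phased_prev is not None and schar != "?" and r in phased_prev:
                hap = phased_prev[r][0 if schar == "P" else 1]
                a = hap[lo + j]
                if a != UNPHASED:
                    votes[a] += 1
                    continue
            gr = genotypes[r, lo + j]
            if gr == 0:
                votes[0] += 1
            elif gr == 2:
                votes[1] += 1
            elif gr == 1 and other >= 0:
                # surrogate heterozygous: its allele on the shared gamete
                # is deducible when its other parent is homozygous
                go = genotypes[other, lo + j]
                if go == 0:
                    votes[1] += 1
                elif go == 2:
                    votes[0] += 1
        total = votes[0] + votes[1]
        if total == 0:
            return UNPHASED, False
        best = 0 if votes[0] >= votes[1] else 1
        if votes[best] / total >= agreement_threshold:
            return best, votes[best] == total and total >= min_confident_votes
        return UNPHASED, False

    for j in het:
        a_pat = parent_force(sire_row, j)
        a_mat = parent_force(dam_row, j)
        strong = a_pat != UNPHASED or a_mat != UNPHASED
        if a_pat == UNPHASED and a_mat == UNPHASED:
            a_pat, sp = side_vote(pat_surrogates, j)
            a_mat, sm = side_vote(mat_surrogates, j)
            strong = (sp if a_pat != UNPHASED else True) and \
                     (sm if a_mat != UNPHASED else True) and \
                     (a_pat != UNPHASED or a_mat != UNPHASED)
        if a_pat != UNPHASED and a_mat != UNPHASED:
            if a_pat + a_mat != 1:  # conflict at a het locus
                continue
            pat[j], mat[j] = a_pat, a_mat
            conf[j] = strong
        elif a_pat != UNPHASED:
            pat[j], mat[j] = a_pat, 1 - a_pat
            conf[j] = strong
        elif a_mat != UNPHASED:
            mat[j], pat[j] = a_mat, 1 - a_mat
            conf[j] = strong
    return pat, mat, conf


def mosaic_switches(gamete: np.ndarray, parent_pat: np.ndarray,
                    parent_mat: np.ndarray) -> int | None:
    """Minimal number of template switches needed to write ``gamete`` as a
    mosaic of the parent's two haplotypes (unphased parent alleles act as
    wildcards).  Returns None when some allele matches neither template —
    evidence of a phasing error rather than recombination."""
    can_p = (parent_pat == UNPHASED) | (parent_pat == gamete)
    can_m = (parent_mat == UNPHASED) | (parent_mat == gamete)
    if np.any(~can_p & ~can_m):
        return None
    switches = 0
    state_p = state_m = True
    for cp, cm in zip(can_p, can_m):
        np_, nm = state_p and cp, state_m and cm
        if not (np_ or nm):
            switches += 1
            np_, nm = cp, cm
        state_p, state_m = np_, nm
    return switches


def build_library(phased: dict, partition: CorePartition, gmap: GeneticMap,
                  genotypes: np.ndarray, completeness_min: float = 0.99,
                  eligible: dict | None = None) -> tuple[HaplotypeLibrary, dict]:
    """Concatenate per-core haplotypes into chromosome-length gametes and
    collect complete ones into the library.

    ``phased`` maps individual row -> {chrom: [(pat_core, mat_core,
    confident_core), ...]} in core order.  A gamete enters the library
    when its non-missing fraction is >= ``completeness_min``, any residual
    unphased allele can be filled from the complement (other gamete +
    observed dosage), and every resolved allele is confidence-flagged (so
    the library holds only strongly supported haplotypes); duplicates are
    collapsed with occurrence counts.

    ``eligible`` optionally maps (row, chrom) -> (pat_ok, mat_ok) flags
    from an upstream quality check (e.g. the parent-mosaic screen);
    gametes flagged False are kept in the long haplotypes but stay out of
    the library.

    Returns (library, long_haplotypes) where long_haplotypes maps
    individual row -> {chrom: (paternal, maternal)} full-length vectors.
    """
    lib_seqs: dict[int, dict[bytes, int]] = {}
    long_haps: dict[int, dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    for i, per_chrom in phased.items():
        long_haps[i] = {}
        for c, core_haps in per_chrom.items():
            s = gmap.chrom_slice(c)
            pat = np.concatenate([h[0] for h in core_haps])
            mat = np.concatenate([h[1] for h in core_haps])
            conf = np.concatenate([h[2] for h in core_haps])
            long_haps[i][int(c)] = (pat, mat)
            g = genotypes[i, s]
            ok = (True, True) if eligible is None else eligible.get(
                (int(i), int(c)), (True, True))
            for hap, other, keep in ((pat, mat, ok[0]), (mat, pat, ok[1])):
                if not keep:
                    continue
                frac = np.mean(hap != UNPHASED)
                if frac < completeness_min:
                    continue
                filled = hap.copy()
                fix = (filled == UNPHASED) & (other != UNPHASED) & (g != MISSING)
                filled[fix] = (g[fix] - other[fix]).astype(np.int8)
                if np.any(filled == UNPHASED) or filled.min() < 0 or filled.max() > 1:
                    continue
                if not conf.all():
                    continue
                key = filled.tobytes()
                lib_seqs.setdefault(int(c), {})
                lib_seqs[int(c)][key] = lib_seqs[int(c)].get(key, 0) + 1
    lib = HaplotypeLibrary()
    for c, seqs in lib_seqs.items():
        w = gmap.chrom_slice(c).stop - gmap.chrom_slice(c).start
        keys = sorted(seqs)  # deterministic order
        lib.haplotypes[c] = np.array(
            [np.frombuffer(k, dtype=np.int8) for k in keys]).reshape(len(keys), w)
        lib.counts[c] = np.array([seqs[k] for k in keys], dtype=np.int64)
    return lib, long_haps


class LongRangePhaser:
    """Orchestrates core partitioning, surrogate phasing and library
    assembly for a set of densely genotyped individuals.

    Parameters mirror the individual operations: ``core_length_mb``
    (default 10), ``agreement_threshold`` (default 0.9), ``max_opposing``
    opposing homozygotes tolerated in a surrogate (default 0, strict
    identity-by-state) and ``completeness_min`` for library entry.
    """

    def __init__(self, core_length_mb: float = 10.0,
                 agreement_threshold: float = 0.9, max_opposing: int = 0,
                 completeness_min: float = 0.99, n_passes: int = 3,
                 library_max_switches: int | None = 3,
                 min_confident_votes: int = 2):
        self.core_length_mb = core_length_mb
        self.agreement_threshold = agreement_threshold
        self.max_opposing = max_opposing
        self.completeness_min = completeness_min
        self.n_passes = n_passes
        self.library_max_switches = library_max_switches
        self.min_confident_votes = min_confident_votes

    def run(self, genotypes: np.ndarray, pedigree: Pedigree,
            gmap: GeneticMap, individuals: np.ndarray | None = None):
        """Phase ``individuals`` (default: every fully genotyped row) and
        build the haplotype library.

        Voting is repeated for ``n_passes``: from the second pass on, a
        half-sib surrogate votes with its already-resolved shared-side
        haplotype, which resolves loci where single-pass genotype
        deduction runs dry.  Surrogate sets (opposing-homozygote filter)
        are computed once; only the votes are iterated.

        Returns (library, long_haplotypes, partition).
        """
        if individuals is None:
            individuals = np.flatnonzero(np.all(genotypes != MISSING, axis=1))
        individuals = [int(i) for i in individuals]
        partition = partition_cores(gmap, self.core_length_mb)
        sidx, didx = pedigree.sire_index, pedigree.dam_index
        genotyped = ~np.all(genotypes == MISSING, axis=1)

        # candidate relatives per individual, fixed across passes
        cand_cache: dict[int, dict[str, list]] = {}
        for i in individuals:
            cand_cache[i] = {
                side: [(rank, r, other, schar)
                       for rank, r, other, schar
                       in _candidate_relatives(i, side, pedigree)
                       if genotyped[r]]
                for side in ("paternal", "maternal")}

        def surrogate_lists(i, core, phased_prev):
            """Opposing-homozygote filter, sharpened on re-passes by a
            haplotype-consistency check: a half-sib whose resolved
            shared-side haplotype conflicts with the individual's resolved
            side haplotype inside the core cannot share that gamete."""
            lo, hi = core
            gi = genotypes[i, lo:hi]
            out = []
            for sk, side in enumerate(("paternal", "maternal")):
                scored = []
                for rank, r, other, schar in cand_cache[i][side]:
                    opp = count_opposing_homozygotes(gi, genotypes[r, lo:hi])
                    if opp > self.max_opposing:
                        continue
                    if (phased_prev is not None and schar != "?"
                            and r in phased_prev and i in phased_prev):
                        hap_i = phased_prev[i][sk][lo:hi]
                        hap_r = phased_prev[r][0 if schar == "P" else 1][lo:hi]
                        both = ((gi == 1) & (hap_i != UNPHASED)
                                & (hap_r != UNPHASED))
                        conflicts = int(np.count_nonzero(
                            both & (hap_i != hap_r)))
                        if conflicts > self.max_opposing:
                            continue
                    scored.append((rank, opp, r, other, schar))
                scored.sort()
                out.append([(r, other, schar)
                            for _, _, r, other, schar in scored])
            return out[0], out[1]

        phased: dict[int, dict[int, list]] = {}
        phased_prev: dict[int, tuple[np.ndarray, np.ndarray]] | None = None
        for p in range(max(1, self.n_passes)):
            # unanimity on the anchoring pass: early wrong assignments
            # self-reinforce through the consistency filter
            thr = 1.0 if (p == 0 and self.n_passes > 1) else self.agreement_threshold
            phased = {}
            for i in individuals:
                phased[i] = {}
                for c in gmap.chromosomes:
                    core_haps = []
                    for core in partition.chrom_cores(c):
                        pats, mats = surrogate_lists(i, core, phased_prev)
                        core_haps.append(phase_core(
                            i, genotypes, pats, mats, core, thr,
                            sire_row=int(sidx[i]), dam_row=int(didx[i]),
                            phased_prev=phased_prev,
                            min_confident_votes=self.min_confident_votes))
                    phased[i][int(c)] = core_haps
            # full-length vectors for the next voting pass
            phased_prev = {}
            for i in individuals:
                pat = np.full(gmap.n_loci, UNPHASED, dtype=np.int8)
                mat = np.full(gmap.n_loci, UNPHASED, dtype=np.int8)
                for c in gmap.chromosomes:
                    s = gmap.chrom_slice(c)
                    pat[s] = np.concatenate([h[0] for h in phased[i][int(c)]])
                    mat[s] = np.concatenate([h[1] for h in phased[i][int(c)]])
                phased_prev[i] = (pat, mat)

        # library quality screen: each complete gamete must be a
        # plausible (low-switch) mosaic of its parent's phased haplotypes
        eligible = None
        if self.library_max_switches is not None and phased_prev is not None:
            eligible = {}
            for i in individuals:
                for c in gmap.chromosomes:
                    s = gmap.chrom_slice(c)
                    flags = []
                    for parent, hap in ((int(sidx[i]), phased_prev[i][0][s]),
                                        (int(didx[i]), phased_prev[i][1][s])):
                        if parent < 0 or parent not in phased_prev or \
                                np.any(hap == UNPHASED):
                            flags.append(True)  # unverifiable: let the
                            # completeness/confidence gates decide
                            continue
                        sw = mosaic_switches(hap, phased_prev[parent][0][s],
                                             phased_prev[parent][1][s])
                        flags.append(sw is not None
                                     and sw <= self.library_max_switches)
                    eligible[(i, int(c))] = (flags[0], flags[1])
        lib, long_haps = build_library(phased, partition, gmap, genotypes,
                                       self.completeness_min, eligible)
        return lib, long_haps, partition
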