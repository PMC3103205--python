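"""Single-locus genotype probabilities ("geneprobs") by iterative peeling.

Genotype information is propagated through the pedigree one locus at a
time under Mendelian transmission and Hardy-Weinberg founder priors:
anterior terms carry information down from ancestors, posterior terms
carry it up from descendants and mates, and the two are iterated to
convergence.  On loop-free pedigrees the fixed point is the exact
posterior; with pedigree loops it is the usual iterative-peeling
approximation.

Each geneprob triple (pAA, pAB, pBB) gets a genotype probability index
(GPI) in [0, 100]: 100 when the genotype is known, 0 when the posterior
carries no information beyond the allele-frequency prior.  Here the GPI is
an entropy ratio, 100 * (1 - H(posterior)/H(prior)).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .pedigree import Pedigree
from .simulate import MISSING

__all__ = [
    "Geneprobs", "estimate_allele_frequencies", "hwe_prior",
    "compute_geneprobs", "brute_force_geneprobs", "compute_gpi",
    "overlay_low_density",
]


@dataclass
class Geneprobs:
    """Genotype probabilities plus their information index."""

    probs: np.ndarray  # (n, L, 3)
    gpi: np.ndarray    # (n, L)


def estimate_allele_frequencies(genotypes: np.ndarray,
                                floor: float = 0.001) -> np.ndarray:
    """Per-locus frequency of allele 1 from observed dosages.

    Loci with no observations default to 0.5; frequencies are clamped to
    [floor, 1 - floor] so HWE priors stay proper.
    """
    g = np.asarray(genotypes)
    obs = g != MISSING
    count = obs.sum(axis=0)
    dose = np.where(obs, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(count > 0, dose / np.maximum(2 * count, 1), 0.5)
    return np.clip(freq, floor, 1.0 - floor)


def hwe_prior(freqs: np.ndarray) -> np.ndarray:
    """(L, 3) Hardy-Weinberg genotype priors for allele-1 frequencies."""
    p = np.asarray(freqs, dtype=float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)


# ---------------------------------------------------------------------------
# pedigree preparation
# ---------------------------------------------------------------------------

# allowed[sire_code, dam_code, child_genotype]: sire/dam codes 0,1,2 observed,
# 3 missing; True if the child genotype is Mendelian-attainable.
def _allowed_table() -> np.ndarray:
    gam = {0: {0}, 1: {0, 1}, 2: {1}, 3: {0, 1}}
    tab = np.zeros((4, 4, 3), dtype=bool)
    for cs in range(4):
        for cd in range(4):
            for x in gam[cs]:
                for y in gam[cd]:
                    tab[cs, cd, x + y] = True
    return tab


_ALLOWED = _allowed_table()


def _extend_single_parents(sidx: np.ndarray, didx: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Give individuals with exactly one known parent a dummy unobserved
    mate so the peeling formulas apply uniformly.  Returns extended parent
    index arrays and the number of dummies appended."""
    sidx = sidx.copy()
    didx = didx.copy()
    n = len(sidx)
    extra = 0
    # one dummy per missing-parent slot, keyed by (known parent, side) so
    # half-sib groups through the known parent share the dummy mate
    dummy_for: dict[tuple[int, int], int] = {}
    for i in range(n):
        if (sidx[i] < 0) != (didx[i] < 0):
            if sidx[i] < 0:
                key = (int(didx[i]), 0)
            else:
                key = (int(sidx[i]), 1)
            if key not in dummy_for:
                dummy_for[key] = n + extra
                extra += 1
            if sidx[i] < 0:
                sidx[i] = dummy_for[key]
            else:
                didx[i] = dummy_for[key]
    if extra:
        sidx = np.concatenate([sidx, -np.ones(extra, dtype=np.int64)])
        didx = np.concatenate([didx, -np.ones(extra, dtype=np.int64)])
    return sidx, didx, extra


def _build_families(sidx: np.ndarray, didx: np.ndarray):
    """CSR family structure: unique (sire,dam) pairs with offspring lists,
    plus per-individual lists of the families in which it is a parent."""
    n = len(sidx)
    fams: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        if sidx[i] >= 0:
            fams.setdefault((int(sidx[i]), int(didx[i])), []).append(i)
    # order by first offspring row: parents precede offspring, so this is a
    # valid top-down order for anterior propagation
    items = sorted(fams.items(), key=lambda kv: kv[1][0])
    F = len(items)
    fam_sire = np.array([k[0] for k, _ in items], dtype=np.int64)
    fam_dam = np.array([k[1] for k, _ in items], dtype=np.int64)
    off_ptr = np.zeros(F + 1, dtype=np.int64)
    off_idx = []
    for f, (_, offs) in enumerate(items):
        off_idx.extend(offs)
        off_ptr[f + 1] = len(off_idx)
    off_idx = np.array(off_idx, dtype=np.int64) if off_idx else np.zeros(0, np.int64)
    pf: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for f in range(F):
        pf[fam_sire[f]].append((f, 0))
        pf[fam_dam[f]].append((f, 1))
    pf_ptr = np.zeros(n + 1, dtype=np.int64)
    pf_idx, pf_side = [], []
    for i in range(n):
        for f, side in pf[i]:
            pf_idx.append(f)
            pf_side.append(side)
        pf_ptr[i + 1] = len(pf_idx)
    pf_idx = np.array(pf_idx, dtype=np.int64) if pf_idx else np.zeros(0, np.int64)
    pf_side = np.array(pf_side, dtype=np.int64) if pf_side else np.zeros(0, np.int64)
    return fam_sire, fam_dam, off_idx, off_ptr, pf_idx, pf_side, pf_ptr


def _clean_conflicts(obs: np.ndarray, sidx: np.ndarray, didx: np.ndarray) -> int:
    """Drop child observations that are Mendelian-impossible given observed
    parent genotypes (in place).  Returns the number dropped."""
    n, L = obs.shape
    dropped = 0
    code = np.where(obs == MISSING, 3, obs)
    for i in range(n):
        if sidx[i] < 0:
            continue
        cs = code[sidx[i]] if sidx[i] < n else np.full(L, 3)
        cd = code[didx[i]] if didx[i] < n else np.full(L, 3)
        child = obs[i]
        mask = child != MISSING
        if not mask.any():
            continue
        ok = _ALLOWED[cs[mask], cd[mask], child[mask]]
        if not ok.all():
            bad = np.flatnonzero(mask)[~ok]
            obs[i, bad] = MISSING
            dropped += len(bad)
    return dropped


# ---------------------------------------------------------------------------
# numba peeling kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _peel_kernel(pen, prior, fam_sire, fam_dam, off_idx, off_ptr,
                 pf_idx, pf_side, pf_ptr, max_iter, tol):  # pragma: no cover
    n = pen.shape[0]
    L = pen.shape[1]
    F = fam_sire.shape[0]
    T = np.zeros((3, 3, 3))
    for gs in range(3):
        ps = gs / 2.0
        for gd in range(3):
            pd = gd / 2.0
            T[gs, gd, 0] = (1 - ps) * (1 - pd)
            T[gs, gd, 1] = ps * (1 - pd) + (1 - ps) * pd
            T[gs, gd, 2] = ps * pd
    a = np.empty((n, L, 3))
    for i in range(n):
        for l in range(L):
            for g in range(3):
                a[i, l, g] = prior[l, g]
    P = np.full((F, 2, L, 3), 1.0 / 3.0)
    post = np.zeros((n, L, 3))
    maxoff = 1
    for f in range(F):
        k = off_ptr[f + 1] - off_ptr[f]
        if k > maxoff:
            maxoff = k
    S = np.empty((maxoff, 3, 3))
    pre = np.empty((maxoff + 1, 3, 3))
    suf = np.empty((maxoff + 1, 3, 3))
    us = np.empty(3)
    ud = np.empty(3)
    w = np.empty(3)
    tmp = np.empty(3)

    for _it in range(max_iter):
        for sweep in range(2):
            for fi in range(F):
                f = fi if sweep == 0 else F - 1 - fi
                s = fam_sire[f]
                d = fam_dam[f]
                k = off_ptr[f + 1] - off_ptr[f]
                for l in range(L):
                    # parent terms excluding this family
                    for g in range(3):
                        us[g] = a[s, l, g] * pen[s, l, g]
                        ud[g] = a[d, l, g] * pen[d, l, g]
                    for idx in range(pf_ptr[s], pf_ptr[s + 1]):
                        f2 = pf_idx[idx]
                        if f2 != f:
                            side = pf_side[idx]
                            for g in range(3):
                                us[g] *= P[f2, side, l, g]
                    for idx in range(pf_ptr[d], pf_ptr[d + 1]):
                        f2 = pf_idx[idx]
                        if f2 != f:
                            side = pf_side[idx]
                            for g in range(3):
                                ud[g] *= P[f2, side, l, g]
                    ssum = us[0] + us[1] + us[2]
                    if ssum > 0:
                        for g in range(3):
                            us[g] /= ssum
                    else:
                        for g in range(3):
                            us[g] = 1.0 / 3.0
                    ssum = ud[0] + ud[1] + ud[2]
                    if ssum > 0:
                        for g in range(3):
                            ud[g] /= ssum
                    else:
                        for g in range(3):
                            ud[g] = 1.0 / 3.0
                    # offspring summaries S_o(gs, gd)
                    for oi in range(k):
                        o = off_idx[off_ptr[f] + oi]
                        for g in range(3):
                            w[g] = pen[o, l, g]
                        for idx in range(pf_ptr[o], pf_ptr[o + 1]):
                            f2 = pf_idx[idx]
                            side = pf_side[idx]
                            for g in range(3):
                                w[g] *= P[f2, side, l, g]
                        sw = w[0] + w[1] + w[2]
                        if sw > 0:
                            for g in range(3):
                                w[g] /= sw
                        else:
                            for g in range(3):
                                w[g] = 1.0 / 3.0
                        for gs in range(3):
                            for gd in range(3):
                                S[oi, gs, gd] = (T[gs, gd, 0] * w[0]
                                                 + T[gs, gd, 1] * w[1]
                                                 + T[gs, gd, 2] * w[2])
                    for gs in range(3):
                        for gd in range(3):
                            pre[0, gs, gd] = 1.0
                            suf[k, gs, gd] = 1.0
                    for oi in range(k):
                        for gs in range(3):
                            for gd in range(3):
                                pre[oi + 1, gs, gd] = pre[oi, gs, gd] * S[oi, gs, gd]
                    for oi in range(k - 1, -1, -1):
                        for gs in range(3):
                            for gd in range(3):
                                suf[oi, gs, gd] = suf[oi + 1, gs, gd] * S[oi, gs, gd]
                    # posterior contributions to the parents
                    for gs in range(3):
                        acc = 0.0
                        for gd in range(3):
                            acc += ud[gd] * pre[k, gs, gd]
                        tmp[gs] = acc
                    ssum = tmp[0] + tmp[1] + tmp[2]
                    for gs in range(3):
                        P[f, 0, l, gs] = tmp[gs] / ssum if ssum > 0 else 1.0 / 3.0
                    for gd in range(3):
                        acc = 0.0
                        for gs in range(3):
                            acc += us[gs] * pre[k, gs, gd]
                        tmp[gd] = acc
                    ssum = tmp[0] + tmp[1] + tmp[2]
                    for gd in range(3):
                        P[f, 1, l, gd] = tmp[gd] / ssum if ssum > 0 else 1.0 / 3.0
                    # anteriors of the offspring (excluding own contribution)
                    for oi in range(k):
                        o = off_idx[off_ptr[f] + oi]
                        for go in range(3):
                            acc = 0.0
                            for gs in range(3):
                                for gd in range(3):
                                    acc += (T[gs, gd, go] * us[gs] * ud[gd]
                                            * pre[oi, gs, gd] * suf[oi + 1, gs, gd])
                            tmp[go] = acc
                        ssum = tmp[0] + tmp[1] + tmp[2]
                        if ssum > 0:
                            for go in range(3):
                                a[o, l, go] = tmp[go] / ssum
                        else:
                            for go in range(3):
                                a[o, l, go] = prior[l, go]
        # full posteriors and convergence check
        diff = 0.0
        for i in range(n):
            for l in range(L):
                for g in range(3):
                    tmp[g] = a[i, l, g] * pen[i, l, g]
                for idx in range(pf_ptr[i], pf_ptr[i + 1]):
                    f2 = pf_idx[idx]
                    side = pf_side[idx]
                    for g in range(3):
                        tmp[g] *= P[f2, side, l, g]
                ssum = tmp[0] + tmp[1] + tmp[2]
                for g in range(3):
                    v = tmp[g] / ssum if ssum > 0 else prior[l, g]
                    dv = v - post[i, l, g]
                    if dv < 0:
                        dv = -dv
                    if dv > diff:
                        diff = dv
                    post[i, l, g] = v
        if diff < tol:
            break
    return post


def compute_geneprobs(pedigree: Pedigree, genotypes: np.ndarray,
                      freqs: np.ndarray, max_iter: int = 50,
                      tol: float = 1e-6) -> np.ndarray:
    """Posterior genotype probabilities for every individual and locus.

    Exact on loop-free pedigrees; locus-independent (each locus is peeled
    separately under its own HWE prior from ``freqs``).  Mendelian-
    inconsistent child observations are dropped with a warning rather than
    crashing.

    Returns an (n, L, 3) array of (pAA, pAB, pBB) with A = allele 0.
    """
    obs = np.array(genotypes, dtype=np.int64, copy=True)
    n, L = obs.shape
    sidx, didx, extra = _extend_single_parents(pedigree.sire_index,
                                               pedigree.dam_index)
    dropped = _clean_conflicts(obs, sidx[:n], didx[:n])
    if dropped:
        warnings.warn(f"dropped {dropped} Mendelian-inconsistent "
                      "genotype observations")
    prior = hwe_prior(freqs)
    pen = np.ones((n + extra, L, 3))
    for g in range(3):
        pen[:n, :, :][obs == g] = 0.0
        pen[:n, :, g][obs == g] = 1.0
    fam = _build_families(sidx, didx)
    post = _peel_kernel(pen, prior, *fam, max_iter, tol)
    post = post[:n]
    # observed entries are exact point masses by construction; enforce
    for g in range(3):
        sel = obs == g
        post[sel] = 0.0
        post[:, :, g][sel] = 1.0
    return post


def brute_force_geneprobs(pedigree: Pedigree, genotypes: np.ndarray,
                          freqs: np.ndarray, limit: int = 10) -> np.ndarray:
    """Exact genotype posteriors by full enumeration of joint genotype
    configurations (founder HWE priors x Mendelian transmission x data).
    Only feasible for tiny pedigrees; serves as the peeling oracle."""
    obs = np.array(genotypes, dtype=np.int64, copy=True)
    n, L = obs.shape
    sidx, didx, extra = _extend_single_parents(pedigree.sire_index,
                                               pedigree.dam_index)
    if n + extra > limit:
        raise ValueError(f"pedigree too large to enumerate ({n + extra} > {limit})")
    _clean_conflicts(obs, sidx[:n], didx[:n])
    prior = hwe_prior(freqs)
    T = np.zeros((3, 3, 3))
    for gs in range(3):
        for gd in range(3):
            ps, pd = gs / 2, gd / 2
            T[gs, gd, 0] = (1 - ps) * (1 - pd)
            T[gs, gd, 1] = ps * (1 - pd) + (1 - ps) * pd
            T[gs, gd, 2] = ps * pd
    m = n + extra
    out = np.zeros((n, L, 3))
    for l in range(L):
        marg = np.zeros((m, 3))
        for cfg in itertools.product(range(3), repeat=m):
            w = 1.0
            for i in range(m):
                if sidx[i] < 0:
                    w *= prior[l, cfg[i]]
                else:
                    w *= T[cfg[sidx[i]], cfg[didx[i]], cfg[i]]
                if i < n and obs[i, l] != MISSING and cfg[i] != obs[i, l]:
                    w = 0.0
                if w == 0.0:
                    break
            if w > 0.0:
                for i in range(m):
                    marg[i, cfg[i]] += w
        total = marg.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        out[:, l, :] = (marg / total)[:n]
    return out


# ---------------------------------------------------------------------------
# GPI and low-density overlay
# ---------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return t.sum(axis=-1)


def compute_gpi(probs: np.ndarray, freqs: np.ndarray,
                observed: np.ndarray | None = None) -> np.ndarray:
    """GPI = 100 * (1 - H(posterior) / H(prior)), clamped to [0, 100].

    Degenerate loci (zero prior entropy) score 100, as do observed
    genotypes when an observation mask is supplied.
    """
    prior = hwe_prior(freqs)
    h_post = _entropy(probs)
    h_prior = _entropy(prior)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        gpi = 100.0 * (1.0 - h_post / h_prior)
    gpi = np.where(h_prior <= 0, 100.0, gpi)
    gpi = np.clip(gpi, 0.0, 100.0)
    if observed is not None:
        gpi = np.where(observed != MISSING, 100.0, gpi)
    return gpi


def overlay_low_density(geneprobs: Geneprobs,
                        panel_genotypes: np.ndarray) -> Geneprobs:
    """Replace geneprobs with point masses wherever a low-density panel
    genotype is observed (GPI -> 100); all other loci are untouched.
    Idempotent.  A panel genotype that lands on a zero-probability class
    is kept, with a warning."""
    probs = geneprobs.probs.copy()
    gpi = geneprobs.gpi.copy()
    sel = panel_genotypes != MISSING
    rows, cols = np.nonzero(sel)
    conflicts = 0
    for i, l in zip(rows, cols):
        g = int(panel_genotypes[i, l])
        if probs[i, l, g] == 0.0:
            conflicts += 1
        probs[i, l, :] = 0.0
        probs[i, l, g] = 1.0
        gpi[i, l] = 100.0
    if conflicts:
        warnings.warn(f"{conflicts} panel genotypes conflicted with "
                      "zero-probability geneprob classes; kept the "
                      "observed genotypes")
    return Geneprobs(probs, gpi)
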