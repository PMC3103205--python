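"""Independent slow reference implementations used as test oracles.

These re-apply the documented rules directly with plain Python loops and
must stay independent of the package's vectorized implementations.
"""

import itertools

import numpy as np


def reference_select_pair(probs, gpi, haplotypes, config):
    """Direct re-application of the haplotype-pair selection rules:
    pre-selection, single-haplotype screening, pair screening under the
    descending GPI schedule (with geometric threshold relaxation when no
    pair survives), and the geneprob-mass score.  Returns the winning
    unordered pair (i, j) or None."""
    L, _ = probs.shape
    H = np.asarray(haplotypes)
    n_hap = len(H)

    def mpg(gpi_min):
        out = []
        for l in range(L):
            p = probs[l]
            top = p.max()
            n_top = int(np.sum(np.abs(p - top) < 1e-9))
            geno = 1 if n_top > 1 else int(np.argmax(p))
            out.append((geno, gpi[l] >= gpi_min))
        return out

    def threshold(which, n_compared, scale):
        explicit = (config.error_threshold_step1 if which == 1
                    else config.error_threshold_step2)
        if explicit is not None:
            return int(scale * int(explicit))
        return max(1, int(scale * max(1, int(0.01 * n_compared))))

    def run_steps(scale):
        # step 1
        m1 = mpg(config.gpi_min_step1)
        compare1 = [l for l in range(L)
                    if m1[l][1] and m1[l][0] in (0, 2)]
        singles = []
        thr1 = threshold(1, len(compare1), scale)
        for h in range(n_hap):
            opposing = 0
            for l in compare1:
                allele = m1[l][0] // 2
                if H[h, l] != allele:
                    opposing += 1
            if opposing <= thr1:
                singles.append(h)
        if not singles:
            return []
        # step 2
        m2 = mpg(0.0)
        pairs = [(i, j) for k, i in enumerate(singles)
                 for j in singles[k:]]
        g = config.gpi_min_step2_start
        used = set()
        mism = {p: 0 for p in pairs}
        n_compared = 0
        alive = None
        while True:
            new = [l for l in range(L) if gpi[l] >= g and l not in used]
            used.update(new)
            n_compared += len(new)
            for (i, j) in pairs:
                for l in new:
                    if H[i, l] + H[j, l] != m2[l][0]:
                        mism[(i, j)] += 1
            thr2 = threshold(2, n_compared, scale)
            ok = [p for p in pairs if mism[p] <= thr2]
            if alive is None:
                alive = ok
                if not alive:
                    return []
            else:
                nxt = [p for p in alive if p in ok]
                if not nxt:
                    break
                alive = nxt
            if len(alive) <= 1 or g <= config.gpi_min_step2_floor:
                break
            g -= config.gpi_step2_decrement
            if g < config.gpi_min_step2_floor:
                g = config.gpi_min_step2_floor
        return alive

    scale = 1.0
    while True:
        alive = run_steps(scale)
        if alive or scale >= config.max_relax:
            break
        scale *= config.adaptive_relax
    if not alive:
        return None
    # step 3: highest sum of geneprob mass of the implied genotype
    best, best_score = None, -np.inf
    for (i, j) in sorted(alive):
        score = sum(probs[l, min(int(H[i, l] + H[j, l]), 2)]
                    for l in range(L))
        if score > best_score + 1e-9:
            best, best_score = (i, j), score
    return best


def gls_blup(A, y, h2):
    """Dense generalized-least-squares animal model: mean + breeding
    values with var(u) = A*h2, var(e) = I*(1-h2) on the phenotype scale."""
    obs = ~np.isnan(y)
    n = len(y)
    Z = np.eye(n)[obs]
    va, ve = h2, 1.0 - h2
    V = Z @ A @ Z.T * va + np.eye(int(obs.sum())) * ve
    Vi = np.linalg.inv(V)
    one = np.ones((int(obs.sum()), 1))
    mu = float(np.linalg.solve(one.T @ Vi @ one, one.T @ Vi @ y[obs])[0])
    u = va * A @ Z.T @ Vi @ (y[obs] - mu)
    return mu, u
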