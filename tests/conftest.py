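import numpy as np
import pytest

from salhi.pedigree import Pedigree


@pytest.fixture
def trio():
    """Sire (1), dam (2), offspring (3)."""
    return Pedigree(np.array([1, 2, 3]), np.array([0, 0, 1]),
                    np.array([0, 0, 2]), np.array(["M", "F", "M"]),
                    np.array([0, 0, 1]))


@pytest.fixture
def nuclear_family():
    """Two founders with three offspring."""
    return Pedigree(np.array([1, 2, 3, 4, 5]), np.array([0, 0, 1, 1, 1]),
                    np.array([0, 0, 2, 2, 2]), np.array(["M", "F", "M", "F", "F"]),
                    np.array([0, 0, 1, 1, 1]))


def random_loopfree_pedigree(rng: np.random.Generator, n_target: int = 8) -> Pedigree:
    """Random pedigree whose marriage graph is a forest (loop-free), so
    iterative peeling is exact: every new mating joins two previously
    unconnected components (union-find)."""
    ids, sire, dam, sex = [1], [0], [0], ["M"]
    comp = {1: 1}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    nid = 1
    while len(ids) < n_target:
        nid += 1
        comp[nid] = nid
        new_sex = "M" if rng.random() < 0.5 else "F"
        if rng.random() < 0.45 or len(ids) < 2:
            ids.append(nid); sire.append(0); dam.append(0); sex.append(new_sex)
            continue
        males = [i for i, s in zip(ids, sex) if s == "M"]
        females = [i for i, s in zip(ids, sex) if s == "F"]
        rng.shuffle(males)
        rng.shuffle(females)
        made = False
        for m in males:
            for f in females:
                if find(m) != find(f):
                    ids.append(nid); sire.append(m); dam.append(f)
                    sex.append(new_sex)
                    comp[find(m)] = find(f)
                    comp[find(nid)] = find(f)
                    made = True
                    break
            if made:
                break
        if not made:
            ids.append(nid); sire.append(0); dam.append(0); sex.append(new_sex)
    return Pedigree(np.array(ids), np.array(sire), np.array(dam),
                    np.array(sex), np.zeros(len(ids), dtype=int))


def drop_genotypes(ped: Pedigree, freqs: np.ndarray,
                   rng: np.random.Generator,
                   mask_prob: float = 0.5) -> np.ndarray:
    """Single-locus gene drop through an arbitrary pedigree (handles
    one-parent individuals by drawing the unknown gamete from the allele
    frequency), then random masking.  Used to feed the peeling oracle."""
    from salhi.simulate import MISSING

    L = len(freqs)
    n = ped.n
    pat = np.zeros((n, L), dtype=np.int8)
    mat = np.zeros((n, L), dtype=np.int8)
    sidx, didx = ped.sire_index, ped.dam_index
    for i in range(n):
        for l in range(L):
            if sidx[i] < 0:
                pat[i, l] = rng.random() < freqs[l]
            else:
                src = (pat, mat)[rng.integers(2)]
                pat[i, l] = src[sidx[i], l]
            if didx[i] < 0:
                mat[i, l] = rng.random() < freqs[l]
            else:
                src = (pat, mat)[rng.integers(2)]
                mat[i, l] = src[didx[i], l]
    g = (pat + mat).astype(np.int8)
    keep = rng.random(g.shape) >= mask_prob
    return np.where(keep, g, MISSING).astype(np.int8)
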