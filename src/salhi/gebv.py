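"""Genomic and pedigree-based breeding value estimation.

`BayesARegressor` fits the classical BayesA model by Gibbs sampling:
y = mu + sum_j x_j a_j + e, with a locus-specific effect variance under a
scaled-inverse-chi-square prior, so every marker has a (shrunken) nonzero
effect.  GEBVs are the marker scores of the prediction candidates.

`PedigreeBLUP` is the marker-free baseline: an animal-model BLUP solved
from the mixed-model equations with the pedigree numerator relationship
matrix (tabular method) and the overall mean as the only fixed effect.

Accuracy is the correlation between (G)EBV and true breeding value,
computed within sex and averaged, because parent-of-origin (imprinting)
effects shift the sexes' breeding-value scales and bias a pooled
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .pedigree import Pedigree

__all__ = ["BayesARegressor", "PedigreeBLUP", "predict_gebv",
           "sexwise_accuracy", "AccuracyReport", "relationship_matrix"]


@njit(cache=True)
def _bayesa_gibbs(X, y, n_iter, burn_in, thin, nu, scale_marker,
                  nu_e, scale_e, seed):  # pragma: no cover
    np.random.seed(seed)
    n, m = X.shape
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s
    a = np.zeros(m)
    var_j = np.full(m, scale_marker * nu / max(nu - 2.0, 1e-3))
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = y - mu
    var_e = 0.0
    for i in range(n):
        var_e += e[i] * e[i]
    var_e = var_e / n + 1e-12

    sum_a = np.zeros(m)
    sum_var_j = np.zeros(m)
    sum_mu = 0.0
    sum_var_e = 0.0
    n_samp = 0
    for it in range(n_iter):
        # intercept: full conditional N(mu + mean(e), var_e / n)
        em = 0.0
        for i in range(n):
            em += e[i]
        em /= n
        delta = em + np.random.normal() * np.sqrt(var_e / n)
        mu += delta
        for i in range(n):
            e[i] -= delta

        # marker effects
        for j in range(m):
            if xtx[j] == 0.0:
                a_new = np.random.normal() * np.sqrt(var_j[j])
                a[j] = a_new
                var_j[j] = (nu * scale_marker + a_new * a_new) / \
                    np.random.chisquare(nu + 1.0)
                continue
            rhs = 0.0
            for i in range(n):
                rhs += X[i, j] * e[i]
            rhs += xtx[j] * a[j]
            c = xtx[j] + var_e / var_j[j]
            mean = rhs / c
            a_new = mean + np.random.normal() * np.sqrt(var_e / c)
            diff = a[j] - a_new
            for i in range(n):
                e[i] += X[i, j] * diff
            a[j] = a_new
            var_j[j] = (nu * scale_marker + a_new * a_new) / \
                np.random.chisquare(nu + 1.0)

        # residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        var_e = (sse + nu_e * scale_e) / np.random.chisquare(n + nu_e)

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_samp += 1
            sum_mu += mu
            sum_var_e += var_e
            for j in range(m):
                sum_a[j] += a[j]
                sum_var_j[j] += var_j[j]
    return (sum_a / n_samp, sum_mu / n_samp, sum_var_j / n_samp,
            sum_var_e / n_samp)


class BayesARegressor(RegressorMixin, BaseEstimator):
    """BayesA marker-effect regression fit by Gibbs sampling.

    Parameters
    ----------
    n_iter, burn_in, thin : chain settings (posterior means are taken over
        post-burn-in thinned samples).
    nu : prior degrees of freedom of the locus effect variances.
    var_prop : assumed proportion of phenotypic variance explained by
        markers; sets the scale of the effect-variance prior.
    random_state : seed; identical seeds give bit-identical fits.

    Attributes
    ----------
    coef_ : posterior-mean allele substitution effects, one per locus.
    intercept_ : posterior-mean intercept (on uncentered dosages).
    effect_var_ : posterior-mean per-locus effect variances.
    resid_var_ : posterior-mean residual variance.
    """

    def __init__(self, n_iter: int = 10_000, burn_in: int = 2_000,
                 thin: int = 10, nu: float = 4.012, var_prop: float = 0.5,
                 random_state: int = 0):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.nu = nu
        self.var_prop = var_prop
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n, m) with len(y) == n")
        if np.isnan(X).any():
            raise ValueError("missing dosages: impute before fitting")
        if np.isnan(y).any():
            raise ValueError("missing phenotypes in training data")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 phenotyped individuals")
        if self.n_iter <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")
        var_y = float(np.var(y))
        if var_y == 0:
            raise ValueError("constant phenotype")
        means = X.mean(axis=0)
        Xc = np.asfortranarray(X - means)
        # prior scales: split var(y) into marker and residual parts
        het = np.maximum((Xc ** 2).mean(axis=0).sum(), 1e-8)
        nu = float(self.nu)
        scale_marker = self.var_prop * var_y * max(nu - 2.0, 1e-3) / nu / het
        nu_e = 4.0
        scale_e = (1.0 - self.var_prop) * var_y * (nu_e - 2.0) / nu_e
        coef, mu_c, evar, rvar = _bayesa_gibbs(
            Xc, y, int(self.n_iter), int(self.burn_in), max(1, int(self.thin)),
            nu, scale_marker, nu_e, scale_e,
            int(self.random_state) % (2 ** 31))
        self.coef_ = coef
        self.intercept_ = float(mu_c - means @ coef)
        self.effect_var_ = evar
        self.resid_var_ = float(rvar)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=np.float64)
        if np.isnan(X).any():
            raise ValueError("missing dosages: impute before predicting")
        return self.intercept_ + X @ self.coef_

    def gebv(self, X):
        """Intercept-free marker score sum_j dosage_ij * effect_j."""
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=np.float64) @ self.coef_


def predict_gebv(effects: np.ndarray, genotypes: np.ndarray) -> np.ndarray:
    """GEBV_i = sum_j dosage_ij * effect_j (no intercept)."""
    G = np.asarray(genotypes, dtype=np.float64)
    effects = np.asarray(effects, dtype=np.float64)
    if G.shape[1] != len(effects):
        raise ValueError("locus count mismatch")
    if np.isnan(G).any():
        raise ValueError("missing dosages: impute before predicting")
    return G @ effects


# ---------------------------------------------------------------------------
# pedigree BLUP
# ---------------------------------------------------------------------------

def relationship_matrix(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix A by the tabular method."""
    n = pedigree.n
    sidx, didx = pedigree.sire_index, pedigree.dam_index
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sidx[i], didx[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0:
            A[i, :i] = 0.5 * A[s, :i]
            A[i, i] = 1.0
        elif d >= 0:
            A[i, :i] = 0.5 * A[d, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


class PedigreeBLUP(BaseEstimator):
    """Animal-model BLUP of breeding values from phenotypes and pedigree.

    Mixed-model equations with the overall mean as the only fixed effect
    and variance ratio lambda = (1 - h2) / h2; unphenotyped individuals
    receive EBVs through the relationship matrix.
    """

    def __init__(self, h2: float = 0.5):
        self.h2 = h2

    def fit(self, pedigree: Pedigree, y: np.ndarray):
        """``y`` has one entry per pedigree member; NaN = no phenotype."""
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must be in (0, 1)")
        y = np.asarray(y, dtype=np.float64)
        n = pedigree.n
        if len(y) != n:
            raise ValueError("phenotype length != pedigree size")
        obs = ~np.isnan(y)
        n_obs = int(obs.sum())
        if n_obs < 2:
            raise ValueError("need at least 2 phenotyped individuals")
        lam = (1.0 - self.h2) / self.h2
        A = relationship_matrix(pedigree)
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular relationship matrix: {exc}") from exc
        # MME: [n_obs      1'Z      ] [mu]   [1'y]
        #      [Z'1   Z'Z + Ainv*lam] [u ] = [Z'y]
        C = np.zeros((n + 1, n + 1))
        rhs = np.zeros(n + 1)
        C[0, 0] = n_obs
        zy = np.where(obs, y, 0.0)
        C[0, 1:] = obs.astype(float)
        C[1:, 0] = obs.astype(float)
        C[1:, 1:] = np.diag(obs.astype(float)) + Ainv * lam
        rhs[0] = zy.sum()
        rhs[1:] = zy
        try:
            sol = np.linalg.solve(C, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular mixed-model equations: {exc}") from exc
        self.mean_ = float(sol[0])
        self.ebv_ = sol[1:]
        self.A_ = A
        return self

    def predict(self, rows: np.ndarray | None = None) -> np.ndarray:
        check_is_fitted(self, "ebv_")
        if rows is None:
            return self.ebv_
        return self.ebv_[np.asarray(rows)]


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    r_male: float
    r_female: float
    r_avg: float
    n_male: int
    n_female: int
    flag: str = ""


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def sexwise_accuracy(values: np.ndarray, tbv: np.ndarray,
                     sex: np.ndarray) -> AccuracyReport:
    """Pearson correlation of predicted vs true breeding values within
    each sex, averaged.  A pooled correlation would be biased whenever the
    sexes differ in breeding-value level (e.g. under paternal imprinting),
    so the two within-sex correlations are reported and averaged; if one
    sex is absent or degenerate, the other carries the average (flagged).
    """
    values = np.asarray(values, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    sex = np.asarray(sex)
    males = sex == "M"
    females = sex == "F"
    r_m = _corr(values[males], tbv[males])
    r_f = _corr(values[females], tbv[females])
    flag = ""
    if np.isnan(r_m) and np.isnan(r_f):
        r_avg = float("nan")
        flag = "no usable sex group"
    elif np.isnan(r_m):
        r_avg, flag = r_f, "males missing or degenerate"
    elif np.isnan(r_f):
        r_avg, flag = r_m, "females missing or degenerate"
    else:
        r_avg = 0.5 * (r_m + r_f)
    return AccuracyReport(r_m, r_f, r_avg, int(males.sum()),
                          int(females.sum()), flag)
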