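"""Relationship matrices, REML variance components and BLUP.

Implements the two mixed-model ingredients of genomic evaluation: the
realised (genomic) relationship matrix G computed from SNP dosages
(VanRaden method 1) and the pedigree numerator relationship matrix A
(tabular method), plus restricted maximum likelihood for the single
random-effect model y = 1*mu + g + e, g ~ N(0, K*sigma2_g), and the
mixed-model solve producing GEBV with prediction error variances.

Variance estimation follows the two-step scheme: sigma2_g is estimated
first by REML, then plugged into the BLUP equations to predict genetic
values for all individuals, phenotyped or not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .simulate import Pedigree

__all__ = [
    "RelationshipMatrix",
    "VarianceComponents",
    "BlupResult",
    "DegenerateMatrixError",
    "compute_grm",
    "compute_nrm",
    "reml_fit",
    "blup_solve",
]


class DegenerateMatrixError(ValueError):
    """Raised for degenerate relationship matrices or phenotype vectors."""


@dataclass
class RelationshipMatrix:
    """Symmetric individual-by-individual relationship matrix."""

    matrix: np.ndarray
    kind: str                # "genomic" or "pedigree"
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or self.ids.size != n:
            raise ValueError("matrix/ids shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return int(self.ids.size)

    def index_of(self, ids: np.ndarray) -> np.ndarray:
        pos = {int(i): k for k, i in enumerate(self.ids)}
        return np.array([pos[int(i)] for i in np.asarray(ids)], dtype=np.int64)


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    log_likelihood: float

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


@dataclass
class BlupResult:
    """BLUP solution: fixed mean, predicted genetic values and their PEV."""

    ids: np.ndarray
    gebv: np.ndarray
    pev: np.ndarray
    mu_hat: float
    vc: VarianceComponents


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

def compute_grm(dosages: np.ndarray, ids: Optional[np.ndarray] = None,
                allele_frequencies: Optional[np.ndarray] = None) -> RelationshipMatrix:
    """Realised genomic relationship matrix, VanRaden method 1.

    G = W W' / (2 * sum_j p_j (1 - p_j)) with W the dosage matrix column-
    centred at 2 p_j. Frequencies default to the observed column means / 2.
    Monomorphic markers are skipped; missing dosages (NaN) are imputed at
    2 p_j, i.e. they contribute zero after centring.
    """
    Z = np.asarray(dosages, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] < 2 or Z.shape[1] < 1:
        raise ValueError("need >= 2 individuals and >= 1 marker")
    if ids is None:
        ids = np.arange(1, Z.shape[0] + 1)
    if allele_frequencies is None:
        p = np.nanmean(Z, axis=0) / 2.0
    else:
        p = np.asarray(allele_frequencies, dtype=np.float64)
        if p.size != Z.shape[1]:
            raise ValueError("allele_frequencies length mismatch")
    with np.errstate(invalid="ignore"):
        poly = (p > 0.0) & (p < 1.0) & (np.nanvar(Z, axis=0) > 0.0)
    if not poly.any():
        raise DegenerateMatrixError("all markers monomorphic")
    p = p[poly]
    W = Z[:, poly] - 2.0 * p
    W = np.where(np.isnan(W), 0.0, W)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (W @ W.T) / denom
    return RelationshipMatrix(matrix=G, kind="genomic", ids=ids)


def compute_nrm(pedigree: Pedigree) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix by the tabular method.

    A_ii = 1 + 0.5 * A(sire, dam); A_ij = 0.5 * (A(j, sire_i) + A(j, dam_i))
    for j earlier in the (parents-first) ordering; unknown parents
    contribute zero.
    """
    n = pedigree.n
    pos = {int(i): k for k, i in enumerate(pedigree.ids)}
    A = np.zeros((n, n))
    for i in range(n):
        s = pos.get(int(pedigree.sire[i]), -1)
        d = pos.get(int(pedigree.dam[i]), -1)
        if s >= i or d >= i:
            raise ValueError("pedigree not sorted parents-before-offspring")
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(matrix=A, kind="pedigree", ids=pedigree.ids.copy())


def _psd_jitter_chol(M: np.ndarray, start: float = 1e-8, tries: int = 5) -> np.ndarray:
    """Cholesky with escalating diagonal jitter (x10, at most ``tries`` levels)."""
    jit = 0.0
    for t in range(tries):
        try:
            return np.linalg.cholesky(M + jit * np.eye(M.shape[0]))
        except np.linalg.LinAlgError:
            jit = start * (10.0 ** t)
    raise DegenerateMatrixError("matrix not positive semidefinite within jitter budget")


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _reml_profile_loglik(h2: float, lam: np.ndarray, yt: np.ndarray,
                         xt: np.ndarray) -> float:
    """Restricted log-likelihood profiled over mu and total variance.

    Works in the eigenbasis of K: lam are eigenvalues, yt = U'y, xt = U'1.
    V = sigma2_p * (h2 * K + (1 - h2) * I) so the scaled covariance is
    diagonal with d_i = h2 * lam_i + 1 - h2.
    """
    n = yt.size
    d = h2 * lam + (1.0 - h2)
    if np.any(d <= 0):
        return -np.inf
    xtd = xt / d
    xvx = float(xt @ xtd)
    mu = float(xtd @ yt) / xvx
    r = yt - mu * xt
    quad = float(r @ (r / d))
    if quad <= 0:
        return -np.inf
    sigma2_p = quad / (n - 1)
    return -0.5 * ((n - 1) * np.log(sigma2_p) + float(np.sum(np.log(d)))
                   + np.log(xvx) + (n - 1))


def reml_fit(y: np.ndarray, K: RelationshipMatrix,
             ids: Optional[np.ndarray] = None,
             eig: Optional[tuple[np.ndarray, np.ndarray]] = None,
             n_grid: int = 21, tol: float = 1e-6) -> VarianceComponents:
    """REML variance components for y = 1*mu + g + e, g ~ N(0, K sigma2_g).

    ``y`` may contain NaN (unphenotyped); ``ids`` selects the rows of K the
    phenotypes refer to (defaults to K.ids aligned with y). The profile
    restricted likelihood is one-dimensional in h2: a coarse grid locates
    the basin, then bounded scalar optimisation refines to ``tol``.
    ``eig`` optionally supplies a precomputed eigendecomposition
    (eigenvalues, eigenvectors) of the phenotyped submatrix of K.
    """
    y = np.asarray(y, dtype=np.float64)
    if ids is None:
        if y.size != K.n:
            raise ValueError("y length must match K when ids not given")
        ids = K.ids
    obs = np.isfinite(y)
    yo = y[obs]
    if yo.size < 10:
        raise ValueError("need >= 10 phenotyped individuals")
    if np.var(yo) <= 0:
        raise DegenerateMatrixError("zero phenotypic variance")
    rows = K.index_of(np.asarray(ids)[obs])
    if eig is None:
        Ko = K.matrix[np.ix_(rows, rows)]
        lam, U = np.linalg.eigh(Ko)
    else:
        lam, U = eig
    lam = np.maximum(lam, 0.0) + 1e-8   # PSD jitter in the eigenbasis
    yt = U.T @ yo
    xt = U.T @ np.ones(yo.size)

    lo, hi = 1e-3, 0.999
    grid = np.linspace(lo, hi, n_grid)
    ll = np.array([_reml_profile_loglik(h, lam, yt, xt) for h in grid])
    k = int(np.argmax(ll))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_grid - 1)]
    res = minimize_scalar(lambda h: -_reml_profile_loglik(h, lam, yt, xt),
                          bounds=(a, b), method="bounded",
                          options={"xatol": tol})
    h2 = float(res.x)
    if ll[k] > -res.fun:
        h2 = float(grid[k])
    best_ll = _reml_profile_loglik(h2, lam, yt, xt)

    d = h2 * lam + (1.0 - h2)
    xtd = xt / d
    mu = float(xtd @ yt) / float(xt @ xtd)
    r = yt - mu * xt
    sigma2_p = float(r @ (r / d)) / (yo.size - 1)
    return VarianceComponents(sigma2_g=h2 * sigma2_p,
                              sigma2_e=(1.0 - h2) * sigma2_p,
                              log_likelihood=float(best_ll))


# ---------------------------------------------------------------------------
# BLUP
# ---------------------------------------------------------------------------

def blup_solve(y: np.ndarray, K: RelationshipMatrix, vc: VarianceComponents,
               ids: Optional[np.ndarray] = None) -> BlupResult:
    """BLUP of genetic values for every individual in K.

    Solves the equivalent-model form: with observed subset O,
    V = sigma2_g K_OO + sigma2_e I, mu_hat by GLS, and
    g_hat = sigma2_g K[:, O] P (y - mu_hat) with
    P = V^-1 - V^-1 1 (1' V^-1 1)^-1 1' V^-1. PEV_i = sigma2_g K_ii -
    sigma2_g^2 k_i' P k_i, which equals the mixed-model-equation inverse
    diagonal. Handles singular K (e.g. genomic G) without inverting it.
    """
    if vc.sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    y = np.asarray(y, dtype=np.float64)
    if ids is None:
        if y.size != K.n:
            raise ValueError("y length must match K when ids not given")
        ids = K.ids
    obs = np.isfinite(y)
    yo = y[obs]
    rows = K.index_of(np.asarray(ids)[obs])

    Koo = K.matrix[np.ix_(rows, rows)]
    V = vc.sigma2_g * Koo + vc.sigma2_e * np.eye(yo.size)
    Lc = _psd_jitter_chol(V)

    def vsolve(B: np.ndarray) -> np.ndarray:
        z = np.linalg.solve(Lc, B)
        return np.linalg.solve(Lc.T, z)

    ones = np.ones(yo.size)
    Vi1 = vsolve(ones)
    denom = float(ones @ Vi1)
    mu_hat = float(Vi1 @ yo) / denom
    alpha = vsolve(yo - mu_hat * ones)        # = P y at the GLS solution

    Kall_o = K.matrix[:, rows]
    gebv = vc.sigma2_g * (Kall_o @ alpha)

    # PEV: sigma2_g K_ii - sigma2_g^2 k_i' P k_i
    ViK = vsolve(Kall_o.T)                    # V^-1 K_O,all
    quad = np.einsum("ij,ji->i", Kall_o, ViK)
    proj = (Kall_o @ Vi1) ** 2 / denom
    pev = vc.sigma2_g * np.diag(K.matrix) - vc.sigma2_g ** 2 * (quad - proj)
    pev = np.maximum(pev, 0.0)
    return BlupResult(ids=K.ids.copy(), gebv=gebv, pev=pev, mu_hat=mu_hat, vc=vc)
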