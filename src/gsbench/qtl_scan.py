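"""QTL localisation: GRAMMAR association scan and SNP-effect profiles.

GRAMMAR is a two-step mixed-model association test: phenotypes are first
adjusted for the polygenic (family) effect with a pedigree-BLUP fit, and
the residuals are then regressed on each SNP dosage in turn. Because the
polygenic adjustment absorbs part of the marker signal, the test is
conservative under the null.

Effect profiles normalise the absolute posterior-mean SNP effects of a
whole-genome regression fit to the largest effect, mirroring how such
profiles are plotted for QTL inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinship import RelationshipMatrix, blup_solve, reml_fit
from .simulate import GenomeMap, Pedigree
from .wgr import SnpEffectVector

__all__ = ["ScanResult", "EffectProfile", "grammar_scan", "effect_profile"]


@dataclass
class ScanResult:
    """Per-SNP association results; untested (monomorphic) SNP carry NaN."""

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    beta_scan: np.ndarray
    p_value: np.ndarray
    tested: np.ndarray          # bool

    @property
    def neg_log10_p(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return -np.log10(self.p_value)


@dataclass
class EffectProfile:
    snp_id: np.ndarray
    pos: np.ndarray
    abs_effect_proportion: np.ndarray
    all_zero: bool = False


def grammar_scan(y: np.ndarray, K: RelationshipMatrix | Pedigree,
                 Z: np.ndarray, gmap: GenomeMap,
                 ids: np.ndarray | None = None) -> ScanResult:
    """Two-step polygenic-adjusted single-SNP scan.

    Step 1 fits y = mu + g + e with g ~ N(0, K sigma2_g) (REML variance
    components, then BLUP) and takes residuals y - mu_hat - g_hat over the
    phenotyped individuals. Step 2 regresses the residuals on each SNP
    dosage; the two-sided p-value comes from the t statistic of the slope.
    ``K`` may be given as a pedigree (the classical formulation, numerator
    relationship A) or as any prebuilt relationship matrix.
    """
    if isinstance(K, Pedigree):
        from .kinship import compute_nrm
        K = compute_nrm(K)
    y = np.asarray(y, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[0] != y.size:
        raise ValueError("rows of Z must match y")
    vc = reml_fit(y, K, ids=ids)
    fit = blup_solve(y, K, vc, ids=ids)
    obs = np.isfinite(y)
    rows = K.index_of(np.asarray(ids)[obs]) if ids is not None else np.flatnonzero(obs)
    resid = y[obs] - fit.mu_hat - fit.gebv[rows]

    Zo = Z[obs]
    n = resid.size
    zbar = Zo.mean(axis=0)
    zc = Zo - zbar
    szz = (zc ** 2).sum(axis=0)
    tested = szz > 0
    if n < 3:
        raise ValueError("need >= 3 phenotyped individuals")

    beta = np.full(Z.shape[1], np.nan)
    pval = np.full(Z.shape[1], np.nan)
    rc = resid - resid.mean()
    szy = zc.T @ rc
    with np.errstate(invalid="ignore", divide="ignore"):
        b = szy / szz
        sse = (rc ** 2).sum() - b * szy
        se = np.sqrt(np.maximum(sse, 0.0) / (n - 2) / szz)
        # se == 0 with a nonzero slope is a perfect fit, not a null result
        t = np.where(se > 0, b / se, np.where(b != 0, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    beta[tested] = b[tested]
    pval[tested] = np.clip(p[tested], np.finfo(float).tiny, 1.0)
    return ScanResult(snp_id=gmap.snp_id.copy(), chrom=gmap.chrom.copy(),
                      pos=gmap.pos.copy(), beta_scan=beta, p_value=pval,
                      tested=tested)


def effect_profile(effects: SnpEffectVector, gmap: GenomeMap) -> EffectProfile:
    """Absolute SNP effects as a proportion of the largest absolute effect."""
    beta = np.asarray(effects.beta, dtype=np.float64)
    if beta.size != gmap.n_loci:
        raise ValueError(f"effects ({beta.size}) do not align with map ({gmap.n_loci})")
    amax = float(np.abs(beta).max()) if beta.size else 0.0
    if amax == 0.0:
        warnings.warn("all SNP effects are zero; profile is identically zero")
        return EffectProfile(snp_id=gmap.snp_id.copy(), pos=gmap.pos.copy(),
                             abs_effect_proportion=np.zeros_like(beta), all_zero=True)
    return EffectProfile(snp_id=gmap.snp_id.copy(), pos=gmap.pos.copy(),
                         abs_effect_proportion=np.abs(beta) / amax)
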