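"""Evaluation of genomic predictions.

Accuracy is the Pearson correlation between true and estimated breeding
values; improvement is expressed relative to the pedigree-BLUP baseline.
The explained genetic variance uses the infinitesimal-model approximation
that links accuracy, prediction error variance and genetic variance:

    Var(EBV) = r^2 sigma2_g,   PEV = (1 - r^2) sigma2_g,
    hence sigma2_g = Var(EBV) + PEV.

Cross-method agreement is summarised as a matrix of pairwise correlations
between GEBV vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvaluationReport",
    "ConcordanceMatrix",
    "accuracy",
    "improvement_over_blup",
    "variance_explained",
    "concordance",
    "evaluate_method",
]


@dataclass
class EvaluationReport:
    """Per-method evaluation: accuracy, % gain over pedigree BLUP, implied h2."""

    method_name: str
    r: float
    improvement_pct: float | None
    h2_hat: float | None
    sigma2_g_hat: float | None

    def to_dict(self) -> dict:
        return {"method": self.method_name, "r": self.r,
                "improvement_pct": self.improvement_pct,
                "h2_hat": self.h2_hat, "sigma2_g_hat": self.sigma2_g_hat}


@dataclass
class ConcordanceMatrix:
    methods: list
    correlations: np.ndarray

    @property
    def min_offdiag(self) -> float:
        n = len(self.methods)
        mask = ~np.eye(n, dtype=bool)
        return float(self.correlations[mask].min())

    @property
    def max_offdiag(self) -> float:
        n = len(self.methods)
        mask = ~np.eye(n, dtype=bool)
        return float(self.correlations[mask].max())


def accuracy(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation between true and estimated breeding values."""
    tbv = np.asarray(tbv, dtype=np.float64)
    gebv = np.asarray(gebv, dtype=np.float64)
    if tbv.size != gebv.size or tbv.size < 3:
        raise ValueError("need >= 3 paired values of equal length")
    if np.std(tbv) == 0 or np.std(gebv) == 0:
        raise ValueError("zero variance in tbv or gebv")
    return float(np.corrcoef(tbv, gebv)[0, 1])


def improvement_over_blup(r_method: float, r_blup: float) -> float:
    """Accuracy gain over the pedigree-BLUP baseline, in percent."""
    if r_blup <= 0:
        raise ValueError("baseline accuracy must be positive")
    return 100.0 * (r_method - r_blup) / r_blup


def variance_explained(gebv: np.ndarray, pev: np.ndarray,
                       sigma2_e_hat: float) -> tuple[float, float, float]:
    """(sigma2_g_hat, r2, h2_hat) from the infinitesimal-model identities.

    sigma2_g_hat = Var(gebv) + mean(pev); r2 = Var(gebv) / sigma2_g_hat;
    h2_hat = sigma2_g_hat / (sigma2_g_hat + sigma2_e_hat).
    """
    gebv = np.asarray(gebv, dtype=np.float64)
    pev = np.asarray(pev, dtype=np.float64)
    if np.any(pev < 0):
        raise ValueError("pev must be non-negative")
    v_ebv = float(np.var(gebv))
    sigma2_g = v_ebv + float(np.mean(pev))
    if sigma2_g <= 0:
        raise ValueError("degenerate: zero explained genetic variance")
    r2 = v_ebv / sigma2_g
    h2 = sigma2_g / (sigma2_g + sigma2_e_hat)
    return sigma2_g, r2, h2


def concordance(gebv_by_method: dict) -> ConcordanceMatrix:
    """Pairwise Pearson correlations between the methods' GEBV vectors."""
    methods = list(gebv_by_method)
    if len(methods) < 2:
        raise ValueError("need >= 2 methods")
    lengths = {np.asarray(v).size for v in gebv_by_method.values()}
    if len(lengths) != 1:
        raise ValueError("GEBV vectors must cover identical individual sets")
    M = np.column_stack([np.asarray(gebv_by_method[m], dtype=np.float64)
                         for m in methods])
    C = np.corrcoef(M.T)
    np.fill_diagonal(C, 1.0)
    return ConcordanceMatrix(methods=methods, correlations=C)


def evaluate_method(method_name: str, tbv: np.ndarray, gebv: np.ndarray,
                    pev: np.ndarray | None = None,
                    sigma2_e_hat: float | None = None,
                    r_blup: float | None = None) -> EvaluationReport:
    """Assemble one report row: accuracy, improvement and implied h2."""
    r = accuracy(tbv, gebv)
    imp = improvement_over_blup(r, r_blup) if r_blup is not None else None
    s2g = h2 = None
    if pev is not None and sigma2_e_hat is not None:
        s2g, _, h2 = variance_explained(gebv, pev, sigma2_e_hat)
    return EvaluationReport(method_name=method_name, r=r, improvement_pct=imp,
                            h2_hat=h2, sigma2_g_hat=s2g)
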