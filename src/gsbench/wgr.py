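"""Bayesian whole-genome regression by Gibbs sampling.

Four prior families for SNP effects in the model
``y = mu + sum_j z_j beta_j + e``:

* **LASSO** — Laplace prior, represented as a normal-exponential scale
  mixture (beta_j | tau2_j ~ N(0, tau2_j), tau2_j ~ Exp(lambda^2 / 2)), so
  every update is a Gibbs draw.
* **Bayes A** — scaled Student-t prior, represented as a normal with
  per-SNP scaled-inverse-chi-square variance (shape ``df``, scale
  ``lambda``).
* **BBn** (also known as Bayes C) — spike-and-slab: a proportion ``pi`` of
  SNP carry an effect drawn from a normal slab with shared variance
  ``sigma2_snp``; the rest are exactly zero.
* **BBt** — spike-and-slab with a scaled Student-t slab (per-SNP variance
  as in Bayes A).

All hyperparameters (lambda, df, pi, sigma2_snp) can be fixed or estimated
from the data under flat priors; ``df`` uses a bounded flat prior on
[0.5, 9] sampled by random-walk Metropolis on log(df) with reflection,
step size adapted during burn-in toward 20-40% acceptance and then frozen.
Indicator updates marginalise the SNP effect (integrated-likelihood ratio)
for mixing. When ``df`` is estimated the whole chain schedule is stretched
by ``df_estimation_multiplier`` (default 5).

The inner sampling loop is compiled with numba; identical inputs and seed
give bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "SnpEffectVector",
    "PosteriorSummary",
    "run_chain",
    "gebv_from_effects",
    "METHODS",
]

METHODS = ("lasso", "bayesa", "bbn", "bbt")
_METHOD_CODE = {m: i for i, m in enumerate(METHODS)}

DF_BOUNDS = (0.5, 9.0)
HYPER_BOUNDS = (1e-8, 1e8)


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Prior family and hyperparameters; ``None`` means estimate from data.

    ``lambda_`` is the Laplace rate for LASSO and the scaled-t scale for
    Bayes A / BBt; ``df`` the t shape (Bayes A / BBt only); ``pi_`` the
    proportion of SNP with nonzero effect (BBn / BBt only); ``sigma2_snp``
    the shared normal-slab variance (BBn only).
    """

    method: str
    lambda_: Optional[float] = None
    df: Optional[float] = None
    pi_: Optional[float] = None
    sigma2_snp: Optional[float] = None

    def __post_init__(self) -> None:
        self.method = self.method.lower()
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.method in ("lasso", "bbn") and self.df is not None:
            raise ValueError(f"df is not a parameter of {self.method}")
        if self.method in ("lasso", "bayesa") and self.pi_ is not None:
            raise ValueError(f"pi is not a parameter of {self.method}")
        if self.method != "bbn" and self.sigma2_snp is not None:
            raise ValueError("sigma2_snp is only a parameter of bbn")
        if self.df is not None and not (DF_BOUNDS[0] <= self.df):
            raise ValueError(f"fixed df must be >= {DF_BOUNDS[0]}")
        if self.pi_ is not None and not (0.0 < self.pi_ <= 1.0):
            raise ValueError("pi must be in (0, 1]")

    @property
    def uses_df(self) -> bool:
        return self.method in ("bayesa", "bbt")

    @property
    def uses_pi(self) -> bool:
        return self.method in ("bbn", "bbt")

    @property
    def estimates_df(self) -> bool:
        return self.uses_df and self.df is None


@dataclass
class ChainConfig:
    """MCMC schedule. Defaults give the standard 210,000-cycle chain:
    10,000 burn-in cycles plus 10,000 retained realisations separated by
    20 cycles. With an estimated ``df`` the burn-in and thinning interval
    are stretched by ``df_estimation_multiplier``, making the chain that
    many times longer while retaining the same number of realisations."""

    burn_in: int = 10000
    n_samples: int = 10000
    thin: int = 20
    df_estimation_multiplier: int = 5
    seed: int = 0
    fit_intercept: bool = True
    fixed_sigma2_e: Optional[float] = None
    recompute_interval: int = 100   # cycles between full residual refreshes

    def __post_init__(self) -> None:
        for name in ("burn_in", "n_samples", "thin", "df_estimation_multiplier"):
            if getattr(self, name) < 1 and name != "burn_in":
                raise ValueError(f"{name} must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    @property
    def total_cycles(self) -> int:
        return self.burn_in + self.n_samples * self.thin

    def effective_schedule(self, df_estimated: bool) -> tuple[int, int, int]:
        """(burn_in, n_samples, thin) actually run; x multiplier on the
        burn-in and thinning interval when df is estimated."""
        if df_estimated:
            m = self.df_estimation_multiplier
            return self.burn_in * m, self.n_samples, self.thin * m
        return self.burn_in, self.n_samples, self.thin

    def effective_total_cycles(self, df_estimated: bool) -> int:
        b, n, t = self.effective_schedule(df_estimated)
        return b + n * t


@dataclass
class SnpEffectVector:
    """Posterior-mean allele-substitution effects, aligned with a marker panel."""

    snp_id: np.ndarray
    beta: np.ndarray
    inclusion_prob: Optional[np.ndarray] = None


@dataclass
class PosteriorSummary:
    """Posterior means and uncertainty from one chain."""

    method: str
    snp_effects: SnpEffectVector
    mu_hat: float
    sigma2_e_hat: float
    hyper_estimates: dict
    ids: np.ndarray
    gebv: np.ndarray
    pev: np.ndarray
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rand_invgauss(mu, lam):
    # Michael-Schucany-Haas
    v = np.random.standard_normal()
    w = v * v
    x = mu + mu * mu * w / (2.0 * lam) - (mu / (2.0 * lam)) * math.sqrt(
        4.0 * mu * lam * w + mu * mu * w * w)
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True, inline="always")
def _log_sichi2_sum(df, scale, sum_log_sv, sum_inv_sv, m):
    # sum_j log ScaledInvChi2(sv_j; df, scale)
    h = 0.5 * df
    return (m * (h * math.log(h * scale) - math.lgamma(h))
            - (h + 1.0) * sum_log_sv - h * scale * sum_inv_sv)


@njit(cache=True)
def _run_gibbs(seed, y, Zt, Zt_all, method,
               est_lambda, est_df, est_pi, est_s2snp,
               fit_intercept, fixed_s2e,
               lam0, df0, pi0, s2snp0,
               burn_in, n_samples, thin, recompute_interval,
               df_lo, df_hi, hyp_lo, hyp_hi):
    """Single-site Gibbs sampler shared by all four prior families.

    method: 0=lasso, 1=bayesa, 2=bbn, 3=bbt. Returns posterior
    accumulators; every random draw comes from numba's stream seeded here,
    so output is reproducible bit for bit.
    """
    np.random.seed(seed)
    m, n = Zt.shape
    N = Zt_all.shape[1]

    c = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Zt[j, i] * Zt[j, i]
        c[j] = s

    beta = np.zeros(m)
    delta = np.ones(m, dtype=np.int64)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    mu = ybar if fit_intercept else 0.0
    vy = 0.0
    for i in range(n):
        vy += (y[i] - ybar) ** 2
    vy /= n
    s2e = fixed_s2e if fixed_s2e > 0.0 else vy

    # method-of-moments scale: half the phenotypic variance spread over markers
    sum_vz = 0.0
    for j in range(m):
        zb = 0.0
        for i in range(n):
            zb += Zt[j, i]
        zb /= n
        sum_vz += c[j] / n - zb * zb
    if sum_vz <= 0.0:
        sum_vz = 1.0
    v0 = 0.5 * vy / sum_vz
    if v0 <= 0.0:
        v0 = 1e-6

    lam = lam0
    if lam <= 0.0:
        lam = math.sqrt(2.0 / v0) if method == 0 else v0
    df = df0
    pi = pi0
    s2snp = s2snp0 if s2snp0 > 0.0 else v0 / max(pi, 1e-3)
    sv = np.full(m, v0)       # per-SNP prior variances (tau2 for lasso)

    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu

    # df Metropolis adaptation
    df_step = 0.3
    df_acc = 0          # window counter for adaptation
    df_try = 0
    df_acc_total = 0
    df_try_total = 0
    gtmp = np.zeros(N)

    total = burn_in + n_samples * thin
    beta_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    g_sum = np.zeros(N)
    g_sumsq = np.zeros(N)
    mu_sum = 0.0
    s2e_sum = 0.0
    tr_lam = np.empty(n_samples)
    tr_df = np.empty(n_samples)
    tr_pi = np.empty(n_samples)
    tr_s2snp = np.empty(n_samples)
    kept = 0

    for cycle in range(total):
        # ---- intercept
        if fit_intercept:
            eb = 0.0
            for i in range(n):
                eb += e[i]
            eb /= n
            mu_new = mu + eb + np.random.standard_normal() * math.sqrt(s2e / n)
            d = mu_new - mu
            for i in range(n):
                e[i] -= d
            mu = mu_new

        # ---- SNP effects
        for j in range(m):
            cj = c[j]
            bj = beta[j]
            r = cj * bj
            for i in range(n):
                r += Zt[j, i] * e[i]
            if method == 0 or method == 1:
                vj = sv[j]
                lhs = cj + s2e / vj
                mean = r / lhs
                bnew = mean + np.random.standard_normal() * math.sqrt(s2e / lhs)
            else:
                vj = s2snp if method == 2 else sv[j]
                # marginal log Bayes factor slab vs spike
                log_bf = 0.5 * (math.log(s2e / (s2e + cj * vj))
                                + r * r * vj / (s2e * (s2e + cj * vj)))
                logit = math.log(pi / (1.0 - pi)) + log_bf if pi < 1.0 else 1e30
                if logit == 0.0:
                    take = False           # exact tie broken toward the spike
                elif logit > 35.0:
                    take = True
                elif logit < -35.0:
                    take = False
                else:
                    take = np.random.random() < 1.0 / (1.0 + math.exp(-logit))
                if take:
                    lhs = cj + s2e / vj
                    mean = r / lhs
                    bnew = mean + np.random.standard_normal() * math.sqrt(s2e / lhs)
                    delta[j] = 1
                else:
                    bnew = 0.0
                    delta[j] = 0
            d = bnew - bj
            if d != 0.0:
                for i in range(n):
                    e[i] -= Zt[j, i] * d
            beta[j] = bnew

            # per-SNP scale updates
            if method == 0:
                ab = abs(bnew)
                if ab < 1e-10:
                    ab = 1e-10
                mu_ig = lam / ab
                if mu_ig > 1e8:
                    mu_ig = 1e8
                inv_t = _rand_invgauss(mu_ig, lam * lam)
                t2 = 1.0 / inv_t
                if t2 < 1e-12:
                    t2 = 1e-12
                sv[j] = t2
            elif method == 1:
                sv[j] = (df * lam + bnew * bnew) / np.random.chisquare(df + 1.0)
            elif method == 3:
                if delta[j] == 1:
                    sv[j] = (df * lam + bnew * bnew) / np.random.chisquare(df + 1.0)
                else:
                    sv[j] = df * lam / np.random.chisquare(df)

        # ---- residual variance (flat prior on the variance)
        if fixed_s2e <= 0.0:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            s2e = sse / np.random.chisquare(n - 2.0)
            if s2e < 1e-12:
                s2e = 1e-12

        # ---- hyperparameters
        if method == 0 and est_lambda:
            sum_t2 = 0.0
            for j in range(m):
                sum_t2 += sv[j]
            u = np.random.gamma(m + 0.5, 2.0 / sum_t2)
            lam = math.sqrt(u)
            if lam < hyp_lo:
                lam = hyp_lo
            elif lam > hyp_hi:
                lam = hyp_hi
        if (method == 1 or method == 3) and est_lambda:
            sum_inv = 0.0
            for j in range(m):
                sum_inv += 1.0 / sv[j]
            lam = np.random.gamma(0.5 * m * df + 1.0, 2.0 / (df * sum_inv))
            if lam < hyp_lo:
                lam = hyp_lo
            elif lam > hyp_hi:
                lam = hyp_hi
        if method == 2 and est_s2snp:
            m1 = 0
            ssb = 0.0
            for j in range(m):
                if delta[j] == 1:
                    m1 += 1
                    ssb += beta[j] * beta[j]
            if m1 >= 3:
                s2snp = ssb / np.random.chisquare(m1 - 2.0)
                if s2snp < 1e-10:
                    s2snp = 1e-10
                elif s2snp > hyp_hi:
                    s2snp = hyp_hi
        if (method == 2 or method == 3) and est_pi:
            m1 = 0
            for j in range(m):
                m1 += delta[j]
            pi = np.random.beta(1.0 + m1, 1.0 + m - m1)
            if pi < 1e-6:
                pi = 1e-6
            elif pi > 1.0 - 1e-6:
                pi = 1.0 - 1e-6
        if (method == 1 or method == 3) and est_df:
            sum_log = 0.0
            sum_inv = 0.0
            for j in range(m):
                sum_log += math.log(sv[j])
                sum_inv += 1.0 / sv[j]
            ldf = math.log(df)
            lprop = ldf + df_step * np.random.standard_normal()
            llo = math.log(df_lo)
            lhi = math.log(df_hi)
            # reflect into bounds
            for _ in range(64):
                if lprop < llo:
                    lprop = 2.0 * llo - lprop
                elif lprop > lhi:
                    lprop = 2.0 * lhi - lprop
                else:
                    break
            dfp = math.exp(lprop)
            # flat prior on df itself; log-scale walk needs the Jacobian df
            loga = (_log_sichi2_sum(dfp, lam, sum_log, sum_inv, m) + lprop
                    - _log_sichi2_sum(df, lam, sum_log, sum_inv, m) - ldf)
            df_try += 1
            df_try_total += 1
            if math.log(np.random.random() + 1e-300) < loga:
                df = dfp
                df_acc += 1
                df_acc_total += 1
            if cycle < burn_in and df_try % 100 == 0:
                rate = df_acc / 100.0
                if rate > 0.4:
                    df_step *= 1.2
                elif rate < 0.2:
                    df_step /= 1.2
                df_acc = 0

        # ---- drift control: full residual refresh
        if (cycle + 1) % recompute_interval == 0:
            for i in range(n):
                acc = y[i] - mu
                e[i] = acc
            for j in range(m):
                bj = beta[j]
                if bj != 0.0:
                    for i in range(n):
                        e[i] -= Zt[j, i] * bj

        # ---- retention
        if cycle >= burn_in and (cycle - burn_in + 1) % thin == 0:
            for j in range(m):
                beta_sum[j] += beta[j]
                incl_sum[j] += delta[j]
            for k in range(N):
                gtmp[k] = 0.0
            for j in range(m):
                bj = beta[j]
                if bj != 0.0:
                    for k in range(N):
                        gtmp[k] += Zt_all[j, k] * bj
            for k in range(N):
                g_sum[k] += gtmp[k]
                g_sumsq[k] += gtmp[k] * gtmp[k]
            mu_sum += mu
            s2e_sum += s2e
            tr_lam[kept] = lam
            tr_df[kept] = df
            tr_pi[kept] = pi
            tr_s2snp[kept] = s2snp
            kept += 1

    acc_rate = df_acc_total / df_try_total if df_try_total > 0 else 0.0
    return (beta_sum, incl_sum, g_sum, g_sumsq, mu_sum, s2e_sum,
            tr_lam, tr_df, tr_pi, tr_s2snp, kept, df_step, acc_rate)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def run_chain(y: np.ndarray, Z: np.ndarray, prior: PriorSpec,
              config: Optional[ChainConfig] = None,
              snp_id: Optional[np.ndarray] = None,
              ids: Optional[np.ndarray] = None) -> PosteriorSummary:
    """Run one MCMC chain and summarise the posterior.

    ``Z`` is the full individuals-by-markers dosage matrix; rows whose
    phenotype is NaN are excluded from the likelihood but still receive a
    GEBV (the posterior mean of their Z beta, on the genetic scale without
    the intercept) and a PEV (the posterior variance of that sum).
    Zero-variance marker columns are dropped with a warning and reported
    with effect 0.
    """
    config = config or ChainConfig()
    y = np.asarray(y, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or y.size != Z.shape[0]:
        raise ValueError("y length must match rows of Z")
    if np.any(np.isinf(y)):
        raise ValueError("non-finite phenotype values")
    N, m_all = Z.shape
    if ids is None:
        ids = np.arange(1, N + 1, dtype=np.int64)
    if snp_id is None:
        snp_id = np.array([f"snp{j + 1}" for j in range(m_all)], dtype=object)

    obs = np.isfinite(y)
    if obs.sum() < 2:
        raise ValueError("need >= 2 phenotyped individuals")
    Zo = Z[obs]
    keep = Zo.var(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance marker columns")
    Zt = np.ascontiguousarray(Zo[:, keep].T)
    Zt_all = np.ascontiguousarray(Z[:, keep].T)

    est_lambda = prior.lambda_ is None
    est_df = prior.estimates_df
    est_pi = prior.uses_pi and prior.pi_ is None
    est_s2snp = prior.method == "bbn" and prior.sigma2_snp is None

    burn, n_samples, thin = config.effective_schedule(est_df)
    seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2 ** 31))

    (beta_sum, incl_sum, g_sum, g_sumsq, mu_sum, s2e_sum,
     tr_lam, tr_df, tr_pi, tr_s2snp, kept, df_step, df_acc_rate) = _run_gibbs(
        seed, y[obs], Zt, Zt_all, _METHOD_CODE[prior.method],
        est_lambda, est_df, est_pi, est_s2snp,
        config.fit_intercept,
        -1.0 if config.fixed_sigma2_e is None else float(config.fixed_sigma2_e),
        -1.0 if prior.lambda_ is None else float(prior.lambda_),
        4.0 if prior.df is None else float(prior.df),
        0.5 if prior.pi_ is None else float(prior.pi_),
        -1.0 if prior.sigma2_snp is None else float(prior.sigma2_snp),
        burn, n_samples, thin, config.recompute_interval,
        DF_BOUNDS[0], DF_BOUNDS[1], HYPER_BOUNDS[0], HYPER_BOUNDS[1])

    beta = np.zeros(m_all)
    beta[keep] = beta_sum / kept
    incl = np.zeros(m_all)
    incl[keep] = incl_sum / kept
    gebv = g_sum / kept
    pev = np.maximum(g_sumsq / kept - gebv ** 2, 0.0)

    hyper: dict[str, float] = {"lambda": float(tr_lam.mean())}
    traces: dict[str, np.ndarray] = {"lambda": tr_lam}
    if prior.uses_df:
        hyper["df"] = float(tr_df.mean())
        traces["df"] = tr_df
    if prior.uses_pi:
        hyper["pi"] = float(tr_pi.mean())
        traces["pi"] = tr_pi
    if prior.method == "bbn":
        hyper["sigma2_snp"] = float(tr_s2snp.mean())
        traces["sigma2_snp"] = tr_s2snp

    effects = SnpEffectVector(
        snp_id=np.asarray(snp_id, dtype=object), beta=beta,
        inclusion_prob=incl if prior.uses_pi else None)
    return PosteriorSummary(
        method=prior.method, snp_effects=effects,
        mu_hat=mu_sum / kept, sigma2_e_hat=s2e_sum / kept,
        hyper_estimates=hyper, ids=np.asarray(ids, dtype=np.int64),
        gebv=gebv, pev=pev,
        diagnostics={"traces": traces, "n_retained": int(kept),
                     "df_step": float(df_step),
                     "df_acceptance_rate": float(df_acc_rate),
                     "schedule": {"burn_in": burn, "n_samples": n_samples,
                                  "thin": thin,
                                  "total_cycles": burn + n_samples * thin}})


def gebv_from_effects(Z_new: np.ndarray, effects: SnpEffectVector,
                      mu_hat: float = 0.0, snp_id: Optional[np.ndarray] = None,
                      trait_scale: bool = False) -> np.ndarray:
    """GEBV as the sum of SNP effects given genotypes: Z_new @ beta.

    When ``snp_id`` is given the columns of ``Z_new`` are aligned to the
    effect vector by identifier; any mismatch raises with the offending
    ids. ``trait_scale`` adds the intercept.
    """
    Z_new = np.asarray(Z_new, dtype=np.float64)
    beta = effects.beta
    if snp_id is not None:
        snp_id = np.asarray(snp_id, dtype=object)
        want = {s: k for k, s in enumerate(effects.snp_id)}
        missing = [str(s) for s in snp_id if s not in want]
        if missing or snp_id.size != effects.snp_id.size:
            extra = [str(s) for s in effects.snp_id if s not in set(snp_id.tolist())]
            raise ValueError(f"marker panels differ; missing={missing[:5]} extra={extra[:5]}")
        order = np.array([want[s] for s in snp_id])
        beta = beta[order]
    elif Z_new.shape[1] != beta.size:
        raise ValueError(f"Z has {Z_new.shape[1]} columns, effects has {beta.size}")
    g = Z_new @ beta
    return g + mu_hat if trait_scale else g
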