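"""Heterogeneity and horizontal-pleiotropy diagnostics.

Two complementary checks on an instrument set:

* Cochran's Q over the per-SNP Wald ratios — excess heterogeneity
  relative to the fixed-effects IVW fit suggests pleiotropy or model
  misfit, and drives the fixed/random-effects choice downstream.
* MR-PRESSO — a simulation-based residual-sum-of-squares framework with
  (1) a global pleiotropy test comparing the observed weighted RSS of
  leave-one-out IVW residuals against a parametric null, (2) a per-SNP
  outlier test on the same simulated residuals with Bonferroni
  flagging, and (3) a distortion test comparing the IVW estimate before
  and after outlier removal against random removals.

Monte Carlo p-values carry the +1/(K+1) correction and are therefore
never zero; fixed seeds reproduce them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MrResult, RatioEstimate, ivw, wald_ratio
from .sumstats import HarmonizedInstrument


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with df = J - 1 and its upper-tail chi-square p."""

    q_statistic: float
    df: int
    pvalue: float

    def __post_init__(self) -> None:
        if self.q_statistic < 0 or self.df < 1:
            raise ValueError("invalid heterogeneity result")


@dataclass
class PressoReport:
    """Full MR-PRESSO output: global test, outliers, distortion, corrected IVW."""

    rss_observed: float
    global_pvalue: float
    per_snp_pvalues: dict[str, float]
    outliers: list[str]
    corrected: MrResult
    distortion_coefficient: float | None = None
    distortion_pvalue: float | None = None
    n_simulations: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "rss_observed": self.rss_observed,
            "global_pvalue": self.global_pvalue,
            "per_snp_pvalues": self.per_snp_pvalues,
            "outliers": self.outliers,
            "distortion_coefficient": self.distortion_coefficient,
            "distortion_pvalue": self.distortion_pvalue,
            "corrected": self.corrected.to_dict(),
            "n_simulations": self.n_simulations,
            "seed": self.seed,
        }


def cochran_q(ratios: list[RatioEstimate]) -> HeterogeneityResult:
    """Q = sum w_j (beta_j - beta_IVW)^2 against chi-square_{J-1}."""
    if len(ratios) < 2:
        raise ValueError("Cochran's Q needs at least 2 ratios")
    b = np.array([r.beta_ratio for r in ratios])
    w = np.array([r.weight for r in ratios])
    beta_ivw = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - beta_ivw) ** 2))
    df = len(ratios) - 1
    return HeterogeneityResult(q_statistic=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


@dataclass
class PressoGlobalResult:
    """Global-test output retaining the simulated residual distributions
    needed by the per-SNP outlier test."""

    rss_observed: float
    global_pvalue: float
    rsids: list[str]
    observed_wsq: np.ndarray          # (J,) weighted squared residuals
    simulated_wsq: np.ndarray         # (K, J)
    simulated_rss: np.ndarray = field(default=None)  # (K,)
    n_simulations: int = 0
    seed: int | None = None


def _loo_ivw(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, one per SNP.

    The IVW estimate equals a weighted regression of G on g through the
    origin with weights w = sigma_y^-2; dropping SNP j subtracts its
    terms from the two sums.  Supports batched inputs of shape (..., J).
    """
    num = np.sum(w * g * G, axis=-1, keepdims=True) - w * g * G
    den = np.sum(w * g * g, axis=-1, keepdims=True) - w * g * g
    return num / den


def presso_global(
    instruments: list[HarmonizedInstrument],
    n_simulations: int = 1000,
    seed: int | None = None,
) -> PressoGlobalResult:
    """MR-PRESSO global pleiotropy test.

    The observed statistic is RSS = sum_j w_j r_j^2 where
    r_j = Gamma_hat_j - gamma_hat_j * beta_(-j) (leave-one-out IVW) and
    w_j = sigma_y_j^-2.  The null distribution is built by simulating
    Gamma*_j ~ N(gamma_hat_j * beta_(-j), sigma_y_j) and
    gamma*_j ~ N(gamma_hat_j, sigma_x_j) and recomputing RSS identically
    on each replicate.  Requires at least 4 instruments (leave-one-out
    IVW needs 3) and at least 100 simulations.
    """
    J = len(instruments)
    if J < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    if n_simulations < 100:
        raise ValueError("n_simulations must be >= 100")
    g = np.array([i.gamma_hat for i in instruments])
    G = np.array([i.capital_gamma_hat for i in instruments])
    sx = np.array([i.sigma_x for i in instruments])
    sy = np.array([i.sigma_y for i in instruments])
    w = sy ** -2.0

    loo = _loo_ivw(g, G, w)
    resid = G - g * loo
    observed_wsq = w * resid ** 2
    rss_obs = float(np.sum(observed_wsq))

    rng = np.random.default_rng(seed)
    g_star = rng.normal(g, sx, size=(n_simulations, J))
    G_star = rng.normal(g * loo, sy, size=(n_simulations, J))
    loo_star = _loo_ivw(g_star, G_star, w)
    wsq_star = w * (G_star - g_star * loo_star) ** 2
    rss_star = wsq_star.sum(axis=1)

    p_global = float((1 + np.sum(rss_star >= rss_obs)) / (n_simulations + 1))
    return PressoGlobalResult(
        rss_observed=rss_obs,
        global_pvalue=p_global,
        rsids=[i.rsid for i in instruments],
        observed_wsq=observed_wsq,
        simulated_wsq=wsq_star,
        simulated_rss=rss_star,
        n_simulations=n_simulations,
        seed=seed,
    )


def presso_outlier(
    glob: PressoGlobalResult,
    alpha: float = 0.05,
) -> tuple[list[str], dict[str, float]]:
    """Per-SNP outlier test on the retained simulated residuals.

    SNP j's p-value is the Monte Carlo upper-tail probability of its
    observed weighted squared residual; it is flagged when
    p < alpha / J (Bonferroni).  Returns (flagged rsids, rsid -> p).
    """
    K = glob.n_simulations
    J = len(glob.rsids)
    exceed = np.sum(glob.simulated_wsq >= glob.observed_wsq, axis=0)
    pvals = (1 + exceed) / (K + 1)
    per_snp = {r: float(p) for r, p in zip(glob.rsids, pvals)}
    threshold = alpha / J
    flagged = [r for r, p in per_snp.items() if p < threshold]
    return flagged, per_snp


def presso_distortion(
    instruments: list[HarmonizedInstrument],
    outliers: list[str],
    n_resamples: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, MrResult]:
    """Distortion test: does removing the flagged outliers move the IVW
    estimate more than removing the same number of random SNPs?

    Returns (distortion coefficient in percent, two-sided empirical p,
    corrected fixed-effects IVW on the non-outlier subset).
    """
    if not outliers:
        raise ValueError("distortion test needs at least one outlier")
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    outset = set(outliers)
    keep = [i for i in instruments if i.rsid not in outset]
    if not keep:
        raise ValueError("all instruments flagged as outliers; nothing to correct")

    beta_all = ivw([wald_ratio(i) for i in instruments], model="fixed").beta
    corrected = ivw([wald_ratio(i) for i in keep], model="fixed")
    coef = 100.0 * (beta_all - corrected.beta) / abs(corrected.beta)

    rng = np.random.default_rng(seed)
    J, k = len(instruments), len(outliers)
    coefs = np.empty(n_resamples)
    for b in range(n_resamples):
        drop = set(rng.choice(J, size=k, replace=False))
        sub = [ins for j, ins in enumerate(instruments) if j not in drop]
        beta_sub = ivw([wald_ratio(i) for i in sub], model="fixed").beta
        coefs[b] = 100.0 * (beta_all - beta_sub) / abs(beta_sub)
    p = float((1 + np.sum(np.abs(coefs) >= abs(coef))) / (n_resamples + 1))
    return float(coef), p, corrected


def run_presso(
    instruments: list[HarmonizedInstrument],
    n_simulations: int = 1000,
    n_resamples: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PressoReport:
    """Full MR-PRESSO pass: global test, outlier flagging, and (when any
    outlier is found) the distortion test with the corrected estimate.

    With no outliers the "corrected" row is simply fixed-effects IVW on
    all instruments, matching how result tables report MR-PRESSO when
    nothing is removed.
    """
    glob = presso_global(instruments, n_simulations=n_simulations, seed=seed)
    flagged, per_snp = presso_outlier(glob, alpha=alpha)
    if flagged:
        coef, dist_p, corrected = presso_distortion(
            instruments, flagged, n_resamples=n_resamples, seed=seed)
    else:
        coef, dist_p = None, None
        corrected = ivw([wald_ratio(i) for i in instruments], model="fixed")
    return PressoReport(
        rss_observed=glob.rss_observed,
        global_pvalue=glob.global_pvalue,
        per_snp_pvalues=per_snp,
        outliers=flagged,
        corrected=corrected,
        distortion_coefficient=coef,
        distortion_pvalue=dist_p,
        n_simulations=n_simulations,
        seed=seed,
    )
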