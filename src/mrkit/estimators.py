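"""Causal-effect estimators for two-sample Mendelian randomization.

Given J harmonized instruments with exposure effects gamma_hat_j (SE
sigma_x_j) and outcome effects Gamma_hat_j (SE sigma_y_j), the per-SNP
Wald ratio is beta_j = Gamma_hat_j / gamma_hat_j with first-order SE
sigma_y_j / |gamma_hat_j|.  The estimators here combine the ratios:

* IVW — inverse-variance-weighted mean of the ratios, equivalently a
  weighted regression of Gamma_hat on gamma_hat through the origin.
  The fixed-effects SE is (sum w_j)^(-1/2); the multiplicative
  random-effects model keeps the same point estimate and scales the SE
  by max(1, sqrt(Q / (J - 1))) with Q Cochran's heterogeneity statistic.
* Weighted median — consistent when instruments carrying >= 50% of the
  weight are valid; SE by parametric bootstrap.
* MR-Egger — weighted regression with a free intercept; a nonzero
  intercept indicates directional horizontal pleiotropy and the slope
  is the pleiotropy-adjusted causal estimate (under InSIDE).

All p-values use the normal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .sumstats import HarmonizedInstrument


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with its first-order weight w = se^-2."""

    rsid: str
    beta_ratio: float
    se_ratio: float

    def __post_init__(self) -> None:
        if not (self.se_ratio > 0):
            raise ValueError(f"{self.rsid}: ratio SE must be positive")

    @property
    def weight(self) -> float:
        return self.se_ratio ** -2


@dataclass(frozen=True)
class MrResult:
    """One method's causal estimate, Table-row shaped."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    notes: str = ""

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError("se must be positive")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if not (0 < self.pvalue <= 1):
            raise ValueError("pvalue must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalue, "n_snp": self.n_snp, "notes": self.notes,
        }


def confidence_interval(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory confidence interval beta +/- z * se."""
    if not (se > 0):
        raise ValueError("se must be positive")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf((1 + level) / 2)
    return float(beta - z * se), float(beta + z * se)


def _normal_p(beta: float, se: float) -> float:
    # floor keeps extreme z-scores inside the (0, 1] invariant
    return float(min(1.0, max(2 * stats.norm.sf(abs(beta) / se), 1e-300)))


def wald_ratio(instr: HarmonizedInstrument) -> RatioEstimate:
    """Single-SNP causal estimate Gamma_hat / gamma_hat.

    SE is the first-order delta approximation sigma_y / |gamma_hat|
    (exposure-side uncertainty ignored, the usual choice for strong
    instruments).
    """
    if instr.gamma_hat == 0:
        raise ZeroDivisionError(f"{instr.rsid}: exposure effect is zero")
    return RatioEstimate(
        rsid=instr.rsid,
        beta_ratio=instr.capital_gamma_hat / instr.gamma_hat,
        se_ratio=instr.sigma_y / abs(instr.gamma_hat),
    )


def ivw(ratios: list[RatioEstimate], model: str = "fixed") -> MrResult:
    """Inverse-variance-weighted estimate over Wald ratios.

    Fixed and (multiplicative) random-effects models share the point
    estimate; the random model inflates the SE by
    max(1, sqrt(Q / (J - 1))), so random SE >= fixed SE always.
    A single ratio degenerates to the Wald ratio.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be fixed|random")
    if not ratios:
        raise ValueError("ivw needs at least one ratio")
    b = np.array([r.beta_ratio for r in ratios])
    w = np.array([r.weight for r in ratios])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    notes = ""
    if len(ratios) == 1:
        notes = "single instrument: degenerates to the Wald ratio"
    elif model == "random":
        q = float(np.sum(w * (b - beta) ** 2))
        se *= max(1.0, np.sqrt(q / (len(ratios) - 1)))
    lo, hi = confidence_interval(beta, se)
    return MrResult(
        method=f"IVW_{model}", beta=beta, se=se, ci_low=lo, ci_high=hi,
        pvalue=_normal_p(beta, se), n_snp=len(ratios), notes=notes,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median via linear interpolation of the standardized
    cumulative weights s_j = (cumsum(w)_j - w_j/2) / sum(w) at s = 0.5."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, v))


def weighted_median(ratios: list[RatioEstimate], n_boot: int = 1000,
                    seed: int | None = None) -> MrResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Each bootstrap replicate redraws beta_j ~ Normal(beta_j, se_j) and
    recomputes the weighted median; the SE is the SD of the replicates.
    Requires >= 3 instruments and n_boot >= 100.
    """
    if len(ratios) < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    b = np.array([r.beta_ratio for r in ratios])
    se = np.array([r.se_ratio for r in ratios])
    w = np.array([r.weight for r in ratios])
    beta = _weighted_median(b, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(b, se, size=(n_boot, len(ratios)))
    reps = np.empty(n_boot)
    for k in range(n_boot):
        reps[k] = _weighted_median(draws[k], w)
    se_boot = float(np.std(reps, ddof=1))
    lo, hi = confidence_interval(beta, se_boot)
    return MrResult(
        method="weighted_median", beta=beta, se=se_boot, ci_low=lo, ci_high=hi,
        pvalue=_normal_p(beta, se_boot), n_snp=len(ratios),
        notes=f"bootstrap SE, n_boot={n_boot}, seed={seed}",
    )


def egger(instruments: list[HarmonizedInstrument]) -> tuple[MrResult, MrResult]:
    """MR-Egger weighted regression; returns (slope, intercept) results.

    Instruments are first oriented so every exposure effect is
    non-negative (both gamma_hat and Gamma_hat negated where needed —
    the fit must be invariant to arbitrary allele coding).  The model
    Gamma_hat = alpha + beta * gamma_hat is fit by weighted least
    squares with weights sigma_y^-2; standard errors carry the
    multiplicative overdispersion factor max(1, sqrt(RSS_w / (J - 2))).
    """
    if len(instruments) < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    g = np.array([i.gamma_hat for i in instruments])
    G = np.array([i.capital_gamma_hat for i in instruments])
    sy = np.array([i.sigma_y for i in instruments])
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    if np.allclose(g, g[0]):
        raise ValueError("all exposure effects identical: design matrix singular")

    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=sy ** -2).fit()
    scale = max(1.0, float(fit.scale))  # fit.scale = weighted RSS / (J - 2)
    cov = np.asarray(fit.normalized_cov_params) * scale
    alpha, beta = float(fit.params[0]), float(fit.params[1])
    se_a, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    lo_b, hi_b = confidence_interval(beta, se_b)
    lo_a, hi_a = confidence_interval(alpha, se_a)
    slope = MrResult(method="egger_slope", beta=beta, se=se_b, ci_low=lo_b,
                     ci_high=hi_b, pvalue=_normal_p(beta, se_b),
                     n_snp=len(instruments))
    intercept = MrResult(method="egger_intercept", beta=alpha, se=se_a,
                         ci_low=lo_a, ci_high=hi_a, pvalue=_normal_p(alpha, se_a),
                         n_snp=len(instruments),
                         notes="nonzero intercept signals directional pleiotropy")
    return slope, intercept
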