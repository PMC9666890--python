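"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator embodies the standard two-sample MR generative model: a
binary exposure measured on the log-odds scale in one cohort and a
quantitative (SD-scale) outcome in another, linked per SNP j by

    Gamma_j = beta * gamma_j + alpha_j

where gamma_j is the SNP's true exposure effect, beta the causal effect
of interest, and alpha_j a horizontal-pleiotropy effect (zero for valid
instruments).  Sampling noise follows the usual allele-frequency /
sample-size approximation: a SNP with minor-allele frequency p in a
GWAS of n samples has standard error about (2 p (1-p) n)^(-1/2) on the
standardized scale, so the per-SNP SEs are driven by maf and n exactly
as in real summary statistics.

Defaults mirror a FinnGen-scale binary exposure (n = 218,754) against a
UK-Biobank-CMR-scale quantitative outcome (n = 35,648), with instrument
effect variance chosen so selected instruments are strong (per-SNP F
well above the conventional 10).

Every random quantity flows from a single seed; a fixed config + seed
reproduces the study byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .instruments import LdMatrix
from .sumstats import (HarmonizedInstrument, SummaryTable, VariantAssociation,
                       complement_allele)

_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]

_P_FLOOR = 1e-300  # keep extreme z-scores inside the (0, 1] invariant


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic two-sample study."""

    n_snps: int = 55
    n_exposure: int = 218754
    n_outcome: int = 35648
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_type: str = "binary"
    var_gamma: float = 1e-3          # variance of true instrument effects
    beta_causal: float = 0.12
    pleio_fraction: float = 0.0      # pi: share of SNPs with alpha != 0
    pleio_mean: float = 0.0          # mu_alpha
    pleio_sd: float = 0.0            # sigma_alpha
    inside_violation: bool = False   # correlate alpha with gamma
    inside_slope: float = 0.3
    ld_blocks: int = 0               # 0 = independent panel
    ld_rho: float = 0.0
    eaf_jitter_sd: float = 0.01      # between-sample eaf noise
    significant_only: bool = True    # condition panel on p < sig_threshold
    sig_threshold: float = 5e-8
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.pleio_fraction <= 1):
            raise ValueError("pleio_fraction must be in [0, 1]")
        if not (self.var_gamma > 0):
            raise ValueError("var_gamma must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated study."""

    beta_causal: float
    gamma: np.ndarray          # true per-SNP exposure effects
    alpha: np.ndarray          # true per-SNP pleiotropic effects
    pleiotropic: np.ndarray    # boolean flags
    maf: np.ndarray | None = None
    planted_outliers: list[str] = field(default_factory=list)


@dataclass
class SimulatedStudy:
    """Paired synthetic exposure/outcome tables with their generator truth."""

    exposure: SummaryTable
    outcome: SummaryTable
    ld: LdMatrix
    truth: SimulationTruth
    config: SimulationConfig

    @property
    def rsids(self) -> list[str]:
        return list(self.exposure.records)

    def instruments(self) -> list[HarmonizedInstrument]:
        """Instruments on the generator's own allele coding (no
        harmonization needed): one per SNP, exposure and outcome effects
        already on the same effect allele."""
        out = []
        for rsid in self.rsids:
            e, o = self.exposure[rsid], self.outcome[rsid]
            out.append(HarmonizedInstrument(
                rsid=rsid, effect_allele=e.effect_allele, other_allele=e.other_allele,
                gamma_hat=e.beta, sigma_x=e.se,
                capital_gamma_hat=o.beta, sigma_y=o.se,
                exposure_eaf=e.eaf, outcome_pvalue=o.pvalue,
            ))
        return out


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2 * stats.norm.sf(np.abs(beta / se)), _P_FLOOR)


def simulate_ld_matrix(n_snps: int, n_blocks: int, rho: float) -> LdMatrix:
    """Block-diagonal AR(1) r^2 panel: within a block r^2(i, j) =
    rho^(2|i-j|), zero across blocks, unit diagonal.  rho = 0 gives the
    identity (independent SNPs)."""
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    rsids = [f"rs{i + 1}" for i in range(n_snps)]
    r2 = np.eye(n_snps)
    if n_blocks > 0 and rho > 0:
        bounds = np.array_split(np.arange(n_snps), n_blocks)
        for block in bounds:
            for i in block:
                for j in block:
                    r2[i, j] = rho ** (2 * abs(int(i) - int(j)))
    return LdMatrix(rsids, r2)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Draw one synthetic two-sample study under ``cfg``.

    With ``significant_only`` set (the default), SNPs are rejection-
    sampled until the observed exposure association passes the
    genome-wide threshold — reproducing the winner's-curse conditioning
    a real instrument-selection pipeline applies.  The returned truth
    refers to the post-selection panel.
    """
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snps

    maf = np.empty(J)
    gamma = np.empty(J)
    gamma_hat = np.empty(J)
    sigma_x = np.empty(J)
    filled = 0
    max_rounds = 1000
    for _ in range(max_rounds):
        need = J - filled
        if need == 0:
            break
        m = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=need)
        g = rng.normal(0.0, np.sqrt(cfg.var_gamma), size=need)
        sx = (2 * m * (1 - m) * cfg.n_exposure) ** -0.5
        gh = rng.normal(g, sx)
        if cfg.significant_only:
            ok = _pvalue(gh, sx) < cfg.sig_threshold
        else:
            ok = np.ones(need, dtype=bool)
        k = int(ok.sum())
        sl = slice(filled, filled + k)
        maf[sl], gamma[sl], gamma_hat[sl], sigma_x[sl] = m[ok], g[ok], gh[ok], sx[ok]
        filled += k
    if filled < J:
        raise RuntimeError(
            "could not draw enough genome-wide-significant SNPs; "
            "raise var_gamma or disable significant_only")

    # pleiotropic effects are defined on the oriented (exposure-
    # increasing) scale: allele coding is arbitrary, so a nonzero mean
    # pleiotropic effect is only meaningful relative to each SNP's
    # exposure-effect direction.  alpha is drawn as N(mu, sd) on that
    # scale and mapped back through sign(gamma).
    pleio = rng.random(J) < cfg.pleio_fraction
    alpha_oriented = np.where(pleio, rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=J), 0.0)
    if cfg.inside_violation:
        alpha_oriented = alpha_oriented + np.where(pleio, cfg.inside_slope * np.abs(gamma), 0.0)
    alpha = np.where(gamma < 0, -alpha_oriented, alpha_oriented)

    sigma_y = (2 * maf * (1 - maf) * cfg.n_outcome) ** -0.5
    capital_gamma_hat = rng.normal(cfg.beta_causal * gamma + alpha, sigma_y)

    if not cfg.significant_only and not np.any(_pvalue(gamma_hat, sigma_x) < cfg.sig_threshold):
        import logging
        logging.getLogger("mrkit.simulate").warning(
            "no genome-wide-significant SNP in this draw")

    ld = simulate_ld_matrix(J, cfg.ld_blocks, cfg.ld_rho)
    rsids = ld.rsids

    # genomic coordinates: LD blocks are contiguous 100 kb-spaced runs,
    # separate blocks live far apart so clump windows never span them
    if cfg.ld_blocks > 0:
        block_of = np.concatenate([
            np.full(len(b), i) for i, b in enumerate(np.array_split(np.arange(J), cfg.ld_blocks))
        ])
        within = np.concatenate([
            np.arange(len(b)) for b in np.array_split(np.arange(J), cfg.ld_blocks)
        ])
        chroms = [str(int(b) % 22 + 1) for b in block_of]
        pos = (block_of.astype(int) // 22 + 1) * 100_000_000 + within * 100_000
    else:
        chroms = [str(j % 22 + 1) for j in range(J)]
        pos = (np.arange(J) // 22 + 1) * 10_000_000

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=J)
    eaf_exp = np.clip(maf + rng.normal(0, cfg.eaf_jitter_sd, size=J), 0.001, 0.999)
    eaf_out = np.clip(maf + rng.normal(0, cfg.eaf_jitter_sd, size=J), 0.001, 0.999)

    exposure = SummaryTable("exposure", cfg.exposure_type, cfg.n_exposure)
    outcome = SummaryTable("outcome", "quantitative", cfg.n_outcome)
    p_exp = _pvalue(gamma_hat, sigma_x)
    p_out = _pvalue(capital_gamma_hat, sigma_y)
    for j, rsid in enumerate(rsids):
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        exposure.add(VariantAssociation(
            rsid=rsid, chrom=chroms[j], pos=int(pos[j]), effect_allele=ea,
            other_allele=oa, eaf=float(eaf_exp[j]), beta=float(gamma_hat[j]),
            se=float(sigma_x[j]), pvalue=float(p_exp[j]), n=cfg.n_exposure))
        outcome.add(VariantAssociation(
            rsid=rsid, chrom=chroms[j], pos=int(pos[j]), effect_allele=ea,
            other_allele=oa, eaf=float(eaf_out[j]), beta=float(capital_gamma_hat[j]),
            se=float(sigma_y[j]), pvalue=float(p_out[j]), n=cfg.n_outcome))

    truth = SimulationTruth(beta_causal=cfg.beta_causal, gamma=gamma, alpha=alpha,
                            pleiotropic=pleio, maf=maf)
    return SimulatedStudy(exposure=exposure, outcome=outcome, ld=ld,
                          truth=truth, config=cfg)


def scramble_outcome_representation(study: SimulatedStudy, seed: int | None = None) -> SimulatedStudy:
    """Re-express the outcome table's allele coding at random — swapped
    effect/other alleles and/or opposite strand — without changing any
    underlying effect.  Harmonization must undo every change; this
    exercises the full truth table including palindromes."""
    rng = np.random.default_rng(seed)
    new_outcome = SummaryTable(study.outcome.trait_name, study.outcome.trait_type,
                               study.outcome.sample_size)
    for rec in study.outcome.records.values():
        ea, oa, beta, eaf = rec.effect_allele, rec.other_allele, rec.beta, rec.eaf
        if rng.random() < 0.5:  # swap effect/other
            ea, oa, beta = oa, ea, -beta
            eaf = None if eaf is None else 1 - eaf
        if rng.random() < 0.5:  # report on the opposite strand
            ea, oa = complement_allele(ea), complement_allele(oa)
        new_outcome.add(dataclasses.replace(rec, effect_allele=ea, other_allele=oa,
                                            beta=beta, eaf=eaf))
    return dataclasses.replace(study, outcome=new_outcome)


def simulate_additional_outcome(
    study: SimulatedStudy,
    trait_name: str,
    beta_causal: float,
    n_outcome: int,
    seed: int | None = None,
    pleio_fraction: float = 0.0,
    pleio_mean: float = 0.0,
    pleio_sd: float = 0.0,
) -> SummaryTable:
    """Draw a further outcome GWAS against the same instrument panel.

    Reuses the study's true exposure effects and allele frequencies so
    several outcomes can share one exposure-side selection — the usual
    situation when one exposure GWAS is analysed against a family of
    phenotypes measured in another biobank.
    """
    if study.truth.maf is None:
        raise ValueError("study lacks stored allele frequencies")
    rng = np.random.default_rng(seed)
    J = len(study.rsids)
    gamma, maf = study.truth.gamma, study.truth.maf
    pleio = rng.random(J) < pleio_fraction
    alpha_oriented = np.where(pleio, rng.normal(pleio_mean, pleio_sd, size=J), 0.0)
    alpha = np.where(gamma < 0, -alpha_oriented, alpha_oriented)
    sigma_y = (2 * maf * (1 - maf) * n_outcome) ** -0.5
    Gamma = rng.normal(beta_causal * gamma + alpha, sigma_y)
    eaf = np.clip(maf + rng.normal(0, study.config.eaf_jitter_sd, size=J), 0.001, 0.999)
    pvals = _pvalue(Gamma, sigma_y)

    table = SummaryTable(trait_name, "quantitative", n_outcome)
    for j, rsid in enumerate(study.rsids):
        ref = study.exposure[rsid]
        table.add(VariantAssociation(
            rsid=rsid, chrom=ref.chrom, pos=ref.pos,
            effect_allele=ref.effect_allele, other_allele=ref.other_allele,
            eaf=float(eaf[j]), beta=float(Gamma[j]), se=float(sigma_y[j]),
            pvalue=float(pvals[j]), n=n_outcome))
    return table


def plant_outliers(study: SimulatedStudy, k: int, magnitude: float,
                   seed: int | None = None, direction: str = "raw") -> SimulatedStudy:
    """Inject k horizontally pleiotropic outliers.

    Each chosen SNP's outcome effect gains ``magnitude`` outcome
    standard errors; truth flags are updated.  k = 0 is the identity.

    ``direction`` controls the pleiotropy's orientation on the causal
    (ratio) scale.  "raw" adds +magnitude * sigma_y to every chosen
    outcome effect regardless of allele coding; with mixed gamma_hat
    signs the induced ratio shifts partially cancel, so the pleiotropy
    is balanced-ish.  "aligned" multiplies by sign(gamma_hat), making
    every outlier push the causal estimate the same way — genuinely
    directional pleiotropy.
    """
    if direction not in ("raw", "aligned"):
        raise ValueError("direction must be raw|aligned")
    J = len(study.rsids)
    if k >= J:
        raise ValueError("cannot plant as many outliers as instruments")
    if k == 0:
        return study
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(study.rsids, size=k, replace=False).tolist())
    chosen_set = set(chosen)

    new_outcome = SummaryTable(study.outcome.trait_name, study.outcome.trait_type,
                               study.outcome.sample_size)
    shift: dict[str, float] = {}
    for rec in study.outcome.records.values():
        if rec.rsid in chosen_set:
            s = 1.0
            if direction == "aligned":
                s = float(np.sign(study.exposure[rec.rsid].beta)) or 1.0
            shift[rec.rsid] = magnitude * rec.se * s
            beta = rec.beta + shift[rec.rsid]
            rec = dataclasses.replace(
                rec, beta=beta,
                pvalue=float(max(2 * stats.norm.sf(abs(beta / rec.se)), _P_FLOOR)))
        new_outcome.add(rec)

    idx = {r: i for i, r in enumerate(study.rsids)}
    alpha = study.truth.alpha.copy()
    pleio = study.truth.pleiotropic.copy()
    for rsid in chosen:
        j = idx[rsid]
        alpha[j] += shift[rsid]
        pleio[j] = True
    truth = SimulationTruth(beta_causal=study.truth.beta_causal,
                            gamma=study.truth.gamma, alpha=alpha, pleiotropic=pleio,
                            planted_outliers=sorted(set(study.truth.planted_outliers) | chosen_set))
    return dataclasses.replace(study, outcome=new_outcome, truth=truth)


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write exposure.tsv, outcome.tsv, ld.tsv and truth.json."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.exposure.to_frame().to_csv(outdir / "exposure.tsv", sep="\t", index=False)
    study.outcome.to_frame().to_csv(outdir / "outcome.tsv", sep="\t", index=False)
    study.ld.to_tsv(outdir / "ld.tsv")
    truth = {
        "beta_causal": study.truth.beta_causal,
        "gamma": study.truth.gamma.tolist(),
        "alpha": study.truth.alpha.tolist(),
        "pleiotropic": study.truth.pleiotropic.astype(bool).tolist(),
        "maf": None if study.truth.maf is None else study.truth.maf.tolist(),
        "planted_outliers": study.truth.planted_outliers,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
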