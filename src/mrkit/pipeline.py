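"""End-to-end per-outcome Mendelian randomization analysis.

One exposure GWAS against any number of outcome GWASs:

1. exposure-side instrument selection once — genome-wide significance,
   LD clumping, confounder-trait exclusion;
2. per outcome — harmonization, outcome-association (Bonferroni)
   exclusion, per-SNP F report;
3. estimation — fixed- and random-effects IVW, weighted median,
   MR-Egger slope and intercept;
4. diagnostics — Cochran's Q (which picks the primary IVW model:
   fixed effects when the Q-test p exceeds ``q_alpha``, random effects
   otherwise) and MR-PRESSO with its outlier-corrected estimate.

Reports carry every estimate, the instrument audit trail, and the full
configuration, and serialize deterministically: identical config + seed
yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators, instruments as insel, pleiotropy, sumstats

logger = logging.getLogger("mrkit.pipeline")


@dataclass(frozen=True)
class AnalysisConfig:
    clump: insel.ClumpConfig = insel.ClumpConfig()
    palindrome_eaf_window: float = 0.08
    q_alpha: float = 0.05            # fixed/random switch threshold
    presso_k: int = 1000             # global-test simulations
    presso_b: int = 1000             # distortion resamples
    presso_alpha: float = 0.05
    outcome_alpha: float = 0.05      # Bonferroni numerator for outcome filter
    n_boot: int = 1000               # weighted-median bootstrap
    remove_weak: bool = False
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0 < self.q_alpha < 1):
            raise ValueError("q_alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class OutcomeReport:
    """All results for one outcome, Table-style."""

    outcome_name: str
    rows: list[estimators.MrResult]
    heterogeneity: pleiotropy.HeterogeneityResult
    presso: pleiotropy.PressoReport | None
    primary_method: str              # IVW_fixed | IVW_random
    n_snp: int
    f_statistics: dict[str, float]
    audit_trail: list[dict]
    instruments: list[sumstats.HarmonizedInstrument]
    config: AnalysisConfig
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome_name,
            "n_snp": self.n_snp,
            "primary_method": self.primary_method,
            "rows": [r.to_dict() for r in self.rows],
            "heterogeneity": {
                "q": self.heterogeneity.q_statistic,
                "df": self.heterogeneity.df,
                "pvalue": self.heterogeneity.pvalue,
            },
            "presso": None if self.presso is None else self.presso.to_dict(),
            "f_statistics": self.f_statistics,
            "audit_trail": self.audit_trail,
            "config": self.config.to_dict(),
            "error": self.error,
        }


def select_exposure_instruments(
    exposure: sumstats.SummaryTable,
    ld: insel.LdMatrix | None,
    exclusions: dict[str, list[str]] | None,
    cfg: AnalysisConfig,
    audit: list[dict],
) -> list[str]:
    """Exposure-side selection, done once per analysis: significance ->
    clump -> confounder-trait exclusion."""
    sig = insel.filter_significant(exposure, cfg.clump.p_threshold)
    logger.info("significant at p<%g: %d", cfg.clump.p_threshold, len(sig))
    clumped = insel.ld_clump(sig, exposure, ld, cfg.clump, drop_log=audit)
    logger.info("after clumping: %d", len(clumped))
    kept = insel.exclude_by_trait_list(clumped, exclusions or {}, drop_log=audit)
    logger.info("after trait exclusion: %d", len(kept))
    return kept


def analyse_outcome(
    exposure: sumstats.SummaryTable,
    outcome: sumstats.SummaryTable,
    selected: list[str],
    cfg: AnalysisConfig,
    audit_prefix: list[dict],
) -> OutcomeReport:
    """Harmonize one outcome against the pre-selected exposure
    instruments, run every estimator and diagnostic, and apply the
    heterogeneity rule for the primary method."""
    audit = list(audit_prefix)
    instr = sumstats.harmonize(exposure, outcome, selected,
                               palindrome_eaf_window=cfg.palindrome_eaf_window,
                               drop_log=audit)
    instr = insel.exclude_outcome_associated(instr, alpha=cfg.outcome_alpha, drop_log=audit)
    iset = insel.build_instrument_set(instr, provenance=audit, remove_weak=cfg.remove_weak)
    instr = iset.instruments
    if len(instr) < 3:
        raise ValueError(
            f"{outcome.trait_name}: only {len(instr)} instruments survive filtering (need >= 3)")

    seq = np.random.SeedSequence(cfg.seed)
    wm_seed, presso_seed = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seq.spawn(2)]

    ratios = [estimators.wald_ratio(i) for i in instr]
    het = pleiotropy.cochran_q(ratios)
    rows = [
        estimators.ivw(ratios, model="fixed"),
        estimators.ivw(ratios, model="random"),
        estimators.weighted_median(ratios, n_boot=cfg.n_boot, seed=wm_seed),
    ]
    slope, intercept = estimators.egger(instr)
    rows += [slope, intercept]

    presso = None
    if len(instr) >= 4:
        presso = pleiotropy.run_presso(instr, n_simulations=cfg.presso_k,
                                       n_resamples=cfg.presso_b,
                                       alpha=cfg.presso_alpha, seed=presso_seed)
        corrected = dataclasses.replace(presso.corrected, method="presso_corrected")
        rows.append(corrected)

    primary = "IVW_fixed" if het.pvalue > cfg.q_alpha else "IVW_random"
    return OutcomeReport(
        outcome_name=outcome.trait_name, rows=rows, heterogeneity=het,
        presso=presso, primary_method=primary, n_snp=len(instr),
        f_statistics=iset.f_statistics, audit_trail=iset.provenance,
        instruments=instr, config=cfg,
    )


def run_analysis(
    exposure: sumstats.SummaryTable,
    outcomes: list[sumstats.SummaryTable],
    ld: insel.LdMatrix | None = None,
    exclusions: dict[str, list[str]] | None = None,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> list[OutcomeReport]:
    """Full analysis: shared exposure-side selection, then per-outcome
    harmonization, estimation, and diagnostics.  An outcome with fewer
    than 3 surviving instruments is reported as an explicit error record
    rather than aborting the run."""
    shared_audit: list[dict] = []
    selected = select_exposure_instruments(exposure, ld, exclusions, cfg, shared_audit)
    reports = []
    for outcome in outcomes:
        try:
            reports.append(analyse_outcome(exposure, outcome, selected, cfg, shared_audit))
        except ValueError as exc:
            logger.error("outcome %s failed: %s", outcome.trait_name, exc)
            reports.append(OutcomeReport(
                outcome_name=outcome.trait_name, rows=[],
                heterogeneity=pleiotropy.HeterogeneityResult(0.0, 1, 1.0),
                presso=None, primary_method="none", n_snp=0, f_statistics={},
                audit_trail=shared_audit, instruments=[], config=cfg, error=str(exc)))
    return reports


def _round3(x: float) -> str:
    """Display rounding: half-even to 3 decimals (Python's float repr of
    round(), which uses banker's rounding)."""
    return format(round(x, 3), ".3f")


def report_table(report: OutcomeReport) -> pd.DataFrame:
    """Method-by-row table mirroring the usual MR results layout:
    n SNPs, method, 'Beta (Se)', P, heterogeneity-test P on the first
    row only."""
    rows = []
    for i, r in enumerate(report.rows):
        rows.append({
            "outcome": report.outcome_name,
            "n_snp": r.n_snp,
            "method": r.method,
            "beta_se": f"{_round3(r.beta)} ({_round3(r.se)})",
            "pvalue": f"{r.pvalue:.2E}",
            "heterogeneity_p": f"{report.heterogeneity.pvalue:.3G}" if i == 0 else "",
        })
    return pd.DataFrame(rows)


def forest_data(report: OutcomeReport) -> pd.DataFrame:
    """Per-SNP ratio estimates with SEs — plain-data export for forest
    and funnel plots."""
    ratios = [estimators.wald_ratio(i) for i in report.instruments]
    return pd.DataFrame({
        "rsid": [r.rsid for r in ratios],
        "beta_ratio": [r.beta_ratio for r in ratios],
        "se_ratio": [r.se_ratio for r in ratios],
        "precision": [1 / r.se_ratio for r in ratios],
    })


def write_report(reports: list[OutcomeReport], outdir, formats=("tsv", "json", "markdown")) -> list[Path]:
    """Serialize every outcome report.  Per outcome:
    <name>.report.{tsv,json,md}, <name>.instruments.tsv,
    <name>.presso.json (when run), forest_<name>.tsv."""
    if not reports:
        raise ValueError("no reports to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for rep in reports:
        name = rep.outcome_name
        if rep.error is not None:
            p = outdir / f"{name}.error.json"
            p.write_text(json.dumps({"outcome": name, "error": rep.error}, indent=2,
                                    sort_keys=True) + "\n")
            written.append(p)
            continue
        table = report_table(rep)
        if "tsv" in formats:
            p = outdir / f"{name}.report.tsv"
            table.to_csv(p, sep="\t", index=False)
            written.append(p)
        if "json" in formats:
            p = outdir / f"{name}.report.json"
            p.write_text(json.dumps(rep.to_dict(), indent=2, sort_keys=True) + "\n")
            written.append(p)
        if "markdown" in formats:
            p = outdir / f"{name}.report.md"
            p.write_text(table.to_markdown(index=False) + "\n")
            written.append(p)
        p = outdir / f"{name}.instruments.tsv"
        sumstats.instruments_to_frame(rep.instruments).to_csv(p, sep="\t", index=False)
        written.append(p)
        p = outdir / f"forest_{name}.tsv"
        forest_data(rep).to_csv(p, sep="\t", index=False)
        written.append(p)
        if rep.presso is not None:
            p = outdir / f"{name}.presso.json"
            p.write_text(json.dumps(rep.presso.to_dict(), indent=2, sort_keys=True) + "\n")
            written.append(p)
    return written
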