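"""Instrument selection for two-sample Mendelian randomization.

Reproduces the standard filter chain for choosing exposure instruments:
genome-wide significance, greedy LD clumping (index-SNP selection within
a kilobase window at an r-squared cutoff), removal of variants known to
associate with confounding traits, removal of variants directly
associated with the outcome (Bonferroni threshold), and per-SNP
F-statistics as the instrument-strength report.

The chain's order is fixed: significance -> clump -> trait exclusion ->
(harmonize, in :mod:`mrkit.sumstats`) -> outcome-association exclusion
-> F report.  An audit trail records the stage at which each candidate
left.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedInstrument, SummaryTable

logger = logging.getLogger("mrkit.instruments")


@dataclass(frozen=True)
class ClumpConfig:
    """LD clumping parameters (defaults follow common GWAS practice:
    genome-wide significance 5e-8, r^2 < 0.001 within 500 kb)."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 500.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")
        if not (self.window_kb > 0):
            raise ValueError("window_kb must be > 0")


class LdMatrix:
    """Pairwise squared-correlation (r^2) matrix over an rsid panel.

    Symmetric with unit diagonal; values in [0, 1].
    """

    def __init__(self, rsids: list[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (len(rsids), len(rsids)):
            raise ValueError("r2 shape does not match rsid count")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-12):
            raise ValueError("r2 diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self.rsids = list(rsids)
        self.r2 = r2
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, a: str, b: str) -> float | None:
        """r^2 between two rsids, or None when either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids)

    @classmethod
    def from_tsv(cls, path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy())

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class InstrumentSet:
    """Post-filter instruments with per-SNP F values and an audit trail."""

    instruments: list[HarmonizedInstrument]
    f_statistics: dict[str, float] = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        rsids = [i.rsid for i in self.instruments]
        if len(rsids) != len(set(rsids)):
            raise ValueError("duplicate rsids in instrument set")

    def __len__(self) -> int:
        return len(self.instruments)


def filter_significant(table: SummaryTable, p_threshold: float = 5e-8) -> list[str]:
    """rsids with p below the significance threshold, ascending p.

    Ties on p are broken lexicographically by rsid for determinism.
    """
    hits = [(r.pvalue, r.rsid) for r in table.records.values() if r.pvalue < p_threshold]
    if not hits:
        logger.warning("%s: no variant passes p < %g", table.trait_name, p_threshold)
    return [rsid for _, rsid in sorted(hits)]


def ld_clump(
    candidates: list[str],
    table: SummaryTable,
    ld: LdMatrix | None,
    cfg: ClumpConfig = ClumpConfig(),
    drop_log: list[dict] | None = None,
) -> list[str]:
    """Greedy index-SNP selection (Plink-style clumping).

    Repeatedly takes the smallest-p remaining candidate as an index SNP
    and removes every remaining candidate on the same chromosome within
    ``window_kb`` whose r^2 against the index is >= ``r2_threshold``.
    When ``ld`` is None, distance alone removes.  A candidate missing
    from a provided LD matrix has unknown r^2 and is removed whenever it
    is inside the window (conservative).  Returns index SNPs in
    selection order; output is invariant under input permutation (p-value
    ties broken by rsid).
    """
    if drop_log is None:
        drop_log = []
    pending = sorted(candidates, key=lambda r: (table[r].pvalue, r))
    kept: list[str] = []
    removed: set[str] = set()
    for idx_rsid in pending:
        if idx_rsid in removed:
            continue
        kept.append(idx_rsid)
        idx = table[idx_rsid]
        for other in pending:
            if other == idx_rsid or other in removed or other in kept:
                continue
            oth = table[other]
            if oth.chrom != idx.chrom:
                continue
            if abs(oth.pos - idx.pos) > cfg.window_kb * 1000:
                continue
            if ld is None:
                in_ld = True  # distance-only pruning
            else:
                r2 = ld.get(idx_rsid, other)
                if r2 is None:
                    logger.info("clump: r2 unknown for (%s, %s); removing conservatively",
                                idx_rsid, other)
                    in_ld = True
                else:
                    in_ld = r2 >= cfg.r2_threshold
            if in_ld:
                removed.add(other)
                drop_log.append({"rsid": other, "stage": "clump",
                                 "reason": f"clumped_by:{idx_rsid}"})
    return kept


def exclude_by_trait_list(
    rsids: list[str],
    exclusion: dict[str, list[str]],
    drop_log: list[dict] | None = None,
) -> list[str]:
    """Remove instruments listed as associated with confounding traits.

    ``exclusion`` maps rsid -> list of trait names (e.g. BMI, coronary
    heart disease, diabetes).  Removals are logged once per rsid with
    all traits.
    """
    if drop_log is None:
        drop_log = []
    kept = []
    for rsid in rsids:
        traits = exclusion.get(rsid)
        if traits:
            drop_log.append({"rsid": rsid, "stage": "trait_exclusion",
                             "reason": "associated_traits:" + ";".join(sorted(set(traits)))})
            logger.info("excluded %s (associated with %s)", rsid, ", ".join(sorted(set(traits))))
        else:
            kept.append(rsid)
    return kept


def read_exclusion_list(path) -> dict[str, list[str]]:
    """Two-column TSV (rsid, trait) -> rsid -> traits mapping.  An empty
    file yields an empty mapping."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["rsid", "trait"], dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    mapping: dict[str, list[str]] = {}
    for rsid, trait in zip(df["rsid"], df["trait"]):
        mapping.setdefault(str(rsid), []).append(str(trait))
    return mapping


def exclude_outcome_associated(
    instruments: list[HarmonizedInstrument],
    alpha: float = 0.05,
    drop_log: list[dict] | None = None,
) -> list[HarmonizedInstrument]:
    """Drop instruments directly associated with the outcome.

    The threshold is Bonferroni: alpha / J where J is the number of
    instruments entering this filter.  An instrument is removed when its
    outcome-association p-value is strictly below the threshold (a p
    exactly equal to alpha/J is retained).  Outcome p-values come from
    the harmonized record when present, otherwise from the normal
    approximation on |Gamma_hat / sigma_y|.
    """
    if drop_log is None:
        drop_log = []
    j = len(instruments)
    if j == 0:
        return []
    threshold = alpha / j
    kept = []
    for ins in instruments:
        p = ins.outcome_pvalue
        if p is None:
            p = 2 * stats.norm.sf(abs(ins.capital_gamma_hat / ins.sigma_y))
        if p < threshold:
            drop_log.append({"rsid": ins.rsid, "stage": "outcome_association",
                             "reason": f"outcome_p={p:.3g}<{threshold:.3g}"})
            logger.info("excluded %s: outcome p %.3g < %.3g (0.05/%d)", ins.rsid, p, threshold, j)
        else:
            kept.append(ins)
    return kept


def f_statistic(gamma_hat: float, sigma_x: float) -> float:
    """Single-SNP instrument-strength F = (gamma_hat / sigma_x)^2.

    F > 10 is the conventional bar for "not a weak instrument".
    """
    if not (sigma_x > 0):
        raise ValueError("sigma_x must be > 0")
    return (gamma_hat / sigma_x) ** 2


def build_instrument_set(
    instruments: list[HarmonizedInstrument],
    provenance: list[dict] | None = None,
    weak_f_threshold: float = 10.0,
    remove_weak: bool = False,
) -> InstrumentSet:
    """Attach F-statistics; weak instruments (F <= threshold) are flagged
    in the log and removed only when ``remove_weak`` is set."""
    provenance = list(provenance or [])
    fstats = {i.rsid: f_statistic(i.gamma_hat, i.sigma_x) for i in instruments}
    weak = [r for r, f in fstats.items() if f <= weak_f_threshold]
    for rsid in weak:
        logger.warning("weak instrument %s: F = %.2f <= %g", rsid, fstats[rsid], weak_f_threshold)
    if remove_weak and weak:
        for rsid in weak:
            provenance.append({"rsid": rsid, "stage": "weak_instrument",
                               "reason": f"F={fstats[rsid]:.3g}"})
        instruments = [i for i in instruments if i.rsid not in set(weak)]
        fstats = {r: f for r, f in fstats.items() if r not in set(weak)}
    return InstrumentSet(instruments=instruments, f_statistics=fstats, provenance=provenance)
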