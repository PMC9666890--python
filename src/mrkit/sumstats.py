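"""GWAS summary-statistics I/O and allele harmonization.

Two-sample Mendelian randomization combines per-variant association
estimates from an exposure GWAS and an outcome GWAS.  Before any causal
estimate can be formed the two tables must refer to the same effect
allele for every instrument: effect/other alleles may be swapped between
studies, reported on opposite strands, or (for A/T and C/G palindromes)
irresolvable from the alleles alone.  This module reads delimited
summary tables into validated records and aligns outcome effects onto
the exposure's effect allele.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mrkit.sumstats")

VALID_BASES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Standard field names a column map must cover.
MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue")
OPTIONAL_FIELDS = ("chrom", "pos", "eaf", "n")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association record in one GWAS.

    ``beta`` is on the log-odds scale for binary traits and in phenotype
    SD (or native) units for quantitative traits.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str = ""
    pos: int = 0
    eaf: float | None = None
    n: float | None = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValueError(f"{self.rsid}: alleles must be single uppercase A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if not (self.se > 0):
            raise ValueError(f"{self.rsid}: se must be > 0")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.rsid}: pvalue must be in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.rsid}: eaf must be in (0, 1)")
        if self.n is not None and not (self.n > 0):
            raise ValueError(f"{self.rsid}: n must be > 0")


@dataclass
class SummaryTable:
    """A trait's GWAS summary statistics, keyed by rsid (unique)."""

    trait_name: str
    trait_type: str  # "binary" | "quantitative"
    sample_size: int
    records: dict[str, VariantAssociation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"trait_type must be binary|quantitative, got {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __getitem__(self, rsid: str) -> VariantAssociation:
        return self.records[rsid]

    def add(self, rec: VariantAssociation) -> None:
        if rec.rsid in self.records:
            raise ValueError(f"duplicate rsid {rec.rsid} in table {self.trait_name}")
        self.records[rec.rsid] = rec

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": r.rsid,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": np.nan if r.n is None else r.n,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's exposure and outcome effects on a common effect allele.

    ``gamma_hat``/``sigma_x`` are the exposure-side effect and SE,
    ``capital_gamma_hat``/``sigma_y`` the outcome-side effect and SE,
    all referring to ``effect_allele``.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    gamma_hat: float
    sigma_x: float
    capital_gamma_hat: float
    sigma_y: float
    flags: frozenset[str] = frozenset()
    exposure_eaf: float | None = None
    outcome_pvalue: float | None = None

    def __post_init__(self) -> None:
        if not (self.sigma_x > 0 and self.sigma_y > 0):
            raise ValueError(f"{self.rsid}: standard errors must be positive")


def complement_allele(base: str) -> str:
    """Watson–Crick complement of a single base (A<->T, C<->G)."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not a valid base: {base!r}") from None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is A/T or C/G in either order.

    For such pairs the strand cannot be resolved from alleles alone;
    orientation must come from allele frequencies or the variant is
    dropped.
    """
    for a in (effect_allele, other_allele):
        if a not in VALID_BASES:
            raise ValueError(f"not a valid base: {a!r}")
    return complement_allele(effect_allele) == other_allele


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sumstats(
    path,
    column_map: dict[str, str],
    trait_name: str,
    trait_type: str,
    sample_size: int,
    delimiter: str = "\t",
) -> SummaryTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    column_map
        Mapping from file column name to standard field name; must cover
        rsid, effect_allele, other_allele, beta, se, pvalue.  chrom,
        pos, eaf, n are optional.
    trait_name, trait_type, sample_size
        Trait metadata; sample_size is used downstream when a record
        carries no per-SNP n.

    Rows violating record invariants (indels, se<=0, out-of-range p or
    eaf, duplicate rsid) are dropped and counted in the log.  Lowercase
    alleles are accepted and uppercased.  An unreadable file, a missing
    mandatory column, or zero valid rows is fatal.
    """
    covered = set(column_map.values())
    missing = [f for f in MANDATORY_FIELDS if f not in covered]
    if missing:
        raise ValueError(f"column_map missing mandatory field(s): {', '.join(missing)}")

    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=delimiter, dtype=str)
    absent = [c for c in column_map if c not in df.columns]
    if absent:
        raise ValueError(f"input file lacks mapped column(s): {', '.join(absent)}")
    df = df.rename(columns=column_map)

    table = SummaryTable(trait_name=trait_name, trait_type=trait_type, sample_size=sample_size)
    dropped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            eaf = d.get("eaf")
            n = d.get("n")
            rec = VariantAssociation(
                rsid=str(d["rsid"]),
                chrom=str(d.get("chrom", "") or ""),
                pos=int(float(d["pos"])) if d.get("pos") not in (None, "") else 0,
                effect_allele=str(d["effect_allele"]).strip().upper(),
                other_allele=str(d["other_allele"]).strip().upper(),
                eaf=None if eaf in (None, "", "NA") or pd.isna(eaf) else float(eaf),
                beta=float(d["beta"]),
                se=float(d["se"]),
                pvalue=float(d["pvalue"]),
                n=None if n in (None, "", "NA") or pd.isna(n) else float(n),
            )
            rec.validate()
            table.add(rec)
        except (ValueError, TypeError) as exc:
            dropped += 1
            logger.warning("dropped row (%s): %s", d.get("rsid", "?"), exc)
    if dropped:
        logger.warning("%s: dropped %d invalid row(s), kept %d", trait_name, dropped, len(table))
    if len(table) == 0:
        raise ValueError(f"{path}: no valid rows after validation")
    return table


def _orientation(exp: VariantAssociation, out: VariantAssociation) -> tuple[str, ...] | None:
    """Classify how the outcome allele pair relates to the exposure pair.

    Returns a tuple of flags from {sign_flipped, strand_flipped}, empty
    for a direct match, or None when the pairs are irreconcilable.
    Palindromic pairs are handled separately by the caller.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    if (out.effect_allele, out.other_allele) == (ea, oa):
        return ()
    if (out.effect_allele, out.other_allele) == (oa, ea):
        return ("sign_flipped",)
    cea, coa = complement_allele(out.effect_allele), complement_allele(out.other_allele)
    if (cea, coa) == (ea, oa):
        return ("strand_flipped",)
    if (cea, coa) == (oa, ea):
        return ("strand_flipped", "sign_flipped")
    return None


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    rsids: list[str],
    palindrome_eaf_window: float = 0.08,
    drop_log: list[dict] | None = None,
) -> list[HarmonizedInstrument]:
    """Align outcome effects onto the exposure's effect allele.

    For each requested rsid present in both tables the outcome record is
    matched to the exposure allele pair directly, with swapped alleles
    (outcome beta negated, eaf flipped), or after strand complementing.
    Palindromic (A/T, C/G) variants are kept only when both tables carry
    an allele frequency, both frequencies lie outside
    0.5 +/- ``palindrome_eaf_window``, and the frequencies agree on the
    orientation; otherwise they are dropped as strand-ambiguous.

    Every drop (absent from outcome, irreconcilable alleles, ambiguous
    palindrome) is appended to ``drop_log`` with a reason code and is
    never fatal.
    """
    if not (0 <= palindrome_eaf_window < 0.5):
        raise ValueError("palindrome_eaf_window must be in [0, 0.5)")
    if drop_log is None:
        drop_log = []

    out: list[HarmonizedInstrument] = []
    for rsid in rsids:
        if rsid not in exposure:
            raise KeyError(f"instrument {rsid} absent from exposure table")
        if rsid not in outcome:
            drop_log.append({"rsid": rsid, "stage": "harmonize", "reason": "absent_from_outcome"})
            logger.info("harmonize: %s absent from outcome, dropped", rsid)
            continue
        exp, outc = exposure[rsid], outcome[rsid]

        if is_palindromic(exp.effect_allele, exp.other_allele):
            if not is_palindromic(outc.effect_allele, outc.other_allele):
                drop_log.append({"rsid": rsid, "stage": "harmonize", "reason": "irreconcilable_alleles"})
                continue
            if {outc.effect_allele, outc.other_allele} != {exp.effect_allele, exp.other_allele}:
                drop_log.append({"rsid": rsid, "stage": "harmonize", "reason": "irreconcilable_alleles"})
                continue
            keep, flip = _resolve_palindrome(exp, outc, palindrome_eaf_window)
            if not keep:
                drop_log.append({"rsid": rsid, "stage": "harmonize", "reason": "ambiguous_palindrome"})
                logger.info("harmonize: %s palindromic and ambiguous, dropped", rsid)
                continue
            flags = {"palindromic"}
            beta_y = outc.beta
            if flip:
                beta_y = -beta_y
                flags.add("sign_flipped")
            out.append(_build(exp, outc, beta_y, flags))
            continue

        orient = _orientation(exp, outc)
        if orient is None:
            drop_log.append({"rsid": rsid, "stage": "harmonize", "reason": "irreconcilable_alleles"})
            logger.info("harmonize: %s alleles irreconcilable (%s/%s vs %s/%s)", rsid,
                        exp.effect_allele, exp.other_allele, outc.effect_allele, outc.other_allele)
            continue
        beta_y = -outc.beta if "sign_flipped" in orient else outc.beta
        out.append(_build(exp, outc, beta_y, set(orient)))
    return out


def _resolve_palindrome(exp: VariantAssociation, outc: VariantAssociation,
                        window: float) -> tuple[bool, bool]:
    """Decide whether a palindromic pair is orientable from frequencies.

    Returns (keep, flip_sign).  Keep requires both eafs present and both
    outside [0.5-window, 0.5+window]; the orientation is concordant when
    the frequencies fall on the same side of 0.5 (outcome effect allele
    = exposure effect allele), discordant when on opposite sides (the
    outcome's effect allele is the exposure's other allele, so the
    outcome beta flips).
    """
    if exp.eaf is None or outc.eaf is None:
        return False, False
    lo, hi = 0.5 - window, 0.5 + window
    if lo <= exp.eaf <= hi or lo <= outc.eaf <= hi:
        return False, False
    same_side = (exp.eaf > 0.5) == (outc.eaf > 0.5)
    if outc.effect_allele == exp.effect_allele:
        return True, not same_side
    # outcome lists the complementary orientation; same frequency side
    # then implies the outcome effect allele matches after a strand flip
    return True, not same_side


def _build(exp: VariantAssociation, outc: VariantAssociation, beta_y: float,
           flags: set[str]) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        rsid=exp.rsid,
        effect_allele=exp.effect_allele,
        other_allele=exp.other_allele,
        gamma_hat=exp.beta,
        sigma_x=exp.se,
        capital_gamma_hat=beta_y,
        sigma_y=outc.se,
        flags=frozenset(flags),
        exposure_eaf=exp.eaf,
        outcome_pvalue=outc.pvalue,
    )


def instruments_to_frame(instruments: list[HarmonizedInstrument]) -> pd.DataFrame:
    """Tabulate harmonized instruments (TSV-ready, flags joined by ',')."""
    return pd.DataFrame(
        {
            "rsid": [i.rsid for i in instruments],
            "effect_allele": [i.effect_allele for i in instruments],
            "other_allele": [i.other_allele for i in instruments],
            "gamma_hat": [i.gamma_hat for i in instruments],
            "sigma_x": [i.sigma_x for i in instruments],
            "capital_gamma_hat": [i.capital_gamma_hat for i in instruments],
            "sigma_y": [i.sigma_y for i in instruments],
            "flags": [",".join(sorted(i.flags)) for i in instruments],
        }
    )
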