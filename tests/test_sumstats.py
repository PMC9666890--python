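"""Reading, validation, and allele harmonization of summary statistics."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.sumstats import (SummaryTable, complement_allele, harmonize,
                            is_palindromic, read_sumstats)

from conftest import make_variant

COLUMNS = {c: c for c in ("rsid", "chrom", "pos", "effect_allele", "other_allele",
                          "eaf", "beta", "se", "pvalue", "n")}

TSV_HEADER = "rsid\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"


def write_tsv(path, rows):
    lines = [TSV_HEADER] + [
        "\t".join(str(x) for x in row) + "\n" for row in rows]
    path.write_text("".join(lines))
    return path


GOOD_ROWS = [
    ("rs1", "1", 1000, "A", "G", 0.3, 0.05, 0.005, 1e-10, 100000),
    ("rs2", "1", 600000, "C", "T", 0.2, 0.04, 0.006, 1e-9, 100000),
    ("rs3", "2", 5000, "G", "A", 0.4, -0.03, 0.005, 1e-8, 100000),
    ("rs4", "2", 900000, "T", "C", 0.1, 0.06, 0.007, 1e-12, 100000),
    ("rs5", "3", 1000, "A", "C", 0.25, 0.02, 0.004, 1e-7, 100000),
]


class TestReadSumstats:
    def test_well_formed_file_reads_all_rows(self, tmp_path):
        p = write_tsv(tmp_path / "x.tsv", GOOD_ROWS)
        t = read_sumstats(p, COLUMNS, "ht", "binary", 218754)
        assert len(t) == 5
        assert t["rs3"].beta == -0.03

    def test_invalid_rows_dropped_not_fatal(self, tmp_path):
        rows = GOOD_ROWS[:4] + [("rs6", "3", 2000, "A", "G", 0.3, 0.05, 0.0, 1e-6, 100000)]
        t = read_sumstats(write_tsv(tmp_path / "x.tsv", rows), COLUMNS, "ht", "binary", 1)
        assert len(t) == 4 and "rs6" not in t

    def test_lowercase_alleles_uppercased(self, tmp_path):
        rows = [(r, c, p, ea.lower(), oa.lower(), *rest)
                for (r, c, p, ea, oa, *rest) in GOOD_ROWS]
        t = read_sumstats(write_tsv(tmp_path / "x.tsv", rows), COLUMNS, "ht", "binary", 1)
        assert len(t) == 5
        assert t["rs1"].effect_allele == "A" and t["rs1"].other_allele == "G"

    def test_indels_rejected(self, tmp_path):
        rows = GOOD_ROWS[:2] + [("rs7", "1", 3000, "AT", "A", 0.3, 0.02, 0.01, 0.5, 1000)]
        t = read_sumstats(write_tsv(tmp_path / "x.tsv", rows), COLUMNS, "ht", "binary", 1)
        assert len(t) == 2

    def test_missing_mandatory_column_fatal(self, tmp_path):
        cols = {k: v for k, v in COLUMNS.items() if k != "se"}
        with pytest.raises(ValueError, match="se"):
            read_sumstats(write_tsv(tmp_path / "x.tsv", GOOD_ROWS), cols, "ht", "binary", 1)

    def test_all_rows_invalid_fatal(self, tmp_path):
        rows = [("rs1", "1", 1, "A", "A", 0.3, 0.1, 0.01, 0.5, 10)]
        with pytest.raises(ValueError, match="no valid rows"):
            read_sumstats(write_tsv(tmp_path / "x.tsv", rows), COLUMNS, "ht", "binary", 1)

    def test_gzip_transparent(self, tmp_path):
        import gzip
        p = tmp_path / "x.tsv.gz"
        body = TSV_HEADER + "\t".join(str(x) for x in GOOD_ROWS[0]) + "\n"
        with gzip.open(p, "wt") as fh:
            fh.write(body)
        assert len(read_sumstats(p, COLUMNS, "ht", "binary", 1)) == 1


class TestAlleles:
    @pytest.mark.parametrize("base,comp", [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")])
    def test_complement(self, base, comp):
        assert complement_allele(base) == comp
        assert complement_allele(complement_allele(base)) == base

    def test_complement_rejects_garbage(self):
        with pytest.raises(ValueError):
            complement_allele("N")

    @pytest.mark.parametrize("ea,oa,pal", [
        ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
        ("A", "G", False), ("A", "C", False), ("G", "T", False),
    ])
    def test_palindromic(self, ea, oa, pal):
        assert is_palindromic(ea, oa) is pal


def tables_for(exp_variant, out_variant):
    exposure = SummaryTable("exp", "binary", 218754)
    exposure.add(exp_variant)
    outcome = SummaryTable("out", "quantitative", 35648)
    outcome.add(out_variant)
    return exposure, outcome


class TestHarmonize:
    # hand-written truth table for a non-palindromic exposure pair A/G, beta +0.05:
    # (outcome ea, oa) -> (harmonized outcome beta, expected flags)
    TRUTH_TABLE = [
        ("A", "G", 0.02, +0.02, set()),
        ("G", "A", -0.03, +0.03, {"sign_flipped"}),
        ("T", "C", 0.02, +0.02, {"strand_flipped"}),
        ("C", "T", 0.02, -0.02, {"strand_flipped", "sign_flipped"}),
    ]

    @pytest.mark.parametrize("ea,oa,beta_in,beta_out,flags", TRUTH_TABLE)
    def test_orientation_truth_table(self, ea, oa, beta_in, beta_out, flags):
        exp = make_variant(ea="A", oa="G", beta=0.05)
        out = make_variant(ea=ea, oa=oa, beta=beta_in, se=0.008)
        e, o = tables_for(exp, out)
        [ins] = harmonize(e, o, ["rs1"])
        assert ins.capital_gamma_hat == pytest.approx(beta_out)
        assert set(ins.flags) == flags
        assert ins.gamma_hat == 0.05 and ins.effect_allele == "A"

    def test_irreconcilable_alleles_dropped_with_log(self):
        e, o = tables_for(make_variant(ea="A", oa="G"), make_variant(ea="A", oa="C"))
        log = []
        assert harmonize(e, o, ["rs1"], drop_log=log) == []
        assert log[0]["reason"] == "irreconcilable_alleles"

    def test_absent_from_outcome_dropped_not_fatal(self):
        e, _ = tables_for(make_variant(), make_variant())
        o = SummaryTable("out", "quantitative", 1000)
        log = []
        assert harmonize(e, o, ["rs1"], drop_log=log) == []
        assert log[0]["reason"] == "absent_from_outcome"

    def test_rsid_absent_from_exposure_fatal(self):
        e, o = tables_for(make_variant(), make_variant())
        with pytest.raises(KeyError):
            harmonize(e, o, ["rs999"])

    def test_palindrome_mid_frequency_dropped(self):
        exp = make_variant(ea="A", oa="T", eaf=0.50)
        out = make_variant(ea="A", oa="T", eaf=0.50, se=0.008)
        e, o = tables_for(exp, out)
        log = []
        assert harmonize(e, o, ["rs1"], palindrome_eaf_window=0.08, drop_log=log) == []
        assert log[0]["reason"] == "ambiguous_palindrome"

    def test_palindrome_missing_eaf_dropped(self):
        exp = make_variant(ea="C", oa="G", eaf=0.2)
        out = make_variant(ea="C", oa="G", eaf=None)
        e, o = tables_for(exp, out)
        assert harmonize(e, o, ["rs1"]) == []

    @pytest.mark.parametrize("out_ea,out_oa,out_eaf,expect_sign", [
        ("A", "T", 0.2, +1),   # same allele label, same frequency side: concordant
        ("A", "T", 0.8, -1),   # same label, opposite side: strand-swapped, flip
        ("T", "A", 0.8, -1),   # swapped label, frequency confirms the swap: flip
        ("T", "A", 0.2, +1),   # swapped label but frequency says strand flip: no flip
    ])
    def test_palindrome_resolved_by_frequency(self, out_ea, out_oa, out_eaf, expect_sign):
        exp = make_variant(ea="A", oa="T", eaf=0.2, beta=0.05)
        out = make_variant(ea=out_ea, oa=out_oa, eaf=out_eaf, beta=0.02, se=0.008)
        e, o = tables_for(exp, out)
        [ins] = harmonize(e, o, ["rs1"], palindrome_eaf_window=0.08)
        assert ins.capital_gamma_hat == pytest.approx(expect_sign * 0.02)

    def test_idempotent(self):
        exp = make_variant(ea="A", oa="G", beta=0.05)
        out = make_variant(ea="G", oa="A", beta=-0.03, eaf=0.7, se=0.008)
        e, o = tables_for(exp, out)
        [first] = harmonize(e, o, ["rs1"])
        # re-express the harmonized instrument as an outcome record and re-run
        out2 = make_variant(ea=first.effect_allele, oa=first.other_allele,
                            beta=first.capital_gamma_hat, eaf=0.3, se=first.sigma_y)
        e2, o2 = tables_for(exp, out2)
        [second] = harmonize(e2, o2, ["rs1"])
        assert second.capital_gamma_hat == first.capital_gamma_hat
        assert second.gamma_hat == first.gamma_hat

    @given(beta=st.floats(-0.5, 0.5, allow_nan=False), se=st.floats(0.001, 0.1))
    @settings(max_examples=50, deadline=None)
    def test_sign_consistency(self, beta, se):
        """Negating an outcome beta AND swapping its alleles is a no-op."""
        exp = make_variant(ea="A", oa="G", beta=0.05)
        out1 = make_variant(ea="A", oa="G", beta=beta, se=se)
        out2 = make_variant(ea="G", oa="A", beta=-beta, eaf=0.7, se=se)
        i1 = harmonize(*tables_for(exp, out1), ["rs1"])[0]
        i2 = harmonize(*tables_for(exp, out2), ["rs1"])[0]
        assert i1.capital_gamma_hat == pytest.approx(i2.capital_gamma_hat)
        assert i1.gamma_hat == i2.gamma_hat

    def test_output_never_exceeds_request_and_drops_logged(self, clean_study):
        from mrkit.simulate import scramble_outcome_representation
        study = scramble_outcome_representation(clean_study, seed=3)
        log = []
        rsids = study.rsids
        instruments = harmonize(study.exposure, study.outcome, rsids, drop_log=log)
        assert len(instruments) + len(log) == len(rsids)
        assert all(entry["reason"] for entry in log)
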