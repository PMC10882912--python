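"""Summary-statistics I/O and allele harmonization."""

import dataclasses
import math

import pytest
from hypothesis import given, settings, strategies as st

from helpers import make_snp
from pwmr.errors import ConfigError, DuplicateVariantError, EmptyInputError, EmptyOverlapError
from pwmr.sumstats import (
    COMPLEMENT,
    SumstatsTable,
    format_or,
    format_p,
    harmonize,
    read_sumstats,
    write_results_table,
)

HEADER = "variant_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"


def _write(tmp_path, lines, name="sumstats.tsv"):
    path = tmp_path / name
    path.write_text(HEADER + "".join(lines))
    return path


ROW = "rs{i}\t1\t{pos}\tA\tG\t0.3\t0.1\t{se}\t0.01\t5000\n"


class TestReadSumstats:
    def test_well_formed_file_passes_through(self, tmp_path):
        path = _write(tmp_path, [ROW.format(i=i, pos=1000 + i, se=0.05) for i in range(3)])
        table = read_sumstats(path)
        assert len(table) == 3 and table.n_skipped == 0
        assert table["rs1"].beta == pytest.approx(0.1)

    def test_invariant_violations_are_skipped_and_counted(self, tmp_path):
        rows = [ROW.format(i=0, pos=1000, se=0.05), ROW.format(i=1, pos=1001, se=0.0)]
        table = read_sumstats(_write(tmp_path, rows))
        assert len(table) == 1 and table.n_skipped == 1

    def test_duplicate_variant_id_raises_with_name(self, tmp_path):
        rows = [ROW.format(i=7, pos=1000, se=0.05)] * 2
        with pytest.raises(DuplicateVariantError, match="rs7"):
            read_sumstats(_write(tmp_path, rows))

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("variant_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(ConfigError):
            read_sumstats(path)

    def test_zero_valid_rows_is_empty_input(self, tmp_path):
        path = _write(tmp_path, [ROW.format(i=0, pos=1000, se=-1)])
        with pytest.raises(EmptyInputError):
            read_sumstats(path)

    def test_column_map_and_gzip(self, tmp_path):
        import gzip

        content = HEADER.replace("beta", "effect_size") + ROW.format(i=0, pos=9, se=0.05).replace(
            "0.1", "0.25", 1
        )
        path = tmp_path / "s.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(content)
        table = read_sumstats(path, column_map={"beta": "effect_size"})
        assert table["rs0"].beta == pytest.approx(0.25)


def _tables(exp_rec, out_rec):
    e = SumstatsTable.from_records("exp", "quantitative", [exp_rec])
    o = SumstatsTable.from_records("out", "binary", [out_rec])
    return e, o


class TestHarmonize:
    @pytest.mark.parametrize(
        "out_kwargs, action, beta_out",
        [
            (dict(ea="A", oa="G", beta=0.2), "kept", 0.2),
            (dict(ea="G", oa="A", beta=0.2), "sign_flipped", -0.2),
            (dict(ea="T", oa="C", beta=0.2), "kept", 0.2),  # strand complement
            (dict(ea="C", oa="T", beta=0.2), "sign_flipped", -0.2),
            (dict(ea="A", oa="C", beta=0.2), "dropped_mismatch", None),
        ],
    )
    def test_allele_orientation_rules(self, out_kwargs, action, beta_out):
        e, o = _tables(
            make_snp(ea="A", oa="G", beta=0.1),
            make_snp(**out_kwargs),
        )
        (pair,) = harmonize(e, o)
        assert pair.action == action
        if beta_out is not None:
            assert pair.beta_out == pytest.approx(beta_out)

    def test_palindromic_uninformative_at_half(self):
        e, o = _tables(
            make_snp(ea="A", oa="T", eaf=0.50), make_snp(ea="A", oa="T", eaf=0.50)
        )
        (pair,) = harmonize(e, o)
        assert pair.action == "dropped_palindromic"

    def test_palindromic_informative_same_side_kept(self):
        e, o = _tables(
            make_snp(ea="A", oa="T", eaf=0.20), make_snp(ea="A", oa="T", eaf=0.22)
        )
        (pair,) = harmonize(e, o)
        assert pair.action == "kept"

    def test_palindromic_swapped_orientation_flips_then_compares(self):
        e, o = _tables(
            make_snp(ea="A", oa="T", eaf=0.20),
            make_snp(ea="T", oa="A", eaf=0.80, beta=0.3),
        )
        (pair,) = harmonize(e, o)
        assert pair.action == "sign_flipped"
        assert pair.beta_out == pytest.approx(-0.3)
        assert pair.eaf_out == pytest.approx(0.2)

    def test_palindromic_missing_eaf_dropped(self):
        e, o = _tables(
            make_snp(ea="C", oa="G", eaf=None), make_snp(ea="C", oa="G", eaf=0.2)
        )
        (pair,) = harmonize(e, o)
        assert pair.action == "dropped_palindromic"

    def test_no_overlap_raises(self):
        e = SumstatsTable.from_records("e", "quantitative", [make_snp(vid="rs1")])
        o = SumstatsTable.from_records("o", "binary", [make_snp(vid="rs2")])
        with pytest.raises(EmptyOverlapError):
            harmonize(e, o)

    def test_idempotence(self):
        """Harmonizing an already-harmonized outcome changes nothing."""
        e = SumstatsTable.from_records(
            "e",
            "quantitative",
            [
                make_snp(vid="rs1", ea="A", oa="G", beta=0.1),
                make_snp(vid="rs2", ea="C", oa="T", beta=-0.2, pos=2_000_000),
                make_snp(vid="rs3", ea="A", oa="T", eaf=0.15, pos=3_000_000),
            ],
        )
        o = SumstatsTable.from_records(
            "o",
            "binary",
            [
                make_snp(vid="rs1", ea="G", oa="A", beta=0.3),
                make_snp(vid="rs2", ea="C", oa="T", beta=0.1, pos=2_000_000),
                make_snp(vid="rs3", ea="A", oa="T", eaf=0.17, beta=0.2, pos=3_000_000),
            ],
        )
        first = [p for p in harmonize(e, o) if p.kept]
        # rebuild the outcome in the exposure's orientation from the result
        rebuilt = SumstatsTable.from_records(
            "o2",
            "binary",
            [
                dataclasses.replace(
                    e[p.variant_id], beta=p.beta_out, eaf=p.eaf_out, se=p.se_out
                )
                for p in first
            ],
        )
        second = harmonize(e, rebuilt)
        assert all(p.action == "kept" for p in second)
        assert [p.beta_out for p in second] == pytest.approx([p.beta_out for p in first])

    @settings(max_examples=50, deadline=None)
    @given(
        beta=st.floats(-1, 1, allow_nan=False),
        eaf=st.floats(0.01, 0.99),
        ea=st.sampled_from(["A", "C", "G", "T"]),
        oa=st.sampled_from(["A", "C", "G", "T"]),
    )
    def test_sign_flip_involution(self, beta, eaf, ea, oa):
        """Re-encoding every outcome record on the opposite allele leaves the
        harmonized effect unchanged."""
        if ea == oa:
            return
        e, o = _tables(
            make_snp(ea="A", oa="G", beta=0.1, eaf=0.3),
            make_snp(ea=ea, oa=oa, beta=beta, eaf=eaf),
        )
        swapped = SumstatsTable.from_records(
            "o_swapped",
            "binary",
            [make_snp(ea=oa, oa=ea, beta=-beta, eaf=1 - eaf)],
        )
        p1 = harmonize(e, o)[0]
        p2 = harmonize(e, swapped)[0]
        assert p1.kept == p2.kept
        if p1.kept:
            assert p1.beta_out == pytest.approx(p2.beta_out)


class TestResultsTable:
    def test_formatting_rules(self, tmp_path):
        path = tmp_path / "out.tsv"
        write_results_table(
            [{"protein": "PCSK9", "or": 1.2734, "pvalue": 0.000141}], path
        )
        body = path.read_text().splitlines()[1].split("\t")
        assert body[1] == "1.273"
        assert body[2] == "1.41E-04"

    def test_zero_rows_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_results_table([], path, or_columns=("or",), p_columns=("pvalue",))
        assert path.read_text() == "or\tpvalue\n"

    def test_roundtrip_to_printed_precision(self, tmp_path):
        import pandas as pd

        path = tmp_path / "rt.tsv"
        rows = [{"id": "a", "or": 1.27344, "pvalue": 8.184e-8}]
        write_results_table(rows, path)
        back = pd.read_csv(path, sep="\t")
        assert back.loc[0, "or"] == pytest.approx(1.273, abs=5e-4)
        assert back.loc[0, "pvalue"] == pytest.approx(8.18e-8, rel=5e-3)

    def test_formatters(self):
        assert format_or(1.2734) == "1.273"
        assert format_p(0.000141) == "1.41E-04"
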