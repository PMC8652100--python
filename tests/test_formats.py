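"""Dialect sniffing, delimited/VCF parsing, and output round trips."""

import gzip
import math

import numpy as np
import pandas as pd
import pysam
import pytest

import gwasmunge as gm
from gwasmunge.errors import CheckError, FormatError


def _write(path, data: bytes, comp: str):
    if comp == "none":
        path.write_bytes(data)
    elif comp == "gz":
        with gzip.open(path, "wb") as fh:
            fh.write(data)
    else:
        with pysam.BGZFile(str(path), "wb") as fh:
            fh.write(data)


HEADERS = ["SNP", "CHR", "BP", "A1", "A2", "P"]
ROWS = [["rs1", "1", "100", "A", "G", "0.5"], ["rs2", "2", "200", "C", "T", "0.01"]]


def _payload(sep):
    lines = [sep.join(HEADERS)] + [sep.join(r) for r in ROWS]
    return ("\n".join(lines) + "\n").encode()


class TestSniff:
    def test_vcf_marker_wins(self):
        desc = gm.sniff_format(b"##fileformat=VCFv4.2\n", "##fileformat=VCFv4.2\n#CHROM\tPOS\n")
        assert desc.container == "vcf" and desc.delimiter is None

    def test_comma_delimited(self):
        text = "SNP,CHR,BP,P\nrs1,1,100,0.5\n"
        desc = gm.sniff_format(text.encode(), text)
        assert (desc.container, desc.delimiter) == ("delimited", "comma")

    def test_tab_preferred_over_space(self):
        text = "SNP\tCHR\tBP\nrs1\t1\t100\n"
        desc = gm.sniff_format(text.encode(), text)
        assert desc.delimiter == "tab"

    def test_bgzip_detected_from_bc_subfield(self, tmp_path):
        p = tmp_path / "x.tsv.bgz"
        _write(p, _payload("\t"), "bgz")
        assert gm.sniff_path(p).compression == "bgzip"

    def test_plain_gzip_not_bgzip(self, tmp_path):
        p = tmp_path / "x.tsv.gz"
        _write(p, _payload("\t"), "gz")
        assert gm.sniff_path(p).compression == "gzip"

    def test_undecidable_delimiter_names_candidates(self):
        with pytest.raises(FormatError, match="tab.*comma.*space|delimiter"):
            gm.sniff_format(b"onecolumn\n", "onecolumn\nvalue\n")


@pytest.mark.parametrize("ext,sep", [("tsv", "\t"), ("txt", " "), ("csv", ",")])
@pytest.mark.parametrize("comp", ["none", "gz", "bgz"])
def test_all_delimited_extension_combinations_parse(tmp_path, ext, sep, comp):
    suffix = f".{ext}" + ("" if comp == "none" else f".{comp}")
    p = tmp_path / ("s" + suffix)
    _write(p, _payload(sep), comp)
    rt = gm.read_sumstats(p)
    assert rt.headers == HEADERS
    assert rt.rows == ROWS


class TestReadDelimited:
    def test_compression_transparency(self, tmp_path):
        plain, gz = tmp_path / "a.csv", tmp_path / "a.csv.gz"
        _write(plain, _payload(","), "none")
        _write(gz, _payload(","), "gz")
        a, b = gm.read_sumstats(plain), gm.read_sumstats(gz)
        assert a.headers == b.headers and a.rows == b.rows

    def test_ragged_row_error_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("SNP\tP\nrs1\t0.5\nrs2\t0.1\textra\n")
        with pytest.raises(FormatError, match="line.*4|4.*line|ragged"):
            gm.read_sumstats(p)

    def test_comment_lines_before_header_skipped(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("## produced by some tool\nSNP\tP\nrs1\t0.5\n")
        rt = gm.read_sumstats(p)
        assert rt.headers == ["SNP", "P"] and len(rt.rows) == 1

    def test_space_delimited_handles_runs(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("SNP  CHR   BP\nrs1   1  100\n")
        rt = gm.read_sumstats(p)
        assert rt.rows == [["rs1", "1", "100"]]


def _toy_vcf(tmp_path, samples=("TRAIT",), lp=7.0):
    header = pysam.VariantHeader()
    header.contigs.add("1")
    header.formats.add("ES", 1, "Float", "effect size")
    header.formats.add("SE", 1, "Float", "standard error")
    header.formats.add("LP", 1, "Float", "-log10 p")
    for s in samples:
        header.add_sample(s)
    path = str(tmp_path / "t.vcf")
    with pysam.VariantFile(path, "w", header=header) as vf:
        rec = vf.new_record(contig="1", start=99, stop=100, alleles=("A", "G"), id="rs1")
        for s in samples:
            rec.samples[s]["ES"] = 0.1
            rec.samples[s]["SE"] = 0.02
            rec.samples[s]["LP"] = lp
        vf.write(rec)
    return path


class TestReadGwasVcf:
    def test_field_mapping_and_lp_to_p(self, tmp_path):
        rt = gm.read_gwas_vcf(_toy_vcf(tmp_path))
        df = rt.to_frame()
        row = df.iloc[0]
        # REF is the non-effect allele A1, ALT the effect allele A2
        assert (row["SNP"], row["CHR"], row["BP"]) == ("rs1", "1", "100")
        assert (row["A1"], row["A2"]) == ("A", "G")
        assert float(row["BETA"]) == pytest.approx(0.1, rel=1e-6)
        assert float(row["P"]) == pytest.approx(1e-7, rel=1e-6)

    def test_multi_sample_requires_selection(self, tmp_path):
        path = _toy_vcf(tmp_path, samples=("height", "bmi"))
        with pytest.raises(FormatError, match="height.*bmi|bmi.*height"):
            gm.read_gwas_vcf(path)
        rt = gm.read_gwas_vcf(path, sample="bmi")
        assert len(rt.rows) == 1

    def test_underflow_lp_keeps_textual_p(self, tmp_path):
        rt = gm.read_gwas_vcf(_toy_vcf(tmp_path, lp=350.0))
        p = rt.to_frame().iloc[0]["P"]
        assert float(p) == 0.0 and "350" in p


class TestWriteOutput:
    def test_tabular_round_trip(self, tmp_path, clean_table, backend):
        out = tmp_path / "out.tsv.gz"
        gm.write_output(clean_table, out, format="tabular")
        rerun, report = gm.run_pipeline(gm.read_sumstats(out), gm.QCConfig(), backend)
        assert report.total_dropped == 0 and report.total_imputed == 0
        assert list(rerun["SNP"]) == list(clean_table["SNP"])
        for col in ("BETA", "SE", "P", "FRQ"):
            assert np.allclose(rerun[col].astype(float), clean_table[col].astype(float))

    def test_vcf_round_trip(self, tmp_path, clean_table):
        out = tmp_path / "out.vcf.gz"
        gm.write_output(clean_table, out, format="vcf")
        df = gm.read_gwas_vcf(out).to_frame()
        assert list(df["SNP"]) == list(clean_table["SNP"].astype(str))
        assert list(df["A1"]) == list(clean_table["A1"])
        assert list(df["A2"]) == list(clean_table["A2"])
        assert np.allclose(
            pd.to_numeric(df["BETA"]), clean_table["BETA"].astype(float), rtol=1e-5
        )
        # LP is serialized with ~6 significant digits, so P carries ~1e-5 rel err
        assert np.allclose(
            pd.to_numeric(df["P"]), clean_table["P"].astype(float), rtol=1e-4
        )

    def test_ldsc_columns_and_z_from_beta_se(self, tmp_path, clean_table):
        out = tmp_path / "out.ldsc.gz"
        gm.write_output(clean_table, out, format="ldsc")
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == ["SNP", "A1", "A2", "Z", "N"]
        assert np.allclose(df["Z"], clean_table["BETA"] / clean_table["SE"])

    def test_ldsc_z_from_p_when_no_se(self, tmp_path, clean_table):
        from scipy.stats import norm

        t = clean_table.drop(columns=["SE"])
        out = tmp_path / "o.gz"
        gm.write_output(t, out, format="ldsc")
        df = pd.read_csv(out, sep="\t")
        expect = np.sign(t["BETA"]) * np.abs(norm.ppf(t["P"] / 2))
        assert np.allclose(df["Z"], expect)

    def test_ldsc_requires_n_and_signed(self, tmp_path, clean_table):
        with pytest.raises(CheckError, match="N"):
            gm.write_output(clean_table.drop(columns=["N"]), tmp_path / "x", format="ldsc")
        bare = clean_table.drop(columns=["BETA", "SE"])
        with pytest.raises(CheckError, match="signed"):
            gm.write_output(bare, tmp_path / "y", format="ldsc")
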