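"""Reference-dependent harmonization: imputation, on-reference, flipping."""

import numpy as np
import pandas as pd
import pytest

import gwasmunge as gm
from gwasmunge import harmonize
from gwasmunge.reference import ReferenceBackend, ReferenceVariant


@pytest.fixture(scope="module")
def mini_backend():
    return ReferenceBackend(
        [
            ReferenceVariant("rs1", "1", 1000, "C", ("T",)),
            ReferenceVariant("rs2", "2", 2000, "A", ("G",)),
            ReferenceVariant("rs3", "3", 3000, "G", ("T", "A")),   # multiallelic
            # positional collision pair on 4:4000
            ReferenceVariant("rs4", "4", 4000, "A", ("C",)),
            ReferenceVariant("rs5", "4", 4000, "G", ("T",)),
        ]
    )


class TestImputeChrBp:
    def test_missing_bp_filled(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs1"], CHR=["1"], BP=[""])
        out, cells = harmonize.impute_chr_bp(df, mini_backend)
        assert out.iloc[0]["BP"] == 1000
        assert cells == [("rs1", "BP", 1000)]

    def test_present_row_untouched(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs1"], CHR=["1"], BP=["999"])
        out, cells = harmonize.impute_chr_bp(df, mini_backend)
        assert out.iloc[0]["BP"] == "999" and cells == []

    def test_unknown_rsid_stays_missing(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs99"], CHR=[""], BP=[""])
        out, cells = harmonize.impute_chr_bp(df, mini_backend)
        assert cells == [] and str(out.iloc[0]["CHR"]).strip() in ("", "nan", "<NA>")


class TestImputeRsid:
    def test_unique_locus_filled(self, mini_backend, make_frame):
        df = make_frame(SNP=[""], CHR=["2"], BP=["2000"])
        out, cells = harmonize.impute_rsid(df, mini_backend)
        assert out.iloc[0]["SNP"] == "rs2" and len(cells) == 1

    def test_colliding_locus_resolved_by_alleles(self, mini_backend, make_frame):
        df = make_frame(SNP=[""], CHR=["4"], BP=["4000"], A1=["G"], A2=["T"])
        out, _ = harmonize.impute_rsid(df, mini_backend)
        assert out.iloc[0]["SNP"] == "rs5"

    def test_colliding_locus_without_alleles_left_missing(self, mini_backend, make_frame):
        df = make_frame(SNP=[""], CHR=["4"], BP=["4000"])
        out, cells = harmonize.impute_rsid(df, mini_backend)
        assert out.iloc[0]["SNP"] == "" and cells == []

    def test_uncatalogued_locus_left_missing(self, mini_backend, make_frame):
        df = make_frame(SNP=[""], CHR=["9"], BP=["123"])
        out, cells = harmonize.impute_rsid(df, mini_backend)
        assert out.iloc[0]["SNP"] == "" and cells == []


class TestImputeAlleles:
    def test_missing_a1_gets_ref(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs1"], A1=[""], A2=["T"])
        out, cells = harmonize.impute_alleles(df, mini_backend)
        assert out.iloc[0]["A1"] == "C" and ("rs1", "A1", "C") in cells

    def test_missing_a2_biallelic_gets_alt(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs2"], A1=["A"], A2=[""])
        out, _ = harmonize.impute_alleles(df, mini_backend)
        assert out.iloc[0]["A2"] == "G"

    def test_missing_a2_multiallelic_left_missing(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs3"], A1=["G"], A2=[""])
        out, cells = harmonize.impute_alleles(df, mini_backend)
        assert str(out.iloc[0]["A2"]).strip() in ("", "nan", "<NA>")
        assert cells == []


class TestValidateRsids:
    @pytest.mark.parametrize(
        "snp,valid", [("rs123", True), ("ss123", False), ("rs12a", False)]
    )
    def test_regex_and_retention(self, snp, valid, make_frame):
        df, flagged = harmonize.validate_rsids(make_frame(SNP=[snp]))
        assert len(df) == 1  # flagged rows are retained
        assert bool(df.iloc[0]["_rsid_valid"]) is valid
        assert flagged == (0 if valid else 1)


class TestOnReference:
    def test_stale_rsid_corrected_positionally(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs888"], CHR=["1"], BP=["1000"], A1=["C"], A2=["T"])
        kept, dropped, _, corrected = harmonize.check_on_reference(df, mini_backend)
        assert corrected == 1 and kept.iloc[0]["SNP"] == "rs1" and len(dropped) == 0

    def test_absent_everywhere_dropped(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs888"], CHR=["9"], BP=["1"], A1=["C"], A2=["T"])
        kept, dropped, reasons, _ = harmonize.check_on_reference(df, mini_backend)
        assert len(kept) == 0 and len(dropped) == 1 and "reference" in reasons[0]

    def test_valid_row_untouched(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs2"], CHR=["2"], BP=["2000"], A1=["A"], A2=["G"])
        kept, dropped, _, corrected = harmonize.check_on_reference(df, mini_backend)
        assert len(kept) == 1 and corrected == 0


class TestStrandAmbiguous:
    @pytest.mark.parametrize(
        "a1,a2,removed",
        [("A", "T", True), ("G", "C", True), ("A", "G", False), ("T", "G", False)],
    )
    def test_palindromic_pairs(self, a1, a2, removed, make_frame):
        df = make_frame(SNP=["rs1"], A1=[a1], A2=[a2])
        kept, dropped = harmonize.remove_strand_ambiguous(df)
        assert (len(dropped) == 1) is removed


class TestNonBiallelic:
    def test_multiallelic_site_removed(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs3", "rs2"], A1=["G", "A"], A2=["T", "G"])
        kept, dropped = harmonize.remove_nonbiallelic(df, mini_backend)
        assert list(kept["SNP"]) == ["rs2"] and list(dropped["SNP"]) == ["rs3"]

    def test_uncatalogued_row_kept(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs77"], A1=["A"], A2=["G"])
        kept, dropped = harmonize.remove_nonbiallelic(df, mini_backend)
        assert len(kept) == 1 and len(dropped) == 0


class TestFlipAlleles:
    def test_a1_matches_ref_kept(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs2"], A1=["A"], A2=["G"], BETA=[0.2])
        kept, dropped, _, recs = harmonize.flip_alleles(df, mini_backend)
        assert recs[0].action == "kept" and float(kept.iloc[0]["BETA"]) == 0.2

    def test_flip_transforms_all_effect_columns(self, mini_backend, make_frame):
        df = make_frame(
            SNP=["rs2"], A1=["G"], A2=["A"], BETA=[0.2], FRQ=[0.3], OR=[2.0],
            Z=[1.5], SE=[0.1], P=[0.05],
        )
        kept, _, _, recs = harmonize.flip_alleles(df, mini_backend)
        row = kept.iloc[0]
        assert recs[0].action == "flipped"
        assert (row["A1"], row["A2"]) == ("A", "G")
        assert float(row["BETA"]) == -0.2
        assert float(row["FRQ"]) == pytest.approx(0.7)
        assert float(row["OR"]) == pytest.approx(0.5)
        assert float(row["Z"]) == -1.5
        assert float(row["SE"]) == 0.1 and float(row["P"]) == 0.05  # untouched

    def test_neither_orientation_dropped(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs2"], A1=["C"], A2=["T"], BETA=[0.2])
        kept, dropped, reasons, recs = harmonize.flip_alleles(df, mini_backend)
        assert len(kept) == 0 and recs[0].action == "dropped_no_match"
        assert "neither orientation" in reasons[0]

    def test_or_zero_on_flip_dropped_distinctly(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs2"], A1=["G"], A2=["A"], OR=[0.0])
        kept, dropped, reasons, recs = harmonize.flip_alleles(df, mini_backend)
        assert recs[0].action == "dropped_or_zero" and "OR=0" in reasons[0]

    def test_uncatalogued_passes_through(self, mini_backend, make_frame):
        df = make_frame(SNP=["rs77"], A1=["T"], A2=["G"], BETA=[0.1])
        kept, dropped, _, recs = harmonize.flip_alleles(df, mini_backend)
        assert len(kept) == 1 and recs[0].action == "kept"

    def test_one_record_per_row(self, mini_backend, make_frame):
        df = make_frame(
            SNP=["rs1", "rs2", "rs77"], A1=["C", "G", "T"],
            A2=["T", "A", "G"], BETA=[0.1, 0.2, 0.3],
        )
        _, _, _, recs = harmonize.flip_alleles(df, mini_backend)
        assert len(recs) == 3


class TestFlipProperties:
    def test_involution_restores_ground_truth(self, backend):
        spec = gm.CorruptionSpec(flipped=15)
        raw, truth = gm.make_sumstats_fixture(backend, seed=41, n_rows=60, corruption=spec)
        table, report = gm.run_pipeline(raw, gm.QCConfig(), backend)
        out = table.set_index("SNP")
        for rsid in truth.rows["flipped"]:
            orig = truth.originals[rsid]
            row = out.loc[rsid]
            assert (row["A1"], row["A2"]) == (orig["A1"], orig["A2"])
            assert float(row["BETA"]) == pytest.approx(float(orig["BETA"]), abs=1e-12)
            assert float(row["FRQ"]) == pytest.approx(float(orig["FRQ"]), abs=1e-12)

    def test_post_flip_a1_equals_catalogue_ref(self, backend):
        spec = gm.CorruptionSpec(flipped=15)
        raw, _ = gm.make_sumstats_fixture(backend, seed=42, n_rows=60, corruption=spec)
        table, _ = gm.run_pipeline(raw, gm.QCConfig(), backend)
        refs = backend.query_by_rsid(table["SNP"])
        assert all(table.iloc[i]["A1"] == refs[table.iloc[i]["SNP"]].ref
                   for i in range(len(table)))

    def test_idempotent_second_pass_flips_nothing(self, backend):
        spec = gm.CorruptionSpec(flipped=15)
        raw, _ = gm.make_sumstats_fixture(backend, seed=43, n_rows=60, corruption=spec)
        table, _ = gm.run_pipeline(raw, gm.QCConfig(), backend)
        again, dropped, _, recs = harmonize.flip_alleles(table.copy(), backend)
        assert all(r.action == "kept" for r in recs) and len(dropped) == 0
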