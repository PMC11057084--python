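"""Reading, validation, and allele harmonization of summary statistics."""

import numpy as np
import pandas as pd
import pytest

from summr.errors import SchemaError, ValidationError
from summr.gwas_io import (
    DROPPED_MISSING,
    DROPPED_PALINDROMIC,
    FLIPPED,
    KEPT,
    LDMatrix,
    harmonize_pair,
    read_association_table,
    read_ld_matrix,
    write_association_table,
    write_ld_matrix,
)

from conftest import make_table


class TestReadWrite:
    def test_round_trip_preserves_values(self, tmp_path, simple_table):
        path = tmp_path / "t.tsv"
        write_association_table(simple_table, path, seed=3)
        back = read_association_table(path, "trait", "quantitative")
        pd.testing.assert_frame_equal(back.data, simple_table.data, rtol=1e-12)

    def test_gzip_transparent(self, tmp_path, simple_table):
        path = tmp_path / "t.tsv.gz"
        simple_table.data.to_csv(path, sep="\t", index=False, compression="gzip")
        back = read_association_table(path, "trait", "quantitative")
        assert len(back) == 3

    def test_column_map(self, tmp_path, simple_table):
        path = tmp_path / "t.tsv"
        simple_table.data.rename(columns={"variant_id": "SNP", "pval": "P"}).to_csv(
            path, sep="\t", index=False
        )
        back = read_association_table(
            path, "trait", "quantitative", column_map={"SNP": "variant_id", "P": "pval"}
        )
        assert list(back.data["variant_id"]) == ["rs1", "rs2", "rs3"]

    def test_missing_column_names_it(self, tmp_path, simple_table):
        path = tmp_path / "t.tsv"
        simple_table.data.drop(columns=["eaf"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="eaf"):
            read_association_table(path, "trait", "quantitative")

    def test_se_zero_cites_row(self):
        with pytest.raises(ValidationError, match=r"se <= 0 at row\(s\) 2"):
            make_table(se=(0.05, 0.0, 0.05))

    def test_duplicate_variant_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            make_table(variant_id=("rs1", "rs1", "rs3"))

    def test_eaf_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="eaf"):
            make_table(eaf=(0.3, 1.0, 0.3))

    def test_header_only_empty_table_ok(self, tmp_path, simple_table):
        path = tmp_path / "t.tsv"
        simple_table.data.iloc[:0].to_csv(path, sep="\t", index=False)
        back = read_association_table(path, "trait", "quantitative")
        assert len(back) == 0


class TestLDMatrix:
    def test_round_trip(self, tmp_path):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = LDMatrix(["rs1", "rs2"], r)
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path, seed=1)
        back = read_ld_matrix(path)
        assert back.variant_ids == ["rs1", "rs2"]
        np.testing.assert_allclose(back.r, r, rtol=1e-12)

    def test_r2_and_missing(self):
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, -0.6], [-0.6, 1.0]]))
        assert ld.r2("rs1", "rs2") == pytest.approx(0.36)
        assert ld.r2("rs1", "rs9") is None

    def test_rejects_asymmetric(self):
        with pytest.raises(ValidationError, match="symmetric"):
            LDMatrix(["a", "b"], np.array([[1.0, 0.2], [0.5, 1.0]]))

    def test_rejects_non_psd(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValidationError, match="PSD"):
            LDMatrix(["a", "b", "c"], bad)


def _two_tables(out_effect="A", out_other="G", out_beta=0.2, out_eaf=0.3,
                exp_effect="A", exp_other="G", exp_eaf=0.3):
    exposure = make_table(
        trait_name="exp", variant_id=("rs1",), pos=(1000,),
        effect_allele=(exp_effect,), other_allele=(exp_other,), eaf=(exp_eaf,),
        beta=(0.1,), se=(0.02,), pval=(1e-7,),
    )
    outcome = make_table(
        trait_name="out", trait_type="binary", variant_id=("rs1",), pos=(1000,),
        effect_allele=(out_effect,), other_allele=(out_other,), eaf=(out_eaf,),
        beta=(out_beta,), se=(0.05,), pval=(1e-4,),
    )
    return exposure, outcome


class TestHarmonize:
    def test_identity_orientation_kept(self):
        exposure, outcome = _two_tables()
        pair = harmonize_pair(exposure, outcome, ["rs1"])
        assert pair.log["rs1"] == KEPT
        assert pair.data["Gamma"].iloc[0] == pytest.approx(0.2)

    def test_swapped_alleles_flip_sign(self):
        exposure, outcome = _two_tables(out_effect="G", out_other="A", out_eaf=0.7)
        pair = harmonize_pair(exposure, outcome, ["rs1"])
        assert pair.log["rs1"] == FLIPPED
        assert pair.data["Gamma"].iloc[0] == pytest.approx(-0.2)

    def test_strand_flip_reconciled(self):
        # outcome coded on the other strand: A/G -> T/C
        exposure, outcome = _two_tables(out_effect="T", out_other="C")
        pair = harmonize_pair(exposure, outcome, ["rs1"])
        assert pair.log["rs1"] == KEPT
        assert pair.data["Gamma"].iloc[0] == pytest.approx(0.2)

    def test_palindromic_band_midpoint_dropped(self):
        exposure, outcome = _two_tables(
            exp_effect="A", exp_other="T", out_effect="A", out_other="T", out_eaf=0.50,
            exp_eaf=0.3,
        )
        pair = harmonize_pair(exposure, outcome, ["rs1"])
        assert pair.log["rs1"] == DROPPED_PALINDROMIC
        assert len(pair) == 0

    def test_palindromic_outside_band_eaf_inferred(self):
        # both minor on the same side: keep; opposite sides: flip
        exposure, outcome = _two_tables(
            exp_effect="A", exp_other="T", out_effect="A", out_other="T",
            exp_eaf=0.2, out_eaf=0.25,
        )
        assert harmonize_pair(exposure, outcome, ["rs1"]).log["rs1"] == KEPT
        exposure, outcome = _two_tables(
            exp_effect="A", exp_other="T", out_effect="A", out_other="T",
            exp_eaf=0.2, out_eaf=0.75,
        )
        pair = harmonize_pair(exposure, outcome, ["rs1"])
        assert pair.log["rs1"] == FLIPPED
        assert pair.data["Gamma"].iloc[0] == pytest.approx(-0.2)

    def test_missing_instrument_logged(self):
        exposure, _ = _two_tables()
        outcome = make_table(
            trait_name="out", trait_type="binary", variant_id=("rs9",), pos=(99,),
            effect_allele=("A",), other_allele=("G",), eaf=(0.3,),
            beta=(0.1,), se=(0.05,), pval=(0.5,),
        )
        pair = harmonize_pair(exposure, outcome, ["rs1"])
        assert pair.log["rs1"] == DROPPED_MISSING

    def test_irreconcilable_dropped_not_error(self):
        exposure, outcome = _two_tables(out_effect="A", out_other="C")
        pair = harmonize_pair(exposure, outcome, ["rs1"])
        assert pair.log["rs1"] == "dropped-irreconcilable"

    def test_idempotence(self):
        """Harmonizing an already-aligned orientation changes nothing."""
        exposure, outcome = _two_tables()
        first = harmonize_pair(exposure, outcome, ["rs1"])
        again = harmonize_pair(exposure, outcome, ["rs1"])
        pd.testing.assert_frame_equal(first.data, again.data)

    def test_double_flip_symmetry(self):
        """Swapping outcome alleles + negating beta + complementing EAF is a no-op."""
        rng = np.random.default_rng(5)
        k = 12
        alleles = [("A", "G"), ("T", "C"), ("C", "A"), ("A", "T")] * 3
        exposure = make_table(
            trait_name="exp",
            variant_id=[f"rs{i}" for i in range(k)],
            pos=list(range(1000, 1000 + k)),
            effect_allele=[a for a, _ in alleles],
            other_allele=[b for _, b in alleles],
            eaf=list(rng.uniform(0.05, 0.40, k)),
            beta=list(rng.normal(0, 0.05, k)),
            se=[0.01] * k,
            pval=[1e-8] * k,
        )
        out_df = exposure.data.copy()
        out_df["beta"] = rng.normal(0, 0.05, k)
        outcome = make_table(
            trait_name="out", trait_type="binary",
            variant_id=list(out_df["variant_id"]), pos=list(out_df["pos"]),
            effect_allele=list(out_df["effect_allele"]),
            other_allele=list(out_df["other_allele"]),
            eaf=list(out_df["eaf"]), beta=list(out_df["beta"]),
            se=[0.02] * k, pval=[0.01] * k,
        )
        flipped = outcome.data.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        from summr.gwas_io import AssociationTable

        outcome_flipped = AssociationTable("out", "binary", flipped)
        ids = list(exposure.data["variant_id"])
        a = harmonize_pair(exposure, outcome, ids)
        b = harmonize_pair(exposure, outcome_flipped, ids)
        pd.testing.assert_frame_equal(a.data, b.data)
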