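"""Summary-statistics I/O and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from protmr.sumstats import (harmonize, read_sumstats, write_sumstats,
                             validate_sumstats, read_gene_annotations,
                             write_gene_annotations, GeneAnnotation)

from conftest import make_sumstats


class TestReadWrite:
    def test_round_trip_is_identity(self, tmp_path):
        df = make_sumstats(["rs1", "rs2", "rs3"], beta=[0.1, -0.25, 0.0313],
                           se=[0.01, 0.2, 0.031], pval=[1e-8, 0.5, 0.03])
        path = tmp_path / "s.tsv"
        write_sumstats(df, path)
        back = read_sumstats(path)
        pd.testing.assert_frame_equal(back, df)
        assert back.attrs["n_dropped"] == 0

    def test_gzip_round_trip(self, tmp_path):
        df = make_sumstats(["rs1", "rs2"])
        path = tmp_path / "s.tsv.gz"
        write_sumstats(df, path)
        pd.testing.assert_frame_equal(read_sumstats(path), df)

    def test_invalid_rows_dropped_and_counted(self):
        df = make_sumstats(["rs1", "rs2", "rs3", "rs4", "rs5"],
                           se=[0.05, 0.0, 0.05, 0.05, 0.05],
                           pval=[0.5, 0.5, 1.5, 0.5, 0.5],
                           other_allele=["G", "G", "G", "A", "G"],
                           eaf=[0.3, 0.3, 0.3, 0.3, 1.2])
        clean = validate_sumstats(df)
        assert list(clean["variant_id"]) == ["rs1"]
        assert clean.attrs["n_dropped"] == 4
        assert clean.attrs["drop_reasons"]["nonpositive_se"] == 1
        assert clean.attrs["drop_reasons"]["identical_alleles"] == 1

    def test_unparseable_numeric_rejects_row_only(self):
        df = make_sumstats(["rs1", "rs2"]).astype({"beta": object})
        df.loc[1, "beta"] = "not-a-number"
        clean = validate_sumstats(df)
        assert list(clean["variant_id"]) == ["rs1"]

    def test_missing_mandatory_column_raises(self, tmp_path):
        df = make_sumstats(["rs1"]).drop(columns=["se"])
        path = tmp_path / "s.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(KeyError, match="se"):
            read_sumstats(path)

    def test_dialect_mapping(self, tmp_path):
        df = make_sumstats(["rs1", "rs2"])
        renamed = df.rename(columns={
            "variant_id": "rsids", "chrom": "#chrom",
            "effect_allele": "alt", "other_allele": "ref",
            "eaf": "af_alt", "se": "sebeta"})
        path = tmp_path / "fg.tsv"
        renamed.to_csv(path, sep="\t", index=False)
        back = read_sumstats(path, "finngen-like")
        assert list(back["variant_id"]) == ["rs1", "rs2"]
        np.testing.assert_allclose(back["se"], df["se"])

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_sumstats(tmp_path / "x.tsv", "nope")


def test_gene_annotation_round_trip(tmp_path):
    genes = {"P1": GeneAnnotation("G1", "P1", "2", 100, 200, "+")}
    write_gene_annotations(genes, tmp_path / "g.tsv")
    back = read_gene_annotations(tmp_path / "g.tsv")
    assert back["P1"] == genes["P1"]
    with pytest.raises(ValueError):
        GeneAnnotation("G1", "P1", "2", 300, 200)


class TestHarmonize:
    def test_matching_alleles_pass_through(self):
        exp = make_sumstats(["rs1"], beta=0.5)
        out = make_sumstats(["rs1"], beta=0.1)
        pairs = harmonize(exp, out)
        assert pairs.loc[0, "beta_out"] == 0.1
        assert not pairs.loc[0, "flipped"]

    def test_swapped_alleles_negate_outcome(self):
        exp = make_sumstats(["rs1"], effect_allele="A", other_allele="G",
                            beta=0.5)
        out = make_sumstats(["rs1"], effect_allele="G", other_allele="A",
                            beta=0.1, eaf=0.7)
        pairs = harmonize(exp, out)
        assert pairs.loc[0, "beta_out"] == -0.1
        assert pairs.loc[0, "flipped"]
        assert pairs.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_palindromic_dropped_by_default(self):
        exp = make_sumstats(["rs1", "rs2"],
                            effect_allele=["A", "A"],
                            other_allele=["T", "G"])
        out = make_sumstats(["rs1", "rs2"],
                            effect_allele=["A", "A"],
                            other_allele=["T", "G"])
        pairs = harmonize(exp, out, "drop")
        assert list(pairs["variant_id"]) == ["rs2"]

    @pytest.mark.parametrize("eaf_exp,eaf_out,kept,negated", [
        (0.1, 0.12, True, False),     # concordant rare allele
        (0.1, 0.9, True, True),       # discordant: strand flip implied
        (0.1, 0.5, False, False),     # outcome eaf ambiguous -> drop
        (0.45, 0.45, False, False),   # both ambiguous -> drop
    ])
    def test_palindromic_eaf_policy(self, eaf_exp, eaf_out, kept, negated):
        exp = make_sumstats(["rs1"], effect_allele="A", other_allele="T",
                            eaf=eaf_exp, beta=0.5)
        out = make_sumstats(["rs1"], effect_allele="A", other_allele="T",
                            eaf=eaf_out, beta=0.2)
        pairs = harmonize(exp, out, "keep_if_eaf_informative")
        assert (len(pairs) == 1) is kept
        if kept:
            expected = -0.2 if negated else 0.2
            assert pairs.loc[0, "beta_out"] == pytest.approx(expected)

    def test_irreconcilable_alleles_excluded(self):
        exp = make_sumstats(["rs1"], effect_allele="A", other_allele="G")
        out = make_sumstats(["rs1"], effect_allele="A", other_allele="C")
        assert harmonize(exp, out).empty

    def test_empty_intersection_warns_not_raises(self, caplog):
        exp = make_sumstats(["rs1"])
        out = make_sumstats(["rs2"])
        with caplog.at_level("WARNING"):
            pairs = harmonize(exp, out)
        assert pairs.empty
        assert any("no shared" in r.message for r in caplog.records)

    def test_idempotent_and_magnitude_preserving(self, rng):
        k = 40
        exp = make_sumstats([f"rs{i}" for i in range(k)],
                            beta=rng.normal(size=k),
                            effect_allele="A", other_allele="G")
        out = exp.copy()
        swap = rng.random(k) < 0.5
        out.loc[swap, ["effect_allele", "other_allele"]] = ["G", "A"]
        out.loc[swap, "beta"] = -out.loc[swap, "beta"]
        out.loc[swap, "eaf"] = 1 - out.loc[swap, "eaf"]
        pairs = harmonize(exp, out)
        # sign-reconciled: aligned outcome betas equal the exposure's
        np.testing.assert_allclose(pairs["beta_out"], exp["beta"])
        np.testing.assert_allclose(np.abs(pairs["beta_out"]),
                                   np.abs(out["beta"]))
        # idempotence: harmonizing already-aligned tables changes nothing
        again = harmonize(exp, exp.copy())
        assert not again["flipped"].any()
        np.testing.assert_allclose(again["beta_out"], exp["beta"])
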