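"""Summary-statistic I/O, instrument selection, and harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mrkit
from mrkit import (
    CorrelationMatrix,
    HarmonizationError,
    NoInstrumentsError,
    ValidationError,
    VariantAssociation,
    harmonize,
    read_correlation_matrix,
    read_sumstats,
    sd_to_pgml,
    select_instruments,
    write_correlation_matrix,
    write_sumstats,
)
from mrkit.errors import ConfigurationError

from conftest import make_assoc


def write_table(path, rows, header="SNP\teffect_allele\tother_allele\teaf\tbeta\tse\tpval"):
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadSumstats:
    def test_reads_rows_in_order(self, tmp_path):
        p = write_table(tmp_path / "x.tsv", [
            f"rs{i}\tA\tG\t0.3\t0.{i}\t0.05\t1e-9" for i in range(1, 6)
        ])
        recs = read_sumstats(p)
        assert [r.variant_id for r in recs] == [f"rs{i}" for i in range(1, 6)]
        assert recs[2].beta == pytest.approx(0.3)

    def test_rejects_nonpositive_se_rows(self, tmp_path, caplog):
        p = write_table(tmp_path / "x.tsv", [
            "rs1\tA\tG\t0.3\t0.1\t0.05\t1e-9",
            "rs2\tA\tG\t0.3\t0.1\t0\t1e-9",
        ])
        with caplog.at_level("INFO"):
            recs = read_sumstats(p)
        assert [r.variant_id for r in recs] == ["rs1"]
        assert "rejected 1" in caplog.text

    def test_rejects_unparseable_beta(self, tmp_path):
        p = write_table(tmp_path / "x.tsv", [
            "rs1\tA\tG\t0.3\tnot_a_number\t0.05\t1e-9",
            "rs2\tA\tG\t0.3\t0.1\t0.05\t1e-9",
        ])
        assert [r.variant_id for r in read_sumstats(p)] == ["rs2"]

    def test_uppercases_alleles(self, tmp_path):
        p = write_table(tmp_path / "x.tsv", ["rs1\ta\tg\t0.3\t0.1\t0.05\t1e-9"])
        rec = read_sumstats(p)[0]
        assert (rec.effect_allele, rec.other_allele) == ("A", "G")

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = write_table(tmp_path / "x.tsv", ["rs1\tA\tG\t0.1\t0.05\t1e-9"],
                        header="SNP\teffect_allele\tother_allele\tbeta\tse\tpval")
        with pytest.raises(ConfigurationError, match="stderr"):
            read_sumstats(p, column_map={"se": "stderr"})
        # absent optional columns (eaf here) are simply skipped
        assert read_sumstats(p)[0].eaf is None

    def test_comma_dialect_autodetected(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("SNP,effect_allele,other_allele,eaf,beta,se,pval\n"
                     "rs1,A,G,0.3,0.1,0.05,1e-9\n")
        assert read_sumstats(p)[0].beta == pytest.approx(0.1)

    def test_roundtrip_through_writer(self, tmp_path, ad_shaped_study):
        path = tmp_path / "exp.tsv"
        write_sumstats(ad_shaped_study.exposure_stats, path)
        back = read_sumstats(path)
        for a, b in zip(ad_shaped_study.exposure_stats, back):
            assert a == b


class TestVariantAssociation:
    @pytest.mark.parametrize("kw", [
        dict(se=-0.1), dict(se=0.0), dict(ea="A", oa="A"),
        dict(ea="AT"), dict(pvalue=0.0), dict(pvalue=1.5), dict(eaf=1.2),
    ])
    def test_invariants_enforced(self, kw):
        with pytest.raises(ValidationError):
            make_assoc(**kw)

    def test_palindromic_detection(self):
        assert make_assoc(ea="A", oa="T").is_palindromic
        assert make_assoc(ea="C", oa="G").is_palindromic
        assert not make_assoc(ea="A", oa="G").is_palindromic


class TestSelectInstruments:
    def test_strict_threshold(self):
        recs = [make_assoc(vid=f"rs{i}", pvalue=p)
                for i, p in enumerate([1e-9, 4e-8, 6e-8])]
        kept = select_instruments(recs, 5e-8)
        assert [r.variant_id for r in kept] == ["rs0", "rs1"]

    def test_inclusive_flag(self):
        recs = [make_assoc(vid="rs1", pvalue=5e-8)]
        with pytest.raises(NoInstrumentsError):
            select_instruments(recs, 5e-8)
        assert select_instruments(recs, 5e-8, inclusive=True) == recs

    def test_five_genome_wide_instruments_kept(self, ad_shaped_study):
        kept = select_instruments(ad_shaped_study.exposure_stats)
        assert len(kept) == 5

    def test_empty_result_raises_with_threshold(self):
        recs = [make_assoc(pvalue=0.5)]
        with pytest.raises(NoInstrumentsError) as err:
            select_instruments(recs, 5e-8)
        assert err.value.p_threshold == 5e-8

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=30),
           st.floats(1e-10, 0.99), st.floats(1e-10, 0.99))
    def test_threshold_monotonicity(self, ps, t1, t2):
        lo, hi = sorted([t1, t2])
        recs = [make_assoc(vid=f"rs{i}", pvalue=p) for i, p in enumerate(ps)]

        def ids(t):
            try:
                return {r.variant_id for r in select_instruments(recs, t)}
            except NoInstrumentsError:
                return set()

        assert ids(lo) <= ids(hi)


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        exp = [make_assoc(ea="A", oa="G", beta=0.2)]
        out = [make_assoc(ea="G", oa="A", beta=0.1)]
        pair = harmonize(exp, out).pairs[0]
        assert pair.y == pytest.approx(-0.1)
        assert pair.flipped

    def test_identical_coding_copies_unchanged(self):
        exp = [make_assoc(beta=0.2)]
        out = [make_assoc(beta=0.1)]
        pair = harmonize(exp, out).pairs[0]
        assert (pair.x, pair.y, pair.flipped) == (0.2, 0.1, False)

    def test_strand_complement_resolved(self):
        exp = [make_assoc(ea="A", oa="G", beta=0.2)]
        out = [make_assoc(ea="T", oa="C", beta=0.1)]   # other strand, same allele
        pair = harmonize(exp, out).pairs[0]
        assert pair.y == pytest.approx(0.1)
        assert not pair.flipped

    def test_palindrome_near_half_dropped(self):
        exp = [make_assoc(ea="A", oa="T", eaf=0.49)]
        out = [make_assoc(ea="A", oa="T", eaf=0.49),
               make_assoc(vid="rs000002")]
        exp.append(make_assoc(vid="rs000002"))
        iset = harmonize(exp, out, palindrome_eaf_limit=0.42)
        assert [p.variant_id for p in iset.pairs] == ["rs000002"]
        assert iset.dropped[0].dropped_reason == "palindromic_ambiguous"

    def test_palindrome_clear_frequency_retained(self):
        exp = [make_assoc(ea="A", oa="T", eaf=0.2, beta=0.2)]
        out = [make_assoc(ea="A", oa="T", eaf=0.22, beta=0.1)]
        pair = harmonize(exp, out, palindrome_eaf_limit=0.42).pairs[0]
        assert pair.y == pytest.approx(0.1)

    def test_palindrome_discordant_frequency_dropped(self):
        exp = [make_assoc(ea="A", oa="T", eaf=0.2), make_assoc(vid="rs2")]
        out = [make_assoc(ea="A", oa="T", eaf=0.8), make_assoc(vid="rs2")]
        iset = harmonize(exp, out)
        assert iset.dropped[0].dropped_reason == "palindromic_ambiguous"

    def test_palindrome_missing_eaf_dropped(self):
        exp = [make_assoc(ea="A", oa="T", eaf=None), make_assoc(vid="rs2")]
        out = [make_assoc(ea="A", oa="T", eaf=0.2), make_assoc(vid="rs2")]
        assert harmonize(exp, out).dropped[0].dropped_reason == "palindromic_ambiguous"

    def test_missing_in_outcome_dropped_with_reason(self):
        exp = [make_assoc(vid="rs1"), make_assoc(vid="rs2")]
        out = [make_assoc(vid="rs1")]
        iset = harmonize(exp, out)
        assert [p.variant_id for p in iset.pairs] == ["rs1"]
        assert iset.dropped[0].dropped_reason == "missing_in_outcome"

    def test_no_overlap_raises(self):
        with pytest.raises(HarmonizationError):
            harmonize([make_assoc(vid="rs1")], [make_assoc(vid="rs9")])

    def test_idempotent(self, ad_shaped_study):
        first = harmonize(ad_shaped_study.exposure_stats, ad_shaped_study.outcome_stats)
        # re-express the harmonized set as association records and re-harmonize
        exp2, out2 = [], []
        for exp, pair in zip(ad_shaped_study.exposure_stats, first.pairs):
            exp2.append(exp)
            out2.append(VariantAssociation(
                pair.variant_id, exp.effect_allele, exp.other_allele,
                pair.y, pair.sy, 0.5, eaf=exp.eaf,
            ))
        second = harmonize(exp2, out2)
        for a, b in zip(first.pairs, second.pairs):
            assert (a.variant_id, a.x, a.y) == (b.variant_id, b.x, b.y)

    @given(st.booleans(), st.floats(-0.5, 0.5), st.floats(0.05, 0.45),
           st.sampled_from(["AG", "CT", "AT", "CG"]))
    def test_sign_convention_invariance(self, relabel, beta_out, eaf, alleles):
        """Relabelling the outcome's alleles (and negating beta, complementing
        EAF) must give an identical harmonized set or an identical drop."""
        ea, oa = alleles[0], alleles[1]
        exp = [make_assoc(ea=ea, oa=oa, beta=0.2, eaf=eaf)]
        out_plain = [make_assoc(ea=ea, oa=oa, beta=beta_out, eaf=eaf)]
        out_flip = [make_assoc(ea=oa, oa=ea, beta=-beta_out, eaf=1 - eaf)]
        other = out_flip if relabel else out_plain

        def result(out):
            try:
                p = harmonize(exp, out).pairs[0]
                return ("kept", p.y, p.sy)
            except HarmonizationError:
                return ("dropped", None, None)

        r1, r2 = result(out_plain), result(other)
        assert r1[0] == r2[0]
        if r1[0] == "kept":
            assert r1[1] == pytest.approx(r2[1], abs=1e-12)
            assert r1[2] == pytest.approx(r2[2])


class TestCorrelationMatrix:
    def test_identity_roundtrip(self, tmp_path):
        ids = ["rs1", "rs2"]
        path = tmp_path / "ld.tsv"
        write_correlation_matrix(CorrelationMatrix.identity(ids), path)
        cm = read_correlation_matrix(path, ids)
        assert np.array_equal(cm.r, np.eye(2))

    def test_reordered_to_requested_ids(self, tmp_path):
        ids = ["rs1", "rs2", "rs3"]
        r = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
        path = tmp_path / "ld.tsv"
        write_correlation_matrix(CorrelationMatrix(tuple(ids), r), path)
        cm = read_correlation_matrix(path, ["rs3", "rs1", "rs2"])
        perm = [2, 0, 1]
        assert np.allclose(cm.r, r[np.ix_(perm, perm)])

    def test_write_read_bit_identical(self, tmp_path):
        ids = ["rs1", "rs2"]
        r = np.array([[1.0, 0.34567891], [0.34567891, 1.0]])
        path = tmp_path / "ld.tsv"
        write_correlation_matrix(CorrelationMatrix(tuple(ids), r), path)
        assert np.array_equal(read_correlation_matrix(path, ids).r, r)

    def test_bad_diagonal_rejected(self, tmp_path):
        path = tmp_path / "ld.tsv"
        pd.DataFrame([[0.9, 0.1], [0.1, 1.0]], index=["rs1", "rs2"],
                     columns=["rs1", "rs2"]).to_csv(path, sep="\t")
        with pytest.raises(ValidationError):
            read_correlation_matrix(path, ["rs1", "rs2"])

    def test_asymmetry_beyond_tolerance_rejected(self, tmp_path):
        path = tmp_path / "ld.tsv"
        pd.DataFrame([[1.0, 0.5], [0.3, 1.0]], index=["rs1", "rs2"],
                     columns=["rs1", "rs2"]).to_csv(path, sep="\t")
        with pytest.raises(ValidationError):
            read_correlation_matrix(path, ["rs1", "rs2"])

    def test_missing_id_named(self, tmp_path):
        path = tmp_path / "ld.tsv"
        write_correlation_matrix(CorrelationMatrix.identity(["rs1"]), path)
        with pytest.raises(ValidationError, match="rs9"):
            read_correlation_matrix(path, ["rs1", "rs9"])

    def test_not_psd_rejected(self):
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValidationError):
            CorrelationMatrix(("rs1", "rs2", "rs3"), r)


@pytest.mark.parametrize("x_sd,expected", [(1.0, 625.0), (0.0, 0.0), (2.0, 1250.0)])
def test_sd_to_pgml(x_sd, expected):
    assert sd_to_pgml(x_sd) == expected
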