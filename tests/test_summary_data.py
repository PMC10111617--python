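import numpy as np
import pytest

from mrmediate import (
    HarmonizedSet,
    SnpRecord,
    harmonize,
    ivw,
    read_summary_stats,
    write_summary_stats,
)
from mrmediate.summary_data import gaussian_pvalue

from conftest import make_record, simulated_instruments


class TestReadWrite:
    def test_three_row_tsv_round_trip(self, tmp_path):
        path = tmp_path / "stats.tsv"
        path.write_text(
            "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-23\t10000\n"
            "rs2\t2\t200\tC\tT\t0.4\t-0.05\t0.02\t0.012\t10000\n"
            "rs3\t3\t300\tG\tA\tNA\t0.02\t0.02\t0.32\tNA\n"
        )
        records = read_summary_stats(path)
        assert [r.snp_id for r in records] == ["rs1", "rs2", "rs3"]
        assert [r.beta for r in records] == [0.1, -0.05, 0.02]
        assert records[2].eaf is None and records[2].n is None

    def test_unparsable_beta_rejected_with_count(self, tmp_path):
        path = tmp_path / "stats.tsv"
        path.write_text(
            "SNP\tEA\tOA\tBETA\tSE\tP\n"
            "rs1\tA\tG\tNA\t0.01\t0.5\n"
            "rs2\tA\tG\t0.1\t0.01\t0.5\n"
        )
        records = read_summary_stats(
            path,
            {"snp_id": "SNP", "effect_allele": "EA", "other_allele": "OA",
             "beta": "BETA", "se": "SE", "pval": "P"},
        )
        assert len(records) == 1
        assert read_summary_stats.last_n_rejected == 1

    def test_indels_rejected(self, tmp_path):
        path = tmp_path / "stats.tsv"
        path.write_text(
            "SNP\tEA\tOA\tBETA\tSE\tP\n"
            "rs1\tAT\tG\t0.1\t0.01\t0.5\n"
            "rs2\tA\tG\t0.1\t0.01\t0.5\n"
        )
        cmap = {"snp_id": "SNP", "effect_allele": "EA", "other_allele": "OA",
                "beta": "BETA", "se": "SE", "pval": "P"}
        assert len(read_summary_stats(path, cmap)) == 1

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "stats.tsv"
        path.write_text("SNP\tEA\tOA\tBETA\tSE\nrs1\tA\tG\t0.1\t0.01\n")
        with pytest.raises(ValueError, match="pval"):
            read_summary_stats(path)

    def test_write_then_read_preserves_records(self, tmp_path):
        records = [
            make_record("rs1", beta=0.123456789, se=0.0123, eaf=0.25, n=5000),
            make_record("rs2", ea="C", oa="T", beta=-0.05, se=0.02),
        ]
        path = tmp_path / "out.tsv"
        write_summary_stats(records, path)
        back = read_summary_stats(path)
        assert back == records

    def test_write_read_write_is_byte_identical(self, tmp_path):
        records = [make_record("rs1", beta=1 / 3, se=0.0123456789, eaf=0.2, n=100)]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_summary_stats(records, p1)
        write_summary_stats(read_summary_stats(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_eaf_serialized_as_na(self, tmp_path):
        path = tmp_path / "out.tsv"
        write_summary_stats([make_record("rs1")], path)
        header, row = path.read_text().strip().split("\n")
        assert row.split("\t")[header.split("\t").index("EAF")] == "NA"

    def test_gzip_round_trip(self, tmp_path):
        records = [make_record("rs1"), make_record("rs2", beta=-0.2)]
        path = tmp_path / "out.tsv.gz"
        write_summary_stats(records, path)
        assert read_summary_stats(path) == records

    def test_empty_write_refused(self, tmp_path):
        with pytest.raises(ValueError):
            write_summary_stats([], tmp_path / "empty.tsv")


class TestSnpRecordValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"se": -0.01},
            {"se": 0.0},
            {"pval": 0.0},
            {"pval": 1.5},
            {"ea": "A", "oa": "A"},
            {"ea": "N"},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_record(**kwargs)


class TestHarmonize:
    def test_matching_alleles_kept_unchanged(self):
        h = harmonize(
            [make_record("rs1", "A", "G", beta=0.1)],
            [make_record("rs1", "A", "G", beta=0.2)],
        )
        assert h.beta_out[0] == 0.2 and h.n_flipped == 0

    def test_swapped_alleles_flip_outcome_sign(self):
        h = harmonize(
            [make_record("rs1", "A", "G", beta=0.1)],
            [make_record("rs1", "G", "A", beta=0.2)],
        )
        assert h.beta_out[0] == -0.2 and h.n_flipped == 1

    def test_strand_complement_resolved(self):
        # exposure A/G; outcome on the other strand T/C -> same direction
        h = harmonize(
            [make_record("rs1", "A", "G", beta=0.1)],
            [make_record("rs1", "T", "C", beta=0.2)],
        )
        assert h.beta_out[0] == 0.2
        # complement-swapped C/T -> sign flip
        h2 = harmonize(
            [make_record("rs1", "A", "G", beta=0.1)],
            [make_record("rs1", "C", "T", beta=0.2)],
        )
        assert h2.beta_out[0] == -0.2

    def test_palindromic_snps_deleted(self):
        h = harmonize(
            [make_record("rs1", "A", "T", beta=0.1), make_record("rs2", "A", "G")],
            [make_record("rs1", "A", "T", beta=0.2), make_record("rs2", "A", "G")],
        )
        assert h.n_dropped_palindromic == 1
        assert h.snp_ids == ["rs2"]

    def test_irreconcilable_alleles_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="irreconcilable"):
            h = harmonize(
                [make_record("rs1", "A", "G"), make_record("rs2", "A", "G")],
                [make_record("rs1", "A", "C"), make_record("rs2", "A", "G")],
            )
        assert h.snp_ids == ["rs2"]

    def test_zero_shared_snps_is_an_error(self):
        with pytest.raises(ValueError, match="share no SNPs"):
            harmonize([make_record("rs1")], [make_record("rs2")])

    def test_idempotent_on_harmonized_pair(self):
        exposure = [make_record("rs1", "A", "G", beta=0.1),
                    make_record("rs2", "C", "T", beta=-0.3)]
        outcome = [make_record("rs1", "G", "A", beta=0.2),
                   make_record("rs2", "C", "T", beta=0.4)]
        h1 = harmonize(exposure, outcome)
        # rebuild record lists in the harmonized frame and harmonize again
        realigned = [
            make_record(s, e.effect_allele, e.other_allele, beta=float(bo), se=float(so))
            for s, e, bo, so in zip(h1.snp_ids, exposure, h1.beta_out, h1.se_out)
        ]
        h2 = harmonize(exposure, realigned)
        assert h2.n_flipped == 0 and h2.n_dropped_palindromic == 0
        np.testing.assert_array_equal(h1.beta_out, h2.beta_out)

    def test_exposure_allele_flip_leaves_causal_estimate_invariant(self):
        h, study = simulated_instruments(seed=3)
        flipped_exposure = []
        for r in study.exposure_stats:
            flipped_exposure.append(
                SnpRecord(
                    snp_id=r.snp_id, effect_allele=r.other_allele,
                    other_allele=r.effect_allele, beta=-r.beta, se=r.se,
                    pval=r.pval, chrom=r.chrom, pos=r.pos,
                    eaf=None if r.eaf is None else 1 - r.eaf, n=r.n,
                )
            )
        from mrmediate import select_by_pvalue

        h_flip = harmonize(
            select_by_pvalue(flipped_exposure, 5e-8), study.outcome_stats
        )
        np.testing.assert_allclose(h_flip.beta_exp, -h.beta_exp)
        assert ivw(h_flip).beta == pytest.approx(ivw(h).beta, rel=1e-12)

    def test_palindromic_fraction_recovered_exactly(self):
        h, study = simulated_instruments(
            seed=7, threshold=1.0, frac_palindromic=0.3, n_snp_null=200
        )
        n_total = len(study.exposure_stats)
        n_palindromic = len(study.truth.palindromic_ids)
        assert h.n_dropped_palindromic == n_palindromic
        assert h.nsnp == n_total - n_palindromic


def test_gaussian_pvalue_matches_two_sided_tail():
    assert gaussian_pvalue(1.959964, 1.0) == pytest.approx(0.05, rel=1e-4)
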