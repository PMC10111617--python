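import itertools

import numpy as np
import pytest

from mrmediate import (
    LdMatrix,
    clump,
    f_statistic,
    f_statistic_from_r2,
    select_by_pvalue,
    steiger_filter,
    steiger_table,
)
from mrmediate.instruments import variance_explained

from conftest import make_record, simulated_instruments, toy_harmonized


def _records_with_pvals(pvals):
    return [
        make_record(f"rs{i+1}", beta=1.0, se=1.0, pval=p, chrom="1", pos=1000 * i)
        for i, p in enumerate(pvals)
    ]


class TestSelectByPvalue:
    def test_genome_wide_threshold(self):
        recs = _records_with_pvals([1e-9, 1e-7, 1e-3])
        assert [r.snp_id for r in select_by_pvalue(recs, 5e-8)] == ["rs1"]

    def test_relaxed_threshold_keeps_two(self):
        recs = _records_with_pvals([1e-9, 1e-7, 1e-3])
        assert len(select_by_pvalue(recs, 1e-5)) == 2

    def test_threshold_one_keeps_all(self):
        recs = _records_with_pvals([1e-9, 1e-7, 1.0])
        assert select_by_pvalue(recs, 1.0) == recs

    def test_empty_result_mentions_relaxed_threshold(self):
        with pytest.raises(ValueError, match="1e-05"):
            select_by_pvalue(_records_with_pvals([0.5]), 5e-8)

    def test_strict_inequality(self):
        recs = _records_with_pvals([1e-5, 1e-6])
        assert [r.snp_id for r in select_by_pvalue(recs, 1e-5)] == ["rs2"]


def _block_ld(snp_ids, blocks, r):
    """Constant-r blocks, zero elsewhere."""
    k = len(snp_ids)
    m = np.eye(k)
    for block in blocks:
        for i, j in itertools.permutations(block, 2):
            m[i, j] = r
    return LdMatrix(snp_ids=list(snp_ids), r=m)


class TestClump:
    def test_correlated_pair_keeps_best_pvalue(self):
        recs = [
            make_record("rsA", beta=7.0, se=1.0, chrom="1", pos=1000),
            make_record("rsB", beta=6.5, se=1.0, chrom="1", pos=2000),
        ]
        ld = _block_ld(["rsA", "rsB"], [[0, 1]], np.sqrt(0.5))
        kept = clump(recs, ld, r2_threshold=0.1)
        assert [r.snp_id for r in kept] == ["rsA"]

    def test_identity_ld_keeps_everything(self):
        recs = _records_with_pvals([1e-9, 1e-8, 1e-7])
        ld = LdMatrix([r.snp_id for r in recs], np.eye(3))
        assert len(clump(recs, ld)) == 3

    def test_two_blocks_keep_per_block_minimum(self):
        # oracle: with two constant-r blocks and no cross-block LD, any
        # greedy accept order that prefers smaller p keeps exactly the
        # per-block minimum-p SNP, computed here independently
        rng = np.random.default_rng(5)
        pvals = rng.uniform(1e-12, 1e-8, 10)
        recs = [
            make_record(f"rs{i}", beta=8.0, se=1.0, pval=p, chrom="1", pos=i * 100)
            for i, p in enumerate(pvals)
        ]
        blocks = [list(range(5)), list(range(5, 10))]
        ld = _block_ld([r.snp_id for r in recs], blocks, 0.95)  # r^2 ~ 0.9
        expected = {
            min((recs[i] for i in block), key=lambda r: r.pval).snp_id
            for block in blocks
        }
        kept = clump(recs, ld, r2_threshold=0.9)
        assert {r.snp_id for r in kept} == expected

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(11)
        recs = [
            make_record(f"rs{i}", beta=8.0, se=1.0, pval=p, chrom="1", pos=i * 100)
            for i, p in enumerate(rng.uniform(1e-12, 1e-8, 8))
        ]
        ld = _block_ld([r.snp_id for r in recs], [range(4), range(4, 8)], 0.9)
        ref = clump(recs, ld, r2_threshold=0.5)
        for perm_seed in range(3):
            shuffled = list(np.random.default_rng(perm_seed).permutation(recs))
            assert clump(shuffled, ld, r2_threshold=0.5) == ref

    def test_commutes_with_pvalue_selection(self):
        # holds whenever each block's minimum-p SNP is itself significant
        pvals = [1e-12, 1e-7, 1e-6, 2e-6, 3e-4, 0.02,
                 1e-11, 5e-7, 4e-6, 8e-6, 2e-4, 0.40]
        recs = [
            make_record(f"rs{i}", beta=8.0, se=1.0, pval=p, chrom="1", pos=i * 100)
            for i, p in enumerate(pvals)
        ]
        ld = _block_ld([r.snp_id for r in recs], [range(6), range(6, 12)], 0.95)
        a = clump(select_by_pvalue(recs, 1e-5), ld, r2_threshold=0.5)
        b = select_by_pvalue(clump(recs, ld, r2_threshold=0.5), 1e-5)
        assert a == b
        assert {r.snp_id for r in a} == {"rs0", "rs6"}

    def test_window_limits_pruning(self):
        # perfectly correlated but 20 Mb apart -> both kept
        recs = [
            make_record("rsA", beta=8.0, se=1.0, chrom="1", pos=1),
            make_record("rsB", beta=7.0, se=1.0, chrom="1", pos=20_000_001),
        ]
        ld = _block_ld(["rsA", "rsB"], [[0, 1]], 1.0)
        assert len(clump(recs, ld, r2_threshold=0.1, window_kb=10_000)) == 2

    def test_missing_ld_means_independent(self):
        recs = _records_with_pvals([1e-9, 1e-8])
        assert len(clump(recs, None)) == 2


class TestFStatistic:
    def test_arithmetic(self):
        assert f_statistic(make_record(beta=0.1, se=0.01)) == pytest.approx(100.0)

    def test_weak_instrument_boundary(self):
        rec = make_record(beta=np.sqrt(10) * 0.01, se=0.01)
        assert f_statistic(rec) == pytest.approx(10.0)

    def test_algebraic_identity_with_r2_form(self):
        # F = (n-2) R^2 / (1 - R^2) with R^2 = t^2/(t^2+n-2) equals t^2
        rec = make_record(beta=0.07, se=0.011, n=50_000)
        t2 = (rec.beta / rec.se) ** 2
        r2 = variance_explained(np.array([rec.beta / rec.se]), rec.n)[0]
        assert (rec.n - 2) * r2 / (1 - r2) == pytest.approx(t2, rel=1e-12)
        assert f_statistic(rec) == pytest.approx(t2)

    def test_r2_based_f_requires_eaf_and_n(self):
        with pytest.raises(ValueError):
            f_statistic_from_r2(make_record(beta=0.1, se=0.01))
        f = f_statistic_from_r2(make_record(beta=0.1, se=0.01, eaf=0.3, n=10_000))
        assert f > 0


class TestSteiger:
    def test_dominant_exposure_signal_retained(self):
        h = toy_harmonized(n=5, seed=1, slope=0.0, noise=0.1)
        h.beta_exp[:] = 10 * h.se_exp
        h.beta_out[:] = 1 * h.se_out
        kept = steiger_filter(h, 100_000, 100_000)
        assert kept.nsnp == 5

    def test_reverse_direction_removed(self):
        h = toy_harmonized(n=5, seed=1)
        h.beta_exp[:] = 2 * h.se_exp
        h.beta_out[:] = 20 * h.se_out
        with pytest.raises(ValueError, match="every SNP"):
            steiger_filter(h, 100_000, 100_000)

    def test_reverse_causal_snps_removed_in_simulation(self):
        removed = total = 0
        for seed in range(5):
            h, study = simulated_instruments(
                seed=seed,
                n_exp=100_000, n_med=100_000,
                n_out=100_000, n_case=50_000, n_control=50_000,
                reverse_causal_snps=20,
            )
            filtered = steiger_filter(h, 100_000, 100_000, alpha=0.05)
            reverse = set(study.truth.reverse_causal_ids)
            present = [s for s in h.snp_ids if s in reverse]
            kept = [s for s in filtered.snp_ids if s in reverse]
            total += len(present)
            removed += len(present) - len(kept)
        assert total > 50
        assert removed / total >= 0.9

    def test_table_reports_per_snp_r2(self):
        h = toy_harmonized(n=4, seed=3)
        table = steiger_table(h, 50_000, 50_000)
        assert set(table.columns) >= {"r2_exposure", "r2_outcome", "steiger_p"}
        assert (table["r2_exposure"] >= 0).all()


def test_min_f_exceeds_ten_on_default_scenario():
    """Selected instruments at 5e-8 are never weak at UKB-scale n."""
    for seed in range(20):
        h, _ = simulated_instruments(seed=seed)
        f = (h.beta_exp / h.se_exp) ** 2
        assert f.min() > 10


class TestLdMatrix:
    def test_round_trip_tsv(self, tmp_path):
        ld = _block_ld(["rs1", "rs2", "rs3"], [[0, 1]], 0.5)
        ld.to_tsv(tmp_path / "ld.tsv")
        back = LdMatrix.from_tsv(tmp_path / "ld.tsv")
        assert back.snp_ids == ld.snp_ids
        np.testing.assert_allclose(back.r, ld.r, atol=1e-6)

    def test_asymmetric_rejected(self):
        m = np.eye(2)
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            LdMatrix(["a", "b"], m)
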