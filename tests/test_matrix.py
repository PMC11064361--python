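"""Contact-matrix core: binning, balancing, normalization, decay, SCC."""

import numpy as np
import pytest

from hic3d import matrix as M
from hic3d.genome import BinnedGenome

from conftest import random_symmetric


def make_cm(mat: np.ndarray, resolution: int = 100,
            state: str = M.RAW) -> M.ContactMatrix:
    g = BinnedGenome({"chr1": mat.shape[0] * resolution}, resolution)
    return M.ContactMatrix(genome=g, data={"chr1": mat}, state=state)


class TestBinContacts:
    def test_single_pair_lands_in_both_triangles(self, small_genome):
        cm = M.bin_contacts([("chr1", 150, "chr1", 250)], small_genome)
        assert cm.data["chr1"][1, 2] == 1
        assert cm.data["chr1"][2, 1] == 1
        assert cm.total_contacts == 1

    def test_interchromosomal_pair_dropped_and_counted(self, small_genome):
        cm = M.bin_contacts([("chr1", 10, "chr2", 10)], small_genome)
        assert cm.dropped_pairs == 1
        assert cm.total_contacts == 0

    def test_column_sums_match_direct_tabulation(self):
        g = BinnedGenome({"chr1": 5_000}, resolution=100)  # 50 bins
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 5_000, size=(10_000, 2))
        pairs = [("chr1", int(a), "chr1", int(b)) for a, b in pos]
        cm = M.bin_contacts(pairs, g)
        # independent oracle: tabulate per-bin endpoint counts directly
        expect = np.zeros(50)
        for a, b in pos:
            expect[a // 100] += 1
            expect[b // 100] += 1
        got = cm.data["chr1"].sum(axis=0) + np.diag(cm.data["chr1"])
        assert np.array_equal(got, expect)

    def test_retained_pair_count_conserved(self, small_genome):
        rng = np.random.default_rng(1)
        pairs = [("chr1", int(a), "chr1", int(b))
                 for a, b in rng.integers(0, 5_000, size=(500, 2))]
        cm = M.bin_contacts(pairs, small_genome)
        assert np.triu(cm.data["chr1"]).sum() == 500

    def test_malformed_line_raises_with_line_number(self, small_genome):
        with pytest.raises(M.MalformedPairError, match="line 2"):
            list(M.parse_pairs(["chr1 1 chr1 2", "chr1 oops chr1 2"],
                               small_genome))

    def test_unknown_chromosome_rejected_not_fatal(self, small_genome):
        recs = list(M.parse_pairs(["chrZ 1 chrZ 2", "chr1 1 chr1 2"],
                                  small_genome))
        assert len(recs) == 1


class TestKrBalance:
    def test_constant_matrix_unchanged_up_to_scale(self):
        cm = make_cm(np.full((8, 8), 3.0))
        bal = M.kr_balance(cm)
        ratio = bal.data["chr1"] / cm.data["chr1"]
        assert np.allclose(ratio, ratio[0, 0])
        sums = bal.data["chr1"].sum(axis=0)
        assert np.allclose(sums, sums[0])

    def test_zero_row_masked_and_remainder_balanced(self):
        a = random_symmetric(10, seed=2)
        a[3, :] = 0
        a[:, 3] = 0
        bal = M.kr_balance(make_cm(a))
        assert bal.masked["chr1"][3]
        assert np.all(bal.data["chr1"][3] == 0)
        keep = ~bal.masked["chr1"]
        sums = bal.data["chr1"][np.ix_(keep, keep)].sum(axis=0)
        assert sums.std() / sums.mean() < 1e-5

    def test_matches_independent_ipf_oracle(self):
        a = random_symmetric(20, seed=3)
        bal = M.kr_balance(make_cm(a), tolerance=1e-10)
        # independent oracle: plain iterative proportional fitting
        x = np.ones(20)
        scale = a.sum(axis=0).mean()
        an = a / scale
        for _ in range(20_000):
            s = x * (an @ x)
            x = x / np.sqrt(s)
        oracle = (x[:, None] * an) * x[None, :]
        oracle *= a.sum() / oracle.sum()
        assert np.allclose(bal.data["chr1"], oracle, rtol=1e-6)

    def test_balancing_is_idempotent(self):
        a = random_symmetric(15, seed=4)
        bal = M.kr_balance(make_cm(a), tolerance=1e-10)
        again = M.kr_balance(
            make_cm(bal.data["chr1"].copy()), tolerance=1e-10)
        assert np.allclose(again.data["chr1"], bal.data["chr1"], rtol=1e-5)

    def test_bias_vectors_reconstruct_raw(self):
        a = random_symmetric(12, seed=5)
        bal = M.kr_balance(make_cm(a))
        b = bal.biases["chr1"]
        recon = bal.data["chr1"] * b[:, None] * b[None, :]
        assert np.allclose(recon, a, rtol=1e-6)

    def test_rejects_non_raw_input(self):
        cm = make_cm(np.ones((5, 5)), state=M.BALANCED)
        with pytest.raises(ValueError, match="raw"):
            M.kr_balance(cm)


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        a = random_symmetric(10, seed=6)
        outs = M.quantile_normalize([make_cm(a.copy()), make_cm(a.copy())])
        for o in outs:
            assert np.allclose(o.data["chr1"], a)

    def test_two_sample_mean_distribution(self):
        a = random_symmetric(10, seed=7)
        outs = M.quantile_normalize([make_cm(a.copy()), make_cm(2 * a)])
        # doubling preserves ranks, so both map to the elementwise mean
        assert np.allclose(outs[0].data["chr1"], 1.5 * a)
        assert np.allclose(outs[1].data["chr1"], 1.5 * a)

    def test_sorted_vectors_identical_and_ranks_preserved(self):
        mats = [random_symmetric(12, seed=s) for s in (8, 9, 10)]
        outs = M.quantile_normalize([make_cm(m) for m in mats])
        iu = np.triu_indices(12)
        sorted_vecs = [np.sort(o.data["chr1"][iu]) for o in outs]
        for v in sorted_vecs[1:]:
            assert np.allclose(v, sorted_vecs[0])
        for m, o in zip(mats, outs):
            before = np.argsort(m[iu], kind="stable")
            after = np.argsort(o.data["chr1"][iu], kind="stable")
            assert np.array_equal(before, after)

    def test_mismatched_genomes_rejected(self, small_genome):
        g2 = BinnedGenome({"chr1": 5_000}, resolution=50)
        cm1 = M.ContactMatrix(genome=small_genome, data={
            "chr1": np.ones((50, 50)), "chr2": np.ones((30, 30))})
        cm2 = M.ContactMatrix(genome=g2, data={"chr1": np.ones((100, 100))})
        with pytest.raises(ValueError):
            M.quantile_normalize([cm1, cm2])


class TestExpectedAndOE:
    def test_constant_matrix_every_stratum_mean_is_c(self):
        prof = M.expected_by_distance(make_cm(np.full((6, 6), 4.0)))
        assert np.allclose(prof.means["chr1"], 4.0)

    def test_three_by_three_arithmetic(self):
        a = np.array([[1.0, 2.0, 5.0], [2.0, 1.0, 4.0], [5.0, 4.0, 1.0]])
        prof = M.expected_by_distance(make_cm(a))
        assert prof.means["chr1"][1] == pytest.approx(3.0)

    def test_simulated_decay_slope_recovered(self):
        n = 300
        idx = np.arange(n)
        lam = 1000.0 / (1.0 + np.abs(np.subtract.outer(idx, idx)))
        rng = np.random.default_rng(11)
        a = rng.poisson(lam).astype(float)
        a = np.triu(a) + np.triu(a, 1).T
        prof = M.expected_by_distance(make_cm(a))
        d = np.arange(1, n)
        slope = np.polyfit(np.log1p(d), np.log(prof.means["chr1"][1:]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_oe_constant_matrix_all_ones(self):
        cm = make_cm(np.full((6, 6), 4.0))
        oe = M.observed_over_expected(cm, M.expected_by_distance(cm))
        assert np.allclose(oe.data["chr1"], 1.0)
        assert oe.state == M.OE

    def test_oe_stratum_means_near_one(self):
        a = random_symmetric(40, seed=12)
        cm = make_cm(a)
        oe = M.observed_over_expected(cm, M.expected_by_distance(cm))
        prof = M.expected_by_distance(oe)
        assert np.allclose(prof.means["chr1"], 1.0)


class TestStratumAdjustedCorrelation:
    def test_self_correlation_is_one(self):
        a = random_symmetric(60, seed=13)
        cm = make_cm(a)
        sim = M.stratum_adjusted_correlation(cm, cm)
        assert sim.scc == pytest.approx(1.0)

    def test_symmetric_in_argument_order(self):
        a, b = random_symmetric(60, seed=14), random_symmetric(60, seed=15)
        s1 = M.stratum_adjusted_correlation(make_cm(a), make_cm(b))
        s2 = M.stratum_adjusted_correlation(make_cm(b), make_cm(a))
        assert s1.scc == pytest.approx(s2.scc)

    def test_scale_invariance(self):
        a, b = random_symmetric(60, seed=16), random_symmetric(60, seed=17)
        s1 = M.stratum_adjusted_correlation(make_cm(a), make_cm(b))
        s2 = M.stratum_adjusted_correlation(make_cm(a), make_cm(5 * b))
        assert s1.scc == pytest.approx(s2.scc, abs=1e-9)

    def test_within_stratum_shuffle_decorrelates(self):
        n = 400
        idx = np.arange(n)
        lam = 500.0 / (1.0 + np.abs(np.subtract.outer(idx, idx))) ** 0.8
        rng = np.random.default_rng(18)
        a = np.triu(rng.poisson(lam).astype(float))
        a = a + np.triu(a, 1).T
        b = np.zeros_like(a)
        for d in range(n):
            vals = np.diagonal(a, offset=d).copy()
            rng.shuffle(vals)
            b[idx[: n - d], idx[: n - d] + d] = vals
        b = np.triu(b) + np.triu(b, 1).T
        s = M.stratum_adjusted_correlation(make_cm(a), make_cm(b),
                                           smoothing_halfwidth=0)
        assert abs(s.scc) < 0.1

    def test_all_constant_strata_rejected(self):
        cm = make_cm(np.full((30, 30), 2.0))
        with pytest.raises(ValueError, match="stra"):
            M.stratum_adjusted_correlation(cm, cm)
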