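"""Directionality index, DI-HMM TAD calling, insulation score, sub-TAD
partitioning and boundary dynamics."""

import numpy as np
import pytest

from hic3d import domains as D
from hic3d import matrix as M
from hic3d import simulate as sim
from hic3d.genome import BinnedGenome
from scipy import stats


def cm_from(mat: np.ndarray, state: str = M.BALANCED) -> M.ContactMatrix:
    g = BinnedGenome({"chr1": mat.shape[0] * 100}, 100)
    return M.ContactMatrix(genome=g, data={"chr1": mat}, state=state)


def block_matrix(sizes, boost=2.0, base=10.0):
    n = sum(sizes)
    a = np.full((n, n), base)
    start = 0
    for s in sizes:
        a[start:start + s, start:start + s] *= boost
        start += s
    return a


class TestDirectionalityIndex:
    def _matrix_with_sums(self, a_sum, b_sum, half_width=2):
        """Bin 4 sees upstream total a_sum and downstream total b_sum."""
        n = 9
        m = np.zeros((n, n))
        m[4, 2], m[4, 3] = a_sum / 2, a_sum / 2
        m[4, 5], m[4, 6] = b_sum / 2, b_sum / 2
        m = np.maximum(m, m.T)
        m += 1e-9  # avoid fully-masked rows
        return cm_from(m)

    @pytest.mark.parametrize("a,b,expect", [
        (10.0, 30.0, 10.0),   # hand evaluation: E=20, (100+100)/20 = +10
        (30.0, 10.0, -10.0),  # antisymmetric
        (7.0, 7.0, 0.0),
    ])
    def test_hand_computed_values(self, a, b, expect):
        track = D.directionality_index(self._matrix_with_sums(a, b),
                                       half_width=2, chrom="chr1")
        assert track.di[4] == pytest.approx(expect, abs=1e-6)

    def test_reversal_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(20.0, (40, 40)).astype(float)
        a = (a + a.T) / 2
        fwd = D.directionality_index(cm_from(a), half_width=5,
                                     chrom="chr1").di
        rev = D.directionality_index(cm_from(a[::-1, ::-1].copy()),
                                     half_width=5, chrom="chr1").di
        assert np.allclose(fwd, -rev[::-1], equal_nan=True)

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            D.directionality_index(cm_from(np.ones((10, 10))), half_width=0)


class TestDiHmmDomains:
    def test_two_planted_blocks_give_one_internal_junction(self):
        rng = np.random.default_rng(1)
        lam = block_matrix([50, 50], boost=2.0, base=20.0)
        a = rng.poisson(lam).astype(float)
        a = np.triu(a) + np.triu(a, 1).T
        cm = cm_from(a)
        track = D.directionality_index(cm, chrom="chr1")
        oe = M.observed_over_expected(cm, M.expected_by_distance(cm))
        dom = D.di_hmm_domains(track, seed=0, oe=oe.data["chr1"])
        assert len(dom.junctions) == 1
        assert abs(dom.junctions[0] - 50) <= 1

    def test_uniform_matrix_no_junctions(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(30.0, (60, 60)).astype(float)
        a = (a + a.T) / 2
        cm = cm_from(a)
        track = D.directionality_index(cm, chrom="chr1")
        oe = M.observed_over_expected(cm, M.expected_by_distance(cm))
        dom = D.di_hmm_domains(track, seed=0, oe=oe.data["chr1"])
        assert dom.junctions == []

    def test_mirrored_matrix_gives_mirrored_calls(self):
        rng = np.random.default_rng(3)
        lam = block_matrix([30, 40, 30], boost=2.5, base=20.0)
        a = rng.poisson(lam).astype(float)
        a = np.triu(a) + np.triu(a, 1).T
        rev = a[::-1, ::-1].copy()
        n = a.shape[0]

        def call(mat):
            cm = cm_from(mat)
            t = D.directionality_index(cm, chrom="chr1")
            oe = M.observed_over_expected(cm, M.expected_by_distance(cm))
            return D.di_hmm_domains(t, seed=0, oe=oe.data["chr1"]).junctions

        fwd = call(a)
        bwd = sorted(n - j for j in call(rev))
        assert all(any(abs(x - y) <= 1 for y in bwd) for x in fwd)

    def test_too_few_usable_bins_rejected(self):
        track = D.DITrack(chromosome="chr1", upstream=np.zeros(10),
                          downstream=np.zeros(10), di=np.full(10, np.nan),
                          half_width=2)
        with pytest.raises(ValueError, match="usable"):
            D.di_hmm_domains(track)


class TestInsulationScore:
    def test_uniform_matrix_normalized_zero(self):
        track = D.insulation_score(cm_from(np.full((30, 30), 5.0)),
                                   window=5, chrom="chr1")
        callable_ = ~np.isnan(track.normalized)
        assert callable_.sum() == 30 - 10
        assert np.allclose(track.normalized[callable_], 0.0, atol=1e-12)

    def test_two_block_minimum_at_junction(self):
        a = block_matrix([10, 10], boost=3.0, base=10.0)
        track = D.insulation_score(cm_from(a), window=4, chrom="chr1")
        assert np.nanargmin(track.normalized) in (9, 10)  # both windows
        # straddling the junction are fully cross-block

    def test_short_chromosome_all_no_call(self):
        track = D.insulation_score(cm_from(np.ones((7, 7))), window=4,
                                   chrom="chr1")
        assert np.isnan(track.normalized).all()

    def test_mean_linear_insulation_near_one(self):
        rng = np.random.default_rng(4)
        a = rng.poisson(20.0, (80, 80)).astype(float)
        a = (a + a.T) / 2
        track = D.insulation_score(cm_from(a), window=8, chrom="chr1")
        callable_ = ~np.isnan(track.normalized)
        assert np.mean(2 ** track.normalized[callable_]) == pytest.approx(
            1.0, abs=0.05)

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            D.insulation_score(cm_from(np.ones((10, 10))), window=0)


class TestPartitionSubtads:
    def is_track(self, values):
        values = np.asarray(values, dtype=float)
        return D.ISTrack(chromosome="chr1", raw=values.copy(),
                         normalized=values, window=3)

    def test_single_prominent_minimum_splits_in_two(self):
        values = np.zeros(20)
        values[10] = -0.8
        parent = D.DomainSet(chromosome="chr1", domains=[(0, 20)])
        out = D.partition_subtads(parent, self.is_track(values), min_depth=0.5)
        assert out.subdomains[(0, 20)] == [(0, 10), (10, 20)]

    def test_monotone_track_keeps_parent_whole(self):
        values = np.linspace(0, 1, 20)
        parent = D.DomainSet(chromosome="chr1", domains=[(0, 20)])
        out = D.partition_subtads(parent, self.is_track(values), min_depth=0.3)
        assert out.subdomains[(0, 20)] == [(0, 20)]

    def test_minimum_near_edge_ignored(self):
        values = np.zeros(20)
        values[1] = -0.9
        parent = D.DomainSet(chromosome="chr1", domains=[(0, 20)])
        out = D.partition_subtads(parent, self.is_track(values), min_depth=0.5)
        assert out.subdomains[(0, 20)] == [(0, 20)]

    def test_subtads_tile_parent_exactly(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.5, size=60)
        parent = D.DomainSet(chromosome="chr1", domains=[(5, 35), (35, 58)])
        out = D.partition_subtads(parent, self.is_track(values), min_depth=0.2)
        for dom, subs in out.subdomains.items():
            assert subs[0][0] == dom[0] and subs[-1][1] == dom[1]
            for (a, b), (c, _) in zip(subs, subs[1:]):
                assert b == c
            assert all(e > s for s, e in subs)


class TestBoundaryDynamics:
    def dset(self, domains):
        return D.DomainSet(chromosome="chr1", domains=domains)

    def test_identical_sets_all_shared(self):
        d = self.dset([(0, 10), (10, 20)])
        out = D.boundary_dynamics(d, self.dset([(0, 10), (10, 20)]))
        assert out["gained"] == [] and out["lost"] == []
        assert len(out["shared"]) == 3

    def test_one_bin_shift_within_slack_is_shared(self):
        out = D.boundary_dynamics(self.dset([(0, 10), (10, 20)]),
                                  self.dset([(0, 11), (11, 20)]),
                                  slack_bins=1)
        assert out["gained"] == [] and out["lost"] == []

    def test_planted_boundary_losses_recovered(self):
        truth = sim.make_truth(seed=3, n_boundary_changes=2)
        lost_truth = []
        for chrom in truth.genome.chromsizes:
            b1 = set(truth.boundaries("condition1", chrom))
            b2 = set(truth.boundaries("condition2", chrom))
            lost_truth.extend(sorted(b1 - b2))
        assert len(lost_truth) == 2

        found = []
        for chrom in truth.genome.chromsizes:
            maps = {}
            for k, cond in enumerate(("condition1", "condition2")):
                m = sim.simulate_contact_map(truth, cond, seed=40 + k)
                b = M.kr_balance(m)
                oe = M.observed_over_expected(b, M.expected_by_distance(b))
                t = D.directionality_index(b, chrom=chrom)
                maps[cond] = D.di_hmm_domains(t, seed=0, oe=oe.data[chrom])
            dyn = D.boundary_dynamics(maps["condition1"], maps["condition2"])
            found.extend(dyn["lost"])
        matched = sum(any(abs(f - t) <= 1 for f in found) for t in lost_truth)
        assert matched == len(lost_truth)

    def test_replicate_insulation_tracks_correlate(self):
        truth = sim.make_truth(seed=4)
        tracks = []
        for k in range(2):
            m = sim.simulate_contact_map(truth, "condition1", seed=50 + k)
            b = M.kr_balance(m)
            tracks.append(D.insulation_score(b, window=10, chrom="chr1"))
        x, y = tracks[0].normalized, tracks[1].normalized
        ok = ~np.isnan(x) & ~np.isnan(y)
        rho, _ = stats.spearmanr(x[ok], y[ok])
        assert rho > 0.8

    def test_mismatched_chromosomes_rejected(self):
        d1 = D.DomainSet(chromosome="chr1", domains=[(0, 5)])
        d2 = D.DomainSet(chromosome="chr2", domains=[(0, 5)])
        with pytest.raises(ValueError):
            D.boundary_dynamics(d1, d2)
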