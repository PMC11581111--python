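import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxmap.volio import GroupDesign, Volume3D
from voxmap.voxelstats import (
    DesignError,
    extract_clusters,
    fdr_threshold,
    permutation_pvalues,
    voxelwise_t,
)

from oracles import bh_stepup, exhaustive_perm_p, flood_fill_components, pooled_t_scalar

SPACING = (10.0, 10.0, 10.0)


def _vols(values_per_sample, shape=(1, 1, 1)):
    out = []
    for v in values_per_sample:
        arr = np.full(shape, float(v)) if np.isscalar(v) else np.asarray(v, dtype=float)
        out.append(Volume3D(arr.reshape(shape), SPACING, space="atlas"))
    return out


def _design(n1, n2):
    return GroupDesign(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n1 + n2)],
        "group": ["g1"] * n1 + ["g2"] * n2,
    }))


def _mask(shape=(1, 1, 1)):
    return Volume3D(np.ones(shape, dtype=bool), SPACING, space="atlas")


class TestVoxelwiseT:
    def test_identical_stacks_give_zero(self):
        stack = _vols([1.0, 2.0])
        t = voxelwise_t(stack, _vols([1.0, 2.0]), _mask())
        assert np.all(t.values == 0)

    def test_hand_computed_single_voxel(self):
        t = voxelwise_t(_vols([2.0, 4.0]), _vols([0.0, 0.0]), _mask())
        expected = pooled_t_scalar([2.0, 4.0], [0.0, 0.0])
        assert t.values[0, 0, 0] == pytest.approx(expected)
        assert expected == pytest.approx(3.0)  # (3-0)/sqrt(1*(1/2+1/2))

    def test_swapping_groups_negates_t(self):
        rng = np.random.default_rng(0)
        a = [rng.random((3, 3, 3)) for _ in range(3)]
        b = [rng.random((3, 3, 3)) for _ in range(3)]
        mask = _mask((3, 3, 3))
        t1 = voxelwise_t(_vols(a, (3, 3, 3)), _vols(b, (3, 3, 3)), mask)
        t2 = voxelwise_t(_vols(b, (3, 3, 3)), _vols(a, (3, 3, 3)), mask)
        assert np.allclose(t1.values, -t2.values)

    def test_fewer_than_two_per_group_rejected(self):
        with pytest.raises(DesignError):
            voxelwise_t(_vols([1.0]), _vols([0.0, 1.0]), _mask())


class TestPermutationP:
    @pytest.mark.parametrize("direction", ["group1_greater", "group2_greater"])
    def test_exhaustive_3v3_matches_oracle_exactly(self, direction):
        rng = np.random.default_rng(42)
        for _ in range(10):
            values = rng.normal(size=6).tolist()
            stat = permutation_pvalues(
                _vols(values), _design(3, 3), direction, n_perm=2000, seed=0, mask=_mask()
            )
            assert stat.exhaustive
            expected = exhaustive_perm_p(values, 3, direction)
            assert stat.p_map.values[0, 0, 0] == expected

    def test_strict_maximum_gives_one_over_twenty(self):
        values = [10.0, 11.0, 12.0, 0.0, 1.0, 2.0]
        stat = permutation_pvalues(
            _vols(values), _design(3, 3), "group1_greater", n_perm=2000, seed=0, mask=_mask()
        )
        assert stat.p_map.values[0, 0, 0] == pytest.approx(1.0 / 20.0)

    def test_identical_data_gives_p_one(self):
        stat = permutation_pvalues(
            _vols([5.0] * 6), _design(3, 3), "group1_greater", n_perm=2000, seed=0, mask=_mask()
        )
        assert stat.p_map.values[0, 0, 0] == 1.0

    def test_sampled_path_deterministic_and_bounded(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=12).tolist()
        kwargs = dict(direction="group1_greater", n_perm=200, seed=7, mask=_mask())
        s1 = permutation_pvalues(_vols(values), _design(6, 6), **kwargs)
        s2 = permutation_pvalues(_vols(values), _design(6, 6), **kwargs)
        assert not s1.exhaustive
        assert np.array_equal(s1.p_map.values, s2.p_map.values)
        p = s1.p_map.values[0, 0, 0]
        assert 1.0 / 201.0 <= p <= 1.0

    def test_null_pvalues_stochastically_uniform_or_larger(self):
        # exchangeable null data: pooled empirical CDF of p must not exceed
        # the uniform CDF by more than a loose one-sided KS band
        rng = np.random.default_rng(9)
        dplus = []
        for rep in range(3):
            shape = (8, 8, 8)
            stacks = [rng.normal(size=shape) for _ in range(8)]
            stat = permutation_pvalues(
                _vols(stacks, shape), _design(4, 4), "group1_greater",
                n_perm=2000, seed=rep, mask=_mask(shape),
            )
            p = stat.p_map.values.ravel()
            grid = np.arange(1, 71) / 70.0
            ecdf = np.array([(p <= g + 1e-12).mean() for g in grid])
            dplus.append(float((ecdf - grid).max()))
        assert max(dplus) < 0.1


class TestFDR:
    def test_small_worked_example(self):
        # step-up by hand: sorted p vs k*q/m = .01,.02,.03,.04,.05;
        # 0.039 > 0.03 and 0.041 > 0.04, so only the first two pass
        pvals = [0.001, 0.008, 0.039, 0.041, 0.27]
        stat = _fake_stat(pvals, (5, 1, 1))
        cutoff, sig, adj = fdr_threshold(stat, q=0.05)
        o_cut, o_rej, o_adj = bh_stepup(pvals, 0.05)
        assert cutoff == pytest.approx(0.008)
        assert cutoff == o_cut
        assert np.array_equal(sig.values.ravel(), o_rej)
        assert sig.values.ravel().tolist() == [True, True, False, False, False]
        assert np.allclose(adj.values.ravel(), o_adj)

    def test_random_vectors_match_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = int(rng.integers(5, 200))
            pvals = rng.random(m)
            q = float(rng.uniform(0.01, 0.5))
            shape = (m, 1, 1)
            stat = _fake_stat(pvals, shape)
            cutoff, sig, adj = fdr_threshold(stat, q)
            o_cut, o_rej, o_adj = bh_stepup(pvals, q)
            assert cutoff == pytest.approx(o_cut, abs=0)
            assert np.array_equal(sig.values.ravel(), o_rej)
            assert np.allclose(adj.values.ravel(), o_adj, atol=1e-12)

    def test_all_ones_empty(self):
        stat = _fake_stat(np.ones(10), (10, 1, 1))
        cutoff, sig, _ = fdr_threshold(stat, q=0.05)
        assert cutoff == 0.0
        assert not sig.values.any()

    def test_monotone_in_q(self):
        rng = np.random.default_rng(2)
        pvals = rng.random(100)
        stat = _fake_stat(pvals, (100, 1, 1))
        _, sig_small, _ = fdr_threshold(stat, q=0.05)
        stat2 = _fake_stat(pvals, (100, 1, 1))
        _, sig_big, _ = fdr_threshold(stat2, q=0.2)
        assert not (sig_small.values & ~sig_big.values).any()


def _fake_stat(pvals, shape):
    from voxmap.voxelstats import VoxelStatMap

    p = Volume3D(np.asarray(pvals, dtype=float).reshape(shape), SPACING, space="atlas")
    mask = Volume3D(np.ones(shape, dtype=bool), SPACING, space="atlas")
    return VoxelStatMap(
        t_map=p.like(np.zeros(shape)), p_map=p, p_adj_map=None,
        analysis_mask=mask, direction="group1_greater", n_perm=1, seed=0,
    )


class TestClusters:
    def test_extent_boundary_399_rejected_at_400(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        flat = np.zeros(20 * 20 * 20, dtype=bool)
        # a single 6-connected slab of exactly 399 voxels
        mask[:, :, :] = False
        count = 0
        for x in range(20):
            for y in range(20):
                if count < 399:
                    mask[x, y, 5] = True
                    count += 1
        sig = Volume3D(mask, SPACING, space="atlas")
        cs = extract_clusters(sig, min_size_vox=400)
        assert len(cs.records) == 0
        cs2 = extract_clusters(sig, min_size_vox=399)
        assert len(cs2.records) == 1 and cs2.records.iloc[0]["n_voxels"] == 399

    def test_ordering_by_descending_size(self):
        mask = np.zeros((30, 30, 10), dtype=bool)
        mask[1:11, 1:11, 2:7] = True  # 500
        mask[15:24, 15:25, 2:7] = True  # 450
        sig = Volume3D(mask, SPACING, space="atlas")
        cs = extract_clusters(sig, min_size_vox=100)
        assert cs.records["n_voxels"].tolist() == [500, 450]
        assert cs.records["cluster_id"].tolist() == [1, 2]
        lab = cs.labels.values
        assert (lab[1:11, 1:11, 2:7] == 1).all()
        assert (lab[15:24, 15:25, 2:7] == 2).all()

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_random_sparse_masks_match_flood_fill(self, connectivity):
        rng = np.random.default_rng(4)
        for _ in range(10):
            mask = rng.random((16, 16, 16)) > 0.9
            sig = Volume3D(mask, SPACING, space="atlas")
            cs = extract_clusters(sig, min_size_vox=1, connectivity=connectivity)
            n, sizes = flood_fill_components(mask, connectivity)
            assert len(cs.records) == n
            assert cs.records["n_voxels"].tolist() == sizes

    def test_volume_mm3_from_spacing(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[0:5, 0, 0] = True
        sig = Volume3D(mask, (10.0, 20.0, 10.0), space="atlas")
        cs = extract_clusters(sig, min_size_vox=1)
        assert cs.records.iloc[0]["volume_mm3"] == pytest.approx(5 * 10 * 20 * 10 * 1e-9)
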