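import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import voxmap as vm
from voxmap.cluster_validate import (
    UndefinedDensityError,
    cell_count,
    cell_density,
    label_density,
    one_tailed_t,
    validate_all,
    validate_cluster,
    warp_cluster_to_tissue,
)
from voxmap.segment import SegmentationMask
from voxmap.volio import AffineTransform, GroupDesign, Volume3D
from voxmap.voxelstats import extract_clusters

from oracles import flood_fill_components, pooled_t_scalar

SPACING = (10.0, 10.0, 10.0)


def _mask_vol(arr, spacing=SPACING, space="tissue"):
    return Volume3D(np.asarray(arr, dtype=bool), spacing, space=space)


def _seg(arr, kind="aggregate"):
    return SegmentationMask(_mask_vol(arr), label_kind=kind)


class TestWarpClusterToTissue:
    def test_identity_same_grid(self):
        rng = np.random.default_rng(0)
        cl = rng.random((12, 12, 12)) > 0.8
        out = warp_cluster_to_tissue(
            _mask_vol(cl, space="atlas"), AffineTransform.identity(), (12, 12, 12), SPACING
        )
        assert out.values.dtype == bool
        assert np.array_equal(out.values, cl)

    def test_two_times_upsampling_scales_box_by_eight(self):
        cl = np.zeros((16, 16, 16), dtype=bool)
        cl[4:8, 5:9, 6:10] = True  # 4^3 = 64 voxels
        out = warp_cluster_to_tissue(
            _mask_vol(cl, (10, 10, 10), space="atlas"),
            AffineTransform.identity(),
            (32, 32, 32),
            (5.0, 5.0, 5.0),
        )
        assert int(out.values.sum()) == 64 * 8

    def test_nonempty_when_overlapping(self):
        cl = np.zeros((8, 8, 8), dtype=bool)
        cl[4, 4, 4] = True
        out = warp_cluster_to_tissue(
            _mask_vol(cl, space="atlas"), AffineTransform.identity(), (8, 8, 8), SPACING
        )
        assert out.values.any()


class TestDensities:
    def test_label_density_superset_is_100(self):
        cl = np.zeros((6, 6, 6), dtype=bool)
        cl[1:4, 1:4, 1:4] = True
        assert label_density(_seg(np.ones((6, 6, 6))), _mask_vol(cl)) == 100.0

    def test_label_density_disjoint_is_0(self):
        cl = np.zeros((6, 6, 6), dtype=bool)
        cl[0, 0, 0] = True
        assert label_density(_seg(np.zeros((6, 6, 6))), _mask_vol(cl)) == 0.0

    def test_label_density_hand_tally(self):
        cl = np.zeros((6, 6, 6), dtype=bool)
        cl[0, 0, 0:12].flat = True  # placeholder; set explicit 12 voxels below
        cl[:] = False
        cl[0, 0, :6] = True
        cl[1, 0, :6] = True  # 12 cluster voxels
        seg = np.zeros((6, 6, 6), dtype=bool)
        seg[0, 0, 0] = seg[0, 0, 3] = seg[1, 0, 5] = True  # 3 inside
        seg[5, 5, 5] = True  # outside the cluster
        assert label_density(_seg(seg), _mask_vol(cl)) == 25.0

    def test_empty_cluster_is_error(self):
        with pytest.raises(UndefinedDensityError):
            label_density(_seg(np.ones((4, 4, 4))), _mask_vol(np.zeros((4, 4, 4))))

    def test_cell_count_two_isolated_voxels(self):
        cells = np.zeros((8, 8, 8), dtype=bool)
        cells[1, 1, 1] = cells[5, 5, 5] = True
        cl = np.ones((8, 8, 8), dtype=bool)
        assert cell_count(_seg(cells, "cell"), _mask_vol(cl)) == 2

    def test_diagonal_pair_counts_two_at_connectivity_6(self):
        cells = np.zeros((8, 8, 8), dtype=bool)
        cells[3, 3, 3] = cells[4, 4, 3] = True  # touch only diagonally
        cl = np.ones((8, 8, 8), dtype=bool)
        assert cell_count(_seg(cells, "cell"), _mask_vol(cl)) == 2
        n6, _ = flood_fill_components(cells, 6)
        n26, _ = flood_fill_components(cells, 26)
        assert (n6, n26) == (2, 1)  # the oracle distinguishes the conventions

    def test_face_adjacent_pair_counts_one(self):
        cells = np.zeros((8, 8, 8), dtype=bool)
        cells[3, 3, 3] = cells[3, 3, 4] = True
        assert cell_count(_seg(cells, "cell"), _mask_vol(np.ones((8, 8, 8), bool))) == 1

    def test_cell_density_physical_volume(self):
        cells = np.zeros((10, 10, 10), dtype=bool)
        cells[2, 2, 2] = cells[7, 7, 7] = True
        cl = np.ones((10, 10, 10), dtype=bool)
        d = cell_density(_seg(cells, "cell"), _mask_vol(cl, (10.0, 10.0, 10.0)))
        expected = 2 / (1000 * 1e-6)  # 1000 voxels of 1e-6 mm^3
        assert d == pytest.approx(expected)


class TestOneTailedT:
    def test_closed_form_example(self):
        g1 = [4.0, 5.0, 6.0, 5.0]
        g2 = [1.0, 2.0, 1.0, 2.0]
        t, p = one_tailed_t(g1, g2, "group1_greater")
        t_hand = pooled_t_scalar(g1, g2)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(float(sstats.t.sf(t_hand, df=6)))
        rec = validate_cluster(
            {"a": 4, "b": 5, "c": 6, "d": 5}, {"e": 1, "f": 2, "g": 1, "h": 2},
            "group1_greater", alpha=0.05,
        )
        assert rec.valid

    def test_identical_groups_p_half_invalid(self):
        rec = validate_cluster({"a": 1, "b": 2}, {"c": 1, "d": 2}, "group1_greater", 0.05)
        assert rec.t == 0.0
        assert rec.p_one_tailed == pytest.approx(0.5)
        assert not rec.valid

    def test_direction_reversal_complements_p(self):
        g1, g2 = [4.0, 5.0, 7.0], [3.0, 3.5, 4.0]
        _, p_fwd = one_tailed_t(g1, g2, "group1_greater")
        _, p_rev = one_tailed_t(g1, g2, "group2_greater")
        assert p_fwd + p_rev == pytest.approx(1.0)

    def test_zero_variance_equal_means_p_one(self):
        t, p = one_tailed_t([2.0, 2.0], [2.0, 2.0], "group1_greater")
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_separated_means(self):
        _, p = one_tailed_t([3.0, 3.0], [1.0, 1.0], "group1_greater")
        assert p == 0.0
        _, p_rev = one_tailed_t([3.0, 3.0], [1.0, 1.0], "group2_greater")
        assert p_rev == 1.0


def _toy_validation_setup():
    """Two clusters; g1 samples carry dense label inside cluster 1."""
    shape = (16, 16, 16)
    sig = np.zeros(shape, dtype=bool)
    sig[2:8, 2:8, 2:8] = True
    sig[10:14, 10:14, 10:14] = True
    clusters = extract_clusters(Volume3D(sig, SPACING, space="atlas"), min_size_vox=10)
    design = GroupDesign(pd.DataFrame({
        "sample_id": ["a", "b", "c", "d"],
        "group": ["g1", "g1", "g2", "g2"],
    }))
    rng = np.random.default_rng(8)
    segs, transforms, grids = {}, {}, {}
    for s in ["a", "b", "c", "d"]:
        seg = np.zeros(shape, dtype=bool)
        frac = 0.6 if s in ("a", "b") else 0.1
        sel = rng.random(shape) < frac
        seg[2:8, 2:8, 2:8] = sel[2:8, 2:8, 2:8]
        segs[s] = _seg(seg)
        transforms[s] = AffineTransform.identity()
        grids[s] = (shape, SPACING)
    return clusters, segs, transforms, grids, design


class TestValidateAll:
    def test_empty_cluster_set_gives_empty_report(self):
        clusters = extract_clusters(
            Volume3D(np.zeros((8, 8, 8), dtype=bool), SPACING, space="atlas"), 1
        )
        design = GroupDesign(pd.DataFrame({
            "sample_id": list("abcd"), "group": ["g1", "g1", "g2", "g2"],
        }))
        report = validate_all(clusters, {}, {}, {}, design)
        assert report.records == []

    def test_enriched_cluster_valid_in_effect_direction(self):
        clusters, segs, transforms, grids, design = _toy_validation_setup()
        report = validate_all(clusters, segs, transforms, grids, design,
                              metric="label_density_pct", alpha=0.05)
        by_id = {r.cluster_id: r for r in report.records}
        assert by_id[1].valid  # the enriched cluster
        assert set(report.valid_cluster_ids) <= set(clusters.cluster_ids)

    def test_sample_order_invariance(self):
        clusters, segs, transforms, grids, design = _toy_validation_setup()
        r1 = validate_all(clusters, segs, transforms, grids, design)
        shuffled = GroupDesign(design.table.iloc[[3, 1, 2, 0]].reset_index(drop=True))
        r2 = validate_all(clusters, segs, transforms, grids, shuffled)
        for a, b in zip(r1.records, r2.records):
            assert a.cluster_id == b.cluster_id
            assert a.per_sample == b.per_sample
            assert a.p_one_tailed == pytest.approx(b.p_one_tailed)

    def test_missing_sample_binding_rejected(self):
        clusters, segs, transforms, grids, design = _toy_validation_setup()
        del segs["a"]
        with pytest.raises(KeyError):
            validate_all(clusters, segs, transforms, grids, design)
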