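"""Channel detection, skeleton graph, flow routing, Hack ordering and the
network statistics, validated against brute-force oracles and fixture
ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from marshnet.fixtures import FixtureSpec, make_dtm, make_random_mask
from marshnet.network import (ChannelMask, DTMRaster, analyze_dtm,
                              bifurcation_ratios, detect_channels,
                              exceedance, exceedance_at, flow_accumulation,
                              hack_order, hortonian_drainage_density,
                              ks_similarity, orient_skeleton,
                              pattern_correlation, skeletonize,
                              stream_counts, unchanneled_path_length,
                              watershed_areas)


def brute_force_edt(mask: np.ndarray, px: float) -> np.ndarray:
    rr, cc = np.nonzero(mask)
    out = np.empty(mask.shape)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            out[i, j] = np.sqrt((rr - i) ** 2 + (cc - j) ** 2).min()
    return out * px


class TestDetection:
    def test_flat_plane_has_no_channels(self):
        dtm = DTMRaster(np.zeros((32, 32)), 0.5)
        assert detect_channels(dtm, 3.0, 0.01).count == 0

    def test_carved_channel_recovered_exactly(self):
        spec = FixtureSpec(kind="straight-channel", channel_depth=0.3)
        dtm, gt = make_dtm(spec)
        mask = detect_channels(dtm, 5.0, 0.05)
        assert np.array_equal(mask.mask, gt.channel_pixels)

    def test_threshold_monotonicity(self):
        dtm, _ = make_dtm(FixtureSpec(kind="nested-orders"))
        loose = detect_channels(dtm, 5.0, 0.02).mask
        tight = detect_channels(dtm, 5.0, 0.2).mask
        assert np.all(tight <= loose)

    def test_window_must_span_a_pixel(self):
        dtm = DTMRaster(np.zeros((8, 8)), 0.5)
        with pytest.raises(ValueError):
            detect_channels(dtm, 0.1, 0.01)

    def test_nodata_cells_are_excluded(self):
        elev = np.zeros((16, 16))
        nodata = np.zeros((16, 16), bool)
        nodata[:4, :4] = True
        elev[:4, :4] = -99.0    # extreme values hidden behind the mask
        dtm = DTMRaster(elev, 0.5, nodata)
        mask = detect_channels(dtm, 2.0, 0.01)
        assert not mask.mask[:4, :4].any()
        assert not mask.mask[4:, 4:].any()


class TestDistanceTransform:
    def test_pythagorean_offset(self):
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True
        upl = unchanneled_path_length(ChannelMask(mask, 0.5))
        assert upl[3, 4] == pytest.approx(2.5)     # 3-4-5 triangle
        assert upl[0, 0] == 0.0

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            unchanneled_path_length(ChannelMask(np.zeros((5, 5), bool), 0.5))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_masks(self, seed):
        mask = make_random_mask((64, 64), 0.01, seed)
        upl = unchanneled_path_length(ChannelMask(mask, 0.5))
        assert np.array_equal(upl, brute_force_edt(mask, 0.5))


class TestSkeleton:
    def test_straight_channel_single_section(self):
        spec = FixtureSpec(kind="straight-channel")
        dtm, gt = make_dtm(spec)
        skel = skeletonize(ChannelMask(gt.channel_pixels, 0.5))
        assert len(skel.sections) == 1
        assert skel.total_length == pytest.approx(gt.total_length,
                                                  abs=2 * 0.5)

    def test_y_junction_topology(self):
        dtm, gt = make_dtm(FixtureSpec(kind="y-junction"))
        skel = skeletonize(ChannelMask(gt.channel_pixels, 0.5))
        orient_skeleton(skel, dtm=dtm)
        assert len(skel.sections) == 3
        kinds = [skel.node_kind(n) for n in skel.graph.nodes]
        assert kinds.count("junction") == 1
        assert kinds.count("head") == 2
        assert kinds.count("outlet") == 1

    def test_resampled_spacing(self):
        dtm, gt = make_dtm(FixtureSpec(kind="y-junction"))
        skel = skeletonize(ChannelMask(gt.channel_pixels, 0.5))
        for sec in skel.sections:
            gaps = np.diff(sec.point_arc)
            if gaps.size:
                assert np.allclose(gaps, 0.5, atol=1e-9)

    def test_single_pixel_mask(self):
        mask = np.zeros((8, 8), bool)
        mask[4, 4] = True
        skel = skeletonize(ChannelMask(mask, 0.5))
        assert len(skel.graph.nodes) == 1


class TestFlowRouting:
    def test_tilted_plane_outlet_collects_everything(self):
        grid = np.arange(10)[::-1][:, None] * 0.001 * np.ones((10, 10))
        acc = flow_accumulation(DTMRaster(grid, 0.5))
        # every column drains straight down its own rows
        assert np.allclose(acc[-1, :], 10 * 0.25)
        assert acc.max() == pytest.approx(10 * 0.25)
        # non-decreasing downstream along each column
        assert np.all(np.diff(acc, axis=0) >= 0)

    def test_two_branch_partition_matches_analysis(self):
        spec = FixtureSpec(kind="two-branch-basin")
        dtm, gt = make_dtm(spec)
        acc = flow_accumulation(dtm)
        j1, j2 = np.nonzero(gt.channel_pixels[0])[0]
        assert acc[-1, j1] == pytest.approx(gt.branch_areas["left"])
        assert acc[-1, j2] == pytest.approx(gt.branch_areas["right"])

    def test_pit_is_filled_and_drains(self):
        grid = np.arange(12)[::-1][:, None] * 0.01 * np.ones((12, 12))
        grid[5:7, 5:7] -= 0.5           # a closed depression
        acc = flow_accumulation(DTMRaster(grid, 1.0))
        assert acc[-1, :].sum() + acc[0, :].sum() >= grid.size * 0.5
        assert np.isfinite(acc).all()

    def test_area_non_decreasing_downstream_on_fixture(self):
        dtm, gt = make_dtm(FixtureSpec(kind="nested-orders"))
        skel = gt.to_skeleton(0.5, dtm.shape)
        orient_skeleton(skel, dtm=dtm)
        watershed_areas(dtm, skel)
        for sec in skel.sections:
            # arc increases upstream, so area must not increase with arc
            assert np.all(np.diff(sec.area) <= 1e-9)


class TestHackOrdering:
    def test_single_channel_all_order_one(self):
        dtm, gt = make_dtm(FixtureSpec(kind="straight-channel"))
        skel = gt.to_skeleton(0.5, dtm.shape)
        orient_skeleton(skel, dtm=dtm)
        hack_order(skel)
        assert [s.order for s in skel.sections] == [1]
        assert list(stream_counts(skel)) == [1]

    def test_nested_orders_recovered(self):
        dtm, gt = make_dtm(FixtureSpec(kind="nested-orders"))
        skel = gt.to_skeleton(0.5, dtm.shape)
        orient_skeleton(skel, dtm=dtm)
        watershed_areas(dtm, skel)
        hack_order(skel)
        orders = sorted({(s.order, s.subbasin) for s in skel.sections})
        assert sorted(o for o, _ in orders) == gt.stream_orders
        assert list(stream_counts(skel)) == list(gt.stream_counts)
        skel.consistency_check()

    def test_every_section_ordered_once(self):
        dtm, gt = make_dtm(FixtureSpec(kind="nested-orders"))
        skel = gt.to_skeleton(0.5, dtm.shape)
        orient_skeleton(skel, dtm=dtm)
        hack_order(skel)
        assert all(s.order is not None for s in skel.sections)
        # sections grouped by subbasin partition the section set
        total = sum(
            sum(1 for s in skel.sections if s.subbasin == b)
            for b in {s.subbasin for s in skel.sections})
        assert total == len(skel.sections)

    def test_order_invariant_under_section_relabeling(self):
        dtm, gt = make_dtm(FixtureSpec(kind="nested-orders"))
        skel = gt.to_skeleton(0.5, dtm.shape)
        orient_skeleton(skel, dtm=dtm)
        hack_order(skel)
        baseline = sorted(s.order for s in skel.sections)
        relabeled = gt.to_skeleton(0.5, dtm.shape)
        relabeled.sections = relabeled.sections[::-1]
        for i, s in enumerate(relabeled.sections):
            s.id = i
        for _, _, d in relabeled.graph.edges(data=True):
            d["section"] = len(relabeled.sections) - 1 - d["section"]
        orient_skeleton(relabeled, dtm=dtm)
        hack_order(relabeled)
        assert sorted(s.order for s in relabeled.sections) == baseline


class TestStatistics:
    def test_bifurcation_ratio_examples(self):
        assert list(bifurcation_ratios([2, 6])) == [3.0]
        assert list(bifurcation_ratios([1, 2, 1])) == [2.0, 0.5]
        assert bifurcation_ratios([5]).size == 0

    def test_drainage_density(self):
        dtm, gt = make_dtm(FixtureSpec(kind="straight-channel"))
        skel = gt.to_skeleton(0.5, dtm.shape)
        assert hortonian_drainage_density(skel, 1000.0) == pytest.approx(
            gt.total_length / 1000.0)
        doubled = gt.to_skeleton(1.0, dtm.shape)   # doubled pixel size
        assert hortonian_drainage_density(doubled, 1000.0) == pytest.approx(
            2 * gt.total_length / 1000.0)
        with pytest.raises(ValueError):
            hortonian_drainage_density(skel, 0.0)

    def test_exceedance_basics(self):
        assert exceedance_at([1, 2, 3, 4], 2.5)[0] == pytest.approx(0.5)
        assert exceedance_at([1, 2, 3, 4], 0.0)[0] == 1.0
        assert exceedance_at([1, 2, 3, 4], 4.0)[0] == 0.0
        with pytest.raises(ValueError):
            exceedance([])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_exceedance_matches_counting(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.exponential(10.0, size=1000)
        probes = rng.uniform(0, 40, size=20)
        expected = np.array([(x > q).sum() / x.size for q in probes])
        assert np.allclose(exceedance_at(x, probes), expected)

    def test_exceedance_curve_is_nonincreasing_and_order_invariant(self):
        rng = np.random.default_rng(7)
        x = rng.gamma(2.0, 5.0, 500)
        vals, probs = exceedance(x)
        assert np.all(np.diff(probs) <= 0)
        vals2, probs2 = exceedance(x[::-1])
        assert np.array_equal(vals, vals2)
        assert np.array_equal(probs, probs2)

    def test_ks_similarity_endpoints_and_example(self):
        a = np.array([1.0, 2.0, 3.0])
        sim, p = ks_similarity(a, a)
        assert sim == 1.0
        sim, _ = ks_similarity([1, 2, 3], [10, 20, 30])
        assert sim == 0.0
        sim, _ = ks_similarity([1, 2], [1, 3])
        assert sim == pytest.approx(0.5)           # sup ECDF gap = 0.5
        sim_o, _ = ks_similarity([2, 1], [3, 1])   # order invariance
        assert sim_o == sim
        with pytest.raises(ValueError):
            ks_similarity([], [1.0])

    def test_pattern_correlation(self, rng):
        S = rng.standard_normal((50, 50))
        assert pattern_correlation(S, 2 * S + 1) == pytest.approx(1.0)
        assert pattern_correlation(S, -S) == pytest.approx(-1.0)
        other = rng.standard_normal((100, 100))
        noise = rng.standard_normal((100, 100))
        assert abs(pattern_correlation(other, noise)) < 0.05
        with pytest.raises(ValueError):
            pattern_correlation(np.ones((4, 4)), S[:4, :4])


class TestEndToEnd:
    @pytest.mark.parametrize("kind", ["straight-channel", "y-junction",
                                      "nested-orders"])
    def test_pipeline_recovers_ground_truth(self, kind):
        dtm, gt = make_dtm(FixtureSpec(kind=kind))
        mask, skel, stats = analyze_dtm(dtm, 3.0, 0.05)
        assert np.array_equal(mask.mask, gt.channel_pixels)
        assert list(stats.stream_counts) == list(gt.stream_counts)
        assert stats.max_order == len(gt.stream_counts)
        # thinning pulls centerline ends back from the mask ends by a few
        # pixels per section, so total length is only approximate
        assert stats.total_length == pytest.approx(gt.total_length,
                                                   rel=0.15)

    def test_featureless_terrain_yields_empty_stats(self):
        dtm = DTMRaster(np.zeros((32, 32)), 0.5)
        mask, skel, stats = analyze_dtm(dtm, 3.0, 0.05)
        assert skel is None
        assert stats.max_order == 0
        assert stats.drainage_density == 0.0
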