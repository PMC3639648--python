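import numpy as np
import pytest

from vesselcut.graphcut_seg import (
    B_C,
    B_D,
    F_C,
    F_D,
    NEIGHBOR_OFFSETS,
    PipelineConfig,
    SegGraph,
    assign_seeds,
    build_graph,
    extract_centerline,
    labeling_energy,
    min_cut_segment,
    quantize_capacity,
    seed_distances,
    segment,
)
from vesselcut.io_fixtures import Image2D
from _oracles import enumerate_min_energy


def random_graph(rng, H=3, W=4, k=1.0, eta=0.05):
    """A random but well-formed SegGraph with one F_d and one B_d seed."""
    vl_sym = rng.random((H, W))
    intensity = rng.random((H, W))
    centerline = np.zeros((H, W), dtype=bool)
    centerline[rng.integers(H), rng.integers(W)] = True
    seeds = assign_seeds(vl_sym, centerline, t_h=0.7, t_l=0.2)
    if not (seeds.labels == B_D).any():
        seeds.labels[np.unravel_index(np.argmin(vl_sym + centerline),
                                      (H, W))] = B_D
    dist = seed_distances(seeds)
    return build_graph(intensity, seeds, dist, vl_sym, k=k, eta=eta)


class TestExtractCenterline:
    def test_empty_mask_gives_empty_centerline(self):
        assert not extract_centerline(np.zeros((8, 8), bool)).any()

    def test_solid_bar_thins_to_single_pixel_path(self):
        mask = np.zeros((15, 25), dtype=bool)
        mask[5:10, 2:23] = True  # 21x5 bar
        center = extract_centerline(mask)
        # away from the endpoints each column crosses the skeleton once
        per_column = center[:, 6:19].sum(axis=0)
        assert (per_column == 1).all()

    def test_centerline_subset_of_mask(self):
        rng = np.random.default_rng(0)
        mask = rng.random((30, 30)) < 0.4
        center = extract_centerline(mask)
        assert not (center & ~mask).any()


class TestAssignSeeds:
    def test_rule_table(self):
        vl = np.array([[0.05, 0.3, 0.9]])
        seeds = assign_seeds(vl, np.zeros((1, 3), bool), t_h=0.5, t_l=0.1)
        np.testing.assert_array_equal(seeds.labels[0], [B_D, B_C, F_C])

    def test_centerline_overrides_likeness(self):
        vl = np.zeros((2, 2))
        center = np.array([[True, False], [False, False]])
        seeds = assign_seeds(vl, center, t_h=0.5, t_l=0.1)
        assert seeds.labels[0, 0] == F_D
        assert (seeds.labels[center == False] == B_D).all()  # noqa: E712

    def test_all_background_when_no_structure(self):
        seeds = assign_seeds(np.zeros((3, 3)), np.zeros((3, 3), bool),
                             t_h=0.5, t_l=0.1)
        assert (seeds.labels == B_D).all()

    def test_classes_partition_pixels(self):
        rng = np.random.default_rng(1)
        vl = rng.random((10, 10))
        center = rng.random((10, 10)) < 0.1
        seeds = assign_seeds(vl, center, t_h=0.6, t_l=0.3)
        assert np.isin(seeds.labels, [F_D, F_C, B_C, B_D]).all()
        assert (seeds.labels[center] == F_D).all()
        off = ~center
        assert (seeds.labels[off & (vl > 0.6)] == F_C).all()
        assert (seeds.labels[off & (vl < 0.3)] == B_D).all()

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            assign_seeds(np.zeros((2, 2)), np.zeros((2, 2), bool),
                         t_h=0.2, t_l=0.5)


class TestSeedDistances:
    def test_row_example(self):
        labels = np.full((1, 5), B_C, dtype=np.int8)
        labels[0, 0] = F_D
        labels[0, 4] = B_D
        seeds = assign_seeds(np.full((1, 5), 0.4),
                             labels == F_D, t_h=0.5, t_l=0.1)
        seeds.labels = labels
        dist = seed_distances(seeds)
        assert dist.d_f[0, 1] == pytest.approx(1.0)
        assert dist.d_b[0, 1] == pytest.approx(3.0)
        assert dist.D_F[0, 1] == pytest.approx(0.25)

    def test_seed_pixels_have_extreme_normalized_distance(self):
        rng = np.random.default_rng(2)
        center = np.zeros((8, 8), bool)
        center[2, 3] = True
        seeds = assign_seeds(rng.random((8, 8)), center, t_h=2.0, t_l=0.2)
        dist = seed_distances(seeds)
        assert dist.D_F[2, 3] == 0.0
        assert (dist.D_F[seeds.labels == B_D] == 1.0).all()

    def test_df_db_sum_to_one(self):
        rng = np.random.default_rng(3)
        center = np.zeros((10, 10), bool)
        center[5, 5] = True
        seeds = assign_seeds(rng.random((10, 10)), center, t_h=0.8, t_l=0.3)
        dist = seed_distances(seeds)
        np.testing.assert_allclose(dist.D_F + dist.D_B, 1.0, atol=1e-12)
        assert dist.D_F.min() >= 0.0 and dist.D_F.max() <= 1.0

    def test_geodesic_distances_exceed_euclidean_across_edges(self):
        labels = np.full((5, 9), B_C, dtype=np.int8)
        labels[2, 0] = F_D
        labels[2, 8] = B_D
        seeds = assign_seeds(np.full((5, 9), 0.4), labels == F_D,
                             t_h=0.5, t_l=0.1)
        seeds.labels = labels
        intensity = np.zeros((5, 9))
        intensity[:, 4:] = 1.0  # a hard edge in the middle
        d_eu = seed_distances(seeds)
        d_geo = seed_distances(seeds, metric="geodesic", intensity=intensity)
        assert d_geo.d_f[2, 8] > d_eu.d_f[2, 8]

    def test_empty_seed_set_rejected(self):
        seeds = assign_seeds(np.zeros((3, 3)), np.zeros((3, 3), bool),
                             t_h=0.5, t_l=0.1)  # all B_d, no F_d
        with pytest.raises(ValueError):
            seed_distances(seeds)


class TestBuildGraph:
    def _simple(self, vl=0.8, df=0.4):
        labels = np.array([[F_D, F_C], [B_C, B_D]], dtype=np.int8)
        seeds = assign_seeds(np.full((2, 2), 0.4),
                             labels == F_D, t_h=0.5, t_l=0.1)
        seeds.labels = labels

        class D:
            D_F = np.full((2, 2), df)
            D_B = 1.0 - np.full((2, 2), df)

        return seeds, D()

    def test_seed_tlinks_are_hard(self):
        seeds, dist = self._simple()
        g = build_graph(np.zeros((2, 2)), seeds, dist,
                        np.full((2, 2), 0.8))
        assert g.u_s[0, 0] == g.inf_cap and g.u_t[0, 0] == 0.0
        assert g.u_s[1, 1] == 0.0 and g.u_t[1, 1] == g.inf_cap

    def test_candidate_tlink_values(self):
        seeds, dist = self._simple()
        g = build_graph(np.zeros((2, 2)), seeds, dist,
                        np.full((2, 2), 0.8), w1=2.0, w2=0.5)
        # F_c at (0,1): U_S = 2*0.8/0.4 = 4, U_T = 0.5*0.8/0.4 = 1
        assert g.u_s[0, 1] == pytest.approx(4.0, abs=1e-12)
        assert g.u_t[0, 1] == pytest.approx(1.0, abs=1e-12)
        # B_c at (1,0): swapped pair
        assert g.u_s[1, 0] == pytest.approx(1.0, abs=1e-12)
        assert g.u_t[1, 0] == pytest.approx(4.0, abs=1e-12)

    def test_nlink_contrast_formula(self):
        seeds, dist = self._simple()
        intensity = np.array([[0.5, 0.5], [0.2, 0.9]])
        g = build_graph(intensity, seeds, dist, np.full((2, 2), 0.8),
                        k=1.0, eta=0.01)
        # equal-intensity horizontal neighbors: 1/(0 + 0.01) = 100
        assert g.nlinks[(0, 1)][0, 0] == pytest.approx(100.0, abs=1e-9)
        # vertical pair (0,0)-(1,0): 1/(0.3 + 0.01)
        assert g.nlinks[(1, 0)][0, 0] == pytest.approx(1 / 0.31, abs=1e-9)

    def test_nlinks_scale_with_k(self):
        seeds, dist = self._simple()
        g1 = build_graph(np.zeros((2, 2)), seeds, dist,
                         np.full((2, 2), 0.8), k=1.0)
        g3 = build_graph(np.zeros((2, 2)), seeds, dist,
                         np.full((2, 2), 0.8), k=3.0)
        for off in NEIGHBOR_OFFSETS:
            np.testing.assert_allclose(g3.nlinks[off], 3.0 * g1.nlinks[off])

    def test_use_db_for_bc_switch(self):
        seeds, dist = self._simple(df=0.25)
        g = build_graph(np.zeros((2, 2)), seeds, dist,
                        np.full((2, 2), 0.8), w1=2.0, w2=0.5,
                        use_db_for_bc=True)
        # B_c at (1,0) now divides by D_B = 0.75
        assert g.u_t[1, 0] == pytest.approx(2.0 * 0.8 / 0.75, abs=1e-12)

    def test_weight_order_enforced(self):
        seeds, dist = self._simple()
        with pytest.raises(ValueError):
            build_graph(np.zeros((2, 2)), seeds, dist,
                        np.full((2, 2), 0.8), w1=0.9, w2=0.5)


class TestMinCut:
    def test_two_pixel_enumeration(self):
        u_s = np.array([[5.0, 0.0]])
        u_t = np.array([[0.0, 5.0]])
        nlinks = {off: np.zeros((1, 2)) for off in NEIGHBOR_OFFSETS}
        nlinks[(0, 1)][0, 0] = 1.0
        g = SegGraph(u_s=u_s, u_t=u_t, nlinks=nlinks, inf_cap=1e9)
        res = min_cut_segment(g)
        np.testing.assert_array_equal(res.mask, [[True, False]])
        assert res.energy == pytest.approx(1.0, abs=1e-9)
        assert res.flow == pytest.approx(1.0, rel=1e-6)

    def test_energy_matches_exhaustive_enumeration(self):
        """On twenty random 3x4 graphs the cut's energy equals the brute
        minimum over all 2^12 labelings."""
        for trial in range(20):
            rng = np.random.default_rng(100 + trial)
            g = random_graph(rng)
            res = min_cut_segment(g)
            best, best_lab = enumerate_min_energy(g.u_s, g.u_t, g.nlinks)
            assert res.energy == pytest.approx(best, rel=1e-9, abs=1e-9), \
                f"trial {trial}"
            # and the returned labeling achieves it
            assert labeling_energy(g, res.mask) == pytest.approx(
                best, rel=1e-9, abs=1e-9)

    def test_flow_equals_cut_capacity_exactly_in_solver_units(self):
        for trial in range(5):
            rng = np.random.default_rng(300 + trial)
            g = random_graph(rng, H=6, W=7)
            res = min_cut_segment(g)
            scale = res.capacity_scale
            cut = 0
            cut += quantize_capacity(g.u_t, scale, g.inf_cap)[res.mask].sum()
            cut += quantize_capacity(g.u_s, scale, g.inf_cap)[~res.mask].sum()
            H, W = res.mask.shape
            for (dr, dc), cap in g.nlinks.items():
                capq = quantize_capacity(cap, scale, g.inf_cap)
                for r in range(H):
                    for c in range(W):
                        r2, c2 = r + dr, c + dc
                        if 0 <= r2 < H and 0 <= c2 < W and \
                                res.mask[r, c] != res.mask[r2, c2]:
                            cut += capq[r, c]
            assert int(cut) == res.flow_units

    def test_seed_respect(self):
        for trial in range(5):
            rng = np.random.default_rng(200 + trial)
            g = random_graph(rng, H=5, W=5)
            res = min_cut_segment(g)
            assert res.mask[g.u_s >= g.inf_cap].all()
            assert not res.mask[g.u_t >= g.inf_cap].any()

    def test_all_foreground_when_everything_seeded(self):
        H, W = 3, 3
        u_s = np.full((H, W), 10.0)
        u_t = np.zeros((H, W))
        nlinks = {off: np.ones((H, W)) for off in NEIGHBOR_OFFSETS}
        g = SegGraph(u_s=u_s, u_t=u_t, nlinks=nlinks, inf_cap=10.0)
        res = min_cut_segment(g)
        assert res.mask.all()
        assert res.flow == pytest.approx(0.0, abs=1e-12)


class TestSegmentPipeline:
    def test_constant_image_yields_empty_mask(self):
        with pytest.warns(UserWarning):
            res = segment(Image2D(np.full((40, 40), 0.6)))
        assert not res.mask.any()

    def test_determinism(self, vessel_disk_phantom):
        a = segment(vessel_disk_phantom.image)
        b = segment(vessel_disk_phantom.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_mask_contains_centerline_and_avoids_bd(self, vessel_disk_phantom):
        res, stages = segment(vessel_disk_phantom.image, return_stages=True)
        seeds = stages["seeds"]
        assert res.mask[seeds.labels == F_D].all()
        assert not res.mask[seeds.labels == B_D].any()

    def test_smoothness_reduces_isolated_pixels(self, vessel_disk_phantom):
        from scipy import ndimage as ndi

        def isolated(mask):
            lab, n = ndi.label(mask, structure=np.ones((3, 3)))
            if n == 0:
                return 0
            return int((np.bincount(lab.ravel())[1:] == 1).sum())

        low = segment(vessel_disk_phantom.image, PipelineConfig(k=0.5))
        high = segment(vessel_disk_phantom.image, PipelineConfig(k=5.0))
        assert isolated(high.mask) <= isolated(low.mask)

    def test_fov_mask_restricts_output(self, vessel_disk_phantom):
        px = vessel_disk_phantom.image.pixels
        fov = np.zeros(px.shape, dtype=bool)
        fov[:, :64] = True
        res = segment(Image2D(px, fov_mask=fov))
        assert not res.mask[~fov].any()

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = PipelineConfig(k=2.5, scales=(1.0, 2.0), t_num=12)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        loaded = PipelineConfig.from_yaml(p)
        assert loaded == cfg
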