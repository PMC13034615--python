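import numpy as np
import pytest

from lamvaso.depth import (DISTANCE_BIN_EDGES_MM, bin_layers, column_field,
                           compute_depth, distance_bins, euclidean_distance_map,
                           geodesic_distance, make_disk, n_distance_bins,
                           resample_depth)
from lamvaso.grids import Segmentation, Volume3D
from lamvaso.phantom import PhantomSpec, build_anatomical, build_ribbon, build_slab


@pytest.fixture(scope="module")
def small_shell():
    spec = PhantomSpec(domain_shape=(48, 48, 12), shell_inner_radius_mm=10.0,
                       shell_outer_radius_mm=12.0)
    seg, depth_truth = build_ribbon(spec)
    return spec, seg, depth_truth


class TestDepth:
    def test_annulus_mid_depth_value(self, small_shell):
        # voxel at r = 11 on the r_w=10/r_p=12 shell: alpha = 23/44 = 0.5227
        spec, seg, truth = small_shell
        seg_fine, _ = build_anatomical(spec)
        alpha = resample_depth(compute_depth(seg_fine, "equivolume"), seg)
        h = np.asarray(spec.voxel_size_mm)
        idx = np.indices(seg.gm_mask.shape)
        r = np.hypot((idx[0] + 0.5) * h[0], (idx[1] + 0.5) * h[1])
        near = seg.gm_mask & (np.abs(r - 11.0) < 0.15)
        assert near.sum() > 10
        # the voxel at exactly r=11 has alpha = 23/44; voxels in the band are
        # compared against the closed form at their own radius
        assert np.nanmean(alpha.data[near]) == pytest.approx(23 / 44, abs=0.03)
        from lamvaso.phantom import annulus_equivolume_depth

        ref = annulus_equivolume_depth(r[near], 10.0, 12.0)
        assert np.nanmax(np.abs(alpha.data[near] - ref)) < 0.03

    def test_boundary_voxels_near_0_and_1(self, small_shell):
        spec, seg, truth = small_shell
        alpha = compute_depth(seg, "equivolume")
        gm = seg.gm_mask
        # most superficial / deepest voxels approach the surface values
        assert np.nanmin(alpha.data[gm]) < 0.2
        assert np.nanmax(alpha.data[gm]) > 0.8

    def test_equivolume_beats_equidistant_on_curved_shell(self, small_shell):
        # discriminating check: the curvature correction must reduce the error
        spec, seg, truth = small_shell
        gm = seg.gm_mask
        e_ev = np.nanmean(np.abs(compute_depth(seg, "equivolume").data - truth.data)[gm])
        e_ed = np.nanmean(np.abs(compute_depth(seg, "equidistant").data - truth.data)[gm])
        assert e_ev < e_ed

    def test_slab_equivolume_equals_equidistant(self):
        seg, truth = build_slab(PhantomSpec())
        gm = seg.gm_mask
        ev = compute_depth(seg, "equivolume").data
        ed = compute_depth(seg, "equidistant").data
        assert np.nanmax(np.abs(ev - ed)[gm]) < 0.02

    def test_missing_compartment_warns(self):
        labels = np.full((8, 8, 8), 2, dtype=np.int16)
        seg = Segmentation(Volume3D(labels, (0.5,) * 3))
        with pytest.warns(UserWarning, match="lacks"):
            out = compute_depth(seg)
        assert np.isnan(out.data).all()


class TestLayers:
    def test_bin_examples(self):
        data = np.full((1, 1, 3), np.nan)
        data[0, 0] = [0.5, 0.0, 1.0]
        d = Volume3D(data, (0.5,) * 3)
        assert list(bin_layers(d, 3)[0, 0]) == [2, 1, 3]
        assert list(bin_layers(d, 11)[0, 0]) == [6, 1, 11]

    def test_bins_partition_gm(self, small_shell):
        spec, seg, truth = small_shell
        lab = bin_layers(truth, 11)
        gm = seg.gm_mask
        assert np.all(lab[gm] >= 1) and np.all(lab[gm] <= 11)
        assert np.all(lab[~gm] == 0)

    def test_uniform_depth_gives_near_equal_occupancy(self):
        # oracle: histogram of uniform alpha values across equal-width bins
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 1, size=(20, 20, 5))
        lab = bin_layers(Volume3D(data, (0.5,) * 3), 11)
        counts = np.bincount(lab.ravel())[1:]
        assert counts.max() / counts.min() < 1.3

    def test_depth_monotone_along_columns(self, small_shell):
        spec, seg, truth = small_shell
        alpha = compute_depth(seg, "equivolume")
        col = column_field(alpha)
        gm = seg.gm_mask
        coords = np.argwhere(gm & (truth.data > 0.3) & (truth.data < 0.5))[::35]
        h = np.asarray(spec.voxel_size_mm)
        for c in coords:
            vec = col[tuple(c)]
            step = np.round(vec * 1.0 / h).astype(int)  # ~1 mm along the column
            nxt = tuple(c + step)
            if gm[nxt]:
                assert alpha.data[nxt] > alpha.data[tuple(c)] - 0.02


class TestGeodesic:
    def test_straight_corridor(self):
        mask = np.zeros((12, 3, 3), dtype=bool)
        mask[1:12, 1, 1] = True
        d = geodesic_distance(mask, (1, 1, 1), (0.5, 0.5, 0.5))
        assert d[11, 1, 1] == pytest.approx(5.0)

    def test_diagonal_step_length(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = mask[2, 2, 2] = True
        d = geodesic_distance(mask, (1, 1, 1), (1.0, 1.0, 1.0))
        assert d[2, 2, 2] == pytest.approx(np.sqrt(3.0))

    def test_l_shaped_corridor_matches_networkx(self):
        import networkx as nx

        mask = np.zeros((8, 8, 1), dtype=bool)
        mask[0:8, 0, 0] = True
        mask[7, 0:8, 0] = True
        mask[3, 0:3, 0] = True  # a notch branch
        vs = (0.7, 0.9, 1.1)
        d = geodesic_distance(mask, (0, 0, 0), vs)
        g = nx.Graph()
        coords = [tuple(c) for c in np.argwhere(mask)]
        for c in coords:
            for o in np.ndindex(3, 3, 3):
                off = np.array(o) - 1
                if not off.any():
                    continue
                nb = tuple(np.array(c) + off)
                if nb in set(coords):
                    g.add_edge(c, nb, weight=float(np.linalg.norm(off * np.array(vs))))
        ref = nx.single_source_dijkstra_path_length(g, (0, 0, 0))
        for c in coords:
            assert d[c] == ref[c]

    def test_geodesic_at_least_euclidean(self, small_shell):
        spec, seg, _ = small_shell
        gm = seg.gm_mask
        seed = tuple(np.argwhere(gm)[0])
        geo = geodesic_distance(gm, seed, spec.voxel_size_mm)
        euc = euclidean_distance_map(gm, seed, spec.voxel_size_mm)
        ok = gm & np.isfinite(geo)
        assert np.all(geo[ok] >= euc[ok] - 1e-9)

    def test_seed_outside_mask_errors(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            geodesic_distance(mask, (2, 2, 2), (1, 1, 1))


class TestDisk:
    def test_huge_radius_covers_whole_ribbon(self, small_shell):
        spec, seg, truth = small_shell
        alpha = compute_depth(seg, "equivolume")
        seed = tuple(np.argwhere(seg.gm_mask)[50])
        disk = make_disk(alpha, seed, radius_mm=1000.0)
        assert disk.sum() > 0.97 * seg.gm_mask.sum()

    def test_zero_radius_single_column(self, small_shell):
        spec, seg, truth = small_shell
        alpha = compute_depth(seg, "equivolume")
        seed = tuple(np.argwhere(seg.gm_mask & (truth.data > 0.4) & (truth.data < 0.6))[0])
        disk = make_disk(alpha, seed, radius_mm=0.0)
        assert 0 < disk.sum() < 40
        assert disk[seed]

    def test_disk_arc_extent_matches_radius(self, small_shell):
        # on the cylinder, a 6 mm disk spans ~12 mm of arc at mid-depth
        spec, seg, truth = small_shell
        alpha = compute_depth(seg, "equivolume")
        gm = seg.gm_mask
        h = np.asarray(spec.voxel_size_mm)
        idx = np.indices(gm.shape)
        theta = np.arctan2((idx[1] + 0.5) * h[1], (idx[0] + 0.5) * h[0])
        mid = gm & (truth.data > 0.4) & (truth.data < 0.6)
        cand = np.argwhere(mid & (np.abs(theta - np.pi / 4) < 0.05))
        seed = tuple(cand[len(cand) // 2])
        disk = make_disk(alpha, seed, radius_mm=6.0)
        r_mid = 11.0
        arc = (theta[disk & mid].max() - theta[disk & mid].min()) * r_mid
        assert arc == pytest.approx(12.0, abs=1.5)

    def test_seed_off_gm_errors(self, small_shell):
        spec, seg, truth = small_shell
        alpha = compute_depth(seg, "equivolume")
        with pytest.raises(ValueError, match="not a gray-matter"):
            make_disk(alpha, (0, 0, 0), 5.0)


class TestDistanceBins:
    def test_bin_assignment_examples(self):
        mask = np.zeros((40, 1, 1), dtype=bool)
        mask[:, 0, 0] = True
        bins = distance_bins(mask, (0, 0, 0), (1.0, 1.0, 1.0))
        assert bins[3, 0, 0] == 2        # 3.0 mm -> [2, 4)
        assert bins[14, 0, 0] == 0       # 14.0 mm -> beyond the last edge
        assert bins[13, 0, 0] == 7       # 13.0 mm -> [12, 14)
        assert bins[0, 0, 0] == 1

    def test_seven_bins_defined(self):
        assert n_distance_bins(DISTANCE_BIN_EDGES_MM) == 7

    def test_bins_disjoint_and_within_mask(self, small_shell):
        spec, seg, _ = small_shell
        gm = seg.gm_mask
        peak = tuple(np.argwhere(gm)[200])
        bins = distance_bins(gm, peak, spec.voxel_size_mm)
        assert np.all(bins[~gm] == 0)
        assert set(np.unique(bins)) <= set(range(8))

    def test_geodesic_variant_ge_euclidean_bins(self, small_shell):
        spec, seg, _ = small_shell
        gm = seg.gm_mask
        peak = tuple(np.argwhere(gm)[200])
        be = distance_bins(gm, peak, spec.voxel_size_mm, metric="euclidean")
        bg = distance_bins(gm, peak, spec.voxel_size_mm, metric="geodesic")
        both = (be > 0) & (bg > 0)
        assert np.all(bg[both] >= be[both])
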