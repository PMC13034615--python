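import numpy as np
import pytest

from lamvaso.grids import CSF, GRAY_MATTER, WHITE_MATTER, StimDesign
from lamvaso.phantom import (DIGITS, PhantomSpec, annulus_equivolume_depth,
                             build_ribbon, build_slab, gamma_bump,
                             interleave_series, make_design, paint_digits,
                             realized_triphasic_extrema, simulate_run,
                             sustained_response, triphasic_kernel)
from lamvaso.preproc import split_interleaved


class TestRibbonGeometry:
    def test_closed_form_depth_matches_hand_value(self):
        # annulus r_w=10, r_p=12: voxel at r=11 -> (144-121)/(144-100) = 23/44
        assert annulus_equivolume_depth(11.0, 10.0, 12.0) == pytest.approx(23 / 44)
        assert annulus_equivolume_depth(12.0, 10.0, 12.0) == 0.0   # pial surface
        assert annulus_equivolume_depth(10.0, 10.0, 12.0) == 1.0   # WM surface

    def test_closed_form_matches_volume_integration(self):
        # independent oracle: alpha(r) should equal the shell-volume fraction
        # between r and r_p computed by numerical integration
        r_w, r_p = 10.0, 12.0
        rr = np.linspace(r_w, r_p, 2001)
        # cylindrical shell volume element ~ 2*pi*r dr (unit height)
        total = np.trapezoid(2 * np.pi * rr, rr)
        for r0 in (10.5, 11.0, 11.7):
            sel = rr >= r0
            frac = np.trapezoid(2 * np.pi * rr[sel], rr[sel]) / total
            assert annulus_equivolume_depth(r0, r_w, r_p) == pytest.approx(frac, abs=1e-6)

    def test_ribbon_labels_and_truth(self, small_spec):
        seg, depth = build_ribbon(small_spec)
        labels = seg.labels.data
        assert set(np.unique(labels)) <= {WHITE_MATTER, GRAY_MATTER, CSF}
        gm = seg.gm_mask
        assert gm.sum() > 0
        vals = depth.data[gm]
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.isnan(depth.data[~gm]).all()

    def test_gm_single_connected_component(self, small_spec):
        from scipy import ndimage

        seg, _ = build_ribbon(small_spec)
        _, n = ndimage.label(seg.gm_mask, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_shell_exceeding_domain_rejected(self):
        with pytest.raises(ValueError, match="exceeds domain"):
            build_ribbon(PhantomSpec(domain_shape=(16, 16, 8),
                                     shell_inner_radius_mm=10, shell_outer_radius_mm=12))

    def test_slab_depth_linear(self):
        spec = PhantomSpec()
        seg, depth = build_slab(spec, thickness_mm=3.0)
        gm = seg.gm_mask
        assert np.nanmin(depth.data[gm]) >= 0 and np.nanmax(depth.data[gm]) <= 1
        # alpha decreases with z (CSF above)
        zs = np.indices(gm.shape)[2]
        for z1, z2 in [(3, 4), (4, 5)]:
            a1 = np.nanmean(depth.data[gm & (zs == z1)])
            a2 = np.nanmean(depth.data[gm & (zs == z2)])
            assert a1 > a2


class TestPaintDigits:
    def test_zero_amplitude_gives_zero_maps(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, bold_amp_pct=0.0, cbv_amp_pct=0.0)
        seg, depth = build_ribbon(spec)
        truth = paint_digits(seg, depth, spec)
        for d in DIGITS:
            assert not truth.digit_amplitude_maps[d].data.any()
            assert not truth.cbv_amplitude_maps[d].data.any()

    def test_depth_profile_definition(self):
        from lamvaso.phantom import _depth_profile

        # linear-to-surface: maximum at the pial surface, stated floor at WM
        assert _depth_profile(0.0, "linear_to_surface", 0.3) == pytest.approx(1.0)
        assert _depth_profile(1.0, "linear_to_surface", 0.3) == pytest.approx(0.3)
        # mid-depth peak: unimodal with maximum at alpha = 0.5
        a = np.linspace(0, 1, 101)
        prof = _depth_profile(a, "mid_depth_peak", 0.4)
        assert np.argmax(prof) == 50

    def test_amplitudes_confined_to_gm(self, small_spec):
        seg, depth = build_ribbon(small_spec)
        truth = paint_digits(seg, depth, small_spec)
        gm = seg.gm_mask
        for d in DIGITS:
            assert not truth.digit_amplitude_maps[d].data[~gm].any()

    def test_default_triphasic_trends(self):
        # generator contract: A1 strictly decreasing, A2 strictly increasing
        # across surround bins
        tp = PhantomSpec().triphasic_params
        assert np.all(np.diff(tp["A1"]) < 0)
        assert np.all(np.diff(tp["A2"]) > 0)
        assert np.all(np.asarray(tp["A2"]) >= 0)  # trough stored as magnitude

    def test_overlapping_centres_warn(self, small_spec):
        import dataclasses

        spec = dataclasses.replace(small_spec, digit_centers_deg=(44.0, 45.0, 46.0))
        seg, depth = build_ribbon(spec)
        with pytest.warns(UserWarning, match="overlap"):
            truth = paint_digits(seg, depth, spec)
        assert truth.overlap_warned


class TestResponseShapes:
    def test_sustained_plateau_is_unit(self):
        t = np.linspace(0, 60, 601)
        y = sustained_response(t, 30.0)
        assert y.max() == pytest.approx(1.0, abs=1e-6)
        assert y[0] == 0.0
        assert y[-1] < 0.05  # decayed after offset

    def test_gamma_bump_peaks_at_mode(self):
        t = np.linspace(0, 40, 4001)
        for mode in (6.0, 14.0, 26.0):
            y = gamma_bump(t, mode)
            assert t[np.argmax(y)] == pytest.approx(mode, abs=0.02)
            assert y.max() == pytest.approx(1.0, abs=1e-9)

    def test_realized_extrema_ordering(self):
        tp = PhantomSpec().triphasic_params
        for i, b in enumerate(tp["bins"]):
            t1, a1, t2, a2, t3, a3 = realized_triphasic_extrema(
                tp["A1"][i], tp["t1"][i], tp["A2"][i], tp["t2"][i],
                tp["A3"][i], tp["t3"][i], 30.0)
            assert 0 < t1 < t2 <= 30.0
            assert a1 > 0 > a2
            if tp["A3"][i] > 0:
                assert 0 < t3 <= 15.4

    def test_triphasic_kernel_silent_before_onset(self):
        t = np.linspace(-20, 0, 50)
        y = triphasic_kernel(t, 0.4, 10, 0.3, 22, 0.2, 6, 30.0)
        assert np.all(y == 0)


class TestDesign:
    def test_design_valid_and_snapped(self):
        spec = PhantomSpec()
        des = make_design(spec, 5)
        all_on = sorted(t for d in DIGITS for t in des.onsets_s[d])
        assert len(all_on) == 3 * spec.n_blocks_per_digit
        # onsets land on the pairTR grid
        for t in all_on:
            assert (t / spec.pair_tr_s) == pytest.approx(round(t / spec.pair_tr_s), abs=1e-9)
        # blocks do not overlap
        assert np.all(np.diff(all_on) >= spec.block_on_s)

    def test_no_immediate_digit_repeats(self):
        spec = PhantomSpec()
        for seed in range(5):
            des = make_design(spec, seed)
            order = sorted(((t, d) for d in DIGITS for t in des.onsets_s[d]))
            seq = [d for _, d in order]
            assert all(a != b for a, b in zip(seq, seq[1:]))

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimDesign(conditions=("D2", "D3"), onsets_s={"D2": [0.0], "D3": [10.0]},
                       duration_s=30.0, run_length_volumes=100)


class TestSimulation:
    def test_seed_determinism(self, noiseless_sim):
        s = noiseless_sim
        n2, b2, m2 = simulate_run(s["seg"], s["truth"], s["design"], s["spec"], 99)
        assert np.array_equal(n2.data, s["nulled"].data)
        assert np.array_equal(b2.data, s["bold"].data)
        assert np.array_equal(m2.params, s["motion"].params)

    def test_different_seeds_differ(self, noiseless_sim):
        import dataclasses

        s = noiseless_sim
        spec_noisy = dataclasses.replace(s["spec"], noise_sd_bold=10.0)
        _, a, _ = simulate_run(s["seg"], s["truth"], s["design"], spec_noisy, 1)
        _, b, _ = simulate_run(s["seg"], s["truth"], s["design"], spec_noisy, 2)
        assert not np.array_equal(a.data, b.data)

    def test_noiseless_background_is_baseline(self, noiseless_sim):
        s = noiseless_sim
        # a corner voxel far from any patch: constant at the tissue baseline
        # (after the non-steady transient on the first three pairs)
        trace = s["bold"].data[0, 0, 0, 3:]
        assert np.allclose(trace, trace[0])

    def test_plateau_ratio_follows_cbv(self, noiseless_sim):
        # nulled/bold during a long plateau ~ (1 - v) * N0/B0
        s = noiseless_sim
        truth, spec = s["truth"], s["spec"]
        d = "D2"
        pk = truth.peak_voxel_truth[d]
        v_amp = truth.cbv_amplitude_maps[d].data[pk] / 100.0
        on = s["design"].onsets_s[d][0]
        k = int(round(on / spec.pair_tr_s)) + 6  # late in the plateau
        ratio = float(s["nulled"].data[pk][k]) / float(s["bold"].data[pk][k])
        expect = (1.0 - v_amp * 1.0) * 700.0 / 1000.0
        assert ratio == pytest.approx(expect, rel=0.02)

    def test_interleave_split_roundtrip(self, noiseless_sim):
        s = noiseless_sim
        run = interleave_series(s["nulled"], s["bold"])
        assert run.n_volumes == 2 * s["nulled"].n_volumes
        n2, b2 = split_interleaved(run)
        assert np.array_equal(n2.data, s["nulled"].data)
        assert np.array_equal(b2.data, s["bold"].data)
        assert b2.t0_s == pytest.approx(run.tr_s)

    def test_motion_trace_matches_volumes(self, noiseless_sim):
        s = noiseless_sim
        assert s["motion"].n_volumes == s["design"].run_length_volumes
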