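import numpy as np
import pandas as pd
import pytest

from lamvaso.era import (ERAMatrix, WINDOW_LEN, WINDOW_PRE, clean_timeseries,
                         era_from_trials, extract_era, extract_trials,
                         extract_triphasic, pool_over_digits)
from lamvaso.grids import MotionTrace, Series4D, StimDesign

TR = 1.925


def make_series(data, tr=TR):
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 1:
        data = data[None, :]
    return Series4D(data[:, None, None, :], (0.5,) * 3, tr_s=tr, contrast="bold")


class TestClean:
    def test_pure_linear_ramp_becomes_zero(self):
        y = 100.0 + 0.3 * np.arange(50)
        out = clean_timeseries(make_series(y))
        assert np.allclose(out.data, 0.0, atol=1e-8)

    def test_constant_series_becomes_zero(self):
        out = clean_timeseries(make_series(np.full(40, 7.0)))
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_boxcar_plateau_recovered_in_percent(self):
        # mean * (1 + 0.02 * boxcar): plateau ~ +2% minus the detrending bias
        n = 200
        box = np.zeros(n)
        box[80:120] = 1.0
        y = 500.0 * (1.0 + 0.02 * box)
        out = clean_timeseries(make_series(y)).data.ravel()
        # brute-force OLS oracle
        X = np.column_stack([np.ones(n), np.linspace(-1, 1, n)])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        expect = 100.0 * resid / y.mean()
        assert np.allclose(out, expect, atol=1e-8)
        plateau = out[85:115].mean() - out[:60].mean()
        assert plateau == pytest.approx(2.0, abs=0.1)

    def test_motion_regressed_out(self):
        rng = np.random.default_rng(0)
        n = 80
        motion = MotionTrace(rng.normal(0, 0.05, (n, 6)))
        y = 100.0 + 3.0 * motion.params[:, 0]
        out = clean_timeseries(make_series(y), motion)
        assert np.allclose(out.data, 0.0, atol=1e-8)

    def test_zero_mean_voxel_masked(self):
        out = clean_timeseries(make_series(np.zeros(40)))
        assert np.isnan(out.data).all()

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="rows"):
            clean_timeseries(make_series(np.ones(40)), MotionTrace(np.zeros((39, 6))))


class TestWindowing:
    def test_window_is_86_samples(self):
        assert WINDOW_LEN == 86

    def test_trial_near_run_edge_dropped_and_counted(self):
        traces = np.zeros((1, 85))
        trials, dropped = extract_trials(traces, [20 * TR], TR)
        assert trials.shape[0] == 0 and dropped == 1

    def test_valid_trial_kept(self):
        traces = np.arange(200, dtype=float)[None, :]
        trials, dropped = extract_trials(traces, [30 * TR], TR)
        assert dropped == 0
        assert trials.shape == (1, 1, WINDOW_LEN)
        assert trials[0, 0, WINDOW_PRE] == 30.0  # onset sample

    def test_ci_zero_for_identical_trials(self):
        tr = np.ones((5, 2, WINDOW_LEN))
        era = era_from_trials({"D2": tr}, [(1, 1), (1, 2)], TR)
        assert np.allclose(era.ci95, 0.0)
        assert era.n_trials[0] == 5

    def test_empty_region_labels_error(self):
        s = make_series(np.random.default_rng(1).normal(size=(4, 300)))
        des = StimDesign(("D2",), {"D2": [30 * TR]}, 30.0, 300)
        with pytest.raises(ValueError, match="empty"):
            extract_era(s, des, np.zeros((4, 1, 1), dtype=int), np.ones((4, 1, 1), dtype=int))


def era_from_trace(y):
    values = np.asarray(y, dtype=float)[None, None, :]
    return ERAMatrix(conditions=["D2"], compartments=[(1, 1)], values=values,
                     ci95=np.zeros_like(values), n_trials=np.array([8]),
                     n_dropped=np.array([0]), tr_s=TR)


class TestTriphasic:
    def test_triangular_bump_ttp(self):
        # bump peaking 5 volumes after onset -> TTP = 5 * 1.925 = 9.625 s
        y = np.zeros(WINDOW_LEN)
        up = WINDOW_PRE + np.arange(0, 6)
        y[up] = np.arange(6) / 5.0
        y[WINDOW_PRE + 6: WINDOW_PRE + 11] = (np.arange(4, -1, -1)) / 5.0 - 0.2
        feat = extract_triphasic(era_from_trace(y), duration_s=30.0)
        assert feat.ttp_initial_s.iloc[0] == pytest.approx(5 * TR) == pytest.approx(9.625)

    def test_post_window_spans_15_4_seconds(self):
        assert 8 * TR == pytest.approx(15.4)

    def test_known_kernel_recovered_on_grid(self):
        from lamvaso.phantom import triphasic_kernel

        t = np.arange(-WINDOW_PRE, WINDOW_LEN - WINDOW_PRE) * TR
        y = triphasic_kernel(t, 0.4, 10.0, 0.3, 24.0, 0.25, 6.0, 30.0)
        feat = extract_triphasic(era_from_trace(y), duration_s=30.0)
        r = feat.iloc[0]
        assert abs(r.ttp_initial_s - 10.0) <= TR
        assert abs(r.ttp_trough_s - 24.0) <= TR
        assert abs(r.ttp_post_s - 6.0) <= TR
        assert r.amp_initial_pct > 0 > r.amp_trough_pct

    def test_trough_never_before_peak(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            y = rng.normal(0, 1, WINDOW_LEN)
            feat = extract_triphasic(era_from_trace(y), duration_s=30.0)
            assert (feat.ttp_initial_s <= feat.ttp_trough_s).all()

    def test_tie_breaks_to_earliest_time(self):
        y = np.zeros(WINDOW_LEN)
        y[WINDOW_PRE + 3] = 1.0
        y[WINDOW_PRE + 9] = 1.0  # equal maxima
        feat = extract_triphasic(era_from_trace(y), duration_s=30.0,
                                 baseline="run_mean")
        assert feat.ttp_initial_s.iloc[0] == pytest.approx(3 * TR)

    def test_window_too_short_errors(self):
        era = era_from_trace(np.zeros(WINDOW_LEN))
        with pytest.raises(ValueError, match="window"):
            extract_triphasic(era, duration_s=30.0, post_window_volumes=60)


class TestPooling:
    def _era(self, scale, n_trials):
        values = np.full((1, 2, WINDOW_LEN), scale, dtype=float)
        return ERAMatrix(["D2"], [(1, 1), (2, 1)], values,
                         np.full_like(values, 0.1), np.array([n_trials]),
                         np.array([0]), TR)

    def test_identical_tables_pool_to_same(self):
        eras = {d: self._era(1.5, 4) for d in ("D2", "D3", "D4")}
        pooled = pool_over_digits(eras, {d: "D2" for d in eras})
        assert np.allclose(pooled.values, 1.5)
        assert pooled.n_trials[0] == 12

    def test_trial_weighting(self):
        eras = {"D2": self._era(1.0, 8), "D3": self._era(4.0, 4)}
        pooled = pool_over_digits(eras, {"D2": "D2", "D3": "D2"})
        assert np.allclose(pooled.values, (8 * 1.0 + 4 * 4.0) / 12)

    def test_disjoint_compartments_error(self):
        a = self._era(1.0, 4)
        b = self._era(1.0, 4)
        b.compartments = [(9, 1), (10, 1)]
        with pytest.raises(ValueError, match="disjoint"):
            pool_over_digits({"D2": a, "D3": b}, {"D2": "D2", "D3": "D2"})


class TestParameterRecovery:
    def test_amplitude_recovery_within_20pct(self, default_pipeline):
        """Median relative error of recovered initial-peak / trough amplitudes
        vs the realised injected kernel extrema, bins 4-14 mm."""
        res = default_pipeline
        truth = res["truth"].triphasic_truth
        ref = truth[(truth.digit == "D2") & (truth.layer == 2)].set_index("distance_bin")
        f = res["features_collapsed"]
        f = f[f.region >= 3]
        rel = []
        for _, row in f.iterrows():
            r = ref.loc[int(row.region) - 1]
            rel += [abs(row.amp_initial_pct - r.A1) / r.A1,
                    abs(abs(row.amp_trough_pct) - r.A2) / r.A2]
        assert np.median(rel) <= 0.20

    def test_pooled_posterior_peak_only_beyond_6mm(self, noiseless_pipeline):
        # the injected post-stimulus peak is absent in the 4-6 mm bin and
        # grows with distance
        f = noiseless_pipeline["features_collapsed"]
        f = f[f.region >= 4].sort_values("region")
        assert (np.diff(f.amp_post_pct) > -0.05).all()


class TestPipelineERA:
    def test_preferred_digit_plateau_matches_injection(self, noiseless_pipeline):
        # superficial layer of each digit ROI: plateau ~ mean injected BOLD
        # amplitude of the ROI's superficial voxels (within 25%: the ROI mixes
        # patch-edge voxels and the run-mean baseline sits slightly high)
        res = noiseless_pipeline
        era = res["eras_roi"]["bold"]
        truth, rois = res["truth"], res["rois"]
        lay = res["layers_era"]
        for i, d in enumerate(("D2", "D3", "D4"), start=1):
            ci = era.conditions.index(d)
            ki = era.compartments.index((i, 1))
            sel = rois.masks[d] & (lay == 1)
            injected = truth.digit_amplitude_maps[d].data[sel].mean()
            trace = era.values[ci, ki]
            plateau = trace[WINDOW_PRE + 4: WINDOW_PRE + 15].mean() - \
                np.mean(trace[WINDOW_PRE - 4: WINDOW_PRE])
            assert plateau == pytest.approx(injected, rel=0.25)

    def test_vaso_responses_smaller_than_bold(self, noiseless_pipeline):
        res = noiseless_pipeline
        bold = res["eras_roi"]["bold"]
        vaso = res["eras_roi"]["vaso"]
        for i, d in enumerate(("D2", "D3", "D4"), start=1):
            ci = bold.conditions.index(d)
            ki = bold.compartments.index((i, 1))
            b = bold.values[ci, ki, WINDOW_PRE + 4: WINDOW_PRE + 15].mean()
            v = vaso.values[ci, ki, WINDOW_PRE + 4: WINDOW_PRE + 15].mean()
            assert abs(v) < abs(b)
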