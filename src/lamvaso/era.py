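"""Model-free event-related averages and triphasic feature extraction.

Signal changes are expressed in percent of the voxel's run mean (the run
mean, not the pre-stimulus mean, is the baseline; a pre-stimulus baseline is
available as an option).  The trial window spans -15..+70 volumes around
stimulus onset inclusive (86 samples) on the effective (upsampled) time grid.

Triphasic features per compartment: the initial peak is the highest
deflection within the stimulation period; the trough is the lowest deflection
after the peak and before the end of stimulation; the post-stimulus peak is
the highest deflection within eight volumes (~15.4 s at an effective TR of
1.925 s) after stimulus offset.  Initial-peak and trough times are relative
to onset, post-peak times to offset; ties resolve to the earliest time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import MotionTrace, Series4D

WINDOW_PRE = 15
WINDOW_POST = 70
WINDOW_LEN = WINDOW_PRE + WINDOW_POST + 1  # inclusive on both sides


# ---------------------------------------------------------------------------
# voxelwise cleaning
# ---------------------------------------------------------------------------

def clean_timeseries(series: Series4D, motion: MotionTrace | None = None) -> Series4D:
    """Detrend, regress out motion + outlier spikes, convert to % change.

    Per voxel: OLS removal of intercept + linear trend + the six demeaned
    motion parameters + one spike per flagged volume, then
    ``100 * residual / mean`` of the ORIGINAL series.  Voxels whose mean is
    (near) zero are NaN.
    """
    n = series.n_volumes
    cols = [np.ones(n), np.linspace(-1.0, 1.0, n)]
    if motion is not None:
        if motion.n_volumes != n:
            raise ValueError(f"motion has {motion.n_volumes} rows for {n} volumes")
        cols.extend((motion.params - motion.params.mean(axis=0)).T)
        for i in np.flatnonzero(motion.outlier_flags):
            spike = np.zeros(n)
            spike[i] = 1.0
            cols.append(spike)
    X = np.column_stack(cols)
    Y = series.data.reshape(-1, n).T.astype(np.float64)
    finite = np.all(np.isfinite(Y), axis=0)
    beta = np.linalg.lstsq(X, np.where(finite, Y, 0.0), rcond=None)[0]
    resid = Y - X @ beta
    mean = series.data.reshape(-1, n).astype(np.float64).mean(axis=1)
    scale = np.abs(mean)
    ok = finite & (scale > 1e-9 * max(np.nanmax(scale), 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * resid.T / mean[:, None]
    pct[~ok] = np.nan
    return series.with_data(pct.reshape(series.data.shape).astype(np.float32))


# ---------------------------------------------------------------------------
# trial extraction and averaging
# ---------------------------------------------------------------------------

@dataclass
class ERAMatrix:
    """condition x compartment x time event-related averages (% change)."""

    conditions: list
    compartments: list           # (region_label, layer_bin) tuples
    values: np.ndarray           # (n_cond, n_comp, WINDOW_LEN)
    ci95: np.ndarray             # half-width across trials, same shape
    n_trials: np.ndarray         # (n_cond,), trials entering each average
    n_dropped: np.ndarray        # (n_cond,), truncated trials at run edges
    tr_s: float

    @property
    def times_vol(self) -> np.ndarray:
        return np.arange(-WINDOW_PRE, WINDOW_POST + 1)

    @property
    def times_s(self) -> np.ndarray:
        return self.times_vol * self.tr_s

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ci, cond in enumerate(self.conditions):
            for ki, (reg, lay) in enumerate(self.compartments):
                for ti, tv in enumerate(self.times_vol):
                    rows.append(dict(condition=cond, region=reg, layer=lay,
                                     time_vol=int(tv), time_s=tv * self.tr_s,
                                     value=self.values[ci, ki, ti],
                                     ci95=self.ci95[ci, ki, ti],
                                     n=int(self.n_trials[ci])))
        return pd.DataFrame(rows)


def compartment_traces(cleaned: Series4D, region_labels: np.ndarray,
                       layer_labels: np.ndarray) -> tuple[list, np.ndarray]:
    """Mean % change trace per (region, layer) compartment.

    Regions and layers are positive integer label maps; compartments with no
    voxels get an all-NaN row.
    """
    n = cleaned.n_volumes
    flat = cleaned.data.reshape(-1, n)
    comps, traces = [], []
    for reg in np.unique(region_labels[region_labels > 0]):
        for lay in np.unique(layer_labels[layer_labels > 0]):
            comps.append((int(reg), int(lay)))
            sel = ((region_labels == reg) & (layer_labels == lay)).ravel()
            if sel.any():
                traces.append(np.nanmean(flat[sel], axis=0))
            else:
                traces.append(np.full(n, np.nan))
    return comps, np.asarray(traces)


def extract_trials(traces: np.ndarray, onsets_s, tr_s: float, t0_s: float = 0.0
                   ) -> tuple[np.ndarray, int]:
    """Slice the -15..+70 window around each onset from compartment traces.

    Returns (trials, n_dropped) with trials shaped
    (n_kept, n_comp, WINDOW_LEN); onsets whose window leaves the run are
    dropped and counted.
    """
    n = traces.shape[1]
    kept, dropped = [], 0
    for on in onsets_s:
        idx = int(round((on - t0_s) / tr_s))
        lo, hi = idx - WINDOW_PRE, idx + WINDOW_POST + 1
        if lo < 0 or hi > n:
            dropped += 1
            continue
        kept.append(traces[:, lo:hi])
    if kept:
        return np.stack(kept), dropped
    return np.empty((0, traces.shape[0], WINDOW_LEN)), dropped


def era_from_trials(trial_stacks: dict, compartments: list, tr_s: float,
                    dropped: dict | None = None) -> ERAMatrix:
    """Average per-condition trial stacks (possibly pooled across runs).

    ``trial_stacks`` maps condition -> (n_trials, n_comp, WINDOW_LEN).  The
    95% CI half-width uses the t distribution across trials and is NaN where
    fewer than two trials contribute.
    """
    conds = list(trial_stacks)
    n_comp = len(compartments)
    values = np.full((len(conds), n_comp, WINDOW_LEN), np.nan)
    ci = np.full_like(values, np.nan)
    n_tr = np.zeros(len(conds), dtype=int)
    n_dr = np.zeros(len(conds), dtype=int)
    for i, cond in enumerate(conds):
        tr = trial_stacks[cond]
        n_tr[i] = tr.shape[0]
        if dropped:
            n_dr[i] = dropped.get(cond, 0)
        if tr.shape[0] == 0:
            continue
        values[i] = tr.mean(axis=0)
        if tr.shape[0] >= 2:
            sd = tr.std(axis=0, ddof=1)
            tcrit = stats.t.ppf(0.975, tr.shape[0] - 1)
            ci[i] = tcrit * sd / np.sqrt(tr.shape[0])
    return ERAMatrix(conditions=conds, compartments=compartments, values=values,
                     ci95=ci, n_trials=n_tr, n_dropped=n_dr, tr_s=tr_s)


def extract_era(cleaned_runs, designs, region_labels: np.ndarray,
                layer_labels: np.ndarray) -> ERAMatrix:
    """Event-related averages over one or more cleaned runs.

    ``cleaned_runs`` and ``designs`` are parallel sequences (a single run may
    be passed bare).  Trials are pooled across runs before averaging.
    """
    if isinstance(cleaned_runs, Series4D):
        cleaned_runs = [cleaned_runs]
        designs = [designs]
    if not np.any(region_labels > 0):
        raise ValueError("no compartments: region labels are empty")
    stacks: dict[str, list] = {}
    dropped: dict[str, int] = {}
    comps = None
    tr_s = cleaned_runs[0].tr_s
    for run, des in zip(cleaned_runs, designs):
        comps_run, traces = compartment_traces(run, region_labels, layer_labels)
        comps = comps_run if comps is None else comps
        for cond in des.conditions:
            trials, ndrop = extract_trials(traces, des.onsets_s[cond], run.tr_s, run.t0_s)
            stacks.setdefault(cond, []).append(trials)
            dropped[cond] = dropped.get(cond, 0) + ndrop
    merged = {c: np.concatenate(v, axis=0) for c, v in stacks.items()}
    return era_from_trials(merged, comps, tr_s, dropped)


# ---------------------------------------------------------------------------
# triphasic features
# ---------------------------------------------------------------------------

def extract_triphasic(era: ERAMatrix, duration_s: float,
                      post_window_volumes: int = 8,
                      conditions: list | None = None,
                      baseline: str = "prestim",
                      prestim_volumes: int = 4) -> pd.DataFrame:
    """Per-(condition, region, layer) peak / trough / post-peak times and
    amplitudes from the across-trial mean traces.

    Amplitudes are deflections: by default each trace is referenced to the
    mean of the last ``prestim_volumes`` pre-onset volumes (a window short
    enough not to overlap the previous trial's post-stimulus peak), which
    removes the compartment-constant offset that the run-mean % baseline
    leaves behind.  ``baseline="run_mean"`` reads raw trace values instead.
    Returns a tidy table with TTPs in seconds (initial peak and trough
    relative to onset, post-stimulus peak relative to offset).
    """
    tr = era.tr_s
    n_stim = int(np.floor(duration_s / tr + 1e-9))      # last volume within stim
    i_on = WINDOW_PRE                                   # onset index in window
    i_off_first = i_on + n_stim + 1                     # first volume after offset
    need = i_off_first + post_window_volumes
    if need > WINDOW_LEN:
        raise ValueError("trial window too short for the post-stimulus search")
    if baseline not in ("prestim", "run_mean"):
        raise ValueError(f"unknown baseline {baseline!r}")
    rows = []
    conds = conditions if conditions is not None else era.conditions
    for cond in conds:
        ci = era.conditions.index(cond)
        for ki, (reg, lay) in enumerate(era.compartments):
            y = era.values[ci, ki]
            if not np.all(np.isfinite(y[i_on:need])):
                continue
            if baseline == "prestim":
                y = y - np.nanmean(y[i_on - prestim_volumes: i_on])
            stim = y[i_on: i_on + n_stim + 1]
            i_pk = int(np.argmax(stim))
            t_pk = i_pk * tr
            after = stim[i_pk + 1:]
            if len(after) == 0:
                continue
            i_tr = i_pk + 1 + int(np.argmin(after))
            t_tr = i_tr * tr
            post = y[i_off_first: i_off_first + post_window_volumes]
            i_po = int(np.argmax(post))
            t_po = (i_off_first - i_on + i_po) * tr - duration_s

            def read(arr, i):
                # amplitude as the mean over extremum +-1 volume: the injected
                # deflections are several volumes wide, so this barely biases
                # the amplitude while clearly reducing its reading noise
                return float(np.mean(arr[max(i - 1, 0): i + 2]))

            rows.append(dict(
                condition=cond, region=reg, layer=lay,
                ttp_initial_s=t_pk, amp_initial_pct=read(stim, i_pk),
                ttp_trough_s=t_tr, amp_trough_pct=read(stim, i_tr),
                ttp_post_s=t_po, amp_post_pct=read(post, i_po),
            ))
    df = pd.DataFrame(rows)
    if len(df) and not (df.ttp_initial_s <= df.ttp_trough_s).all():
        raise AssertionError("trough found before the initial peak")
    return df


def pool_over_digits(eras: dict, conditions: dict) -> ERAMatrix:
    """Trial-weighted pooling of per-digit ERAs on aligned compartments.

    ``eras`` maps digit -> ERAMatrix (e.g. distance-bin compartments around
    that digit's peak) and ``conditions`` maps digit -> which condition of
    that ERA to pool (normally the digit's own stimulation).  Compartments
    present in only some digits are pooled over the digits that have data;
    completely disjoint compartment sets are an error.  CI half-widths
    combine as independent means.
    """
    digits = list(eras)
    comp_sets = [set(k for k in eras[d].compartments) for d in digits]
    common_any = set.union(*comp_sets)
    if not set.intersection(*comp_sets):
        raise ValueError("per-digit compartment sets are disjoint; nothing to pool")
    comps = sorted(common_any)
    tr_s = eras[digits[0]].tr_s
    values = np.full((1, len(comps), WINDOW_LEN), np.nan)
    ci = np.full_like(values, np.nan)
    n_tot = 0
    for ki, comp in enumerate(comps):
        num = np.zeros(WINDOW_LEN)
        civ = np.zeros(WINDOW_LEN)
        wsum = 0.0
        for d in digits:
            era = eras[d]
            if comp not in era.compartments:
                continue
            cidx = era.conditions.index(conditions[d])
            kidx = era.compartments.index(comp)
            w = float(era.n_trials[cidx])
            v = era.values[cidx, kidx]
            if w == 0 or not np.any(np.isfinite(v)):
                continue
            num += w * v
            c = era.ci95[cidx, kidx]
            civ += np.where(np.isfinite(c), (w * c) ** 2, 0.0)
            wsum += w
        if wsum > 0:
            values[0, ki] = num / wsum
            ci[0, ki] = np.sqrt(civ) / wsum
    n_tot = sum(int(eras[d].n_trials[eras[d].conditions.index(conditions[d])])
                for d in digits)
    return ERAMatrix(conditions=["pooled"], compartments=comps, values=values,
                     ci95=ci, n_trials=np.array([n_tot]),
                     n_dropped=np.array([0]), tr_s=tr_s)


def laminar_zprofile(statmap_z: np.ndarray, layer_labels: np.ndarray,
                     mask: np.ndarray, n_bins: int = 11) -> np.ndarray:
    """Mean z per depth bin (1 = superficial) within a mask; NaN where empty."""
    out = np.full(n_bins, np.nan)
    for b in range(1, n_bins + 1):
        sel = mask & (layer_labels == b)
        if sel.any():
            out[b - 1] = float(np.nanmean(statmap_z[sel]))
    return out
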