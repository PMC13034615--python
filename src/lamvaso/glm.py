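"""Voxelwise GLM: gamma HRF, cosine high-pass, confounds, contrast z-maps,
fixed-effects run combination and FDR thresholding.

The hemodynamic response is a gamma density parameterised by its mean lag and
standard deviation (mean 6 s, sd 3 s by default, i.e. shape k = 4 and scale
theta = 1.5 s since k*theta = 6 and k*theta**2 = 9).  High-pass filtering is
realised as a discrete-cosine drift basis in the design matrix (an equivalent
projection to filtering the data, with a simpler contract).  No prewhitening
is applied: inference assumes temporally white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grids import MotionTrace, Series4D, StimDesign

Z_CAP = 40.0  # |z| cap for numerically perfect fits


def make_hrf(tr_s: float, mean_lag_s: float = 6.0, sd_s: float = 3.0,
             truncate_s: float = 32.0) -> tuple[np.ndarray, np.ndarray]:
    """Gamma HRF sampled at ``tr_s``, truncated at 32 s, peak-normalised.

    Returns (times, kernel).  shape = (mean/sd)**2, scale = sd**2/mean.
    """
    if mean_lag_s <= 0 or sd_s <= 0:
        raise ValueError("HRF mean lag and sd must be positive")
    scale = sd_s**2 / mean_lag_s
    shape = (mean_lag_s / sd_s) ** 2
    t = np.arange(0.0, truncate_s, tr_s)
    h = stats.gamma.pdf(t, shape, scale=scale)
    h /= h.max()
    return t, h


@dataclass
class DesignMatrix:
    matrix: np.ndarray           # (n_volumes, n_regressors)
    names: list[str]
    tr_s: float
    condition_names: list[str] = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def condition_indices(self) -> list[int]:
        return [self.names.index(c) for c in self.condition_names]


@dataclass
class Contrast:
    """Named weight vector over the condition regressors.

    When ``conditions`` is given, weights are matched to design columns by
    condition *name*, so the same contrast applies correctly to runs whose
    conditions appear in a different order.
    """

    name: str
    weights: np.ndarray
    conditions: tuple = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)) or not np.any(self.weights):
            raise ValueError("contrast weights must be finite with >= 1 nonzero entry")
        if self.conditions is not None:
            self.conditions = tuple(self.conditions)
            if len(self.conditions) != len(self.weights):
                raise ValueError("one weight per named condition is required")

    def full_vector(self, design: DesignMatrix) -> np.ndarray:
        c = np.zeros(design.matrix.shape[1])
        if self.conditions is not None:
            for w, name in zip(self.weights, self.conditions):
                c[design.names.index(name)] = w
        else:
            for w, idx in zip(self.weights, design.condition_indices()):
                c[idx] = w
        return c


def winner_contrasts(conditions) -> list[Contrast]:
    """digit > other digits, e.g. D2: [+1, -0.5, -0.5] (winner-take-all)."""
    conditions = tuple(conditions)
    n = len(conditions)
    out = []
    for i, c in enumerate(conditions):
        w = np.full(n, -1.0 / (n - 1))
        w[i] = 1.0
        out.append(Contrast(f"{c}_gt_others", w, conditions))
    return out


def rest_contrasts(conditions) -> list[Contrast]:
    """digit > rest, e.g. D2: [1, 0, 0]."""
    conditions = tuple(conditions)
    out = []
    for i, c in enumerate(conditions):
        w = np.zeros(len(conditions))
        w[i] = 1.0
        out.append(Contrast(f"{c}_gt_rest", w, conditions))
    return out


def n_cosine_drifts(duration_s: float, highpass_hz: float) -> int:
    """Number of DCT drift columns below the cutoff: floor(2 * T * f_c)."""
    return int(np.floor(2.0 * duration_s * highpass_hz))


def _dct_basis(n: int, n_comp: int) -> np.ndarray:
    i = np.arange(n)
    cols = [np.cos(np.pi * k * (2 * i + 1) / (2 * n)) for k in range(1, n_comp + 1)]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def convolved_regressor(onsets_s, duration_s: float, n_volumes: int, tr_s: float,
                        t0_s: float = 0.0, hrf_mean_s: float = 6.0,
                        hrf_sd_s: float = 3.0) -> np.ndarray:
    """Boxcar convolved with the gamma HRF, sampled on the volume grid and
    normalised to unit plateau (so betas are in signal units)."""
    dt = 0.05
    run_end = t0_s + n_volumes * tr_s
    t_fine = np.arange(0.0, run_end + 33.0, dt)
    box = np.zeros_like(t_fine)
    for on in onsets_s:
        box[(t_fine >= on) & (t_fine < on + duration_s)] = 1.0
    _, h = make_hrf(dt, hrf_mean_s, hrf_sd_s)
    conv = np.convolve(box, h)[: len(t_fine)]
    ref = np.convolve(np.ones(int(round(duration_s / dt))), h).max()
    conv /= ref  # unit plateau for an isolated block
    t_vol = t0_s + tr_s * np.arange(n_volumes)
    return np.interp(t_vol, t_fine, conv)


def build_design(design: StimDesign, motion: MotionTrace | None,
                 n_volumes: int, tr_s: float, t0_s: float = 0.0,
                 highpass_hz: float = 0.01, hrf_mean_s: float = 6.0,
                 hrf_sd_s: float = 3.0) -> DesignMatrix:
    """Assemble the per-run design matrix.

    Columns: one convolved regressor per condition, an intercept, a DCT drift
    basis up to the high-pass cutoff, six demeaned motion regressors, and one
    spike column per flagged outlier volume.
    """
    cols, names = [], []
    for cond in design.conditions:
        cols.append(convolved_regressor(design.onsets_s[cond], design.duration_s,
                                        n_volumes, tr_s, t0_s, hrf_mean_s, hrf_sd_s))
        names.append(cond)
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    n_drift = n_cosine_drifts(n_volumes * tr_s, highpass_hz)
    drift = _dct_basis(n_volumes, n_drift)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    if motion is not None:
        if motion.n_volumes != n_volumes:
            raise ValueError(
                f"motion trace has {motion.n_volumes} rows for {n_volumes} volumes"
            )
        demeaned = motion.params - motion.params.mean(axis=0)
        for k, nm in enumerate(("tx", "ty", "tz", "rx", "ry", "rz")):
            cols.append(demeaned[:, k])
            names.append(f"motion_{nm}")
        for i in np.flatnonzero(motion.outlier_flags):
            spike = np.zeros(n_volumes)
            spike[i] = 1.0
            cols.append(spike)
            names.append(f"outlier_{i}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the QR diagonal
        r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [names[i] for i in np.where(r < 1e-8 * r.max())[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(X, names, tr_s, condition_names=list(design.conditions))


@dataclass
class StatMap:
    """Per-voxel contrast statistics on one grid."""

    contrast: str
    beta: np.ndarray
    variance: np.ndarray   # variance of the contrast estimate
    t: np.ndarray
    z: np.ndarray
    df: float

    def p_values(self, sided: str = "one") -> np.ndarray:
        if sided == "one":
            return stats.norm.sf(self.z)
        if sided == "two":
            return 2.0 * stats.norm.sf(np.abs(self.z))
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Map t quantiles to standard-normal quantiles, capped at |z| = 40."""
    t = np.asarray(t, dtype=float)
    z = np.full_like(t, np.nan)
    ok = np.isfinite(t)
    # work on |t| for numerical symmetry, via the log survival function
    logp = stats.t.logsf(np.abs(t[ok]), df)
    z[ok] = np.sign(t[ok]) * (-stats.norm.ppf(np.exp(np.clip(logp, -700, 0))))
    z[np.isinf(t)] = np.sign(t[np.isinf(t)]) * Z_CAP
    return np.clip(z, -Z_CAP, Z_CAP)


def fit_glm(series: Series4D, design: DesignMatrix, contrasts: list[Contrast],
            sign: float = 1.0) -> list[StatMap]:
    """Ordinary least squares per voxel with t -> z conversion.

    ``sign=-1`` flips beta/t/z, used for VASO where activation decreases the
    signal.  Voxels with zero temporal variance (or NaNs) are masked.
    """
    X = design.matrix
    n, p = X.shape
    if series.n_volumes != n:
        raise ValueError(f"series has {series.n_volumes} volumes, design has {n} rows")
    shape = series.spatial_shape
    Y = series.data.reshape(-1, n).T.astype(np.float64)  # (n, V)
    finite = np.all(np.isfinite(Y), axis=0)
    nonconst = Y.std(axis=0) > 0
    ok = finite & nonconst
    df = n - np.linalg.matrix_rank(X)
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    beta = np.full((p, Y.shape[1]), np.nan)
    beta[:, ok] = pinv @ Y[:, ok]
    resid = Y[:, ok] - X @ beta[:, ok]
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    out = []
    for con in contrasts:
        c = con.full_vector(design)
        cvar = float(c @ xtx_inv @ c)
        cb = np.full(Y.shape[1], np.nan)
        cb[ok] = c @ beta[:, ok]
        var = np.full(Y.shape[1], np.nan)
        var[ok] = cvar * sigma2
        with np.errstate(invalid="ignore", divide="ignore"):
            t = cb / np.sqrt(var)
        # perfect fits: keep the effect direction at the documented cap
        exact = ok.copy()
        exact[ok] = sigma2 <= 1e-24 * np.maximum(np.einsum("ij,ij->j", Y[:, ok], Y[:, ok]) / n, 1e-300)
        t[exact & (cb != 0)] = np.inf * np.sign(cb[exact & (cb != 0)])
        z = t_to_z(t, df)
        out.append(StatMap(contrast=con.name,
                           beta=(sign * cb).reshape(shape),
                           variance=var.reshape(shape),
                           t=(sign * t).reshape(shape),
                           z=(sign * z).reshape(shape),
                           df=float(df)))
    return out


def fixed_effects(maps: list[StatMap]) -> StatMap:
    """Inverse-variance-weighted combination of per-run contrast estimates.

    beta = sum(beta_i / var_i) / sum(1 / var_i); var = 1 / sum(1 / var_i);
    z = beta / sqrt(var).  Masked (non-finite) runs are excluded per voxel.
    A single map is returned unchanged.
    """
    if not maps:
        raise ValueError("no maps to combine")
    if len(maps) == 1:
        return maps[0]
    name = maps[0].contrast
    shape = maps[0].beta.shape
    for m in maps[1:]:
        if m.contrast != name:
            raise ValueError(f"mixed contrasts: {name} vs {m.contrast}")
        if m.beta.shape != shape:
            raise ValueError("grid mismatch across runs")
    betas = np.stack([m.beta for m in maps])
    vars_ = np.stack([m.variance for m in maps])
    w = np.where(np.isfinite(vars_) & (vars_ > 0) & np.isfinite(betas), 1.0 / vars_, 0.0)
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(wsum > 0, (w * np.where(w > 0, betas, 0.0)).sum(axis=0) / wsum, np.nan)
        var = np.where(wsum > 0, 1.0 / wsum, np.nan)
        ratio = beta / np.sqrt(var)
    # t keeps the uncapped ratio so downstream argmax can break z-cap ties
    return StatMap(contrast=name, beta=beta, variance=var, t=ratio,
                   z=np.clip(ratio, -Z_CAP, Z_CAP),
                   df=float(sum(m.df for m in maps)))


def fdr_threshold(p_values: np.ndarray, q: float = 0.001) -> np.ndarray:
    """Benjamini-Hochberg step-up over the supplied voxel population.

    Returns the boolean significance mask (same shape as ``p_values``);
    non-finite entries never reject.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    flat = p.ravel()
    ok = np.isfinite(flat)
    if ok.sum() == 0:
        return out
    reject, *_ = multipletests(flat[ok], alpha=q, method="fdr_bh")
    tmp = np.zeros(flat.shape, dtype=bool)
    tmp[ok] = reject
    return tmp.reshape(p.shape)
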