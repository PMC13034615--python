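"""Nulled/BOLD preprocessing: from an interleaved run to a BOLD-corrected
VASO series, plus quality maps (T1w-EPI, tSNR) and motion summaries.

Conventions used throughout (stated once, applied everywhere):

* sample (n-1) standard deviation;
* the first framewise-displacement value is 0 by definition;
* division guard: voxel-timepoints where the BOLD denominator falls below a
  fraction of the voxel's run mean are set to NaN rather than blowing up;
* "VB17" alignment convention (duplicate the first *nulled* volume); the
  alternative platform convention (duplicate the first BOLD volume) is
  exposed as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import MotionTrace, Series4D, Volume3D, check_same_grid


# ---------------------------------------------------------------------------
# interleave handling
# ---------------------------------------------------------------------------

def split_interleaved(run: Series4D, nulled_first: bool = True
                      ) -> tuple[Series4D, Series4D]:
    """Separate an interleaved acquisition into nulled and BOLD series.

    Each output has tr = pairTR (twice the interleaved spacing); the second
    contrast of each pair carries a ``t0_s`` offset of one volTR.
    """
    n = run.n_volumes
    if n % 2 != 0:
        raise ValueError(f"interleaved run has an odd number of volumes ({n})")
    pair_tr = 2.0 * run.tr_s
    vol_tr = run.tr_s
    first = run.with_data(run.data[..., 0::2], tr_s=pair_tr,
                          contrast="nulled" if nulled_first else "bold", t0_s=run.t0_s)
    second = run.with_data(run.data[..., 1::2], tr_s=pair_tr,
                           contrast="bold" if nulled_first else "nulled",
                           t0_s=run.t0_s + vol_tr)
    if nulled_first:
        return first, second
    return second, first


def replace_nonsteady(s: Series4D, n_replace: int = 3) -> Series4D:
    """Overwrite the first ``n_replace`` volumes with the following ones.

    Volumes 1..3 (1-based) become copies of volumes 4..6, removing the
    pre-steady-state signal excess without changing the series length.
    """
    if s.n_volumes < 2 * n_replace:
        raise ValueError(
            f"need at least {2 * n_replace} volumes to replace the first "
            f"{n_replace}, got {s.n_volumes}"
        )
    out = s.data.copy()
    out[..., :n_replace] = s.data[..., n_replace:2 * n_replace]
    return s.with_data(out)


# ---------------------------------------------------------------------------
# temporal upsampling (local Lagrange, order up to 7)
# ---------------------------------------------------------------------------

def _lagrange_weights(nodes: np.ndarray, x: float) -> np.ndarray:
    w = np.ones(len(nodes))
    for i, xi in enumerate(nodes):
        for j, xj in enumerate(nodes):
            if i != j:
                w[i] *= (x - xj) / (xi - xj)
    return w


def upsample_temporal(s: Series4D, factor: int = 2) -> Series4D:
    """Temporal upsampling by piecewise 7th-order polynomial interpolation.

    New samples between input samples are interpolated with a Lagrange
    polynomial through the 8 nearest samples (4 on each side); near the run
    edges the window shrinks symmetrically, degrading gracefully to lower
    order.  Values at original sample positions are copied exactly, so the
    operation is the identity on the original grid and exact on polynomials
    of degree <= 7 at interior points.
    """
    if factor < 2:
        raise ValueError("upsampling factor must be >= 2")
    n = s.n_volumes
    if n < 8:
        raise ValueError(f"need >= 8 volumes to upsample, got {n}")
    flat = s.data.reshape(-1, n)
    out = np.empty((flat.shape[0], n * factor), dtype=np.float64)
    out[:, ::factor] = flat
    for sub in range(1, factor):
        frac = sub / factor
        for k in range(n - 1):
            m = min(4, k + 1, n - 1 - k)  # symmetric half-window
            nodes = np.arange(k - m + 1, k + m + 1, dtype=float)
            w = _lagrange_weights(nodes, k + frac)
            out[:, k * factor + sub] = flat[:, k - m + 1: k + m + 1] @ w
        # beyond the last input sample: extrapolate from the final window
        nodes = np.arange(n - 2, n, dtype=float)
        w = _lagrange_weights(nodes, n - 1 + frac)
        out[:, (n - 1) * factor + sub] = flat[:, n - 2: n] @ w
    return s.with_data(
        out.reshape(*s.spatial_shape, n * factor).astype(s.data.dtype),
        tr_s=s.tr_s / factor,
    )


def align_nulled_bold(nulled: Series4D, bold: Series4D, convention: str = "vb17"
                      ) -> tuple[Series4D, Series4D]:
    """Temporal alignment of the upsampled nulled and BOLD series.

    VB17 convention: the first nulled volume is duplicated and the series
    truncated to the BOLD length, shifting the nulled series by one
    (upsampled) sample.  The "ve" convention does the same to the BOLD
    series instead.
    """
    if nulled.n_volumes == 0 or bold.n_volumes == 0:
        raise ValueError("cannot align empty series")
    if nulled.n_volumes != bold.n_volumes:
        raise ValueError(
            f"length mismatch after alignment: nulled {nulled.n_volumes}, "
            f"bold {bold.n_volumes}"
        )
    if abs(nulled.tr_s - bold.tr_s) > 1e-9:
        raise ValueError("series must be upsampled to the same tr before alignment")

    def shift(s: Series4D, n_keep: int) -> Series4D:
        # prepending a duplicate puts sample i at the old sample i-1's time,
        # i.e. the series' nominal t0 moves one (upsampled) tr earlier
        data = np.concatenate([s.data[..., :1], s.data], axis=-1)[..., :n_keep]
        return s.with_data(data, t0_s=s.t0_s - s.tr_s)

    if convention == "vb17":
        return shift(nulled, bold.n_volumes), bold
    if convention == "ve":
        return nulled, shift(bold, nulled.n_volumes)
    raise ValueError(f"unknown alignment convention {convention!r}")


def bold_correct(nulled: Series4D, bold: Series4D, guard_frac: float = 0.05
                 ) -> Series4D:
    """Dynamic division: VASO = nulled / BOLD, voxelwise and timewise.

    Removes the multiplicative BOLD contamination of the nulled series.
    Voxel-timepoints where |BOLD| < ``guard_frac`` x the voxel's mean |BOLD|
    are set to NaN instead of producing infinities.
    """
    check_same_grid(nulled, bold, "nulled and bold")
    if nulled.n_volumes != bold.n_volumes:
        raise ValueError("nulled and bold must have equal length")
    denom = bold.data.astype(np.float64)
    guard = guard_frac * np.nanmean(np.abs(denom), axis=-1, keepdims=True)
    bad = np.abs(denom) < guard
    denom = np.where(bad, np.nan, denom)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaso = nulled.data.astype(np.float64) / denom
    return nulled.with_data(vaso.astype(np.float32), contrast="vaso")


# ---------------------------------------------------------------------------
# quality maps
# ---------------------------------------------------------------------------

def compute_t1w_epi(nulled: Series4D, bold: Series4D) -> Volume3D:
    """T1-weighted EPI-space image as the inverse variation coefficient
    (mean / sd) of the concatenated nulled and BOLD time courses.

    The inversion-recovery acquisition makes the temporal mean strongly
    T1-weighted; scaling both inputs by a constant leaves the map unchanged.
    Zero-variance voxels are NaN.
    """
    check_same_grid(nulled, bold, "nulled and bold")
    cat = np.concatenate([nulled.data, bold.data], axis=-1).astype(np.float64)
    mean = cat.mean(axis=-1)
    sd = cat.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        icv = np.where(sd > 0, mean / sd, np.nan)
    return Volume3D(icv, nulled.voxel_size_mm, name="t1w_epi")


def compute_tsnr(s: Series4D, detrend: bool = True) -> Volume3D:
    """Temporal SNR: temporal mean / temporal sd (after linear detrending).

    Detrending (default on) removes slow drifts so the sd reflects noise.
    Constant voxels are NaN (the infinite-tSNR guard).
    """
    if s.n_volumes < 2:
        raise ValueError("need >= 2 volumes for tSNR")
    data = s.data.astype(np.float64)
    mean = data.mean(axis=-1)
    if detrend:
        n = s.n_volumes
        t = np.arange(n) - (n - 1) / 2.0
        slope = (data * t).sum(axis=-1) / (t**2).sum()
        data = data - slope[..., None] * t
    sd = data.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tsnr = np.where(sd > 0, mean / sd, np.nan)
    return Volume3D(tsnr, s.voxel_size_mm, name=f"tsnr_{s.contrast}")


def framewise_displacement(m: MotionTrace, head_radius_mm: float = 50.0) -> np.ndarray:
    """Per-volume framewise displacement in mm.

    FD_t = sum |delta translation| + head_radius * sum |delta rotation|,
    rotations in radians; FD of the first volume is 0.
    """
    d = np.abs(np.diff(m.params, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def detect_motion_outliers(fd: np.ndarray) -> np.ndarray:
    """Volumes with FD above the 75th percentile + 1.5 x IQR of the run."""
    q1, q3 = np.percentile(fd, [25, 75])
    return fd > q3 + 1.5 * (q3 - q1)


@dataclass
class QCReport:
    """Per-run quality summary."""

    tsnr_nulled: Volume3D
    tsnr_bold: Volume3D
    tsnr_vaso: Volume3D
    fd_mm: np.ndarray
    outlier_flags: np.ndarray
    fd_threshold_desc: str = "75th percentile + 1.5*IQR"

    @property
    def n_fd_over_threshold(self) -> int:
        return int(self.outlier_flags.sum())

    def summary(self) -> dict:
        return {
            "n_volumes": int(len(self.fd_mm)),
            "fd_mean_mm": float(np.mean(self.fd_mm)),
            "fd_max_mm": float(np.max(self.fd_mm)),
            "n_fd_over_threshold": self.n_fd_over_threshold,
            "fd_threshold": self.fd_threshold_desc,
        }


def preprocess_run(run: Series4D, motion: MotionTrace | None = None,
                   upsample_factor: int = 2, convention: str = "vb17",
                   nulled_first: bool = True,
                   ) -> tuple[Series4D, Series4D, Series4D, QCReport | None]:
    """Full per-run chain: split -> steady-state fix -> upsample -> align ->
    BOLD-correct.  Returns (vaso, bold_upsampled, nulled_upsampled, qc)."""
    nulled, bold = split_interleaved(run, nulled_first=nulled_first)
    nulled = replace_nonsteady(nulled)
    bold = replace_nonsteady(bold)
    tsnr_n = compute_tsnr(nulled)
    tsnr_b = compute_tsnr(bold)
    nulled_up = upsample_temporal(nulled, upsample_factor)
    bold_up = upsample_temporal(bold, upsample_factor)
    nulled_al, bold_al = align_nulled_bold(nulled_up, bold_up, convention=convention)
    vaso = bold_correct(nulled_al, bold_al)
    qc = None
    if motion is not None:
        fd = framewise_displacement(motion)
        qc = QCReport(
            tsnr_nulled=tsnr_n, tsnr_bold=tsnr_b, tsnr_vaso=compute_tsnr(vaso),
            fd_mm=fd, outlier_flags=detect_motion_outliers(fd),
        )
    return vaso, bold_al, nulled_al, qc
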