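"""Synthetic cortical phantom with analytically known ground truth.

The phantom emulates a slab of primary somatosensory cortex imaged with an
interleaved blood-nulled / not-nulled (BOLD) acquisition:

* a curved gray-matter ribbon shaped as a quarter-cylinder shell, for which
  the equivolume cortical depth has the closed form
  ``alpha(r) = (r_p**2 - r**2) / (r_p**2 - r_w**2)`` (0 at the pial surface,
  1 at the white-matter surface), plus a flat-slab variant in which equivolume
  and equidistant depth coincide;
* three adjacent "digit" patches on the shell driven by a 30 s on-off block
  design, with a BOLD amplitude profile increasing toward the surface and a
  CBV profile peaking at mid-depth;
* a distance-dependent triphasic surround response (initial peak, trough,
  post-stimulus peak) injected per 2 mm Euclidean distance bin from each
  patch centre;
* multiplicative BOLD contamination of the nulled series, so that dividing
  nulled by BOLD recovers the injected ``1 - v(t)`` CBV signal;
* i.i.d. Gaussian thermal noise at contrast-specific amplitude and a short
  inversion-recovery-like transient on the first three volume pairs.

Both volumes of an interleaved pair carry the signal evaluated at the shared
pair time ``k * pairTR``; the within-pair acquisition offset (volTR) is
represented in the series metadata only.  Signal evolution on the sub-pairTR
timescale is not simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import (
    CSF,
    GRAY_MATTER,
    WHITE_MATTER,
    MotionTrace,
    Segmentation,
    Series4D,
    StimDesign,
    Volume3D,
)

DIGITS = ("D2", "D3", "D4")
#: per-3-layer-bin scaling of the surround response (superficial, middle, deep);
#: the surround negativity is strongest superficially
LAYER_FACTORS = (1.2, 1.0, 0.8)

# default per-distance-bin triphasic parameters, bins 2..6 (i.e. 4-14 mm).
# Amplitudes in % signal change (trough stored as magnitude), times in seconds
# from stimulus onset (t1, t2) or offset (t3).  The trends follow the observed
# surround behaviour: initial peak shrinking and arriving earlier with
# distance, trough deepening and arriving earlier, post-stimulus peak emerging
# beyond 6-8 mm and arriving later with distance.
DEFAULT_TRIPHASIC = {
    "bins": (2, 3, 4, 5, 6),
    "A1": (0.50, 0.42, 0.34, 0.26, 0.18),
    "t1": (14.0, 12.0, 10.0, 8.0, 6.0),
    "A2": (0.10, 0.17, 0.24, 0.31, 0.38),
    "t2": (26.0, 24.5, 23.0, 21.5, 20.0),
    "A3": (0.00, 0.12, 0.17, 0.20, 0.22),
    "t3": (0.0, 4.0, 5.5, 7.0, 8.5),
}

# nulled/BOLD baseline intensity per tissue code (arbitrary scanner units)
BASELINE_BOLD = {0: 50.0, 1: 900.0, 2: 1000.0, 3: 1100.0}
BASELINE_NULLED = {0: 50.0, 1: 850.0, 2: 700.0, 3: 300.0}

#: multiplicative excess signal on the first three pairs (pre steady state)
NONSTEADY_FACTORS = (0.25, 0.12, 0.05)


@dataclass
class PhantomSpec:
    """All tunable phantom parameters with study-condition defaults."""

    domain_shape: tuple[int, int, int] = (64, 64, 12)
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    shell_inner_radius_mm: float = 12.0  # r_w, white-matter surface
    shell_outer_radius_mm: float = 15.0  # r_p, pial surface
    digit_centers_deg: tuple[float, float, float] = (25.0, 45.0, 65.0)
    patch_fwhm_mm: float = 3.0
    bold_profile: str = "linear_to_surface"
    bold_amp_pct: float = 5.0        # sustained BOLD response at the surface
    bold_floor_frac: float = 0.3     # deep/superficial amplitude ratio
    cbv_profile: str = "mid_depth_peak"
    cbv_amp_pct: float = 1.5         # sustained CBV response at mid-depth
    cbv_floor_frac: float = 0.4
    triphasic_params: dict = field(default_factory=lambda: dict(DEFAULT_TRIPHASIC))
    pair_tr_s: float = 3.85
    block_on_s: float = 30.0
    block_off_s: float = 30.0
    n_blocks_per_digit: int = 4
    lead_in_s: float = 30.8          # rest before the first block (8 pairs)
    noise_sd_bold: float = 33.0
    noise_sd_nulled: float = 33.0
    seed: int = 0

    def __post_init__(self):
        if self.shell_inner_radius_mm >= self.shell_outer_radius_mm:
            raise ValueError("shell_inner_radius_mm must be < shell_outer_radius_mm")
        if np.any(np.asarray(self.voxel_size_mm) <= 0):
            raise ValueError("voxel_size_mm must be positive")
        tp = self.triphasic_params
        for key in ("A1", "A2", "A3"):
            vals = np.asarray(tp[key], dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"triphasic amplitude {key} must be finite")
            if key == "A2" and np.any(vals < 0):
                raise ValueError("trough amplitude A2 is stored as a magnitude (>= 0)")

    @property
    def vol_tr_s(self) -> float:
        """Within-pair offset of the second (BOLD) volume; half a pairTR."""
        return self.pair_tr_s / 2.0

    @property
    def effective_tr_s(self) -> float:
        """Sampling interval of the temporally upsampled analysis grid."""
        return self.pair_tr_s / 2.0


@dataclass
class PhantomTruth:
    """Ground truth injected by the generator, for downstream validation."""

    depth_truth: Volume3D                       # closed-form equivolume depth (NaN off GM)
    digit_amplitude_maps: dict                  # digit -> Volume3D, sustained BOLD % amplitude
    cbv_amplitude_maps: dict                    # digit -> Volume3D, sustained CBV % amplitude
    surround_bins: dict                         # digit -> int volume, distance bin (-1 off)
    layer_factor_map: np.ndarray                # per-voxel surround layer scaling (NaN off GM)
    triphasic_truth: pd.DataFrame               # (digit, distance_bin, layer) -> realized features
    peak_voxel_truth: dict                      # digit -> (i, j, k)
    patch_half_max: dict                        # digit -> bool volume (amp >= half max)
    overlap_warned: bool = False


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _voxel_coords_mm(shape, voxel_size):
    h = np.asarray(voxel_size, dtype=float)
    axes = [(np.arange(n) + 0.5) * h[i] for i, n in enumerate(shape)]
    return np.meshgrid(*axes, indexing="ij")


def annulus_equivolume_depth(r, r_w, r_p):
    """Closed-form equal-volume depth on a cylindrical annulus.

    0 at the pial surface (r = r_p), 1 at the white-matter surface (r = r_w).
    """
    return (r_p**2 - r**2) / (r_p**2 - r_w**2)


def build_ribbon(spec: PhantomSpec) -> tuple[Segmentation, Volume3D]:
    """Quarter-cylinder cortical ribbon with its analytic equivolume depth.

    The cylinder axis runs along z through the (x=0, y=0) corner of the
    domain, so the whole domain is the first angular quadrant.  WM fills the
    inside of the shell, CSF the outside.
    """
    r_w, r_p = spec.shell_inner_radius_mm, spec.shell_outer_radius_mm
    h = np.asarray(spec.voxel_size_mm)
    extent = np.asarray(spec.domain_shape[:2]) * h[:2]
    if r_p >= min(extent):
        raise ValueError(
            f"shell (outer radius {r_p} mm) exceeds domain extent {tuple(extent)} mm"
        )
    X, Y, _ = _voxel_coords_mm(spec.domain_shape, spec.voxel_size_mm)
    r = np.hypot(X, Y)
    labels = np.full(spec.domain_shape, CSF, dtype=np.int16)
    labels[r < r_p] = GRAY_MATTER
    labels[r < r_w] = WHITE_MATTER
    seg = Segmentation(Volume3D(labels, spec.voxel_size_mm, name="segmentation"))

    depth = np.full(spec.domain_shape, np.nan, dtype=np.float64)
    gm = seg.gm_mask
    depth[gm] = annulus_equivolume_depth(r[gm], r_w, r_p)
    return seg, Volume3D(depth, spec.voxel_size_mm, name="depth_truth")


def build_anatomical(spec: PhantomSpec, geometry: str = "shell", factor: int = 3
                     ) -> tuple[Segmentation, Volume3D]:
    """Anatomical-grade segmentation: same geometry on a x``factor`` finer
    grid (odd factor, so fine voxel centres include the functional ones).

    Mirrors the acquisition design, where the anatomy used for layering is
    segmented at ~3x the functional resolution.
    """
    import dataclasses

    if factor % 2 == 0:
        raise ValueError("anatomical upsampling factor must be odd")
    fine = dataclasses.replace(
        spec,
        domain_shape=tuple(factor * n for n in spec.domain_shape),
        voxel_size_mm=tuple(v / factor for v in spec.voxel_size_mm),
    )
    if geometry == "shell":
        return build_ribbon(fine)
    if geometry == "slab":
        return build_slab(fine)
    raise ValueError(f"unknown geometry {geometry!r}")


def build_slab(spec: PhantomSpec, thickness_mm: float = 3.0) -> tuple[Segmentation, Volume3D]:
    """Flat-slab variant: GM sheet normal to z, WM below, CSF above.

    Zero curvature, so equivolume depth equals equidistant depth exactly;
    truth depth is linear in z (0 at the CSF face).
    """
    h = np.asarray(spec.voxel_size_mm)
    nz = spec.domain_shape[2]
    z_extent = nz * h[2]
    if thickness_mm >= z_extent:
        raise ValueError("slab thickness exceeds domain")
    z_lo = (z_extent - thickness_mm) / 2.0
    z_hi = z_lo + thickness_mm
    _, _, Z = _voxel_coords_mm(spec.domain_shape, spec.voxel_size_mm)
    labels = np.full(spec.domain_shape, CSF, dtype=np.int16)
    labels[Z < z_hi] = GRAY_MATTER
    labels[Z < z_lo] = WHITE_MATTER
    seg = Segmentation(Volume3D(labels, spec.voxel_size_mm, name="segmentation"))
    depth = np.full(spec.domain_shape, np.nan, dtype=np.float64)
    gm = seg.gm_mask
    depth[gm] = (z_hi - Z[gm]) / thickness_mm
    return seg, Volume3D(depth, spec.voxel_size_mm, name="depth_truth")


# ---------------------------------------------------------------------------
# response shapes
# ---------------------------------------------------------------------------

def gamma_bump(t, mode_s: float, scale_s: float = 1.0):
    """Peak-normalised gamma-shaped bump with its mode at ``mode_s``."""
    t = np.asarray(t, dtype=float)
    k = mode_s / scale_s + 1.0
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    # log-space for numerical stability at large shape parameters
    log_peak = (k - 1.0) * np.log(mode_s) - mode_s / scale_s
    out[pos] = np.exp((k - 1.0) * np.log(tp) - tp / scale_s - log_peak)
    return out


def sustained_response(t, duration_s: float, hrf_mean_s: float = 6.0, hrf_sd_s: float = 3.0):
    """Boxcar convolved with a gamma HRF, normalised to unit plateau.

    Evaluated at times ``t`` (seconds) relative to block onset; zero before
    onset and after the response has decayed.
    """
    from .glm import make_hrf  # standard HRF lives with the GLM machinery

    dt = 0.05
    t_hrf, h = make_hrf(dt, mean_lag_s=hrf_mean_s, sd_s=hrf_sd_s)
    n_box = int(round(duration_s / dt))
    pad = len(t_hrf)
    box = np.zeros(n_box + pad)
    box[:n_box] = 1.0
    resp = np.convolve(box, h)[: n_box + pad] * dt
    resp /= resp.max()
    t_fine = np.arange(len(resp)) * dt
    t = np.asarray(t, dtype=float)
    return np.interp(t, t_fine, resp, left=0.0, right=0.0)


def triphasic_kernel(t, A1, t1, A2, t2, A3, t3, duration_s: float, scale_s: float = 1.0):
    """Sum of three gamma-shaped components: onset peak, trough, offset peak.

    ``t`` is in seconds relative to stimulus onset; ``t3`` is relative to
    stimulus offset.  The trough amplitude ``A2`` is a magnitude.
    """
    t = np.asarray(t, dtype=float)
    y = A1 * gamma_bump(t, t1, scale_s) - A2 * gamma_bump(t, t2, scale_s)
    if A3 > 0:
        y = y + A3 * gamma_bump(t - duration_s, t3, scale_s)
    return y


def realized_triphasic_extrema(A1, t1, A2, t2, A3, t3, duration_s,
                               post_window_s: float = 15.4, dt: float = 0.01):
    """Extrema of the summed kernel on a fine grid: the injected ground truth.

    Component overlap shifts the extrema slightly away from the nominal
    (t1, t2, t3), so the truth table stores the realised values.  Returns
    (t_peak, a_peak, t_trough, a_trough, t_post, a_post); post-peak fields are
    NaN when A3 == 0.  Times for the post-stimulus peak are relative to offset.
    """
    t = np.arange(dt, duration_s + post_window_s, dt)
    y = triphasic_kernel(t, A1, t1, A2, t2, A3, t3, duration_s)
    stim = t <= duration_s
    i_peak = int(np.argmax(y[stim]))
    t_peak, a_peak = t[stim][i_peak], y[stim][i_peak]
    after = stim & (t > t_peak)
    i_tr = int(np.argmin(y[after]))
    t_trough, a_trough = t[after][i_tr], y[after][i_tr]
    if A3 > 0:
        post = (t > duration_s) & (t <= duration_s + post_window_s)
        i_po = int(np.argmax(y[post]))
        t_post, a_post = t[post][i_po] - duration_s, y[post][i_po]
    else:
        t_post, a_post = np.nan, np.nan
    return t_peak, a_peak, t_trough, a_trough, t_post, a_post


# ---------------------------------------------------------------------------
# digit patches and surround truth
# ---------------------------------------------------------------------------

def _depth_profile(alpha, tag: str, floor_frac: float):
    if tag == "linear_to_surface":
        return floor_frac + (1.0 - floor_frac) * (1.0 - alpha)
    if tag == "mid_depth_peak":
        return floor_frac + (1.0 - floor_frac) * np.exp(-((alpha - 0.5) ** 2) / (2 * 0.18**2))
    raise ValueError(f"unknown depth profile tag {tag!r}")


def paint_digits(seg: Segmentation, depth_truth: Volume3D, spec: PhantomSpec,
                 geometry: str = "shell") -> PhantomTruth:
    """Create per-digit amplitude maps, surround bins and the truth table.

    Each digit is a 2D Gaussian patch on the unrolled cortical surface
    (arc-length x axial coordinates on the shell; in-plane coordinates on the
    slab) multiplied by a depth profile.  Surround voxels at >= 4 mm
    Euclidean distance from the patch-centre voxel carry the per-bin
    triphasic parameters, scaled by a 3-layer factor (strongest
    superficially).
    """
    centers = np.asarray(spec.digit_centers_deg, dtype=float)
    if len(np.unique(centers)) != 3:
        raise ValueError("three distinct digit centres are required")
    gm = seg.gm_mask
    h = np.asarray(spec.voxel_size_mm)
    shape = seg.labels.data.shape
    X, Y, Z = _voxel_coords_mm(shape, spec.voxel_size_mm)
    r_mid = 0.5 * (spec.shell_inner_radius_mm + spec.shell_outer_radius_mm)
    if geometry == "shell":
        theta = np.arctan2(Y, X)      # 0..pi/2 on the quarter shell
        u = theta * r_mid             # arc-length coordinate on the mid surface
        v = Z
        v_c = shape[2] * h[2] / 2.0
        u_centers = np.deg2rad(centers) * r_mid
    elif geometry == "slab":
        # digits along x at the y midline; depth runs along z
        u = X
        v = Y
        v_c = shape[1] * h[1] / 2.0
        u_centers = centers / 90.0 * shape[0] * h[0]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    sep = np.min(np.abs(np.diff(np.sort(u_centers))))
    overlap_warned = False
    if sep < spec.patch_fwhm_mm:
        warnings.warn(
            f"digit patch centres are {sep:.2f} mm apart, closer than the "
            f"{spec.patch_fwhm_mm} mm patch FWHM: truth patches overlap"
        )
        overlap_warned = True

    alpha = depth_truth.data
    layer_bin = np.full(shape, -1, dtype=np.int16)
    a_gm = np.clip(alpha[gm], 0.0, 1.0)
    layer_bin[gm] = np.clip(np.ceil(a_gm * 3).astype(int), 1, 3)
    lf_map = np.full(shape, np.nan)
    lf_map[gm] = np.asarray(LAYER_FACTORS)[layer_bin[gm] - 1]

    tp = spec.triphasic_params
    bins = tuple(tp["bins"])

    amp_maps, cbv_maps, bin_maps, peak_vox, half_max = {}, {}, {}, {}, {}
    rows = []
    gauss_c = 4.0 * np.log(2.0) / spec.patch_fwhm_mm**2
    for digit, u_d in zip(DIGITS, u_centers):
        s2 = (u - u_d) ** 2 + (v - v_c) ** 2
        patch = np.where(gm, np.exp(-gauss_c * s2), 0.0)
        bold_amp = np.where(
            gm, spec.bold_amp_pct * patch * _depth_profile(alpha, spec.bold_profile, spec.bold_floor_frac), 0.0
        )
        cbv_amp = np.where(
            gm, spec.cbv_amp_pct * patch * _depth_profile(alpha, spec.cbv_profile, spec.cbv_floor_frac), 0.0
        )
        amp_maps[digit] = Volume3D(bold_amp, spec.voxel_size_mm, name=f"{digit}_bold_amp")
        cbv_maps[digit] = Volume3D(cbv_amp, spec.voxel_size_mm, name=f"{digit}_cbv_amp")
        pk = np.unravel_index(int(np.argmax(bold_amp)), shape)
        peak_vox[digit] = tuple(int(i) for i in pk)
        half_max[digit] = bold_amp >= 0.5 * bold_amp.max()

        centre_mm = (np.asarray(pk) + 0.5) * h
        dist = np.sqrt((X - centre_mm[0]) ** 2 + (Y - centre_mm[1]) ** 2 + (Z - centre_mm[2]) ** 2)
        bmap = np.full(shape, -1, dtype=np.int16)
        db = np.floor(dist / 2.0).astype(int)
        in_range = gm & (db >= min(bins)) & (db <= max(bins))
        bmap[in_range] = db[in_range]
        bin_maps[digit] = bmap

        for b, A1, t1, A2, t2, A3, t3 in zip(
            bins, tp["A1"], tp["t1"], tp["A2"], tp["t2"], tp["A3"], tp["t3"]
        ):
            tpk, apk, ttr, atr, tpo, apo = realized_triphasic_extrema(
                A1, t1, A2, t2, A3, t3, spec.block_on_s
            )
            for lay, f in enumerate(LAYER_FACTORS, start=1):
                rows.append(
                    dict(
                        digit=digit, distance_bin=b, layer=lay,
                        A1=f * apk, t1=tpk, A2=f * abs(atr), t2=ttr,
                        A3=f * apo if np.isfinite(apo) else np.nan, t3=tpo,
                    )
                )

    truth_table = pd.DataFrame(rows)
    return PhantomTruth(
        depth_truth=depth_truth,
        digit_amplitude_maps=amp_maps,
        cbv_amplitude_maps=cbv_maps,
        surround_bins=bin_maps,
        layer_factor_map=lf_map,
        triphasic_truth=truth_table,
        peak_voxel_truth=peak_vox,
        patch_half_max=half_max,
        overlap_warned=overlap_warned,
    )


# ---------------------------------------------------------------------------
# stimulus design
# ---------------------------------------------------------------------------

def make_design(spec: PhantomSpec, seed: int) -> StimDesign:
    """Pseudo-randomised block order: shuffled digit permutations, no digit
    stimulated twice in a row, onsets snapped to the pairTR grid."""
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        order = []
        for _ in range(spec.n_blocks_per_digit):
            order.extend(rng.permutation(len(DIGITS)).tolist())
        if not any(a == b for a, b in zip(order, order[1:])):
            break
    block_s = spec.block_on_s + spec.block_off_s
    onsets = {d: [] for d in DIGITS}
    last_pair = 0
    for k, di in enumerate(order):
        t = spec.lead_in_s + k * block_s
        pair = int(round(t / spec.pair_tr_s))
        onsets[DIGITS[di]].append(pair * spec.pair_tr_s)
        last_pair = pair
    # run long enough for a -15..+70 effective-grid window around every block
    n_pairs = last_pair + 36
    return StimDesign(
        conditions=DIGITS,
        onsets_s={d: sorted(onsets[d]) for d in DIGITS},
        duration_s=spec.block_on_s,
        run_length_volumes=2 * n_pairs,
    )


# ---------------------------------------------------------------------------
# run simulation
# ---------------------------------------------------------------------------

def signal_courses(seg: Segmentation, truth: PhantomTruth, design: StimDesign,
                   spec: PhantomSpec):
    """Noise-free fractional signal components on the pair-time grid.

    Returns ``(voxels, b, v)``: flat indices of voxels carrying any signal,
    the fractional BOLD modulation ``b`` and CBV modulation ``v`` as
    (n_voxels, n_pairs) arrays, so that the clean series are
    ``bold = B0 * (1 + b)`` and ``nulled = N0 * (1 - v) * (1 + b)``.
    """
    n_pairs = design.run_length_volumes // 2
    t = np.arange(n_pairs) * spec.pair_tr_s
    shape = seg.labels.data.shape

    sus = {}
    for d in DIGITS:
        course = np.zeros(n_pairs)
        for on in design.onsets_s[d]:
            course += sustained_response(t - on, design.duration_s)
        sus[d] = course

    tp = spec.triphasic_params
    bins = tuple(tp["bins"])
    tri = {}
    for d in DIGITS:
        for bi, b_idx in enumerate(bins):
            course = np.zeros(n_pairs)
            for on in design.onsets_s[d]:
                course += triphasic_kernel(
                    t - on, tp["A1"][bi], tp["t1"][bi], tp["A2"][bi], tp["t2"][bi],
                    tp["A3"][bi], tp["t3"][bi], design.duration_s,
                )
            tri[(d, b_idx)] = course

    active = np.zeros(shape, dtype=bool)
    for d in DIGITS:
        active |= truth.digit_amplitude_maps[d].data > 0
        active |= truth.surround_bins[d] >= 0
    vox = np.flatnonzero(active.ravel())

    b = np.zeros((len(vox), n_pairs))
    v = np.zeros((len(vox), n_pairs))
    lf = truth.layer_factor_map.ravel()[vox]
    for d in DIGITS:
        a_bold = truth.digit_amplitude_maps[d].data.ravel()[vox] / 100.0
        a_cbv = truth.cbv_amplitude_maps[d].data.ravel()[vox] / 100.0
        b += a_bold[:, None] * sus[d][None, :]
        v += a_cbv[:, None] * sus[d][None, :]
        vb = truth.surround_bins[d].ravel()[vox]
        for b_idx in bins:
            sel = vb == b_idx
            if np.any(sel):
                b[sel] += (lf[sel] / 100.0)[:, None] * tri[(d, b_idx)][None, :]
    return vox, b, v


def _baseline_map(labels: np.ndarray, table: dict) -> np.ndarray:
    out = np.zeros(labels.shape)
    for code, val in table.items():
        out[labels == code] = val
    return out


def simulate_motion(n_volumes: int, rng: np.random.Generator,
                    n_spikes: int = 2) -> MotionTrace:
    """Slow drift plus jitter, with a few single-volume excursions."""
    from scipy.ndimage import gaussian_filter1d

    steps = rng.normal(0.0, 0.008, size=(n_volumes, 6))
    steps[:, 3:] *= 0.002 / 0.008  # rotations in radians, ~0.1 deg scale
    params = gaussian_filter1d(np.cumsum(steps, axis=0), sigma=3.0, axis=0)
    if n_spikes and n_volumes > 10:
        idx = rng.choice(np.arange(5, n_volumes), size=n_spikes, replace=False)
        for i in idx:
            params[i, rng.integers(0, 3)] += rng.choice([-1.0, 1.0]) * 0.9
    return MotionTrace(params)


def simulate_run(seg: Segmentation, truth: PhantomTruth, design: StimDesign,
                 spec: PhantomSpec, seed: int,
                 ) -> tuple[Series4D, Series4D, MotionTrace]:
    """One interleaved run, returned as separated nulled and BOLD series.

    Identical ``seed`` gives bit-identical output.  The nulled series carries
    ``t0_s = 0`` and the BOLD series ``t0_s = volTR``; both are sampled at
    pairTR.  Motion is returned as a nuisance trace only (one row per acquired
    volume, i.e. 2 x n_pairs) and does not displace the images.
    """
    n_pairs = design.run_length_volumes // 2
    labels = seg.labels.data
    shape = labels.shape
    rng = np.random.default_rng(seed)

    vox, b, v = signal_courses(seg, truth, design, spec)
    B0 = _baseline_map(labels, BASELINE_BOLD)
    N0 = _baseline_map(labels, BASELINE_NULLED)

    bold = np.repeat(B0.ravel()[:, None], n_pairs, axis=1).astype(np.float64)
    nulled = np.repeat(N0.ravel()[:, None], n_pairs, axis=1).astype(np.float64)
    bold[vox] = B0.ravel()[vox, None] * (1.0 + b)
    nulled[vox] = N0.ravel()[vox, None] * (1.0 - v) * (1.0 + b)

    for k, f in enumerate(NONSTEADY_FACTORS):
        bold[:, k] *= 1.0 + f
        nulled[:, k] *= 1.0 + f

    nulled += rng.normal(0.0, spec.noise_sd_nulled, size=nulled.shape)
    bold += rng.normal(0.0, spec.noise_sd_bold, size=bold.shape)
    motion = simulate_motion(2 * n_pairs, rng)

    nulled_s = Series4D(
        nulled.reshape(*shape, n_pairs).astype(np.float32),
        spec.voxel_size_mm, tr_s=spec.pair_tr_s, contrast="nulled", t0_s=0.0,
    )
    bold_s = Series4D(
        bold.reshape(*shape, n_pairs).astype(np.float32),
        spec.voxel_size_mm, tr_s=spec.pair_tr_s, contrast="bold", t0_s=spec.vol_tr_s,
    )
    return nulled_s, bold_s, motion


def interleave_series(nulled: Series4D, bold: Series4D) -> Series4D:
    """Merge separated series back into the acquired interleaved ordering."""
    if nulled.n_volumes != bold.n_volumes:
        raise ValueError("nulled and bold must have equal length to interleave")
    shape = nulled.spatial_shape
    out = np.empty((*shape, 2 * nulled.n_volumes), dtype=nulled.data.dtype)
    out[..., 0::2] = nulled.data
    out[..., 1::2] = bold.data
    return Series4D(out, nulled.voxel_size_mm, tr_s=nulled.tr_s / 2.0,
                    contrast="interleaved", t0_s=nulled.t0_s)
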