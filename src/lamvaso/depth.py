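"""Cortical depth, layers, columns and within-gray-matter distances.

Depth convention: normalized depth ``alpha`` is 0 at the pial (CSF) surface
and 1 at the white-matter surface, defined on gray-matter voxels only.
Connectivity is 26-neighbour everywhere; coordinates are 0-based voxel
indices and physical units are mm via the voxel size.

The equivolume depth corrects the equidistant (distance-ratio) depth for
local curvature: for a locally cylindrical cortical patch with signed mean
curvature ``kappa`` (positive when the pial side is convex, as on a gyral
crown) and thickness ``T``, the fraction of tissue volume between a voxel and
the pial surface is

    alpha_ev = s * (2 + s*tau) / (2 + (2*s - 1) * tau),   tau = kappa * T,

where ``s`` is the equidistant depth from the pial surface.  Flat cortex
(kappa -> 0) reduces to alpha_ev = s.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.spatial import cKDTree

from .grids import Segmentation, Volume3D

#: half-open Euclidean distance-bin edges in mm (seven 2 mm bins, 0-14 mm)
DISTANCE_BIN_EDGES_MM = tuple(float(x) for x in range(0, 15, 2))


# ---------------------------------------------------------------------------
# depth estimation
# ---------------------------------------------------------------------------

def _signed_boundary_distance(mask: np.ndarray, voxel_size, sigma_mm: float,
                              supersample: int, near_sigmas: float = 3.0):
    """Signed distance (mm, positive outside ``mask``) to a tissue interface.

    The binary mask is supersampled (nearest-neighbour, odd factor so fine
    centres align with native ones) and blurred with an isotropic Gaussian of
    ``sigma_mm``.  Near the interface the blurred fraction g of a flat
    boundary satisfies g = Phi(-d/sigma), so d = -sigma * Phi^{-1}(g) gives a
    sub-voxel distance that averages the label staircase; beyond
    ``near_sigmas`` standard deviations the Euclidean distance to the g > 0.5
    level set takes over.
    """
    if supersample % 2 == 0:
        raise ValueError("supersample factor must be odd")
    from scipy.stats import norm as _norm

    h = np.asarray(voxel_size, dtype=float)
    f = supersample
    m = mask.astype(float)
    if f > 1:
        for ax in range(3):
            m = np.repeat(m, f, axis=ax)
    hf = h / f
    centre = tuple(slice(f // 2, None, f) for _ in range(3))
    g = ndimage.gaussian_filter(m, sigma=sigma_mm / hf)
    thr = g > 0.5
    a = ndimage.distance_transform_edt(~thr, sampling=hf)
    b = ndimage.distance_transform_edt(thr, sampling=hf)
    d_edt = (a - b)[centre] - float(np.mean(hf)) / 2.0
    d_inv = -sigma_mm * _norm.ppf(np.clip(g[centre], 1e-15, 1.0 - 1e-15))
    return np.where(np.abs(d_inv) < near_sigmas * sigma_mm, d_inv, d_edt)


def _level_set_curvature(field: np.ndarray, voxel_size, smooth_mm: float = 0.5):
    """Signed mean curvature kappa = div(m), m the unit vector toward the
    pial surface (decreasing depth); positive on gyral crowns."""
    h = np.asarray(voxel_size, dtype=float)
    sm = ndimage.gaussian_filter(np.clip(field, -1.0, 2.0), smooth_mm / h)
    grads = np.gradient(sm, *h)
    norm = np.sqrt(sum(g**2 for g in grads))
    norm = np.where(norm > 1e-12, norm, np.inf)
    kappa = sum(np.gradient(-grads[i] / norm, h[i], axis=i) for i in range(3))
    return ndimage.gaussian_filter(kappa, smooth_mm / h)


def depth_fields(seg: Segmentation, sigma_mm: float = 0.9, supersample: int = 3,
                 thickness_smooth_mm: float = 1.5, ripple_smooth_mm: float = 0.5):
    """Equidistant depth ``s``, curvature ``kappa`` and thickness ``T`` over
    the whole domain (``s`` extends linearly beyond GM via signed distances).

    Both signed boundary distances carry a first-order curvature correction
    (a Gaussian-blurred curved interface shifts the apparent boundary by
    sigma**2 * kappa / 2); the thickness field is smoothed because cortical
    thickness varies slowly compared with voxel quantization noise, and the
    depth is symmetrised, s = (d_csf - d_wm + T) / 2T, so independent
    boundary errors average rather than add.
    """
    h = np.asarray(seg.voxel_size_mm)
    d_c0 = _signed_boundary_distance(seg.csf_mask, h, sigma_mm, supersample)
    d_w0 = _signed_boundary_distance(seg.wm_mask, h, sigma_mm, supersample)
    with np.errstate(invalid="ignore", divide="ignore"):
        s0 = d_c0 / np.where(np.abs(d_c0 + d_w0) > 1e-6, d_c0 + d_w0, np.nan)
    kappa = _level_set_curvature(np.nan_to_num(s0, nan=0.5), h)
    d_c = d_c0 + sigma_mm**2 * kappa / 2.0
    d_w = d_w0 - sigma_mm**2 * kappa / 2.0
    T = ndimage.gaussian_filter(d_c + d_w, thickness_smooth_mm / h)
    u = ndimage.gaussian_filter((d_c - d_w) / 2.0, ripple_smooth_mm / h) \
        + ripple_smooth_mm**2 * kappa / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (u + T / 2.0) / np.where(np.abs(T) > 1e-6, T, np.nan)
    return s, kappa, T


def compute_depth(seg: Segmentation, metric: str = "equivolume",
                  sigma_mm: float = 0.9, supersample: int | None = None) -> Volume3D:
    """Normalized cortical depth of each GM voxel (0 pial, 1 WM).

    ``metric="equidistant"`` is the distance-ratio depth; ``"equivolume"``
    applies the closed-form equal-volume reparameterisation for a locally
    cylindrical patch (see module docstring), which reduces to equidistant
    where the cortex is flat.  GM voxels without reachable boundaries are NaN
    with a warning.  ``supersample`` defaults to 3 for voxels coarser than
    0.3 mm and 1 otherwise (an already anatomical-grade grid).
    """
    if metric not in ("equidistant", "equivolume"):
        raise ValueError(f"unknown depth metric {metric!r}")
    gm = seg.gm_mask
    if not (seg.csf_mask.any() and seg.wm_mask.any()):
        warnings.warn("segmentation lacks a WM or CSF compartment; depth is undefined")
        return Volume3D(np.full(gm.shape, np.nan), seg.voxel_size_mm, name=f"depth_{metric}")
    if supersample is None:
        supersample = 1 if float(np.mean(seg.voxel_size_mm)) <= 0.3 else 3
    s, kappa, T = depth_fields(seg, sigma_mm=sigma_mm, supersample=supersample)
    if metric == "equivolume":
        tau = kappa * T
        denom = 2.0 + (2.0 * s - 1.0) * tau
        denom = np.where(np.abs(denom) > 1e-6, denom, np.nan)
        alpha = s * (2.0 + s * tau) / denom
    else:
        alpha = s
    out = np.full(gm.shape, np.nan)
    out[gm] = np.clip(alpha[gm], 0.0, 1.0)
    return Volume3D(out, seg.voxel_size_mm, name=f"depth_{metric}")


def resample_depth(depth_fine: Volume3D, seg_native: Segmentation,
                   factor: int = 3) -> Volume3D:
    """Sample a depth map computed on an anatomical-grade (x``factor``) grid
    at the native functional voxel centres (factor must be odd so centres
    coincide)."""
    if factor % 2 == 0:
        raise ValueError("resampling factor must be odd")
    centre = tuple(slice(factor // 2, None, factor) for _ in range(3))
    data = depth_fine.data[centre]
    if data.shape != seg_native.labels.data.shape:
        raise ValueError("fine grid is not an integer multiple of the native grid")
    out = np.where(seg_native.gm_mask, data, np.nan)
    return Volume3D(out, seg_native.voxel_size_mm, name=depth_fine.name)


def bin_layers(depth: Volume3D, n_bins: int) -> np.ndarray:
    """Equal-width depth bins; bin 1 is most superficial, 0 marks non-GM.

    bin = ceil(alpha * n) clamped to [1, n], so the bins partition GM.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 layer bins")
    alpha = depth.data
    gm = np.isfinite(alpha)
    out = np.zeros(alpha.shape, dtype=np.int16)
    out[gm] = np.clip(np.ceil(alpha[gm] * n_bins), 1, n_bins).astype(np.int16)
    return out


def column_field(depth: Volume3D, sigma_vox: float = 1.0) -> np.ndarray:
    """Per-GM-voxel unit vector along increasing depth (toward WM).

    Returned as an (x, y, z, 3) array, NaN where undefined.  The depth map is
    extended by nearest-neighbour before smoothing so the gradient is stable
    at the ribbon borders.
    """
    h = np.asarray(depth.voxel_size_mm)
    alpha = depth.data
    gm = np.isfinite(alpha)
    # nearest-GM extension of alpha outside the ribbon
    idx = ndimage.distance_transform_edt(~gm, sampling=h, return_distances=False,
                                         return_indices=True)
    filled = alpha[tuple(idx)]
    sm = ndimage.gaussian_filter(filled, sigma=sigma_vox)
    grads = np.gradient(sm, *h)
    vec = np.stack(grads, axis=-1)
    norm = np.linalg.norm(vec, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        vec = np.where(norm > 1e-12, vec / norm, np.nan)
    vec[~gm] = np.nan
    return vec


# ---------------------------------------------------------------------------
# voxel-graph geodesics
# ---------------------------------------------------------------------------

_OFFSETS = np.array([(i, j, k)
                     for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                     if (i, j, k) > (0, 0, 0)])  # 13 positive half-space offsets


def _mask_graph(mask: np.ndarray, voxel_size) -> tuple[coo_matrix, np.ndarray]:
    """Sparse 26-connected graph over mask voxels, edge weights = Euclidean
    step length in mm (anisotropic voxel sizes respected)."""
    h = np.asarray(voxel_size, dtype=float)
    node_id = np.full(mask.shape, -1, dtype=np.int64)
    coords = np.argwhere(mask)
    node_id[mask] = np.arange(len(coords))
    rows, cols, w = [], [], []
    for off in _OFFSETS:
        length = float(np.sqrt(np.sum((off * h) ** 2)))
        src_sl = tuple(slice(max(0, -o), mask.shape[a] - max(0, o)) for a, o in enumerate(off))
        dst_sl = tuple(slice(max(0, o), mask.shape[a] + min(0, o) or None) for a, o in enumerate(off))
        a_ids = node_id[src_sl]
        b_ids = node_id[dst_sl]
        ok = (a_ids >= 0) & (b_ids >= 0)
        rows.append(a_ids[ok])
        cols.append(b_ids[ok])
        w.append(np.full(int(ok.sum()), length))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = np.concatenate(w)
    n = len(coords)
    graph = coo_matrix((np.concatenate([w, w]),
                        (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                       shape=(n, n))
    return graph.tocsr(), node_id


def geodesic_distance(mask: np.ndarray, seed: tuple[int, int, int], voxel_size
                      ) -> np.ndarray:
    """Shortest-path distance (mm) from ``seed`` through the 26-connected
    voxel graph of ``mask``; +inf where unreachable, NaN outside the mask."""
    seed = tuple(int(i) for i in seed)
    if not mask[seed]:
        raise ValueError(f"seed voxel {seed} is outside the mask")
    graph, node_id = _mask_graph(mask, voxel_size)
    dist = _csgraph_dijkstra(graph, directed=False, indices=node_id[seed])
    out = np.full(mask.shape, np.nan)
    out[mask] = dist
    return out


def make_disk(depth: Volume3D, seed: tuple[int, int, int], radius_mm: float = 12.0,
              mid_band: tuple[float, float] = (0.3, 0.7)) -> np.ndarray:
    """Geodesic gray-matter disk of a given along-cortex radius.

    The geodesic distance is computed within the mid-depth shell
    (``alpha`` in ``mid_band``) from the seed's nearest mid-depth voxel; every
    GM voxel inherits the distance of its nearest shell voxel (its column
    foot-point), so the disk spans all depths over the selected patch.
    A ``radius_mm`` of 0 degenerates to the single column through the seed.
    """
    alpha = depth.data
    gm = np.isfinite(alpha)
    if not gm[tuple(int(i) for i in seed)]:
        raise ValueError(f"disk seed {tuple(seed)} is not a gray-matter voxel")
    shell = gm & (alpha >= mid_band[0]) & (alpha <= mid_band[1])
    if not shell.any():
        raise ValueError("mid-depth shell is empty; cannot flatten the ribbon")
    h = np.asarray(depth.voxel_size_mm)
    shell_coords = np.argwhere(shell)
    tree = cKDTree(shell_coords * h)
    seed_mm = (np.asarray(seed, dtype=float) + 0.0) * h
    _, i_near = tree.query(seed_mm)
    foot_seed = tuple(shell_coords[i_near])
    geo = geodesic_distance(shell, foot_seed, depth.voxel_size_mm)
    if not np.isfinite(geo[foot_seed]):
        raise ValueError("seed cannot be connected to the mid-depth shell")
    gm_coords = np.argwhere(gm)
    _, foot_idx = tree.query(gm_coords * h)
    foot_dist = geo[tuple(shell_coords[foot_idx].T)]
    disk = np.zeros(gm.shape, dtype=bool)
    disk[tuple(gm_coords.T)] = np.isfinite(foot_dist) & (foot_dist <= radius_mm)
    return disk


# ---------------------------------------------------------------------------
# distance bins
# ---------------------------------------------------------------------------

def euclidean_distance_map(mask: np.ndarray, peak: tuple[int, int, int], voxel_size
                           ) -> np.ndarray:
    """Straight-line mm distance from the peak voxel centre, NaN off mask."""
    h = np.asarray(voxel_size, dtype=float)
    coords = np.indices(mask.shape).reshape(3, -1).T * h
    peak_mm = np.asarray(peak, dtype=float) * h
    d = np.linalg.norm(coords - peak_mm, axis=1).reshape(mask.shape)
    return np.where(mask, d, np.nan)


def distance_bins(mask: np.ndarray, peak: tuple[int, int, int], voxel_size,
                  edges_mm=DISTANCE_BIN_EDGES_MM, metric: str = "euclidean"
                  ) -> np.ndarray:
    """Half-open distance bins within gray matter: bin b covers
    [edges[b-1], edges[b]) mm from the peak voxel; 0 = unassigned.

    The default is straight-line (Euclidean) distance restricted to GM;
    ``metric="geodesic"`` is the along-cortex variant.
    """
    peak = tuple(int(i) for i in peak)
    if not mask[peak]:
        raise ValueError(f"peak voxel {peak} is outside the mask")
    if metric == "euclidean":
        d = euclidean_distance_map(mask, peak, voxel_size)
    elif metric == "geodesic":
        d = geodesic_distance(mask, peak, voxel_size)
    else:
        raise ValueError(f"unknown distance metric {metric!r}")
    edges = np.asarray(edges_mm, dtype=float)
    out = np.zeros(mask.shape, dtype=np.int16)
    ok = np.isfinite(d) & (d >= edges[0]) & (d < edges[-1])
    out[ok] = np.digitize(d[ok], edges[1:-1], right=False) + 1
    return out


def n_distance_bins(edges_mm=DISTANCE_BIN_EDGES_MM) -> int:
    return len(edges_mm) - 1
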