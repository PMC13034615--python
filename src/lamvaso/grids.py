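"""Voxel-grid containers shared by every pipeline stage.

All arrays are axis-aligned scalar lattices indexed ``[x, y, z]`` (plus a
trailing time axis for 4D series).  Physical units are millimetres via
``voxel_size_mm``; voxel coordinates are 0-based indices and the physical
position of voxel ``i`` along an axis is ``(i + 0.5) * voxel_size_mm`` so that
the lattice origin sits at a corner of the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

# tissue codes used by every Segmentation
BACKGROUND, WHITE_MATTER, GRAY_MATTER, CSF = 0, 1, 2, 3
TISSUE_CODES = (BACKGROUND, WHITE_MATTER, GRAY_MATTER, CSF)

CONTRASTS = ("nulled", "bold", "vaso", "interleaved")


def _as_triple(v) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(v, dtype=float), (3,))
    if np.any(arr <= 0):
        raise ValueError(f"voxel size must be positive, got {arr}")
    return tuple(float(x) for x in arr)


@dataclass
class Volume3D:
    """A scalar volume with isotropic-or-not voxel size in mm."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D needs a 3D array, got shape {self.data.shape}")
        self.voxel_size_mm = _as_triple(self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def voxel_centers_mm(self, idx: np.ndarray) -> np.ndarray:
        """Physical centre coordinates (mm) of voxel indices, shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return (idx + 0.5) * np.asarray(self.voxel_size_mm)


@dataclass
class Series4D:
    """Time-ordered stack of volumes sharing one grid.

    ``tr_s`` is the time between successive volumes of this series (pairTR for
    a split nulled/BOLD series, pairTR/2 after temporal upsampling) and
    ``t0_s`` the acquisition offset of the first volume.
    """

    data: np.ndarray  # (x, y, z, t)
    voxel_size_mm: tuple[float, float, float]
    tr_s: float
    contrast: str
    t0_s: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"Series4D needs a 4D array, got shape {self.data.shape}")
        self.voxel_size_mm = _as_triple(self.voxel_size_mm)
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}, got {self.contrast!r}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def times_s(self) -> np.ndarray:
        return self.t0_s + self.tr_s * np.arange(self.n_volumes)

    def with_data(self, data: np.ndarray, **kw) -> "Series4D":
        return replace(self, data=data, **kw)


@dataclass
class Segmentation:
    """Integer tissue labels: 0 background, 1 WM, 2 GM, 3 CSF."""

    labels: Volume3D

    def __post_init__(self):
        vals = np.unique(self.labels.data)
        bad = set(vals.tolist()) - set(TISSUE_CODES)
        if bad:
            raise ValueError(f"segmentation contains labels outside {TISSUE_CODES}: {sorted(bad)}")

    @property
    def gm_mask(self) -> np.ndarray:
        return self.labels.data == GRAY_MATTER

    @property
    def wm_mask(self) -> np.ndarray:
        return self.labels.data == WHITE_MATTER

    @property
    def csf_mask(self) -> np.ndarray:
        return self.labels.data == CSF

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return self.labels.voxel_size_mm


@dataclass
class StimDesign:
    """Block onsets per condition, in seconds from run start."""

    conditions: tuple[str, ...]
    onsets_s: dict  # condition -> sorted list of onsets
    duration_s: float
    run_length_volumes: int  # volumes on the effective (analysis) grid

    def __post_init__(self):
        self.conditions = tuple(self.conditions)
        for cond in self.conditions:
            ons = np.asarray(self.onsets_s[cond], dtype=float)
            if np.any(ons < 0):
                raise ValueError(f"negative onset for {cond}")
            if np.any(np.diff(ons) <= 0):
                raise ValueError(f"onsets for {cond} must be strictly increasing")
        allon = np.sort(np.concatenate([np.asarray(self.onsets_s[c], float) for c in self.conditions]))
        if np.any(np.diff(allon) < self.duration_s):
            raise ValueError("stimulation blocks overlap across conditions")

    def all_onsets(self) -> list[tuple[str, float]]:
        ev = [(c, float(t)) for c in self.conditions for t in self.onsets_s[c]]
        return sorted(ev, key=lambda x: x[1])


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray  # (n_volumes, 6)
    outlier_flags: np.ndarray = field(default=None)

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion trace must be (n, 6), got {self.params.shape}")
        if self.outlier_flags is None:
            self.outlier_flags = np.zeros(self.params.shape[0], dtype=bool)
        self.outlier_flags = np.asarray(self.outlier_flags, dtype=bool)
        if self.outlier_flags.shape[0] != self.params.shape[0]:
            raise ValueError("outlier flags length must equal number of volumes")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    def half(self, first: bool) -> "MotionTrace":
        """Even (first=True) or odd volumes of an interleaved acquisition."""
        sl = slice(0, None, 2) if first else slice(1, None, 2)
        return MotionTrace(self.params[sl], self.outlier_flags[sl])


def check_same_grid(a, b, what: str = "inputs") -> None:
    sa = a.data.shape[:3] if hasattr(a, "data") else a.labels.data.shape
    sb = b.data.shape[:3] if hasattr(b, "data") else b.labels.data.shape
    va = getattr(a, "voxel_size_mm")
    vb = getattr(b, "voxel_size_mm")
    if sa != sb or not np.allclose(va, vb):
        raise ValueError(f"{what} are on different grids: {sa}@{va} vs {sb}@{vb}")
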