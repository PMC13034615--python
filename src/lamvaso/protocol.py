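"""Acquisition-protocol description and the simple quantities derived from it.

These mirror the study conditions the phantom emulates: a 3D-EPI SS-SI VASO
protocol with a pairTR of 3850 ms (volTR 1601 ms), 22 slices of 1.29 mm, and
a 30 s on-off vibrotactile block design with up to 3 runs of 4 repetitions
per digit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .depth import DISTANCE_BIN_EDGES_MM, n_distance_bins


@dataclass(frozen=True)
class AcquisitionProtocol:
    n_slices: int = 22
    slice_thickness_mm: float = 1.29
    inplane_resolution_mm: float = 0.75
    pair_tr_ms: float = 3850.0
    vol_tr_ms: float = 1601.0
    block_on_s: float = 30.0
    block_off_s: float = 30.0
    n_runs: int = 3
    reps_per_run_per_digit: int = 4
    total_volumes_acquired: int = 9198   # nulled + BOLD, across the cohort
    fd_outlier_volumes: int = 30         # FD above the in-plane voxel size

    @property
    def slab_coverage_mm(self) -> float:
        """Coverage in the slice direction."""
        return self.n_slices * self.slice_thickness_mm

    @property
    def effective_tr_s(self) -> float:
        """Sampling interval after x2 temporal upsampling."""
        return self.pair_tr_ms / 2.0 / 1000.0

    def post_stim_window_s(self, n_volumes: int = 8) -> float:
        """Duration of an n-volume window on the effective grid."""
        return n_volumes * self.effective_tr_s

    @property
    def motion_outlier_pct(self) -> float:
        """Percentage of acquired volumes with FD above the voxel size."""
        return 100.0 * self.fd_outlier_volumes / self.total_volumes_acquired

    @property
    def reps_per_digit(self) -> int:
        return self.n_runs * self.reps_per_run_per_digit

    @property
    def n_distance_bins(self) -> int:
        return n_distance_bins(DISTANCE_BIN_EDGES_MM)
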