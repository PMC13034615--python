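"""Build the digit ROIs: equivolume depth (on an anatomical-grade x3 grid),
12 mm geodesic disk, FDR q=0.001 winner-take-all masks, largest cluster,
0.45 mm columnar depth propagation, and multi-digit overlap removal; then
the per-digit peak voxels and seven 2 mm Euclidean distance bins.

Reads results/data + results/glm, writes results/roi/.
"""

import json
from pathlib import Path

import numpy as np

from lamvaso import io as lio
from lamvaso.depth import (DISTANCE_BIN_EDGES_MM, bin_layers, column_field,
                           compute_depth, distance_bins, make_disk, resample_depth)
from lamvaso.glm import StatMap
from lamvaso.grids import Volume3D
from lamvaso.phantom import DIGITS, PhantomSpec, build_anatomical
from lamvaso.roi import build_digit_rois, find_peak_voxel

DATA, GLM = Path("results/data"), Path("results/glm")
OUT = Path("results/roi")
OUT.mkdir(parents=True, exist_ok=True)

seg = lio.read_segmentation(DATA / "segmentation.nii")
gm = seg.gm_mask
spec = PhantomSpec()
seg_fine, _ = build_anatomical(spec)
depth = resample_depth(compute_depth(seg_fine, "equivolume"), seg)
lio.write_volume(OUT / "depth_equivolume.nii", depth)
column = column_field(depth)
layers3 = bin_layers(depth, 3)
layers11 = bin_layers(depth, 11)
lio.write_volume(OUT / "layers3.nii", Volume3D(layers3, seg.voxel_size_mm), dtype=np.int16)
lio.write_volume(OUT / "layers11.nii", Volume3D(layers11, seg.voxel_size_mm), dtype=np.int16)


def load_map(mod, name):
    z = lio.read_volume(GLM / f"{mod}_{name}_z.nii").data
    beta = lio.read_volume(GLM / f"{mod}_{name}_beta.nii").data
    return StatMap(contrast=name, beta=beta, variance=np.ones_like(z), t=z, z=z, df=1)


peaks = {d: find_peak_voxel(load_map("bold", f"{d}_gt_rest"), gm) for d in DIGITS}
centroid = np.mean([np.asarray(peaks[d]) for d in DIGITS], axis=0)
gm_coords = np.argwhere(gm)
disk_seed = tuple(gm_coords[np.argmin(
    np.linalg.norm((gm_coords - centroid) * np.asarray(seg.voxel_size_mm), axis=1))])
disk = make_disk(depth, disk_seed, radius_mm=12.0)
print(f"geodesic disk seeded at {tuple(int(i) for i in disk_seed)} "
      f"(centroid of the digit peaks): "
      f"{int((disk & gm).sum())} of {int(gm.sum())} GM voxels")

winner = {d: load_map("bold", f"{d}_gt_others") for d in DIGITS}
rois = build_digit_rois(winner, disk, gm, column, seg.voxel_size_mm, q=0.001)
bins = {d: distance_bins(gm & disk, peaks[d], seg.voxel_size_mm,
                         DISTANCE_BIN_EDGES_MM) for d in DIGITS}

lio.write_volume(OUT / "digit_rois.nii", Volume3D(rois.label_map, seg.voxel_size_mm),
                 dtype=np.int16)
for d in DIGITS:
    lio.write_volume(OUT / f"{d}_distance_bins.nii",
                     Volume3D(bins[d], seg.voxel_size_mm), dtype=np.int16)
lio.write_json(OUT / "roi_provenance.json", rois.provenance)
lio.write_json(OUT / "peak_voxels.json", {d: list(peaks[d]) for d in DIGITS})
vol = rois.volumes_mm3()
print("digit ROI volumes (mm^3):", {d: round(v, 1) for d, v in vol.items()},
      "| overlap-removed voxels:", rois.provenance["overlap_removed_voxels"])
print(f"wrote {OUT}")
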