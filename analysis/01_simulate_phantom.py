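"""Simulate the cortical phantom: segmentation, digit patches with triphasic
surround truth, and three interleaved nulled/BOLD stimulation runs.

Writes to results/data/: segmentation + truth depth NIfTIs, one interleaved
4D run per session, BIDS-style events and motion TSVs, and the injected
triphasic truth table.
"""

import sys
from pathlib import Path

import numpy as np

from lamvaso import io as lio
from lamvaso.phantom import (DIGITS, PhantomSpec, build_ribbon, interleave_series,
                             make_design, paint_digits, simulate_run)
from lamvaso.pipeline import _run_seed

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

spec = PhantomSpec(seed=SEED)
seg, depth_truth = build_ribbon(spec)
truth = paint_digits(seg, depth_truth, spec)
print(f"quarter-cylinder ribbon: {seg.gm_mask.sum()} GM voxels, "
      f"shell {spec.shell_inner_radius_mm}-{spec.shell_outer_radius_mm} mm, "
      f"voxels {spec.voxel_size_mm[0]} mm")
print(f"digit patches at {spec.digit_centers_deg} deg, FWHM {spec.patch_fwhm_mm} mm; "
      f"peak truth voxels: { {d: truth.peak_voxel_truth[d] for d in DIGITS} }")

lio.write_segmentation(OUT / "segmentation.nii", seg)
lio.write_volume(OUT / "depth_truth.nii", depth_truth)
lio.write_table_tsv(OUT / "triphasic_truth.tsv", truth.triphasic_truth)

n_runs = 3
for r in range(n_runs):
    des = make_design(spec, _run_seed(SEED, r))
    nulled, bold, motion = simulate_run(seg, truth, des, spec, _run_seed(SEED, r) + 1)
    run4d = interleave_series(nulled, bold)
    lio.write_series(OUT / f"run-{r + 1}_interleaved.nii", run4d)
    lio.write_events_tsv(OUT / f"run-{r + 1}_events.tsv", des)
    lio.write_motion_tsv(OUT / f"run-{r + 1}_motion.tsv", motion)
    print(f"run {r + 1}: {run4d.n_volumes} interleaved volumes "
          f"({des.run_length_volumes // 2} pairs at pairTR {spec.pair_tr_s} s), "
          f"{sum(len(des.onsets_s[d]) for d in DIGITS)} blocks")
print(f"wrote phantom data to {OUT}")
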