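"""Quantify the triphasic surround response: per distance bin, the initial
peak (highest deflection during stimulation), the trough (lowest deflection
after the peak, before stimulation ends) and the post-stimulus peak (highest
deflection within 8 volumes, ~15.4 s, after offset), with times relative to
onset (peak, trough) or offset (post peak).

Also summarises the laminar z profiles (11 depth bins) within each digit ROI.
Reads results/{era,glm,roi}, writes results/features/.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from lamvaso import io as lio
from lamvaso.era import ERAMatrix, WINDOW_LEN, extract_triphasic, laminar_zprofile
from lamvaso.phantom import DIGITS

ERA, GLM, ROI = Path("results/era"), Path("results/glm"), Path("results/roi")
OUT = Path("results/features")
OUT.mkdir(parents=True, exist_ok=True)


def era_from_tsv(path) -> ERAMatrix:
    df = pd.read_csv(path, sep="\t")
    conds = list(dict.fromkeys(df.condition))
    comps = sorted(set(zip(df.region, df.layer)))
    values = np.full((len(conds), len(comps), WINDOW_LEN), np.nan)
    ci95 = np.full_like(values, np.nan)
    n = np.zeros(len(conds), dtype=int)
    tr = float(np.diff(sorted(df.time_s.unique()))[0])
    for ci, c in enumerate(conds):
        sub = df[df.condition == c]
        n[ci] = sub.n.iloc[0]
        for ki, comp in enumerate(comps):
            rows = sub[(sub.region == comp[0]) & (sub.layer == comp[1])].sort_values("time_vol")
            values[ci, ki] = rows.value.to_numpy()
            ci95[ci, ki] = rows.ci95.to_numpy()
    return ERAMatrix(conds, comps, values, ci95, n, np.zeros(len(conds), int), tr)


pooled = era_from_tsv(ERA / "era_distance_bold_pooled_layer_mean.tsv")
feat = extract_triphasic(pooled, duration_s=30.0)
lio.write_table_tsv(OUT / "triphasic_features.tsv", feat)
f = feat[feat.region >= 3].sort_values("region")
print("pooled BOLD triphasic features across 4-14 mm distance bins "
      "(mean across layers):")
print(f.round(3).to_string(index=False))
print("trend checks: initial-peak amplitude vs distance rho "
      f"{spearmanr(f.region, f.amp_initial_pct).statistic:+.2f} (expected negative), "
      "trough magnitude vs distance rho "
      f"{spearmanr(f.region, -f.amp_trough_pct).statistic:+.2f} (expected positive)")

pooled_layers = era_from_tsv(ERA / "era_distance_bold_pooled.tsv")
feat_layers = extract_triphasic(pooled_layers, duration_s=30.0)
lio.write_table_tsv(OUT / "triphasic_features_by_layer.tsv", feat_layers)

# laminar z profiles within the digit ROIs
layers11 = lio.read_volume(ROI / "layers11.nii").data.astype(np.int16)
roi_labels = lio.read_volume(ROI / "digit_rois.nii").data.astype(np.int16)
rows = []
for mod in ("bold", "vaso"):
    for i, d in enumerate(DIGITS, start=1):
        z = lio.read_volume(GLM / f"{mod}_{d}_gt_rest_z.nii").data
        prof = laminar_zprofile(z, layers11, roi_labels == i, n_bins=11)
        rows += [dict(modality=mod, digit=d, layer_bin=b + 1, mean_z=v)
                 for b, v in enumerate(prof)]
profiles = pd.DataFrame(rows)
lio.write_table_tsv(OUT / "laminar_profiles.tsv", profiles)
pb = profiles[profiles.modality == "bold"].groupby("layer_bin").mean_z.mean()
pv = profiles[profiles.modality == "vaso"].groupby("layer_bin").mean_z.mean()
print(f"BOLD laminar profile rises toward the surface "
      f"(rho vs depth bin {spearmanr(pb.index, pb.values).statistic:+.2f}); "
      f"VASO peaks at depth bin {int(pv.idxmax())} of 11 (mid-depth)")
print(f"wrote {OUT}")
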