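"""Standard-format I/O: NIfTI-1 volumes/series, BIDS-style events and motion
TSVs, tidy feature tables.

NIfTI conventions: RAS-positive diagonal affines built from the voxel size,
float32 data for continuous maps, int16 for label maps; the series TR is
stored in ``pixdim[4]`` and the acquisition offset in ``toffset``; the
contrast tag travels in the ``descrip`` header field.  Write->read round
trips preserve data bit-exactly and the grid metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import TISSUE_CODES, MotionTrace, Segmentation, Series4D, StimDesign, Volume3D

MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag([*voxel_size_mm, 1.0])
    return aff


def write_volume(path, vol: Volume3D, dtype=np.float32) -> Path:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), _affine(vol.voxel_size_mm))
    img.header["descrip"] = vol.name.encode()[:79]
    nib.save(img, str(path))
    return Path(path)


def read_volume(path) -> Volume3D:
    img = nib.load(str(path))
    return Volume3D(np.asanyarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3]),
                    name=img.header["descrip"].item().decode(errors="replace"))


def write_series(path, s: Series4D, dtype=np.float32) -> Path:
    img = nib.Nifti1Image(np.asarray(s.data, dtype=dtype), _affine(s.voxel_size_mm))
    hdr = img.header
    hdr.set_zooms((*s.voxel_size_mm, s.tr_s))
    hdr["toffset"] = s.t0_s
    hdr["descrip"] = f"contrast={s.contrast}".encode()[:79]
    nib.save(img, str(path))
    return Path(path)


def read_series(path) -> Series4D:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    desc = img.header["descrip"].item().decode(errors="replace")
    contrast = desc.split("contrast=")[-1] if "contrast=" in desc else "bold"
    return Series4D(np.asanyarray(img.dataobj),
                    tuple(float(z) for z in zooms[:3]),
                    tr_s=float(zooms[3]), contrast=contrast,
                    t0_s=float(img.header["toffset"]))


def write_segmentation(path, seg: Segmentation) -> Path:
    return write_volume(path, seg.labels, dtype=np.int16)


def read_segmentation(path) -> Segmentation:
    vol = read_volume(path)
    bad = set(np.unique(vol.data).tolist()) - set(TISSUE_CODES)
    if bad:
        raise ValueError(f"{path}: label values outside {TISSUE_CODES}: {sorted(bad)}")
    return Segmentation(Volume3D(vol.data.astype(np.int16), vol.voxel_size_mm,
                                 name=vol.name))


def check_grids_match(path_a, vol_a, path_b, vol_b) -> None:
    if vol_a.data.shape[:3] != vol_b.data.shape[:3] or \
            not np.allclose(vol_a.voxel_size_mm, vol_b.voxel_size_mm):
        raise ValueError(f"grid mismatch between {path_a} and {path_b}")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_events_tsv(path, design: StimDesign) -> Path:
    rows = [dict(onset=t, duration=design.duration_s, trial_type=c)
            for c, t in design.all_onsets()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_events_tsv(path, run_length_volumes: int) -> StimDesign:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"{path}: events TSV needs an '{col}' column")
    conds = tuple(sorted(dict.fromkeys(df.trial_type)))
    dur = float(df.duration.iloc[0])
    onsets = {c: sorted(df.loc[df.trial_type == c, "onset"].astype(float)) for c in conds}
    return StimDesign(conditions=conds, onsets_s=onsets, duration_s=dur,
                      run_length_volumes=run_length_volumes)


def write_motion_tsv(path, m: MotionTrace) -> Path:
    df = pd.DataFrame(m.params, columns=MOTION_COLS)
    df["outlier"] = m.outlier_flags.astype(int)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_motion_tsv(path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: motion TSV is missing columns {missing}")
    flags = df["outlier"].astype(bool).to_numpy() if "outlier" in df.columns else None
    return MotionTrace(df[MOTION_COLS].to_numpy(float), flags)


def write_table_tsv(path, df: pd.DataFrame) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_json(path, obj) -> Path:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return Path(path)
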