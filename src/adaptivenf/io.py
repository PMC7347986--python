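"""Readers and writers for the standard on-disk formats.

Volumes go to NIfTI-1 via nibabel, motion traces to 6-column whitespace text
(one row per TR), event tables and cross-validation results to tab-separated
files, and censor masks to the common one-0/1-per-line convention (1 = keep).
Every writer has a paired reader and all pairs round-trip.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decode import WeightMap
from .preproc import CensorMask, MotionTrace
from .synthdata import VolumeSeries


def write_volume_series(vs: VolumeSeries, path, voxel_size_mm: float = 3.0) -> None:
    import nibabel as nib

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(vs.data.astype(np.float32), affine)
    img.header.set_zooms((voxel_size_mm,) * 3 + (vs.tr_seconds,))
    nib.save(img, str(path))


def read_volume_series(path, mask: np.ndarray) -> VolumeSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    tr = float(img.header.get_zooms()[3])
    return VolumeSeries(data=data, mask=mask, tr_seconds=tr)


def write_mask(mask: np.ndarray, path, voxel_size_mm: float = 3.0) -> None:
    import nibabel as nib

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_mask(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_weight_map(wm: WeightMap, path, voxel_size_mm: float = 3.0) -> None:
    import nibabel as nib

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(wm.to_volume().astype(np.float32), affine), str(path))


def write_motion(motion: MotionTrace, path) -> None:
    np.savetxt(str(path), motion.values, fmt="%.8f")


def read_motion(path, tr_seconds: float = 2.0) -> MotionTrace:
    values = np.loadtxt(str(path))
    return MotionTrace(values=np.atleast_2d(values), tr_seconds=tr_seconds)


def write_censor(mask: CensorMask, path) -> None:
    with open(path, "w") as fh:
        fh.write(mask.to_lines())


def read_censor(path) -> CensorMask:
    with open(path) as fh:
        return CensorMask.from_lines(fh.read())


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
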