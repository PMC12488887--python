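"""Reading and writing session artifacts.

Series and maps are NIfTI (0.1 mm in-plane pixdim, frames along the third
axis); trial tables are CSV; configuration and provenance are JSON
sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import TRIAL_COLUMNS, PowerDopplerSeries, validate_trials


def save_series(series: PowerDopplerSeries, path):
    affine = np.diag([series.pixdim_mm, series.pixdim_mm, 1.0, 1.0])
    img = nib.Nifti1Image(series.data.astype(np.float32), affine)
    img.header.set_zooms((series.pixdim_mm, series.pixdim_mm, series.frame_interval_s))
    nib.save(img, str(path))


def load_series(path, meta=None) -> PowerDopplerSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    data = np.asarray(img.dataobj, dtype=float)
    dt = float(zooms[2]) if len(zooms) > 2 and zooms[2] > 0 else 1.0
    return PowerDopplerSeries(
        data=data,
        pixdim_mm=float(zooms[0]),
        frame_times_s=np.arange(data.shape[2]) * dt,
        meta=meta or {},
    )


def save_map(array2d, path, pixdim_mm: float = 0.1):
    affine = np.diag([pixdim_mm, pixdim_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array2d, dtype=np.float32), affine), str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_trials(trials: pd.DataFrame, path):
    validate_trials(trials)
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def load_trials(path) -> pd.DataFrame:
    return validate_trials(pd.read_csv(path))


def save_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def load_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
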