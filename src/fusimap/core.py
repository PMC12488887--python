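"""Shared containers and direction conventions.

The pipeline operates on one recording session at a time: a 2D coronal
Power Doppler plane sampled at 1 Hz with ~100 um in-plane voxels, plus a
per-trial event table for the memory-guided saccade task (8 peripheral
targets, 45 deg apart). Angles follow the screen convention: 0 deg is
horizontal into the contralateral (right, for a left-hemisphere recording)
hemifield, 90 deg is up, angles increase counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The eight peripheral target directions, degrees.
DIRECTIONS_DEG = np.arange(0, 360, 45)

#: Directions strictly inside the contralateral hemifield (-90, +90).
CONTRA_DIRECTIONS = (315, 0, 45)
#: Directions strictly inside the ipsilateral hemifield.
IPSI_DIRECTIONS = (135, 180, 225)

#: Column order of a trial table.
TRIAL_COLUMNS = [
    "trial_id",
    "direction_deg",
    "t_fix_on",
    "t_cue_on",
    "t_cue_off",
    "t_go",
    "t_move_end",
    "t_reward",
]

_EVENT_COLUMNS = TRIAL_COLUMNS[2:]


def wrap_angle_deg(a):
    """Wrap angles into [0, 360)."""
    return np.asarray(a, dtype=float) % 360.0


def signed_angle_deg(a):
    """Wrap angles into (-180, 180], 0 = contralateral horizontal."""
    a = np.asarray(a, dtype=float) % 360.0
    return np.where(a > 180.0, a - 360.0, a)


def angular_difference_deg(a, b):
    """Smallest absolute angular difference, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def is_contralateral(angle_deg):
    """True where an angle lies strictly inside the contralateral hemifield."""
    s = signed_angle_deg(angle_deg)
    return (s > -90.0) & (s < 90.0)


@dataclass
class PowerDopplerSeries:
    """One session's Power Doppler plane over time.

    Parameters
    ----------
    data : ndarray, shape (ny, nx, n_frames)
        Voxel intensities (arbitrary positive units before scaling).
    pixdim_mm : float
        In-plane voxel spacing, default 0.1 mm (100 um).
    frame_times_s : ndarray, shape (n_frames,)
        Strictly increasing frame timestamps; 1 Hz by default.
    meta : dict
        Free-form session metadata (plane id, day index, provenance).
    """

    data: np.ndarray
    pixdim_mm: float = 0.1
    frame_times_s: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (ny, nx, n_frames)")
        if self.frame_times_s is None:
            self.frame_times_s = np.arange(self.data.shape[2], dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frame_times_s.shape != (self.data.shape[2],):
            raise ValueError("frame_times_s length must match n_frames")
        if self.data.shape[2] >= 2 and not np.all(np.diff(self.frame_times_s) > 0):
            raise ValueError("frame_times_s must be strictly increasing")

    @property
    def shape(self):
        return self.data.shape[:2]

    @property
    def n_frames(self):
        return self.data.shape[2]

    @property
    def frame_interval_s(self):
        if self.n_frames < 2:
            return 1.0
        return float(self.frame_times_s[1] - self.frame_times_s[0])

    def copy_with(self, data, **meta_updates):
        meta = dict(self.meta)
        meta.update(meta_updates)
        return PowerDopplerSeries(
            data=np.asarray(data, dtype=float),
            pixdim_mm=self.pixdim_mm,
            frame_times_s=self.frame_times_s.copy(),
            meta=meta,
        )

    def frame_index(self, t_s):
        """Index of the frame nearest time ``t_s``."""
        return int(np.argmin(np.abs(self.frame_times_s - float(t_s))))


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check a trial table for required columns and ordered event times."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    ev = trials[_EVENT_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.diff(ev, axis=1) > 0):
        raise ValueError("per-trial event times must be strictly increasing")
    bad = set(np.unique(trials["direction_deg"])) - set(DIRECTIONS_DEG.tolist())
    if bad:
        raise ValueError(f"unknown direction labels: {sorted(bad)}")
    return trials
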