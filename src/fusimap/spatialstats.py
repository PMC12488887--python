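"""Spatial autocorrelation profile of voxel time series.

For every seed voxel, neighbors are binned into half-open annuli
(max(0, i - step), i] millimetres away (center-to-center), the Pearson
correlation between the seed's time series and each annulus voxel's series
is averaged per bin and assigned to the seed, and the profile reports the
image-wide mean and standard deviation of those per-seed values at each
distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PowerDopplerSeries


def spatial_autocorrelation(series: PowerDopplerSeries, step_mm: float = 0.1,
                            max_mm: float = 3.0, return_maps: bool = False):
    """Distance profile of pairwise time-series correlation.

    Returns a DataFrame with columns (distance_mm, mean_r, sd_r, n_seeds)
    where ``distance_mm`` is the upper edge of each annulus; optionally
    also per-bin seed maps. Voxels with constant time series are excluded.
    The seed itself never contributes to its own bins.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames")
    ny, nx, nt = series.data.shape
    Z = series.data.reshape(ny * nx, nt)
    mu = Z.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, keepdims=True)
    ok = (sd[:, 0] > 0)
    Zn = np.where(sd > 0, (Z - mu) / sd, 0.0).reshape(ny, nx, nt)
    ok = ok.reshape(ny, nx)

    pix = series.pixdim_mm
    max_vox = int(np.floor(max_mm / pix))
    n_bins = int(np.ceil(max_mm / step_mm))
    # per-offset accumulation: r(seed, seed+offset) summed into the offset's bin
    sums = np.zeros((n_bins, ny, nx))
    counts = np.zeros((n_bins, ny, nx))
    for dy in range(-max_vox, max_vox + 1):
        for dx in range(-max_vox, max_vox + 1):
            if dy == 0 and dx == 0:
                continue
            d_mm = np.hypot(dy, dx) * pix
            if d_mm > max_mm:
                continue
            b = int(np.ceil(d_mm / step_mm - 1e-9)) - 1
            ys = slice(max(0, dy), min(ny, ny + dy))
            xs = slice(max(0, dx), min(nx, nx + dx))
            yt = slice(max(0, -dy), min(ny, ny - dy))
            xt = slice(max(0, -dx), min(nx, nx - dx))
            r = np.einsum("ijt,ijt->ij", Zn[yt, xt], Zn[ys, xs]) / nt
            valid = ok[yt, xt] & ok[ys, xs]
            sums[b][yt, xt] += np.where(valid, r, 0.0)
            counts[b][yt, xt] += valid

    rows = []
    maps = {}
    for b in range(n_bins):
        with np.errstate(divide="ignore", invalid="ignore"):
            per_seed = sums[b] / counts[b]
        per_seed = np.where(counts[b] > 0, per_seed, np.nan)
        valid = ~np.isnan(per_seed)
        rows.append({
            "distance_mm": (b + 1) * step_mm,
            "mean_r": float(np.nanmean(per_seed)) if valid.any() else np.nan,
            "sd_r": float(np.nanstd(per_seed)) if valid.any() else np.nan,
            "n_seeds": int(valid.sum()),
        })
        if return_maps:
            maps[(b + 1) * step_mm] = per_seed
    profile = pd.DataFrame(rows)
    return (profile, maps) if return_maps else profile
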