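"""Preferred-direction, circular-moment, laterality, and topography summaries.

The per-voxel input is an 8-vector of Cohen's d values, one per saccade
direction. The preferred direction is the angle of the weighted circular
centroid of the eight response vectors after scaling the peak (signed)
response to 1; the centroid magnitude in [0, 1] measures tuning strength.
Circular standard deviation, angular skewness, and angular kurtosis follow
the standard trigonometric-moment definitions on the clipped-nonnegative
weight distribution. The laterality index contrasts mean responses to the
contralateral triplet {315, 0, 45} deg against the ipsilateral triplet
{135, 180, 225} deg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CONTRA_DIRECTIONS,
    DIRECTIONS_DEG,
    IPSI_DIRECTIONS,
    is_contralateral,
    signed_angle_deg,
)

_THETA = np.deg2rad(DIRECTIONS_DEG)
_UNIT = np.exp(1j * _THETA)

#: Sulcal-depth fraction separating dorsal from ventral LIP.
LIP_DV_BOUNDARY = 0.53

#: Returned for the circular SD of a (near-)uniform distribution.
CIRC_SD_CAP = np.sqrt(-2.0 * np.log(1e-12))


def _scaled_weights(d8, normalization="abs"):
    """Peak-normalized weights w_k = d_k / peak.

    ``normalization='abs'`` (default) divides by max |d_k|, which keeps the
    scaling stable for pure-suppression profiles (all d_k <= 0), whose
    signed maximum hovers near zero and would otherwise blow the weights
    up; ``'signed'`` divides by max d_k. For any profile with a positive
    peak the two agree.
    """
    d8 = np.asarray(d8, dtype=float)
    if normalization == "abs":
        peak = np.abs(d8).max(axis=0)
    elif normalization == "signed":
        peak = d8.max(axis=0)
    else:
        raise ValueError("normalization must be 'abs' or 'signed'")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = d8 / peak
    return np.where(peak == 0, 0.0, w)


def preferred_direction(d8, normalization="abs"):
    """Center-of-mass preferred direction and tuning magnitude.

    ``d8`` has shape (8, ...). Returns (angle_deg in [0, 360), magnitude in
    [0, 1]); an all-zero vector yields NaN angle and magnitude 0. With the
    signed weights, suppression pushes the centroid away: a voxel whose
    response is suppressed for one direction is reported as preferring the
    opposite direction.
    """
    w = _scaled_weights(d8, normalization)
    denom = np.abs(w).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.tensordot(_UNIT, w, axes=(0, 0)) / denom
    valid = denom > 0
    C = np.where(valid, C, 0.0)
    angle = np.degrees(np.angle(C)) % 360.0
    angle = np.where(valid, angle, np.nan)
    mag = np.clip(np.abs(C), 0.0, 1.0)
    return angle, mag


def circular_moments(d8):
    """Circular SD, angular skewness, angular kurtosis of the clipped weights.

    Weights are the peak-scaled responses with negative entries clipped to
    zero (the moments require a distribution). Returns (circ_sd_rad, skew,
    kurt); a zero total weight raises ValueError for a single vector and
    yields NaN entries for array input.
    """
    w = np.clip(_scaled_weights(d8), 0.0, None)
    total = w.sum(axis=0)
    if np.ndim(total) == 0 and total == 0:
        raise ValueError("zero total weight: no nonnegative responses")
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = np.tensordot(_UNIT, w, axes=(0, 0)) / total
    rbar = np.abs(m1)
    mu = np.angle(m1)
    circ_sd = np.sqrt(-2.0 * np.log(np.clip(rbar, 1e-12, 1.0)))
    circ_sd = np.minimum(circ_sd, CIRC_SD_CAP)
    # uncorrected trigonometric-moment skewness / kurtosis about the mean
    if np.ndim(mu) == 0:
        skew = (w * np.sin(2.0 * (_THETA - mu))).sum() / total
        kurt = (w * np.cos(2.0 * (_THETA - mu))).sum() / total
    else:
        wf = w.reshape(8, -1)
        muf = np.asarray(mu).reshape(-1)
        tot = np.asarray(total).reshape(-1)
        ang = _THETA[:, None] - muf[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            skew = (wf * np.sin(2.0 * ang)).sum(axis=0) / tot
            kurt = (wf * np.cos(2.0 * ang)).sum(axis=0) / tot
        skew = skew.reshape(np.shape(mu))
        kurt = kurt.reshape(np.shape(mu))
        bad = np.asarray(total) == 0
        circ_sd = np.where(bad, np.nan, circ_sd)
        skew = np.where(bad, np.nan, skew)
        kurt = np.where(bad, np.nan, kurt)
    return circ_sd, skew, kurt


def laterality_index(d8):
    """(R_contra - R_ipsi) / (|R_contra| + |R_ipsi|), in [-1, 1].

    R_contra is the mean response over {315, 0, 45} deg and R_ipsi over
    {135, 180, 225} deg; both-zero responses return 0 by convention.
    """
    d8 = np.asarray(d8, dtype=float)
    ci = [int(d) // 45 for d in CONTRA_DIRECTIONS]
    ii = [int(d) // 45 for d in IPSI_DIRECTIONS]
    rc = d8[ci].mean(axis=0)
    ri = d8[ii].mean(axis=0)
    denom = np.abs(rc) + np.abs(ri)
    with np.errstate(divide="ignore", invalid="ignore"):
        li = (rc - ri) / denom
    return np.where(denom == 0, 0.0, li)


def _disk_offsets(radius):
    r = int(np.ceil(radius))
    offs = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)
            if dy * dy + dx * dx <= radius * radius]
    return offs


def smooth_stat_map(values, significant_mask, radius_vox: float = 1.0,
                    angular: bool = False):
    """Disk-mean smoothing restricted to significant voxels.

    Each significant voxel is replaced by the mean over significant
    neighbors within ``radius_vox`` (itself included); non-significant
    voxels are untouched. Angular maps are averaged as unit vectors.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(significant_mask, dtype=bool)
    if angular:
        rad = np.deg2rad(values)
        cx = smooth_stat_map(np.cos(rad), mask, radius_vox, angular=False)
        sx = smooth_stat_map(np.sin(rad), mask, radius_vox, angular=False)
        out = values.copy()
        out[mask] = np.degrees(np.arctan2(sx[mask], cx[mask])) % 360.0
        return out
    ny, nx = values.shape
    num = np.zeros_like(values)
    den = np.zeros_like(values)
    v = np.where(mask, values, 0.0)
    m = mask.astype(float)
    for dy, dx in _disk_offsets(radius_vox):
        ys = slice(max(0, dy), min(ny, ny + dy))
        xs = slice(max(0, dx), min(nx, nx + dx))
        yt = slice(max(0, -dy), min(ny, ny - dy))
        xt = slice(max(0, -dx), min(nx, nx - dx))
        num[yt, xt] += v[ys, xs]
        den[yt, xt] += m[ys, xs]
    out = values.copy()
    sel = mask & (den > 0)
    out[sel] = num[sel] / den[sel]
    return out


def ap_gradient(ap_position_mm, preferred_direction_deg,
                contralateral_only: bool = True):
    """OLS line of preferred direction (wrapped, signed degrees) on AP position.

    Returns (slope_deg_per_mm, intercept_deg, F, p). By default the fit is
    restricted to voxels preferring contralateral directions so the linear
    fit is not distorted by the 180-deg wrap.
    """
    ap = np.asarray(ap_position_mm, dtype=float)
    ang = signed_angle_deg(preferred_direction_deg)
    if contralateral_only:
        keep = (ang > -90.0) & (ang < 90.0)
        ap, ang = ap[keep], ang[keep]
    if ap.size < 3:
        raise ValueError("need at least 3 voxels for the AP regression")
    X = np.column_stack([np.ones_like(ap), ap])
    beta, _, _, _ = np.linalg.lstsq(X, ang, rcond=None)
    fit = X @ beta
    rss = ((ang - fit) ** 2).sum()
    tss = ((ang - ang.mean()) ** 2).sum()
    dof = ap.size - 2
    if rss <= 1e-12 * max(tss, 1.0):
        return float(beta[1]), float(beta[0]), np.inf, 0.0
    F = (tss - rss) / (rss / dof)
    p = float(stats.f.sf(F, 1, dof))
    return float(beta[1]), float(beta[0]), float(F), p


def population_summaries(preferred_deg, significant_mask, atlas,
                         depth_bins: int = 20):
    """Per-region counts, contralateral fractions, and an LIP depth profile.

    Returns (regions, depth) DataFrames. ``regions`` has one row per atlas
    region with voxel counts, significant-voxel counts, and the fraction of
    significant voxels preferring contralateral directions. ``depth``
    histograms the sulcal-depth fraction of significant LIP voxels with the
    53% dorsal/ventral LIP boundary marked.
    """
    mask = np.asarray(significant_mask, dtype=bool)
    pref = np.asarray(preferred_deg, dtype=float)
    rows = []
    for name, code in atlas.region_codes.items():
        if name == "background":
            continue
        region = atlas.label_map == code
        sig = region & mask
        n_sig = int(sig.sum())
        contra = float(is_contralateral(pref[sig]).mean()) if n_sig else np.nan
        rows.append({
            "region": name,
            "n_voxels": int(region.sum()),
            "n_significant": n_sig,
            "frac_significant": n_sig / max(int(region.sum()), 1),
            "contralateral_fraction": contra,
        })
    regions = pd.DataFrame(rows)

    lip_sig = atlas.mask("LIP") & mask
    depths = atlas.depth_fraction[lip_sig]
    edges = np.linspace(0.0, 1.0, depth_bins + 1)
    counts, _ = np.histogram(depths, bins=edges)
    depth = pd.DataFrame({
        "depth_lo": edges[:-1],
        "depth_hi": edges[1:],
        "n_voxels": counts,
    })
    depth.attrs["lip_dv_boundary"] = LIP_DV_BOUNDARY
    return regions, depth
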