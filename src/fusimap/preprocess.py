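"""Preprocessing for the GLM and decoding paths, plus rigid motion correction.

GLM path: Gaussian spatial smoothing (FWHM = one 100-um voxel), a per-voxel
discrete-cosine high-pass removing components slower than 128 s, and grand
mean scaling of the whole series to 100.

Decode path: per-voxel removal of a 50-frame centered moving-average trend
(edge-truncated), then pillbox (disk-mean) spatial smoothing of radius
2 voxels.

Motion correction estimates a rigid translation per frame against a
temporal-median template via upsampled phase correlation and resamples each
frame accordingly.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .core import PowerDopplerSeries

#: FWHM-to-sigma conversion: sigma = FWHM / (2 sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def pillbox_kernel(radius: int) -> np.ndarray:
    """Normalized disk kernel of the given voxel radius (center included)."""
    r = int(radius)
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (x ** 2 + y ** 2) <= r ** 2
    return disk / disk.sum()


def pillbox_filter(image: np.ndarray, radius: int) -> np.ndarray:
    """Disk-mean smoothing with nearest-edge replication."""
    return ndimage.convolve(image, pillbox_kernel(radius), mode="nearest")


def gaussian_filter_fwhm(image: np.ndarray, fwhm_vox: float) -> np.ndarray:
    """Gaussian smoothing parameterized by FWHM in voxels."""
    return ndimage.gaussian_filter(image, fwhm_vox * FWHM_TO_SIGMA, mode="nearest")


def dct_highpass_basis(n_frames: int, dt_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Orthonormal low-frequency DCT columns to regress out (constant excluded).

    The number of retained drift components follows the usual neuroimaging
    convention: k = 1 .. floor(2 * n * dt / cutoff), i.e. all discrete-cosine
    modes with period longer than ``cutoff_s``.
    """
    n_basis = int(np.floor(2.0 * n_frames * dt_s / cutoff_s))
    t = np.arange(n_frames)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_frames)) for k in range(1, n_basis + 1)]
    if not cols:
        return np.zeros((n_frames, 0))
    B = np.stack(cols, axis=1)
    return B / np.linalg.norm(B, axis=0)


def highpass_series(data2d: np.ndarray, dt_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Remove low-frequency drift from (n_voxels, n_frames) rows.

    Implemented as projection out of the low-frequency DCT subspace; the
    per-voxel mean is retained.
    """
    B = dct_highpass_basis(data2d.shape[1], dt_s, cutoff_s)
    if B.shape[1] == 0:
        return data2d
    return data2d - (data2d @ B) @ B.T


def grand_mean_scale(data: np.ndarray, target: float = 100.0) -> np.ndarray:
    """Scale so the grand mean over all voxels and frames equals ``target``."""
    m = data.mean()
    if m == 0:
        raise ValueError("cannot grand-mean scale all-zero data")
    return data * (target / m)


def preprocess_glm(series: PowerDopplerSeries, fwhm_vox: float = 1.0,
                   highpass_cutoff_s: float = 128.0,
                   grand_mean: float = 100.0) -> PowerDopplerSeries:
    """GLM path: smooth -> high-pass -> grand mean scaling."""
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames")
    ny, nx, nt = series.data.shape
    out = np.empty_like(series.data)
    for f in range(nt):
        out[:, :, f] = gaussian_filter_fwhm(series.data[:, :, f], fwhm_vox)
    flat = highpass_series(out.reshape(ny * nx, nt), series.frame_interval_s,
                           highpass_cutoff_s)
    out = grand_mean_scale(flat, grand_mean).reshape(ny, nx, nt)
    return series.copy_with(out, preprocessing="glm")


def moving_average_detrend(data2d: np.ndarray, window: int = 50) -> np.ndarray:
    """Subtract a centered moving average (edge-truncated) from each row.

    An even window is realized as a symmetric (window+1)-tap kernel with
    half-weight endpoints, so the trend estimate is unbiased on linear
    drifts; near the edges the window truncates to the available frames.
    """
    nt = data2d.shape[1]
    w = min(window, nt - 1 if nt > 1 else 1)
    if w % 2 == 0:
        kernel = np.ones(w + 1)
        kernel[0] = kernel[-1] = 0.5
    else:
        kernel = np.ones(w)
    counts = np.convolve(np.ones(nt), kernel, mode="same")
    trend = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, data2d)
    return data2d - trend / counts


def preprocess_decode(series: PowerDopplerSeries, detrend_window: int = 50,
                      pillbox_radius: int = 2) -> PowerDopplerSeries:
    """Decode path: moving-average detrend, then pillbox smoothing."""
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames")
    ny, nx, nt = series.data.shape
    flat = moving_average_detrend(series.data.reshape(ny * nx, nt), detrend_window)
    out = flat.reshape(ny, nx, nt)
    smoothed = np.empty_like(out)
    kernel = pillbox_kernel(pillbox_radius)
    for f in range(nt):
        smoothed[:, :, f] = ndimage.convolve(out[:, :, f], kernel, mode="nearest")
    return series.copy_with(smoothed, preprocessing="decode")


def motion_correct(series: PowerDopplerSeries, reference: str | int = "median",
                   upsample_factor: int = 10, max_shift_vox: float = 10.0):
    """Rigid (translation) registration of every frame to a template.

    Returns the corrected series and the applied per-frame shifts (voxels,
    (dy, dx)); the correction translates each frame by the estimated shift
    so that it best matches the template. Shifts are capped at
    ``max_shift_vox`` as a guard against spurious estimates on
    uninformative frames.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to motion correct")
    data = series.data
    norms = np.abs(data).sum(axis=(0, 1))
    if np.any(norms == 0):
        raise ValueError("all-zero frames cannot be registered")
    if reference == "median":
        template = np.median(data, axis=2)
    elif reference == "mean":
        template = data.mean(axis=2)
    else:
        template = data[:, :, int(reference)]

    nt = series.n_frames
    shifts = np.zeros((nt, 2))
    out = np.empty_like(data)
    for f in range(nt):
        shift, _, _ = phase_cross_correlation(
            template, data[:, :, f], upsample_factor=upsample_factor,
            normalization=None,
        )
        shift = np.clip(shift, -max_shift_vox, max_shift_vox)
        shifts[f] = shift
        out[:, :, f] = ndimage.shift(data[:, :, f], shift, order=1, mode="nearest")
    return series.copy_with(out, motion_corrected=True), shifts
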