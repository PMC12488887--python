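"""Searchlight localization of decodable direction information.

A pillbox region of interest (default radius 200 um = 2 voxels) is centered
on every voxel in turn; the full multicoder pipeline runs in miniature on
the ROI's voxels with 10-fold cross-validation, and the resulting percent
correct, mean angular error, and binomial p-value are assigned to the
center voxel. When an atlas is supplied the ROI is restricted to voxels on
the same side of the sulcal fold as the center, so a searchlight centered
in one bank never mixes in the opposite bank. Each ROI runs the same
z-score -> PCA(95% variance) -> dual-LDA architecture as the whole-image
decoder, through a lean numpy path sized for tens of thousands of tiny
fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PowerDopplerSeries
from .decode import (
    angular_error,
    binomial_p,
    build_feature_stack,
    combine_components,
    horizontal_label,
    movement_end_timepoint,
    percent_correct,
    trial_end_timepoint,
    vertical_label,
    _folds,
)


def _lda_fit_predict(Ztr, labels, Zte, classes, ridge=1e-6):
    """Pooled-covariance LDA with empirical priors (lean numpy path).

    Algebraically the standard LDA rule; a small ridge on the pooled
    within-class covariance keeps the solve stable when the ROI supplies
    nearly as many features as training samples. Used only inside the
    searchlight loop, where per-ROI scikit-learn estimator overhead would
    dominate the runtime; equivalence with scikit-learn's LDA on
    well-conditioned data is covered by tests.
    """
    n, p = Ztr.shape
    means = np.stack([Ztr[labels == c].mean(axis=0) for c in classes])
    priors = np.array([(labels == c).mean() for c in classes])
    Sw = np.zeros((p, p))
    for i, c in enumerate(classes):
        d = Ztr[labels == c] - means[i]
        Sw += d.T @ d
    Sw /= max(n - len(classes), 1)
    Sw[np.diag_indices_from(Sw)] += ridge * max(np.trace(Sw) / p, 1e-12)
    W = np.linalg.solve(Sw, means.T)                       # (p, k)
    b = -0.5 * np.einsum("kp,pk->k", means, W) + np.log(priors)
    scores = Zte @ W + b
    return np.asarray(classes)[np.argmax(scores, axis=1)]


def _multicoder_cv_fast(X, y, folds, pca_variance=0.95):
    """Cross-validated multicoder predictions for one small ROI.

    Same architecture as the whole-image decoder (train-fold z-score, PCA
    retaining ``pca_variance`` cumulative variance, dual 3-class LDA) but
    with the linear algebra done directly in numpy: per-ROI estimator
    objects would dominate the searchlight runtime.
    """
    yh = horizontal_label(y)
    yv = vertical_label(y)
    preds = np.full(len(y), np.nan)
    classes = [-1, 0, 1]
    for train_idx, test_idx in folds:
        mu = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Ztr = (X[train_idx] - mu) / sd
        Zte = (X[test_idx] - mu) / sd
        if pca_variance is not None:
            center = Ztr.mean(axis=0)
            c = Ztr - center
            _, S, Vt = np.linalg.svd(c, full_matrices=False)
            var = S ** 2
            frac = np.cumsum(var) / max(var.sum(), 1e-300)
            k = int(np.searchsorted(frac, pca_variance) + 1)
            Ztr = c @ Vt[:k].T
            Zte = (Zte - center) @ Vt[:k].T
        h = _lda_fit_predict(Ztr, yh[train_idx], Zte, classes)
        v = _lda_fit_predict(Ztr, yv[train_idx], Zte, classes)
        preds[test_idx] = combine_components(h, v)
    return preds


def _disk_offsets(radius_vox: float):
    r = int(np.ceil(radius_vox))
    return [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)
            if dy * dy + dx * dx <= radius_vox * radius_vox]


def searchlight_map(series: PowerDopplerSeries, trials: pd.DataFrame,
                    atlas=None, radius_um: float = 200.0,
                    timepoint: int | None = None, scheme: str = "10fold",
                    respect_sulcus: bool = True, mask=None, seed: int = 0,
                    min_roi_voxels: int = 2, pca_variance: float = 0.95):
    """Per-voxel decoding metrics from a moving pillbox ROI.

    Returns a dict with ``percent_correct``, ``angular_error_deg`` and
    ``binomial_p`` maps (NaN where undefined: outside the mask, or where
    the sulcus-restricted ROI holds fewer than ``min_roi_voxels`` voxels).
    """
    ny, nx = series.shape
    if timepoint is None:
        timepoint = trial_end_timepoint(trials)
    radius_vox = radius_um / (series.pixdim_mm * 1000.0)
    offsets = _disk_offsets(radius_vox)
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    side = None
    if respect_sulcus and atlas is not None:
        side = atlas.sulcus_side

    stack = build_feature_stack(series, trials, timepoint)  # (n, T, ny, nx)
    n = stack.shape[0]
    y = trials["direction_deg"].to_numpy(dtype=float)
    folds = _folds(y, scheme, seed)

    pc_map = np.full((ny, nx), np.nan)
    err_map = np.full((ny, nx), np.nan)
    p_map = np.full((ny, nx), np.nan)

    for cy in range(ny):
        for cx in range(nx):
            if not mask[cy, cx]:
                continue
            if side is not None and side[cy, cx] == 0:
                continue
            rows, cols = [], []
            for dy, dx in offsets:
                yy, xx = cy + dy, cx + dx
                if not (0 <= yy < ny and 0 <= xx < nx):
                    continue
                if side is not None and side[yy, xx] != side[cy, cx]:
                    continue
                rows.append(yy)
                cols.append(xx)
            if len(rows) < min_roi_voxels:
                continue
            X = stack[:, :, rows, cols].reshape(n, -1)
            preds = _multicoder_cv_fast(X, y, folds, pca_variance=pca_variance)
            pc = percent_correct(preds, y)
            pc_map[cy, cx] = pc
            err_map[cy, cx] = np.nanmean(angular_error(preds, y))
            p_map[cy, cx] = binomial_p(int(round(pc / 100.0 * n)), n)
    return {
        "percent_correct": pc_map,
        "angular_error_deg": err_map,
        "binomial_p": p_map,
        "timepoint": timepoint,
    }


def threshold_overlay(err_map, q_map, top_fraction: float = 0.10,
                      q_thresh: float = 0.01):
    """Mask of the best ``top_fraction`` significant searchlight voxels.

    Voxels must first pass ``q_map <= q_thresh``; among those, the lowest
    angular errors are kept (count = floor(top_fraction * n_significant),
    at least 1 when any voxel is significant). Ties are broken
    deterministically by raveled voxel index.
    """
    err = np.asarray(err_map, dtype=float)
    q = np.asarray(q_map, dtype=float)
    sig = np.flatnonzero((q <= q_thresh) & ~np.isnan(err))
    out = np.zeros(err.shape, dtype=bool)
    if sig.size == 0:
        return out
    n_keep = max(1, int(np.floor(top_fraction * sig.size)))
    order = sig[np.lexsort((sig, err.ravel()[sig]))]
    out.ravel()[order[:n_keep]] = True
    return out


def dice_coefficient(mask_a, mask_b) -> float:
    """Dice-Sorenson coefficient 2|A^B| / (|A| + |B|); NaN if both empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def glm_searchlight_overlap(glm_q_map, searchlight_q_map,
                            thresh: float = 0.001) -> float:
    """Overlap of the GLM and searchlight FDR-thresholded masks.

    Both inputs are FDR-corrected q-value maps; the comparison uses the
    modified searchlight variant (movement-end timepoint, no sulcus
    restriction) computed upstream. Returns the Dice-Sorenson coefficient,
    or NaN when both masks are empty (such sessions are excluded from
    summaries).
    """
    a = np.asarray(glm_q_map, dtype=float) <= thresh
    b = np.nan_to_num(np.asarray(searchlight_q_map, dtype=float), nan=1.0) <= thresh
    return dice_coefficient(a, b)
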