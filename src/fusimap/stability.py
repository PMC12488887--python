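"""Cross-session decoding without retraining, and CW-SSIM image similarity.

A decoder fitted on all trials of one session is applied unchanged to the
trials of another session recorded from (nominally) the same coronal plane;
degradation relative to the train session's 10-fold baseline quantifies how
stable the underlying mesoscopic populations are. The complex-wavelet
structural similarity index (CW-SSIM) between the two sessions' vascular
images serves as the explanatory covariate: because it compares local
complex steerable-pyramid coefficients, it tolerates small translations and
contrast changes while remaining sensitive to genuine anatomical change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.registration import phase_cross_correlation

from .core import PowerDopplerSeries
from .decode import (
    angular_error,
    binomial_p,
    build_features,
    cross_validate,
    fit_multicoder,
    percent_correct,
    predict_multicoder,
    trial_end_timepoint,
)

# ---------------------------------------------------------------------------
# complex steerable pyramid + CW-SSIM


def _steerable_bands(image, levels=4, orientations=16):
    """Complex steerable-pyramid subbands (frequency domain, decimated).

    Radial raised-cosine masks split the spectrum into dyadic rings; angular
    cos^(Q-1) masks restricted to a half-plane make the bands analytic
    (complex-valued). Coarse levels are decimated by cropping the spectrum
    (the band's support fits the reduced Nyquist exactly), as in the
    standard pyramid construction, so window statistics at every level are
    computed over comparably independent coefficients.
    """
    ny, nx = image.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    r = np.hypot(fy, fx)
    theta = np.arctan2(fy, fx)
    F = np.fft.fft2(image)

    def radial_mask(lo, hi):
        # raised-cosine band-pass between radii lo and hi (cycles/sample)
        m = np.zeros_like(r)
        rise = (r >= lo / 2) & (r < lo)
        m[rise] = np.cos(np.pi / 2 * np.log2(np.clip(r[rise], 1e-9, None) / lo)) ** 2
        flat = (r >= lo) & (r <= hi)
        m[flat] = 1.0
        fall = (r > hi) & (r <= 2 * hi)
        m[fall] = np.cos(np.pi / 2 * (1 + np.log2(np.clip(r[fall], 1e-9, None) / (2 * hi)))) ** 2
        return m

    def decimate_spectrum(G, factor):
        if factor == 1:
            return G
        Gs = np.fft.fftshift(G)
        cy, cx = Gs.shape[0] // 2, Gs.shape[1] // 2
        hy, hx = Gs.shape[0] // (2 * factor), Gs.shape[1] // (2 * factor)
        crop = Gs[cy - hy:cy + hy, cx - hx:cx + hx]
        return np.fft.ifftshift(crop) / factor ** 2

    bands = []
    q = orientations
    for lev in range(levels):
        hi = 0.5 / (2 ** lev)
        lo = hi / 2
        factor = 2 ** lev  # classic dyadic sampling of bandpass level lev
        if min(ny, nx) // factor < 8:
            break  # image too small for further levels
        rad = radial_mask(lo, hi)
        for k in range(q):
            ang0 = np.pi * k / q
            d = np.angle(np.exp(1j * (theta - ang0)))
            amask = np.where(np.abs(d) < np.pi / 2, np.cos(d) ** (q - 1), 0.0)
            band = np.fft.ifft2(decimate_spectrum(F * rad * amask, factor))
            bands.append(band)
    return bands


def _local_sums(a, window):
    return ndimage.uniform_filter(a, size=window, mode="constant") * window * window


def cw_ssim(img_a, img_b, levels: int = 4, orientations: int = 16,
            window: int = 7, K: float = 0.0) -> float:
    """Complex-wavelet structural similarity in [0, 1].

    Per subband and per 7x7 sliding window,
    S = (2 |sum c_a conj(c_b)| + K) / (sum |c_a|^2 + sum |c_b|^2 + K);
    the result averages S over windows and subbands. Identical images give
    1. Constant (zero-energy) images are only comparable to themselves:
    identical constants return 1.0, otherwise NaN is returned as an
    undefined-similarity flag.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if np.array_equal(a, b):
        return 1.0
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    bands_a = _steerable_bands(a, levels, orientations)
    bands_b = _steerable_bands(b, levels, orientations)
    scores = []
    for ca, cb in zip(bands_a, bands_b):
        cross = _local_sums((ca * np.conj(cb)).real, window) ** 2 \
            + _local_sums((ca * np.conj(cb)).imag, window) ** 2
        cross = 2.0 * np.sqrt(np.clip(cross, 0, None))
        energy = _local_sums(np.abs(ca) ** 2, window) + _local_sums(np.abs(cb) ** 2, window)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (cross + K) / (energy + K)
        valid = energy > 1e-15 * energy.max() if energy.max() > 0 else np.zeros_like(energy, bool)
        if valid.any():
            scores.append(s[valid].mean())
    return float(np.clip(np.mean(scores), 0.0, 1.0)) if scores else float("nan")


# ---------------------------------------------------------------------------
# cross-session decoding


def align_to_template(series: PowerDopplerSeries, template: np.ndarray,
                      upsample_factor: int = 10, max_shift_vox: float = 10.0):
    """Translate every frame of a session so its mean image matches a template.

    Shifts are capped at ``max_shift_vox``: when two sessions share little
    anatomy, phase correlation can lock onto a spurious distant peak, and a
    plausible-magnitude misregistration is preferable to a wild one.
    """
    mean_img = series.data.mean(axis=2)
    shift, _, _ = phase_cross_correlation(template, mean_img,
                                          upsample_factor=upsample_factor,
                                          normalization=None)
    shift = np.clip(shift, -max_shift_vox, max_shift_vox)
    if np.allclose(shift, 0):
        return series, shift
    out = np.empty_like(series.data)
    for f in range(series.n_frames):
        out[:, :, f] = ndimage.shift(series.data[:, :, f], shift, order=1,
                                     mode="nearest")
    return series.copy_with(out, aligned_shift_vox=tuple(shift)), shift


def cross_session_decode(train_series: PowerDopplerSeries, train_trials: pd.DataFrame,
                         test_series: PowerDopplerSeries, test_trials: pd.DataFrame,
                         timepoint: int | None = None, seed: int = 0,
                         align: bool = True, baseline: bool = True,
                         preprocess: bool = True) -> dict:
    """Train on one whole (raw) session, test unchanged on another.

    The test session is first rigidly aligned (translation only) to the
    train session's temporal-mean vascular image - alignment must happen on
    the raw Power Doppler intensities, because the detrended decode-path
    series has a near-zero mean image with nothing to register. Both
    sessions then go through the decode-path preprocessing, a multicoder is
    fitted on every train trial with the dynamic end-of-trial feature
    window, and applied unchanged to the test trials. Pass
    ``preprocess=False`` if both sessions are already preprocessed and
    aligned. Calling this with the same object as train and test is
    rejected: that would silently leak test data into training.

    Returns percent correct, mean angular error, binomial p, the CW-SSIM
    between the two vascular images, and (when ``baseline``) the train
    session's stratified 10-fold accuracy plus the normalized accuracy
    (cross-session / within-session).
    """
    if train_series is test_series or train_series.data is test_series.data:
        raise ValueError("train and test sessions must be distinct "
                         "(use cross_validate for within-session decoding)")
    if train_series.shape != test_series.shape:
        raise ValueError("sessions must share an image grid after alignment")
    if timepoint is None:
        timepoint = trial_end_timepoint(train_trials)
    vascular_train = train_series.data.mean(axis=2)
    vascular_test = test_series.data.mean(axis=2)
    if align:
        test_series, shift = align_to_template(test_series, vascular_train)
    else:
        shift = np.zeros(2)
    similarity = cw_ssim(vascular_train, vascular_test)
    if preprocess:
        from .preprocess import preprocess_decode
        train_series = preprocess_decode(train_series)
        test_series = preprocess_decode(test_series)

    X_train, y_train = build_features(train_series, train_trials, timepoint)
    X_test, y_test = build_features(test_series, test_trials, timepoint)
    model = fit_multicoder(X_train, y_train)
    preds = predict_multicoder(model, X_test)
    pc = percent_correct(preds, y_test)
    err = float(np.nanmean(angular_error(preds, y_test)))
    n = len(y_test)
    out = {
        "percent_correct": pc,
        "mean_angular_error_deg": err,
        "binomial_p": binomial_p(int(round(pc / 100.0 * n)), n),
        "n_test_trials": n,
        "timepoint": timepoint,
        "alignment_shift_vox": tuple(np.asarray(shift, dtype=float)),
        "cw_ssim": similarity,
    }
    if baseline:
        within = cross_validate(train_series, train_trials, scheme="10fold",
                                timepoints=[timepoint], seed=seed)
        base_pc = float(within.percent_correct[0])
        out["within_session_percent_correct"] = base_pc
        out["normalized_accuracy"] = pc / base_pc if base_pc > 0 else np.nan
    return out


def similarity_vs_performance(pairs) -> dict:
    """Correlate vascular-image similarity with cross-session performance.

    ``pairs`` is an iterable of dicts (or a DataFrame) with at least
    ``cw_ssim`` and ``percent_correct`` (optionally
    ``mean_angular_error_deg``). Returns Pearson and Spearman correlations
    with p-values; constant inputs yield NaN correlations (undefined-flag).
    """
    df = pd.DataFrame(pairs)
    out = {"n_pairs": len(df)}
    for metric in ("percent_correct", "mean_angular_error_deg"):
        if metric not in df:
            continue
        x, y = df["cw_ssim"].to_numpy(float), df[metric].to_numpy(float)
        if len(df) < 2 or np.std(x) == 0 or np.std(y) == 0:
            out[f"pearson_{metric}"] = (np.nan, np.nan)
            out[f"spearman_{metric}"] = (np.nan, np.nan)
            continue
        pr = stats.pearsonr(x, y)
        sr = stats.spearmanr(x, y)
        out[f"pearson_{metric}"] = (float(pr.statistic), float(pr.pvalue))
        out[f"spearman_{metric}"] = (float(sr.statistic), float(sr.pvalue))
    return out
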