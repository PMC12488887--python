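"""Single-trial direction decoding with the PCA + dual-LDA multicoder.

Features are whole-image voxel intensities over a dynamic window of frames
after cue onset, z-scored with train-fold statistics and reduced by PCA
retaining 95% of the variance. Two 3-class linear discriminants predict the
horizontal (left / center / right) and vertical (down / center / up)
movement components, which are combined into one of the eight target
angles; a joint (center, center) prediction yields a ninth "center" class.
Significance uses a 1-sided binomial test against the conservative 1/8
chance level for percent correct, and a permutation null of uniform
directional guesses for the mean absolute angular error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .core import (
    DIRECTIONS_DEG,
    PowerDopplerSeries,
    angular_difference_deg,
    validate_trials,
)

#: Sentinel angle for the "center" prediction (not one of the 8 targets).
CENTER = np.nan

_H_LABEL = {0: 1, 45: 1, 315: 1, 90: 0, 270: 0, 135: -1, 180: -1, 225: -1}
_V_LABEL = {45: 1, 90: 1, 135: 1, 0: 0, 180: 0, 225: -1, 270: -1, 315: -1}


def horizontal_label(direction_deg):
    """-1 left / 0 center / +1 right for each of the 8 target angles."""
    return np.vectorize(lambda d: _H_LABEL[int(d) % 360])(direction_deg)


def vertical_label(direction_deg):
    """-1 down / 0 center / +1 up for each of the 8 target angles."""
    return np.vectorize(lambda d: _V_LABEL[int(d) % 360])(direction_deg)


def combine_components(h, v):
    """Combine (h, v) in {-1,0,1}^2 into an angle; (0,0) -> center (NaN)."""
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    angle = np.degrees(np.arctan2(v, h)) % 360.0
    return np.where((h == 0) & (v == 0), CENTER, angle)


def trial_end_timepoint(trials: pd.DataFrame) -> int:
    """Median number of whole frames from cue onset to reward (trial end)."""
    span = (trials["t_reward"] - trials["t_cue_on"]).to_numpy(dtype=float)
    return int(np.floor(np.median(span)))


def movement_end_timepoint(trials: pd.DataFrame) -> int:
    """Median number of whole frames from cue onset to movement end."""
    span = (trials["t_move_end"] - trials["t_cue_on"]).to_numpy(dtype=float)
    return int(np.floor(np.median(span)))


def build_feature_stack(series: PowerDopplerSeries, trials: pd.DataFrame,
                        timepoint: int) -> np.ndarray:
    """Per-trial frame stack, shape (n_trials, timepoint + 1, ny, nx).

    Frame ``k`` of trial ``i`` is the series frame ``k`` steps after that
    trial's cue-onset frame, clamped to the trial's last frame (reward) for
    trials whose events end before the requested timepoint.
    """
    validate_trials(trials)
    if timepoint < 0:
        raise ValueError("timepoint is indexed from cue onset; must be >= 0")
    ny, nx = series.shape
    out = np.empty((len(trials), timepoint + 1, ny, nx))
    for i, (_, tr) in enumerate(trials.iterrows()):
        cue = series.frame_index(tr.t_cue_on)
        last = min(series.frame_index(tr.t_reward), series.n_frames - 1)
        for k in range(timepoint + 1):
            out[i, k] = series.data[:, :, min(cue + k, last)]
    return out


def build_features(series: PowerDopplerSeries, trials: pd.DataFrame,
                   timepoint: int):
    """Dynamic-window feature matrix (n_trials, n_voxels * (timepoint+1)).

    Columns are voxel rasters stacked frame-major: all voxels at cue+0,
    then all voxels at cue+1, etc. Returns (X, labels_deg).
    """
    stack = build_feature_stack(series, trials, timepoint)
    n = stack.shape[0]
    X = stack.reshape(n, -1)
    y = trials["direction_deg"].to_numpy(dtype=float)
    return X, y


@dataclass
class MulticoderModel:
    """Fitted z-score + PCA + dual-LDA decoder."""

    train_mean: np.ndarray
    train_sd: np.ndarray
    pca: PCA | None
    lda_h: LinearDiscriminantAnalysis
    lda_v: LinearDiscriminantAnalysis
    n_components: int
    meta: dict = field(default_factory=dict)

    def transform(self, X):
        Z = (np.asarray(X, dtype=float) - self.train_mean) / self.train_sd
        return self.pca.transform(Z) if self.pca is not None else Z


def fit_multicoder(X, y_deg, pca_variance: float = 0.95,
                   skip_pca: bool = False) -> MulticoderModel:
    """Fit the multicoder on training trials.

    z-scoring and the PCA basis are estimated from the training data only;
    PCA retains the smallest number of components reaching ``pca_variance``
    cumulative explained variance. Each discriminant is a plain
    pooled-covariance LDA with empirical class priors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_deg)
    yh = horizontal_label(y)
    yv = vertical_label(y)
    for name, labels in (("horizontal", yh), ("vertical", yv)):
        if len(np.unique(labels)) < 3:
            raise ValueError(f"{name} problem is missing a class in training data")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd
    pca = None
    n_comp = Z.shape[1]
    if not skip_pca:
        pca = PCA(n_components=pca_variance, svd_solver="full")
        Z = pca.fit_transform(Z)
        n_comp = pca.n_components_
    lda_h = LinearDiscriminantAnalysis().fit(Z, yh)
    lda_v = LinearDiscriminantAnalysis().fit(Z, yv)
    return MulticoderModel(train_mean=mean, train_sd=sd, pca=pca,
                           lda_h=lda_h, lda_v=lda_v, n_components=n_comp,
                           meta={"n_features": X.shape[1]})


def predict_multicoder(model: MulticoderModel, X):
    """Predicted angles in degrees; NaN encodes the "center" class."""
    Z = model.transform(X)
    h = model.lda_h.predict(Z)
    v = model.lda_v.predict(Z)
    return combine_components(h, v)


def angular_error(pred_deg, true_deg, center_policy: str = "ninety"):
    """Absolute angular error in [0, 180] degrees per prediction.

    Center (NaN) predictions carry no directional information; by default
    they are scored 90 deg, the expected error of a direction-uninformative
    guess. ``center_policy='exclude'`` returns NaN for them instead.
    """
    pred = np.asarray(pred_deg, dtype=float)
    true = np.asarray(true_deg, dtype=float)
    err = angular_difference_deg(np.where(np.isnan(pred), 0.0, pred), true)
    if center_policy == "ninety":
        return np.where(np.isnan(pred), 90.0, err)
    if center_policy == "exclude":
        return np.where(np.isnan(pred), np.nan, err)
    raise ValueError("center_policy must be 'ninety' or 'exclude'")


def percent_correct(pred_deg, true_deg):
    pred = np.asarray(pred_deg, dtype=float)
    true = np.asarray(true_deg, dtype=float)
    hits = (~np.isnan(pred)) & (angular_difference_deg(np.where(np.isnan(pred), 0, pred), true) == 0)
    return 100.0 * hits.mean()


def null_angular_error_pmf():
    """Exact error distribution of a uniform guess over the 8 directions.

    By symmetry the absolute angular error of a uniform random guess takes
    values {0, 45, 90, 135, 180} deg with probabilities {1, 2, 2, 2, 1}/8,
    independent of the true direction; its mean is exactly 90 deg.
    """
    return {0.0: 1 / 8, 45.0: 2 / 8, 90.0: 2 / 8, 135.0: 2 / 8, 180.0: 1 / 8}


def binomial_p(k: int, n: int, chance: float = 1.0 / 8.0) -> float:
    """1-sided binomial tail P(K >= k | n, chance)."""
    return float(stats.binom.sf(k - 1, n, chance))


def permutation_p(observed_mean_error: float, n_trials: int, seed: int = 0,
                  n_replicates: int = 10_000) -> float:
    """Permutation p-value for the mean absolute angular error.

    Each replicate draws ``n_trials`` uniform directional guesses; the
    error of each guess follows the exact null pmf. The p-value is
    (1 + #{replicate mean < observed}) / (R + 1), so smaller errors are
    more significant and p is never exactly 0.
    """
    pmf = null_angular_error_pmf()
    vals = np.array(list(pmf))
    probs = np.array(list(pmf.values()))
    rng = np.random.default_rng(seed)
    draws = rng.choice(vals, size=(n_replicates, n_trials), p=probs)
    means = draws.mean(axis=1)
    return float((1 + np.sum(means < observed_mean_error)) / (n_replicates + 1))


@dataclass
class DecodeMetrics:
    """Per-timepoint cross-validated decoding results."""

    timepoints: np.ndarray
    percent_correct: np.ndarray
    mean_angular_error_deg: np.ndarray
    binomial_p: np.ndarray
    permutation_p: np.ndarray
    bonferroni_significant: np.ndarray
    predictions: np.ndarray        # (n_timepoints, n_trials), NaN = center
    true_deg: np.ndarray
    meta: dict = field(default_factory=dict)

    def confusion(self, timepoint_index: int = -1) -> pd.DataFrame:
        """Row-normalized 8 true x 9 predicted confusion table (percent)."""
        pred = self.predictions[timepoint_index]
        cols = [f"{int(d)}" for d in DIRECTIONS_DEG] + ["center"]
        table = pd.DataFrame(0.0, index=[f"{int(d)}" for d in DIRECTIONS_DEG],
                             columns=cols)
        for t, p in zip(self.true_deg, pred):
            col = "center" if np.isnan(p) else f"{int(p)}"
            table.loc[f"{int(t)}", col] += 1
        sums = table.sum(axis=1).replace(0, 1)
        return 100.0 * table.div(sums, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timepoint": self.timepoints,
            "percent_correct": self.percent_correct,
            "mean_angular_error_deg": self.mean_angular_error_deg,
            "binomial_p": self.binomial_p,
            "permutation_p": self.permutation_p,
            "bonferroni_significant": self.bonferroni_significant,
        })


def _folds(y, scheme, seed):
    n = len(y)
    if scheme == "loo":
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    if scheme == "10fold":
        k = min(10, int(np.min(np.unique(y, return_counts=True)[1])))
        if k < 2:
            raise ValueError("fewer trials than folds")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros(n), y))
    raise ValueError("scheme must be 'loo' or '10fold'")


def cross_validate(series: PowerDopplerSeries, trials: pd.DataFrame,
                   scheme: str = "loo", timepoints=None, seed: int = 0,
                   pca_variance: float = 0.95, skip_pca: bool = False,
                   alpha: float = 0.01, center_policy: str = "ninety",
                   permutation_replicates: int = 10_000) -> DecodeMetrics:
    """Cross-validated multicoder decoding at one or more timepoints.

    ``timepoints`` are frame offsets from cue onset (default: trial end
    only). Test-fold labels are never seen during fitting; folds are
    stratified by direction for the 10-fold scheme.
    """
    if timepoints is None:
        timepoints = [trial_end_timepoint(trials)]
    timepoints = list(timepoints)
    y = trials["direction_deg"].to_numpy(dtype=float)
    folds = _folds(y, scheme, seed)

    max_tp = max(timepoints)
    stack = build_feature_stack(series, trials, max_tp)
    n = stack.shape[0]

    preds = np.full((len(timepoints), n), np.nan)
    pc = np.zeros(len(timepoints))
    err = np.zeros(len(timepoints))
    bp = np.zeros(len(timepoints))
    pp = np.zeros(len(timepoints))
    for ti, tp in enumerate(timepoints):
        X = stack[:, :tp + 1].reshape(n, -1)
        for train_idx, test_idx in folds:
            model = fit_multicoder(X[train_idx], y[train_idx],
                                   pca_variance=pca_variance, skip_pca=skip_pca)
            preds[ti, test_idx] = predict_multicoder(model, X[test_idx])
        pc[ti] = percent_correct(preds[ti], y)
        errs = angular_error(preds[ti], y, center_policy)
        err[ti] = np.nanmean(errs)
        k = int(round(pc[ti] / 100.0 * n))
        bp[ti] = binomial_p(k, n)
        pp[ti] = permutation_p(err[ti], n, seed=seed + 7 * ti,
                               n_replicates=permutation_replicates)
    m = len(timepoints)
    bonf = (np.minimum(bp, pp) * m) < alpha
    return DecodeMetrics(
        timepoints=np.array(timepoints),
        percent_correct=pc,
        mean_angular_error_deg=err,
        binomial_p=bp,
        permutation_p=pp,
        bonferroni_significant=bonf,
        predictions=preds,
        true_deg=y,
        meta={"scheme": scheme, "seed": seed, "n_trials": n},
    )


def backproject_weights(model: MulticoderModel, image_shape, n_window_frames: int,
                        top_fraction: float = 0.10):
    """Map pairwise LDA boundaries back into voxel space.

    For every ordered pair of the 8 directions: the horizontal and vertical
    boundary weights (constants discarded) are projected through the
    transposed PCA basis, reshaped to the feature window and summed over
    frames. Weights stay on the z-scored feature scale, where magnitude
    reflects a voxel's importance to the boundary. The two axis images are
    multiplied when the pair differs on both axes (followed by a signed
    square root to keep a comparable scale); when only one axis differs,
    that axis's image is used unchanged. Values outside the ``top_fraction``
    most extreme (|value|) are zeroed.

    Returns ``{(dir_i, dir_j): image}`` for i < j.
    """
    ny, nx = image_shape

    def boundary_image(lda, ci, cj):
        classes = list(lda.classes_)
        w = lda.coef_[classes.index(ci)] - lda.coef_[classes.index(cj)]
        if model.pca is not None:
            w = model.pca.components_.T @ w
        return w.reshape(n_window_frames, ny, nx).sum(axis=0)

    out = {}
    for i, di in enumerate(DIRECTIONS_DEG):
        for dj in DIRECTIONS_DEG[i + 1:]:
            hi, hj = int(horizontal_label(di)), int(horizontal_label(dj))
            vi, vj = int(vertical_label(di)), int(vertical_label(dj))
            h_img = boundary_image(model.lda_h, hi, hj) if hi != hj else None
            v_img = boundary_image(model.lda_v, vi, vj) if vi != vj else None
            if h_img is not None and v_img is not None:
                img = h_img * v_img
                img = np.sign(img) * np.sqrt(np.abs(img))
            elif h_img is not None:
                img = h_img
            elif v_img is not None:
                img = v_img
            else:
                continue
            thresh = np.quantile(np.abs(img), 1.0 - top_fraction)
            out[(int(di), int(dj))] = np.where(np.abs(img) >= thresh, img, 0.0)
    return out
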