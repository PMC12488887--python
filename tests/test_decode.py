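"""Multicoder decoding: features, fitting, prediction, metrics, significance."""

import numpy as np
import pandas as pd
import pytest

from fusimap.core import DIRECTIONS_DEG, PowerDopplerSeries
from fusimap.decode import (
    angular_error,
    backproject_weights,
    binomial_p,
    build_features,
    combine_components,
    cross_validate,
    fit_multicoder,
    horizontal_label,
    null_angular_error_pmf,
    percent_correct,
    permutation_p,
    predict_multicoder,
    trial_end_timepoint,
    vertical_label,
)
from fusimap.synthdata import (
    NoiseSpec,
    PatchSpec,
    TaskConfig,
    make_atlas,
    make_ground_truth,
    make_task_schedule,
    simulate_session,
)
from fusimap.preprocess import preprocess_decode


def toy_trials(n=8, seed=0):
    return make_task_schedule(TaskConfig.monkey_l(), n, seed=seed)


class TestLabelGeometry:
    @pytest.mark.parametrize("deg,h,v", [
        (0, 1, 0), (45, 1, 1), (90, 0, 1), (135, -1, 1),
        (180, -1, 0), (225, -1, -1), (270, 0, -1), (315, 1, -1),
    ])
    def test_screen_geometry_mapping(self, deg, h, v):
        assert horizontal_label(deg) == h
        assert vertical_label(deg) == v

    @pytest.mark.parametrize("h,v,expected", [
        (1, 1, 45.0), (0, 1, 90.0), (-1, 0, 180.0), (1, 0, 0.0),
        (-1, -1, 225.0), (0, -1, 270.0),
    ])
    def test_combination_quadrants(self, h, v, expected):
        assert combine_components(h, v) == expected

    def test_center_center_yields_center_class(self):
        assert np.isnan(combine_components(0, 0))

    def test_roundtrip_over_all_eight(self):
        for d in DIRECTIONS_DEG:
            assert combine_components(horizontal_label(d), vertical_label(d)) == d


class TestBuildFeatures:
    def test_window_sizes(self):
        tr = toy_trials()
        n_frames = int(tr.t_reward.max()) + 12
        series = PowerDopplerSeries(
            data=np.arange(16.0 * n_frames).reshape(4, 4, n_frames))
        X0, y = build_features(series, tr, 0)
        X2, _ = build_features(series, tr, 2)
        assert X0.shape == (8, 16)
        assert X2.shape == (8, 48)
        np.testing.assert_array_equal(y, tr.direction_deg)

    def test_manual_stacking_oracle(self):
        tr = toy_trials(8).iloc[:2].reset_index(drop=True)
        n_frames = int(tr.t_reward.max()) + 12
        rng = np.random.default_rng(5)
        data = rng.normal(size=(2, 2, n_frames))
        series = PowerDopplerSeries(data=data)
        X, _ = build_features(series, tr, 1)
        for i, (_, row) in enumerate(tr.iterrows()):
            cue = series.frame_index(row.t_cue_on)
            expected = np.concatenate(
                [data[:, :, cue].ravel(), data[:, :, cue + 1].ravel()])
            np.testing.assert_array_equal(X[i], expected)

    def test_short_trials_clamp_to_last_frame(self):
        tr = toy_trials(8)
        n_frames = int(tr.t_reward.max()) + 12
        data = np.random.default_rng(0).normal(size=(2, 2, n_frames))
        series = PowerDopplerSeries(data=data)
        big = 60  # beyond every trial's end
        X, _ = build_features(series, tr, big)
        row = tr.iloc[0]
        last = series.frame_index(row.t_reward)
        tail = X[0].reshape(big + 1, 4)[-1]
        np.testing.assert_array_equal(tail, data[:, :, last].ravel())

    def test_negative_timepoint_rejected(self):
        tr = toy_trials()
        series = PowerDopplerSeries(
            data=np.zeros((2, 2, int(tr.t_reward.max()) + 12)))
        with pytest.raises(ValueError):
            build_features(series, tr, -1)


class TestMulticoder:
    def _separable(self, n_per=6, sd=0.01, seed=0):
        """Gaussian clusters: one informative 2D subspace per axis."""
        rng = np.random.default_rng(seed)
        y = np.repeat(DIRECTIONS_DEG, n_per).astype(float)
        rng.shuffle(y)
        centers = np.column_stack(
            [np.cos(np.deg2rad(y)), np.sin(np.deg2rad(y))])
        X = np.hstack([centers + rng.normal(0, sd, centers.shape),
                       rng.normal(0, sd, (len(y), 20))])
        return X, y

    def test_perfectly_separable_training_accuracy(self):
        X, y = self._separable()
        model = fit_multicoder(X, y)
        preds = predict_multicoder(model, X)
        assert percent_correct(preds, y) == 100.0

    def test_n_components_on_constructed_spectrum(self, rng):
        # 2 latent directions mixed densely into 10 features carry ~all
        # variance even after per-feature z-scoring
        n = 40
        basis = rng.normal(size=(2, 10))
        scores = rng.normal(0, 10, (n, 2))
        X = scores @ basis + rng.normal(0, 1e-4, (n, 10))
        y = np.repeat(DIRECTIONS_DEG, 5).astype(float)
        model = fit_multicoder(X, y)
        assert model.n_components == 2

    def test_missing_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        y = np.array([0.0, 0.0, 45.0, 45.0, 315.0, 315.0])  # all "right"
        with pytest.raises(ValueError, match="missing a class"):
            fit_multicoder(X, y)

    def test_zscore_and_pca_fit_on_train_only(self):
        X, y = self._separable()
        model = fit_multicoder(X[:24], y[:24])
        np.testing.assert_allclose(model.train_mean, X[:24].mean(axis=0))

    def test_test_labels_never_influence_predictions(self):
        """Leak guard: predictions on held-out data are a function of the
        features only."""
        X, y = self._separable(sd=0.5)
        model = fit_multicoder(X[:32], y[:32])
        p1 = predict_multicoder(model, X[32:])
        p2 = predict_multicoder(model, X[32:])  # labels unused by contract
        np.testing.assert_array_equal(p1, p2)


class TestAngularError:
    @pytest.mark.parametrize("pred,true,expected", [
        (0.0, 0.0, 0.0), (315.0, 45.0, 90.0), (180.0, 0.0, 180.0),
        (350.0, 10.0, 20.0), (45.0, 90.0, 45.0),
    ])
    def test_wraparound_cases(self, pred, true, expected):
        assert angular_error(pred, true) == expected

    def test_center_scored_ninety_by_default(self):
        assert angular_error(np.nan, 135.0) == 90.0

    def test_center_excluded_policy(self):
        assert np.isnan(angular_error(np.nan, 135.0, center_policy="exclude"))


class TestSignificance:
    def test_all_correct_closed_form(self):
        assert binomial_p(20, 20) == pytest.approx((1 / 8) ** 20, rel=1e-9)

    def test_null_pmf_enumeration(self):
        pmf = null_angular_error_pmf()
        assert pmf == {0.0: 1 / 8, 45.0: 2 / 8, 90.0: 2 / 8,
                       135.0: 2 / 8, 180.0: 1 / 8}
        mean = sum(v * p for v, p in pmf.items())
        assert mean == 90.0

    def test_permutation_p_at_the_null_mean(self):
        p = permutation_p(90.0, n_trials=100, seed=1, n_replicates=4000)
        assert 0.35 < p < 0.65

    def test_small_observed_error_significant(self):
        # null SD ~ 57.3/sqrt(n) deg: 30 deg at n=100 is ~10 SD below 90
        assert permutation_p(30.0, n_trials=100, seed=1) < 1e-3

    def test_permutation_p_never_zero(self):
        assert permutation_p(0.0, 10, seed=0, n_replicates=100) == pytest.approx(1 / 101)


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def clean_session(self):
        """Noise-free session with strong diverse tuning: decodable."""
        atlas = make_atlas((24, 24), band_width=7, seed=31)
        spec = PatchSpec(n_patches=12, radius_um=(100, 250),
                         amplitude_range=(0.25, 0.35),
                         kappa_range=(1.0, 2.0), suppression_fraction=0.0,
                         contralateral_fraction=0.6)
        truth = make_ground_truth((24, 24), atlas, spec, seed=31)
        trials = make_task_schedule(TaskConfig.monkey_l(), 48, seed=32)
        series = simulate_session(truth, trials,
                                  noise=NoiseSpec(cv=0.005, drift_amplitude=0.0),
                                  seed=33)
        return preprocess_decode(series), trials

    def test_near_noise_free_session_decodes_far_above_chance(self, clean_session):
        series, trials = clean_session
        m = cross_validate(series, trials, scheme="loo")
        # class-heterogeneous pooled covariance keeps this below 100% even
        # at negligible noise, but far above the 12.5% chance level
        assert m.percent_correct[-1] >= 60.0
        assert m.mean_angular_error_deg[-1] <= 25.0

    def test_shuffled_labels_fall_to_chance(self, clean_session):
        series, trials = clean_session
        rng = np.random.default_rng(9)
        sh = trials.copy()
        sh["direction_deg"] = rng.permutation(sh["direction_deg"].to_numpy())
        m = cross_validate(series, sh, scheme="loo")
        n = len(sh)
        se = 100 * np.sqrt(0.125 * 0.875 / n)
        assert abs(m.percent_correct[-1] - 12.5) < 3.5 * se

    def test_ten_fold_stratified_runs(self, clean_session):
        series, trials = clean_session
        m = cross_validate(series, trials, scheme="10fold", seed=4)
        assert m.percent_correct[-1] >= 60.0

    def test_confusion_rows_sum_to_100(self, clean_session):
        series, trials = clean_session
        m = cross_validate(series, trials, scheme="10fold", seed=4)
        conf = m.confusion()
        np.testing.assert_allclose(conf.sum(axis=1), 100.0)

    def test_accuracy_monotone_in_snr(self):
        """Decoder accuracy rises with planted SNR across a 4-point sweep."""
        atlas = make_atlas((24, 24), band_width=7, seed=41)
        spec = PatchSpec(n_patches=12, radius_um=(100, 250),
                         suppression_fraction=0.0, contralateral_fraction=0.6)
        truth = make_ground_truth((24, 24), atlas, spec, seed=41)
        trials = make_task_schedule(TaskConfig.monkey_l(), 48, seed=42)
        accs = []
        for cv in (0.5, 0.15, 0.05, 0.01):
            series = simulate_session(truth, trials, noise=NoiseSpec(cv=cv),
                                      seed=43)
            m = cross_validate(preprocess_decode(series), trials,
                               scheme="10fold", seed=5)
            accs.append(m.percent_correct[-1])
        assert all(a <= b + 5.0 for a, b in zip(accs, accs[1:]))  # monotone up
        assert accs[-1] > accs[0] + 20.0

    def test_fewer_trials_than_folds_rejected(self, clean_session):
        series, trials = clean_session
        with pytest.raises(ValueError):
            cross_validate(series, trials.iloc[:8], scheme="10fold")


class TestBackprojection:
    def test_identity_pca_recovers_raw_weights(self):
        rng = np.random.default_rng(2)
        y = np.repeat(DIRECTIONS_DEG, 6).astype(float)
        X = rng.normal(size=(48, 16))
        X += np.outer(np.cos(np.deg2rad(y)), np.linspace(1, 2, 16))
        model = fit_multicoder(X, y, skip_pca=True)
        imgs = backproject_weights(model, (4, 4), 1)
        classes = list(model.lda_h.classes_)
        w = (model.lda_h.coef_[classes.index(1)]
             - model.lda_h.coef_[classes.index(-1)])
        expected = w.reshape(4, 4)
        # pair (0, 180) differs only horizontally: right vs left
        img = imgs[(0, 180)]
        nz = img != 0
        np.testing.assert_allclose(img[nz], expected[nz])

    def test_single_informative_voxel_survives_threshold(self):
        rng = np.random.default_rng(3)
        y = np.repeat(DIRECTIONS_DEG, 6).astype(float)
        X = rng.normal(0, 0.05, size=(48, 25))
        X[:, 7] += np.cos(np.deg2rad(y)) + 0.5 * np.sin(np.deg2rad(y))
        model = fit_multicoder(X, y, skip_pca=True)
        imgs = backproject_weights(model, (5, 5), 1)
        img = imgs[(45, 225)]  # differs on both axes
        assert img.ravel()[7] != 0.0

    def test_single_axis_pair_has_no_sqrt_rescaling(self):
        rng = np.random.default_rng(4)
        y = np.repeat(DIRECTIONS_DEG, 6).astype(float)
        X = rng.normal(size=(48, 9))
        X[:, 0] += np.cos(np.deg2rad(y))
        X[:, 1] += np.sin(np.deg2rad(y))
        model = fit_multicoder(X, y, skip_pca=True)
        imgs = backproject_weights(model, (3, 3), 1, top_fraction=1.0)
        classes = list(model.lda_v.classes_)
        w = (model.lda_v.coef_[classes.index(1)]
             - model.lda_v.coef_[classes.index(-1)])
        # (45, 315): up vs down, horizontal class identical (right)
        np.testing.assert_allclose(imgs[(45, 315)].ravel(), w)
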