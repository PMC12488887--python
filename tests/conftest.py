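"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from fusimap.core import PowerDopplerSeries
from fusimap.glm import build_design, cohens_d_map, direction_f_test, fdr_correct, fit_glm
from fusimap.preprocess import preprocess_decode, preprocess_glm
from fusimap.synthdata import (
    PatchSpec,
    TaskConfig,
    make_atlas,
    make_ground_truth,
    make_task_schedule,
    simulate_session,
)


@pytest.fixture(scope="session")
def default_session():
    """Default study-condition session: 64x64 plane, 96 trials, Monkey-L timing."""
    atlas = make_atlas((64, 64), seed=11)
    truth = make_ground_truth((64, 64), atlas, PatchSpec(), seed=11)
    trials = make_task_schedule(TaskConfig.monkey_l(), 96, seed=12)
    series = simulate_session(truth, trials, seed=13)
    return {"atlas": atlas, "truth": truth, "trials": trials, "series": series}


@pytest.fixture(scope="session")
def default_glm(default_session):
    """GLM-path preprocessing + fitted GLM on the default session."""
    g = preprocess_glm(default_session["series"])
    design = build_design(default_session["trials"], g.n_frames)
    result = fit_glm(g, design)
    direction_f_test(result)
    result.q_map = fdr_correct(result.p_map)
    result.cohens_d = cohens_d_map(g, default_session["trials"])
    return {"series": g, "result": result}


@pytest.fixture(scope="session")
def default_decode_series(default_session):
    return preprocess_decode(default_session["series"])


@pytest.fixture(scope="session")
def small_session():
    """Small fast session for unit tests: 32x32 plane, 32 trials."""
    atlas = make_atlas((32, 32), band_width=8, seed=21)
    truth = make_ground_truth(
        (32, 32), atlas,
        PatchSpec(n_patches=16, radius_um=(100.0, 300.0)), seed=21)
    trials = make_task_schedule(TaskConfig.monkey_l(), 32, seed=22)
    series = simulate_session(truth, trials, seed=23)
    return {"atlas": atlas, "truth": truth, "trials": trials, "series": series}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def flat_series():
    """Constant-in-time series with spatial structure, 40 frames."""
    img = np.linspace(1.0, 2.0, 16 * 16).reshape(16, 16)
    data = np.repeat(img[:, :, None], 40, axis=2)
    return PowerDopplerSeries(data=data)
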