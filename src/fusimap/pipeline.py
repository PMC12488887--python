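"""End-to-end orchestration: simulate -> preprocess -> map -> decode -> report.

A RunConfig names the stages to run and their parameters; one master seed
is expanded into fixed, independent per-stage streams so adding a stage
never perturbs the randomness of earlier ones, and the whole run is
deterministic given the seed. Each stage writes versioned outputs plus a
JSON log of its parameters into the run directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .core import PowerDopplerSeries, is_contralateral
from .decode import cross_validate, trial_end_timepoint, movement_end_timepoint
from .glm import build_design, cohens_d_map, direction_f_test, fdr_correct, fit_glm
from .preprocess import preprocess_decode, preprocess_glm
from .searchlight import glm_searchlight_overlap, searchlight_map, threshold_overlay
from .spatialstats import spatial_autocorrelation
from .synthdata import (
    PatchSpec,
    TaskConfig,
    make_atlas,
    make_ground_truth,
    make_task_schedule,
    simulate_session,
)
from .tuning import preferred_direction, population_summaries

ALL_STAGES = ["simulate", "preprocess", "glm", "tuning", "decode",
              "searchlight", "autocorr", "report"]

# fixed per-stage spawn keys: appending stages never shifts earlier streams
_STAGE_KEYS = {name: i for i, name in enumerate(ALL_STAGES)}


def stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master_seed), _STAGE_KEYS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    shape: tuple = (64, 64)
    n_trials: int = 96
    task: dict = field(default_factory=dict)
    patches: dict = field(default_factory=dict)
    glm_q_thresh: float = 0.01
    overlap_q_thresh: float = 0.001
    autocorr_max_mm: float = 1.0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.shape = tuple(cfg.shape)
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns in-memory results per stage."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    state: dict = {}

    def require(name):
        if name not in state:
            raise RuntimeError(f"stage requires missing upstream artifact: {name}")
        return state[name]

    for stage in config.stages:
        if stage == "simulate":
            seed = stage_seed(config.seed, "simulate")
            atlas = make_atlas(config.shape, seed=seed)
            truth = make_ground_truth(config.shape, atlas,
                                      PatchSpec(**config.patches), seed=seed)
            task = TaskConfig(**config.task) if config.task else TaskConfig.monkey_l()
            trials = make_task_schedule(task, config.n_trials, seed=seed + 1)
            series = simulate_session(truth, trials, seed=seed + 2)
            state.update(atlas=atlas, truth=truth, trials=trials, raw=series)
            io.save_series(series, out / "session_raw.nii")
            io.save_trials(trials, out / "trials.csv")
            io.save_map(truth.preferred_direction_deg, out / "truth_direction.nii")
            io.save_map(atlas.label_map, out / "atlas_labels.nii")
            io.save_json({"seed": seed, "shape": list(config.shape),
                          "n_trials": config.n_trials}, out / "simulate.json")
            results["simulate"] = {"n_trials": len(trials),
                                   "n_tuned_voxels": int(truth.tuned_mask.sum())}
        elif stage == "preprocess":
            raw = require("raw")
            state["glm_series"] = preprocess_glm(raw)
            state["decode_series"] = preprocess_decode(raw)
            io.save_json({"paths": ["glm", "decode"]}, out / "preprocess.json")
            results["preprocess"] = {"n_frames": raw.n_frames}
        elif stage == "glm":
            series = require("glm_series")
            trials = require("trials")
            design = build_design(trials, series.n_frames)
            res = fit_glm(series, design)
            direction_f_test(res)
            res.q_map = fdr_correct(res.p_map)
            res.cohens_d = cohens_d_map(series, trials)
            state["glm_result"] = res
            io.save_map(res.F_map, out / "glm_F.nii")
            io.save_map(res.q_map, out / "glm_q.nii")
            design.to_frame().to_csv(out / "design_matrix.csv", index=False)
            results["glm"] = {
                "n_significant": int((res.q_map < config.glm_q_thresh).sum())}
        elif stage == "tuning":
            res = require("glm_result")
            atlas = require("atlas")
            angle, mag = preferred_direction(res.cohens_d)
            sig = res.q_map < config.glm_q_thresh
            regions, depth = population_summaries(angle, sig, atlas)
            state.update(pref_angle=angle, pref_mag=mag, sig_mask=sig)
            io.save_map(angle, out / "preferred_direction.nii")
            io.save_map(mag, out / "tuning_magnitude.nii")
            regions.to_csv(out / "region_summary.csv", index=False)
            lip = regions.set_index("region")
            results["tuning"] = {
                "lip_contralateral_fraction":
                    float(lip.loc["LIP", "contralateral_fraction"]),
                "n_significant": int(sig.sum()),
            }
        elif stage == "decode":
            series = require("decode_series")
            trials = require("trials")
            metrics = cross_validate(series, trials, scheme="loo",
                                     seed=stage_seed(config.seed, "decode"))
            state["decode_metrics"] = metrics
            metrics.to_frame().to_csv(out / "decode_metrics.csv", index=False)
            metrics.confusion().to_csv(out / "confusion.csv")
            results["decode"] = {
                "percent_correct": float(metrics.percent_correct[-1]),
                "mean_angular_error_deg": float(metrics.mean_angular_error_deg[-1]),
            }
        elif stage == "searchlight":
            series = require("decode_series")
            trials = require("trials")
            atlas = require("atlas")
            res = require("glm_result")
            sl = searchlight_map(series, trials, atlas=atlas,
                                 timepoint=movement_end_timepoint(trials),
                                 respect_sulcus=False, mask=atlas.cortex_mask,
                                 seed=stage_seed(config.seed, "searchlight"))
            finite = ~np.isnan(sl["binomial_p"])
            sl_q = np.full(sl["binomial_p"].shape, np.nan)
            sl_q[finite] = fdr_correct(sl["binomial_p"][finite])
            dsc = glm_searchlight_overlap(res.q_map, sl_q,
                                          thresh=config.overlap_q_thresh)
            state["searchlight"] = sl
            io.save_map(sl["angular_error_deg"], out / "searchlight_error.nii")
            io.save_map(sl["percent_correct"], out / "searchlight_pc.nii")
            results["searchlight"] = {"dice_vs_glm": dsc}
        elif stage == "autocorr":
            series = require("decode_series")
            profile = spatial_autocorrelation(series, max_mm=config.autocorr_max_mm)
            profile.to_csv(out / "spatial_autocorrelation.csv", index=False)
            results["autocorr"] = {
                "r_at_0.1mm": float(profile["mean_r"].iloc[0]),
                "r_at_max": float(profile["mean_r"].iloc[-1]),
            }
        elif stage == "report":
            io.save_json(results, out / "report.json")
        else:
            raise ValueError(f"unknown stage: {stage}")
    return results
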