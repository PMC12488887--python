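"""Voxelwise general linear model of direction-dependent memory activity.

Each voxel's preprocessed time series is modelled as a linear combination
of task regressors (fixation; one memory and one movement regressor per
direction; reward) convolved with a single-gamma hemodynamic response
function, plus an intercept. An F contrast over the eight memory-direction
coefficients identifies voxels whose delay-period response depends on the
planned saccade direction, and Benjamini-Hochberg correction controls the
false discovery rate over voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DIRECTIONS_DEG, PowerDopplerSeries, validate_trials


@dataclass
class HRFParams:
    """Single-gamma hemodynamic response parameters.

    tau_s : time constant of the gamma kernel (s)
    delta_s : pure onset delay (s)
    n_phase : phase delay (shape parameter); the kernel peaks at
        ``delta_s + (n_phase - 1) * tau_s`` seconds.
    """

    tau_s: float = 1.0
    delta_s: float = 1.0
    n_phase: int = 3

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.n_phase < 1:
            raise ValueError("n_phase must be >= 1")
        if self.delta_s < 0:
            raise ValueError("delta_s must be >= 0")


def gamma_hrf(params: HRFParams | None = None, t_s: np.ndarray | None = None):
    """Sampled single-gamma HRF kernel, normalized to unit sum.

    h(t) = 0 for t < delta; h(t) ~ ((t-delta)/tau)^(n-1) exp(-(t-delta)/tau)
    otherwise. With the default 1 Hz sampling the kernel spans 32 s, well
    past the point where the gamma density has decayed to ~0.
    """
    params = params or HRFParams()
    if t_s is None:
        t_s = np.arange(0.0, 32.0, 1.0)
    t_s = np.asarray(t_s, dtype=float)
    if t_s.size == 0:
        raise ValueError("empty time grid")
    u = (t_s - params.delta_s) / params.tau_s
    h = np.where(u > 0, np.power(np.clip(u, 0, None), params.n_phase - 1) * np.exp(-np.clip(u, 0, None)), 0.0)
    # t exactly at delta: u=0 -> 0 for n>1, 1 for n=1
    if params.n_phase == 1:
        h = np.where(u >= 0, np.exp(-np.clip(u, 0, None)), 0.0)
    s = h.sum()
    if s <= 0:
        raise ValueError("HRF kernel has zero mass on this grid")
    return h / s


@dataclass
class DesignMatrix:
    """Named task regressors convolved with the HRF, one row per frame."""

    matrix: np.ndarray  # (n_frames, n_columns)
    names: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("names must match matrix columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("column names must be unique")

    @property
    def memory_columns(self):
        return [i for i, n in enumerate(self.names) if n.startswith("memory_")]

    def column(self, name):
        return self.matrix[:, self.names.index(name)]

    def to_frame(self):
        return pd.DataFrame(self.matrix, columns=self.names)


def _boxcar(frame_times, start, stop, dt=1.0):
    """Fractional overlap of [start, stop) with each frame's interval.

    Sub-frame events (e.g. a ~0.5 s movement period sampled at 1 Hz) then
    contribute proportionally instead of vanishing whenever they miss a
    frame tick, which would leave an all-zero (collinear) column.
    """
    lo = np.maximum(frame_times, start)
    hi = np.minimum(frame_times + dt, stop)
    return np.clip(hi - lo, 0.0, None) / dt


def build_design(trials: pd.DataFrame, n_frames: int, hrf_kernel=None,
                 frame_times=None) -> DesignMatrix:
    """Boxcar task regressors convolved with the HRF, truncated to n_frames.

    Regressors: fixation (fix-on to cue-on, pooled), memory per direction
    (cue-off to go), movement per direction (go to movement end), reward
    (reward delivery frame), and a constant. Columns whose events never
    occur are omitted and recorded in ``meta['omitted']``.
    """
    validate_trials(trials)
    if hrf_kernel is None:
        hrf_kernel = gamma_hrf()
    if frame_times is None:
        frame_times = np.arange(n_frames, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    dt = frame_times[1] - frame_times[0] if n_frames > 1 else 1.0
    t_max = frame_times[-1] + dt
    ev = trials[["t_fix_on", "t_reward"]].to_numpy(dtype=float)
    if ev.min() < 0 or trials["t_reward"].max() >= t_max:
        raise ValueError("trial events fall outside the sampled frame range")

    cols, names = [], []
    fix = np.zeros(n_frames)
    for _, tr in trials.iterrows():
        fix += _boxcar(frame_times, tr.t_fix_on, tr.t_cue_on, dt)
    cols.append(np.clip(fix, 0, 1))
    names.append("fixation")

    omitted = []
    for kind, start_col, stop_col in (
        ("memory", "t_cue_off", "t_go"),
        ("movement", "t_go", "t_move_end"),
    ):
        for d in DIRECTIONS_DEG:
            sub = trials[trials.direction_deg == d]
            if len(sub) == 0:
                omitted.append(f"{kind}_{d}")
                continue
            box = np.zeros(n_frames)
            for _, tr in sub.iterrows():
                box += _boxcar(frame_times, tr[start_col], tr[stop_col], dt)
            cols.append(np.clip(box, 0, 1))
            names.append(f"{kind}_{d}")

    rew = np.zeros(n_frames)
    for _, tr in trials.iterrows():
        rew += _boxcar(frame_times, tr.t_reward, tr.t_reward + 1.0, dt)
    if rew.any():
        cols.append(np.clip(rew, 0, 1))
        names.append("reward")
    else:
        omitted.append("reward")

    keep = [i for i, c in enumerate(cols) if np.any(c)]
    omitted += [names[i] for i in range(len(cols)) if i not in keep]
    cols = [cols[i] for i in keep]
    names = [names[i] for i in keep]
    X = np.stack(cols, axis=1)
    X = np.apply_along_axis(lambda c: np.convolve(c, hrf_kernel)[:n_frames], 0, X)
    X = np.column_stack([X, np.ones(n_frames)])
    names.append("constant")
    return DesignMatrix(matrix=X, names=names, meta={"omitted": omitted})


@dataclass
class GLMResult:
    """Per-voxel OLS fit plus derived statistical maps."""

    beta: np.ndarray          # (n_regressors, ny, nx)
    sigma2: np.ndarray        # (ny, nx) residual variance
    dof: int
    design: DesignMatrix
    shape: tuple
    F_map: np.ndarray | None = None
    p_map: np.ndarray | None = None
    q_map: np.ndarray | None = None
    cohens_d: np.ndarray | None = None  # (8, ny, nx)


def fit_glm(series: PowerDopplerSeries, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares per voxel."""
    X = design.matrix
    n, p = X.shape
    if series.n_frames != n:
        raise ValueError("design rows must equal series frames")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    ny, nx = series.shape
    Y = series.data.reshape(ny * nx, n).T  # (n_frames, n_voxels)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    return GLMResult(
        beta=beta.reshape(p, ny, nx),
        sigma2=sigma2.reshape(ny, nx),
        dof=dof,
        design=design,
        shape=(ny, nx),
    )


def direction_f_test(result: GLMResult):
    """F-test for equality of the eight memory-direction coefficients.

    Framed as a contrast of 7 independent pairwise differences on the full
    model; algebraically identical to the full-vs-reduced model comparison.
    """
    mem = result.design.memory_columns
    if len(mem) < 2:
        raise ValueError("design has fewer than two memory regressors")
    p = result.design.matrix.shape[1]
    k = len(mem)
    C = np.zeros((k - 1, p))
    for i in range(k - 1):
        C[i, mem[i]] = 1.0
        C[i, mem[i + 1]] = -1.0
    X = result.design.matrix
    XtX_inv = np.linalg.inv(X.T @ X)
    M = C @ XtX_inv @ C.T
    M_inv = np.linalg.inv(M)
    ny, nx = result.shape
    B = result.beta.reshape(p, ny * nx)
    CB = C @ B                       # (k-1, n_voxels)
    quad = np.einsum("iv,ij,jv->v", CB, M_inv, CB)
    sigma2 = result.sigma2.reshape(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = quad / ((k - 1) * sigma2)
    F = np.where(sigma2 > 0, F, 0.0)
    pvals = stats.f.sf(F, k - 1, result.dof)
    result.F_map = F.reshape(ny, nx)
    result.p_map = pvals.reshape(ny, nx)
    return result.F_map, result.p_map


def fdr_correct(p_map, scope="plane"):
    """Benjamini-Hochberg q-values.

    ``scope='plane'`` corrects one map (array in, array out);
    ``scope='all-planes'`` takes a list of maps and corrects across the
    concatenation, mirroring the across-session analysis.
    """
    if scope == "plane":
        p = np.asarray(p_map, dtype=float)
        q = multipletests(p.ravel(), method="fdr_bh")[1]
        return q.reshape(p.shape)
    if scope == "all-planes":
        maps = [np.asarray(m, dtype=float) for m in p_map]
        flat = np.concatenate([m.ravel() for m in maps])
        q = multipletests(flat, method="fdr_bh")[1]
        out, i = [], 0
        for m in maps:
            out.append(q[i:i + m.size].reshape(m.shape))
            i += m.size
        return out
    raise ValueError("scope must be 'plane' or 'all-planes'")


def cohens_d_map(series: PowerDopplerSeries, trials: pd.DataFrame,
                 baseline_window_s=(-1.0, 1.0), pool_baseline=False):
    """Standardized per-direction memory response, per voxel.

    For each direction: the response sample is the frame nearest the end of
    the memory period on each of that direction's trials; the baseline
    sample pools frames within ``baseline_window_s`` of cue onset over the
    same trials (or over all trials when ``pool_baseline``). Cohen's d uses
    the two-sample pooled standard deviation; positive d = CBV increase.
    Returns an array of shape (8, ny, nx).
    """
    validate_trials(trials)
    ny, nx = series.shape
    data = series.data.reshape(ny * nx, series.n_frames)
    t = series.frame_times_s

    base_all = []
    if pool_baseline:
        for _, tr in trials.iterrows():
            sel = (t >= tr.t_cue_on + baseline_window_s[0]) & (t <= tr.t_cue_on + baseline_window_s[1])
            base_all.append(data[:, sel])
        base_all = np.concatenate(base_all, axis=1)

    out = np.full((len(DIRECTIONS_DEG), ny * nx), np.nan)
    for di, d in enumerate(DIRECTIONS_DEG):
        sub = trials[trials.direction_deg == d]
        if len(sub) == 0:
            raise ValueError(f"direction {d} has zero trials")
        resp_idx = [series.frame_index(tr.t_go) for _, tr in sub.iterrows()]
        resp = data[:, resp_idx]
        if pool_baseline:
            base = base_all
        else:
            parts = []
            for _, tr in sub.iterrows():
                sel = (t >= tr.t_cue_on + baseline_window_s[0]) & (t <= tr.t_cue_on + baseline_window_s[1])
                parts.append(data[:, sel])
            base = np.concatenate(parts, axis=1)
        n1, n2 = resp.shape[1], base.shape[1]
        m1, m2 = resp.mean(axis=1), base.mean(axis=1)
        v1 = resp.var(axis=1, ddof=1) if n1 > 1 else np.zeros(ny * nx)
        v2 = base.var(axis=1, ddof=1) if n2 > 1 else np.zeros(ny * nx)
        sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / max(n1 + n2 - 2, 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            dvals = (m1 - m2) / sp
        out[di] = np.where(sp > 0, dvals, 0.0)
    return out.reshape(len(DIRECTIONS_DEG), ny, nx)
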