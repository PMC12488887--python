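"""Synthetic fUSI sessions with known directional ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: spatially contiguous patches of cortex sharing one preferred
direction with abrupt transitions between patches, a mostly contralateral
bias, direction-dependent fractional CBV responses up to ~20-30% (with
occasional suppression), gamma-HRF temporal smoothing, a multiplicative
vascular-intensity background, slow drift, optional frame-to-frame rigid
motion, and between-session plane shifts. Every stochastic choice is driven
by an explicit seed so sessions are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    CONTRA_DIRECTIONS,
    DIRECTIONS_DEG,
    IPSI_DIRECTIONS,
    TRIAL_COLUMNS,
    PowerDopplerSeries,
)
from .glm import HRFParams, gamma_hrf

REGION_CODES = {
    "background": 0,
    "LIP": 1,
    "MIP": 2,
    "VIP": 3,
    "Area5": 4,
    "Area7": 5,
    "MP": 6,
}


@dataclass
class TaskConfig:
    """Memory-guided saccade timing. Durations are uniform (low, high) in s."""

    n_directions: int = 8
    eccentricity_deg: float = 20.0   # metadata only
    fixation_dur: tuple = (3.75, 4.25)
    memory_dur: tuple = (3.75, 4.25)
    hold_dur: tuple = (0.6, 0.9)
    iti_dur: tuple = (4.0, 6.0)
    cue_dur_s: float = 0.4
    saccade_latency: tuple = (0.4, 0.6)
    frame_rate_hz: float = 1.0

    def __post_init__(self):
        if self.n_directions != 8:
            raise ValueError("task uses 8 equally spaced directions")
        for name in ("fixation_dur", "memory_dur", "hold_dur", "iti_dur", "saccade_latency"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 < low <= high")

    @classmethod
    def monkey_l(cls):
        """Fixation/memory 4 +/- 0.25 s, hold 0.75 +/- 0.15 s, ITI 5 +/- 1 s."""
        return cls(fixation_dur=(3.75, 4.25), memory_dur=(3.75, 4.25),
                   hold_dur=(0.6, 0.9), iti_dur=(4.0, 6.0))

    @classmethod
    def monkey_p(cls):
        """Fixation/memory 5 +/- 1 s, hold 1 +/- 0.5 s, ITI 8 +/- 2 s."""
        return cls(fixation_dur=(4.0, 6.0), memory_dur=(4.0, 6.0),
                   hold_dur=(0.5, 1.5), iti_dur=(6.0, 10.0))


@dataclass
class RegionAtlas:
    """Schematic anatomical labels around a drawn sulcus.

    label_map : int codes per REGION_CODES
    sulcus_side : 0 = non-cortex, 1 = lateral bank (side A), 2 = medial bank
    depth_fraction : fraction of sulcal depth in [0, 1] (0 at the surface)
    ap_position_mm : anterior-posterior plane coordinate (EBZ-relative;
        more negative = more posterior)
    """

    label_map: np.ndarray
    sulcus_side: np.ndarray
    depth_fraction: np.ndarray
    ap_position_mm: float = -4.0
    region_codes: dict = field(default_factory=lambda: dict(REGION_CODES))

    def __post_init__(self):
        if np.any((self.depth_fraction < 0) | (self.depth_fraction > 1)):
            raise ValueError("depth_fraction must lie in [0, 1]")
        cortical = self.label_map > 0
        if np.any(cortical & (self.sulcus_side == 0)):
            raise ValueError("sulcus_side must be defined for every cortical voxel")

    def mask(self, region):
        return self.label_map == self.region_codes[region]

    @property
    def cortex_mask(self):
        return self.label_map > 0


def make_atlas(shape, ap_position_mm=-4.0, band_width=12, seed=0) -> RegionAtlas:
    """Schematic banded atlas around a slanted sulcus polyline.

    The sulcus runs top-to-bottom with a gentle slant; voxels within
    ``band_width`` of the sulcus on its lateral side are labelled LIP and on
    the medial side MIP; farther bands become Area 7 / Area 5; the deepest
    rows near the sulcus tip are VIP, and the far-medial edge is MP. No
    histological fidelity is claimed - the atlas only provides plausible
    region masks, sulcus sides, and a depth coordinate.
    """
    ny, nx = shape
    rows = np.arange(ny)[:, None]
    cols = np.arange(nx)[None, :]
    sulcus_col = nx / 2 + 0.25 * (rows - ny / 2)  # polyline x(y)
    signed = cols - sulcus_col                    # <0 lateral, >0 medial
    dist = np.abs(signed)

    label = np.zeros(shape, dtype=np.int16)
    side = np.zeros(shape, dtype=np.int8)
    lateral = signed < 0
    medial = signed > 0
    in_band = (dist >= 1) & (dist <= band_width)
    far_band = (dist > band_width) & (dist <= 2 * band_width)
    deep = rows >= int(0.8 * ny)

    label[lateral & in_band] = REGION_CODES["LIP"]
    label[medial & in_band] = REGION_CODES["MIP"]
    label[lateral & far_band] = REGION_CODES["Area7"]
    label[medial & far_band] = REGION_CODES["Area5"]
    label[(dist <= 2 * band_width) & deep & (label > 0)] = REGION_CODES["VIP"]
    label[medial & (dist > 2 * band_width)] = REGION_CODES["MP"]

    side[(label > 0) & lateral] = 1
    side[(label > 0) & medial] = 2

    depth = np.clip(np.broadcast_to(rows / max(ny - 1, 1), shape).astype(float), 0, 1)
    return RegionAtlas(label_map=label, sulcus_side=side, depth_fraction=depth,
                       ap_position_mm=ap_position_mm)


def make_task_schedule(config: TaskConfig, n_trials: int, seed: int,
                       t_start_s: float = 10.0) -> pd.DataFrame:
    """Balanced, seed-randomized trial schedule with uniform state durations.

    Each of the 8 directions appears floor(n/8) or ceil(n/8) times; fixation
    and memory durations are drawn independently per trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    reps, extra = divmod(n_trials, len(DIRECTIONS_DEG))
    dirs = np.repeat(DIRECTIONS_DEG, reps)
    if extra:
        dirs = np.concatenate([dirs, rng.choice(DIRECTIONS_DEG, extra, replace=False)])
    rng.shuffle(dirs)

    def draw(bounds):
        lo, hi = bounds
        return rng.uniform(lo, hi)

    rows = []
    t = float(t_start_s)
    for i, d in enumerate(dirs):
        t_fix = t
        t_cue_on = t_fix + draw(config.fixation_dur)
        t_cue_off = t_cue_on + config.cue_dur_s
        t_go = t_cue_off + draw(config.memory_dur)
        t_move_end = t_go + draw(config.saccade_latency)
        t_reward = t_move_end + draw(config.hold_dur)
        rows.append((i, int(d), t_fix, t_cue_on, t_cue_off, t_go, t_move_end, t_reward))
        t = t_reward + draw(config.iti_dur)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@dataclass
class PatchSpec:
    """Placement rules for directionally tuned patches."""

    n_patches: int = 48
    radius_um: tuple = (100.0, 400.0)
    direction_rule: str = "random"        # or "ap_gradient"
    contralateral_fraction: float = 0.88
    amplitude_range: tuple = (0.10, 0.30)
    suppression_fraction: float = 0.10
    kappa_range: tuple = (0.5, 4.0)
    ap_gradient_deg_per_mm: float = -15.0  # signed pref angle vs AP position
    ap_gradient_ref_mm: float = -5.0       # plane where the gradient crosses 0 deg


@dataclass
class GroundTruth:
    """Per-voxel generative parameters (the recovery target)."""

    preferred_direction_deg: np.ndarray  # NaN where untuned
    kappa: np.ndarray
    amplitude: np.ndarray                # signed fractional CBV modulation
    baseline: np.ndarray                 # vascular intensity background
    atlas: RegionAtlas
    patch_id: np.ndarray | None = None   # 0 = untuned, 1..n = patch index
    meta: dict = field(default_factory=dict)

    @property
    def tuned_mask(self):
        return ~np.isnan(self.preferred_direction_deg)

    @property
    def effective_direction_deg(self):
        """Direction the centroid analysis is expected to recover.

        For an excitatory patch this is the planted preferred direction;
        for a suppression patch (negative amplitude) the response centroid
        points away from the suppressed direction, so the expected recovery
        is the planted direction + 180 deg.
        """
        eff = self.preferred_direction_deg.copy()
        flip = self.tuned_mask & (self.amplitude < 0)
        eff[flip] = (eff[flip] + 180.0) % 360.0
        return eff

    @property
    def shape(self):
        return self.preferred_direction_deg.shape

    def direction_gain(self, direction_deg):
        """Von-Mises-shaped fractional response to one trial direction."""
        gain = np.zeros(self.shape)
        m = self.tuned_mask
        dtheta = np.deg2rad(direction_deg - self.preferred_direction_deg[m])
        gain[m] = self.amplitude[m] * np.exp(self.kappa[m] * (np.cos(dtheta) - 1.0))
        return gain


def make_vascular_baseline(shape, seed, mean_intensity=100.0, n_vessels=6):
    """Smoothed lognormal field with a few bright vessel tracks."""
    rng = np.random.default_rng(seed)
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    base = np.exp(1.2 * field_ / max(field_.std(), 1e-12))
    ny, nx = shape
    for _ in range(n_vessels):
        y = rng.uniform(0, ny)
        x = rng.uniform(0, nx)
        ang = rng.uniform(0, 2 * np.pi)
        for _step in range(int(1.5 * max(ny, nx))):
            iy, ix = int(y) % ny, int(x) % nx
            base[iy, ix] += 4.0
            ang += rng.normal(0, 0.25)
            y += np.sin(ang)
            x += np.cos(ang)
    base = ndimage.gaussian_filter(base, 0.8)
    return base * (mean_intensity / base.mean())


def _place_patches(lip_mask, spec, pixdim_mm, rng):
    """Disjoint contiguous disk patches inside the LIP mask."""
    ny, nx = lip_mask.shape
    vox_um = pixdim_mm * 1000.0
    r_lo, r_hi = spec.radius_um
    if r_hi < vox_um:
        raise ValueError("patch radius smaller than one voxel")
    candidates = np.argwhere(lip_mask)
    rows = np.arange(ny)[:, None]
    cols = np.arange(nx)[None, :]
    patches, centers, radii = [], [], []
    attempts = 0
    while len(patches) < spec.n_patches and attempts < 400 * spec.n_patches:
        attempts += 1
        cy, cx = candidates[rng.integers(len(candidates))]
        r_vox = rng.uniform(r_lo, r_hi) / vox_um
        ok = all(
            np.hypot(cy - py, cx - px) >= r_vox + pr
            for (py, px), pr in zip(centers, radii)
        )
        if not ok:
            continue
        disk = (rows - cy) ** 2 + (cols - cx) ** 2 <= r_vox ** 2
        disk &= lip_mask
        if patches:
            claimed = np.logical_or.reduce(patches)
            disk &= ~claimed  # earlier patches keep shared boundary voxels
        if disk.sum() < 1:
            continue
        patches.append(disk)
        centers.append((cy, cx))
        radii.append(r_vox)
    return patches, centers, radii


def _assign_directions(patches, spec, atlas, rng):
    """Per-patch preferred directions honouring the contralateral target.

    For the ``random`` rule, patch directions are drawn within the
    contralateral triplet {315, 0, 45} or the complement, with patches
    (largest first) greedily assigned to the contralateral group until the
    voxel-weighted contralateral fraction meets the target; this keeps the
    realized fraction within roughly one small patch of the target. For the
    ``ap_gradient`` rule, the mean preferred angle varies linearly with the
    plane's AP coordinate and per-patch jitter is added.
    """
    sizes = np.array([p.sum() for p in patches], dtype=float)
    n = len(patches)
    if spec.direction_rule == "ap_gradient":
        mu = spec.ap_gradient_deg_per_mm * (atlas.ap_position_mm - spec.ap_gradient_ref_mm)
        dirs = []
        for _ in range(n):
            jitter = rng.normal(0, 25.0)
            angle = (mu + jitter) % 360.0
            dirs.append(DIRECTIONS_DEG[np.argmin(np.abs(((DIRECTIONS_DEG - angle + 180) % 360) - 180))])
        return np.array(dirs, dtype=float)

    order = np.argsort(-sizes)
    total = sizes.sum()
    contra = np.zeros(n, dtype=bool)
    acc = 0.0
    for i in order:
        if (acc + sizes[i]) / total <= spec.contralateral_fraction + sizes[order[-1]] / (2 * total):
            contra[i] = True
            acc += sizes[i]
    # the non-contralateral share is planted on the ipsilateral triplet
    # {135, 180, 225}: the vertical directions 90/270 sit exactly on the
    # open-interval laterality boundary, where any estimation noise would
    # make the planted contralateral fraction unidentifiable
    ipsi_pool = np.array(IPSI_DIRECTIONS)
    dirs = np.where(
        contra,
        rng.choice(np.array(CONTRA_DIRECTIONS), n),
        rng.choice(ipsi_pool, n),
    )
    if spec.contralateral_fraction >= 1.0:
        dirs = rng.choice(np.array(CONTRA_DIRECTIONS), n)
    return dirs.astype(float)


def make_ground_truth(shape, atlas: RegionAtlas, patch_spec: PatchSpec | None = None,
                      seed: int = 0, pixdim_mm: float = 0.1) -> GroundTruth:
    """Plant tuned patches in LIP and record per-voxel generative truth."""
    spec = patch_spec or PatchSpec()
    rng = np.random.default_rng(seed)
    lip = atlas.mask("LIP")
    if not lip.any():
        raise ValueError("atlas contains no LIP voxels")
    patches, centers, radii = _place_patches(lip, spec, pixdim_mm, rng)
    # the contralateral target applies to the directions the centroid
    # analysis recovers; a suppressed patch recovers its planted
    # direction + 180, so assign effective directions first and flip the
    # stored planted direction for suppressed patches
    eff_dirs = _assign_directions(patches, spec, atlas, rng)
    n_suppress = int(round(spec.suppression_fraction * len(patches)))
    suppress = np.zeros(len(patches), dtype=bool)
    if n_suppress:
        suppress[rng.choice(len(patches), n_suppress, replace=False)] = True

    pref = np.full(shape, np.nan)
    kappa = np.zeros(shape)
    amp = np.zeros(shape)
    patch_id = np.zeros(shape, dtype=np.int32)
    for i, patch in enumerate(patches):
        pref[patch] = (eff_dirs[i] + 180.0) % 360.0 if suppress[i] else eff_dirs[i]
        kappa[patch] = rng.uniform(*spec.kappa_range)
        a = rng.uniform(*spec.amplitude_range)
        amp[patch] = -a if suppress[i] else a
        patch_id[patch] = i + 1

    baseline = make_vascular_baseline(shape, seed=rng.integers(2 ** 31))
    meta = {
        "patch_centers": centers,
        "patch_radii_vox": radii,
        "patch_effective_directions_deg": eff_dirs.tolist(),
        "patch_suppressed": suppress.tolist(),
        "patch_spec": spec,
        "seed": seed,
    }
    return GroundTruth(preferred_direction_deg=pref, kappa=kappa, amplitude=amp,
                       baseline=baseline, atlas=atlas, patch_id=patch_id,
                       meta=meta)


@dataclass
class NoiseSpec:
    """Measurement-noise model for simulated Power Doppler series.

    cv : per-frame multiplicative Gaussian coefficient of variation
    drift_amplitude : fractional amplitude of the slow sinusoidal drift
    drift_period_s : drift period; > 128 s so the GLM high-pass removes it
    motion_sd_vox : per-frame random-walk step of rigid motion (0 = none)
    motion_max_vox : random-walk reflection bound
    """

    cv: float = 0.05
    drift_amplitude: float = 0.02
    drift_period_s: float = 300.0
    motion_sd_vox: float = 0.0
    motion_max_vox: float = 2.0


def simulate_session(truth: GroundTruth, schedule: pd.DataFrame,
                     hrf: HRFParams | None = None,
                     noise: NoiseSpec | None = None,
                     seed: int = 0, n_frames: int | None = None,
                     frame_rate_hz: float = 1.0) -> PowerDopplerSeries:
    """Render a Power Doppler series from ground truth and a schedule.

    Per voxel: signal = baseline * (1 + tuning_gain (x) HRF + drift + noise),
    where the task drive is a boxcar spanning cue onset through the go cue
    for each trial, scaled by the voxel's von-Mises gain for that trial's
    direction, and convolved with the unit-sum gamma HRF.
    """
    hrf = hrf or HRFParams()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate_hz
    needed = int(np.ceil(schedule["t_reward"].max() / dt)) + 10
    if n_frames is None:
        n_frames = needed
    elif n_frames < needed:
        raise ValueError("schedule extends beyond requested series length")
    t = np.arange(n_frames) * dt

    kernel = gamma_hrf(hrf, np.arange(0.0, 32.0, dt))
    drive = np.zeros((len(DIRECTIONS_DEG), n_frames))
    for _, tr in schedule.iterrows():
        di = int(tr.direction_deg) // 45
        drive[di] += (t >= tr.t_cue_on) & (t < tr.t_go)
    drive = np.clip(drive, 0, 1)
    resp = np.apply_along_axis(lambda u: np.convolve(u, kernel)[:n_frames], 1, drive)

    gains = np.stack([truth.direction_gain(d) for d in DIRECTIONS_DEG])  # (8, ny, nx)
    ny, nx = truth.shape
    frac = np.tensordot(gains.reshape(len(DIRECTIONS_DEG), -1).T, resp, axes=1)  # (V, T)

    drift = noise.drift_amplitude * np.sin(
        2 * np.pi * t / noise.drift_period_s + rng.uniform(0, 2 * np.pi)
    )
    eps = rng.normal(0.0, noise.cv, size=(ny * nx, n_frames)) if noise.cv > 0 else 0.0
    data = truth.baseline.reshape(-1, 1) * (1.0 + frac + drift[None, :] + eps)
    data = np.clip(data, 0.0, None).reshape(ny, nx, n_frames)

    shifts = np.zeros((n_frames, 2))
    if noise.motion_sd_vox > 0:
        steps = rng.normal(0, noise.motion_sd_vox, size=(n_frames, 2))
        walk = np.cumsum(steps, axis=0)
        b = noise.motion_max_vox
        walk = b * np.sin(np.clip(walk / b, -np.pi / 2, np.pi / 2))  # soft reflection
        shifts = walk
        for f in range(n_frames):
            data[:, :, f] = ndimage.shift(data[:, :, f], shifts[f], order=1, mode="nearest")

    return PowerDopplerSeries(
        data=data,
        frame_times_s=t,
        meta={
            "seed": seed,
            "injected_shifts_vox": shifts,
            "noise": noise,
            "n_trials": len(schedule),
        },
    )


def perturb_plane(truth: GroundTruth, shift_um: float, seed: int = 0,
                  refresh_fraction: float | None = None,
                  pixdim_mm: float = 0.1) -> GroundTruth:
    """Emulate an imperfectly re-acquired imaging plane on a later day.

    Fields are translated in-plane by ``shift_um`` (along x), and a fraction
    of the vascular background and of the tuned patches is resampled to
    stand in for out-of-plane drift: a ``refresh_fraction`` of the grid
    (selected by a smooth random field, so replacements are contiguous)
    takes its tuning from an independently drawn plane, and the baseline is
    blended with a fresh vascular field with the same weight. The default
    refresh fraction is ``min(1, shift_um / 400)``: the imaging plane is
    ~400 um thick, so a displacement of that order samples essentially
    different tissue.
    """
    ny, nx = truth.shape
    dx = shift_um / (pixdim_mm * 1000.0)
    if abs(dx) >= nx:
        raise ValueError("shift larger than the grid")
    if refresh_fraction is None:
        refresh_fraction = min(1.0, shift_um / 400.0)
    rng = np.random.default_rng(seed)

    if shift_um == 0 and refresh_fraction == 0:
        return replace(truth, meta={**truth.meta, "shift_um": 0.0, "refresh_fraction": 0.0})

    def translate(a, order, cval):
        return ndimage.shift(a, (0.0, dx), order=order, mode="constant", cval=cval)

    pref = translate(truth.preferred_direction_deg, 0, np.nan)
    kappa = translate(truth.kappa, 0, 0.0)
    amp = translate(truth.amplitude, 0, 0.0)
    baseline = translate(truth.baseline, 1, float(np.median(truth.baseline)))
    patch_id = (translate(truth.patch_id.astype(float), 0, 0.0).astype(np.int32)
                if truth.patch_id is not None else None)

    if refresh_fraction > 0:
        fresh_base = make_vascular_baseline(truth.shape, seed=rng.integers(2 ** 31))
        baseline = (1 - refresh_fraction) * baseline + refresh_fraction * fresh_base
        # replace a deterministic fraction of the plane's tuning with an
        # independently drawn patchwork, selected by a smooth random field
        # so the replaced voxels form contiguous regions (out-of-plane
        # drift swaps in nearby, differently tuned tissue)
        spec = truth.meta.get("patch_spec", PatchSpec())
        fresh = make_ground_truth(truth.shape, truth.atlas, spec,
                                  seed=int(rng.integers(2 ** 31)),
                                  pixdim_mm=pixdim_mm)
        field_ = ndimage.gaussian_filter(
            np.random.default_rng(int(rng.integers(2 ** 31))).standard_normal(truth.shape), 2.0)
        thresh = np.quantile(field_, refresh_fraction)
        swap = field_ <= thresh
        pref[swap] = fresh.preferred_direction_deg[swap]
        kappa[swap] = fresh.kappa[swap]
        amp[swap] = fresh.amplitude[swap]
        if patch_id is not None and fresh.patch_id is not None:
            offset = int(patch_id.max()) + 1
            new_ids = np.where(fresh.patch_id > 0, fresh.patch_id + offset, 0)
            patch_id = np.where(swap, new_ids, patch_id).astype(np.int32)

    meta = {**truth.meta, "shift_um": float(shift_um),
            "refresh_fraction": float(refresh_fraction)}
    return GroundTruth(preferred_direction_deg=pref, kappa=kappa, amplitude=amp,
                       baseline=baseline, atlas=truth.atlas, patch_id=patch_id,
                       meta=meta)
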