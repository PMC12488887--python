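# Methods

This note records the models, parameter choices, and numerical decisions
behind `fusimap`, in the spirit of a methods appendix: what is computed,
under which assumptions, and where genuinely open choices were resolved.

## Signal model

A session is a 2D Power Doppler plane (default 64×64 voxels at 0.1 mm)
sampled at 1 Hz while the subject performs memory-guided saccades to eight
targets 45° apart at a single eccentricity. The synthetic generator writes
each voxel as

    I_v(t) = B_v · (1 + g_v(θ(t)) ⊛ h(t) + drift(t) + ε_v(t))

- `B_v` — a static vascular background: a smoothed lognormal field with a
  few bright vessel tracks, scaled to mean 100. It multiplies everything,
  as Power Doppler intensity is proportional to local blood volume.
- `g_v(θ)` — the direction gain. Tuned voxels carry a von-Mises-shaped
  profile `a_v · exp(κ_v (cos(θ − θ_v) − 1))`: `a_v` is the peak fractional
  CBV modulation (default drawn from 0.10–0.30, matching the 10–30%
  event-related changes such recordings show; a 10% minority of patches is
  planted with negative `a_v`, i.e. suppression), `κ_v` sets the tuning
  width (default 0.5–4, spanning broad hemifield tuning to narrow
  single-direction tuning).
- The drive is a boxcar from cue onset to the go cue of each trial,
  convolved with the unit-sum single-gamma HRF (τ = 1 s, δ = 1 s, n = 3;
  peak at δ + (n−1)τ = 3 s). The gamma-density functional form is the
  standard event-related choice for these parameters.
- `drift(t)` — a global sinusoid of fractional amplitude ≤ 2% with a 300 s
  period, slow enough that the 1/128 Hz high-pass of the GLM path removes
  it essentially completely.
- `ε_v(t)` — i.i.d. Gaussian with coefficient of variation 5% per frame.
  No published per-voxel noise level exists for 1 Hz Power Doppler at this
  resolution, so the CV is an explicit free parameter; decoder behaviour is
  verified to be monotone in it over a 10×-range sweep in the tests.
- Optionally a per-frame rigid translation random walk (soft-reflected at a
  bound) emulates within-session motion.

### Ground-truth topography

Tuned voxels form disjoint contiguous disk patches packed inside the
schematic LIP band (radius 100–400 µm; adjacent patches may touch, giving
the abrupt inter-patch transitions characteristic of the mapped cortex;
with the default 48 requested patches ~70% of LIP voxels end up tuned).
Within a patch the preferred direction is constant. Patch directions are
assigned so that a target fraction (default 88%) of tuned voxels prefer
contralateral directions {315°, 0°, 45°}; the remainder is planted on the
ipsilateral triplet {135°, 180°, 225°}. The vertical directions 90°/270°
are deliberately excluded from planting: they sit exactly on the open
interval (−90°, 90°) used to classify laterality, where any estimation
noise flips a voxel's side and the planted contralateral fraction would
stop being a well-defined recovery target. Largest-first greedy assignment
keeps the realized voxel-weighted fraction within ~1–2 points of the
target.

A suppression patch planted at θ is recovered by the centroid analysis at
θ + 180° (see below); `GroundTruth.effective_direction_deg` exposes this
expected recovery, and the contralateral target is applied to effective
directions so the planted fraction means what the recovered fraction
measures.

### Plane perturbation

`perturb_plane` emulates a later session on an imperfectly re-acquired
plane: an in-plane translation plus replacement of a fraction of the plane
(vascular background blended, tuning swapped against an independently
drawn patchwork, selected by a smooth random field so replacements are
contiguous). The default refresh fraction is `min(1, shift/400 µm)`,
anchored on the ~400 µm plane thickness: displacing the plane by its own
thickness samples essentially different tissue. An earlier per-patch
Bernoulli refresh was abandoned — it made the degradation between
realizations so variable that a heavily perturbed plane could decode
better than an unperturbed one.

### What the generator does not emulate

Real Power Doppler noise is non-Gaussian (speckle statistics), spatially
correlated through the vascular tree, and the hemodynamic response varies
across voxels and states; the atlas is schematic (banded regions around a
drawn sulcus polyline, no histological fidelity); eye movements, error
trials, and 2 Hz legacy acquisitions are not modelled. Passing tests
therefore demonstrate that the analysis correctly recovers what this class
of generative model plants — calibration of the statistics, geometry of
the maps, information flow of the decoders — not that it is robust to
every property of real recordings.

## Preprocessing

GLM path: Gaussian smoothing of FWHM 1 voxel (σ ≈ 0.4247 voxels), then a
per-voxel high-pass implemented as projection out of the low-frequency
discrete-cosine subspace (all DCT modes with period > 128 s; the
neuroimaging-standard realization of a drift cutoff), then grand-mean
scaling of the whole series to 100 (global scaling; per-voxel scaling was
rejected because it would erase relative response amplitudes). Boundary
handling for all spatial filters is nearest-edge replication.

Decode path: subtraction of a centered 50-frame moving average
(edge-truncated; an even window is realized as a symmetric 51-tap kernel
with half-weight endpoints so linear drifts detrend exactly), then a
2-voxel-radius pillbox (disk mean).

Motion correction registers every frame to the temporal median by
upsampled phase correlation (subvoxel, 10× upsampling), with shifts capped
at ±10 voxels as a guard on uninformative frames.

## GLM and tuning statistics

Per voxel, OLS on the convolved design (fixation; memory × 8 directions;
movement × 8; reward; constant). Event boxcars are sampled as fractional
overlap with each frame interval, so sub-frame events (the ~0.5 s movement
period at 1 Hz) contribute proportionally instead of aliasing to zero
columns. The direction F-test is a contrast of 7 adjacent differences of
the memory betas — algebraically the full-vs-reduced model comparison,
verified against an explicit refit oracle to 1e−10. FDR is
Benjamini–Hochberg, per plane or across concatenated planes.

Cohen's d per direction compares the frame nearest each trial's memory end
against the pooled frames within ±1 s of cue onset of the same direction's
trials (per-direction baseline by default; pooling across directions is a
flag), with the two-sample pooled SD.

Preferred direction is the circular center of mass of the eight d values
after scaling the peak response to 1. The scaling divides by max |d|
rather than the signed maximum: for a pure-suppression profile the signed
maximum is the least-suppressed response, a value that hovers at zero plus
noise, and dividing by it flips the recovered angle at random. With |d|
scaling the recovery is deterministic — an excitatory voxel recovers its
planted direction, a suppressed voxel the opposite one ("suppression
pushes away"); the signed convention remains available as an option.
Circular SD (√(−2 ln R̄), capped at the value corresponding to R̄ = 1e−12),
angular skewness and kurtosis use the standard trigonometric-moment
definitions on the clipped-nonnegative weights. The laterality index uses
the horizontal triplets {315°, 0°, 45°} vs {135°, 180°, 225°} (verticals
excluded; configurable). The anterior–posterior regression fits preferred
direction (signed degrees) on plane position by OLS, restricted by default
to contralateral-preferring voxels to avoid the 180° wrap.

## Decoding

Features are all voxels over the dynamic window cue+0 … cue+t (trials
ending earlier repeat their last frame); t defaults to the median whole
frames from cue to reward. Per fold: z-score fit on training trials, PCA
keeping the smallest component count reaching 95% cumulative variance,
then two 3-class pooled-covariance LDAs with empirical priors (no
regularization — the PCA step conditions the covariance) for the
horizontal and vertical movement components; (h, v) combine by atan2, and
(center, center) forms a ninth class. Center predictions score 90° angular
error — the expected error of a direction-uninformative guess — so they
are penalized but not maximally (configurable to "exclude"). Percent
correct is tested 1-sided binomial at 1/8 (the conservative end of the
[1/9, 1/8] empirical chance band); angular error against a permutation
null of uniform guesses, whose error distribution is exactly
{0°:1, 45°:2, 90°:2, 135°:2, 180°:1}/8 with mean 90°; the permutation p
uses the (1+count)/(R+1) correction; Bonferroni corrects across evaluated
timepoints. 10-fold CV is stratified by direction so no fold loses a
class.

LDA boundary weights are visualized by projecting each pairwise boundary
(constants discarded) through the transposed PCA basis, staying on the
z-scored feature scale where magnitude measures importance; the horizontal
and vertical images are multiplied for pairs differing on both axes
(followed by a signed square root to keep single-axis and dual-axis pairs
comparable), and thresholded to the 10% most extreme values.

## Searchlight

A pillbox ROI of 200 µm radius (≤13 voxels) centered on every voxel in the
evaluation mask, optionally restricted to the center's side of the sulcus;
10-fold CV of the full multicoder per ROI, metrics assigned to the center.
The in-ROI pipeline is the same z-score → PCA(95%) → dual LDA, executed by
a lean numpy path (economy SVD; pooled-covariance LDA with a 1e−6 relative
ridge): per-ROI estimator objects would dominate the runtime, and the
numpy LDA is verified against scikit-learn's on well-conditioned data. An
earlier shortcut that skipped PCA inside small ROIs was abandoned after it
cost up to ~12 accuracy points — the PCA step denoises tiny ROIs exactly
as it does whole images. The GLM-overlap variant runs at the movement-end
timepoint without the sulcus restriction, both maps are FDR-thresholded at
q ≤ 0.001, and overlap is the Dice–Sørensen coefficient (undefined and
excluded when both masks are empty).

## Cross-session stability

`cross_session_decode` takes raw sessions: the test session is first
rigidly aligned (translation-only upsampled phase correlation of the
temporal-mean vascular images, shifts capped at ±10 voxels — with little
shared anatomy the correlation surface can peak spuriously far away) and
only then detrended, because the decode-path series has a near-zero mean
image with nothing to register. The model is fitted once on every train
trial at the end-of-trial window and applied unchanged; normalized
accuracy divides by the train session's stratified 10-fold accuracy.

CW-SSIM uses a complex steerable pyramid built in the frequency domain:
raised-cosine dyadic radial rings × cos^(Q−1) angular masks on a
half-plane (analytic, complex-valued bands), Q = 16 orientations, 4
levels, bandpass level l sampled at 2^l as in the classic construction.
Per band, sliding 7×7 windows score
S = 2|Σ c_a c_b*| / (Σ|c_a|² + Σ|c_b|²) (K = 0), averaged over windows and
bands. Identical images score exactly 1; constant images are comparable
only to themselves (NaN otherwise). Note the empirical null for
independent noise at this configuration on 64×64 images is ≈ 0.4, not 0 —
sixteen narrowband orientations leave few independent coefficients per
window, which floors the chance similarity; comparisons should therefore
be read relative to that floor, which the monotone plane-change sweeps in
the tests do.

## Spatial autocorrelation

For every seed voxel, annuli (max(0, i−0.1) mm, i mm] of center-to-center
distance collect the Pearson correlations between the seed's and each
annulus voxel's time series; the per-bin mean is assigned to the seed, and
the profile reports the image-wide mean ± SD per bin. The seed never
enters its own bins; empty annuli are skipped; `max_mm` defaults to 3 mm.
Profiles can be computed on raw, GLM-path, or decode-path data — the
choice is the caller's, and smoothing provably inflates the profile
(dominance is a tested property).

## Orchestration and determinism

`run_pipeline` executes configured stages with one master seed expanded
into fixed per-stage streams (`SeedSequence([seed, stage_index])` with
stage indices frozen by name), so adding a stage never perturbs earlier
stages and a full run is bit-reproducible. Stages write NIfTI maps, CSV
tables, and JSON parameter logs to the run directory.

## Problem sizes

The default synthetic study conditions are a 64×64 plane (12.8 mm² of
cortex at 0.1 mm), 96 trials (12 per direction) with Monkey-L timing
(fixation and memory 4 ± 0.25 s, 400 ms cue, hold 0.75 ± 0.15 s, ITI
5 ± 1 s), giving ~1400 frames per session. The stability analyses sweep
plane shifts {0, 100, 300, 600 µm} with fresh ground truth per replicate.
Unit tests use 24–32 voxel grids and 32–48 trials.

## Known limitations

- OLS without prewhitening: serial correlation of CBV noise is not
  modelled (matching the scope of the mapped analysis; AR noise would
  widen the F-test's null slightly on real data).
- The multicoder's 3-class LDAs pool heterogeneous directions per class,
  so even noise-free sessions need not decode at 100%; accuracy saturates
  below that in a direction-coverage-dependent way.
- The searchlight assigns whole-ROI performance to the center voxel;
  localization is intrinsically blurred by the ROI radius.
- CW-SSIM values depend on image size and the orientation count; only
  comparisons within one configuration are meaningful.
- The AP-gradient analysis assumes a linear trend on wrapped angles and is
  restricted to the contralateral range by default; circular-linear
  regression would be needed for full-circle gradients.
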