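# Methods

`neflow` analyzes dual-color two-photon recordings of a green extracellular
norepinephrine (NE) sensor (GRAB-type, expressed on neuropil) and a red
somatic calcium indicator, and ships a synthetic movie generator that
produces such recordings with known ground truth. This note documents the
models, the numerical choices, and what the synthetic benchmarks do and do
not establish.

## The analysis pipeline

**Preprocessing.** Each channel is median-filtered per pixel over a 3-frame
window and mean-binned 2:1 in time (~30 Hz acquisition to ~15 Hz analysis
rate). Frames are registered by rigid translation against the temporal
average of the first five minutes; shifts are estimated by phase
cross-correlation on the structural (red) channel after a light 1.5 px blur
— the NE channel's plumes move on their own and would otherwise hijack the
correlation peak — and near-integer estimates are snapped to the integer
grid so that integer translations are exactly reversible. Cross-channel
bleed-through is removed per pixel by replacing each channel's time series
with the residual of its least-squares regression on the other channel at
the same pixel.

A caveat worth stating explicitly, because the synthetic benchmarks expose
it quantitatively: the per-pixel residual regression removes *any*
component of the channel of interest that correlates with the other
channel, including genuine biology. It is safe exactly when single-pixel
shot noise dominates the cross-channel covariance, so that the fitted slope
reflects the optical leak rather than shared signal. At realistic
single-pixel SNR (the generator's default `noise_sd = 0.15` of baseline)
and with the NE sensor largely absent from somata, the correction leaves
the NE–Ca coupling intact; in a noise-free simulation with full NE signal
inside somata it removes the planted coupling almost entirely.

**Field geometry.** Each soma mask gets a perisomatic "local NE" annulus —
the disk of radius 15 µm (default; configurable) around the soma centroid,
excluding all soma pixels and any pixel already claimed by a lower-indexed
cell's annulus (overlap pixels are excluded, not split) — and a "global NE"
field: the rest of the field of view. Traces are mask means, then linearly
detrended, smoothed with a Gaussian kernel of σ = 1 s, and z-scored
(detrend → smooth → z-score). Patch traces for the spatial autocorrelation
are standardized the same way.

**Spatial autocorrelation.** The FOV is tiled into 10 µm squares; all
pairwise Pearson correlations between patch traces are binned by
center-to-center distance (1 µm rounding) and the binned profile is fitted
with r(d) = a₁·exp(−d/λ₁) + a₂·exp(−d/λ₂) by multi-start bounded least
squares, λ₁ ≤ λ₂ by convention.

**NE synchrony.** Per cell, the Pearson correlation between the local and
global NE traces inside a 30 s sliding window (dense 1-frame stride,
window-centered; edges undefined). The run-average synchrony trace is
thresholded at its own temporal mean: frames strictly below are the "low
synchrony" regime, the remaining defined frames "high".

**Optic-flow event detection.** The NE movie is spatially blurred,
temporally smoothed, detrended and z-scored per pixel; pixels whose
temporal SD falls below 2% of the 99th-percentile SD are zeroed (z-scoring
a signal-free pixel would amplify numerical noise into unit-variance
structure). Horn–Schunck flow is computed between consecutive frames with
the classical Jacobi iteration (α = 1, early stop at mean update < 1e-4).
Critical points are 2×2 plaquettes where both velocity components change
sign, merged by connectivity, classified by the local Jacobian's
eigenvalues (source / sink / saddle / spiral-in / spiral-out), and gated on
the peak flow speed in their neighborhood (30% of the movie's
99th-percentile speed by default) to discard sign flips in noise-level
flow. Frames within twice the temporal kernel of the movie edges are
excluded (filter edge effects).

Per-frame points are linked into tracks (nearest neighbor within 10 px,
gaps ≤ 3 frames, ≥ 2 points); a track's *extreme* center z-value — not its
mean — identifies the event phase, because the temporal smoothing makes
patterns appear before and after the fluorescence transient peaks. High
sources (z ≥ +1) are paired greedily with the earliest subsequent high sink
within 20 µm and 30 s into release events; low/low pairs into reuptake
events. The event onset is the frame where the source's center z first
crosses the threshold (the raw track start is smeared early by smoothing);
the offset is the sink's last crossing. Same-kind events overlapping in
space and time are merged (non-maximum suppression): one plume can shed
several fragmented tracks.

Two analysis scales exist for the spatial blur, both taken from the
recording practice this emulates: 12 px for the main pathway, and ~4 µm
(≈ 3 px at 1.47 µm/px) for the noise-control pathway. For the synthetic
benchmarks the package uses the ~4 µm scale (`scenarios.
SYNTHETIC_EVENT_PARAMS`, with a 2 s temporal kernel): the generator's
plumes start narrow (σ₀ ≈ σ_target/3) and a 12 px blur suppresses their
early phase below the z threshold.

**Event statistics.** Release and reuptake occurrence maps are
Gaussian-splatted (σ = 2 px), normalized, linearized and Pearson-correlated
(spatial r); the per-frame counts of *active* events (onset ≤ t ≤ offset)
give the temporal r. The expression-heterogeneity control residualizes
both maps on the time-mean fluorescence map before correlating. The noise
control permutes each pixel's time series independently (preserving every
pixel's mean, SD and value distribution), re-runs the full
flow→event→correlation pipeline on each of n null movies, and reports
two-tailed p = (1 + #{|null| ≥ |obs|}) / (n_defined + 1).

**Encoding models.** Per cell, ordinary least squares (a Gaussian
identity-link GLM, forced entry) of the standardized Ca trace on
standardized local NE, global NE, population Ca (mean of the other cells'
soma traces) and the local×global NE interaction. The interaction column
is the product of the standardized local and global traces, itself
z-scored over the full run, so its scale is mask-independent in regime
splits. Coefficient standard errors are the plain OLS ones: residual
autocorrelation is *not* corrected, so per-cell p-values are optimistic;
population-level inference (one-sample t across cells) is the primary
readout. Fits are repeated on high/low-synchrony frame masks and across
expanding annulus radii (the global field shrinking correspondingly).
Condition contrasts of correlation tables use a linear mixed model with a
fixed drug effect and uncorrelated random intercepts and drug slopes per
mouse and per cell, fitted by REML as variance components of a single-group
mixed model; the reported df uses the observation-level convention n − 2.

## The generator

The latent NE concentration field is

    baseline (1.0) + global drive + Σ release plumes − Σ reuptake dips,

with a unit-variance Ornstein–Uhlenbeck global drive (τ = 20 s, amplitude
0.1 of baseline). A plume is a diffusing, clearing Gaussian from a point
source: mass M(Δ) = (1 − e^(−Δ/rise)) · e^(−Δ/τ_clear) spreading as
σ(Δ)² = σ₀² + 2DΔ, with σ₀ = σ_target/3 and D set so σ reaches the
configured `diffusion_sigma_um` (12 µm) one clearance time (4 s) after
onset. The spatial integral is proportional to M(Δ): constant between the
end of the release transient and clearance, the sense in which plume mass
is conserved. The center-amplitude profile is normalized so its peak
equals `release_amp`; an event's offset is where the center amplitude
falls below 5% of peak.

Release events are Poisson per varicosity, modulated by an on/off burst
telegraph (release arrives in volleys; `burst_gain = 1` disables
modulation, `burst_per_site` draws independent telegraphs per site).
Reuptake events are gated to the burst-*off* phase — clearance rebounds
between release volleys — which is what makes release and reuptake counts
anti-phase while sites are shared: each reuptake revisits a previously
used release site with probability 0.8 (after a minimum lag), else occurs
at a random site. Amplitude scale is not specified by any measurement we
emulate; `release_amp = 1.0` (100% of baseline at plume peak) and
`global_drive_amp = 0.1` were fixed once so that the standardized
local:local and local:global field correlations land in the regime reported
for such recordings (≈ 0.5 / ≈ 0.7), and are documented here rather than
asserted as biology.

Cells sit on a jittered grid at ≥ 2 annulus radii separation. Each cell's
latent drive is

    β_local · z(annulus NE) + β_globalCa · z(shared population signal)
    + rectification and interaction terms + noise,

convolved with a unit-area exponential calcium kernel (τ = 1 s). Three
deliberate choices make the planted coefficients live on the standardized
scale the analysis estimates:

* the annulus NE regressor is standardized exactly as the analysis
  standardizes its predictors (detrend, 1 s smooth, z) — the cell
  integrates NE over ~1 s, and without this the fitted coefficients
  split unstably across the collinear local/global pair;
* the cell noise is a slow OU process (τ = 4 s) whose variance completes
  the latent to 1 — white noise would be differentially removed by the 1 s
  smoothing and rescale every fitted coefficient upward;
* the rendered green channel passes through a 1 s exponential (sensor
  binding kinetics), matching the calcium kernel's lag so that predictor
  and response are equally delayed.

Optional response components: a quadratic (rectified) term in the shared
drive, orthogonalized against its linear part; and a local×global
interaction drive present only outside release volleys (receptor
saturation during volleys), which is what the regime-split benchmark
recovers. The desipramine condition scales phasic amplitudes (×0.25), the
shared drive (×0.3) and background reuptake (×0.1), slows clearance (×8),
adds a saturating tonic ramp, and halves the cells' NE coupling
(receptor desensitization under sustained agonist).

Rendering: green = sensor-filtered NE × expression map (90% suppressed
inside somata — the sensor expresses on neuropil) + bleed-through (10%)
from red; red = soma disks carrying 1 + 0.25·Ca over a 0.2 neuropil
background + bleed-through from green; per-pixel Gaussian noise
(`noise_sd = 0.15`) plus a slow spatially structured background (AR(1) on
a 16 px grid, amplitude 0.01) that, unlike shot noise, does not average
away within a mask and therefore sets the noise floor of field traces.
Optional rigid drift is applied frame-by-frame and recorded.

## What the benchmarks show — and what they do not

The evaluation scenarios (`neflow.scenarios`) fix the study conditions for
each claim; sizes are scaled to desk hardware (128–160 px fields, 2–12.5
minute runs) and stated in each scenario's docstring. Passing them shows
that the *pipeline* recovers planted structure of the stated kind and
size, under this generator's assumptions: Gaussian plumes from point
sources, spatially uniform sensor expression outside somata, rigid motion
only, Gaussian noise. They do not certify performance on real tissue,
where nonrigid deformation, hemodynamic artifacts, heterogeneous sensor
expression and non-Gaussian noise all violate these assumptions, and where
several observed effects (notably the regime-specific interaction and the
drug effect on coupling) are reproduced here by planting the corresponding
mechanism rather than derived from deeper biophysics.

Findings from the benchmark development that carry scientific content:

* **Collinearity fragility.** Local and global NE traces correlate at
  0.7–0.95; tiny systematic mismatches between what a cell responds to and
  what a mask measures are amplified into large opposite-signed loadings
  on the local/global pair. The clean coefficient-recovery benchmark
  therefore uses temporally homogeneous release — burst-synchronized
  release puts a global-NE component into every cell's population-Ca
  predictor, whose compensation biases the split.
* **Leverage of event epochs.** The product (interaction) regressor has
  heavy tails during release volleys. In regime-split fits, the ~15% of
  frames that the 30 s synchrony window misclassifies near epoch
  boundaries can carry most of the regressor's sum of squares and crush a
  within-regime slope; the regime benchmark therefore uses epochs longer
  than the window and moderate event amplitudes.
* **Correlations are scale-invariant.** Uniformly shrinking all NE signal
  (as transporter blockade does in the generator) cannot change field
  correlations until the signal approaches a noise floor that does not
  average away within masks; the structured background noise supplies that
  floor.

## Numerical choices and limitations

* Horn–Schunck is solved by the classical Jacobi scheme; convergence for
  whole-object translation is slow (the velocity-oracle check runs 8000
  iterations), while the subpixel plume flows the detector consumes are
  well captured within 40–200 iterations.
* The sliding correlation uses cumulative sums; windows with variance
  below 1e-24 are returned as missing.
* The double-exponential fit is multi-start bounded least squares; a flat
  profile converges with arbitrary length scales and is flagged in the
  log.
* Detrending is linear by default (polynomial order configurable); the
  transporter-blockade pathway uses cubic detrending before correlation
  analyses to remove the saturating accumulation ramp.
* Degenerate inputs: constant traces raise on z-scoring (relative 1e-10
  threshold); a regime with fewer than 40 frames yields a missing fit;
  unpaired flow patterns are reported, never silently dropped; a single
  mouse drops the mouse-level random effects with a warning.
* The LME p-value uses a normal-approximation Wald t with n − 2 df, not a
  Satterthwaite correction.
* Event detection assumes plumes separated by a few diffusion scales;
  precision degrades when plumes overlap heavily (dense-release regimes),
  and detected onsets systematically lead true onsets by up to ~1.5 s at a
  2 s temporal kernel (smoothing anticipation).
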