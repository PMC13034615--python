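# Methods

`lamvaso` reconstructs laminar BOLD and VASO (vascular space occupancy)
responses to digit stimulation from an interleaved blood-nulled / not-nulled
acquisition, and validates every stage against a synthetic cortical phantom
with analytically known ground truth.  This note documents the models, the
parameter choices, and what the phantom does and does not emulate.

## The phantom

**Geometry.** Gray matter is a quarter-cylinder shell (inner/"white-matter"
radius 12 mm, outer/"pial" radius 15 mm, i.e. 3 mm cortical thickness) inside
a 32 x 32 x 6 mm box at 0.5 mm isotropic functional resolution, with white
matter filling the inside of the shell and CSF the outside.  On a cylindrical
shell the equivolume depth has the closed form
`alpha(r) = (r_p^2 - r^2) / (r_p^2 - r_w^2)` (0 at the pial surface, 1 at the
white-matter surface), which serves as the depth oracle.  A flat-slab variant
(3 mm sheet) provides the zero-curvature limit in which equivolume and
equidistant depth coincide.  A x3 "anatomical-grade" version of either
segmentation (~0.17 mm voxels, built analytically from the same geometry)
mirrors the common acquisition design in which the anatomy used for layering
is much finer than the functional grid.

**Digit patches.** Three digit representations (D2-D4) are 2D Gaussian
patches (FWHM 3 mm) on the unrolled mid-depth surface, centred at 25, 45 and
65 degrees along the shell (about 4.9 mm apart, a realistic inter-digit
separation on the postcentral gyrus).  Sustained responses are a 30 s boxcar
convolved with the gamma HRF (below), normalised to unit plateau, scaled per
voxel by the patch profile times a depth profile:

* BOLD: linearly increasing toward the pial surface (surface amplitude 5%,
  deep/surface ratio 0.3) — the draining-vein bias;
* CBV: unimodal peak at mid-depth (Gaussian in depth, sd 0.18, peak 1.5%,
  floor ratio 0.4) — the microvascular profile.

The 5% / 1.5% operating point was chosen once so that the phantom reproduces
the z-score ranges the method is designed for (winner-take-all BOLD z up to
~10-40, VASO z ~2-6 at the default noise) — weaker settings make the
FDR-based ROI procedure itself meaningless.  The 25 Hz vibration carrier and
100 ms interruptions of the stimulation are not simulated; stimulation enters
only as the 30 s boxcar, since no analysed quantity depends on the carrier.

**Triphasic surround.** Voxels at 4-14 mm Euclidean distance from a patch
centre carry a distance-binned triphasic response: a positive gamma-shaped
bump at onset (amplitude A1, nominal peak time t1), a negative gamma-shaped
component during stimulation (trough magnitude A2 at t2) and a positive
post-stimulus bump (A3 at t3 after offset).  Defaults per 2 mm bin (4-6 mm up
to 12-14 mm):

| quantity | 4-6 | 6-8 | 8-10 | 10-12 | 12-14 mm |
|---|---|---|---|---|---|
| A1 (%) | 0.50 | 0.42 | 0.34 | 0.26 | 0.18 |
| t1 (s) | 14 | 12 | 10 | 8 | 6 |
| A2 (%) | 0.10 | 0.17 | 0.24 | 0.31 | 0.38 |
| t2 (s) | 26 | 24.5 | 23 | 21.5 | 20 |
| A3 (%) | 0 | 0.12 | 0.17 | 0.20 | 0.22 |
| t3 (s) | — | 4 | 5.5 | 7 | 8.5 |

so the initial peak shrinks and arrives earlier with distance, the trough
deepens and arrives earlier, and the post-stimulus peak emerges beyond
6-8 mm and arrives later — the observed surround ordering.  Because the
three summed components overlap in time, the *realised* extrema of the
summed kernel (computed on a 10 ms grid) are what the truth table stores and
what recovery is judged against.  Amplitudes scale by depth compartment
(superficial/middle/deep = 1.2/1.0/0.8; surround effects are strongest
superficially).  Injection uses Euclidean distance bins from the
amplitude-maximum voxel — the same distance definition the analysis applies —
so the truth table and the recovered table live on the same footing.

**Acquisition model.** Volumes alternate nulled/BOLD with pairTR 3.85 s.
With fractional modulations `b(t)` (BOLD) and `v(t)` (CBV),

    bold(t)   = B0 * (1 + b(t)) + noise
    nulled(t) = N0 * (1 - v(t)) * (1 + b(t)) + noise

so dividing nulled by BOLD exactly removes the multiplicative BOLD
contamination and recovers `1 - v(t)` (times the baseline ratio `N0/B0`).
Both volumes of a pair carry the signal evaluated at the shared pair time;
the within-pair offset (volTR, here pairTR/2) is metadata only — sub-pairTR
signal evolution is not simulated, which is what makes an exact
division-identity check possible.  Baselines per tissue (arbitrary units):
BOLD 50/900/1000/1100 and nulled 50/850/700/300 for
background/WM/GM/CSF (the nulled GM/WM/CSF ordering gives the T1-weighted
EPI contrast).  Noise is i.i.d. Gaussian per volume (sd 33 for both
contrasts, i.e. GM tSNR ~30 for BOLD and ~19 for VASO — above the >10
quality bar for sub-millimetre work).  Temporal autocorrelation is not
simulated; the GLM assumes white noise, and its calibration is checked on
that null.  The first three pairs carry a multiplicative excess
(+25/+12/+5%) emulating the approach to steady state.  Motion is supplied
only as nuisance traces (slow drift + jitter + two single-volume
excursions); images are not actually displaced, as registration is out of
scope.

What the phantom does **not** emulate: k-space/EPI artifacts (distortion,
ghosting, inflow), physiological noise and its laminar structure, temporal
autocorrelation (unless enabled), actual head motion, intersubject anatomy.
Passing tests therefore demonstrate the correctness and calibration of the
analysis chain, not robustness to those real-data effects.

## Preprocessing

Split interleaved volumes (nulled first) → replace volumes 1-3 with 4-6
(steady-state fix) → temporal upsampling x2 by local Lagrange interpolation
through the 8 nearest samples (7th order; the window shrinks symmetrically at
run edges, so values at original sample positions are preserved exactly and
polynomials up to degree 7 are interpolated exactly) → alignment by
duplicating the first nulled volume and truncating to the BOLD length (the
VB17 convention; duplicating the first BOLD volume instead is the "ve"
flag).  The duplication shifts the nulled series one upsampled sample
earlier on the index grid, which the series' `t0_s` metadata records and the
design builder and trial extractor honour.  BOLD correction divides nulled
by BOLD voxelwise and timewise; denominators below 5% of the voxel's mean
|BOLD| are set to NaN rather than producing infinities (configurable guard).

Quality maps: tSNR = temporal mean / temporal sd after linear detrending
(constant voxels NaN); T1w-EPI = mean/sd of the concatenated nulled+BOLD
series (inverse variation coefficient); framewise displacement
`FD = sum |d trans| + 50 mm * sum |d rot|` with FD(1) = 0, and motion
outliers above the 75th percentile + 1.5 IQR of the run's FD.  Sample
(n-1) standard deviations are used throughout.

## Cortical depth and geometry

Boundary distances are estimated from Gaussian-blurred tissue indicators:
for a flat interface blurred with an isotropic Gaussian of width sigma the
tissue fraction is `Phi(d / sigma)`, so inverting the blurred indicator gives
a sub-voxel signed distance that averages the label staircase (sigma =
0.9 mm, on a x3 supersampled grid for coarse segmentations); beyond ~3 sigma
the Euclidean distance to the 0.5 level set takes over.  A curved interface
shifts the apparent boundary by `sigma^2 * kappa / 2`, which is corrected
using the level-set curvature `kappa = div(unit gradient of depth)`
(estimated from a 0.5 mm-smoothed field; positive on gyral crowns).  The
depth is then symmetrised, `s = (d_csf - d_wm + T) / (2 T)` with a 1.5 mm
smoothed thickness field `T`, so independent errors of the two boundaries
average rather than add.  The equivolume depth applies the closed-form
reparameterisation for a locally cylindrical patch,

    alpha = s * (2 + s * tau) / (2 + (2 s - 1) * tau),   tau = kappa * T,

which reduces to `alpha = s` where the cortex is flat.  In the pipeline the
depth is computed on the anatomical-grade (x3) segmentation and sampled at
the functional voxel centres; on the shell phantom this is accurate to
~0.007 in depth units (vs ~0.03 when computed directly on the 0.5 mm
labels, where quantization of the boundary position dominates).

Layer bins are equal-width in alpha (`bin = ceil(alpha * n)`, bin 1 most
superficial; 11 bins for z profiles, 3 for event-related averages).  Columns
are the unit gradient of the smoothed depth.  Geodesic distances run through
the 26-connected voxel graph with Euclidean edge lengths (anisotropic voxel
sizes respected).  The geodesic disk flattens the ribbon through a mid-depth
band (alpha in [0.3, 0.7]; wide enough to stay connected at 0.5 mm
resolution): geodesic distance within the band from the seed's nearest
band voxel, inherited by every GM voxel from its nearest band voxel (its
column foot-point), thresholded at the disk radius (12 mm default).
Distance bins are half-open 2 mm Euclidean bins 0-14 mm within GM (the
straight-line definition is the default; an along-cortex geodesic variant is
a switch).
Coordinates are 0-based voxel indices; physical units mm via voxel size.

## GLM

The HRF is a gamma density with mean lag 6 s and sd 3 s (shape 4, scale
1.5 s), truncated at 32 s and peak-normalised; condition regressors are the
boxcar convolved with it on a 50 ms grid, normalised to unit plateau so
betas are in signal units.  High-pass filtering is a discrete-cosine drift
basis up to 0.01 Hz (`floor(2 T f_c)` columns) in the design matrix — an
equivalent projection to filtering the data with a simpler contract.  Six
demeaned motion regressors and one spike per flagged outlier volume complete
the design; rank deficiency is an error naming the collinear columns.

Fitting is voxelwise OLS; t statistics map to z through the t-distribution
quantile transform, capped at |z| = 40 for numerically perfect fits (the
uncapped ratio is retained for tie-breaking).  VASO maps are sign-inverted
(activation decreases the VASO signal).  Runs combine by inverse-variance
weighting of betas (combined variance `1/sum(1/var_i)`, z recomputed);
whether to combine betas or z is not uniquely determined by common practice —
inverse-variance on betas is the documented choice here.  FDR uses
Benjamini-Hochberg over the disk's GM voxels at q = 0.001 (whole-GM is a
switch).  p-values for the winner-take-all masks are one-sided (positive
contrast) by default: a two-sided threshold also admits voxels that respond
strongly to the *other* digits, which the step-5 overlap removal would then
delete from every ROI.  No prewhitening is applied; the phantom's default
noise is white, and the null-calibration test is run on series fed directly
to the fitter (x2 interpolation makes upsampled noise serially correlated,
a miscalibration the pipeline shares with common practice and which the
methods here do not attempt to model).

## Digit ROIs

Per digit: FDR-threshold the winner map over the disk GM → binarize → keep
the largest 26-connected cluster (ties: smallest linear index) → propagate
across depth with a cylinder of radius 0.45 mm oriented along the local
column (line sampled at quarter-voxel steps over the full depth; a voxel
becomes active if any active voxel lies within the cylinder), so each active
column contributes all depths and depth bins end up with similar counts →
remove voxels claimed by more than one digit.  All counts (suprathreshold,
largest cluster, propagated, overlap-removed) are recorded in the
provenance.  The peak voxel is the GM argmax of the digit-vs-rest z; voxels
tied at the z cap rank by effect size, remaining ties by lowest linear index
(without the effect-size tie-break a zero-noise phantom, where every
responsive voxel saturates the cap, would pick an arbitrary corner of the
activation).

## Event-related averages and triphasic features

Voxel series are cleaned by OLS removal of intercept, linear trend, motion
and outlier spikes, then expressed as % of the voxel's run mean (a
pre-stimulus baseline option exists but is off by default —
note the run mean sits slightly above rest, so cleaned traces are negatively
offset in proportion to how active a voxel was over the run).  Trials are
-15..+70 volumes around onset inclusive (86 samples at the effective TR of
1.925 s); trials whose window leaves the run are dropped and counted.
Compartment traces average voxels within (region x layer); trials pool
across runs; the 95% CI across trials uses the t distribution.  Distance-bin
averages around each digit's peak pool over the three digits with trial
weights; the distance-trend quantification uses the mean across layers (one
trace per bin), which is far less noisy than any single layer.

Triphasic features per compartment: initial peak = argmax within the
stimulation period (16 volumes); trough = argmin after the peak and before
stimulation end; post-stimulus peak = argmax within 8 volumes (~15.4 s)
after offset.  Ties take the earliest time.  Times are reported in seconds
relative to onset (peak, trough) or offset (post peak).  Amplitudes are
deflections relative to the mean of the last 4 pre-onset volumes (a window
short enough to clear the previous trial's post-stimulus peak): this removes
the compartment-dependent run-mean offset that would otherwise corrupt the
trough-vs-distance ordering wherever a bin overlaps a neighbouring digit's
patch.  The amplitude at an extremum is read as the mean over the extremum
±1 volume — the injected deflections are several volumes wide, so this
barely biases the amplitude while clearly reducing reading noise.  TTPs are
unaffected by either choice.

## Numerical and design notes

* Problem sizes: 64 x 64 x 12 voxels at 0.5 mm, 215 volume pairs per run
  (~828 s), 3 runs, 12 blocks per run — i.e. 12 repetitions per digit, the
  top of the studied range.  Onsets are snapped to the pairTR grid so trial
  windows align with samples.
* Determinism: every stochastic step draws from `numpy` Generators seeded
  from the pipeline seed; identical configs reproduce identical outputs.
* Degenerate inputs: constant voxels are NaN in tSNR/T1w-EPI and masked in
  the GLM; empty suprathreshold sets yield empty ROIs with a warning; the
  division guard and the z cap prevent infinities.
* The trial window (-15 and +70 inclusive) and one-sided FDR are documented
  resolutions of genuinely ambiguous conventions; both have switches.
* Known limitations: no prewhitening (see above); peak-voxel localisation
  at default noise wanders by ~1 voxel, which mixes adjacent distance bins
  near their edges and is the dominant uncertainty in the outermost bin;
  the run-mean baseline convention biases absolute amplitudes low wherever
  a compartment is active for part of the run.
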