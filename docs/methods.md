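# Methods

`imagerylink` implements an individual-differences analysis that asks whether
people who report more vivid auditory imagery differ in (a) regional
gray-matter volume and (b) the representational specificity of their cortical
responses to heard vocal sounds. Because no raw cohort data are distributed,
the package pairs every analysis stage with a synthetic-data generator whose
ground truth is known, so the claims the pipeline makes can be validated as
parameter recovery.

## Behavioral instruments and correlation machinery

The auditory instrument has two 14-item subscales rated 1-7: *vividness*
(clarity of an evoked sound image) and *control* (ease of transforming one
image into another). Subscale scores are item means; the total score is the
mean of the two subscale scores. The visual instrument has 16 items rated
1-5 where low raw values mean vivid imagery; the score is inverted
(`6 - mean`) so that on both instruments higher means more vivid. Missing or
out-of-range items are rejected, not imputed.

Brain-behavior associations use Pearson correlations with two-sided t-based
p-values; partial correlations residualize both variables on
`[intercept | covariates]` by OLS and reduce the degrees of freedom to
`n - 2 - k`. Fisher's z = atanh(r) is the variance-stabilizing transform
used before averaging correlations. Because identical patterns would give
r = 1 and an infinite z, |r| is clipped at 1 - 1e-7 before the transform
(configurable; clipping only matters for degenerate inputs and moves
realistic values by less than 1e-6).

## Volumes, spheres, smoothing

A `VoxelGrid` is an axis-aligned millimeter frame: the center of voxel
(i, j, k) is `origin + index * voxel_size`. Sphere ROIs contain exactly the
voxels whose centers lie within the radius, boundary inclusive; on a 2-mm
isotropic grid a 12-mm sphere centered on a voxel center contains 925
voxels, which is the geometry the ROI analyses assume. Gaussian smoothing
is separable with sigma = FWHM / (2 sqrt(2 ln 2)) per axis, zero-padded at
the box boundary by default. The analysis mask keeps a voxel only if every
subject's gray-matter value is at least 0.05 (the absolute-threshold
convention; "any subject below threshold" and "all subjects above" coincide
under it). Only diagonal, positive NIfTI affines are supported;
reorientation is out of scope.

## Structure-behavior GLM

Each voxel's gray matter is regressed on an intercept, one imagery score of
interest, and five nuisance covariates: age, gender (binary indicator),
total gray-matter volume, digit span (short-term memory proxy), and years
of musical training. The contrast statistic is t = beta/SE with
df = n - 7; at the default n = 74 this gives t(67). Covariates are not
standardized (the t statistic is invariant to affine column rescaling given
the intercept). The API accepts exactly one interest column per fit: the
two auditory subscales are too collinear to co-occupy a design. Voxels
with numerically zero residual variance are excluded and counted. Z scores
are the standard-normal deviates with the same tail probability as the t
(computed in log space to survive large t).

ROI summaries ("gray-matter residuals") are per-subject cluster means
residualized on the intercept + nuisance design; they are what gets
scatterplotted and partially correlated against the behavioral scores.

## Permutation inference instead of random-field theory

Cluster-level family-wise error uses a cluster-forming threshold of
p < 0.005 (uncorrected, strictly greater-than cutoff), 18-connectivity
components (configurable 6/18/26), and the permutation null of the maximum
cluster size. The GLM permutation scheme is Freedman-Lane: residualize the
data on the nuisance-only model, permute residual rows, add the nuisance
fit back, refit the full model. p-values are plus-one corrected,
(b + 1)/(m + 1), so they are never zero; when fewer distinct permutations
exist than requested the group is enumerated exhaustively (with the
identity included, making the correction exact). Small-volume correction
is the same machinery with the max statistic restricted to an a-priori
12-mm sphere. This is a deliberate methodological substitution for
random-field-theory cluster correction with nonstationarity adjustment:
permutation inference is exact under exchangeability and needs no
smoothness estimation, at the price of simulation error controlled by the
permutation count. No attempt is made to reproduce RFT-corrected p-values
numerically.

The permutation engine never materializes the permuted data matrix: with
thin-QR bases of the design, permuting the rows of the n-by-p orthonormal
factors is algebraically equivalent and reduces each permutation to two
small-matrix products, which keeps a 100-permutation pass over ~10^5 voxels
in the low seconds.

## Condition ANOVA

The second level consumes per-subject, per-condition t-maps directly
(first-level hemodynamic modeling is out of scope). The F map is the
classical within-subject one-way decomposition, F = MS_cond / MS_error with
df = (k - 1, (k - 1)(n - 1)); five conditions and 56 subjects give
F(4, 220). No sphericity correction is applied, matching the uncorrected
df convention. Cluster correction permutes condition labels independently
within each subject.

## Representational similarity analysis

Per subject, the five vocal-condition t-maps are sampled at the sphere's
voxels (deterministic lexicographic order); all 10 unordered pairs are
Pearson-correlated, Fisher-transformed, and averaged; the five
vocal-vs-rotated pairs are summarized the same way (transform-then-average
in both cases, for consistency). Correlations use all sphere voxels
without further gray-matter masking. The summary is then correlated -
plainly or partially with the VBM nuisance set - against vividness; the
sign convention is that negative r means more distinct condition patterns
(higher specificity) in people with more vivid imagery.

## Spectral rotation

Rotation mirrors the spectrum about 2 kHz by amplitude modulation with a
4-kHz sinusoid followed by a 3.8-kHz low-pass, so a component at f Hz
reappears at 4000 - f Hz and 2 kHz is fixed. Before modulation the signal
is equalized by a 33-tap linear-phase FIR whose magnitude approximates
LTAS(|4000 - f|)/LTAS(f), where the long-term average speech spectrum is
modeled as a documented piecewise log-linear curve: flat below 420 Hz (the
roll-off of real speech below ~120 Hz is deliberately ignored) and falling
at 9 dB/octave above. The fit is weighted least squares with inverse
squared magnitude weighting so the error is controlled on a dB scale; at a
16-kHz rate the realized response tracks the target within about 2 dB over
300-3700 Hz (33 taps give proportionally less resolution at higher rates).
The low-pass is a Kaiser-window FIR with at least 60 dB attenuation at
4.2 kHz; both filters are odd-length linear phase and applied with centered
convolution, so output duration equals input duration exactly. The
modulator phase is zero at sample zero for determinism. An optional
pre-modulation band-limit is available; only the post-modulation filter is
always applied. Outputs exceeding full scale are peak-normalized with a
logged gain.

The vocalization generator is a fixture synthesizer, not a voice model: a
harmonic stack with category-specific fundamental contour (neutral 120 Hz
flat, laughter 220 Hz with 5-Hz bursts, scream 450 Hz rising with vibrato,
pleasure 180 Hz falling, disgust 140 Hz wandering), band-passed noise mix,
and an attack/release envelope. Durations draw from a normal distribution
with mean 1018 ms and SD 326 ms, clipped symmetrically (250-1786 ms) so the
clipped mean is unchanged.

## Synthetic data and calibration

All generators are pure functions of (config, seed); ground truth (effect
masks, latent couplings) travels beside the data and is never read by
analysis code.

*Cohort.* Vividness, control, and visual-imagery scores are a trivariate
normal with target correlations (0.68 vividness-control, 0.57
auditory-visual, 0.40 control-visual), affinely mapped to each scale's
descriptive mean/SD (4.96/0.95, 5.28/0.95, 3.63/0.81) and clipped to the
scale ranges; clipping at these targets is mild, so sample correlations
track the latent targets (verified to ±0.03 at n = 5000). Covariates:
age ~ N(42.61, 17.11) clipped to 20-81; gender Bernoulli(40/74); total
gray matter N(620, 60) in arbitrary units; digit span rounded
N(7.08, 1.21) clipped to 4-9; musical training: 30/74 prevalence with
years N(6.03, 4.47) clipped to 1-20, else zero.

*Gray-matter maps* (1.5-mm grid, default 48x56x48 box rather than a whole
head, to keep desk-scale runtimes). A radially tapering baseline plus
per-subject smooth Gaussian noise (intrinsic 4-mm FWHM combined with the
10-mm analysis smoothing in a single pass) plus an ellipsoidal implant of
~11.5 mL - the volume scale of the structural cluster the pipeline is
expected to recover - whose amplitude is linear in the subject's
standardized vividness. The slope is set from the empirically measured SD
of the ROI-mean noise so that the ROI gray-matter-vividness correlation
targets 0.46; per-seed sampling variation remains because the noise is
never exactly orthogonal to vividness. Values are floored at zero and maps
are returned already smoothed.

*Condition t-maps* (2-mm grid, default 49x57x49). Per subject and vocal
condition: a shared unit-variance pattern A over the grid, plus a
condition-specific pattern confined to the target sphere with per-subject
amplitude d_s ("distinctness"), plus white voxel noise (variance 0.03).
Within the sphere the expected pairwise condition correlation is
1/(1 + d_s^2 + sigma^2), so d_s is obtained by inverting a linear model on
the Fisher-z scale: z_s = atanh(0.83) + lambda * w_s with lambda chosen to
give the target similarity SD (0.10), and w_s a standard latent correlated
with standardized vividness at |rho| = 0.34 (negative coupling: vivid
imagers get more distinct patterns). This makes the cohort mean
within-vocal similarity sit near 0.83 and the similarity-vividness
correlation target -0.34 without any empirical attenuation correction
(the measurement noise of a 925-voxel, 10-pair summary is negligible
against the between-subject spread). The rotated condition shares a damped
copy of A (gain 0.7) plus its own sphere pattern. Functional noise is
spatially white: first-level modeling is out of scope and the within-sphere
similarity statistics are insensitive to spatial autocorrelation; only the
structural stream, where cluster inference depends on smoothness, simulates
smooth noise.

What the generators do *not* emulate: anatomy (no tissue classes,
no registration error), BOLD physics, non-Gaussian questionnaire response
styles, site or scanner effects, and any spatial structure in the
functional noise. Passing recovery tests therefore shows the pipeline's
statistics are correct and well calibrated under the stated model - not
that the effects would survive the messiness of real acquisitions.

## Problem sizes and numerical choices

Defaults: n = 74 structural / 56 functional subjects; 1000 permutations in
production runs (tests use 100-150, the minimum the plus-one correction
needs for p = 0.05 resolution at these sizes); cluster-forming p = 0.005;
connectivity 18; Fisher clip 1e-7; OLS via thin QR with residual sums
guarded against cancellation (voxels whose RSS falls below 100 eps of the
total sum of squares are treated as exact fits and excluded). Recovery
tests run 50 seeds at the full default sizes; detection-rate and type-I
checks run at reduced replicate counts and grids chosen so the whole suite
stays in the minutes range, with thresholds set to the corresponding
binomial tolerance rather than the asymptotic rate.

## Known limitations

- Permutation p-values carry simulation error ~1/sqrt(m); corrected
  p-values near 0.05 need m >> 100 to be stable.
- The equalizer's 33-tap budget limits spectral fidelity at rates far above
  16 kHz; the tap count is part of the algorithm's definition and is kept.
- The generators' calibration targets are population values; any single
  synthetic cohort scatters around them exactly as a real cohort would
  around its population effect.
- Cluster peak coordinates are reported at voxel centers of the synthetic
  box frame; no template registration is performed, so coordinates are
  MNI-like only by convention.
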