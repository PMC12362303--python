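# Methods

This note documents the models implemented in `navdyn`, the synthetic
cohort's generative assumptions, and the numerical choices that matter when
interpreting its outputs.

## Signal conditioning

Raw region-averaged series are processed strictly per run (306 frames at
TR 2 s covering six 102 s trials):

1. **Percent signal change**: `y = (x - mean(x)) / mean(x) * 100`, the mean
   taken over the whole run. A zero run mean raises an error naming the
   region; nothing propagates NaN.
2. **Confound regression** (OLS with intercept): 24 motion regressors (the
   6 rigid-body parameters, their backward-difference derivatives with the
   first frame set to 0, squares, and squared derivatives), framewise
   displacement, and the 5 lowest non-constant DCT-II basis columns
   `cos(pi * j * (2t+1) / (2n))`, j = 1..5 (exactly zero-mean and mutually
   orthogonal). FD follows the 50 mm-sphere convention:
   `FD_t = sum|d trans| + 50 * sum|d rot|`, `FD_1 = 0`; the participant
   motion covariate is the mean FD over all frames of all runs. A
   rank-deficient confound matrix falls back to pseudo-inverse least squares
   with a logged warning (this happens by design when motion is disabled in
   simulations).
3. **Z-scoring** per region over the run, sample SD (n−1). Because Pearson
   correlation is affine-invariant, the n−1 vs n choice cannot affect any
   similarity result; it only fixes the scale of stored tables.

Navigation windows are 30 frames; the first 4 are discarded against
hemodynamic carry-over, leaving 26 analysis frames per episode. Baselines
for the activation measure are the last 2 frames of each of the two fixation
phases (4 frames per trial); activation = mean(retained navigation frames) −
mean(baseline frames) on the percent-signal series. Trial onsets must fall
on the TR grid; misalignment is an error, not silent rounding.

Spatial-memory performance is the proportion of correct responses over
scored trials; a missing response scores incorrect, and flagged episodes can
be excluded from the denominator.

## Similarity, decoding, and permutation inference

Segments are z-scored at the run level, so ICS reduces to a dot product of
centered, unit-norm 26-vectors. Fisher-Z uses `arctanh` with |r| clipped at
1 − 1e−7 so a perfect correlation stays finite. Decoding predicts the
episode with maximal ICS among the 24 leave-one-out templates; exact ties go
to the lowest episode index and are flagged.

**Mean-ICS permutation test.** Each null draw correlates canonical
templates with individual segments of a different, randomly selected
episode. The default null ("relabel") permutes every participant's episode
labels independently and rebuilds the leave-one-out templates from the
relabeled data. Episode relabeling within participant is measure-preserving
under the null hypothesis of no stimulus-locked structure, so the test is
calibrated; we measured a type-I rate of 0.0525 over 400 null cohorts at
alpha = 0.05. Two cheaper variants that re-pair the *original* templates
with a random different-episode segment (same or any participant) are kept
behind a strategy switch for sensitivity analyses; they are anticonservative
(~0.10–0.14 measured type-I) because reused templates drop the
mutual-reflection covariance between participants' leave-one-out statistics,
and they are therefore not the default. All permutation p-values use the
add-one estimator `(1 + #null >= observed) / (1 + n_perm)` and are never 0.

**Decoding permutation test.** Null draws permute the episode labels of the
templates and re-run the argmax decoder; the null accuracy centers on 1/24.

**Condition contrast.** Decoding accuracy is first averaged over
participants per episode, then compared between cue conditions (6 landmark
vs 6 no-landmark episodes) with a pooled-variance two-sample t-test,
df = 6 + 6 − 2 = 10. Episodes, not participants, are the unit here.

## Event model

The HRF is the standard double gamma: response gamma shape 6, undershoot
shape 16, both scale 1 s, undershoot ratio 1/6, truncated at 32 s and
peak-normalized (peak ≈ 5 s). Convolution happens causally at the streams'
native 10 Hz, then the regressor is sampled at frame onset times (a
midpoint-sampling flag exists). Landmark viewing is binarized per landmark
trial at the 80th percentile (linear-interpolation definition, strict `>`),
so tie-free 600-sample ratios mark exactly 120 timepoints; participant-level
gaze flags are averaged in 100 ms bins, binarized at 0.5, and the group
ratio is the fraction of participants on a landmark per bin. The regression
`Y_k = b1*X_turn + b2*X_view + i + e` is fit per region by OLS on the
z-scored concatenation of all retained frames (624 in the default design),
with two-tailed coefficient tests and BH-FDR across regions downstream.

## ISFC

The seed's individual dynamics (bilateral hippocampal formation by default:
mean of the L and R segments; single-hemisphere seeds are accepted) are
correlated with each cortical target's leave-one-out template, Fisher-Z
transformed, and averaged over episodes **on the Z scale**. The target set
excludes both hemispheres of the seed region (44 targets for the
hippocampal seed). With seed = target the computation reduces exactly to
ICS (unit-tested). Seed-wise summaries average the motion-partialled
ISFC-performance correlation over targets for every bilateral seed.

## Group statistics

- **Partial correlations** regress mean FD out of both variables (OLS with
  intercept) and correlate the residuals. The p-value uses the exact null
  density of r via the t equivalence `t = r*sqrt((n-2)/(1-r^2))`; tests
  verify agreement with direct numeric integration of the beta-function
  density to 1e−6. n is the participant count, with no df reduction for the
  motion regression — marginally anti-conservative, and documented as such.
- **Age regression**: measure, age, and motion all z-scored; VIF for age is
  `1/(1 - r_am^2)` — 1.32 at the generator's target age-motion correlation
  of 0.493.
- **Mediation**: X = age, M = a region's coupling measure, Y = performance,
  Z = motion, all z-scored; three OLS fits; classic Sobel
  `z = ab / sqrt(a^2 SE_b^2 + b^2 SE_a^2)` with a two-tailed normal
  reference (no product-of-SEs third term, no bootstrap CIs). The OLS
  identity `c = c' + a*b` holds to numerical precision whenever the three
  fits share the confound, and is asserted in tests. Candidate gating
  (test only regions with `a < 0`, `p < 0.05`) is a flag, on by default;
  the full table is always produced with a candidate marker.
- **BH-FDR** via the standard step-up procedure (statsmodels).

## The synthetic cohort

**What it emulates.** 76 participants (45 aged 20–30, 31 aged 50–65; ages
integer-uniform within group), 46 bilateral regions, 24 episodes (6 per cue
condition — local landmarks, distal cues, both, neither — dealt over 4 runs
as evenly as 6-trial runs allow), 102 s trials, TR 2 s, a separate 42-person
eye-tracking cohort at 250 Hz, and 24 two-alternative memory questions with
a 5% non-response rate.

**Event streams.** Each episode has 4–8 turns as half-cosine
angular-velocity bumps (1–3 s wide, peak 20–60 deg/s, onsets ≥ 2 s apart)
with the navigator stationary in the first and last 2 s; the profile shape
is our choice, as only turn counts and the stationary margins are
externally constrained. Landmark episodes carry a latent group gaze-ratio
profile (3–6 viewing bumps plus a small smooth baseline that keeps the
series tie-free).

**Canonical signal.** For region k, episode e:
`g = b1[k]*z(X_turn) + b2[k]*z(X_view) + lam[k]*latent[k,e]`, with
`lam = sqrt(1 - b1^2 - b2^2)` and the latent a Gaussian-smoothed white-noise
process (4 s FWHM) unique to each region × episode — this is what makes
episodes decodable beyond their event structure. The landmark drive uses
the same binarized viewing mask the analysis fits, so beta recovery is
well-posed. g is standardized per region over the retained-frame
concatenation; an individual's navigation signal is
`w[i,k]*g + sqrt(1 - w[i,k]^2)*eps` with unit-variance white noise, so the
individual-to-canonical correlation averages to the coupling weight w.
Default per-region base weights span 0.03–0.24 (visual stream high,
hippocampal formation low); these are tuning constants chosen once so the
region-mean ICS lands in the band regional intersubject-correlation studies
report (~0.02–0.22 at n = 76), not claims about any dataset.

**Aging and behavior.** The latent mediator
`M = a*z(age) + sqrt(1-a^2)*eps` (a = −0.5) shifts the medial-temporal
coupling weights (`w += 0.05*M` for hippocampal formation and
parahippocampal region); latent performance is
`b*M + c'*z(age) + resid` (b = 0.5, c' = −0.4, residual variance set for a
unit-variance latent). Trial correctness is Bernoulli with probability
`0.70 + 0.12 * latent`. Motion propensity follows the same linear-in-age
form with gamma = 0.493 — the simplest structure matching the reported
age-motion correlation — and scales a 6-parameter random-walk with 2%
spike frames; FD-proportional artifacts are added to all regions so motion
genuinely confounds ICS. Runs also carry low-frequency drift (two random
cosines, 80/120 s periods) and a 1000-unit baseline so percent-change
conversion is meaningful.

**What it does not emulate** (hence what passing tests do not show about
real data): no voxel space, no vestibular/active-navigation signal, no
hemispheric asymmetries, no heteroscedastic or physiologically structured
noise, no eye-tracker artifacts, and binomially-noised behavior only.

## Known quantitative behaviors

- **Binomial attenuation.** A 24-trial proportion-correct measures the
  latent performance with binomial noise, attenuating standardized
  behavioral path coefficients by roughly 20% (e.g. an age-performance
  correlation of −0.65 on the latent scale observes near −0.54). The
  mediation-recovery suites therefore evaluate the estimator on the
  generator's continuous performance scale, where a, b, and c' are defined;
  the binomial layer is a property of the measurement, not the estimator.
- **Drift-regression attenuation of condition-level betas.** The run-wise
  DCT confound regression absorbs part of the between-episode mean
  structure of the landmark regressor (landmark episodes recur at roughly
  the trial period), attenuating the recovered landmark beta by a few
  hundredths under default artifacts. The recovery suite runs at high
  coupling (w = 0.9, n = 16) with artifacts disabled to verify the
  estimation identity itself; both betas recover within ±0.05 there.
- **Finite-cohort ICS attenuation.** The leave-one-out template carries
  residual noise of variance (1−w²)/(n−1), so the measured ICS is
  `w^2 / sqrt(w^2 + (1-w^2)/(n-1))` in expectation — noticeably below w in
  small demo cohorts, converging to w at n = 76.

## Problem sizes used by the test and acceptance suites

Chosen as the package's own balance of statistical resolution and runtime:
full-size (n = 76, 46 regions) for the single pipeline run with 1000
permutation draws; 16-participant, 6-region cohorts × 20 seeds for beta
recovery; 500 cohorts of 76 for mediation recovery; 400 null cohorts × 300
draws for permutation calibration; demo cohorts of 10–16 participants for
the remaining property tests.

## Reproducibility

All randomness flows from one master seed through named substreams (design,
truth, streams, motion, bold_canonical, bold_noise, gaze, behavior), so any
module can be regenerated independently and identical (config, seed) pairs
are byte-identical. Pipeline outputs are TSV with `%.17g` floats (exact
float64 round-trip) plus a manifest recording the config hash, seed, and
library versions.
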