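# Methods

This note documents the models, numerical choices and simulation conditions
behind duoscale, and what the test battery does and does not establish.

## Scale geometry

An axis is an ordered set of intensity descriptors with reference ranks
0..12 ('no sensation' at rank 0) and positive relative magnitudes (RMs) for
ranks 1..12. Positions are a linear map of log10(RM) onto `[0, span]`, with
the smallest positive RM at 0 and the largest at `span`; 'no sensation'
(RM 0, log undefined) is pinned to position 0 and excluded from the log
grid. `span` is configurable (default 100 rating units): the recorded
rating unit is not intrinsic to the method, and every downstream statistic
is invariant to it up to the same linear rescaling (tested).

Two numerical details:

* **Strict ordering.** The log map sends the rank-1 descriptor to 0, where
  the 'no sensation' anchor already sits, and repaired ties would coincide
  too. Positions are therefore passed through an epsilon chain
  (`span * 1e-6` per step) that enforces strictly increasing positions
  without visibly moving anything. The chain scales with `span`, preserving
  homogeneity.
* **Non-monotone tables.** Both packaged RM columns contain one genuine
  adjacent inversion (pain: faint > very weak; fatigue: moderate > barely
  strong). `build_axis` rejects non-monotone RMs by default, naming the
  offending pair; a permissive mode pools adjacent violators
  (pool-adjacent-violators on log RM, i.e. the isotonic least-squares fit)
  and logs loudly. The packaged axes are built in permissive mode. The
  toolkit reports inversions (`check_monotonicity`) rather than hiding
  them.

Cursor position and numeric rating are related by the identity on
`[0, span]` (a monotone bijection hook exists for alternative mappings);
out-of-range positions clamp to the boundary with a warning, since a cursor
may legitimately rest on the scale end.

## Descriptor scaling

Magnitude-estimation responses (peak handgrip force; button-press duration,
both strictly positive, 3 trials per stimulus) are processed as:

1. per-cell geometric mean over trials;
2. **modulus equalization**: each cell mean divided by the geometric grand
   mean of its participant x modality x stimulus-type block, so a block's
   standardized values multiply to 1. "Standardized within subject,
   condition and stimulus" admits several readings; modulus equalization is
   the normalization standard in the magnitude-estimation lineage this
   procedure comes from, removes each participant's idiosyncratic response
   unit exactly (tested as modulus invariance), and is the choice made here.
3. **calibration**: per participant and modality, OLS of log response on log
   line length over the 7-length line condition gives the Stevens exponent
   beta and intercept alpha (natural-log units). Calibration is per
   participant (pooled fitting would mix response units); a beta <= 0 is
   rejected as non-invertible.
4. **inversion and aggregation**: descriptor responses are mapped to
   line-length equivalents `m = exp((log r - alpha)/beta)` and aggregated by
   geometric mean across modalities, then across participants. The global
   scale of the result is not identified (calibration removes units);
   comparisons against the packaged tables first rescale to a common
   geometric mean.

The exact line lengths of the original procedure are not recorded anywhere;
the simulator uses a 7-step geometric ladder 1..64 (arbitrary units), which
only needs to span a decent log range for the calibration to be
well-conditioned.

The fatigue-vs-pain comparison is a paired two-sided t-test over the 12
descriptors (df = 11). Differences whose spread is at float-noise level
relative to their mean are reported as degenerate (|t| = inf) rather than
producing a meaningless huge statistic.

## Task design

Schedules are pseudorandom subject to exact constraints. Conditions
(change dim1 / dim2 / both / neither) are a shuffled multiset with exact
per-condition counts, which makes the two change indicators exactly
uncorrelated within a schedule. Stimulus values are drawn uniformly over
the stated physical ranges (distributions are not recorded in the source
procedure; uniform is the neutral choice and a config hook exists). A
changed dimension must move by at least 10% of its range (configurable) so
that "change" is perceptually well defined; the draw is uniform over the
admissible set, not rejection-sampled. Unchanged dimensions carry the
previous value forward bit-for-bit.

Durations: drawn uniformly within bounds, then repaired —

* visual: waterfilling (proportional shifts with clipping) to the exact
  195,000-ms total, then largest-remainder integer rounding within bounds;
* auditory: affine renormalization to sample mean 8000 ms and sd 1450 ms,
  clipped to [5600, 10500] ms with mean-preserving repair, then integer
  rounding to the exact 192,000-ms total (so the sample mean is exactly
  8000 ms and the part duration falls inside the stated 189–196-s window).

Structure: the visual run is 21 epochs (an initial circle plus 20 changes;
the first epoch carries the label `initial`). An auditory part is 24 sound
epochs, each carrying one change condition; the first epoch's condition is
defined against an implicit baseline sound stored on the schedule. The
arithmetic forces this: 25 sounds at mean 8 s would exceed the stated part
duration. Auditory stimulus streams are keyed by (seed, sound set) only, so
a set reused in another part is the same stimuli — sets exist to be rotated
across parts.

Counterbalancing: axis assignment alternates by participant parity;
descriptor-set order alternates with period 4 (phase-shifted so it is not
confounded with axis assignment); part order and set-to-part assignment
cycle through rows of a 3x3 Latin square. Every factor is balanced to
within one participant at any cohort size.

## Rating pipeline

Streams sampled about every 20 ms are averaged into 250-ms bins (mean, not
last-sample: robust to frame jitter), timestamped at bin centers; each
sample is treated as covering one acquisition frame, so a stream of n
frames spans `n * dt` ms and yields `floor(duration/250)` bins with any
trailing partial bin dropped. Bins left empty by acquisition gaps carry the
previous value forward, logged. Epochs are half-open `[onset,
onset+duration)`, so a boundary sample joins the later epoch. Each retained
sample carries the current epoch's value of the rated dimension, the
concurrent other-dimension value, and the preceding epoch's value of the
rated dimension; first-epoch samples have no previous value and are dropped
by models that use one (no imputation).

Predictor coding: size (px), brightness (grayscale level 0–245, larger =
brighter) and frequency (Hz) enter raw; attenuation is reversed and
normalized to loudness `(65 - dB)/50` in [0, 1] so the predictor increases
with perceived volume. A configurable `lag_ms` can shift ratings backwards
to compensate a fixed response latency (default 0; the original analysis
recorded none). `exclude_transition_ms` optionally drops samples near epoch
transitions; 125 ms (half a bin) removes exactly the bins that straddle a
stimulus change and mix two stimulus levels. The default is 0; the
parameter-recovery protocol uses 125 ms so the fitted linear model is
correctly specified (a straddling bin's mean is a mixture no linear model
in the epoch values can represent).

## Regression models

The original three-level hierarchical analyses (timepoints within design
cells within participants within age groups) are re-expressed as two-level
linear mixed models: participant random intercept, optionally random slopes
for the level-1 predictors, with group-level moderators (age group, scale
type, sound set, stimulus type) as fixed cross-level interaction terms.
The fixed-effect targets are identical and pseudo-levels with 2–3 units are
avoided. Fitting is REML via statsmodels MixedLM.

Conventions:

* Level-1 predictors are grand-mean centered by default in the packaged
  rating-accuracy spec. Besides being the standard practice, centering
  decorrelates participant-level intercepts from participant-level slopes,
  which matters for slope standard errors.
* Random slopes use a full (unstructured) random-effects covariance,
  estimated on standardized copies of the predictors for numerical
  conditioning (an affine reparametrization; fixed effects and their
  standard errors are unchanged). During development an
  independent-components structure was found to undercover the generating
  coefficients in calibration runs and was replaced by the unstructured
  fit.
* Optimizers are tried in sequence (L-BFGS, BFGS, Powell); a random-slopes
  fit that still fails or is singular falls back to the random-intercept
  model, flagged on the result.
* Degrees of freedom follow the hierarchical-modelling convention: terms
  involving a participant-level moderator — and, under random slopes, all
  terms, since their uncertainty is between-participant dominated — use
  `df = n_groups - 2`; purely level-1 terms in random-intercept fits use
  the residual df. Labels: p < 0.05 significant, 0.05 <= p < 0.1 trend,
  else n.s.
* "Variance explained" is the proportional reduction in level-1 residual
  variance between a null and a full model on the same rows, floored at 0.
* Serial autocorrelation of the 250-ms residuals is ignored in the default
  fit, as in the original analysis; this is a known limitation (see below).

Descriptor-magnitude models average the 3 trials per cell first, regress
the response on stimulus intensity (line length, or descriptor reference
rank — the rank is the intensity metric by construction of the scale), and
moderate by stimulus type and age group; moderators observed at a single
level are excluded as constants.

## Synthetic participants

The simulator provides the statistical structure the analyses assume — no
more. Continuous rater: per epoch, a normalized target
`gain*u_current + w_i*u_other + w_c*u_previous + offset` (u = the coded
stimulus value rescaled to [0,1], optionally power-transformed with
exponent gamma) is mapped affinely onto `[0, span]` through a fixed
population-level envelope with 3-sigma headroom over the heterogeneity
parameters. The envelope plays the role of an experimenter calibrating
stimulus ranges so ratings stay on-scale: without it, targets beyond the
axis ends would truncate and attenuate every regression coefficient. The
map is common to all participants, so the implied population regression
coefficients have a closed form (`true_linear_coefficients`, gamma = 1
only); with all weights and heterogeneity at zero it reduces to the
identity and the rater tracks `span * u_current` exactly. The latent rating
relaxes toward the target as a first-order exponential with time constant
`lag_tau`; observed samples add iid Gaussian noise and clamp to the scale.

Defaults (chosen once, as study conditions): `interference_w = -0.06`,
`carryover_w = +0.16` — signs and relative sizes mirroring the published
visual-task coefficient pattern (current dominant; other-dimension effect
small and negative; previous-epoch effect intermediate and positive), used
as generator inputs, not reproduction targets; `noise_sd = 5` rating units
on span 100; heterogeneity `gain_sd = 0.10`, `weight_sd = 0.04`,
`intercept_sd = 0.03` (plausible inter-individual variation, and the
between-participant variance the mixed models estimate); `lag_tau = 0` in
the defaults so the recovery benchmark isolates the static mapping, with a
`realistic()` preset (400 ms) for demos and lag studies. Responder:
`beta_grip = 1.7` (the classic force-production exponent),
`beta_button = 1.1` (duration matching is near-linear), log-normal trial
noise (`lognoise_sd = 0.15` in the noisy study condition), optional
per-participant modulus spread. Rankings: independent adjacent
transpositions applied left-to-right at a configurable swap probability.

What the simulator does **not** emulate: congruency effects beyond the
linear interference term, motor dynamics of the trackball, drifting
attention or fatigue over a run, autocorrelated rating noise, saturation
psychophysics at scale ends, and the age effects reported for real cohorts
(the age moderator is zero unless explicitly injected). Passing recovery
tests therefore show that the pipeline estimates what the generative model
encodes — not that real raters behave this way.

## Validation battery: problem sizes and what each run shows

All seeds are fixed in the tests; every quantity below is recomputed at
test time, none is stored.

* Reference-table statistics: paired t over the packaged tables
  (t(11) = -1.38 within 0.01) and exactly the two known adjacent
  inversions.
* Schedule contracts over 100 seeds per task: exact condition counts,
  duration bounds, exact totals/means.
* Downsampling: a full 195-s, 20-ms stream gives 780 bins whose means
  match a brute-force per-bin tally (equality up to float summation
  order).
* Descriptor-scaling recovery: noiseless runs recover (alpha, beta) and
  RMs proportional to truth at machine precision; with lognoise 0.15 and
  30 participants, RM rank order is perfect in each of 100 seeded runs
  against a 12-step geometric intensity ladder spanning the reference
  range. The ladder, not the packaged table, is the truth here: the
  packaged columns contain near-ties and two true inversions, against
  which perfect rank recovery is undefined under any noise.
* Mixed-model recovery: 100 seeded cohorts of 32 participants on the full
  visual design (about 23,000 records per cohort), random-slopes fit with
  transition exclusion; generating signs recovered in 100/100 cohorts and
  each coefficient's 95% CI covers its generating value in >= 93 of 100.
  Moderator calibration: 200 seeded null cohorts of 16 participants on a
  scaled-down design (8 changes, 65 s — chosen to keep the Monte Carlo
  tractable) give an age-moderator rejection rate within 0.05 +/- 0.03.
* Package invariances: span rescaling preserves t-ratios and labels;
  rescaling one participant's response modulus leaves RMs unchanged;
  identical seeds give byte-identical outputs; every simulator TSV is read
  back bit-exactly by the analysis readers (floats are written in shortest
  round-trip form and parsed with round-trip precision).

## Known limitations

* The displayed geometry of the original scale (pixel layout, whether the
  historical hand-tuned positions differ from a pure log map) is not
  recoverable; only ordering and log spacing are modelled.
* Mixed-model p-values use Wald t statistics with the df conventions above,
  not Satterthwaite/Kenward–Roger corrections; with random slopes and 32
  participants the calibration runs above are the evidence they behave.
* Ignoring residual autocorrelation inflates level-1 precision for data
  with a real response lag; an AR-aware fit is not provided, only the
  transient-exclusion and lag-offset controls.
* The published human-data coefficients and variance percentages are not
  reproducible without the raw participant data; they enter only as
  generator effect-size inputs and sign/structure checks.
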