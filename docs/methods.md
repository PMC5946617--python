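# Methods

## Model

The memory colour effect is treated as one-dimensional cue fusion along
each stimulus's typical-hue axis in the isoluminant DKL chromaticity
plane (background grey at the origin, arbitrary plane units).  The axis
is the unit direction of the mean typical adjustment; the orthogonal
component of every adjustment is discarded after projection, since the
effect is defined along the typical-hue dimension only.

Two Gaussian cues are estimated from projected repeated adjustments:
the prior (typical adjustments of the object) and the signal (grey
adjustments of a colour-neutral disk).  Reliabilities are inverse
variances, and the posterior is the precision-weighted average
M = w1·P + w2·S with w1 = r1/(r1+r2) and SD = sqrt(1/(r1+r2)).  The
model is fully determined by data; it has no fitted parameters.
Structural consequences, both covered by tests: M always lies between
the cue means (with S at grey and P positive, 0 ≤ M ≤ P, so negative
effects are unpredictable by design), and M grows with signal variance
whenever P > S (an unreliable grey percept cedes weight to memory).

Assumptions: both cues are Gaussian on the projected axis; repeats are
exchangeable; the disk's grey adjustments characterise the observer's
grey-perception noise for every object; adjustments for different
objects share no other coupling.

### Sign convention

Projections are positive toward the typical colour.  Observers
compensate for the memory colour they perceive, so grey adjustments of
colour-diagnostic objects sit opposite the typical hue; the measured
effect is the *negated* mean projection of those adjustments.  A
positive measured effect therefore means the canonical compensating
shift, a negative one a shift toward the typical colour.

### Analysis levels

* **individual** — cue variances across one observer's 3–5 repeats
  (unbiased, n−1 denominator: with such small n the bias of the n
  denominator is material, and n−1 is the field default).
* **aggregate** — cue means and variances across per-observer mean
  projections.  The variance of observer means empirically realises
  within-observer variance divided by the number of repeats (the
  standard-error construction); the package uses the empirical variance
  of means rather than the analytic var/n, which holds only in
  expectation.  A dedicated check confirms the identity to within 5% at
  10,000 simulated observers.

### Numerical choices

* The posterior SD is sqrt(1/(r1+r2)), the standard deviation of the
  normalised product of the two cue Gaussians; the raw inverse-precision
  form 1/(r1+r2) (the posterior *variance*) is available behind
  `sd_mode="inverse"` for comparison.  A numerical product-of-Gaussians
  integration oracle confirms the closed form to ~1e-14 relative error.
* Zero-variance cues (possible with 3 constant repeats) are handled by
  *opt-in* epsilon-regularisation of reliabilities, 1/(var+eps),
  default eps 1e-9 when enabled.  Without the opt-in, the affected cell
  raises/skips with a logged reason — the analyst must choose knowingly
  rather than receive a silently clamped weight.
* Degenerate hue axes: a mean typical adjustment with radius ≤ 1e-6 is
  declared directionless (true achromatic controls such as a golf ball)
  rather than normalised from numerical noise.
* Per-observer correlations of ±1 (common with 3–5 stimuli) are clamped
  to |r| = 1−1e-12 before the Fisher transform when clamping is enabled
  (default); otherwise the observer is dropped and logged.

## Evaluation approaches

1. **Individual**: Pearson r between predicted and measured effects per
   observer, Fisher z = arctanh(r), one-sample one-tailed t test of z
   across observers; the summary correlation is the inverse-Fisher of
   the mean z.  When several image conditions are analysed together,
   each observer's z is first averaged over per-condition correlations,
   then tested across observers — the computable form of combining
   conditions at the individual level.
2. **Pooled**: one correlation over all observer × stimulus pairs
   (df = n−2); between-observer variation is part of the variation.
3. **Aggregated**: correlation across stimuli of aggregate-level pairs
   (df = n_stimuli − 2), with aggregate cue variances as above.

One-tailed tests take the upper tail of the t distribution of
r·sqrt(df/(1−r²)); a Monte-Carlo null calibration keeps the empirical
type-I rate at alpha = .05 within [0.03, 0.07].  The *relative* memory
colour effect subtracts from each measured effect the mean of its image
condition, removing condition offsets the model cannot express;
predicted effects are left uncentred by default (they are comparable
across conditions), with an option to centre both.  The paired
difference test reports delta = mean(predicted − measured) with
df = n−1, two-tailed.  Stimulus exclusions are configuration, never
hard-coded.  p-values are reported at full precision.

## Synthetic virtual observers

The generator emulates the three measurement types of the modelled
study designs.  Per observer (optional log-normal SD multiplier kappa)
and stimulus: typical adjustments are Gaussian around
prior_mean·(cos θ, sin θ) with on-axis SD kappa·prior_sd; disk greys are
zero-mean with an anisotropic covariance in a daylight frame
(signal_sd_axis along the daylight locus, signal_sd_ortho across it —
grey settings vary most along the blue–yellow daylight axis); grey
adjustments of objects are centred at the *negated* posterior shift
−λ·M·(cos θ, sin θ), with M computed in closed form from the observer's
own generative variances (the signal variance projected onto the
stimulus's hue axis) and the disk's covariance around it.  Isotropic
response noise — input-device/motor noise that the fusion model
deliberately omits — can be added to every adjustment.

λ (*effect adherence*, per stimulus) scales how much of the
model-prescribed shift the data express: λ=1 is model-conforming, λ=0
emulates objects with no memory colour effect, and negative λ (behind
an explicit flag) emulates shifts toward the typical colour.  Ground
truth (generative variances, closed-form M, expected effect λ·w1·P) is
returned for parameter recovery.

Defaults are the modelled study conditions: 15 observers, 5 repeats,
7 fruit-like stimuli with prior means 0.05–0.3 plane units and prior
SDs 0.04–0.16, signal SDs 0.06/0.03 (daylight/orthogonal, daylight
angle π/2), response noise 0, homogeneous observers.  The stimuli
deliberately span weak to strong memory colours so that
between-stimulus spread dominates aggregate estimation noise; they are
plausible in magnitude but not fitted to any empirical dataset (no raw
adjustment data are public).  What the generator does *not* emulate:
image recognisability and visual-feature differences between photo and
outline conditions (conditions differ only through the stimulus
parameters assigned to them), colour constancy under illumination
change, adjustment-trajectory dynamics, and non-Gaussian or correlated
response structure.  Passing closure and recovery tests therefore show
the pipeline is faithful to its own model, not that the model explains
real observers.

## Verification studies and problem sizes

The studies module re-derives every headline claim at desk scale:
fusion oracle (1,000 random cue pairs vs numerical integration),
pipeline closure (λ=1, no response noise, 20 observers × 7 stimuli × 5
repeats; the predicted–measured delta is averaged over 10 replicated
runs and tested against its Monte-Carlo SE, which detects systematic
bias far smaller than any single run's paired t test could), parameter
recovery (100 seeds of the 15 × 8 × 5 design, mean correlation with
ground truth ≈ 0.98), noise attenuation (5-point response-noise grid ×
200 seeds with common random numbers across grid points, so the
monotone decay of mean individual-level correlation is not masked by
between-level Monte-Carlo jitter), and type-I calibration (20,000 null
simulations at 7 pairs).  These sizes keep the full suite a few minutes
on one core while leaving Monte-Carlo error well below every asserted
margin.

## Known limitations

* The model itself is deliberately minimal: no response-noise term, no
  recognisability/realism term, no negative effects — evaluation is
  designed to surface these failures, not absorb them.
* Aggregate weights plug noisy variance estimates into a ratio; with
  ~20 observers this adds O(1/n) bias and spread to predictions that
  the closure study quantifies but does not remove.
* The generator's observer heterogeneity is a single multiplicative SD
  scale; per-cue heterogeneity and between-observer prior-mean
  variation are not modelled.
* Chromaticities are consumed as given; no conversion from device or
  cone space, and no luminance dimension.
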