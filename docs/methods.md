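# Methods

This note documents the models, numerical procedures and design choices
behind `bdat`, and what the simulation-based validation does and does not
establish.

## Item design

Every clip is six 4/4 bars at a base tempo of 125 bpm (beat period
60/125 = 0.48 s, clip 11.52 s).  Bars 1–3 and 5–6 carry the rhythmic
material; bar 4 is the beat drop: beats 2–4 contain no rhythmic cue, only a
drone and the probe.  Beat k of bar b (both 1-based) falls at
`((b−1)·4 + (k−1)) · beat_period`, with the clip starting at bar 1 beat 1 =
0 s.  The probe targets beat 3 (metrically strong) or beat 4 (weak); ON
probes sit exactly on the beat, OFF probes are displaced early or late by a
fraction of the beat period.

Displacement levels come from the perceptual-accuracy scale
`PA(d) = cos(πd)^e` with exponent `e = 4`: seven PA values equally spaced
between PA(0.15) and PA(0.45) are inverted numerically (bisection to
1e−12; the closed form `d = arccos(PA^{1/4})/π` is used as a test oracle)
and rounded to the nearest whole percent, half up, giving
15/18/20/23/26/31/45%.  The scale's endpoints avoid both the displacement
detection threshold (below 15%) and the half-beat ambiguity (a probe 50%
late on beat 3 coincides with one 50% early on beat 4).  Rounding is
configurable; the default reproduces the published level set.

Per track and tempo the bank holds 2 ON items and 2 beats × 2 directions ×
7 levels = 28 OFF items; 30 tracks at one tempo give 900 items, and the
five tempo variants give 4,500.  The five variants for base 125 bpm are the
published constant [119, 122, 125, 128, 132]; note the top value departs
from plain half-up rounding of 125 × 1.05 = 131.25, so the list is kept
verbatim for fidelity to the published bank, while other base tempi use the
multiplicative ±5%/±2.5% rule with half-up rounding (computed in exact
per-mille arithmetic, so e.g. 100 bpm → [95, 98, 100, 103, 105]).  A
default exclusion bundle removes (track 3, ON) and (tracks 12/27/30, OFF),
the cells screened out of the published bank.

## Stimulus audio

Rendering is schematic: a decaying-sine grid click (C#6, 30 ms) on every
beat outside the drop window, a drone (110 Hz, level 0.05, 30 ms fade-in
and -out so it carries no detectable onset and no amplitude periodicity at
the beat rate) spanning the drop, and the probe — a 120 ms decaying tone at
F2 = 87.31 Hz (equal temperament, A4 = 440), the published probe pitch and
duration; the original woodblock timbre is not specified beyond pitch, so a
clean synthetic burst is used.  Event onsets are sample-exact
(`round(t · fs)` at 44.1 kHz); both stereo channels are identical; output
is PCM-16 WAV with a JSON onset sidecar.  `verify_onsets` re-detects onsets
from the rendered buffer with a moving-maximum amplitude envelope (7 ms
window — wider than a half period of F2, or the envelope dips at zero
crossings and re-triggers) and a 0.12 rise threshold over a 1 ms lag, and
checks every planned onset is recovered within ±1 ms with no spurious
detections.  The threshold sits above the amplitude-beat wiggle produced by
the 87 Hz probe tail interfering with the 110 Hz drone and below the
smallest rendered event level.  The psychometric layer never inspects
audio — items are fully described by their design features — so the
schematic timbre has no effect on any model result.

## Response model

Accuracy on a trial is `P = g + (u − g)·logistic(η)` with
`η = x'β + b_person + c_track`.  The asymptotes are fixed at g = 0.4
(1-AFC guessing) and u = 0.98 (ON) / 0.96 (OFF) (1 − inattention), the
published values bundled in `params/on_condition.yaml` and
`params/off_condition.yaml` together with the fixed effects and
random-intercept SDs.  Covariate coding: strength 1 = beat 3 (reference
weak), direction 1 = late (reference early, so the negative printed
direction coefficient encodes better accuracy for early probes),
displacement = level index 1–7.  Level-index coding is a documented default
rather than a reconstruction of the original fit: at 0.41 logits per step
it spans ≈2.5 logits across the bank, consistent with the reported
near-linear accuracy trend, whereas raw-percent coding would imply a
12-logit span.  One printed inconsistency is resolved in favour of the
positive coefficient: the displacement row reports B = 0.41 (SE 0.07) with
a negative z; the positive sign matches the accuracy-increases-with-
displacement finding.

The GLMM→IRT mapping takes a = σ_ID (constant discrimination),
b = −x'β/σ_ID, g and u unchanged, giving a 4PL with abilities standard
normal in the calibration population.  The track effect is dropped at
administration time — each track appears at most once per session and its
calibrated SD is small — but retained in calibration.  Fisher information
of one response is `a²(P−g)²(u−P)² / ((u−g)²P(1−P))`, reducing to
`a²P(1−P)` at g = 0, u = 1.

## Calibration

`fit_explanatory` maximizes the marginal likelihood over β and the two SDs
(optimized on the log scale with bounds, keeping them non-negative);
asymptotes are fixed inputs.  Crossed random effects admit no nested
closed form, so the likelihood is computed by a hybrid scheme:

* conditional on the track effects c, participants are independent and
  each participant's 1-D integral is evaluated by Gauss–Hermite quadrature
  (15 nodes inside the fit; agreement between 15 and 41 nodes is ≈2e−4
  log-units at n = 500);
* the track vector is integrated by Laplace approximation at the mode of
  `Σ_p log f_p(c) − c'c/2σ_track²`, found by L-BFGS with the analytic
  gradient `E_post[score]`; the Hessian uses posterior covariances of the
  per-track scores within participants.

The accuracy lives where it matters: each track effect is informed by
hundreds of responses, so its Gaussian approximation is excellent, whereas
each participant contributes only ~15 binary responses squeezed between
the 0.4 floor and 0.96–0.98 ceiling, where a joint Laplace approximation
(the construction standard mixed-model software applies to crossed
designs, which this package reproduces as a fast starting-value stage and
validates against lme4 in the logistic reduction g = 0, u = 1) is
noticeably attenuated — it shrinks σ_ID and every fixed effect with it.
Person-dimension quadrature removes that attenuation: in replicate
simulations at n = 500 the mean bias of the OFF fixed effects is at the
Monte-Carlo noise floor, versus 10–15% shrinkage for the joint Laplace.

The outer optimizer is L-BFGS-B with forward-difference gradients (step
1e−5, chosen above the inner-solver noise floor; projected-gradient
tolerance 1e−3, far below coefficient SEs).  Standard errors come from the
numerically differentiated observed information at the optimum.
Convergence is reported from the optimizer plus finiteness of the SEs.
A plain Monte-Carlo/Gauss–Hermite integration oracle (`marginal_loglik_mc`,
prior sampling over track effects) validates the hybrid likelihood on
small datasets; the two agree to ~1e−3 log-units on a 10-participant ×
5-track dataset.

`prediction_accuracy` classifies each row by the conditional probability at
the empirical-Bayes random-effect estimates (> 0.5 → predict correct) and
reports the proportion matching the observed response.  Screening follows
the published data-quality rules with explicit defaults: tracks with mean
accuracy strictly below chance 0.5 per condition are flagged (possible
stimulus bias); participants whose most frequent reconstructed on/off
judgment exceeds 0.9 are flagged.

## Adaptive administration

EAP uses a fixed grid θ ∈ [−4, 4], step 0.01, standard-normal prior;
posterior mean and SD follow from the grid weights; with no responses the
estimate is the prior mean 0.  EAP is the default because it is defined for
all-correct/all-incorrect patterns; grid-argmax ML is available.  Item
selection: the first trial takes the bank's difficulty closest to 0;
subsequent trials draw the condition (ON with probability 0.5, mirroring
the fixed design — the original scheduling is not specified) and take the
closest-difficulty item among unused tracks (maximum-information selection
is a flag).  Ties break by seeded uniform choice; one item per track per
session; fixed length, default 25 trials; pseudo-IQ = 100 + 15θ.

## Simulation and validation

The fixed-design simulator draws θ ~ N(0,1), presents each of 30 tracks
once (ON with probability 0.5; OFF perturbation uniform over the 28
variants), and samples responses from the response model with person effect
θ·σ_ID and, optionally (default on for calibration data, off for adaptive
sessions), track effects N(0, σ_track).  Datasets embed their seed and a
parameter fingerprint and regenerate byte-identically.

Validation at the default study conditions (n = 500 simulated participants
for calibration; 500 paired respondents × 25 trials for adaptive recovery):
fixed effects of both models recovered within 2 SEs; 50-replicate mean bias
below 0.1 with ≥80% 2-SE coverage; adaptive selection beats seeded random
selection in final-θ RMSE and correlation; simulated accuracies reproduce
the qualitative findings (strong ON beats easier than weak, early OFF
probes easier than late, accuracy rising across displacement levels).

What passing these tests does *not* show: the simulator draws from the same
model family the fitter assumes, so the validation establishes internal
consistency (correct likelihood, estimator, and wiring), not robustness to
the ways real listeners violate the model — learning or fatigue across
trials, response times, tempo-specific difficulty, item-specific
discrimination, or non-normal ability distributions.  Simulated accuracy
levels are also somewhat higher than the published empirical means, as
expected when generating from the fitted coefficients with level-index
displacement coding; the directional structure, not the absolute level, is
the validated quantity.

## Known limitations

* The Monte-Carlo oracle integrates track effects from their prior and is
  only trustworthy when tracks carry little information (toy data).
* The hybrid likelihood's Laplace step assumes many observations per
  track; with very few participants per track its accuracy degrades
  toward that of a joint Laplace.
* Audio onset verification is designed for the schematic renderer's
  near-instantaneous attacks, not for arbitrary recorded material.
* σ_track estimates at the boundary (true value ≈ 0) are reported as
  small positive numbers (log-scale optimization with a floor), not exact
  zeros.
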