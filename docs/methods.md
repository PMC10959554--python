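# Methods

This note documents the models, conventions, and numerical choices behind
`turngait`, in the order data flows through the package.

## Synthetic trials: what the generator emulates

The generator (`turngait.synthetic`) emulates the laboratory protocol the
analysis is designed for: walk ~5 m straight, turn 90°/180°/360° around a
rod, walk out ≥3 m, markers on both posterior calcanei, both 2nd
metatarsal heads, and the four iliac spines, captured at 120 Hz.

Construction, and the idealizations it makes:

- **Path.** Straight approach, circular arc of radius `turn_radius`,
  straight exit. The protocol it emulates deliberately did not control
  the turning path, so the radius is an explicit free parameter
  (default 1.2 m — large enough that a 90° arc holds at least two steps,
  the generator's minimum for a meaningful turn; sharper or wider turns
  are a parameter away). Curvature changes discontinuously at the arc
  ends; real turners blend in/out, so measured turn amplitudes lose a few
  degrees to threshold clipping in both worlds.
- **Footfalls** at equal arc length `step_length` along the path,
  alternating sides, each offset laterally `±step_width_offset/2` (a
  negative offset places each foot across the midline: a crossover).
  Contacts every `step_interval` seconds.
- **Feet.** Rigid, flat heel–toe pairs 0.20 m long, exactly stationary in
  stance (`stance_fraction` of the 2·`step_interval` gait cycle). Swing
  translates the foot along the path with an arc-length speed profile
  `a + b·sin(πu)` and a sinusoidal 0.05 m vertical lift. The profile's
  endpoint speed is 1.2× the pelvis speed: a pure cosine profile (zero
  endpoint velocity) would place the relative-forward-position minimum
  several frames *after* true toe-off, because a foot that starts its
  swing slower than the pelvis keeps receding; with a super-pelvis
  endpoint speed, the coordinate-based toe-off extremum and the
  velocity-based heel-strike extremum coincide with the construction's
  knots, which is what makes the generator an exact oracle.
- **Pelvis.** A rigid 0.24 × 0.10 m marker rectangle at 0.95 m height,
  centred on the path, moving at the constant speed
  `step_length/step_interval`, yaw locked to the path tangent. Real
  pelvises oscillate about the progression direction within each step;
  that oscillation is deliberately absent so the yaw signal is a clean
  step function of curvature.
- **Noise** is i.i.d. Gaussian per coordinate per frame. No marker
  dropout, soft-tissue artifact, or autocorrelated jitter is modelled, so
  noise-robustness results here bound only the white-noise part of real
  measurement error.

Because contact/lift times and footfall positions are knots of this
construction, the ground truth (`GroundTruth`) is exact, and the
`nominal_parameters` it carries are computed by the *same definitional
formulas* the pipeline applies to detected events — so recovery tests
isolate detection and localization error, not formula disagreements.

**Cohorts.** `CohortDesign` realizes a repeated-measures structure:
trial value = condition mean + subject effect (drawn once per subject) +
trial noise, for cadence, step length, and stance fraction; scenarios are
built to realize those values. Default condition means are normative
values for young adults at self-selected vs volitionally reduced speed
(cadence 113/111/112 vs 93/92/94 steps/min; step length from printed
speed × step time; stance fraction 0.603–0.644), with between-subject and
trial SDs on the scale reported for such cohorts. Turn direction is
randomized once per subject and kept for all their trials, as in the
protocol.

## Event detection

All signals are low-pass filtered before differentiation with a
zero-phase 4th-order Butterworth at 6 Hz (the standard gait-kinematics
choice at 120 Hz); velocities are central differences.

The progression frame is pelvis-local: origin at the 4-marker centroid,
lateral axis RASI→LASI projected to the ground plane, forward = lateral ×
vertical. Using a body-fixed rather than lab-fixed progression direction
is what keeps both detectors valid through 360° turns, and makes every
output invariant to rigid rotations/translations of the lab frame (tested
property).

- **Heel strikes**: candidate minima of the filtered foot-centre vertical
  velocity, gated three ways — prominence above 10% of the signal's IQR,
  depth below 45% of the third-deepest candidate (true landings share the
  trial's steepest descent; filter ripple and noise dips are shallow; the
  third-deepest reference keeps one edge transient from shifting the
  gate), and a stance check that the foot recedes relative to the pelvis
  just after the refined contact. The contact frame itself is refined on
  the *raw* height signal: first frame at which the foot-centre height
  returns to the stance baseline (baseline + max(2 mm, 4·noise scale)).
- **Toe-offs**: candidate minima of the filtered toe forward coordinate in
  the pelvis frame, refined to the raw-signal argmin within ±0.12 s.
- Candidates are thinned by a refractory interval of 0.4× the median
  inter-candidate spacing (earlier frame wins); per-side HS/TO alternation
  is enforced at merge, dropping and logging the later duplicate.

Filtering-then-refining is the load-bearing choice: the 6 Hz filter alone
shifts the kink extrema of piecewise-stationary signals by several frames,
while the raw refinement restores frame-exact timing. On a randomized
sweep of 50+ noise-free scenarios (90/180/360°, cadences 80–130, both
directions) every ground-truth event is recovered within ±1 frame with
zero spurious detections; at 1 mm marker noise the worst error grows to
~±2 frames.

## Turn segmentation

Yaw = unwrapped heading of the pelvis forward axis; rate = central
difference of the 6 Hz-filtered yaw. The turning period is the longest
contiguous run with |rate| > 30°/s (absolute value, so left and right
turns are symmetric); runs shorter than 0.1 s are ignored as noise.
Direction is the sign of the net yaw change over the run. The analysis
window extends from the last toe-off before onset to the first heel strike
after offset. `amplitude_measured` = |yaw(offset) − yaw(onset)| loses the
sub-threshold tails of the turn (a few degrees for the default sharp-ish
geometry; much more for turns barely above threshold — by design of the
threshold rule, not a defect).

## Spatiotemporal parameters

Let the window contain heel strikes t₁ < … < t_n.

- **duration** = t_n − t₁, **n_steps** = n, **cadence** = 60·(n−1)/duration,
  so cadence·duration/60 + 1 ≡ n_steps. The toe-off-led window selects
  *which* events are analyzed, but the whole-turn clock runs heel-strike
  to heel-strike: on uniform gait this makes duration = (n−1)·step
  interval exactly, which is also the internal relation the normative
  turning tables satisfy to printed precision (e.g. 60·2.75/1.46 = 113.0).
  Measuring the same span from the window-start toe-off instead would
  inflate every duration by a constant (2 − 2·stance_fraction)·step
  intervals and break that identity.
- **speed** = pelvis-centroid horizontal path *arc length* over [t₁, t_n]
  divided by duration. Arc length, not displacement: over a 360° turn the
  net displacement is ≈ 0 while the subject plainly keeps walking.
- **Footfalls** = heel position averaged over the 5 frames starting one
  frame after the heel strike (the detected frame can be the last airborne
  sample under quantization; the foot is stationary through early stance,
  so averaging only suppresses noise).
- **Per-leg, per-cycle** (cycles = consecutive same-side heel strikes
  inside the closed window): gait cycle duration, stance duration (to the
  leg's own next toe-off), stance/cycle ratio, initial double support (to
  the contralateral toe-off), stride length (planar distance between the
  cycle's two footfalls), and step length / stride width as the along /
  perpendicular components of the vector from the preceding contralateral
  footfall, taken against the chord through the two contralateral
  footfalls bracketing the step. Width is signed positive when the foot
  lands on its own anatomical side of that chord. The chord convention is
  one of several defensible readings of "the contralateral line of
  progression" on a curved path; it is isolated in one function
  (`_signed_step_components`) so it can be swapped.
  A consequence worth knowing: on a tight arc the chord's sagitta pushes
  the external footfall outside the contralateral line, so a mild
  crossover placement still measures a *positive* external width; the
  crossover sign phenomenon appears once the path is gentle enough
  (sagitta (2·step)²/8R smaller than the offset).
- **Aggregation**: per-cycle series are averaged within trial, then the
  mean and sample SD (n−1) are taken across trials — the two-stage scheme
  matching per-condition trial aggregation. Bootstrap CIs are percentile
  CIs of the across-subject mean.

## Bayesian inference

Per response parameter (a condition mean or a within-subject SD), the
model is a linear mixed model over the 2 (speed) × 3 (amplitude) design
with a subject random intercept. The response is standardized by the SD
of all its subject-condition values; on that scale the fixed effects get
the N(0, 1.6) prior (≈80% prior mass on effects between −2 and 2), the
intercept a vague N(0, 10²), and both SD components half-Cauchy(0, 2.5)
priors via the inverse-gamma scale-mixture — which keeps every full
conditional conjugate, so the sampler is pure Gibbs. Fixed effects and
subject intercepts are drawn as one joint Gaussian block (sampling them
separately mixes poorly through the intercept/mean-random-effect
correlation). Defaults: 4 chains × 5000 draws after 500 warmup,
deterministic given the seed; split-R̂ > 1.01 or ESS < 10,000 raise a
RuntimeWarning, never a silent pass. Variance draws are floored at 1e-12
so constant responses stay finite.

Decisions: the 95% shortest-interval HDI of the standardized contrast
against the ROPE ±0.2 (i.e., ±0.2 SD of all parameter data) — *different*
if disjoint, *practically equivalent* if contained, else *undecided*.
Cohen's *d* (contrast / residual SD, samplewise) and η² (factor share of
the between-cell sum of squares of the 6 posterior cell means) are
reported as effect sizes. Bayes factors use the Savage–Dickey density
ratio with a Silverman-bandwidth KDE at 0 — the KDE is the dominant
tolerance source (a few percent); pMAP is the KDE density ratio at 0
versus the mode. `bf_robustness` re-evaluates the ratio over a prior-SD
grid using the same posterior draws; this is exact only insofar as the
posterior is likelihood-dominated, which is the regime where a robustness
check is informative. No multiplicity correction is applied across
parameters — deliberately, matching the uncorrected-Bayesian analysis
convention this package follows.

Operating characteristics (tested at reduced MCMC, 200 replicates each):
on null cohorts (n = 10 subjects) the false-*different* rate of the speed
contrast is ≤ 10%; with a true standardized effect of 2 the *different*
rate is ≥ 80%.

## Problem sizes and determinism

The test suite and acceptance script run entirely on synthesized data:
single trials are ~900–1300 frames; the event-recovery sweep uses 51
scenarios; the decision-characteristics study uses 400 short-chain fits
(2 × 350 iterations each); cohort end-to-end tests use 4–6 subjects × 2–3
trials. These sizes were chosen so the full distribution of each check is
exercised while a complete run stays in the minutes range on one core.
Every random draw flows from an explicit seed through
`numpy.random.SeedSequence` spawning; identical config + seed reproduce
outputs bit-for-bit.

## Known limitations

- The generator's stance is perfectly stationary and its swing profile
  smooth; detectors tuned here carry no guarantee for pathological gait,
  marker dropout, or soft-tissue artifact.
- The turning path is a single arc; multi-phase or hesitant turns (and
  step-turn vs spin-turn strategies) are out of scope.
- `stance_fraction` must exceed 0.5 (no flight phase): walking only.
- Parameter recovery tests validate the pipeline against its own
  construction conventions (chord-based widths, heel-strike-clocked
  duration); recordings processed with different conventions will differ
  systematically, not randomly.
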