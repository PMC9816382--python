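# Methods

This note records how the Swing Performance Index (SPI) is computed, the
choices made where the procedure was genuinely open, what the synthetic
data do and do not emulate, and the package's known limitations.

## Kinematic model

Pelvic and upper-torso orientation are each reduced to a single
transverse-plane heading: the left-minus-right marker vector (ASIS pair
for the pelvis, acromion pair for the torso) is projected onto the
horizontal plane and its heading taken with `atan2`, in degrees, unwrapped
so no between-frame step exceeds 180°.  Frames where the projected segment
norm falls below 1 nm (markers vertically stacked) inherit the previous
frame's heading; an all-degenerate series is an error.  The vertical axis
is explicit recording metadata (default z-up), never inferred, because the
event rules depend on vertical displacement.

Rotational velocity is the central finite difference
`ω[t] = (θ[t+1] − θ[t−1])·rate/2`, one-sided at the endpoints.  Central
differences are second-order accurate and symmetric in lag; the method's
source describes differentiation only as "rate of change", so the scheme
is our choice.  X-prime is `ω_pelvis − ω_torso` per frame; it is negative
during the downswing, when the torso outpaces the pelvis.

Sign convention: headings are counter-clockwise about the up direction.  A
right-handed golfer's downswing is clockwise seen from above, so reported
velocities are negated for `handedness="right"` (and left unchanged for
left-handers), making downswing pelvis/torso velocities positive for
either handedness.

No smoothing is applied by default.  A zero-lag 4th-order Butterworth
low-pass (2nd-order, forward–backward) is available via
`filter_cutoff_hz` for noisy captures; 10–20 Hz is appropriate for
240 Hz optical data with millimetre-level marker noise.

## Swing events

* **Backswing start** — first frame whose absolute vertical club-marker
  speed exceeds 0.2 m/s, sustained for `min_hold` frames (default 5,
  ≈21 ms at 240 Hz).  The source method states only the threshold; the
  sustain requirement rejects single-frame noise spikes, and the absolute
  value admits takeaways that dip before rising.
* **Top of backswing** — highest vertical club position between start and
  impact, ties to the latest frame.  This event only bounds the downswing
  search window; the 0.2 m/s rule does not define it.
* **Impact** — the frame immediately preceding the first rise in ball
  speed above `ball_launch_threshold` (default 0.5 m/s — far above marker
  noise, far below any real launch speed; the source gives no number).
  Ball speeds are never low-passed: a zero-phase filter smears the launch
  step backwards in time, biasing impact early.  Instead the launch
  threshold is raised to six noise-SDs above the pre-swing mean ball speed
  when that is higher, which keeps detection exact on clean signals and
  false-trigger-free at millimetre noise.  The quasi-static precondition
  is checked on the ball's *drift* (displacement between the mean
  positions of the two halves of the pre-swing window, per unit time,
  tolerance 0.05 m/s), which distinguishes a rolling ball from a noisy
  static one — instantaneous speeds cannot.
* **Follow-through end** — first local minimum of vertical club position
  after impact, plateaus counting from their first frame; if the height is
  still descending at the recording's end, the last frame is returned with
  a warning.

Clubhead speed at impact: marker speed is the one-frame displacement at
impact times the sampling rate; a total-least-squares plane fit (SVD)
followed by an algebraic (Kåsa) planar circle fit over the ±50 frames
around impact (clipped to the recording, minimum 10 frames with a
warning) gives the radius r, and the speed is scaled by (r + 0.05)/r for
the 5 cm marker-to-clubface offset.  A degenerate fit (collinear path)
falls back to the raw marker speed with a warning.

## Metric extraction

The pre-impact window is [top of backswing, impact] — the downswing —
with the impact frame included; the post-impact window is (impact,
follow-through end].  Whether "pre-impact" should start at the backswing
start or at the top is not specified in the source; starting at the top
prevents backswing-direction extrema from masquerading as downswing
peaks, and matches the labelling of the published velocity table.  Peaks
are signed extrema of maximal magnitude (the published X-prime peaks are
negative), ties resolving to the earliest frame.

## Index construction

Stage order: pro z-scoring → amateur oversampling in z-space → PCA fitted
on pro rows → projection of all rows → log distance → scaling.  Choices:

* **Population SD everywhere in the scaling stage.**  This convention
  reproduces the published per-swing integer scores (43/44 exactly, the
  last within 1); the sample-SD variant drifts by about one point on the
  extreme rows.  Selected empirically on the worked example and applied
  consistently (z-scoring, PCA covariance, and σ_ℓ).
* **Oversampling** follows the verbal description exactly: a random
  *original* minority row, its single nearest neighbour among the other
  original minority rows (k = 1, not the conventional k = 5), a uniform
  point on the segment, repeated until counts are equal.  The RNG seed is
  a required argument; results are bit-reproducible.
* **PCA** keeps all k components (k ≤ 3), ordered by decreasing
  eigenvalue, each component's sign fixed so its largest-|loading| entry
  is positive.  The sign rule uses a 1e-9 magnitude tolerance when
  choosing that entry, because with two z-scored variables the loadings
  are exactly ±1/√2 and an exact argmax is unstable to floating-point
  noise.  Scores are sign- and rotation-invariant regardless; the
  convention only makes saved models reproducible across linear-algebra
  backends.  Rank-deficient covariances (e.g. subsets containing X-prime
  together with both of its parents) are allowed: components are still
  returned and near-zero eigenvalues flagged with a warning.
* **Distance floor** ε = 1e-6 keeps ln finite for a swing coinciding with
  the pro centroid; the source is silent on this degenerate case.
* The SPI slope is negative (100 − 10·z): greater distance from the pro
  centroid means a lower score, matching the index's stated reading that
  low values indicate suboptimal rotational technique.  The score is
  invariant to the logarithm base (absorbed by the z-scoring) and to any
  joint orthogonal rotation of PC space; both are asserted in tests.

## Kaiser–Meyer–Olkin screen

KMO is computed from the correlation matrix R and the anti-image partial
correlations `a_ij = −R⁻¹_ij / √(R⁻¹_ii R⁻¹_jj)`; per-variable and overall
values are ratios of summed squared correlations to summed squared
correlations plus squared partials.  Implementation notes:

* The screen applies to the **overall** value only, inclusive at 0.6 — in
  the published selected subset an individual variable at 0.57 survived
  while the overall 0.62 met the criterion.
* Singleton subsets are trivially factorable (KMO is undefined below two
  variables) and pass the screen.
* Which rows enter the KMO is not stated in the source; the default is
  the original (pre-oversampling) rows of both groups, switchable via
  `kmo_population = {original, balanced, pro_only}`.
* A singular correlation matrix (fewer rows than variables, or collinear
  metrics) falls back to the pseudo-inverse with a warning.
* For independent variables the overall KMO settles near 0.5 (partials
  track the raw correlations), not near 0; the tests assert this together
  with exact agreement against a brute-force transcription of the formula
  and exact scale invariance.

## Classifier evaluation

Each candidate subset's SPI is evaluated as a one-feature logistic
regression (intercept + slope) under leave-one-out cross-validation; the
held-out predicted probabilities are pooled and the AUC computed as the
Mann–Whitney statistic with ties counted one half.  The fold unit is one
swing (row); the evaluation table of the source lists swings, and a
`group_by_subject` switch provides the subject-level alternative.  The
SPI model is fitted once on the full dataset and only the classifier is
cross-validated, following the source's stage order; `nested=True` refits
the SPI inside every fold as a sensitivity analysis.  The regression uses
scikit-learn with C = 1e6 — near-unpenalised maximum likelihood with a
deterministic optimizer; under perfect separation the bounded-coefficient
fit still yields probabilities monotone in the score, which is the
intended fallback, and a fold missing a class predicts the prior.
Oversampled rows are included in the evaluation (the balanced 22 + 22 set
underlies the published AUC and group statistics).  Ranking is by AUC
descending, ties to smaller subsets, then canonical metric order.

## Synthetic swings

The generator builds marker-level recordings from closed-form profiles:

* Pelvis/torso headings integrate piecewise raised-cosine velocity
  pulses hitting designed signed peaks: a negative backswing pulse (0.4 ×
  the downswing peak), a downswing rise to the designed peak at a designed
  fraction of the downswing, a fall to the designed impact value, a rise
  to the designed follow-through peak, and a decay to rest.  Profiles are
  C¹ with analytically known extrema.
* Markers sit at ±half-width perpendicular to each heading about fixed
  centres (pelvis width 0.30 m at 1.00 m height, shoulder width 0.40 m at
  1.42 m — plausibility constants used only as ground truth).
* The club marker rides a 1.4 m-radius circle in a plane tilted 0.3 rad
  from vertical; the circle angle follows cubic Hermite keyframes whose
  end velocities are chosen to preclude overshoot, so the height has one
  maximum (top), its arc bottom at impact, and its first post-impact local
  minimum at the designed follow-through end.  The marker's angular rate
  at impact is CSI/(r + 0.05), so the circle-corrected clubhead speed
  recovers the designed CSI.
* The ball is static at the impact point until the impact frame, then
  departs at 1.4 × CSI.
* Optional Gaussian marker noise (seeded) is added to every coordinate.

Ground-truth phase frames are produced by applying the event rules to the
noiseless signals at generation time; metric truth comes from the
analytic velocity profiles.  Recovery on clean recordings is within 0.1%
(tests assert 2%); at 1 mm noise, with a 15 Hz low-pass, within 5%.

The professional preset draws per-swing velocity targets from normal
distributions centred on the published pro cohort means and SDs
(downswing pelvis 415.2 ± 32.9 deg/s, torso 551.7 ± 47.6, impact
288.8 ± 70.9 / 458.5 ± 73.0, follow-through 309.8 ± 42.1 / 929.2 ± 185.1;
CSI 33.15 ± 5.91 m/s).  Draws are clipped so the impact velocity stays
below 95% of both adjacent peaks, keeping the profile well-posed.  The
amateur preset is an invented, parameter-documented degradation — means
× 0.75, SDs × 2, pelvis peak delayed from 55% to 80% of the downswing —
that claims group separability only, not amateur realism.  Consequently,
passing end-to-end tests demonstrate that the pipeline recovers designed
differences, not that it would rank real amateurs identically: real
swings have soft-tissue artefact, marker occlusion, inter-segment timing
structure and non-stationary noise that the generator does not model.

Default problem sizes: cohorts of 11 professionals and 5 amateurs (one
swing each, 2.6 s at 240 Hz) for pipeline tests, chosen to mirror the
reference cohort's shape while keeping the full subset search cheap.

## Worked-example fixture

The 22 professional and 22 amateur (oversampled) principal-component
triples and their published integer scores are embedded as
`worked_example_fixture()`.  The first five amateur rows are the original
participants (their scores match the participant-level table); the rest
are flagged as oversamples.  Re-fitting the scaling stage on the pro rows
reproduces 43 of 44 printed scores exactly and the last within one point
— the residual is the two-decimal rounding of the printed components.
The fixture's distances are taken from the origin (the printed components
are centred by construction); fitting instead to the recomputed pro mean
of the rounded components shifts scores by under half a point.

## Limitations

* The nine metrics describe transverse-plane rotation only; obliquity,
  translation, timing-sequence and angular-position (X-factor) measures
  are out of scope.
* The index is anchored to whatever professional cohort it is fitted on;
  models fitted on different cohorts are not comparable without
  re-anchoring.
* With 1–3 metrics the PCA can be rank-deficient when X-prime metrics are
  combined with both parent signals; distances then live in a lower-
  dimensional subspace.  This is permitted and flagged, not an error.
* C3D is not parsed; convert to TRC or the CSV dialect first.
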