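# Methods

`neuroreach` simulates and analyses the computational core of a
neuronally controlled tabletop reach aid: a camera watches a
marker-bounded work area, a text-to-speech prompt enumerates the
detected objects, the user selects one with a voluntary jaw clench
decoded from EEG band power, and a 3-DoF arm reaches the selected
object.  This note records the models, the parameter choices, and the
limits of what the synthetic experiments can show.

## Arm model and coordinate conventions

The arm is a serial chain described by Denavit–Hartenberg parameters
(θᵢ, αᵢ, aᵢ, dᵢ): a base yaw joint J1 with twist α₁ = π/2, link offset
d₁ = a₀ and link length a₁, followed by two pitch joints J2/J3 with
link lengths a₂ and a₃.  The closed-form end-effector (EE) position is

    Px = cos θ₁ (a₁ + a₂ cos θ₂ + a₃ cos(θ₂+θ₃))
    Py = sin θ₁ (a₁ + a₂ cos θ₂ + a₃ cos(θ₂+θ₃))
    Pz = a₀ + a₂ sin θ₂ + a₃ sin(θ₂+θ₃)

All lengths are **centimetres** (so the planner's squared-error
threshold of 0.1 cm² is dimensionally direct) and all angles radians.
Default link values a₀ = 22, a₁ = 15, a₂ = 13, a₃ = 15 cm follow the
hardware's published link lengths; the exact assignment of the physical
links to the DH symbols is not fully determined by the source drawings,
so the geometry is configurable.  The home pose is (π/2, 0, 0) — the
arm straight out, fully extended.  Joint limits default to a
270° window per servo.

Two frames are used.  The *table frame* has its origin at the centre of
fiducial marker 0, x along the marker-0→1 edge, y into the table, z up;
perception reports targets here.  The *arm frame* sits on the J1 axis;
by default the base stands above table point (0, 30) cm, yawed −90° so
the quarter-annulus the arm can sweep covers the 600 × 300 mm work
area with the home azimuth at one edge.  `ArmGeometry.target_from_world`
converts between the two.

### Inverse kinematics

The closed-form IK used as an oracle is a re-derivation: base azimuth
θ₁ = atan2(y, x), then the planar two-link problem for (a₂, a₃) in the
radial–vertical plane, with the elbow branch chosen by the sign of θ₃
(default elbow-up, θ₃ ≤ 0, so the EE comes down onto the target from
above).  A published closed form for this arm family exists but uses a
different axis convention and contains a dimensionally inconsistent
line, so the implementation is accepted purely through the
forward-kinematics round-trip property (‖FK(IK(p)) − p‖ < 10⁻⁹ cm over
both branches).  Reachability is the planar annulus condition
|a₂ − a₃| ≤ dist ≤ a₂ + a₃ — checked for the direct and the mirrored
azimuth — plus joint limits on the candidate solutions.

## Gradient-descent reach planner

The planner minimises the sum of squared EE coordinate errors
Є = Σᵢ (Pᵢ,target − Pᵢ,current)², using the analytic gradient
∇Є = −2 Jᵀ r (J the position Jacobian, r the residual) and the update
θ ← θ − η ∇Є with one learning rate for all three joints.  Defaults:
η = 0.001, convergence when Є < 0.1 cm², iteration cap 100 000 with an
explicit not-converged status.  Joint limits are enforced by clamping
with a warning, since the loss itself is unconstrained.

**Stability of the step size.**  At η = 0.001 in centimetre units the
descent is stable only while 2η·σ² < 2 for every singular value σ of J.
The azimuthal mode has σ equal to the planar radius, so targets near
the theoretical reach limit (planar radius ≳ 31.6 cm) or arbitrary
poses with the arm fully extended (radius up to 43 cm) can oscillate or
diverge.  Tabletop targets in the *utilized* work annulus converge
monotonically; accordingly the default work-zone layout restricts
object placement to radii 12–30 cm (split into four 22.5° sectors,
Z1–Z4), and the reach studies sample targets there.  Typical plans
converge in 30–60 iterations.

**Servo quantisation.**  Hobby servos register a commanded change only
once it moves at least one resolution quantum from the current
position; the operative quantum is 0.063 rad as published for the
motors (their 50 pulses/revolution rating would imply ≈0.126 rad — the
printed figure is kept and the value is configurable).  The planner
therefore tracks two trajectories: the exact *written* iterate (the
controller keeps updating it even below resolution, so the arm cannot
stall permanently) and the stepped *read* trace that snaps to the
written value at each quantum crossing.  At termination
|read − written| < quantum on every joint, and the terminal error
budget is reported as `sse_threshold + ‖FK(written) − FK(read)‖²`
(both terms cm²; the source combines them loosely, this package makes
the squared-distance interpretation explicit).

**Safe approach.**  Reaches execute in two phases: plan to a hover
point `target + (0, 0, clearance)` (default 5 cm), then descend, with
the elbow (J3) commanded before the shoulder pitch (J2) so the EE
stays above the object until the final drop.

## Planar perception

All targets lie on one plane, so a single 3×3 homography between the
image and the table replaces full camera calibration plus
pose estimation; it is fitted by normalised direct linear transform
(total least squares, via scikit-image) to the corner correspondences
of the visible 50 × 50 mm fiducial markers, and reported with the RMS
pixel reprojection residual.  Pixels are 0-based with the origin at
the top-left corner, x right, y down.  A marker set is usable only if
at least three markers are visible *and* the base marker (id 0) is
among them; anything less aborts the trial with the operator-facing
message "ArUco not found; please recalibrate".  Detection boxes enter
only through their centroids; the reach target's z is the configured
object height (default 0 — the source does not state how object height
enters the target, so it is an explicit parameter).

## Trigger classifier

Each sample carries 160 non-negative band-power features (32 channels
× 5 bands) at 8 samples/s, labelled relaxed (0) or jaw clench (1).
The per-feature threshold sweep evaluates every above/below/band rule
on a quantile grid (resolution 1/200 by default; the grid is a package
choice) and exhaustively returns the most accurate rule, with ties
broken toward the smaller lower threshold and the narrower band.

The production classifier is adaptive boosting of depth-limited
decision trees — 300 estimators, unit learning rate, maximum depth 7,
the published optimum of the hardware study's five-fold search.  The
exact boosting variant was not published; the package uses the
standard discrete (SAMME-style) algorithm from scikit-learn.  The
monotonicity diagnostic exposed by `staged_exponential_loss` tracks
the mean exponential loss of the *half* stage-weighted margin, which
is the surrogate this algorithm provably contracts each round; the
per-round weighted error itself is not a monotone quantity.  The
alternative model is a two-hidden-layer network (80/40 ReLU units,
sigmoid output, 100 epochs, batch size 32) with internally
standardised inputs, trained with Adam and a fixed seed; its
optimiser/loss were not published, so acceptance of this model rests
on qualitative properties only, never on the study's real-data
accuracies.

Metrics keep both F1 formulations (harmonic mean, and
tp/(tp + (fp+fn)/2)) and assert their identity; rates whose
denominator is zero are reported as an explicit undefined marker
rather than 0.  The 95% interval helper implements mean ± 1.96·σ/√n as
printed.  Stream decoding applies a consecutive-positive debounce: an
event fires at the k-th consecutive positive prediction and the
counter resets (k = 1 by default; k = 3 mirrors the proposed
multi-window rule).

## Synthetic data

No recordings from the study are distributed, so the generators
emulate its summary conditions:

* **Band-power streams.**  Three empirical feature patterns: a few
  features whose high values are distinctively relaxed-state, with
  clench samples dropping into a well-separated low band roughly half
  the time (pattern 1, the F7/F8-high-beta-like behaviour — near-zero
  false positives, ≈50% false negatives for the best single rule); a
  majority with heavily overlapping conditional distributions
  (pattern 2); and a few whose clench samples concentrate in a narrow
  low-density band in the relaxed tail (pattern 3).  Band power is
  non-negative and right-skewed, so every family is log-normal.  A
  per-sample latent clench strength (on/off, p = 1/2) is shared across
  all patterned features, the way one masseter artifact drives every
  channel at once; this caps the attainable ensemble accuracy near the
  mid-80s rather than letting many independent detectors push it to
  ~100%.  The default positive fraction of 0.6 pins the best
  single-feature accuracy (≈ 1 − 0.5 × positive fraction plus a small
  in-sample lift) at the top of the study's reported 65.7–70.0% band.
  Feature *structure* (pattern assignment, per-feature locations)
  is seeded separately from per-sample noise, so models trained on one
  stream decode another — channel semantics are a property of the
  subject and headset, not of a recording.  Default stream length is
  1200 samples (2.5 min at 8 samples/s), enough for stable five-fold
  statistics while keeping the ensemble study to a couple of minutes.
* **Scenes.**  Marker corners and object centroids are projected
  through a known world→pixel homography (~12 px/cm with mild
  perspective) with optional i.i.d. pixel noise and marker occlusion.
  Detection boxes are built symmetrically around the projected
  centroid, so noiseless scenes invert exactly; real detectors are
  asymmetric around perspective-projected objects, which this
  deliberately idealises.
* **Sessions.**  Prompts at 200 words/minute with 1500 ms
  inter-statement gaps, 5–8 objects per trial, reaction times
  Normal(0.756 s, 0.14 s) truncated at zero by resampling.  A
  selection is in-window if it lands between the target statement's
  onset and its end plus the 1500 ms gap.

## Trial orchestration

A simulated trial runs: marker validation → homography fit → stream
decode → event/timeline alignment → coordinate mapping → two-phase
reach plan.  The outcome rule (not stated in the source, fixed here) is
trial-level: an event inside the target statement's window is a true
positive; any other event is a false positive; a true clench with no
event is a false negative; a quiet trial is a true negative.  The
latency ledger sums per-activity latencies with `math.fsum` so the
total is exactly the component sum; prompting/actuation entries are
parameterised values, not wall clock.  The emergency override is a
latched halt: any trigger stops actuation at the next iteration and
stays latched until explicitly reset.  Usability is scored by the
standard ten-item scale (odd items response−1, even items 5−response,
sum × 2.5) and the six-subscale workload index (mean of the scaled
subscale scores; raw-to-scaled conversion is left to the instrument,
whose published mapping is not uniformly ×5).

## What the tests do and do not show

Passing suites show that the arithmetic pipeline (kinematics, planner,
mapping, metrics, tallies) is correct and that the classifier pipeline
reproduces the study's *structure* — weak single features in the
configured band, a boosted ensemble better by well over eight points —
on data built to have that structure.  They do not show that real EEG
from new subjects would classify at these accuracies, that a physical
camera/lens matches the idealised homography (no lens distortion is
modelled), or that the servo timing model matches real motors;
hardware latencies enter only as published constants through the
ledger arithmetic.

## Known limitations

* The planner is first-order only; no line search, momentum or
  damping.  Outside the utilized work annulus the published step size
  can oscillate or diverge (reported honestly as not-converged).
* No dynamics, torque, payload or collision modelling beyond the
  vertical-approach ordering.
* The network model's training details are package choices; its
  published accuracy figures are not acceptance anchors.
* Undefined metric rates propagate as `None`; downstream consumers
  must handle the marker.
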