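# Methods

`scopeskill` simulates the measurement-and-assessment chain of a
physical hysteroscopy trainer: a passive encoded arm measuring a real
endoscope, ring targets on the walls of a cavity phantom, a pedal press
per target, and a statistics layer that quantifies learning over a
30-trial session. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic cohort does and
does not emulate.

## Coordinate conventions

Right-handed cavity frame with the origin at the fulcrum **F** (the
entrance orifice), +z into the cavity along the mean insertion axis,
+y superior. Positions in mm; joint angles in radians internally;
rolls and orientation errors in degrees at the API surface.

## Arm kinematics and pose recovery

The positioning chain is a yaw–pitch–pitch 3R arm,

```
T(θ) = T_base · Rz(θ1) · Tx(l1) · Ry(θ2) · Tx(l2) · Ry(θ3) · Tx(l3),
```

with defaults l₁ = 150, l₂ = 200, l₃ = 200 mm and the base ≈ 300 mm from
F, placed above/behind the fulcrum with the home axis aimed at the
region the attachment point sweeps during operation. No published
dimensions exist for such arms in general; any geometry satisfying the
reachability invariants demonstrates the method, so the chain is fully
configurable and the defaults are chosen to keep the operating workspace
(attachment 290–350 mm behind F inside a ~40° cone) far from the yaw
singularity and the workspace boundary.

Pose recovery: the attachment point A comes from the encoded 3R forward
kinematics; the shaft axis is the line A→F; the tip is `A + L·u` with
`u = (F−A)/‖F−A‖`; insertion depth `d = L − ‖F−A‖`. The unencoded gimbal
angles are the solution branch with |θ₄| ≤ 90°, matching a physically
mounted gimbal. Degenerate inputs are reported, not clamped: an
attachment point within 1 µm of F raises a degenerate-axis error, and
`d < −1 nm` raises a retracted-tool error (exact zero insertion is
valid; sub-nanometre negatives from roundoff are clamped to 0).

The inverse map (used only to synthesize encoder logs) solves the 3R
chain in closed form with deterministic branches: yaw from `atan2`,
positive-elbow θ₃. Round-trip error is ~1e-13 mm in practice; tests
enforce 1e-6 mm.

## Oblique optic and camera

The 30° optic's view axis lies on a cone of half-angle 30° about the
shaft; roll selects the position on the cone. Positive roll is clockwise
looking down the shaft from the eyepiece. The optical coupler holds the
camera horizon fixed while the scope rotates, so the roll-zero reference
and the camera up-vector are both gravity-aligned (+y), with a +x
fallback when the axis is vertical. The camera is an ideal pinhole
(70° horizontal FOV, 640×480, no distortion); focal length in pixels is
`(width/2)/tan(fov/2)`.

## Targets, cavity and focus scoring

The cavity is a triangular prism (60 mm os-to-fundus, 40 mm intercornual
width at the fundus, 25 mm anteroposterior) — a deliberate simplification
of the uterine cavity that keeps the ten anatomical stations (fundus,
cornua, ostia, walls, isthmus) geometrically meaningful. Left/right
stations are exact sagittal mirrors.

Each target is a black annulus (outer 6 mm, inner 4 mm) around a 2 mm
LED. The score is the percentage of the fixed on-screen ellipse
(semi-axes 40×28 px at the principal point) inside the ring's **outer**
boundary, computed by Shapely polygon clipping on 128-vertex boundary
approximations; a Monte-Carlo rasterization serves as the independent
oracle in tests (agreement within ±0.5 points). Whether the outer or
inner edge of the annulus delimits the valid zone is a config switch
(`boundary`), defaulting to outer since the LED and inner disc lie
within the ring the trainee is asked to fill. Monotonicity caveat: the
score is non-increasing under overlay growth only while the reticle
centre lies inside the ring region — the regime the exercise operates in.

A target's *ideal focusing pose* is found numerically. For a shaft
direction u, requiring the target centre to sit exactly on the 30° view
cone pins the insertion depth in closed form
(`d = c∥ − c⊥/tan 30°`, viewing distance `D = c⊥/sin 30°`, where c∥, c⊥
are the target centre's components along/off the shaft line); a
Nelder-Mead search over the two shaft angles then trades viewing
distance (preferred 45 mm, falling back to 30/20/12 mm) against
incidence, subject to the tip staying inside the cavity and distal to
the fulcrum. The roll that points the view cone at the ring centre
defines the target's **nominal roll**, against which orientation error
is measured. Every default target is verified focusable (score exactly
100 at the ideal pose).

## Trial engine

Ten targets per trial in one of five fixed orders (assigned round-robin
across trials for reproducibility and uniform exposure), 30 s per
target. The first pedal press per target is binding; at timeout the
target scores 0 and the trial advances — this keeps the trial-mean
accuracy well defined. Logged event accuracy is always recomputed from
the logged encoder sample at the press with the exact clipper, so logs
are self-consistent by construction.

Sampling runs at 50 Hz simulated time (20 ms period, configurable). At
minimum-jerk speeds the path-length discretization error at 50 Hz is
well below 0.1% (tests: refining the sampling changes measured length
by <0.5%), and a full 80×30 cohort stays light enough to simulate in
about a minute.

## Synthetic surgeon

Each subject has five skill channels — per-target movement time (s),
tremor amplitude (mm at the tip), roll tremor (deg), terminal aiming
error (rad), and perceptual press noise (score points) — each following
an exponential approach `level(trial) = c + (a−c)·exp(−k·(trial−1))`.
The *analysis* layer fits `a + b·ln(trial)`; using different generative
and fitted families avoids validating the curve fit against itself.

Per target the agent waits a reaction time (0.25–0.6 s), executes a
minimum-jerk reach in shaft space toward the ideal pose plus a drawn
aiming offset, with two-sinusoid zero-mean jitter per channel, then
makes 0.5–1 s corrective sub-movements (offsets shrinking by ×0.30–0.65,
occasionally re-drawn to model overshoot) until its *perceived* score
reaches 100. Perception is a fast sampled-containment score (vectorized
ring projection + point-in-polygon on 48 deterministic overlay points,
checked at ~8 Hz once the reach completes) plus a per-target threshold
`100 − |N(0, σ_press(trial))|`: early subjects accept imperfect focus,
late subjects demand containment. Pressing before perfect focus and the
coarse perception both produce sub-100 logged accuracy without modelling
vision explicitly.

Cohort priors define three experience classes (novice/intermediate/
expert, proportions 0.45/0.35/0.20) with class-specific means for a and
c per channel (e.g. time 13→6.5 s novice, 8→5.2 s expert) and a shared
learning-rate prior k ~ N(0.13, 0.035) truncated positive. The values
are chosen once to produce initial-to-final gain ratios of roughly 1.7–2
for time, ~2–4 for path length, modest rotation gains and a positive
accuracy trend with shrinking dispersion — the qualitative structure of
a real mixed-experience training cohort. All randomness flows from one
`numpy` SeedSequence per run; reruns are bit-identical.

**What the generator does not emulate.** Real optics and vision (focus
difficulty here is purely geometric, so simulated accuracies compress
into the 95–100 band rather than the 75–90 band seen with real video),
biomechanical tremor spectra, fatigue, order effects beyond the five
rotating sequences, and inter-site variability. Passing the cohort-level
tests therefore shows that the *assessment pipeline* recovers planted
learning structure — not that the generator reproduces human
performance distributions.

## Metrics

Execution time is `t(last event) − t(first sample)`; accuracy averages
the ten event scores with timeouts as 0; orientation error is the mean
smallest wrapped difference |roll_at_press − nominal_roll| (so 359° vs
1° scores 2°); trajectory length sums Euclidean tip steps over resolved
samples; total rotation sums wrapped roll steps. Economy ratios divide
by the ideal baseline for the trial's order: straight-line tip distances
between consecutive ideal poses (entry leg from the home pose included)
and minimal wrapped roll changes. Because the fulcrum constrains tip
motion to arcs, even a noiseless agent's ratio sits slightly above 1
(~1–3%); the ratio is reported dimensionless (published tables appear to
use an additional ×1000 display scaling, which is not applied here).

## Statistics

Per-subject subset means (not pooled trials) feed the paired two-sided
t-test — pairing is by subject, one value per subject per subset. The
95% CI uses the t distribution on n−1 df. Post-hoc power evaluates the
noncentral-t distribution at the observed standardized paired effect
d = mean(diff)/sd(diff) with noncentrality d√n against the two-sided
α = 0.05 critical values (cross-checked against statsmodels' TTestPower
in the tests); required sample size is the smallest integer n reaching
power 0.8 by bisection on the same formula. Degenerate inputs are
defined explicitly: all-zero differences give t = 0, p = 1, a point CI
and infinite required n; zero effect gives power = α. SciPy's
noncentral-t CDF underflows to NaN at large noncentrality; those tails
are replaced by their limits. No multiple-testing correction is applied
across the seven metric rows by default (a Holm option exists), matching
the convention of reporting raw per-row p-values.

Correlations are Pearson r over all (subject, trial) rows for the five
indices, with two-sided p-values; constant columns raise a
zero-variance error rather than returning NaN.

## Problem sizes

The default study conditions are 80 subjects × 30 trials × 10 targets at
50 Hz. The acceptance script simulates that cohort in full (~1 minute);
unit and property tests use smaller cohorts (8–15 subjects) for the
trend, correlation and parameter-recovery checks, with the full-scale
qualitative battery living in the acceptance suite.

## Known limitations

- The ideal-pose search optimizes a soft objective; for near-entrance
  targets it settles on close-range oblique views (viewing distances
  down to ~10 mm), which makes some stations much easier to focus than
  others. Heterogeneous difficulty is realistic but compresses the
  accuracy learning signal (see above).
- Orientation error is measured against a single nominal roll per
  target; a range of valid orientations (stricter for lateral stations)
  would be more clinically faithful and is left as a config hook.
- Encoder noise, backlash and arm calibration are out of scope; encoder
  readings are exact.
- The analysis assumes complete sessions (every subject has all subset
  trials); missing trials raise rather than impute.
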