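# Methods

This note documents the models, numerical choices and limitations behind
`araquant`: what the pipeline assumes, which knobs matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Kinematic model

The trunk frame is right-handed with x anterior, y right-to-left, z up;
the trunk-mounted IMU is the reference for all quantities. Each arm is a
serial chain of seven revolute joints, ordered proximal to distal with the
clinical sign conventions listed in the README. The chain is realized as a
link table of per-joint fixed translations plus rotation axes (a
product-of-exponentials equivalent of a Denavit–Hartenberg table): the
shoulder is a 3-axis cluster at a fixed offset from the sternum (default
0.18 m lateral, 0.10 m up), the upper-arm/forearm/hand translations carry
the segment lengths, and the zero posture is the arm hanging along the
trunk −z axis. The left arm mirrors the rotation axes of the laterally
asymmetric joints (2, 3, 5, 6) so abduction, pronation etc. keep one sign
meaning on both sides. Any link table that realizes this joint order and
zero posture is equivalent for the analysis; the chosen one is locked by
the all-zero-posture unit test.

Segment (sensor) frames are taken to coincide with the anatomical segment
frames after mounting calibration — the redundancy of nine measured
angular-velocity components over seven joint rates makes the estimate
robust to small mounting errors. The 9×7 Jacobian stacks each joint axis,
rotated into the respective sensor frame, zeroed for joints distal to that
sensor. Joint rates are the minimum-norm least-squares solution via an
SVD pseudo-inverse with singular values below 1e−8·σ_max truncated;
rank-deficient postures are flagged per sample rather than failing.

Integration is trapezoidal with angles wrapped to (−π, π] each step, with
the Jacobian re-evaluated at a one-step forward prediction of the posture.
Timestamps must be uniform to 0.1%; all integrators take dt from the data.
The optional drift correction adds K·(ϑ_ref − ϑ̂)·dt per step from an
absolute joint-angle reference; K defaults to 1 s⁻¹, i.e. a first-order
complementary filter with a ≈1 s time constant, so a constant gyro-rate
bias b settles at an angle error of b/K instead of growing linearly.
Because the error term needs the running estimate, the implementation
takes the reference stream (not a precomputed error stream) and forms the
wrapped difference per step.

Absolute orientation from one accelerometer/magnetometer pair is the
Davenport q-method solution of the two-observation Wahba problem with
equal weights. A caution from our Monte-Carlo analysis: with gravity and
a 60°-inclination field the two reference directions are ~150° apart, and
per-vector angular noise is amplified roughly threefold in the weakest
attitude direction (5° noise → ≈21° at the 95th percentile). This is
intrinsic to two-vector attitude estimation (the estimator matches
`scipy.spatial.transform.Rotation.align_vectors` to 1e−8), which is why
the pipeline treats field-based orientation as a slow correction signal,
never as the primary angle estimate.

Trunk angles use a complementary attitude filter: gyro propagation pulled
toward the q-method estimate with per-step weight 0.02 (gyro weight 0.98
at 100 Hz). The accelerometer/magnetometer means over the leading ≥1 s
quasi-static window define the reference vectors, so the calibration pose
is exactly (0, 0, 0); a stream without a static start raises a
calibration error. Reported angles are intrinsic x-y-z rotations relative
to that pose.

## Segmentation

Arc-length parameterization uses a uniform s̄ grid with step Δs̄ = 1/500,
which resolves ~1–2 mm features on the 0.5–1 m ARAT hand paths. Speeds
below 2% of the peak are treated as zero before the arc-length
quadrature, so dwell episodes have exactly flat cumulative arc length and
collapse to single arc points; the threshold absorbs the sensor/estimation
noise floor. Positions are linearly interpolated on the grid and
origin-shifted to start at zero.

The direction-change profile ν(s̄) is the four-quadrant angle between
successive chord tangents (ν ∈ [0, π]; duplicate grid points inherit the
previous tangent and are logged). Candidate phase boundaries are local
minima of the speed profile that have a ν maximum with prominence ≥ π/6
within 2% of s̄. Candidates closer than 5% of s̄ merge; the retained
boundaries are the most prominent speed minima — at a true inter-phase
dwell the hand stops completely, so these dips dominate the shallower
minima that tremor or submovements carve into a stroke — with ties broken
toward the earlier arc point. Fewer candidates than needed raises a
segmentation error carrying the candidate list. A manual-override hook
(`apply_overrides` / `--override`) mirrors the visual-inspection step of
practical workflows; synthetic data never needs it.

Arc-to-time mapping returns, for each arc point, the first time sample
whose cumulative arc length reaches it, searched forward of the previous
match — causally consistent for paths that revisit positions, and
strictly increasing by construction. Onset/termination refinement fits
the cubic minimum-acceleration model by grid search over candidate onsets
in a ±0.5 s window with closed-form least squares per candidate over a
±ΔT window (ΔT = 0.2 s, the initial portion of a bell-shaped reach).
A candidate is valid only if its fitted cubic actually rises (positive
initial jerk and ≥0.5% of the local signal range over ΔT); otherwise a
candidate sitting in the static region fits with zero residual and zero
jerk and would always win. Terminations are refined on the time-reversed
signal. Manipulation phases (grasp, release) are the dwell intervals
between the refined termination of one movement phase and the refined
onset of the next — a convention, since no quantitative criterion for
manipulation boundaries exists; hold phases cover the lead-in/lead-out.

## Parameters

* **Movement time** is purely boundary arithmetic; the task time runs
  from the first movement onset to the last termination, including
  manipulation dwells.
* **Rotational jerk index**: the hand gyro is low-pass filtered
  (zero-phase 4th-order Butterworth, 10 Hz — above the voluntary-movement
  band) before two numerical derivatives (4th-order central stencils;
  two derivatives amplify noise quadratically, hence both precautions).
  η = ln(T⁵/θ_p² ∫‖ω̈‖²dt) is the dimensionless log-jerk: for a fixed
  angle trajectory executed over any duration the T⁵ factor cancels the
  duration dependence exactly. θ_p = 1 for ARAT tasks, which keep hand
  orientation; a config hook exists for tasks with non-unit angular
  displacement. Natural log; a numerically zero integral (constant ω)
  returns −inf with the phase flagged as undefined smoothness. The
  task-level index integrates over the whole first-onset-to-last-
  termination interval, dwells included, matching the task-level movement
  time convention.
* **Trajectory similarity** is computed on full 3-D positions by default
  (a scalar distance-from-start variant is available); both D and ν̂ are
  phase-normalized trapezoidal quadratures on the arc grid, so they
  depend only on the path, not its time course. The reference is the
  coordinate-wise median (lower-median convention for even counts) of
  healthy-group arc trajectories on a common grid, with per-point IQR as
  dispersion. Left-arm paths are mirrored across the sagittal plane
  before comparison so healthy left/right executions pool into one
  reference. Equal weights α = 0.5 m⁻¹, β = 0.5 reflect the similar
  magnitudes of D (meters) and ν̂ (dimensionless) in practice.
* **Trunk stability** ρ is the maximum over the phase of the Euclidean
  norm of the three trunk-angle deviations from phase start; for a
  piecewise-linear single-axis profile it equals the analytic maximum
  exactly.
* **EMG**: all eight forearm electrodes enter the RMS (flexors and
  extensors co-activate during grasping, and summing the bracelet makes
  the result orientation-independent). Normalization divides by the same
  RMS computed over a designated maximal-effort recording (the
  dynamometry stand-in); values above 1 are permitted but warn that the
  reference was submaximal.
* **Statistics**: the Mann–Whitney p-value is computed by exhaustive
  enumeration of the average-rank rank-sum distribution whenever
  C(n₁+n₂, n₁) ≤ 20 000 (valid under ties; covers the n ≤ 8 regime
  exactly) and by the tie-corrected normal approximation otherwise. No
  multiplicity adjustment is applied; raw p-values are reported at
  α = 0.05. Spearman correlation delegates to scipy (Pearson on average
  ranks, two-sided t-approximation).

## Synthetic generator

The generator is the package's validation substrate: joint-space
trajectories built from fifth-order minimum-jerk strokes between task
waypoints (damped least-squares IK is solved only at the waypoints — the
path between them is interpolated directly in joint space), framed by
1.5 s holds and separated by 0.5 s manipulation dwells. Healthy stroke
durations are drawn uniformly from 1.0–1.5 s, keeping whole tasks within
the 5–60 s window of completed executions. Sensor streams are derived
from the same forward kinematics the estimator inverts: gyros from exact
finite-rotation rates of each sensor frame, accelerometers from rotated
gravity plus the sensor point's linear acceleration, magnetometers from a
fixed 60°-inclination unit reference field; IMU rate 100 Hz, EMG 200 Hz.
EMG is amplitude-modulated Gaussian noise with per-channel gains drawn
once per recording; the grasp-to-release envelope scales with a grasp
force proxy that grows with object size, and a 3 s maximal-effort segment
(envelope 1.0) provides the normalization reference.

Impairment is modelled as four mechanisms, each chosen because it moves a
specific parameter in the clinically expected direction: duration scaling
(movement time), overlapping corrective submovements and movement-gated
4–8 Hz band-limited tremor (rotational jerk, trajectory similarity), a
sagittal trunk lean ramping over the reach–transfer interval (trunk
stability), and a co-activation floor on the EMG envelope (muscle
activity). The presets order H < UAF < AF3 < AF2 in every field, with
AF2 (moderate task execution) at duration scale 3, three submovements per
stroke, 0.08 rad/s tremor, 0.15 rad peak lean, and 0.35 co-activation.
A 0.002 rad postural-sway floor applies to every group's trunk.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: soft-tissue artifact and sensor-mounting
misalignment, magnetometer disturbance indoors, finger kinematics and
real grasp aperture, muscle-model EMG (spectral content, fatigue),
packet loss beyond the injected-gap tests, and the diversity of real
patient strategies (the impairment presets are stylized, not fitted to
any cohort). Tremor is gated by movement speed (kinetic tremor), so
resting tremor is absent by construction.

## Numerical and degenerate-input conventions

Pseudo-inverse truncation at 1e−8·σ_max; angle wrapping to (−π, π];
onset grid-search ties resolved toward earlier times among valid
candidates; segmentation candidate ties toward earlier s̄; zero-length
tangents interpolated from the previous chord; paths shorter than 1 µm
raise a degenerate-trajectory error; phases shorter than 10 samples
refuse the jerk metric. Recording gaps ≤ 50 ms are linearly interpolated
and counted; longer gaps or >5% missing samples raise a quality error —
short dropouts are salvaged rather than discarding the session. On-disk
units are SI everywhere; degrees appear only in human-readable text.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use a 30 s round-trip
trajectory at 100 Hz, 100 seeded healthy tasks for segmentation recovery,
30 recordings per group (full generate → corrupt → estimate → segment →
measure loop, 0.002 rad/s gyro noise) for the H/AF2 contrast, and 30
seeds per block size for EMG monotonicity — sizes at which every check is
stable across seeds while the whole suite stays fast enough to run
routinely.

## Known limitations

The joint-speed inversion assumes the sensor frames equal the segment
frames; a mounting-calibration estimation step is out of scope. The
drift-correction loop is exercised against reference joint angles; a
field-to-joint-angle observer (inverse orientation kinematics) is not
implemented, so on real data the correction input must come from an
upstream orientation filter. The trunk filter is complementary, not a
full Kalman filter — the contract (deviation angles from a calibrated
pose) is what is tested. Incomplete task executions (clinical scores 0–1)
are out of scope: their trajectories do not fit the phase model at all.
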