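"""Arm and trunk kinematics from multi-IMU streams.

The upper limb is modelled as a 7-revolute-joint serial chain attached to the
trunk frame (x anterior, y right-to-left, z up; right-handed). Joint order,
proximal to distal, with positive senses:

    1. shoulder flexion(-)/extension(+)
    2. shoulder abduction(-)/adduction(+)
    3. shoulder internal(-)/external(+) rotation
    4. elbow flexion(+)/extension(-)
    5. wrist pronation(-)/supination(+)
    6. wrist ulnar(-)/radial(+) deviation
    7. wrist flexion(+)/extension(-)

The all-zero posture is the arm hanging along the trunk axis (all segments
pointing along -z). Three IMUs per arm (upper arm, wrist/distal forearm,
hand) measure segment angular velocities; stacking them gives a 9-vector
related to the 7 joint rates through a 9x7 Jacobian, inverted in the
least-squares sense with the Moore-Penrose pseudo-inverse. Joint angles
follow by trapezoidal integration, optionally closed-loop corrected against
an absolute (gravity/magnetic-field derived) reference to cancel gyro drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    CalibrationError,
    ContractViolation,
    DegenerateGeometryError,
)

ARM_SENSOR_ORDER = ("upper", "wrist", "hand")
#: number of proximal joints rigidly moving each arm sensor
_SENSOR_JOINT_COUNT = {"upper": 3, "wrist": 5, "hand": 7}

JOINT_NAMES = (
    "shoulder_flex_ext",
    "shoulder_abd_add",
    "shoulder_rotation",
    "elbow_flex_ext",
    "wrist_pron_sup",
    "wrist_uln_rad",
    "wrist_flex_ext",
)


def wrap_angle(x):
    """Wrap angle(s) to (-pi, pi]."""
    w = np.asarray(x, dtype=float)
    w = (w + np.pi) % (2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


@dataclass(frozen=True)
class ImuStream:
    """A time series of 9-DOF IMU samples from one sensor.

    Attributes
    ----------
    t : (N,) seconds, strictly increasing
    gyro : (N, 3) rad/s, sensor frame
    accel : (N, 3) m/s^2 specific force, sensor frame
    mag : (N, 3) normalized magnetic field direction, sensor frame
    sensor_id : one of trunk, L_upper, L_wrist, L_hand, R_upper, R_wrist, R_hand
    """

    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    mag: np.ndarray
    sensor_id: str = "trunk"

    def __post_init__(self):
        t = np.asarray(self.t, float)
        if t.ndim != 1 or len(t) < 2:
            raise ContractViolation("IMU stream needs >= 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ContractViolation(
                f"timestamps not strictly increasing in stream {self.sensor_id!r}"
            )
        for name in ("gyro", "accel", "mag"):
            a = np.asarray(getattr(self, name), float)
            if a.shape != (len(t), 3):
                raise ContractViolation(f"{name} must be (N, 3), got {a.shape}")
            if not np.all(np.isfinite(a)):
                raise ContractViolation(f"non-finite values in {name}")
            object.__setattr__(self, name, a)
        object.__setattr__(self, "t", t)

    def __len__(self):
        return len(self.t)


@dataclass(frozen=True)
class ArmModel:
    """Geometry of one arm as a 7-joint serial chain.

    ``links`` realizes the joint order above as a product of per-joint
    transforms ``Trans(d_j) @ Rot(axis_j, theta_j)`` followed by a final hand
    translation; it plays the role of a Denavit-Hartenberg table for this
    chain. The left arm mirrors the rotation axes of the laterally
    asymmetric joints (2, 3, 5, 6) so that clinical senses (abduction,
    pronation, ...) keep the same sign meaning on both sides.
    """

    handedness: str = "right"
    upper_arm_m: float = 0.30
    forearm_m: float = 0.26
    hand_m: float = 0.08
    shoulder_offset: np.ndarray | None = None

    def __post_init__(self):
        if self.handedness not in ("left", "right"):
            raise ContractViolation("handedness must be 'left' or 'right'")
        for L in (self.upper_arm_m, self.forearm_m, self.hand_m):
            if not (np.isfinite(L) and L > 0):
                raise ContractViolation("segment lengths must be positive")
        if self.shoulder_offset is None:
            side = -1.0 if self.handedness == "right" else 1.0
            object.__setattr__(
                self, "shoulder_offset", np.array([0.0, side * 0.18, 0.10])
            )
        else:
            object.__setattr__(
                self, "shoulder_offset", np.asarray(self.shoulder_offset, float)
            )

    @property
    def links(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-joint (fixed translation, rotation axis) pairs, proximal first."""
        m = -1.0 if self.handedness == "left" else 1.0
        z3 = np.zeros(3)
        ex, ey, ez = np.eye(3)
        return [
            (self.shoulder_offset, ey),            # 1 shoulder flex(-)/ext(+)
            (z3, m * ex),                          # 2 shoulder abd(-)/add(+)
            (z3, m * ez),                          # 3 shoulder int(-)/ext(+) rot
            (np.array([0, 0, -self.upper_arm_m]), -ey),  # 4 elbow flex(+)/ext(-)
            (z3, m * ez),                          # 5 wrist pron(-)/sup(+)
            (np.array([0, 0, -self.forearm_m]), m * ex),  # 6 wrist uln(-)/rad(+)
            (z3, -ey),                             # 7 wrist flex(+)/ext(-)
        ]

    @property
    def tool_offset(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.hand_m])

    @property
    def reach_m(self) -> float:
        return self.upper_arm_m + self.forearm_m + self.hand_m

    @classmethod
    def from_dict(cls, d: dict) -> "ArmModel":
        return cls(
            handedness=d.get("handedness", "right"),
            upper_arm_m=float(d["upper_arm_m"]),
            forearm_m=float(d["forearm_m"]),
            hand_m=float(d["hand_m"]),
            shoulder_offset=d.get("shoulder_offset"),
        )


@dataclass(frozen=True)
class HandPose:
    """Hand frame expressed in the trunk frame at one instant."""

    t: float
    transform: np.ndarray  # 4x4 homogeneous

    @property
    def position(self) -> np.ndarray:
        return self.transform[:3, 3]

    @property
    def rotation(self) -> np.ndarray:
        return self.transform[:3, :3]


@dataclass
class JointStateSeries:
    """Joint angles and rates of one arm over time."""

    t: np.ndarray
    angles: np.ndarray   # (N, 7) rad, wrapped to (-pi, pi]
    speeds: np.ndarray   # (N, 7) rad/s
    degenerate: np.ndarray | None = None  # (N,) bool: rank-deficient Jacobian

    def __len__(self):
        return len(self.t)


@dataclass
class TrunkOrientationSeries:
    """Trunk deviation angles (phi, theta, psi) from the calibration pose."""

    t: np.ndarray
    angles: np.ndarray  # (N, 3) rad, x/y/z deviation

    def __len__(self):
        return len(self.t)


@dataclass(frozen=True)
class CorrectionConfig:
    """Closed-loop drift-correction settings.

    ``gain`` is the scalar (or 7-vector / 7x7) error-correction gain K applied
    to the per-step discrepancy between an absolute joint-angle reference and
    the running integral. gain = 0 reduces to pure open-loop integration.
    """

    gain: float | np.ndarray = 1.0

    def __post_init__(self):
        g = np.asarray(self.gain, float)
        if np.any(g < 0):
            raise ContractViolation("correction gain must be >= 0")


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis (hot path: avoids object churn)."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _check_angles(angles) -> np.ndarray:
    q = np.asarray(angles, float)
    if q.shape != (7,):
        raise ContractViolation(f"expected 7 joint angles, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ContractViolation("joint angles must be finite")
    return q


def forward_kinematics(model: ArmModel, angles, t: float = 0.0) -> HandPose:
    """Pose of the hand in the trunk frame: product of the 7 link transforms."""
    q = _check_angles(angles)
    T = np.eye(4)
    for (d, axis), qi in zip(model.links, q):
        A = np.eye(4)
        A[:3, 3] = d
        A[:3, :3] = _rot(axis, qi)
        T = T @ A
    tool = np.eye(4)
    tool[:3, 3] = model.tool_offset
    return HandPose(t=t, transform=T @ tool)


def segment_rotations(model: ArmModel, angles) -> list[np.ndarray]:
    """Cumulative rotation matrices after joints 1..7 (trunk -> segment)."""
    q = _check_angles(angles)
    R = np.eye(3)
    out = []
    for (_, axis), qi in zip(model.links, q):
        R = R @ _rot(axis, qi)
        out.append(R)
    return out


def hand_positions(model: ArmModel, angles: np.ndarray) -> np.ndarray:
    """Vectorized hand positions for a (N, 7) angle series."""
    angles = np.atleast_2d(np.asarray(angles, float))
    return np.array(
        [forward_kinematics(model, q).position for q in angles]
    )


def arm_jacobian(model: ArmModel, angles) -> np.ndarray:
    """9x7 map from joint rates to stacked sensor angular velocities.

    Rows 0:3, 3:6, 6:9 are the angular velocity of the upper-arm, wrist and
    hand IMU, each expressed in its own sensor frame (assumed coincident with
    the segment frame after mounting calibration). Column j holds the j-th
    joint axis, expressed in each sensor frame, zeroed for joints distal to
    that sensor.
    """
    q = _check_angles(angles)
    rots = segment_rotations(model, q)
    # joint axis j in trunk frame = rotation accumulated over joints < j
    axes_world = []
    R_prev = np.eye(3)
    for (_, axis), R in zip(model.links, rots):
        axes_world.append(R_prev @ np.asarray(axis, float))
        R_prev = R
    J = np.zeros((9, 7))
    for row, name in enumerate(ARM_SENSOR_ORDER):
        njoints = _SENSOR_JOINT_COUNT[name]
        Rs = rots[njoints - 1]
        for j in range(njoints):
            J[3 * row : 3 * row + 3, j] = Rs.T @ axes_world[j]
    return J


def estimate_joint_speeds(
    jacobian: np.ndarray, omega_stack: np.ndarray, rcond: float = 1e-8
) -> tuple[np.ndarray, bool]:
    """Least-squares joint rates from stacked gyro measurements.

    Returns ``(theta_dot, degenerate)`` where ``theta_dot = J^+ Omega`` with a
    singular-value-truncated pseudo-inverse and ``degenerate`` flags a
    rank-deficient Jacobian (some joint-rate combination unobservable at this
    posture).
    """
    J = np.asarray(jacobian, float)
    w = np.asarray(omega_stack, float)
    if J.shape != (9, 7) or w.shape != (9,):
        raise ContractViolation("jacobian must be 9x7 and omega_stack length 9")
    U, s, Vt = np.linalg.svd(J, full_matrices=False)
    keep = s > rcond * s[0] if s[0] > 0 else np.zeros_like(s, bool)
    degenerate = int(keep.sum()) < 7
    inv_s = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    theta_dot = Vt.T @ (inv_s * (U.T @ w))
    return theta_dot, degenerate


def integrate_joint_angles(
    t: np.ndarray,
    speeds: np.ndarray,
    initial: np.ndarray,
    correction: CorrectionConfig | None = None,
    reference_angles: np.ndarray | None = None,
    dt_tol: float = 1e-3,
) -> JointStateSeries:
    """Integrate joint rates into joint angles (trapezoidal), optionally
    closed-loop corrected.

    With a correction gain K and an absolute joint-angle reference stream
    (e.g. derived from gravity/magnetic-field orientation estimates), each
    step adds ``K * (reference - estimate) * dt``, which gives first-order
    error dynamics: a constant gyro bias b settles to a steady-state angle
    error of b / K instead of growing linearly.

    Timestamps must be uniform to within ``dt_tol`` (relative).
    """
    t = np.asarray(t, float)
    V = np.atleast_2d(np.asarray(speeds, float))
    if V.shape != (len(t), 7):
        raise ContractViolation("speeds must be (N, 7)")
    dts = np.diff(t)
    if len(dts) == 0:
        raise ContractViolation("need >= 2 samples to integrate")
    dt = float(np.mean(dts))
    if np.max(np.abs(dts - dt)) > dt_tol * dt:
        raise ContractViolation("non-uniform timestamps beyond tolerance")
    gain = 0.0 if correction is None else np.asarray(correction.gain, float)
    use_corr = reference_angles is not None and np.any(gain > 0)
    if use_corr:
        ref = np.asarray(reference_angles, float)
        if ref.shape != V.shape:
            raise ContractViolation("reference_angles must match speeds shape")

    q = np.empty_like(V)
    q[0] = wrap_angle(np.asarray(initial, float))
    for k in range(len(t) - 1):
        step = 0.5 * (V[k] + V[k + 1]) * dts[k]
        if use_corr:
            delta = wrap_angle(ref[k] - q[k])
            if np.ndim(gain) == 2:
                step = step + dts[k] * (gain @ delta)
            else:
                step = step + dts[k] * gain * delta
        q[k + 1] = wrap_angle(q[k] + step)
    return JointStateSeries(t=t, angles=q, speeds=V)


def estimate_orientation_from_field(
    accel, mag, ref_gravity, ref_field, parallel_tol: float = 1e-6
) -> np.ndarray:
    """Absolute orientation from one accelerometer + magnetometer sample.

    Solves the two-observation Wahba problem with Davenport's q-method:
    returns the unit quaternion (scalar-first, q0 >= 0) whose rotation matrix
    A best maps the reference vectors onto the measured ones
    (``A @ ref ~= measured`` in the least-squares sense, equal weights).
    """
    obs = [np.asarray(accel, float), np.asarray(mag, float)]
    refs = [np.asarray(ref_gravity, float), np.asarray(ref_field, float)]
    for v in obs + refs:
        n = np.linalg.norm(v)
        if not (np.isfinite(n) and n > 0):
            raise ContractViolation("observation/reference vectors must be nonzero")
    b = [v / np.linalg.norm(v) for v in obs]
    r = [v / np.linalg.norm(v) for v in refs]
    if (
        np.linalg.norm(np.cross(b[0], b[1])) < parallel_tol
        or np.linalg.norm(np.cross(r[0], r[1])) < parallel_tol
    ):
        raise DegenerateGeometryError("observation vectors are (near-)parallel")

    B = 0.5 * (np.outer(b[0], r[0]) + np.outer(b[1], r[1]))
    sigma = np.trace(B)
    S = B + B.T
    z = np.array([B[1, 2] - B[2, 1], B[2, 0] - B[0, 2], B[0, 1] - B[1, 0]])
    K = np.empty((4, 4))
    K[0, 0] = sigma
    K[0, 1:] = z
    K[1:, 0] = z
    K[1:, 1:] = S - sigma * np.eye(3)
    vals, vecs = np.linalg.eigh(K)
    q = vecs[:, -1]  # scalar-first [q0, qx, qy, qz]
    # Davenport's eigenvector parameterizes the attitude in the transposed
    # (frame-rotation) convention; conjugate to get the vector-rotation
    # quaternion with R(q) @ ref = measured.
    q = np.array([q[0], -q[1], -q[2], -q[3]])
    if q[0] < 0:
        q = -q
    return q / np.linalg.norm(q)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a scalar-first unit quaternion."""
    q = np.asarray(q, float)
    return Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


def _static_window(stream: ImuStream, min_duration: float, gyro_thresh: float):
    """Index range of the leading quasi-static calibration window."""
    t0 = stream.t[0]
    mask = np.linalg.norm(stream.gyro, axis=1) < gyro_thresh
    n_needed = int(np.searchsorted(stream.t, t0 + min_duration, side="right"))
    if n_needed < 2 or not np.all(mask[:n_needed]):
        raise CalibrationError(
            f"no quasi-static window of {min_duration} s at stream start "
            f"(gyro threshold {gyro_thresh} rad/s)"
        )
    return n_needed


def estimate_trunk_angles(
    stream: ImuStream,
    calibration_s: float = 1.0,
    gyro_weight: float = 0.98,
    static_gyro_thresh: float = 0.2,
) -> TrunkOrientationSeries:
    """Trunk rotation angles (phi, theta, psi) relative to the calibration pose.

    A complementary attitude filter: the gyro propagates orientation between
    samples and each step is pulled toward the absolute gravity/field
    (q-method) estimate with weight ``1 - gyro_weight``. The accelerometer and
    magnetometer means over the leading quasi-static window define the
    reference vectors, so the calibration pose maps to (0, 0, 0) by
    construction. Angles are intrinsic x-y-z rotations of the trunk sensor
    relative to that pose.
    """
    if not 0.0 <= gyro_weight <= 1.0:
        raise ContractViolation("gyro_weight must be in [0, 1]")
    ncal = _static_window(stream, calibration_s, static_gyro_thresh)
    ref_g = stream.accel[:ncal].mean(axis=0)
    ref_m = stream.mag[:ncal].mean(axis=0)

    n = len(stream)
    angles = np.zeros((n, 3))
    # R maps body -> reference (v_ref = R v_body); identity at calibration
    R = Rotation.identity()
    k_meas = 1.0 - gyro_weight
    for k in range(n):
        if k > 0:
            dt = stream.t[k] - stream.t[k - 1]
            R = R * Rotation.from_rotvec(stream.gyro[k - 1] * dt)
            if k_meas > 0:
                q = estimate_orientation_from_field(
                    stream.accel[k], stream.mag[k], ref_g, ref_m
                )
                # q maps ref -> body, so body -> ref is its inverse
                R_meas = Rotation.from_matrix(quat_to_matrix(q).T)
                err = (R.inv() * R_meas).as_rotvec()
                R = R * Rotation.from_rotvec(k_meas * err)
        angles[k] = R.as_euler("xyz")
    return TrunkOrientationSeries(t=stream.t.copy(), angles=angles)


def estimate_arm_joint_angles(
    streams: dict,
    model: ArmModel,
    initial_angles,
    correction: CorrectionConfig | None = None,
    reference_angles: np.ndarray | None = None,
    rcond: float = 1e-8,
) -> JointStateSeries:
    """Full joint-angle estimation for one arm from its three IMU streams.

    ``streams`` maps sensor role ('upper', 'wrist', 'hand') to :class:`ImuStream`
    on a common time base. At each sample the Jacobian is evaluated at the
    current angle estimate, joint rates follow from the pseudo-inverse, and
    the angles advance by the trapezoid rule with optional closed-loop
    correction toward ``reference_angles``.
    """
    missing = [s for s in ARM_SENSOR_ORDER if s not in streams]
    if missing:
        raise ContractViolation(f"missing arm sensor streams: {missing}")
    t = streams["upper"].t
    for name in ARM_SENSOR_ORDER:
        if len(streams[name]) != len(t) or not np.allclose(streams[name].t, t):
            raise ContractViolation("arm sensor streams must share one time base")
    omega = np.hstack([streams[name].gyro for name in ARM_SENSOR_ORDER])  # (N, 9)

    gain = 0.0 if correction is None else np.asarray(correction.gain, float)
    use_corr = reference_angles is not None and np.any(gain > 0)

    n = len(t)
    q = np.empty((n, 7))
    v = np.empty((n, 7))
    degenerate = np.zeros(n, bool)
    q[0] = wrap_angle(np.asarray(initial_angles, float))
    v[0], degenerate[0] = estimate_joint_speeds(
        arm_jacobian(model, q[0]), omega[0], rcond=rcond
    )
    for k in range(n - 1):
        dt = t[k + 1] - t[k]
        # predictor step with current rate, then trapezoid with the rate at
        # the predicted posture
        q_pred = wrap_angle(q[k] + v[k] * dt)
        v[k + 1], degenerate[k + 1] = estimate_joint_speeds(
            arm_jacobian(model, q_pred), omega[k + 1], rcond=rcond
        )
        step = 0.5 * (v[k] + v[k + 1]) * dt
        if use_corr:
            delta = wrap_angle(reference_angles[k] - q[k])
            if np.ndim(gain) == 2:
                step = step + dt * (gain @ delta)
            else:
                step = step + dt * gain * delta
        q[k + 1] = wrap_angle(q[k] + step)
    return JointStateSeries(t=t, angles=q, speeds=v, degenerate=degenerate)
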