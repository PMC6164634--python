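"""Ground-truth-labelled synthetic ARAT recordings.

Generates complete multi-sensor recordings of reach - grasp - transfer -
release - return task executions: joint-space trajectories built from
minimum-jerk strokes between task waypoints, IMU streams synthesized through
the same forward kinematics and Jacobian the estimation pipeline inverts,
trunk lean profiles, and amplitude-modulated surface EMG. Group-dependent
impairment (slowing, corrective submovements, 4-8 Hz kinetic tremor,
compensatory trunk lean, EMG co-activation) emulates the qualitative
contrast between healthy subjects and stroke patients with moderate task
execution. Every stream is reproducible from (task, profile, seed), and the
generator records the exact phase boundaries, so each pipeline stage can be
validated against ground truth without real patient data.

The impairment model is this package's own construction: it is chosen so
that each mechanism provably moves one or more of the reported parameters
(duration scaling -> movement time, tremor/submovements -> rotational jerk
and trajectory similarity, lean -> trunk stability, co-activation -> EMG)
in the clinically expected direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from .errors import ContractViolation, DegenerateGeometryError
from .kinematics import ArmModel, ImuStream, forward_kinematics, segment_rotations
from .metrics import EmgRecording

GRAVITY = np.array([0.0, 0.0, -9.81])  # m/s^2, trunk frame (z up)
#: reference magnetic field direction: 60 degree inclination, unit norm
MAG_REFERENCE = np.array([0.5, 0.0, -np.sqrt(3) / 2])
#: ARAT block side lengths, meters
BLOCK_SIZES = (0.025, 0.05, 0.075, 0.1)

IMU_RATE_HZ = 100.0
EMG_RATE_HZ = 200.0

#: fraction of each sensor's segment length from the proximal joint
_SENSOR_MOUNT = {"upper": 0.5, "wrist": 0.8, "hand": 0.5}


@dataclass(frozen=True)
class TaskSpec:
    """Geometry and phase structure of one ARAT task execution.

    ``waypoints`` are hand targets in the trunk frame (start, object,
    target[, ...]); the hand visits them in order with a manipulation dwell
    after each intermediate visit, then returns to the start.
    """

    subtest: str = "grasp"
    waypoints: Sequence[np.ndarray] = ()
    dwell_durations: Sequence[float] = (0.5, 0.5)
    object_size: float = 0.05
    expected_movement_phases: int = 3

    def __post_init__(self):
        if self.subtest not in ("grasp", "grip", "pinch", "gross"):
            raise ContractViolation("unknown subtest")
        if len(self.waypoints) < 2:
            raise ContractViolation("need >= 2 waypoints")
        if any(d < 0 for d in self.dwell_durations):
            raise ContractViolation("dwell durations must be >= 0")

    @classmethod
    def grasp(cls, object_size: float = 0.05) -> "TaskSpec":
        """Block grasp-and-transfer to shelf: 3 movement phases."""
        return cls(
            subtest="grasp",
            waypoints=(
                np.array([0.28, -0.20, -0.30]),   # resting hand on table
                np.array([0.38, -0.05, -0.28]),   # block on table
                np.array([0.42, -0.12, 0.12]),    # shelf target
            ),
            dwell_durations=(0.5, 0.5),
            object_size=object_size,
            expected_movement_phases=3,
        )

    @classmethod
    def gross(cls) -> "TaskSpec":
        """Gross arm movement (hand to head target and back): 2 phases."""
        return cls(
            subtest="gross",
            waypoints=(
                np.array([0.28, -0.20, -0.30]),
                np.array([0.15, -0.10, 0.35]),    # near-head target
            ),
            dwell_durations=(0.5,),
            object_size=0.0,
            expected_movement_phases=2,
        )


@dataclass(frozen=True)
class ImpairmentProfile:
    """Group-dependent movement-quality degradation applied by the generator.

    ``duration_scale`` multiplies stroke durations; ``n_submovements``
    corrective sub-strokes overlap each stroke; ``tremor_amplitude`` is the
    RMS of 4-8 Hz band-limited joint-rate tremor during movement (rad/s);
    ``trunk_lean_peak`` is the peak sagittal compensation lean (rad);
    ``coactivation_level`` scales baseline EMG during movement (fraction of
    maximal effort).
    """

    group: str = "H"
    duration_scale: float = 1.0
    n_submovements: int = 0
    submovement_amplitude: float = 0.0
    tremor_amplitude: float = 0.0
    trunk_lean_peak: float = 0.0
    coactivation_level: float = 0.05

    def __post_init__(self):
        if self.duration_scale < 1.0:
            raise ContractViolation("duration_scale must be >= 1")
        if self.n_submovements < 0 or not 0 <= self.coactivation_level <= 1:
            raise ContractViolation("invalid impairment parameters")

    @classmethod
    def preset(cls, group: str) -> "ImpairmentProfile":
        """Nominal profiles: H healthy, UAF unaffected arm, AF3/AF2 affected
        arm with normal/moderate task execution. AF2 dominates AF3 dominates
        H in every impairment field."""
        table = {
            "H": cls("H", 1.0, 0, 0.0, 0.0, 0.0, 0.05),
            "UAF": cls("UAF", 1.05, 0, 0.0, 0.005, 0.01, 0.08),
            "AF3": cls("AF3", 1.5, 1, 0.04, 0.05, 0.05, 0.15),
            "AF2": cls("AF2", 3.0, 3, 0.08, 0.15, 0.15, 0.35),
        }
        if group not in table:
            raise ContractViolation(f"unknown group {group!r}")
        return table[group]


@dataclass
class TaskTruth:
    """Ground truth carried alongside the synthesized streams."""

    t: np.ndarray
    joint_angles: np.ndarray          # (N, 7)
    joint_speeds: np.ndarray          # (N, 7)
    hand_path: np.ndarray             # (N, 3), trunk frame
    trunk_angles: np.ndarray          # (N, 3)
    phases: list[dict]                # kind, t_onset, t_term, sbar_onset, sbar_term
    grasp_force_level: float
    initial_angles: np.ndarray

    @property
    def movement_phases(self) -> list[dict]:
        return [p for p in self.phases if p["kind"] not in ("hold", "grasp", "release")]


@dataclass
class SyntheticRecording:
    """One simulated session: truth + per-sensor IMU streams + EMG."""

    truth: TaskTruth
    streams: dict
    emg: EmgRecording
    emg_max: EmgRecording
    model: ArmModel
    task: TaskSpec
    profile: ImpairmentProfile
    seed: int | None = None


def minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Fifth-order minimum-jerk position profile on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_stroke(start, end, T: float, rate: float = IMU_RATE_HZ):
    """Straight minimum-jerk point-to-point stroke.

    Returns ``(t, position)`` sampled at ``rate``; boundary velocity and
    acceleration are zero and the peak speed is 1.875 * ||end-start|| / T.
    """
    if T <= 0:
        raise ContractViolation("stroke duration must be positive")
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    n = max(int(round(T * rate)) + 1, 2)
    t = np.linspace(0.0, T, n)
    sigma = minimum_jerk_profile(t / T)
    return t, start + np.outer(sigma, end - start)


def position_jacobian(model: ArmModel, angles: np.ndarray) -> np.ndarray:
    """3x7 Jacobian of hand position w.r.t. joint angles (trunk frame)."""
    rots = segment_rotations(model, angles)
    # joint origins along the chain
    origins = []
    p = np.zeros(3)
    R_prev = np.eye(3)
    axes_world = []
    for (d, axis), R in zip(model.links, rots):
        p = p + R_prev @ np.asarray(d, float)
        origins.append(p.copy())
        axes_world.append(R_prev @ np.asarray(axis, float))
        R_prev = R
    hand = p + rots[-1] @ model.tool_offset
    J = np.zeros((3, 7))
    for j in range(7):
        J[:, j] = np.cross(axes_world[j], hand - origins[j])
    return J


def solve_ik(
    model: ArmModel,
    target: np.ndarray,
    q0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 300,
    damping: float = 0.02,
) -> np.ndarray:
    """Damped least-squares inverse kinematics for the hand position.

    Used only to pin joint configurations at task waypoints; trajectories
    between waypoints are interpolated directly in joint space.
    """
    target = np.asarray(target, float)
    reach = np.linalg.norm(target - model.shoulder_offset)
    if reach > model.reach_m - 1e-9:
        raise DegenerateGeometryError(
            f"waypoint {target} at {reach:.3f} m exceeds arm reach {model.reach_m:.3f} m"
        )
    q = np.asarray(q0, float).copy()
    for _ in range(max_iter):
        err = target - forward_kinematics(model, q).position
        if np.linalg.norm(err) < tol:
            return q
        J = position_jacobian(model, q)
        JJt = J @ J.T + damping**2 * np.eye(3)
        q = q + J.T @ np.linalg.solve(JJt, err)
    if np.linalg.norm(target - forward_kinematics(model, q).position) > 1e-4:
        raise DegenerateGeometryError(f"IK failed to converge on waypoint {target}")
    return q


def _bump(tau: np.ndarray) -> np.ndarray:
    """Smooth compact bump on [0, 1] with zero value/slope at the ends."""
    tau = np.clip(tau, 0.0, 1.0)
    return 16.0 * tau**2 * (1.0 - tau) ** 2


def _bandlimited_noise(rng, n: int, rate: float, lo: float, hi: float, cols: int):
    """Unit-RMS band-limited Gaussian noise columns."""
    x = rng.standard_normal((n, cols))
    if n > 30:
        sos = butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
        x = sosfiltfilt(sos, x, axis=0)
    rms = np.sqrt(np.mean(x**2, axis=0))
    rms[rms == 0] = 1.0
    return x / rms


_NEUTRAL_Q = np.array([-0.35, -0.15, 0.0, 1.1, 0.2, 0.0, 0.0])


def generate_task(
    task: TaskSpec,
    profile: ImpairmentProfile,
    model: ArmModel | None = None,
    seed: int | None = 0,
    rate: float = IMU_RATE_HZ,
    hold_s: float = 1.5,
    stroke_range: tuple[float, float] = (1.0, 1.5),
) -> SyntheticRecording:
    """Synthesize one complete labelled task execution.

    The hand visits the waypoints through joint-space minimum-jerk strokes
    (IK solved only at the waypoints), separated by manipulation dwells and
    framed by static holds. Impairment adds overlapping corrective
    submovements and movement-gated 4-8 Hz tremor to the joint trajectory,
    a sagittal trunk lean ramping over the reach-transfer interval, and
    duration scaling. Sensor streams are derived from the same kinematic
    model the estimation pipeline uses: gyros from exact finite-rotation
    rates of each sensor frame, accelerometers from rotated gravity plus
    the sensor's linear acceleration, magnetometers from the rotated
    reference field.
    """
    if model is None:
        model = ArmModel()
    rng = np.random.default_rng(seed)
    n_strokes = len(task.waypoints)  # includes the return to start
    if len(task.dwell_durations) < n_strokes - 1:
        raise ContractViolation("need a dwell duration per intermediate waypoint")

    # joint configurations at waypoints (return closes back to the start)
    q_wps = []
    q_prev = _NEUTRAL_Q * (1.0 if model.handedness == "right" else 1.0)
    for wp in task.waypoints:
        q_prev = solve_ik(model, wp, q_prev)
        q_wps.append(q_prev)
    q_wps.append(q_wps[0])  # return stroke target

    durations = rng.uniform(*stroke_range, size=n_strokes) * profile.duration_scale
    dwells = list(task.dwell_durations[: n_strokes - 1])

    dt = 1.0 / rate
    segs = []  # (kind, duration, q_from, q_to)
    segs.append(("hold", hold_s, q_wps[0], q_wps[0]))
    kinds = {3: ["reach_to_grasp", "transfer", "return"], 2: ["transfer", "return"]}[
        task.expected_movement_phases
    ]
    manips = {3: ["grasp", "release"], 2: ["hold"]}[task.expected_movement_phases]
    for i in range(n_strokes):
        segs.append((kinds[i], durations[i], q_wps[i], q_wps[i + 1]))
        if i < n_strokes - 1:
            segs.append((manips[i], dwells[i], q_wps[i + 1], q_wps[i + 1]))
    segs.append(("hold", hold_s, q_wps[0], q_wps[0]))

    # assemble joint trajectory and phase boundary table
    chunks = []
    phase_table = []
    t_cursor = 0.0
    for kind, T, qa, qb in segs:
        n = max(int(round(T * rate)), 1)
        tau = (np.arange(n) * dt) / T
        sigma = minimum_jerk_profile(tau)
        q_seg = qa + sigma[:, None] * (np.asarray(qb) - np.asarray(qa))
        if kind not in ("hold", "grasp", "release") and profile.n_submovements > 0:
            for _ in range(profile.n_submovements):
                center = rng.uniform(0.25, 0.75)
                width = rng.uniform(0.15, 0.3)
                direction = rng.standard_normal(7)
                direction *= profile.submovement_amplitude / np.linalg.norm(direction)
                q_seg = q_seg + np.outer(
                    _bump((tau - center + width / 2) / width), direction
                )
        chunks.append(q_seg)
        phase_table.append(
            {"kind": kind, "t_onset": t_cursor, "t_term": t_cursor + n * dt}
        )
        t_cursor += n * dt
    q = np.vstack(chunks)
    n_total = len(q)
    t = np.arange(n_total) * dt

    # movement-gated kinetic tremor on joint rates
    qdot = np.gradient(q, dt, axis=0)
    if profile.tremor_amplitude > 0:
        hand_speed_gate = np.linalg.norm(np.gradient(q, dt, axis=0), axis=1)
        gate = hand_speed_gate / max(hand_speed_gate.max(), 1e-12)
        tremor_rate = (
            _bandlimited_noise(rng, n_total, rate, 4.0, 8.0, 7)
            * profile.tremor_amplitude
            * gate[:, None]
        )
        tremor_angle = cumulative_trapezoid(tremor_rate, t, axis=0, initial=0.0)
        q = q + tremor_angle
        qdot = qdot + tremor_rate

    hand_path = np.array([forward_kinematics(model, qk).position for qk in q])

    # ground-truth normalized-arc-length boundaries from the true hand path
    speed = np.linalg.norm(np.gradient(hand_path, dt, axis=0), axis=1)
    s = cumulative_trapezoid(speed, t, initial=0.0)
    L = max(s[-1], 1e-12)
    for ph in phase_table:
        ph["sbar_onset"] = float(np.interp(ph["t_onset"], t, s) / L)
        ph["sbar_term"] = float(np.interp(ph["t_term"], t, s) / L)

    # trunk lean: sagittal ramp over reach+transfer, recovery during return
    movement = [p for p in phase_table if p["kind"] not in ("hold",)]
    trunk = np.zeros((n_total, 3))
    if movement:
        t_up0 = movement[0]["t_onset"]
        t_up1 = movement[-1]["t_onset"]  # start of return stroke
        t_dn1 = movement[-1]["t_term"]
        up = minimum_jerk_profile((t - t_up0) / max(t_up1 - t_up0, dt))
        dn = minimum_jerk_profile((t - t_up1) / max(t_dn1 - t_up1, dt))
        lean = profile.trunk_lean_peak * (up - dn)
        trunk[:, 1] = lean
    # postural sway noise floor, present in every group
    trunk += 0.002 * _bandlimited_noise(rng, n_total, rate, 0.2, 2.0, 3)

    streams = _imu_streams(model, t, q, qdot, trunk, rate)
    emg, emg_max = _emg_streams(task, profile, phase_table, t[-1] + dt, rng)

    truth = TaskTruth(
        t=t,
        joint_angles=q,
        joint_speeds=qdot,
        hand_path=hand_path,
        trunk_angles=trunk,
        phases=phase_table,
        grasp_force_level=_grasp_force_level(task),
        initial_angles=q[0].copy(),
    )
    return SyntheticRecording(
        truth=truth,
        streams=streams,
        emg=emg,
        emg_max=emg_max,
        model=model,
        task=task,
        profile=profile,
        seed=seed,
    )


def _grasp_force_level(task: TaskSpec) -> float:
    """Grasp-force proxy: grows with object size, capped below maximal."""
    if task.subtest == "gross":
        return 0.0
    return 0.25 + 0.5 * task.object_size / max(BLOCK_SIZES)


def _imu_streams(model, t, q, qdot, trunk_angles, rate):
    """Exact sensor streams for the three arm IMUs and the trunk IMU."""
    dt = 1.0 / rate
    n = len(t)
    side = "R" if model.handedness == "right" else "L"
    mounts = {"upper": (3, model.upper_arm_m), "wrist": (5, model.forearm_m),
              "hand": (7, model.hand_m)}

    # per-sample chain state
    rot_hist = {k: np.empty((n, 3, 3)) for k in mounts}
    pos_hist = {k: np.empty((n, 3)) for k in mounts}
    for i in range(n):
        rots = segment_rotations(model, q[i])
        # positions of joint origins
        p = np.zeros(3)
        R_prev = np.eye(3)
        origins = []
        for (d, _), R in zip(model.links, rots):
            p = p + R_prev @ np.asarray(d, float)
            origins.append(p.copy())
            R_prev = R
        for name, (njoints, seg_len) in mounts.items():
            R = rots[njoints - 1]
            rot_hist[name][i] = R
            frac = _SENSOR_MOUNT[name]
            base = origins[njoints - 1]
            pos_hist[name][i] = base + R @ np.array([0, 0, -frac * seg_len])

    streams = {}
    for name in mounts:
        R = Rotation.from_matrix(rot_hist[name])
        gyro = np.zeros((n, 3))
        rel = (R[:-1].inv() * R[1:]).as_rotvec() * rate
        gyro[:-1] = rel
        gyro[-1] = rel[-1]
        acc_lin = np.gradient(np.gradient(pos_hist[name], dt, axis=0), dt, axis=0)
        accel = R.inv().apply(acc_lin - GRAVITY)
        mag = R.inv().apply(np.tile(MAG_REFERENCE, (n, 1)))
        streams[f"{side}_{name}"] = ImuStream(
            t=t.copy(), gyro=gyro, accel=accel, mag=mag, sensor_id=f"{side}_{name}"
        )

    Rt = Rotation.from_euler("xyz", trunk_angles)
    gyro_t = np.zeros((n, 3))
    rel = (Rt[:-1].inv() * Rt[1:]).as_rotvec() * rate
    gyro_t[:-1] = rel
    gyro_t[-1] = rel[-1]
    streams["trunk"] = ImuStream(
        t=t.copy(),
        gyro=gyro_t,
        accel=Rt.inv().apply(-GRAVITY),
        mag=Rt.inv().apply(np.tile(MAG_REFERENCE, (n, 1))),
        sensor_id="trunk",
    )
    return streams


def _emg_streams(task, profile, phase_table, total_s, rng):
    """Amplitude-modulated Gaussian EMG plus a maximal-effort segment."""
    n = int(round(total_s * EMG_RATE_HZ))
    t = np.arange(n) / EMG_RATE_HZ
    envelope = np.full(n, 0.02)  # resting noise floor (fraction of maximal)
    movement = [p for p in phase_table if p["kind"] != "hold"]
    force = _grasp_force_level(task)
    for ph in movement:
        m = (t >= ph["t_onset"]) & (t < ph["t_term"])
        envelope[m] = np.maximum(envelope[m], profile.coactivation_level)
    grasp_like = [p for p in movement if p["kind"] in ("grasp", "transfer", "release")]
    if force > 0 and any(p["kind"] == "grasp" for p in movement):
        lo = min(p["t_onset"] for p in grasp_like)
        hi = max(p["t_term"] for p in grasp_like)
        m = (t >= lo) & (t < hi)
        envelope[m] = np.maximum(envelope[m], force)
    gains = rng.uniform(0.7, 1.3, size=8)
    channels = envelope[:, None] * gains[None, :] * rng.standard_normal((n, 8))
    emg = EmgRecording(t=t, channels=channels)

    n_max = int(round(3.0 * EMG_RATE_HZ))
    t_max = np.arange(n_max) / EMG_RATE_HZ
    ch_max = 1.0 * gains[None, :] * rng.standard_normal((n_max, 8))
    return emg, EmgRecording(t=t_max, channels=ch_max)


def corrupt_sensors(
    rec: SyntheticRecording,
    gyro_noise_sd: float = 0.0,
    gyro_bias: float = 0.0,
    accel_noise_sd: float = 0.0,
    mag_noise_sd: float = 0.0,
    seed: int | None = 0,
) -> SyntheticRecording:
    """Additive white noise and constant per-channel bias on the IMU streams.

    Ground truth is untouched; the bias (rad/s) is added to every gyro axis
    of the arm and trunk sensors. Returns a new recording.
    """
    for v in (gyro_noise_sd, gyro_bias, accel_noise_sd, mag_noise_sd):
        if v < 0:
            raise ContractViolation("noise parameters must be >= 0")
    rng = np.random.default_rng(seed)
    new_streams = {}
    for name, st in rec.streams.items():
        gyro = st.gyro + gyro_bias + gyro_noise_sd * rng.standard_normal(st.gyro.shape)
        accel = st.accel + accel_noise_sd * rng.standard_normal(st.accel.shape)
        mag = st.mag + mag_noise_sd * rng.standard_normal(st.mag.shape)
        new_streams[name] = ImuStream(
            t=st.t.copy(), gyro=gyro, accel=accel, mag=mag, sensor_id=st.sensor_id
        )
    return replace(rec, streams=new_streams)
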