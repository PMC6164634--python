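"""Readers and writers for the on-disk recording dialects.

A recording directory holds:

* ``imu.csv`` — long-format IMU samples: ``t, sensor_id, gx, gy, gz, ax,
  ay, az, mx, my, mz`` (s, rad/s, m/s^2, unit field);
* ``emg.csv`` / ``emg_max.csv`` — ``t, ch1..ch8`` task and maximal-effort
  EMG (arbitrary units, 200 Hz);
* ``geometry.yaml`` — arm geometry, initial joint angles and the task
  descriptor;
* ``truth.json`` — optional generator ground truth.

Reading validates units and monotonicity, interpolates short sample gaps
(<= 50 ms by default) and refuses recordings with more than 5% of samples
missing — short dropouts are salvaged and flagged rather than discarding
the session.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig
from .errors import ContractViolation, QualityError
from .kinematics import ArmModel, ImuStream
from .metrics import EmgRecording, ReferenceTrajectory
from .segmentation import Phase, Segmentation
from .synthetic import SyntheticRecording

logger = logging.getLogger(__name__)

IMU_COLUMNS = ["t", "sensor_id", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"]
EMG_COLUMNS = ["t"] + [f"ch{i}" for i in range(1, 9)]
SENSOR_IDS = ("trunk", "L_upper", "L_wrist", "L_hand", "R_upper", "R_wrist", "R_hand")


@dataclass
class RecordingBundle:
    """Parsed, validated streams of one recording session."""

    streams: dict                       # sensor_id -> ImuStream
    emg: EmgRecording | None
    emg_max: EmgRecording | None
    model: ArmModel
    initial_angles: np.ndarray
    expected_movement_phases: int = 3
    subtest: str = "grasp"
    group: str = ""
    truth: dict | None = None
    gap_counts: dict = field(default_factory=dict)
    interpolated: bool = False

    @property
    def side(self) -> str:
        return "R" if self.model.handedness == "right" else "L"

    def arm_streams(self) -> dict:
        side = self.side
        out = {}
        for role in ("upper", "wrist", "hand"):
            key = f"{side}_{role}"
            if key not in self.streams:
                raise ContractViolation(f"missing sensor stream {key!r}")
            out[role] = self.streams[key]
        return out


def write_recording(rec: SyntheticRecording, outdir) -> Path:
    """Write a synthetic recording as the CSV/YAML/JSON dialect above."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for sensor_id, st in sorted(rec.streams.items()):
        df = pd.DataFrame(
            {
                "t": st.t,
                "sensor_id": sensor_id,
                "gx": st.gyro[:, 0], "gy": st.gyro[:, 1], "gz": st.gyro[:, 2],
                "ax": st.accel[:, 0], "ay": st.accel[:, 1], "az": st.accel[:, 2],
                "mx": st.mag[:, 0], "my": st.mag[:, 1], "mz": st.mag[:, 2],
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "imu.csv", index=False, float_format="%.17g"
    )

    for name, emg in (("emg.csv", rec.emg), ("emg_max.csv", rec.emg_max)):
        df = pd.DataFrame(emg.channels, columns=EMG_COLUMNS[1:])
        df.insert(0, "t", emg.t)
        df.to_csv(outdir / name, index=False, float_format="%.17g")

    geometry = {
        "handedness": rec.model.handedness,
        "upper_arm_m": float(rec.model.upper_arm_m),
        "forearm_m": float(rec.model.forearm_m),
        "hand_m": float(rec.model.hand_m),
        "shoulder_offset": [float(v) for v in rec.model.shoulder_offset],
        "initial_angles": [float(v) for v in rec.truth.initial_angles],
        "subtest": rec.task.subtest,
        "object_size": float(rec.task.object_size),
        "expected_movement_phases": int(rec.task.expected_movement_phases),
        "group": rec.profile.group,
    }
    with open(outdir / "geometry.yaml", "w") as fh:
        yaml.safe_dump(geometry, fh, sort_keys=True)

    truth = {
        "phases": rec.truth.phases,
        "grasp_force_level": float(rec.truth.grasp_force_level),
        "group": rec.profile.group,
        "seed": rec.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return outdir


def _repair_stream(t, data, max_gap_s, max_missing_frac, label):
    """Re-grid a stream to uniform sampling, interpolating short gaps."""
    if np.any(np.diff(t) <= 0):
        raise ContractViolation(f"non-monotone time in stream {label!r}")
    dt = float(np.median(np.diff(t)))
    gaps = np.diff(t)
    big = gaps > 1.5 * dt
    n_missing = int(np.sum(np.round(gaps[big] / dt) - 1))
    if np.any(gaps > max_gap_s + 0.5 * dt):
        raise QualityError(
            f"stream {label!r}: gap of {gaps.max():.3f} s exceeds {max_gap_s} s"
        )
    n_expected = int(round((t[-1] - t[0]) / dt)) + 1
    if n_missing / max(n_expected, 1) > max_missing_frac:
        raise QualityError(
            f"stream {label!r}: {n_missing}/{n_expected} samples missing"
        )
    if n_missing == 0:
        return t, data, 0
    tu = t[0] + dt * np.arange(n_expected)
    out = np.column_stack([np.interp(tu, t, data[:, k]) for k in range(data.shape[1])])
    logger.warning("stream %s: interpolated %d missing samples", label, n_missing)
    return tu, out, n_missing


def read_recording(path, config: PipelineConfig | None = None) -> RecordingBundle:
    """Load and validate a recording directory into a :class:`RecordingBundle`."""
    config = config or PipelineConfig()
    path = Path(path)
    imu_path = path / "imu.csv"
    if not imu_path.exists():
        raise ContractViolation(f"missing {imu_path}")
    df = pd.read_csv(imu_path, float_precision="round_trip")
    missing_cols = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ContractViolation(f"imu.csv missing columns: {missing_cols}")

    streams = {}
    gap_counts = {}
    for sensor_id, g in df.groupby("sensor_id", sort=True):
        if sensor_id not in SENSOR_IDS:
            raise ContractViolation(f"unknown sensor_id {sensor_id!r}")
        t = g["t"].to_numpy(float)
        data = g[IMU_COLUMNS[2:]].to_numpy(float)
        t, data, n_missing = _repair_stream(
            t, data, config.max_gap_s, config.max_missing_frac, sensor_id
        )
        gap_counts[sensor_id] = n_missing
        streams[sensor_id] = ImuStream(
            t=t, gyro=data[:, 0:3], accel=data[:, 3:6], mag=data[:, 6:9],
            sensor_id=sensor_id,
        )

    def _read_emg(name):
        p = path / name
        if not p.exists():
            return None
        e = pd.read_csv(p, float_precision="round_trip")
        bad = [c for c in EMG_COLUMNS if c not in e.columns]
        if bad:
            raise ContractViolation(f"{name} missing columns: {bad}")
        t = e["t"].to_numpy(float)
        rate = 1.0 / float(np.median(np.diff(t)))
        if abs(rate - config.emg_rate_hz) > 0.01 * config.emg_rate_hz:
            raise QualityError(
                f"{name}: sampling rate {rate:.1f} Hz, expected {config.emg_rate_hz}"
            )
        return EmgRecording(t=t, channels=e[EMG_COLUMNS[1:]].to_numpy(float))

    with open(path / "geometry.yaml") as fh:
        geo = yaml.safe_load(fh)
    model = ArmModel.from_dict(geo)
    truth = None
    truth_path = path / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)

    return RecordingBundle(
        streams=streams,
        emg=_read_emg("emg.csv"),
        emg_max=_read_emg("emg_max.csv"),
        model=model,
        initial_angles=np.asarray(geo.get("initial_angles", np.zeros(7)), float),
        expected_movement_phases=int(geo.get("expected_movement_phases", 3)),
        subtest=geo.get("subtest", "grasp"),
        group=geo.get("group", ""),
        truth=truth,
        gap_counts=gap_counts,
        interpolated=any(v > 0 for v in gap_counts.values()),
    )


def write_segmentation(seg: Segmentation, path) -> None:
    with open(path, "w") as fh:
        json.dump({"phases": seg.to_records()}, fh, indent=1, sort_keys=True)


def read_segmentation(path) -> Segmentation:
    with open(path) as fh:
        d = json.load(fh)
    phases = [
        Phase(
            index=int(r["index"]), kind=r["kind"],
            sbar_onset=float(r["sbar_onset"]), sbar_term=float(r["sbar_term"]),
            t_onset=float(r["t_onset"]), t_term=float(r["t_term"]),
            auto=bool(r.get("auto", True)),
        )
        for r in d["phases"]
    ]
    return Segmentation(phases=phases)


def apply_overrides(seg: Segmentation, overrides: list[dict]) -> Segmentation:
    """Apply manual boundary adjustments (the visual-inspection hook).

    Each override names a phase ``index`` and any subset of the boundary
    fields; adjusted phases are marked ``auto=False``.
    """
    by_index = {p.index: p for p in seg.phases}
    for ov in overrides:
        p = by_index.get(int(ov["index"]))
        if p is None:
            raise ContractViolation(f"override for unknown phase index {ov['index']}")
        for key in ("sbar_onset", "sbar_term", "t_onset", "t_term"):
            if key in ov:
                setattr(p, key, float(ov[key]))
        p.auto = False
    return seg


def write_reference(ref: ReferenceTrajectory, path) -> None:
    ref.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_reference(path, task: str = "") -> ReferenceTrajectory:
    return ReferenceTrajectory.from_frame(pd.read_csv(path), task=task)
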