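"""End-to-end orchestration: streams in, segmentation + metrics out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import RecordingBundle
from .kinematics import (
    JointStateSeries,
    TrunkOrientationSeries,
    estimate_arm_joint_angles,
    estimate_trunk_angles,
    hand_positions,
)
from .metrics import (
    ReferenceTrajectory,
    SimilarityWeights,
    compute_phase_metrics,
    emg_rms,
    mirror_sagittal,
)
from .segmentation import (
    ArcTrajectory,
    Segmentation,
    TimeTrajectory,
    parameterize_by_arc,
    segment_phases,
)

METRIC_COLUMNS = ["T_m", "eta_rot", "D", "nu_hat", "chi", "rho", "w_n"]


@dataclass
class PipelineResult:
    """Everything one recording produces on its way to the metric table."""

    joints: JointStateSeries
    trunk: TrunkOrientationSeries
    trajectory: TimeTrajectory
    arc: ArcTrajectory
    segmentation: Segmentation
    metrics: pd.DataFrame
    provenance: dict


def hand_trajectory(bundle: RecordingBundle, config: PipelineConfig | None = None):
    """Joint angles + hand path in the trunk frame for one recording."""
    config = config or PipelineConfig()
    joints = estimate_arm_joint_angles(
        bundle.arm_streams(),
        bundle.model,
        bundle.initial_angles,
        rcond=config.pinv_rcond,
    )
    pos = hand_positions(bundle.model, joints.angles)
    return joints, TimeTrajectory(t=joints.t, position=pos)


def run_pipeline(
    bundle: RecordingBundle,
    config: PipelineConfig | None = None,
    reference: ReferenceTrajectory | None = None,
) -> PipelineResult:
    """Run kinematics, segmentation and metric extraction on one recording.

    Deterministic given the bundle and config. Left-arm hand paths are
    mirrored across the trunk sagittal plane before comparison with the
    (right-arm) reference so healthy left/right executions pool. Without a
    reference trajectory D and chi are reported as NaN.
    """
    config = config or PipelineConfig()
    joints, traj = hand_trajectory(bundle, config)
    trunk = estimate_trunk_angles(
        bundle.streams["trunk"],
        calibration_s=config.calibration_s,
        gyro_weight=config.trunk_gyro_weight,
    )
    position = traj.position
    if config.mirror_left and bundle.model.handedness == "left":
        position = mirror_sagittal(position)
        traj = TimeTrajectory(t=traj.t, position=position)

    arc = parameterize_by_arc(
        traj, dsbar=config.dsbar, zero_speed_frac=config.zero_speed_frac
    )
    seg = segment_phases(
        arc,
        bundle.expected_movement_phases,
        coincidence_window=config.coincidence_window,
        nu_prominence=config.nu_prominence,
        min_separation=config.min_separation,
        onset_window=config.onset_window_s,
        onset_delta_T=config.onset_delta_T_s,
    )

    side = bundle.side
    hand_stream = bundle.streams[f"{side}_hand"]
    w_max = None
    if bundle.emg_max is not None and len(bundle.emg_max) > 1:
        w_max = emg_rms(bundle.emg_max, bundle.emg_max.t[0], bundle.emg_max.t[-1])
    metrics = compute_phase_metrics(
        seg,
        arc,
        ref=reference,
        hand_gyro=(hand_stream.t, hand_stream.gyro),
        trunk=trunk,
        emg=bundle.emg,
        w_max=w_max,
        weights=SimilarityWeights(alpha=config.alpha, beta=config.beta),
        theta_p=config.theta_p,
        jerk_lowpass_hz=config.jerk_lowpass_hz,
    )
    metrics.insert(0, "group", bundle.group)
    metrics.insert(1, "task", bundle.subtest)

    provenance = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "gap_counts": bundle.gap_counts,
        "mirrored": bool(
            config.mirror_left and bundle.model.handedness == "left"
        ),
    }
    return PipelineResult(
        joints=joints,
        trunk=trunk,
        trajectory=traj,
        arc=arc,
        segmentation=seg,
        metrics=metrics,
        provenance=provenance,
    )
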