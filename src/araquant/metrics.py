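"""The five movement-quantification parameters and group-level statistics.

Per movement phase (and for the whole task) the pipeline reports:

* movement time ``T_m`` — termination minus onset time;
* rotational jerk index ``eta_rot`` — natural log of the duration- and
  amplitude-normalized integral of the squared second derivative of the
  hand angular velocity (lower = smoother);
* trajectory similarity ``chi = alpha * D + beta * nu_hat`` — weighted sum
  of the RMS Euclidean deviation ``D`` from a healthy-median reference path
  and the pi-normalized RMS direction change ``nu_hat``, both on the
  normalized-arc-length grid (time-course independent by construction);
* trunk stability index ``rho`` — maximal combined angular deviation of the
  trunk from its phase-start orientation;
* normalized muscle activity ``w_hat_n`` — eight-channel EMG RMS relative
  to a maximal-effort (dynamometry) recording.

Group differences use the Mann-Whitney rank-sum test (exact, tie-aware
enumeration for small samples) and relations to clinical scores use
Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations as _combinations
from math import comb as _comb

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as scistats

from .errors import (
    ContractViolation,
    InsufficientSamplesError,
    UndefinedCorrelationError,
)
from .kinematics import TrunkOrientationSeries
from .segmentation import ArcTrajectory, Phase, Segmentation

N_EMG_CHANNELS = 8


@dataclass(frozen=True)
class SimilarityWeights:
    """Weights of the trajectory-similarity combination chi = alpha*D + beta*nu_hat.

    ``alpha`` carries units 1/m so chi is dimensionless. Equal weights
    (0.5 m^-1, 0.5) are the default since D and nu_hat have similar
    magnitudes in practice.
    """

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ContractViolation("similarity weights must be >= 0")


@dataclass
class ReferenceTrajectory:
    """Healthy-group median path for one task on the common arc grid."""

    task: str
    sbar: np.ndarray
    position: np.ndarray      # (M, 3) coordinate-wise median
    dispersion: np.ndarray    # (M, 3) per-point IQR

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sbar": self.sbar,
                "x": self.position[:, 0],
                "y": self.position[:, 1],
                "z": self.position[:, 2],
                "iqr_x": self.dispersion[:, 0],
                "iqr_y": self.dispersion[:, 1],
                "iqr_z": self.dispersion[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, task: str = "") -> "ReferenceTrajectory":
        return cls(
            task=task,
            sbar=df["sbar"].to_numpy(float),
            position=df[["x", "y", "z"]].to_numpy(float),
            dispersion=df[["iqr_x", "iqr_y", "iqr_z"]].to_numpy(float),
        )


@dataclass(frozen=True)
class EmgRecording:
    """Eight-channel surface-EMG recording (arbitrary amplifier units)."""

    t: np.ndarray
    channels: np.ndarray  # (N, 8)

    def __post_init__(self):
        t = np.asarray(self.t, float)
        ch = np.asarray(self.channels, float)
        if ch.ndim != 2 or ch.shape[1] != N_EMG_CHANNELS:
            raise ContractViolation(
                f"EMG must have exactly {N_EMG_CHANNELS} channels, got {ch.shape}"
            )
        if ch.shape[0] != len(t):
            raise ContractViolation("EMG time and channel lengths differ")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "channels", ch)

    def __len__(self):
        return len(self.t)


def mirror_sagittal(position: np.ndarray) -> np.ndarray:
    """Mirror a path across the trunk sagittal plane (flip mediolateral y)."""
    p = np.asarray(position, float).copy()
    p[..., 1] = -p[..., 1]
    return p


def movement_time(seg: Segmentation) -> dict:
    """Per-movement-phase and whole-task movement times (seconds).

    The task time spans the onset of the first movement phase to the
    termination of the last one; in-between dwells count toward the task but
    not toward any movement phase.
    """
    mov = seg.movement_phases
    if not mov:
        raise ContractViolation("segmentation has no movement phases")
    out = {p.kind: p.duration for p in mov}
    out["task"] = mov[-1].t_term - mov[0].t_onset
    return out


def _derivative(y: np.ndarray, dt: float) -> np.ndarray:
    """First derivative, 4th-order central stencil in the interior."""
    y = np.asarray(y, float)
    d = np.gradient(y, dt, axis=0)
    if len(y) >= 5:
        d[2:-2] = (y[:-4] - 8 * y[1:-3] + 8 * y[3:-1] - y[4:]) / (12.0 * dt)
    return d


def rotational_jerk_index(
    t: np.ndarray,
    omega: np.ndarray,
    t_onset: float,
    t_term: float,
    theta_p: float = 1.0,
    lowpass_hz: float = 10.0,
) -> float:
    """Rotational jerk index of the hand over one phase.

    ``eta = ln( T^5 / theta_p^2 * integral ||d^2 omega/dt^2||^2 dt )`` with
    ``T`` the phase duration; theta_p normalizes by the angular displacement
    and defaults to 1 for tasks that keep hand orientation. The angular
    velocity is zero-phase low-pass filtered before the two numerical
    derivatives (each a 4th-order central difference); the filter cutoff
    sits above the voluntary-movement band.

    Returns ``-inf`` for a perfectly constant angular velocity (zero jerk:
    smoothness is undefined/unbounded).
    """
    t = np.asarray(t, float)
    w = np.atleast_2d(np.asarray(omega, float))
    if w.shape[0] != len(t):
        raise ContractViolation("omega and t lengths differ")
    if theta_p <= 0:
        raise ContractViolation("theta_p must be positive")
    if t_term <= t_onset:
        raise ContractViolation("phase must have positive duration")
    dt = float(np.mean(np.diff(t)))
    fs = 1.0 / dt
    if lowpass_hz and lowpass_hz < 0.5 * fs and len(t) > 15:
        sos = sps.butter(4, lowpass_hz, fs=fs, output="sos")
        w = sps.sosfiltfilt(sos, w, axis=0)
    jerk2 = _derivative(_derivative(w, dt), dt)  # d^2 omega / dt^2
    mag2 = np.sum(jerk2**2, axis=1)
    m = (t >= t_onset) & (t <= t_term)
    if m.sum() < 10:
        raise InsufficientSamplesError(
            f"phase [{t_onset}, {t_term}] has {int(m.sum())} samples, need >= 10"
        )
    integral = float(np.trapezoid(mag2[m], t[m]))
    T = t_term - t_onset
    if integral <= 1e-20:  # numerically zero jerk: smoothness undefined
        return -np.inf
    return float(np.log(T**5 / theta_p**2 * integral))


def _lower_median(a: np.ndarray, axis: int = 0) -> np.ndarray:
    """Median with the lower-median convention for even counts."""
    srt = np.sort(a, axis=axis)
    n = a.shape[axis]
    return np.take(srt, (n - 1) // 2, axis=axis)


def build_reference(
    trajs: list[ArcTrajectory], task: str = ""
) -> ReferenceTrajectory:
    """Pointwise-median reference path from healthy-group arc trajectories.

    All inputs must share the arc grid. The median is coordinate-wise with
    the lower-median convention for even counts; dispersion is the
    per-point, per-coordinate interquartile range.
    """
    if len(trajs) < 3:
        raise ContractViolation("need >= 3 trajectories for a reference")
    grid = trajs[0].sbar
    for a in trajs[1:]:
        if len(a.sbar) != len(grid) or not np.allclose(a.sbar, grid):
            raise ContractViolation("trajectories are on different arc grids")
    stack = np.stack([a.position for a in trajs])  # (K, M, 3)
    med = _lower_median(stack, axis=0)
    q75, q25 = np.percentile(stack, [75, 25], axis=0)
    return ReferenceTrajectory(
        task=task, sbar=grid.copy(), position=med, dispersion=q75 - q25
    )


def _phase_slice(sbar: np.ndarray, sbar_onset: float, sbar_term: float):
    if not (0.0 <= sbar_onset < sbar_term <= 1.0):
        raise ContractViolation("phase bounds must satisfy 0 <= onset < term <= 1")
    i0 = int(np.searchsorted(sbar, sbar_onset - 1e-12))
    i1 = int(np.searchsorted(sbar, sbar_term + 1e-12)) - 1
    if i1 - i0 < 1:
        raise ContractViolation("phase interval contains < 2 arc samples")
    return i0, i1 + 1


def euclidean_similarity(
    arc: ArcTrajectory,
    ref: ReferenceTrajectory,
    sbar_onset: float,
    sbar_term: float,
    use_distance: bool = False,
) -> float:
    """RMS Euclidean distance D_i between a path and the reference over a phase.

    ``D = sqrt( 1/(sbar_t - sbar_o) * integral ||p - p_r||^2 dsbar )``.
    With ``use_distance`` the scalar distance-from-start profiles are
    compared instead of the 3-D positions.
    """
    if len(arc.sbar) != len(ref.sbar) or not np.allclose(arc.sbar, ref.sbar):
        raise ContractViolation("arc and reference are on different grids")
    i0, i1 = _phase_slice(arc.sbar, sbar_onset, sbar_term)
    if use_distance:
        ref_dist = np.linalg.norm(ref.position - ref.position[0], axis=1)
        diff2 = (arc.distance[i0:i1] - ref_dist[i0:i1]) ** 2
    else:
        diff2 = np.sum((arc.position[i0:i1] - ref.position[i0:i1]) ** 2, axis=1)
    sb = arc.sbar[i0:i1]
    return float(np.sqrt(np.trapezoid(diff2, sb) / (sb[-1] - sb[0])))


def direction_change_rms(
    arc: ArcTrajectory, sbar_onset: float, sbar_term: float
) -> float:
    """pi-normalized RMS direction change nu_hat_i over a phase; in [0, 1]."""
    i0, i1 = _phase_slice(arc.sbar, sbar_onset, sbar_term)
    sb = arc.sbar[i0:i1]
    nu2 = arc.nu[i0:i1] ** 2
    return float(np.sqrt(np.trapezoid(nu2, sb) / (sb[-1] - sb[0])) / np.pi)


def trajectory_similarity(
    D: float, nu_hat: float, weights: SimilarityWeights = SimilarityWeights()
) -> float:
    """Combined trajectory-similarity parameter chi = alpha*D + beta*nu_hat."""
    if D < 0 or nu_hat < 0:
        raise ContractViolation("similarity inputs must be >= 0")
    return weights.alpha * D + weights.beta * nu_hat


def trunk_stability_index(
    trunk: TrunkOrientationSeries, t_onset: float, t_term: float
) -> float:
    """Maximal combined trunk angular deviation rho_i (rad) over a phase.

    rho is the maximum over the phase of the Euclidean norm of the three
    trunk-angle deviations from their values at phase start.
    """
    m = (trunk.t >= t_onset) & (trunk.t <= t_term)
    if m.sum() < 1:
        raise ContractViolation("no trunk samples inside the phase")
    ang = trunk.angles[m]
    dev = ang - ang[0]
    return float(np.max(np.linalg.norm(dev, axis=1)))


def emg_rms(rec: EmgRecording, t_onset: float, t_term: float) -> float:
    """Eight-channel EMG RMS over a phase.

    ``w_hat = sqrt( 1/T * integral sum_n w_n(t)^2 dt )`` with T the phase
    duration; all eight electrodes contribute, so a constant level c on every
    channel yields ``2*sqrt(2)*c``.
    """
    if t_term <= t_onset:
        raise ContractViolation("phase must have positive duration")
    m = (rec.t >= t_onset) & (rec.t <= t_term)
    if m.sum() < 2:
        raise ContractViolation("phase must contain >= 2 EMG samples")
    total = np.sum(rec.channels[m] ** 2, axis=1)
    tt = rec.t[m]
    return float(np.sqrt(np.trapezoid(total, tt) / (tt[-1] - tt[0])))


def emg_normalize(w_hat: float, w_max: float) -> float:
    """Normalize a phase EMG RMS by the maximal-effort RMS w_hat_MAX.

    Values above 1 are allowed (the reference effort may have been
    submaximal) but trigger a warning.
    """
    if w_max <= 0:
        raise ContractViolation("w_max must be positive")
    ratio = w_hat / w_max
    if ratio > 1.0:
        warnings.warn(
            f"normalized EMG {ratio:.3f} > 1: maximal-effort reference "
            "appears submaximal",
            stacklevel=2,
        )
    return float(ratio)


# ---------------------------------------------------------------------------
# group-level statistics


def mann_whitney(
    x, y, alternative: str = "two-sided", exact_limit: int = 20000
) -> tuple[float, float]:
    """Mann-Whitney rank-sum test with tie-aware exact small-sample p-value.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``.
    When the number of group allocations C(n1+n2, n1) is at most
    ``exact_limit`` the p-value is computed by exhaustive enumeration of the
    average-rank rank-sum distribution (valid under ties); otherwise the
    normal approximation with tie correction and continuity correction is
    used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 1 or y.ndim != 1 or len(x) < 3 or len(y) < 3:
        raise ContractViolation("each group needs >= 3 observations")
    if alternative not in ("two-sided", "greater", "less"):
        raise ContractViolation("bad alternative")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = scistats.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    U = w_obs - n1 * (n1 + 1) / 2.0

    if _comb(n1 + n2, n1) <= exact_limit:
        mu = n1 * (n1 + 1 + n2) / 2.0
        stats = np.array(
            [ranks[list(idx)].sum() for idx in _combinations(range(n1 + n2), n1)]
        )
        eps = 1e-9
        if alternative == "two-sided":
            p = float(np.mean(np.abs(stats - mu) >= abs(w_obs - mu) - eps))
        elif alternative == "greater":
            p = float(np.mean(stats >= w_obs - eps))
        else:
            p = float(np.mean(stats <= w_obs + eps))
        return U, min(p, 1.0)

    res = scistats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    """Pairwise Mann-Whitney p-values with a p <= alpha significance grid."""

    pvalues: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


def group_compare(
    values_by_group: dict,
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> GroupComparison:
    """Pairwise Mann-Whitney comparison of a parameter across subject groups.

    ``values_by_group`` maps group label to a 1-D array of per-recording
    parameter values (>= 3 each). Returns the full pairwise p-value matrix
    and the boolean significance grid at level ``alpha`` (no multiplicity
    adjustment; raw p-values are reported).
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ContractViolation("need >= 2 groups")
    for g, v in values_by_group.items():
        if len(np.atleast_1d(v)) < 3:
            raise ContractViolation(f"group {g!r} has < 3 observations")
    p = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    for ga, gb in _combinations(groups, 2):
        _, pv = mann_whitney(
            np.asarray(values_by_group[ga], float),
            np.asarray(values_by_group[gb], float),
            alternative=alternative,
        )
        p.loc[ga, gb] = pv
        p.loc[gb, ga] = pv
    return GroupComparison(pvalues=p, significant=p <= alpha, alpha=alpha)


def spearman_correlation(values, scores) -> tuple[float, float]:
    """Spearman rank correlation between a parameter and clinical scores.

    Pearson correlation of average ranks with the two-sided t-approximation
    p-value. Raises if either variable has zero variance (undefined ranks
    correlation).
    """
    x = np.asarray(values, float)
    y = np.asarray(scores, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 5:
        raise ContractViolation("need paired 1-D samples with n >= 5")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ContractViolation("non-finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one variable")
    rho, p = scistats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# per-recording assembly


def compute_phase_metrics(
    seg: Segmentation,
    arc: ArcTrajectory,
    ref: ReferenceTrajectory | None = None,
    hand_gyro: tuple[np.ndarray, np.ndarray] | None = None,
    trunk: TrunkOrientationSeries | None = None,
    emg: EmgRecording | None = None,
    w_max: float | None = None,
    weights: SimilarityWeights = SimilarityWeights(),
    theta_p: float = 1.0,
    jerk_lowpass_hz: float = 10.0,
) -> pd.DataFrame:
    """Tidy table of the five parameters per movement phase plus a task row.

    Parameters whose inputs are not supplied come back as NaN. ``hand_gyro``
    is a ``(t, omega)`` pair for the hand sensor, ``w_max`` the
    maximal-effort EMG RMS for normalization.
    """
    rows = []
    mov = seg.movement_phases
    if not mov:
        raise ContractViolation("segmentation has no movement phases")
    task_bounds = (mov[0].sbar_onset, mov[-1].sbar_term)
    task_times = (mov[0].t_onset, mov[-1].t_term)
    targets: list[tuple[str, Phase | None]] = [(p.kind, p) for p in mov]
    targets.append(("task", None))

    for kind, ph in targets:
        if ph is None:
            sb_o, sb_t = task_bounds
            t_o, t_t = task_times
        else:
            sb_o, sb_t = ph.sbar_onset, ph.sbar_term
            t_o, t_t = ph.t_onset, ph.t_term
        row = {"phase": kind, "T_m": t_t - t_o}
        row["eta_rot"] = (
            rotational_jerk_index(
                hand_gyro[0], hand_gyro[1], t_o, t_t, theta_p, jerk_lowpass_hz
            )
            if hand_gyro is not None
            else np.nan
        )
        if ref is not None:
            D = euclidean_similarity(arc, ref, sb_o, sb_t)
        else:
            D = np.nan
        nu_hat = direction_change_rms(arc, sb_o, sb_t)
        row["D"] = D
        row["nu_hat"] = nu_hat
        row["chi"] = (
            trajectory_similarity(D, nu_hat, weights) if np.isfinite(D) else np.nan
        )
        row["rho"] = (
            trunk_stability_index(trunk, t_o, t_t) if trunk is not None else np.nan
        )
        if emg is not None and w_max is not None:
            row["w_n"] = emg_normalize(emg_rms(emg, t_o, t_t), w_max)
        else:
            row["w_n"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
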