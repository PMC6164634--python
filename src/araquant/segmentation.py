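"""Arc-length trajectory parameterization and movement-phase segmentation.

A task execution (reach - grasp - transfer - release - return) is segmented
by re-parameterizing the hand path with normalized arc length s_bar in
[0, 1], which removes the time course: consecutive time samples where the
hand is (near-)stationary collapse onto a single arc point. Phase boundaries
are arc points where a local minimum of movement speed coincides with a
local maximum of the direction-change profile nu(s_bar). Boundaries are
mapped back to time with a causally constrained minimum-distance search and
refined with the minimum-acceleration-with-constraints onset model, in which
the initial portion of a bell-shaped movement grows with the cube of time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .errors import (
    ContractViolation,
    DegenerateTrajectoryError,
    NoOnsetError,
    SegmentationError,
)

logger = logging.getLogger(__name__)

MOVEMENT_KINDS_BY_COUNT = {
    1: ("transfer",),
    2: ("transfer", "return"),
    3: ("reach_to_grasp", "transfer", "return"),
}
# manipulation phase names between movement phases of a 3-phase task
_MANIPULATION_KINDS = {3: ("grasp", "release")}


@dataclass(frozen=True)
class TimeTrajectory:
    """Hand path in the trunk frame as a function of time.

    ``t`` must be (near-)uniform; ``position`` is (N, 3) in meters. Speed is
    the norm of the numerical derivative of position.
    """

    t: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, float)
        p = np.asarray(self.position, float)
        if t.ndim != 1 or len(t) < 10:
            raise ContractViolation("trajectory needs >= 10 samples")
        if p.shape != (len(t), 3):
            raise ContractViolation(f"position must be (N, 3), got {p.shape}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise ContractViolation("non-finite trajectory values")
        if np.any(np.diff(t) <= 0):
            raise ContractViolation("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "position", p)

    @property
    def speed(self) -> np.ndarray:
        v = np.gradient(self.position, self.t, axis=0)
        return np.linalg.norm(v, axis=1)

    def __len__(self):
        return len(self.t)


@dataclass
class ArcTrajectory:
    """Hand path re-parameterized on a uniform normalized-arc-length grid.

    Attributes
    ----------
    sbar : (M,) uniform grid on [0, 1]
    position : (M, 3) path samples, shifted so the path starts at the origin
    distance : (M,) distance from the initial position, d(0) = 0
    speed : (M,) movement speed mapped onto the arc grid
    nu : (M,) direction change between successive tangents, in [0, pi]
    L : total path length in meters
    time_map : (M,) matched time for each arc point (first causal visit)
    source : the originating :class:`TimeTrajectory`
    s_of_t : (N,) arc length at each source time sample (dwells are flat)
    """

    sbar: np.ndarray
    position: np.ndarray
    distance: np.ndarray
    speed: np.ndarray
    nu: np.ndarray
    L: float
    time_map: np.ndarray
    source: TimeTrajectory
    s_of_t: np.ndarray

    def __len__(self):
        return len(self.sbar)

    def index_of(self, sbar_value: float) -> int:
        return int(round(sbar_value * (len(self.sbar) - 1)))


@dataclass
class Phase:
    """One task phase with arc-domain and time-domain boundaries."""

    index: int
    kind: str
    sbar_onset: float
    sbar_term: float
    t_onset: float
    t_term: float
    auto: bool = True

    @property
    def is_movement(self) -> bool:
        return self.kind in ("reach_to_grasp", "transfer", "return")

    @property
    def duration(self) -> float:
        return self.t_term - self.t_onset


@dataclass
class Segmentation:
    """Ordered task phases; movement phases are the hand-transport intervals."""

    phases: list[Phase] = field(default_factory=list)

    @property
    def movement_phases(self) -> list[Phase]:
        return [p for p in self.phases if p.is_movement]

    @property
    def movement_phase_indices(self) -> list[int]:
        return [i for i, p in enumerate(self.phases) if p.is_movement]

    def to_records(self) -> list[dict]:
        return [
            {
                "index": p.index,
                "kind": p.kind,
                "sbar_onset": p.sbar_onset,
                "sbar_term": p.sbar_term,
                "t_onset": p.t_onset,
                "t_term": p.t_term,
                "auto": p.auto,
            }
            for p in self.phases
        ]


@dataclass
class OnsetFit:
    """Result of the cubic minimum-acceleration onset/termination fit."""

    x_o: float
    eta_m: float
    t_o: float
    delta_T: float
    rss: float


def _speeds_with_dwell_floor(traj: TimeTrajectory, zero_speed_frac: float):
    """Speed profile with sub-threshold (dwell) samples forced to zero.

    Zeroing makes the arc length exactly flat through dwells so that all
    stationary time samples share one arc-length value and collapse to a
    single arc point.
    """
    speed = traj.speed
    vmax = float(speed.max(initial=0.0))
    thresh = zero_speed_frac * vmax
    eff = np.where(speed > thresh, speed, 0.0)
    return speed, eff, thresh


def arc_length_profile(
    traj: TimeTrajectory, zero_speed_frac: float = 0.0
) -> tuple[np.ndarray, float]:
    """Cumulative arc length s(t) and total path length L.

    Trapezoidal quadrature of the speed profile; with ``zero_speed_frac`` > 0
    speeds below that fraction of the peak are treated as zero (dwell
    collapse).
    """
    _, eff, _ = _speeds_with_dwell_floor(traj, zero_speed_frac)
    s = cumulative_trapezoid(eff, traj.t, initial=0.0)
    return s, float(s[-1])


def parameterize_by_arc(
    traj: TimeTrajectory,
    dsbar: float = 1.0 / 500.0,
    zero_speed_frac: float = 0.02,
    min_length: float = 1e-6,
) -> ArcTrajectory:
    """Re-parameterize a time trajectory by normalized arc length.

    Positions are linearly interpolated at a uniform s_bar grid with step
    ``dsbar``, origin-shifted so the path starts at zero. Consecutive time
    samples with (near-)zero speed map to the same arc length and therefore
    collapse to a single arc point, making the representation independent of
    dwell durations.
    """
    if not 0 < dsbar <= 0.5:
        raise ContractViolation("dsbar must be in (0, 0.5]")
    speed, eff, _ = _speeds_with_dwell_floor(traj, zero_speed_frac)
    s = cumulative_trapezoid(eff, traj.t, initial=0.0)
    L = float(s[-1])
    if L < min_length:
        raise DegenerateTrajectoryError(f"path length {L:.2e} m below {min_length}")

    # drop repeated arc-length values (flat dwell runs), keep first occurrence
    s_unique, first_idx = np.unique(s, return_index=True)
    m = int(round(1.0 / dsbar)) + 1
    sbar = np.linspace(0.0, 1.0, m)
    s_grid = sbar * L
    pos = np.column_stack(
        [
            np.interp(s_grid, s_unique, traj.position[first_idx, k])
            for k in range(3)
        ]
    )
    p0 = pos[0].copy()
    pos -= p0
    dist = np.linalg.norm(pos, axis=1)
    speed_grid = np.interp(s_grid, s_unique, speed[first_idx])
    nu = direction_change_profile(pos)
    time_map = arc_to_time_from_profile(s, traj.t, sbar)
    return ArcTrajectory(
        sbar=sbar,
        position=pos,
        distance=dist,
        speed=speed_grid,
        nu=nu,
        L=L,
        time_map=time_map,
        source=traj,
        s_of_t=s,
    )


def direction_change_profile(position: np.ndarray) -> np.ndarray:
    """Angle nu between successive unit tangents along an ordered point set.

    nu[k] is the four-quadrant angle between the chords (k-1, k) and
    (k, k+1); the two boundary entries are zero. Zero-length chords
    (duplicate points) inherit the previous tangent and are logged.
    """
    p = np.asarray(position, float)
    if p.ndim != 2 or len(p) < 3:
        raise ContractViolation("need >= 3 points for direction change")
    seg = np.diff(p, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    bad = norms < 1e-15
    if np.any(bad):
        logger.debug("direction_change: %d duplicate points skipped", bad.sum())
        last = None
        for i in range(len(seg)):
            if bad[i]:
                if last is not None:
                    seg[i] = last
                    norms[i] = np.linalg.norm(last)
            else:
                last = seg[i]
        still = norms < 1e-15
        norms[still] = 1.0  # leading duplicates: tangent undefined, nu -> 0
    tangents = seg / norms[:, None]
    a, b = tangents[:-1], tangents[1:]
    cross = np.linalg.norm(np.cross(a, b), axis=1)
    dot = np.einsum("ij,ij->i", a, b)
    nu_mid = np.arctan2(cross, dot)
    nu = np.zeros(len(p))
    nu[1:-1] = nu_mid
    return nu


def direction_change(arc: ArcTrajectory) -> np.ndarray:
    """Direction-change profile nu(s_bar) of an arc-parameterized path."""
    return direction_change_profile(arc.position)


def arc_to_time_from_profile(
    s_of_t: np.ndarray, t: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Map normalized-arc-length points to times, causally and monotonically.

    For each requested point the first time sample whose cumulative arc
    length reaches the target is returned (the first, causally consistent
    visit); the search never moves backwards, so output times are strictly
    increasing even through dwells and path revisits.
    """
    pts = np.asarray(points, float)
    if np.any((pts < 0) | (pts > 1)):
        raise ContractViolation("arc points must lie in [0, 1]")
    L = s_of_t[-1]
    out = np.empty(len(pts))
    j = 0
    n = len(t)
    for i, sb in enumerate(pts):
        target = sb * L
        j = int(np.searchsorted(s_of_t, target - 1e-12 * max(L, 1.0), side="left"))
        j = min(max(j, 0), n - 1)
        if i > 0 and t[j] <= out[i - 1]:
            # enforce strictly increasing output (sub-sample spacing)
            out[i] = np.nextafter(out[i - 1], np.inf)
        else:
            out[i] = t[j]
    return out


def arc_to_time(arc: ArcTrajectory, traj: TimeTrajectory, points) -> np.ndarray:
    """Times of arc points on the source trajectory (minimum-distance match)."""
    del traj  # the stored arc-length profile already encodes the source
    return arc_to_time_from_profile(arc.s_of_t, arc.source.t, np.asarray(points, float))


def refine_onset(
    t: np.ndarray,
    x: np.ndarray,
    t_approx: float,
    window: float = 0.5,
    delta_T: float = 0.2,
    direction: str = "onset",
) -> OnsetFit:
    """Refine a movement onset (or termination) with the cubic model

        x(t) = x_o                                 for t <= t_o
        x(t) = x_o + (1/6) eta_m (t - t_o)^3       for t_o <= t <= t_o + dT

    fitted by grid search over candidate onsets in
    ``[t_approx - window, t_approx + window]`` with the closed-form
    least-squares (x_o, eta_m) per candidate. A termination is refined by
    reversing time. ``eta_m`` is the initial jerk of the movement.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    if t.ndim != 1 or x.shape != t.shape:
        raise ContractViolation("t and x must be matching 1-D arrays")
    if not (t[0] <= t_approx <= t[-1]):
        raise ContractViolation("t_approx outside signal support")
    if direction not in ("onset", "termination"):
        raise ContractViolation("direction must be 'onset' or 'termination'")
    if direction == "termination":
        t_rev = t[0] + (t[-1] - t[::-1])
        fit = refine_onset(
            t_rev, x[::-1], t[0] + (t[-1] - t_approx), window, delta_T, "onset"
        )
        return OnsetFit(
            x_o=fit.x_o,
            eta_m=fit.eta_m,
            t_o=t[0] + (t[-1] - fit.t_o),
            delta_T=fit.delta_T,
            rss=fit.rss,
        )

    lo = max(t[0], t_approx - window)
    hi = min(t[-1] - delta_T, t_approx + window)
    sel = (t >= lo - delta_T) & (t <= t_approx + window + delta_T)
    if np.ptp(x[sel]) < 1e-12 * (1.0 + np.abs(x[sel]).max(initial=0.0)):
        raise NoOnsetError("signal flat in search window; no onset detectable")
    cand_idx = np.nonzero((t >= lo) & (t <= hi))[0]
    if len(cand_idx) == 0:
        raise NoOnsetError("no candidate onsets inside signal support")
    sig_range = float(np.ptp(x[sel]))

    best = None
    for i in cand_idx:
        t_o = t[i]
        m = (t >= t_o - delta_T) & (t <= t_o + delta_T)
        if m.sum() < 4:
            continue
        tt = t[m]
        c = np.where(tt > t_o, (tt - t_o) ** 3 / 6.0, 0.0)
        A = np.column_stack([np.ones_like(tt), c])
        coef, _, _, _ = np.linalg.lstsq(A, x[m], rcond=None)
        rss = float(np.sum((A @ coef - x[m]) ** 2))
        # an onset must actually start a movement: the fitted cubic has to
        # rise appreciably over the window, otherwise a candidate sitting in
        # the static region fits perfectly (rss ~ 0) with eta ~ 0
        rise = coef[1] * delta_T**3 / 6.0
        if not (coef[1] > 0 and rise >= 0.005 * sig_range):
            continue
        if best is None or rss < best.rss - 1e-15:
            best = OnsetFit(
                x_o=float(coef[0]),
                eta_m=float(coef[1]),
                t_o=float(t_o),
                delta_T=delta_T,
                rss=rss,
            )
    if best is None:
        raise NoOnsetError("no rising cubic found in the search window")
    return best


def _dwell_edges(s_of_t: np.ndarray, t: np.ndarray, target_s: float):
    """(last time before leaving, first time reaching) arc length target_s.

    For a boundary at a dwell, ``first`` is the approximate termination of
    the incoming movement phase and ``last`` the approximate onset of the
    outgoing one. A collapsed dwell is a flat run of the cumulative arc
    length; the grid-snapped boundary may sit a sample or two off that run,
    so the search hops onto the nearest flat run within a short neighborhood
    before expanding it.
    """
    n = len(s_of_t)
    idx = int(np.argmin(np.abs(s_of_t - target_s)))

    def _flat(j):
        return (j > 0 and s_of_t[j] == s_of_t[j - 1]) or (
            j + 1 < n and s_of_t[j + 1] == s_of_t[j]
        )

    if not _flat(idx):
        dt = float(np.median(np.diff(t))) if n > 1 else 1.0
        hop = max(5, int(round(0.25 / dt)))
        for off in range(1, hop + 1):
            if idx + off < n and _flat(idx + off):
                idx += off
                break
            if idx - off >= 0 and _flat(idx - off):
                idx -= off
                break
    lo = idx
    while lo > 0 and s_of_t[lo - 1] == s_of_t[idx]:
        lo -= 1
    hi = idx
    while hi + 1 < n and s_of_t[hi + 1] == s_of_t[idx]:
        hi += 1
    return t[hi], t[lo]


def segment_phases(
    arc: ArcTrajectory,
    expected_movement_phases: int,
    coincidence_window: float = 0.02,
    nu_prominence: float = np.pi / 6.0,
    min_separation: float = 0.05,
    edge_margin: float = 0.02,
    refine: bool = True,
    onset_window: float = 0.5,
    onset_delta_T: float = 0.2,
) -> Segmentation:
    """Segment an arc-parameterized task execution into phases.

    Candidate movement-phase boundaries are local minima of the speed
    profile that coincide (within ``coincidence_window`` of s_bar) with a
    local maximum of the direction-change profile nu. Candidates closer than
    ``min_separation`` merge (higher nu prominence wins; ties to the earlier
    arc point) and the ``expected_movement_phases - 1`` most prominent
    interior boundaries are retained. Boundaries are mapped to time through
    the causal minimum-distance transform and, if ``refine``, sharpened with
    the cubic onset model on the distance-from-rest signal. Manipulation
    phases (grasp/release) are the dwell intervals between refined movement
    phases; hold phases cover the lead-in and lead-out.
    """
    if expected_movement_phases not in MOVEMENT_KINDS_BY_COUNT:
        raise ContractViolation("expected_movement_phases must be 1, 2 or 3")
    n_bound = expected_movement_phases - 1
    m = len(arc.sbar)

    # interior candidates: speed minima coinciding with nu maxima. The
    # candidate score is the prominence (depth) of the speed minimum -- at a
    # true inter-phase dwell the hand stops, so these dips dominate the
    # shallower minima that tremor or submovements carve into a stroke.
    nu_peaks, _ = find_peaks(arc.nu, prominence=nu_prominence)
    vmin_peaks, v_props = find_peaks(-arc.speed, prominence=0.0)
    win = max(1, int(np.ceil(coincidence_window * m)))
    candidates = []  # (sbar, score)
    for pk, depth in zip(vmin_peaks, v_props["prominences"]):
        if not (edge_margin <= arc.sbar[pk] <= 1.0 - edge_margin):
            continue
        if not np.any(np.abs(nu_peaks - pk) <= win):
            continue
        candidates.append((float(arc.sbar[pk]), float(depth)))
    candidates.sort()

    # merge close candidates: keep higher prominence, ties to earlier sbar
    merged: list[tuple[float, float]] = []
    for sb, prom in candidates:
        if merged and sb - merged[-1][0] < min_separation:
            if prom > merged[-1][1]:
                merged[-1] = (sb, prom)
        else:
            merged.append((sb, prom))

    if len(merged) < n_bound:
        raise SegmentationError(
            f"found {len(merged)} candidate boundaries, need {n_bound}",
            candidates=merged,
        )
    merged.sort(key=lambda c: (-c[1], c[0]))
    chosen = sorted(sb for sb, _ in merged[:n_bound])
    bounds = [0.0] + chosen + [1.0]

    t = arc.source.t
    pos = arc.source.position
    onsets, terms = [], []
    for i in range(expected_movement_phases):
        on_approx, _ = _dwell_edges(arc.s_of_t, t, bounds[i] * arc.L)
        _, term_approx = _dwell_edges(arc.s_of_t, t, bounds[i + 1] * arc.L)
        t_on, t_term = on_approx, term_approx
        auto_ok = True
        if refine:
            try:
                sig_on = np.linalg.norm(pos - pos[np.searchsorted(t, on_approx)], axis=1)
                t_on = refine_onset(
                    t, sig_on, on_approx, onset_window, onset_delta_T, "onset"
                ).t_o
                sig_tm = np.linalg.norm(
                    pos - pos[min(np.searchsorted(t, term_approx), len(t) - 1)], axis=1
                )
                t_term = refine_onset(
                    t, sig_tm, term_approx, onset_window, onset_delta_T, "termination"
                ).t_o
            except NoOnsetError:
                t_on, t_term = on_approx, term_approx
                auto_ok = False
        if t_term <= t_on:  # refinement collapsed the phase: fall back
            t_on, t_term = on_approx, term_approx
        onsets.append((t_on, auto_ok))
        terms.append(t_term)

    # enforce global time ordering across phases
    for i in range(1, expected_movement_phases):
        if onsets[i][0] < terms[i - 1]:
            mid = 0.5 * (onsets[i][0] + terms[i - 1])
            terms[i - 1] = mid
            onsets[i] = (np.nextafter(mid, np.inf), onsets[i][1])

    kinds = MOVEMENT_KINDS_BY_COUNT[expected_movement_phases]
    manip = _MANIPULATION_KINDS.get(expected_movement_phases)
    phases: list[Phase] = []
    phases.append(
        Phase(0, "hold", 0.0, 0.0, float(t[0]), float(onsets[0][0]))
    )
    for i in range(expected_movement_phases):
        phases.append(
            Phase(
                len(phases),
                kinds[i],
                bounds[i],
                bounds[i + 1],
                float(onsets[i][0]),
                float(terms[i]),
                auto=onsets[i][1],
            )
        )
        if i < expected_movement_phases - 1:
            kind = manip[i] if manip else "hold"
            phases.append(
                Phase(
                    len(phases),
                    kind,
                    bounds[i + 1],
                    bounds[i + 1],
                    float(terms[i]),
                    float(onsets[i + 1][0]),
                )
            )
    phases.append(
        Phase(len(phases), "hold", 1.0, 1.0, float(terms[-1]), float(t[-1]))
    )
    return Segmentation(phases=phases)
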