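"""The five quantification parameters and the rank statistics."""

import warnings
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scistats

from araquant import (
    EmgRecording,
    SimilarityWeights,
    build_reference,
    direction_change_rms,
    emg_normalize,
    emg_rms,
    euclidean_similarity,
    group_compare,
    mann_whitney,
    movement_time,
    rotational_jerk_index,
    spearman_correlation,
    trajectory_similarity,
    trunk_stability_index,
)
from araquant.errors import ContractViolation, UndefinedCorrelationError
from araquant.kinematics import TrunkOrientationSeries
from araquant.metrics import ReferenceTrajectory, _lower_median
from araquant.segmentation import ArcTrajectory, Phase, Segmentation, TimeTrajectory


def make_arc(position, speed=None, nu=None):
    """Minimal hand-built ArcTrajectory on a uniform grid."""
    position = np.asarray(position, float)
    m = len(position)
    sbar = np.linspace(0, 1, m)
    from araquant.segmentation import direction_change_profile

    t = np.linspace(0, 1, m)
    return ArcTrajectory(
        sbar=sbar,
        position=position,
        distance=np.linalg.norm(position - position[0], axis=1),
        speed=np.ones(m) if speed is None else speed,
        nu=direction_change_profile(position) if nu is None else nu,
        L=1.0,
        time_map=t,
        source=TimeTrajectory(t=t, position=position),
        s_of_t=sbar.copy(),
    )


def make_seg(bounds_t, bounds_s=None):
    kinds = ["reach_to_grasp", "transfer", "return"][: len(bounds_t)]
    phases = []
    for k, (kind, (a, b)) in enumerate(zip(kinds, bounds_t)):
        sa, sb = bounds_s[k] if bounds_s else (a / bounds_t[-1][1], b / bounds_t[-1][1])
        phases.append(Phase(k, kind, sa, sb, a, b))
    return Segmentation(phases=phases)


class TestMovementTime:
    def test_single_phase_difference(self):
        seg = make_seg([(1.0, 2.5)])
        assert movement_time(seg)["reach_to_grasp"] == pytest.approx(1.5)

    def test_task_time_spans_first_onset_to_last_termination(self):
        seg = make_seg([(1.0, 2.0), (3.5, 5.0), (6.0, 8.0)])
        out = movement_time(seg)
        assert out["task"] == pytest.approx(7.0)
        assert out["transfer"] == pytest.approx(1.5)


class TestRotationalJerk:
    def test_constant_angular_velocity_is_undefined_smoothness(self):
        t = np.arange(0, 3, 0.01)
        omega = np.tile([0.3, -0.1, 0.2], (len(t), 1))
        eta = rotational_jerk_index(t, omega, 0.5, 2.5, lowpass_hz=0.0)
        assert eta == -np.inf

    def test_duration_scaling_of_dimensionless_jerk(self):
        # closed-form scaling: for a fixed angle trajectory theta(t) = g(t/T)
        # the angular velocity is T^-1 g'(tau), so the squared second
        # derivative of omega integrates to T^-5 * C and the T^5
        # normalization makes eta duration-invariant; for a fixed
        # angular-velocity *shape* f(t/T) the integral scales as T^-3 and
        # eta changes by +2 ln 2 when the duration doubles
        def eta_for(T, fixed_rotation):
            t = np.arange(0, T, T / 3000)
            tau = t / T
            shape = np.sin(np.pi * tau) ** 2
            scale = 1.0 / T if fixed_rotation else 1.0
            omega = np.column_stack([scale * shape, 0 * tau, 0 * tau])
            return rotational_jerk_index(t, omega, 0.0, T - T / 3000, lowpass_hz=0.0)

        assert eta_for(1.0, True) == pytest.approx(eta_for(2.0, True), rel=1e-2)
        assert eta_for(2.0, False) - eta_for(1.0, False) == pytest.approx(
            2.0 * np.log(2.0), rel=1e-2
        )

    def test_tremor_strictly_increases_eta(self, rng):
        t = np.arange(0, 2, 0.01)
        tau = t / 2
        base = np.column_stack([np.sin(np.pi * tau), 0 * tau, 0 * tau])
        worse = 0
        n = 50
        for _ in range(n):
            phase = rng.uniform(0, 2 * np.pi)
            tremor = 0.05 * np.sin(2 * np.pi * 6.0 * t + phase)
            noisy = base + np.column_stack([tremor, 0 * t, 0 * t])
            e0 = rotational_jerk_index(t, base, 0.1, 1.9)
            e1 = rotational_jerk_index(t, noisy, 0.1, 1.9)
            worse += e1 > e0
        assert worse == n

    def test_short_phase_rejected(self):
        t = np.arange(0, 1, 0.01)
        with pytest.raises(Exception):
            rotational_jerk_index(t, np.zeros((len(t), 3)), 0.5, 0.52)


class TestReference:
    def test_identical_copies_reproduce_input(self):
        pos = np.outer(np.linspace(0, 1, 50), [0.3, 0.1, 0.2])
        arcs = [make_arc(pos) for _ in range(5)]
        ref = build_reference(arcs)
        np.testing.assert_allclose(ref.position, pos, atol=1e-12)
        np.testing.assert_allclose(ref.dispersion, 0.0, atol=1e-12)

    def test_median_tracks_concordant_majority(self):
        base = np.outer(np.linspace(0, 1, 50), [0.3, 0.1, 0.2])
        outlier = base + [0.2, -0.3, 0.4]
        ref = build_reference([make_arc(base), make_arc(base), make_arc(outlier)])
        np.testing.assert_allclose(ref.position, base, atol=1e-12)

    def test_even_count_uses_lower_median(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        np.testing.assert_allclose(_lower_median(a, axis=0), [3.0, 4.0])

    def test_grid_mismatch_rejected(self):
        a = make_arc(np.outer(np.linspace(0, 1, 50), [1.0, 0, 0]))
        b = make_arc(np.outer(np.linspace(0, 1, 60), [1.0, 0, 0]))
        with pytest.raises(ContractViolation):
            build_reference([a, a, b])


class TestEuclideanSimilarity:
    def test_identical_paths_give_zero(self):
        pos = np.outer(np.linspace(0, 1, 100), [0.3, 0.1, 0.2])
        arc = make_arc(pos)
        ref = build_reference([make_arc(pos)] * 3)
        assert euclidean_similarity(arc, ref, 0.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_recovered_exactly(self):
        pos = np.outer(np.linspace(0, 1, 100), [0.3, 0.1, 0.2])
        ref = build_reference([make_arc(pos)] * 3)
        offset = np.array([0.018, -0.018, 0.018])  # norm ~ 0.03118
        arc = make_arc(pos + offset)
        # note: make_arc origin-shifts nothing; positions differ by constant
        D = euclidean_similarity(arc, ref, 0.0, 1.0)
        assert D == pytest.approx(np.linalg.norm(offset), abs=1e-9)

    def test_matches_trapezoid_quadrature_oracle(self, rng):
        m = 200
        pos = np.outer(np.linspace(0, 1, m), [0.3, 0.1, 0.2])
        pert = 0.01 * np.column_stack(
            [np.sin(3 * np.pi * np.linspace(0, 1, m) + c) for c in (0, 1, 2)]
        )
        arc = make_arc(pos + pert)
        ref = build_reference([make_arc(pos)] * 3)
        sb_o, sb_t = 0.2, 0.8
        D = euclidean_similarity(arc, ref, sb_o, sb_t)
        sbar = arc.sbar
        mask = (sbar >= sb_o - 1e-12) & (sbar <= sb_t + 1e-12)
        diff2 = np.sum((arc.position[mask] - ref.position[mask]) ** 2, axis=1)
        oracle = np.sqrt(
            np.trapezoid(diff2, sbar[mask]) / (sbar[mask][-1] - sbar[mask][0])
        )
        assert D == pytest.approx(oracle, abs=1e-9)

    def test_empty_interval_rejected(self):
        pos = np.outer(np.linspace(0, 1, 100), [0.3, 0.1, 0.2])
        arc = make_arc(pos)
        ref = build_reference([make_arc(pos)] * 3)
        with pytest.raises(ContractViolation):
            euclidean_similarity(arc, ref, 0.5, 0.5)


class TestDirectionChangeRms:
    def test_straight_path_zero(self):
        arc = make_arc(np.outer(np.linspace(0, 1, 100), [0.3, 0.1, 0.2]))
        assert direction_change_rms(arc, 0.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_pi_profile(self):
        pos = np.outer(np.linspace(0, 1, 100), [1.0, 0, 0])
        arc = make_arc(pos, nu=np.full(100, np.pi / 2))
        assert direction_change_rms(arc, 0.0, 1.0) == pytest.approx(0.5, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        m = 150
        nu = np.abs(np.sin(np.linspace(0, 3, m)))
        arc = make_arc(np.outer(np.linspace(0, 1, m), [1.0, 0, 0]), nu=nu)
        got = direction_change_rms(arc, 0.1, 0.9)
        sbar = arc.sbar
        mask = (sbar >= 0.1 - 1e-12) & (sbar <= 0.9 + 1e-12)
        oracle = (
            np.sqrt(
                np.trapezoid(nu[mask] ** 2, sbar[mask])
                / (sbar[mask][-1] - sbar[mask][0])
            )
            / np.pi
        )
        assert got == pytest.approx(oracle, abs=1e-12)


class TestTrajectorySimilarity:
    def test_paper_default_weights(self):
        assert trajectory_similarity(0.04, 0.2) == pytest.approx(0.12)
        assert trajectory_similarity(0.0, 0.0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        D=st.floats(0, 1),
        nu=st.floats(0, 1),
        a=st.floats(0, 2),
        b=st.floats(0, 2),
    )
    def test_exact_linear_decomposition(self, D, nu, a, b):
        w = SimilarityWeights(alpha=a, beta=b)
        chi = trajectory_similarity(D, nu, w)
        assert chi - (a * D + b * nu) == 0.0


class TestTrunkStability:
    @staticmethod
    def series(t, angles):
        return TrunkOrientationSeries(t=t, angles=angles)

    def test_motionless_trunk_zero(self):
        t = np.linspace(0, 5, 500)
        rho = trunk_stability_index(self.series(t, np.zeros((500, 3))), 1.0, 4.0)
        assert rho == 0.0

    def test_single_axis_ramp_to_ten_degrees(self):
        t = np.linspace(0, 5, 501)
        ang = np.zeros((501, 3))
        ang[:, 1] = np.deg2rad(10.0) * t / 5.0
        rho = trunk_stability_index(self.series(t, ang), 0.0, 5.0)
        assert rho == pytest.approx(0.174533, abs=1e-4)

    def test_two_axis_pythagorean_combination(self):
        t = np.linspace(0, 2, 201)
        ang = np.zeros((201, 3))
        ang[:, 0] = np.deg2rad(3.0) * np.sin(np.pi * t / 2)
        ang[:, 1] = np.deg2rad(4.0) * np.sin(np.pi * t / 2)
        rho = trunk_stability_index(self.series(t, ang), 0.0, 2.0)
        assert rho == pytest.approx(np.deg2rad(5.0), abs=1e-6)

    def test_deviations_relative_to_phase_start(self):
        t = np.linspace(0, 4, 401)
        ang = np.full((401, 3), 0.3)  # large but constant: zero deviation
        rho = trunk_stability_index(self.series(t, ang), 1.0, 3.0)
        assert rho == 0.0

    def test_piecewise_linear_profile_attains_analytic_max(self):
        t = np.linspace(0, 6, 601)
        ang = np.zeros((601, 3))
        ang[:, 2] = np.interp(t, [0, 2, 4, 6], [0.0, 0.08, 0.02, 0.05])
        rho = trunk_stability_index(self.series(t, ang), 0.0, 6.0)
        assert rho == pytest.approx(0.08, abs=1e-9)


class TestEmg:
    @staticmethod
    def rec(channels, rate=200.0):
        n = len(channels)
        return EmgRecording(t=np.arange(n) / rate, channels=channels)

    def test_silence_gives_zero(self):
        assert emg_rms(self.rec(np.zeros((400, 8))), 0.0, 1.9) == 0.0

    def test_constant_channels_analytic_value(self):
        c = 0.37
        w = emg_rms(self.rec(np.full((400, 8), c)), 0.0, 1.9)
        assert w == pytest.approx(2 * np.sqrt(2) * c, abs=1e-9)

    def test_matches_trapezoid_oracle(self, rng):
        ch = rng.standard_normal((500, 8))
        r = self.rec(ch)
        got = emg_rms(r, 0.5, 2.0)
        m = (r.t >= 0.5) & (r.t <= 2.0)
        total = np.sum(ch[m] ** 2, axis=1)
        oracle = np.sqrt(np.trapezoid(total, r.t[m]) / (r.t[m][-1] - r.t[m][0]))
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_channel_count_enforced(self):
        with pytest.raises(ContractViolation):
            EmgRecording(t=np.arange(10) / 200.0, channels=np.zeros((10, 6)))

    def test_normalization_endpoints_and_warning(self):
        assert emg_normalize(0.0, 2.0) == 0.0
        assert emg_normalize(2.0, 2.0) == 1.0
        with pytest.warns(UserWarning):
            assert emg_normalize(3.0, 2.0) == pytest.approx(1.5)
        with pytest.raises(ContractViolation):
            emg_normalize(1.0, 0.0)


def brute_force_rank_sum_p(x, y, alternative="two-sided"):
    """Exhaustive enumeration over group-1 index subsets (average ranks)."""
    pooled = np.concatenate([x, y])
    ranks = scistats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    stats = [
        ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), n1)
    ]
    stats = np.array(stats)
    if alternative == "two-sided":
        return np.mean(np.abs(stats - mu) >= abs(w_obs - mu) - 1e-9)
    if alternative == "greater":
        return np.mean(stats >= w_obs - 1e-9)
    return np.mean(stats <= w_obs + 1e-9)


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = mann_whitney(x, x.copy())
        assert p == 1.0

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            x = rng.standard_normal(6)
            y = rng.standard_normal(7) + rng.uniform(-1, 1)
            _, p = mann_whitney(x, y)
            ref = scistats.mannwhitneyu(x, y, method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_matches_brute_force_with_ties(self, rng):
        x = np.array([1.0, 2.0, 2.0, 5.0, 7.0])
        y = np.array([2.0, 3.0, 5.0, 5.0, 8.0, 8.0])
        for alt in ("two-sided", "greater", "less"):
            _, p = mann_whitney(x, y, alternative=alt)
            assert p == pytest.approx(brute_force_rank_sum_p(x, y, alt), abs=1e-12)

    def test_power_on_shifted_normals(self, rng):
        rejected = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.standard_normal(30) + 2.0
            y = rng.standard_normal(30)
            _, p = mann_whitney(x, y)
            rejected += p <= 0.05
        assert rejected / n_sim > 0.95

    def test_small_groups_rejected(self):
        with pytest.raises(ContractViolation):
            mann_whitney([1.0, 2.0], [3.0, 4.0, 5.0])


class TestGroupCompare:
    def test_pairwise_grid_and_significance(self, rng):
        groups = {
            "H": rng.standard_normal(12),
            "AF3": rng.standard_normal(12) + 1.5,
            "AF2": rng.standard_normal(12) + 4.0,
        }
        out = group_compare(groups)
        assert out.pvalues.loc["H", "AF2"] == out.pvalues.loc["AF2", "H"]
        assert bool(out.significant.loc["H", "AF2"])
        assert np.isnan(out.pvalues.loc["H", "H"])

    def test_needs_two_groups(self):
        with pytest.raises(ContractViolation):
            group_compare({"H": [1.0, 2.0, 3.0]})


class TestSpearman:
    def test_perfectly_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        rho, _ = spearman_correlation(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_correlation(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_average_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0, 8.0, 8.0])
        rho, _ = spearman_correlation(x, y)
        rx = scistats.rankdata(x)
        ry = scistats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_correlation([1.0, 1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0, 5.0])
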