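import numpy as np
import pytest
from hypothesis import given, strategies as st

from sidls import (
    DEFAULT_DESIGN,
    FilterStatus,
    PeptideEvidence,
    RIAPoint,
    RIATrajectory,
    SignalPRecord,
    apply_trajectory_filters,
    build_trajectories,
    compute_ria,
    ria_density_by_class,
)


class TestComputeRia:
    @pytest.mark.parametrize(
        "h,l,expected",
        [(0.0, 1000.0, 0.0), (500.0, 500.0, 0.5), (900.0, 100.0, 0.9)],
    )
    def test_arithmetic(self, h, l, expected):
        assert compute_ria(h, l) == pytest.approx(expected)

    def test_absent_channel_or_zero_total_gives_absent(self):
        assert compute_ria(None, 100.0) is None
        assert compute_ria(100.0, None) is None
        assert compute_ria(0.0, 0.0) is None

    def test_negative_intensity_fatal(self):
        with pytest.raises(ValueError):
            compute_ria(-1.0, 100.0)

    @given(
        h=st.floats(0.0, 1e9),
        l=st.floats(0.0, 1e9),
        scale=st.floats(1e-6, 1e6),
    )
    def test_bounded_and_scale_invariant(self, h, l, scale):
        ria = compute_ria(h, l)
        if ria is not None:
            assert 0.0 <= ria <= 1.0
            scaled = compute_ria(h * scale, l * scale)
            if scaled is not None:  # scaling can underflow the sum to 0
                assert scaled == pytest.approx(ria, abs=1e-9)


def _ev(seq, t, h, l, prot="P1"):
    return PeptideEvidence(seq, prot, h, l, 0, False, False, t, "CAM")


class TestBuildTrajectories:
    def test_one_trajectory_per_peptide_time_ordered(self):
        rows = [_ev("ACDEFGHK", 24.0, 900, 100), _ev("ACDEFGHK", 0.5, 50, 950), _ev("ACDEFGHK", 6.0, 600, 400)]
        (traj,) = build_trajectories(rows)
        assert [p.time_point for p in traj.points] == [0.5, 6.0, 24.0]

    def test_charge_states_merge_by_summed_intensity(self):
        rows = [_ev("ACDEFGHK", 6.0, 100, 900), _ev("ACDEFGHK", 6.0, 300, 700)]
        (traj,) = build_trajectories(rows)
        assert traj.points[0].ria == pytest.approx(400 / 2000)

    def test_single_point_trajectory_survives_building(self):
        (traj,) = build_trajectories([_ev("ACDEFGHK", 24.0, 900, 100)])
        assert len(traj.points) == 1

    def test_requant_imputes_missing_channel_as_zero(self):
        rows = [_ev("ACDEFGHK", 6.0, 1000, None)]
        (off,) = build_trajectories(rows, requant=False)
        assert off.points == ()
        (on,) = build_trajectories(rows, requant=True)
        assert on.points[0].ria == 1.0
        assert on.points[0].single_channel


def _traj(points):
    return RIATrajectory(
        "ACDEFGHK", "P1", "CAM", tuple(RIAPoint(t, r, r * 1e3, (1 - r) * 1e3) for t, r in points)
    )


class TestTrajectoryFilters:
    @pytest.mark.parametrize(
        "points,status",
        [
            ([(0.5, 0.05), (6.0, 0.6), (24.0, 0.95)], FilterStatus.PASS),
            ([(6.0, 0.6), (24.0, 0.9)], FilterStatus.TOO_FEW_POINTS),
            ([(0.5, 0.05), (1.0, 0.1), (2.0, 0.2), (24.0, 0.95)], FilterStatus.MISSING_LATE_POINTS),
            ([(0.5, 0.8), (6.0, 0.4), (24.0, 0.5)], FilterStatus.IMPOSSIBLE_PROFILE),
        ],
    )
    def test_status_assignment(self, points, status):
        assert apply_trajectory_filters(_traj(points), DEFAULT_DESIGN).filter_status is status

    def test_order_too_few_wins_over_missing_late(self):
        out = apply_trajectory_filters(_traj([(0.5, 0.9), (1.0, 0.95)]), DEFAULT_DESIGN)
        assert out.filter_status is FilterStatus.TOO_FEW_POINTS

    def test_tie_between_early_and_late_passes_strict_check(self):
        out = apply_trajectory_filters(_traj([(0.5, 0.5), (6.0, 0.5), (24.0, 0.5)]), DEFAULT_DESIGN)
        assert out.filter_status is FilterStatus.PASS

    def test_epsilon_tolerates_small_inversions(self):
        pts = [(0.5, 0.62), (6.0, 0.6), (24.0, 0.9)]
        assert apply_trajectory_filters(_traj(pts), DEFAULT_DESIGN).filter_status is FilterStatus.IMPOSSIBLE_PROFILE
        assert (
            apply_trajectory_filters(_traj(pts), DEFAULT_DESIGN, epsilon=0.05).filter_status
            is FilterStatus.PASS
        )

    def test_pass_stable_under_removal_of_interior_points(self):
        pts = [(0.5, 0.05), (1.0, 0.1), (2.0, 0.2), (6.0, 0.6), (24.0, 0.95)]
        full = apply_trajectory_filters(_traj(pts), DEFAULT_DESIGN)
        assert full.filter_status is FilterStatus.PASS
        reduced = [p for p in pts if p[0] != 2.0]
        assert apply_trajectory_filters(_traj(reduced), DEFAULT_DESIGN).filter_status is FilterStatus.PASS

    def test_every_trajectory_gets_exactly_one_status(self):
        rng = np.random.default_rng(0)
        times = [0.5, 1.0, 2.0, 6.0, 24.0]
        for _ in range(200):
            n = rng.integers(1, 6)
            ts = sorted(rng.choice(times, size=n, replace=False))
            pts = [(float(t), float(rng.uniform(0, 1))) for t in ts]
            out = apply_trajectory_filters(_traj(pts), DEFAULT_DESIGN)
            assert out.filter_status in {
                FilterStatus.PASS,
                FilterStatus.TOO_FEW_POINTS,
                FilterStatus.MISSING_LATE_POINTS,
                FilterStatus.IMPOSSIBLE_PROFILE,
            }


class TestRiaDensity:
    def _pass_traj(self, acc, ria, n=5):
        pts = tuple(RIAPoint(t, ria, 1, 1) for t in (0.5, 6.0, 24.0))
        return RIATrajectory(
            "ACDEFGHK", acc, "CAM", pts, filter_status=FilterStatus.PASS
        )

    def test_unimodal_peak_at_common_value(self):
        trajs = [self._pass_traj(f"P{i}", 0.5) for i in range(10)]
        sp = [SignalPRecord(f"P{i}", 0.9) for i in range(10)]
        curves = ria_density_by_class(trajs, sp, 24.0)
        grid, dens = curves["secreted"]
        assert grid[np.argmax(dens)] == pytest.approx(0.5, abs=0.01)

    def test_curves_integrate_to_one(self):
        rng = np.random.default_rng(1)
        trajs = [self._pass_traj(f"P{i}", float(rng.uniform(0.6, 1.0))) for i in range(30)]
        sp = [SignalPRecord(f"P{i}", 0.9) for i in range(30)]
        grid, dens = ria_density_by_class(trajs, sp, 24.0)["secreted"]
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_fast_class_concentrates_above_0_9_at_24h(self):
        # at k = 0.3/h the noiseless RIA at 24 h is 1 - exp(-7.2) ~ 0.999,
        # so nearly all density mass should sit above 0.9
        from sidls import SecretomeKinetics, SimulationConfig, simulate_secretome

        cfg = SimulationConfig(n_secreted=20, n_leaked=5, n_regulated=0, k_secreted=0.3, seed=7)
        ev, sp, _ = simulate_secretome(cfg)
        res = SecretomeKinetics.from_frames(ev, sp).fit()
        grid, dens = res.ria_density(24.0)["secreted"]
        mass_high = np.trapezoid(dens[grid > 0.9], grid[grid > 0.9])
        assert mass_high > 0.7

    def test_empty_class_warns_and_returns_empty(self, caplog):
        trajs = [self._pass_traj("P0", 0.5)]
        sp = [SignalPRecord("P0", 0.9)]
        with caplog.at_level("WARNING", logger="sidls"):
            curves = ria_density_by_class(trajs, sp, 24.0)
        assert curves["not_secreted"][0].size == 0
        assert "not_secreted" in caplog.text
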