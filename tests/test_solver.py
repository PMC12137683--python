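"""Shallow-water solver: balance laws, oracles and closure checks."""

import math

import numpy as np
import pytest

import rockerflow as rf
from rockerflow.motion import MotionSettings, make_motion_profile


def ritter_depth(x, t, h0, g=9.81):
    """Closed-form inviscid dam-break (rarefaction) solution.

    Independent oracle: dam at x=0, still water of depth h0 on the
    left, dry bed on the right.
    """
    c0 = math.sqrt(g * h0)
    xi = np.asarray(x) / t
    return np.where(xi < -c0, h0, np.where(xi < 2 * c0, (2 * c0 - xi) ** 2 / (9 * g), 0.0))


def still_tilt(angle_rad):
    return lambda t: angle_rad


class TestWallShear:
    def test_zero_velocity_gives_zero_stress(self, water37):
        assert rf.wall_shear(1e-3, 0.0, water37) == 0.0

    def test_hand_value(self):
        fluid = rf.FluidProperties(density=993.0, viscosity=6.92e-4)
        assert rf.wall_shear(1e-3, 0.1, fluid) == pytest.approx(0.2076, abs=1e-4)

    def test_inverse_proportionality_in_depth(self, water37):
        tau1 = rf.wall_shear(2e-3, 0.1, water37)
        tau2 = rf.wall_shear(1e-3, 0.1, water37)
        assert tau2 == pytest.approx(2 * tau1)

    def test_dry_cells_return_zero(self, water37):
        h = np.array([0.0, 5e-7, 2e-3])
        u = np.array([1.0, 1.0, 1.0])
        tau = rf.wall_shear(h, u, water37, dry_threshold=1e-6)
        assert tau[0] == 0.0 and tau[1] == 0.0 and tau[2] > 0.0

    def test_sign_follows_velocity(self, water37):
        assert rf.wall_shear(1e-3, -0.1, water37) < 0


class TestLakeAtRest:
    def test_level_water_no_rocking_stays_still(self, geom, water37, coarse_cfg):
        st = rf.equilibrium_state(geom, 9e-6, 0.0, coarse_cfg)
        rec = rf.integrate(
            st, still_tilt(0.0), water37, coarse_cfg, 1.0, sample_times=np.array([0.5, 1.0])
        )
        assert np.abs(rec.tau).max() < 1e-12

    @pytest.mark.parametrize("angle_deg", [0.5, 3.0, 7.0])
    def test_tilted_equilibrium_is_exactly_preserved(self, geom, water37, coarse_cfg, angle_deg):
        # Well-balanced property: the hydrostatic state on a fixed tilt
        # (including a dry shoreline at 7 deg) produces no flow.
        st = rf.equilibrium_state(geom, 5e-6, math.radians(angle_deg), coarse_cfg)
        rec = rf.integrate(
            st,
            still_tilt(math.radians(angle_deg)),
            water37,
            coarse_cfg,
            1.0,
            sample_times=np.array([1.0]),
        )
        h = st.h[st.h > coarse_cfg.dry_threshold]
        # tau = 3 mu u / h, so |u| = |tau| h / (3 mu) < 1e-10 m/s.
        u_bound = np.abs(rec.tau).max() * h.max() / (3 * water37.viscosity)
        assert u_bound < 1e-10

    def test_small_fixed_tilt_pools_and_settles(self, geom, water37, coarse_cfg):
        # Start level, hold 0.5 deg: fluid drains to the low end and stops.
        st = rf.equilibrium_state(geom, 5e-6, 0.0, coarse_cfg)
        angle = math.radians(0.5)
        rec = rf.integrate(
            st, still_tilt(angle), water37, coarse_cfg, 60.0,
            sample_times=np.array([1.0, 59.9, 60.0]),
            state_times=np.array([60.0]),
        )
        # The seiche decays: residual shear far below the sloshing phase.
        assert np.abs(rec.tau[-1]).max() < 1e-4
        assert np.abs(rec.tau[-1]).max() < 0.01 * np.abs(rec.tau[0]).max()
        final = rec.states[0]
        # More volume on the low (positive-x) side.
        mid = final.x.size // 2
        assert final.h[mid:].sum() > final.h[:mid].sum()


class TestConservationAndWaves:
    def test_volume_conserved_over_twenty_periods(self, geom, water37):
        cfg = rf.SolverConfig(n_cells=150, spinup_periods=0, record_periods=20)
        profile = make_motion_profile(MotionSettings(7, 40))
        rec = rf.simulate(geom, 5e-6, profile, water37, cfg)
        assert rec.volume_drift < 1e-8

    def test_dam_break_matches_ritter_solution(self):
        # L1 depth error < 2% against the closed-form solution before
        # the front reaches the wall.
        n, L, h0 = 1000, 0.16, 0.002
        dx = L / n
        x = -L / 2 + dx * (np.arange(n) + 0.5)
        h = np.where(x < 0, h0, 0.0)
        inviscid = rf.FluidProperties(density=1000.0, viscosity=1e-12)
        cfg = rf.SolverConfig(n_cells=n, dry_threshold=1e-9)
        t_eval = 0.2
        rec = rf.integrate(
            rf.FlowState(x=x, h=h, q=np.zeros(n)),
            still_tilt(0.0),
            inviscid,
            cfg,
            t_eval,
            state_times=np.array([t_eval]),
        )
        final = rec.states[0]
        h_exact = ritter_depth(final.x, t_eval, h0)
        l1 = np.sum(np.abs(final.h - h_exact)) / np.sum(h_exact)
        assert l1 < 0.02

    def test_small_pulse_travels_at_sqrt_gh(self, water37):
        # A 2% depth pulse on still water propagates at sqrt(g h) +- 5%.
        n, L, h0 = 800, 0.4, 0.005
        dx = L / n
        x = -L / 2 + dx * (np.arange(n) + 0.5)
        h = h0 * (1.0 + 0.02 * np.exp(-((x + 0.1) ** 2) / (2 * 0.01**2)))
        cfg = rf.SolverConfig(n_cells=n)
        c = math.sqrt(water37.gravity * h0)
        travel = 0.15
        t_eval = travel / c
        rec = rf.integrate(
            rf.FlowState(x=x, h=h, q=np.zeros(n)),
            still_tilt(0.0),
            water37,
            cfg,
            t_eval,
            state_times=np.array([t_eval]),
        )
        final = rec.states[0]
        right = final.x > -0.05  # right-going half of the split pulse
        peak_x = final.x[right][np.argmax(final.h[right])]
        measured_c = (peak_x - (-0.1)) / t_eval
        assert measured_c == pytest.approx(c, rel=0.05)

    def test_grid_convergence_of_period_averaged_shear(self, geom, water37):
        # Richardson-style check: successive refinements move the
        # period-averaged shear map by monotonically shrinking amounts.
        from rockerflow.shear import period_average

        profile = make_motion_profile(MotionSettings(7, 40))
        maps = []
        for n in (100, 200, 400):
            cfg = rf.SolverConfig(n_cells=n, spinup_periods=2, record_periods=1)
            rec = rf.simulate(geom, 5e-6, profile, water37, cfg)
            avg = period_average(rec, profile)
            # Coarsen to the 100-cell grid for comparison.
            maps.append(avg.reshape(100, -1).mean(axis=1))
        d1 = np.linalg.norm(maps[1] - maps[0])
        d2 = np.linalg.norm(maps[2] - maps[1])
        assert d2 < d1

    def test_symmetric_profile_gives_mirror_symmetric_average(self, geom, water37):
        from rockerflow.shear import period_average

        profile = make_motion_profile(MotionSettings(7, 30))
        cfg = rf.SolverConfig(n_cells=200, spinup_periods=4, record_periods=2)
        rec = rf.simulate(geom, 5e-6, profile, water37, cfg)
        avg = period_average(rec, profile)
        asym = np.abs(avg - avg[::-1]).max() / avg.max()
        assert asym < 0.02


class TestSimulateContracts:
    def test_fill_volume_validated(self, geom, water37, coarse_cfg):
        profile = make_motion_profile(MotionSettings(7, 40))
        with pytest.raises(ValueError):
            rf.simulate(geom, 0.0, profile, water37, coarse_cfg)
        with pytest.raises(ValueError):
            rf.simulate(geom, 30e-6, profile, water37, coarse_cfg)

    def test_deterministic_reruns(self, geom, water37, coarse_cfg):
        profile = make_motion_profile(MotionSettings(7, 40))
        rec1 = rf.simulate(geom, 5e-6, profile, water37, coarse_cfg)
        rec2 = rf.simulate(geom, 5e-6, profile, water37, coarse_cfg)
        np.testing.assert_array_equal(rec1.tau, rec2.tau)

    def test_record_sampling_rate(self, geom, water37, coarse_cfg):
        profile = make_motion_profile(MotionSettings(7, 40))
        rec = rf.simulate(geom, 5e-6, profile, water37, coarse_cfg)
        assert rec.sample_interval == pytest.approx(1e-3)
        assert np.all(np.isfinite(rec.tau))

    def test_solver_config_validation(self):
        with pytest.raises(ValueError):
            rf.SolverConfig(n_cells=10)
        with pytest.raises(ValueError):
            rf.SolverConfig(cfl_number=1.5)
        with pytest.raises(ValueError):
            rf.SolverConfig(dry_threshold=0.0)
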