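"""Agent model: drift law, field dynamics, motility switch, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotdyn.kinematics import Trajectory, msd_exponent
from spotdyn.sim import (
    BLIND,
    IMMOTILE_FIXED,
    IMMOTILE_STOCHASTIC,
    MOTILE,
    SimParams,
    calibrate_scales,
    chemotactic_drift,
    minutes_to_time_units,
    motile_fraction,
    run_simulation,
    sample_concentration,
    step_motility_state,
    step_positions,
    update_field,
)


def small_params(**kw):
    defaults = dict(n_agents=100, grid_size=32, dt=0.005, t_final=0.5,
                    snapshot_every=10, seed=1)
    defaults.update(kw)
    return SimParams(**defaults)


class TestChemotacticDrift:
    def test_zero_gradient_zero_drift(self):
        p = small_params()
        assert np.allclose(chemotactic_drift(5.0, np.zeros(2), p), 0.0)

    def test_receptor_saturation_limit(self):
        p = small_params()
        g = np.array([1.0, 2.0])
        v = chemotactic_drift(1e12, g, p)
        assert np.linalg.norm(v) < 1e-15

    def test_zero_concentration_closed_form(self):
        p = small_params()
        g = np.array([0.5, -1.5])
        assert np.allclose(chemotactic_drift(0.0, g, p), p.chi0 * g)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            chemotactic_drift(-0.1, np.ones(2), small_params())

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        c1=st.floats(0.0, 1e6),
        c2=st.floats(0.0, 1e6),
        gx=st.floats(-10.0, 10.0),
        gy=st.floats(-10.0, 10.0),
    )
    def test_magnitude_non_increasing_in_concentration(self, c1, c2, gx, gy):
        p = small_params()
        lo, hi = sorted((c1, c2))
        g = np.array([gx, gy])
        v_lo = np.linalg.norm(chemotactic_drift(lo, g, p))
        v_hi = np.linalg.norm(chemotactic_drift(hi, g, p))
        assert v_hi <= v_lo + 1e-12

    def test_vectorized_matches_scalar(self, rng):
        p = small_params()
        c = rng.uniform(0, 10, 8)
        g = rng.normal(size=(8, 2))
        vec = chemotactic_drift(c, g, p)
        for k in range(8):
            assert np.allclose(vec[k], chemotactic_drift(c[k], g[k], p))


class TestFieldUpdate:
    def test_uniform_field_no_agents_decays_exactly(self):
        p = small_params()
        c0 = 3.0 * np.ones((32, 32))
        out = update_field(c0, np.empty((0, 2)), p)
        assert np.allclose(out, 3.0 * (1.0 - p.decay_rate * p.dt))

    def test_single_agent_deposits_into_containing_pixel(self):
        p = small_params()
        field = np.zeros((32, 32))
        out = update_field(field, np.array([[5.7, 9.2]]), p)
        assert out[5, 9] == pytest.approx(p.secretion_rate * p.dt)
        out[5, 9] = 0.0
        assert np.all(out == 0.0)

    def test_mass_balance_per_step(self, rng):
        p = small_params()
        field = rng.uniform(0, 5, (32, 32))
        pos = rng.uniform(0, 32, (100, 2))
        out = update_field(field, pos, p)
        expected = field.sum() * (1.0 - p.decay_rate * p.dt) + 100 * p.secretion_rate * p.dt
        assert out.sum() == pytest.approx(expected, rel=1e-12)
        assert np.all(out >= 0)

    def test_pure_decay_closed_form_over_many_steps(self):
        p = small_params(secretion_rate=0.0, D_chem=0.0)
        field = 2.0 * np.ones((32, 32))
        for n in range(1, 50):
            field = update_field(field, np.empty((0, 2)), p)
            assert np.allclose(field, 2.0 * (1.0 - p.decay_rate * p.dt) ** n)

    def test_cfl_violation_rejected_at_construction(self):
        with pytest.raises(ValueError, match="stability"):
            small_params(D_chem=100.0, dt=0.005)


class TestMotilitySwitch:
    def _one(self, state, clock=0.0):
        return np.array([state], dtype=np.int8), np.array([clock])

    def test_below_threshold_motile_stays(self, rng):
        p = small_params()
        s, c = self._one(MOTILE)
        s2, _ = step_motility_state(s, c, np.array([p.c_star - 1e-9]), rng, p)
        assert s2[0] == MOTILE

    def test_at_threshold_immobilizes_with_refractory_clock(self, rng):
        p = small_params()
        s, c = self._one(MOTILE)
        s2, c2 = step_motility_state(s, c, np.array([p.c_star]), rng, p)
        assert s2[0] == IMMOTILE_FIXED
        assert c2[0] == pytest.approx(p.t_refractory)

    def test_full_cycle_order(self):
        p = small_params(p_reactivate=1.0)  # deterministic release
        rng = np.random.default_rng(0)
        s, c = self._one(MOTILE)
        seen = [MOTILE]
        for _ in range(int((p.t_refractory + p.t_blind) / p.dt) + 10):
            s, c = step_motility_state(s, c, np.array([p.c_star + 1.0]), rng, p)
            if s[0] != seen[-1]:
                seen.append(int(s[0]))
            if len(seen) >= 5:
                break
        # immobilized agents above threshold re-immobilize after the cycle
        assert seen[:5] == [MOTILE, IMMOTILE_FIXED, IMMOTILE_STOCHASTIC, BLIND, MOTILE]

    def test_switch_disabled_never_immobilizes(self, rng):
        p = small_params(motility_switch=False)
        s = np.full(50, MOTILE, dtype=np.int8)
        c = np.zeros(50)
        for _ in range(20):
            s, c = step_motility_state(s, c, np.full(50, 1e6), rng, p)
        assert np.all(s == MOTILE)

    def test_immotile_episode_duration_expectation(self):
        # geometric-wait property: mean episode = t_refractory + dt/p
        p = small_params(p_reactivate=0.02)
        rng = np.random.default_rng(7)
        n = 20000
        s = np.full(n, IMMOTILE_FIXED, dtype=np.int8)
        c = np.full(n, p.t_refractory)
        steps_immotile = np.zeros(n)
        alive = np.ones(n, dtype=bool)
        for _ in range(20000):
            steps_immotile[alive] += 1
            s, c = step_motility_state(s, c, np.zeros(n), rng, p)
            alive = (s == IMMOTILE_FIXED) | (s == IMMOTILE_STOCHASTIC)
            if not alive.any():
                break
        mean_duration = steps_immotile.mean() * p.dt
        expected = p.t_refractory + p.dt / p.p_reactivate
        assert mean_duration == pytest.approx(expected, rel=0.05)


class TestPositions:
    def test_frozen_dynamics_leave_positions_unchanged(self, rng):
        p = small_params(D_agent=0.0, chi0=0.0, r_agent=0.0)
        pos = rng.uniform(0, 32, (50, 2))
        states = np.full(50, MOTILE, dtype=np.int8)
        field = rng.uniform(0, 5, (32, 32))
        out = step_positions(pos, states, field, rng, p)
        assert np.array_equal(out, pos)

    def test_immotile_agents_never_move(self, rng):
        p = small_params(D_agent=2.0, chi0=20.0, r_agent=0.0)
        pos = rng.uniform(0, 32, (60, 2))
        states = np.full(60, IMMOTILE_FIXED, dtype=np.int8)
        states[30:] = IMMOTILE_STOCHASTIC
        # steep field: strong gradient everywhere
        x = np.arange(32)
        field = np.add.outer(x, x).astype(float)
        out = step_positions(pos, states, field, rng, p)
        assert np.array_equal(out, pos)

    def test_blind_agents_ignore_gradient(self):
        p = small_params(D_agent=0.0, chi0=50.0, r_agent=0.0)
        rng = np.random.default_rng(0)
        pos = np.full((20, 2), 16.0)
        states = np.full(20, BLIND, dtype=np.int8)
        x = np.arange(32)
        field = np.add.outer(x, x).astype(float)
        out = step_positions(pos, states, field, rng, p)
        assert np.array_equal(out, pos)  # D=0 and no drift for BLIND

    def test_brownian_limit_msd_exponent(self):
        p = small_params(n_agents=300, grid_size=64, chi0=0.0, D_agent=0.5,
                         r_agent=0.0, motility_switch=False, t_final=3.0,
                         snapshot_every=12, seed=3)
        snaps = run_simulation(p)
        times = np.array([s.time for s in snaps])
        # unwrap periodic jumps per axis before computing displacements
        raw = np.stack([s.positions for s in snaps])  # (T, N, 2)
        jumps = np.diff(raw, axis=0)
        jumps -= 64.0 * np.round(jumps / 64.0)
        unwrapped = np.concatenate([raw[:1], raw[:1] + np.cumsum(jumps, axis=0)])
        trajs = [
            Trajectory(k, times, unwrapped[:, k, :]) for k in range(p.n_agents)
        ]
        res = msd_exponent(trajs, max_lag_fraction=0.5)
        assert res.alpha == pytest.approx(1.0, abs=0.1)


class TestRunSimulation:
    def test_agent_count_conserved_and_states_valid(self):
        p = small_params(t_final=0.25)
        snaps = run_simulation(p)
        assert len(snaps) >= 2
        for s in snaps:
            assert s.n_agents == p.n_agents
            assert np.all((s.states >= MOTILE) & (s.states <= BLIND))
            assert np.all((s.positions >= 0) & (s.positions < p.grid_size))
            assert np.all(s.field >= 0)

    def test_bit_identical_reruns(self):
        p = small_params(t_final=0.5, seed=11)
        a = run_simulation(p)
        b = run_simulation(p)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.positions, sb.positions)
            assert np.array_equal(sa.states, sb.states)
            assert np.array_equal(sa.field, sb.field)

    def test_different_seed_differs(self):
        a = run_simulation(small_params(seed=1))
        b = run_simulation(small_params(seed=2))
        assert not np.array_equal(a[-1].positions, b[-1].positions)

    def test_initial_snapshot_all_motile_zero_field(self):
        snaps = run_simulation(small_params(t_final=0.05))
        assert motile_fraction(snaps[0].states) == 1.0
        assert np.all(snaps[0].field == 0.0)


class TestCalibration:
    def _clustered_snapshots(self, rng):
        from spotdyn.sim import SimState
        from spotdyn.synth import gen_planted_aggregates

        pos, _ = gen_planted_aggregates(2, 300, 3.0, 0, 64, rng)
        n_cluster = pos.shape[0]
        walker = np.array([[10.0, 10.0]])
        speed = 0.8  # px per time-unit
        snaps = []
        for k in range(3):
            positions = np.vstack([pos, walker + [speed * k, 0.0]])
            states = np.full(positions.shape[0], 1, dtype=np.int8)  # immotile
            states[-1] = 0  # the walker is motile
            snaps.append(
                SimState(float(k), positions, states,
                         np.zeros(positions.shape[0]), np.zeros((64, 64)))
            )
        return snaps, speed

    def test_scales_satisfy_defining_relations(self, rng):
        from spotdyn.detect import local_density_map, segment_aggregates

        snaps, speed = self._clustered_snapshots(rng)
        ref_area, ref_speed = 1.0, 0.05
        mm_per_px, hr_per_tu = calibrate_scales(snaps, ref_area, ref_speed)
        areas = []
        for s in snaps:
            dmap = local_density_map(s.positions, 3.0, 64)
            areas += [d.area for d in segment_aggregates(dmap)]
        assert mm_per_px == pytest.approx(np.sqrt(ref_area / np.mean(areas)))
        assert hr_per_tu == pytest.approx(mm_per_px * speed / ref_speed)
        # after calibration the mean area in mm^2 equals the reference
        assert np.mean(areas) * mm_per_px**2 == pytest.approx(ref_area)

    def test_identity_when_area_already_matches(self, rng):
        snaps, speed = self._clustered_snapshots(rng)
        from spotdyn.detect import local_density_map, segment_aggregates

        areas = []
        for s in snaps:
            dmap = local_density_map(s.positions, 3.0, 64)
            areas += [d.area for d in segment_aggregates(dmap)]
        mm_per_px, _ = calibrate_scales(snaps, float(np.mean(areas)), 1.0)
        assert mm_per_px == pytest.approx(1.0)

    def test_no_aggregates_errors(self, rng):
        from spotdyn.sim import SimState

        empty = [
            SimState(float(k), rng.uniform(0, 64, (20, 2)),
                     np.zeros(20, dtype=np.int8), np.zeros(20), np.zeros((64, 64)))
            for k in range(2)
        ]
        with pytest.raises(ValueError, match="calibrate"):
            calibrate_scales(empty, 1.0, 0.05)

    def test_minutes_conversion(self):
        # 1 time-unit == 5 wall-clock minutes
        assert minutes_to_time_units(15.0, 5.0 / 60.0) == pytest.approx(3.0)
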