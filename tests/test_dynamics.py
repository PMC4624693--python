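"""Langevin integrator, Maxwell–Boltzmann initialization, SHAKE/RATTLE."""

import numpy as np
import pytest

import vmms
from vmms.constants import BOLTZMANN_KCAL, ENERGY_CONV
from vmms.dynamics import (SubsystemState, apply_constraints, bbk_step,
                           initialize_velocities, kinetic_energy, langevin_step,
                           rattle, shake, subsystem_rng)


@pytest.fixture
def water_spec():
    return vmms.build_model_hoh_solution()


class TestVelocityInitialization:
    def test_zero_temperature_gives_zero_velocities(self, water_spec):
        v = initialize_velocities(water_spec.topology, 0.0, 3)
        assert np.all(v == 0.0)

    def test_deterministic_for_fixed_seed(self, water_spec):
        v1 = initialize_velocities(water_spec.topology, 300.0, 5)
        v2 = initialize_velocities(water_spec.topology, 300.0, 5)
        np.testing.assert_array_equal(v1, v2)

    def test_equipartition(self):
        from vmms.topology import Topology
        n = 1000
        topo = Topology(masses=np.full(n, 18.0), type_labels=["X"] * n,
                        charge_sets=np.zeros((1, n)),
                        solute_mask=np.zeros(n, dtype=bool),
                        constraints=np.zeros((0, 2), dtype=int),
                        constraint_lengths=np.zeros(0),
                        molecule_ids=np.arange(n))
        v = initialize_velocities(topo, 300.0, 11)
        ke = kinetic_energy(v, topo.masses)
        expected = 1.5 * n * BOLTZMANN_KCAL * 300.0
        assert abs(ke - expected) < 0.05 * expected

    def test_negative_temperature_rejected(self, water_spec):
        with pytest.raises(ValueError):
            initialize_velocities(water_spec.topology, -1.0, 0)


class TestLangevin:
    def test_zero_forces_zero_friction_straight_line(self):
        m = np.array([10.0])
        pos = np.array([[1.0, 2.0, 3.0]])
        vel = np.array([[0.01, -0.02, 0.005]])
        rng = np.random.default_rng(0)
        for _ in range(100):
            pos, vel = bbk_step(pos, vel, np.zeros((1, 3)), m, 1.0, 0.0,
                                300.0, rng)
        np.testing.assert_allclose(pos[0], [1.0 + 0.01 * 100,
                                            2.0 - 0.02 * 100,
                                            3.0 + 0.005 * 100],
                                   rtol=1e-12, atol=1e-12)

    def test_symplectic_limit_energy_drift(self):
        """Zero-friction harmonic oscillator: energy drift < 0.1% over 1e4
        steps (block-averaged to cancel the leapfrog half-step offset)."""
        k, m = 1.0, 12.0
        pos = np.array([[1.0, 0.0, 0.0]])
        vel = np.zeros((1, 3))
        rng = np.random.default_rng(0)
        energies = []
        for _ in range(10000):
            f = -k * pos
            pos, vel = bbk_step(pos, vel, f, np.array([m]), 1.0, 0.0, 300.0, rng)
            e = kinetic_energy(vel, np.array([m])) + 0.5 * k * float(pos[0] @ pos[0])
            energies.append(e)
        e = np.asarray(energies)
        e0 = e[:500].mean()
        drift = abs(e[-500:].mean() - e0)
        assert drift < 1e-3 * e0

    def test_equilibrium_position_variance(self):
        """⟨x²⟩ = kT/k for a thermostatted harmonic oscillator, within 3
        standard errors (replica ensemble for decorrelated statistics)."""
        k, m, T = 1.0, 12.0, 300.0
        n_rep, n_steps, burn = 64, 16000, 2000
        pos = np.zeros((n_rep, 1))
        vel = np.zeros((n_rep, 1))
        rng = np.random.default_rng(123)
        masses = np.full(n_rep, m)
        samples = []
        for step in range(n_steps):
            f = -k * pos
            pos, vel = bbk_step(pos, vel, f, masses, 1.0, 10.0, T, rng)
            if step >= burn and step % 50 == 0:
                samples.append(pos[:, 0] ** 2)
        x2 = np.concatenate(samples)
        expected = BOLTZMANN_KCAL * T / k
        se = x2.std() / np.sqrt(x2.size / 4)  # mild correlation margin
        assert abs(x2.mean() - expected) < 3 * se

    def test_langevin_step_wrapper_advances_time(self, water_spec):
        topo = water_spec.topology
        state = SubsystemState(water_spec.positions,
                               np.zeros_like(water_spec.positions),
                               water_spec.box)
        out = langevin_step(state, np.zeros_like(state.positions), topo,
                            1.0, 10.0, 300.0, np.random.default_rng(0))
        assert out.time == pytest.approx(1.0)

    def test_deterministic_trajectories(self, water_spec):
        spec = water_spec
        runs = []
        for _ in range(2):
            _, en = vmms.simulate_pure_state(
                spec.topology.with_charge_sets(spec.topology.charge_sets[:1]),
                spec.params, spec.box, spec.positions,
                spec.topology.charge_sets[0], 50, friction=10.0,
                rng=subsystem_rng(9, 0), record_every=10)
            runs.append(en)
        assert runs[0] == runs[1]


class TestConstraints:
    def test_satisfied_constraints_unchanged(self, water_spec):
        topo = water_spec.topology
        pos = shake(water_spec.positions, water_spec.positions,
                    topo.constraints, topo.constraint_lengths, topo.masses)
        np.testing.assert_allclose(pos, water_spec.positions, atol=1e-12)

    def test_water_restored_after_free_step(self, water_spec):
        topo = water_spec.topology
        rng = np.random.default_rng(4)
        vel = initialize_velocities(topo, 300.0, rng)
        moved = water_spec.positions + vel * 1.0  # 1 fs free flight
        pos = shake(moved, water_spec.positions, topo.constraints,
                    topo.constraint_lengths, topo.masses, tol=1e-10)
        d = np.linalg.norm(pos[topo.constraints[:, 0]]
                           - pos[topo.constraints[:, 1]], axis=1)
        assert np.abs(d - topo.constraint_lengths).max() < 1e-8

    def test_rattle_removes_bond_velocities(self, water_spec):
        topo = water_spec.topology
        vel = initialize_velocities(topo, 300.0, 7)
        vel = rattle(water_spec.positions, vel, topo.constraints, topo.masses)
        d = water_spec.positions[topo.constraints[:, 0]] \
            - water_spec.positions[topo.constraints[:, 1]]
        rv = np.einsum("ij,ij->i", vel[topo.constraints[:, 0]]
                       - vel[topo.constraints[:, 1]], d)
        assert np.abs(rv / np.linalg.norm(d, axis=1)).max() < 1e-8

    def test_apply_constraints_state_roundtrip(self, water_spec):
        topo = water_spec.topology
        rng = np.random.default_rng(1)
        state = SubsystemState(
            water_spec.positions + 0.01 * rng.standard_normal(
                water_spec.positions.shape),
            initialize_velocities(topo, 300.0, rng), water_spec.box)
        out = apply_constraints(state, topo, tol=1e-10)
        d = np.linalg.norm(out.positions[topo.constraints[:, 0]]
                           - out.positions[topo.constraints[:, 1]], axis=1)
        assert np.abs(d - topo.constraint_lengths).max() < 1e-8

    def test_constraint_lengths_conserved_over_long_run(self, water_spec):
        """Constrained distances stay within tolerance over 10⁴ steps."""
        spec = water_spec
        topo = spec.topology.with_charge_sets(spec.topology.charge_sets[:1])
        state, _ = vmms.simulate_pure_state(
            topo, spec.params, spec.box, spec.positions,
            topo.charge_sets[0], 10000, friction=10.0, seed=2,
            record_every=10000)
        d = np.linalg.norm(state.positions[topo.constraints[:, 0]]
                           - state.positions[topo.constraints[:, 1]], axis=1)
        assert np.abs(d - topo.constraint_lengths).max() < 1e-8


def test_thermostat_reaches_target_temperature(water_spec):
    """A 10-water box at ξ = 10/ps equilibrates to a running-mean kinetic
    temperature within 10% of 300 K."""
    spec = water_spec
    topo = spec.topology.with_charge_sets(spec.topology.charge_sets[:1])
    from vmms.nonbonded import NonbondedWorkspace
    ws = NonbondedWorkspace(topo, spec.params, spec.box)
    rng = subsystem_rng(17, 0)
    masses = topo.masses
    pos = spec.positions.copy()
    vel = initialize_velocities(topo, 300.0, rng)
    vel = rattle(pos, vel, topo.constraints, masses)
    ndof = 3 * topo.n_atoms - topo.constraints.shape[0]
    temps = []
    for k in range(30000):  # 30 ps
        d = ws.evaluate(pos, topo.charge_sets[0])
        ref = pos
        pos, vel = bbk_step(pos, vel, d.forces, masses, 1.0, 10.0, 300.0, rng)
        pos = shake(pos, ref, topo.constraints, topo.constraint_lengths, masses)
        vel = rattle(pos, vel, topo.constraints, masses)
        if k >= 10000 and k % 20 == 0:
            temps.append(2 * kinetic_energy(vel, masses)
                         / (ndof * BOLTZMANN_KCAL))
    assert abs(np.mean(temps) - 300.0) < 30.0
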