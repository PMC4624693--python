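"""VMMS orchestrator: force mixing, velocity rescaling, records, identity
with plain Langevin in the degenerate one-state case."""

import numpy as np
import pytest

import vmms
from vmms.constants import BOLTZMANN_KCAL
from vmms.core import (StateEnergyRecord, VMMSSimulation, VMMSStepError,
                       mix_solute_forces, rescale_solvent_velocities,
                       reweighted_average, simulate_pure_state, state_weight)
from vmms.dynamics import SubsystemState, kinetic_energy, subsystem_rng


@pytest.fixture(scope="module")
def hoh():
    return vmms.build_model_hoh_solution()


class TestMixSoluteForces:
    def test_single_state_identity(self):
        f = np.arange(12.0).reshape(1, 4, 3)
        np.testing.assert_array_equal(mix_solute_forces(f, [1.0]), f[0])

    def test_identical_forces_unchanged(self):
        f = np.random.default_rng(0).random((3, 4, 3))
        f[1] = f[0]
        f[2] = f[0]
        np.testing.assert_allclose(
            mix_solute_forces(f, [0.2, 0.5, 0.3]), f[0], rtol=1e-12)

    def test_half_half_arithmetic(self):
        f = np.zeros((2, 1, 3))
        f[0, 0] = [1.0, 0.0, 0.0]
        f[1, 0] = [0.0, 1.0, 0.0]
        np.testing.assert_allclose(mix_solute_forces(f, [0.5, 0.5]),
                                   [[0.5, 0.5, 0.0]])

    def test_unnormalized_fractions_rejected(self):
        with pytest.raises(ValueError):
            mix_solute_forces(np.zeros((2, 1, 3)), [0.5, 0.6])


class TestRescaleSolventVelocities:
    def _state(self, seed=0):
        rng = np.random.default_rng(seed)
        vel = rng.standard_normal((6, 3)) * 0.01
        return SubsystemState(np.zeros((6, 3)), vel, np.array([20.0] * 3))

    def test_zero_work_is_identity(self):
        s = self._state()
        out = rescale_solvent_velocities(s, 0.0, np.ones(6, dtype=bool),
                                         np.full(6, 10.0))
        np.testing.assert_array_equal(out.velocities, s.velocities)

    def test_kinetic_energy_decrement_is_exact(self):
        s = self._state(1)
        masses = np.full(6, 10.0)
        solvent = np.array([False, False, True, True, True, True])
        ke0 = kinetic_energy(s.velocities[solvent], masses[solvent])
        out = rescale_solvent_velocities(s, ke0 / 2, solvent, masses)
        ke1 = kinetic_energy(out.velocities[solvent], masses[solvent])
        assert abs(ke1 - ke0 / 2) < 1e-10

    def test_solute_velocities_untouched(self):
        s = self._state(2)
        masses = np.full(6, 10.0)
        solvent = np.array([False, False, True, True, True, True])
        out = rescale_solvent_velocities(s, 1e-4, solvent, masses)
        np.testing.assert_array_equal(out.velocities[~solvent],
                                      s.velocities[~solvent])

    def test_excess_work_raises(self):
        s = self._state(3)
        masses = np.full(6, 10.0)
        solvent = np.ones(6, dtype=bool)
        ke = kinetic_energy(s.velocities, masses)
        with pytest.raises(VMMSStepError):
            rescale_solvent_velocities(s, 2 * ke, solvent, masses)


class TestWeightsAndAverages:
    def _record(self, e_mat, x):
        e_mat = np.asarray(e_mat, dtype=float)
        x = np.asarray(x, dtype=float)
        diag = np.diagonal(e_mat)
        return StateEnergyRecord(step=0, time=0.0, e_solute=e_mat,
                                 e_solvent=np.zeros(len(x)),
                                 e_pure=diag, e_vmms=e_mat @ x,
                                 weights=np.ones(len(x)), fractions=x)

    def test_equal_energies_unit_weight(self):
        rec = self._record([[2.0, 2.0], [2.0, 2.0]], [0.5, 0.5])
        assert state_weight(rec, 0) == pytest.approx(1.0)
        assert state_weight(rec, 1) == pytest.approx(1.0)

    def test_pure_state_unit_weight(self):
        rec = self._record([[1.0, 9.0], [4.0, 3.0]], [1.0, 0.0])
        assert state_weight(rec, 0) == pytest.approx(1.0)

    def test_two_kt_gap(self):
        kt = BOLTZMANN_KCAL * 300.0
        rec = self._record([[2 * kt, 0.0], [2 * kt, 0.0]], [0.5, 0.5])
        assert state_weight(rec, 0, temperature=300.0) == \
            pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_unit_weights_plain_mean(self):
        vals = np.arange(10.0)
        mean, ess = reweighted_average(vals, np.ones(10))
        assert mean == pytest.approx(vals.mean())
        assert ess == pytest.approx(10.0)

    def test_constant_values_any_weights(self):
        mean, _ = reweighted_average(np.full(5, 3.3),
                                     np.array([1, 2, 3, 4, 5.0]))
        assert mean == pytest.approx(3.3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            reweighted_average(np.array([]), np.array([]))


class TestVMMSPropagation:
    def test_one_state_bit_identical_to_plain_langevin(self, hoh):
        topo1 = hoh.topology.with_charge_sets(hoh.topology.charge_sets[:1])
        sim = VMMSSimulation(topo1, hoh.params, hoh.box, hoh.positions,
                             [1.0], friction=1.0, seed=7)
        sim.run(200, record_every=50)
        st, _ = simulate_pure_state(topo1, hoh.params, hoh.box, hoh.positions,
                                    topo1.charge_sets[0], 200, friction=1.0,
                                    rng=subsystem_rng(7, 0), record_every=50)
        np.testing.assert_array_equal(sim.subsystems[0].positions, st.positions)
        np.testing.assert_array_equal(sim.subsystems[0].velocities, st.velocities)

    def test_solute_coordinates_identical_across_subsystems(self, hoh):
        sim = VMMSSimulation(hoh.topology, hoh.params, hoh.box, hoh.positions,
                             [0.5, 0.5], friction=1.0, seed=3)
        sim.run(300, record_every=1000)
        sol = hoh.topology.solute_indices
        dev = np.abs(sim.subsystems[0].positions[sol]
                     - sim.subsystems[1].positions[sol])
        assert dev.max() <= 1e-10

    def test_record_identity_and_cadence(self, hoh):
        """Each record obeys E^(j) − E(V_j) = E_P^(j) − Σ_i x_i E_P^(i)
        and records arrive at the requested cadence."""
        sim = VMMSSimulation(hoh.topology, hoh.params, hoh.box, hoh.positions,
                             [0.5, 0.5], friction=1.0, seed=5)
        recs = sim.run(500, record_every=10)
        assert len(recs) == 50
        for r in recs[::7]:
            lhs = r.e_pure - r.e_vmms
            rhs = np.diagonal(r.e_solute) - r.e_solute @ r.fractions
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)
            assert np.all(r.weights > 0) and np.all(np.isfinite(r.weights))

    def test_degenerate_mixture_reproduces_pure_state_solute(self, hoh):
        """x = (1, 0): subsystem 0 must follow the pure state-0 trajectory
        exactly (state 1's box becomes a spectator)."""
        sim = VMMSSimulation(hoh.topology, hoh.params, hoh.box, hoh.positions,
                             [1.0, 0.0], friction=1.0, seed=11)
        sim.run(150, record_every=1000)
        st, _ = simulate_pure_state(
            hoh.topology.with_charge_sets(hoh.topology.charge_sets[:1]),
            hoh.params, hoh.box, hoh.positions, hoh.topology.charge_sets[0],
            150, friction=1.0, rng=subsystem_rng(11, 0), record_every=1000)
        np.testing.assert_allclose(sim.subsystems[0].positions, st.positions,
                                   atol=1e-12)

    def test_fraction_setter_validates(self, hoh):
        sim = VMMSSimulation(hoh.topology, hoh.params, hoh.box, hoh.positions,
                             [0.5, 0.5], friction=1.0, seed=1)
        with pytest.raises(ValueError):
            sim.set_fractions([0.7, 0.7])
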