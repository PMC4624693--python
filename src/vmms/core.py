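"""The VMMS orchestrator.

A virtual mixture of multiple states (VMMS) holds one solute conformation
shared across n subsystems, one per chemical state, each with its own
solvent box.  Per step the solute moves under the molar-fraction-weighted
combination of the per-state solute forces (integrated once, in subsystem
0, then broadcast), each subsystem's solvent moves under its own forces,
and the solvent velocities are rescaled so the extra work done by the
mixed forces is removed from each subsystem's solvent kinetic energy.

Per-state solute energies recorded along the trajectory feed the
reweighting factors w_j = exp(−β Σ_i x_i (E_P^(j) − E_P^(i))) that convert
VMMS-ensemble averages into pure-state canonical averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import kT
from .dynamics import (SubsystemState, bbk_step, initialize_velocities,
                       kinetic_energy, rattle, shake, subsystem_rng)
from .nonbonded import NonbondedParams, NonbondedWorkspace
from .topology import Topology

__all__ = [
    "VMMSState",
    "StateEnergyRecord",
    "VMMSSimulation",
    "VMMSStepError",
    "mix_solute_forces",
    "rescale_solvent_velocities",
    "state_weight",
    "reweighted_average",
    "records_to_arrays",
    "simulate_pure_state",
]

#: exponent clamp before exponentiation of β·ΔE (dimensionless)
EXPONENT_CLAMP = 700.0


class VMMSStepError(RuntimeError):
    """Pathological force mismatch: δ^(i) exceeded the solvent KE."""


@dataclass
class VMMSState:
    """Subsystems, shared-solute contract, and current molar fractions."""

    subsystems: list
    molar_fractions: np.ndarray
    solute_atom_indices: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        self.molar_fractions = np.asarray(self.molar_fractions, dtype=float)
        self.solute_atom_indices = np.asarray(self.solute_atom_indices, dtype=int)
        if abs(self.molar_fractions.sum() - 1.0) > 1e-12:
            raise ValueError("molar fractions must sum to 1")
        if np.any(self.molar_fractions < 0):
            raise ValueError("molar fractions must be non-negative")


@dataclass
class StateEnergyRecord:
    """Per-frame energy bookkeeping across all states and subsystems.

    ``e_solute[j, i]`` is the state-i solute energy evaluated on subsystem
    j's configuration (the cheap multi-charge-state recomputation); the
    diagonal ``e_solute[j, j]`` is the subsystem's own solute energy.
    ``e_solvent[j]`` is E_W^(j).  ``e_pure[j] = E_P^(j,j) + E_W^(j)`` is
    the pure-state energy of box j and
    ``e_vmms[j] = Σ_i x_i E_P^(i,j) + E_W^(j)`` the VMMS-state energy, so
    e_pure − e_vmms is the per-subsystem reweighting exponent.
    """

    step: int
    time: float
    e_solute: np.ndarray
    e_solvent: np.ndarray
    e_pure: np.ndarray
    e_vmms: np.ndarray
    weights: np.ndarray
    fractions: np.ndarray


def mix_solute_forces(per_state_solute_forces: np.ndarray,
                      molar_fractions: np.ndarray) -> np.ndarray:
    """Molar-fraction-weighted solute force combination f = Σ_i x_i f^(i)."""
    x = np.asarray(molar_fractions, dtype=float)
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("molar fractions must sum to 1")
    f = np.asarray(per_state_solute_forces, dtype=float)
    return np.einsum("i,iak->ak", x, f)


def rescale_solvent_velocities(subsystem: SubsystemState, delta_work: float,
                               solvent_mask: np.ndarray,
                               masses: np.ndarray) -> SubsystemState:
    """Scale solvent velocities so their KE drops by exactly ``delta_work``.

    Every solvent velocity is multiplied by √(1 − δ/KE_W); solute
    velocities are untouched.  Raises :class:`VMMSStepError` when δ is not
    smaller than the current solvent kinetic energy.
    """
    if delta_work == 0.0:
        return subsystem
    ke_w = kinetic_energy(subsystem.velocities[solvent_mask], masses[solvent_mask])
    if delta_work >= ke_w:
        raise VMMSStepError(
            f"extra work δ={delta_work:.6g} kcal/mol exceeds solvent KE {ke_w:.6g}")
    scale = np.sqrt(1.0 - delta_work / ke_w)
    vel = subsystem.velocities.copy()
    vel[solvent_mask] *= scale
    out = subsystem.copy()
    out.velocities = vel
    return out


def state_weight(record: StateEnergyRecord, j: int,
                 molar_fractions: np.ndarray | None = None,
                 temperature: float = 300.0) -> float:
    """Reweighting factor w_j = exp(−β Σ_i x_i (E_P^(j) − E_P^(i))).

    All solute energies are evaluated on subsystem j's configuration (row
    j of the record's energy matrix).  Uses the fractions stored on the
    record unless an override is given; β = 1/kT comes from
    ``temperature`` (the run configuration's value).
    """
    x = record.fractions if molar_fractions is None else np.asarray(molar_fractions)
    row = record.e_solute[j]
    arg = (row[j] - float(x @ row)) / kT(temperature)
    return float(np.exp(-np.clip(arg, -EXPONENT_CLAMP, EXPONENT_CLAMP)))


def records_to_arrays(records: list[StateEnergyRecord]):
    """Stack a record stream into (e_solute, fractions, weights) arrays."""
    e_p = np.array([r.e_solute for r in records])
    x = np.array([r.fractions for r in records])
    w = np.array([r.weights for r in records])
    return e_p, x, w


def reweighted_average(values: np.ndarray, weights: np.ndarray):
    """Pure-state ensemble average ⟨P·w⟩/⟨w⟩ with an ESS diagnostic.

    Returns ``(mean, ess)`` where ess = (Σw)²/Σw² is the Kish effective
    sample size of the weighted ensemble.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("no samples")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    mean = float(np.sum(values * weights) / np.sum(weights))
    ess = float(np.sum(weights) ** 2 / np.sum(weights**2))
    return mean, ess


class VMMSSimulation:
    """Propagator for a VMMS system of ``n_states`` subsystems.

    Parameters
    ----------
    topology : Topology
        Shared topology; ``topology.charge_sets`` supplies one charge
        vector per state.
    params : NonbondedParams
    box : array-like
        Cubic/orthorhombic box edges (identical for all subsystems).
    initial_positions : (N, 3) array
        Starting conformation, shared by every subsystem.
    molar_fractions : (n_states,) array
    temperature, friction, dt : floats
        K, 1/ps, fs.
    seed : int
        Master seed; subsystem i uses the stream keyed (seed, i).
    """

    def __init__(self, topology: Topology, params: NonbondedParams, box,
                 initial_positions: np.ndarray, molar_fractions,
                 temperature: float = 300.0, friction: float = 10.0,
                 dt: float = 1.0, seed: int = 0,
                 shake_tol: float = 1e-10):
        self.topology = topology
        self.params = params
        self.n_states = topology.n_states
        self.workspace = NonbondedWorkspace(topology, params, box)
        self.temperature = temperature
        self.friction = friction
        self.dt = dt
        self.shake_tol = shake_tol
        self.kt = kT(temperature)
        self.x = np.asarray(molar_fractions, dtype=float).copy()
        if self.x.shape != (self.n_states,):
            raise ValueError("molar fraction count must match state count")
        if abs(self.x.sum() - 1.0) > 1e-12:
            raise ValueError("molar fractions must sum to 1")
        self.sol_idx = topology.solute_indices
        self.solv_idx = topology.solvent_indices
        self.solvent_mask = ~topology.solute_mask
        cons = topology.constraints
        solv_sel = topology.solvent_constraint_selection()
        self._solv_cons = cons[solv_sel]
        self._solv_lengths = topology.constraint_lengths[solv_sel]
        self.rngs = [subsystem_rng(seed, i) for i in range(self.n_states)]
        pos = np.asarray(initial_positions, dtype=float)
        box = np.asarray(box, dtype=float) * np.ones(3)
        self.subsystems = []
        for i in range(self.n_states):
            vel = initialize_velocities(topology, temperature, self.rngs[i])
            vel = rattle(pos, vel, cons, topology.masses)
            self.subsystems.append(SubsystemState(pos.copy(), vel, box.copy()))
        self.step_count = 0
        self._clamp_warned = False

    # ------------------------------------------------------------------
    @property
    def state(self) -> VMMSState:
        return VMMSState(self.subsystems, self.x.copy(), self.sol_idx,
                         self.step_count)

    def set_fractions(self, x) -> None:
        x = np.asarray(x, dtype=float)
        if abs(x.sum() - 1.0) > 1e-9 or np.any(x < 0):
            raise ValueError("invalid molar fractions")
        self.x = x / x.sum()

    def weight(self, e_row: np.ndarray, j: int) -> float:
        """w_j from subsystem j's per-state solute energies."""
        arg = (e_row[j] - float(self.x @ e_row)) / self.kt
        if abs(arg) > EXPONENT_CLAMP:
            if not self._clamp_warned:
                import warnings
                warnings.warn("reweighting exponent clamped; weights are "
                              "saturated and effective sample size is poor")
                self._clamp_warned = True
            arg = np.clip(arg, -EXPONENT_CLAMP, EXPONENT_CLAMP)
        return float(np.exp(-arg))

    def _record(self, e_matrix: np.ndarray, e_solvent: np.ndarray) -> StateEnergyRecord:
        e_diag = np.diagonal(e_matrix)
        e_mix = e_matrix @ self.x
        e_pure = e_diag + e_solvent
        e_vmms = e_mix + e_solvent
        w = np.array([self.weight(e_matrix[j], j) for j in range(self.n_states)])
        return StateEnergyRecord(step=self.step_count,
                                 time=self.subsystems[0].time,
                                 e_solute=e_matrix.copy(),
                                 e_solvent=e_solvent.copy(),
                                 e_pure=e_pure, e_vmms=e_vmms,
                                 weights=w, fractions=self.x.copy())

    # ------------------------------------------------------------------
    def step(self, collect: bool = False) -> StateEnergyRecord | None:
        """Advance every subsystem by one time step.

        Forces in every subsystem are evaluated with the fraction-mixed
        solute charges Σ_i x_i·q^(i) — each box realizes the VMMS state
        V_j, whose solvent interacts with the mixed-charge solute (the
        pure states enter only through the energy bookkeeping and the
        reweighting factors).  When ``collect`` is true, returns the
        :class:`StateEnergyRecord` for the pre-move conformation.
        """
        topo = self.topology
        masses = topo.masses
        q_mix = self.x @ topo.charge_sets if self.n_states > 1 \
            else topo.charge_sets[0]
        decomps = [self.workspace.evaluate(s.positions, q_mix)
                   for s in self.subsystems]
        record = None
        if collect:
            # row j: every state's solute energy on box j's configuration,
            # with full solute-solvent cross terms (the reweighting
            # exponents are pure-vs-mixed box differences)
            stacked = np.vstack([topo.charge_sets, q_mix])
            per_box = [self.workspace.solute_energies(
                s.positions, stacked, cross="full")
                for s in self.subsystems]
            e_mat = np.array([row[:-1] for row in per_box])
            e_mix = np.array([row[-1] for row in per_box])
            e_box = np.array([d.e_solute + d.e_solvent for d in decomps])
            e_w = e_box - e_mix  # solvent-only part of each box
            record = self._record(e_mat, e_w)

        sol = self.sol_idx
        per_state_sol_forces = np.array([d.forces[sol] for d in decomps])
        f_mix = mix_solute_forces(per_state_sol_forces, self.x)

        # subsystem 0: full step with mixed solute forces, then broadcast
        sub0 = self.subsystems[0]
        f0 = decomps[0].forces.copy()
        f0[sol] = f_mix
        ref0 = sub0.positions
        pos0, vel0 = bbk_step(sub0.positions, sub0.velocities, f0, masses,
                              self.dt, self.friction, self.temperature,
                              self.rngs[0])
        v_solute_pre = vel0[sol].copy()  # pre-constraint, enters δ^(i)
        pos0 = shake(pos0, ref0, topo.constraints, topo.constraint_lengths,
                     masses, self.shake_tol)
        vel0 = rattle(pos0, vel0, topo.constraints, masses, self.shake_tol)
        new_states = [SubsystemState(pos0, vel0, sub0.box, sub0.time + self.dt)]

        for j in range(1, self.n_states):
            sub = self.subsystems[j]
            ref = sub.positions
            pos = sub.positions.copy()
            vel = sub.velocities.copy()
            w_idx = self.solv_idx
            pw, vw = bbk_step(sub.positions[w_idx], sub.velocities[w_idx],
                              decomps[j].forces[w_idx], masses[w_idx],
                              self.dt, self.friction, self.temperature,
                              self.rngs[j])
            pos[w_idx] = pw
            vel[w_idx] = vw
            pos[sol] = pos0[sol]
            vel[sol] = vel0[sol]
            pos = shake(pos, ref, self._solv_cons, self._solv_lengths, masses,
                        self.shake_tol)
            vel = rattle(pos, vel, self._solv_cons, masses, self.shake_tol)
            new_states.append(SubsystemState(pos, vel, sub.box, sub.time + self.dt))

        # velocity rescale: remove the extra work done by the mixed forces
        # (bookkeeping of the per-step δ and the realized KE drop is kept
        # for diagnostics)
        self.last_deltas = np.zeros(self.n_states)
        self.last_ke_drops = np.zeros(self.n_states)
        for j in range(self.n_states):
            df = f_mix - per_state_sol_forces[j]
            delta = float(np.sum(df * v_solute_pre)) * self.dt
            self.last_deltas[j] = delta
            if delta != 0.0:
                ke0 = kinetic_energy(
                    new_states[j].velocities[self.solvent_mask],
                    masses[self.solvent_mask])
                new_states[j] = rescale_solvent_velocities(
                    new_states[j], delta, self.solvent_mask, masses)
                ke1 = kinetic_energy(
                    new_states[j].velocities[self.solvent_mask],
                    masses[self.solvent_mask])
                self.last_ke_drops[j] = ke0 - ke1

        self.subsystems = new_states
        self.step_count += 1
        return record

    def run(self, n_steps: int, record_every: int = 10) -> list[StateEnergyRecord]:
        """Propagate ``n_steps`` steps, collecting a record every
        ``record_every`` steps (cadence counted from the current step)."""
        records = []
        for k in range(n_steps):
            rec = self.step(collect=(k % record_every == 0))
            if rec is not None:
                records.append(rec)
        return records


def simulate_pure_state(topology: Topology, params: NonbondedParams, box,
                        initial_positions: np.ndarray, charges: np.ndarray,
                        n_steps: int, temperature: float = 300.0,
                        friction: float = 10.0, dt: float = 1.0,
                        rng: np.random.Generator | None = None,
                        seed: int | None = None, record_every: int = 10,
                        shake_tol: float = 1e-10):
    """Plain Langevin run of one box under a single charge set.

    Serves as the independent pure-state reference for the reweighting
    checks.  Step structure (force pass, BBK, SHAKE, RATTLE, RNG
    consumption) mirrors the VMMS subsystem-0 path, so a one-state VMMS
    with the same stream is bit-identical.  Returns
    ``(final_state, energies)`` where energies is a list of
    (e_solute, e_solvent) tuples at the record cadence.
    """
    if rng is None:
        rng = subsystem_rng(0 if seed is None else seed, 0)
    masses = topology.masses
    ws = NonbondedWorkspace(topology, params, box)
    charges = np.asarray(charges, dtype=float)
    pos = np.asarray(initial_positions, dtype=float).copy()
    vel = initialize_velocities(topology, temperature, rng)
    vel = rattle(pos, vel, topology.constraints, masses)
    box = np.asarray(box, dtype=float) * np.ones(3)
    state = SubsystemState(pos, vel, box)
    energies = []
    for k in range(n_steps):
        d = ws.evaluate(state.positions, charges)
        if k % record_every == 0:
            # full-cross solute energy, comparable with VMMS records
            e_p = ws.solute_energies(state.positions, charges[None, :],
                                     cross="full")[0]
            energies.append((e_p, d.e_solute + d.e_solvent - e_p))
        ref = state.positions
        pos, vel = bbk_step(state.positions, state.velocities, d.forces,
                            masses, dt, friction, temperature, rng)
        pos = shake(pos, ref, topology.constraints, topology.constraint_lengths,
                    masses, shake_tol)
        vel = rattle(pos, vel, topology.constraints, masses, shake_tol)
        state = SubsystemState(pos, vel, state.box, state.time + dt)
    return state, energies
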