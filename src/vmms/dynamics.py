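"""Langevin dynamics with holonomic constraints (SHAKE/RATTLE).

The integrator is the leapfrog form of the BBK discretization: velocities
live at half steps, and with zero friction the update reduces exactly to
leapfrog/velocity-Verlet position dynamics.  Friction is given in 1/ps,
the time step in fs; forces are kcal/mol/Å and are converted to Å/fs²
through the mass and the kcal/mol ↔ amu·Å²/fs² factor.

Coordinates are never wrapped into the box during dynamics — molecules stay
whole and periodicity enters only through minimum-image distances in the
nonbonded pair sums.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import BOLTZMANN_KCAL, ENERGY_CONV
from .topology import Topology

__all__ = [
    "SubsystemState",
    "ConstraintError",
    "initialize_velocities",
    "bbk_step",
    "langevin_step",
    "shake",
    "rattle",
    "apply_constraints",
    "kinetic_energy",
    "subsystem_rng",
]


class ConstraintError(RuntimeError):
    """SHAKE or RATTLE failed to converge."""


@dataclass
class SubsystemState:
    """Coordinates, velocities and box of one simulation box.

    positions/velocities are (N, 3) in Å and Å/fs; ``box`` holds the three
    edge lengths in Å; ``time`` is in fs.
    """

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")

    def copy(self) -> "SubsystemState":
        return SubsystemState(self.positions.copy(), self.velocities.copy(),
                              self.box.copy(), self.time)


def subsystem_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for subsystem ``index``.

    Streams are keyed by (master_seed, index) so adding subsystems never
    perturbs the noise seen by existing ones.
    """
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(index)]))


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kcal/mol."""
    return 0.5 * ENERGY_CONV * float(np.sum(masses[:, None] * velocities**2))


def initialize_velocities(topology: Topology, temperature: float,
                          rng: np.random.Generator | int) -> np.ndarray:
    """Maxwell–Boltzmann velocity draw at ``temperature`` (K)."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = topology.n_atoms
    if temperature == 0:
        return np.zeros((n, 3))
    kt_md = BOLTZMANN_KCAL * temperature / ENERGY_CONV
    sigma = np.sqrt(kt_md / topology.masses)
    return rng.standard_normal((n, 3)) * sigma[:, None]


def bbk_step(positions: np.ndarray, velocities: np.ndarray, forces: np.ndarray,
             masses: np.ndarray, dt: float, friction: float, temperature: float,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One unconstrained leapfrog-BBK update on raw arrays.

    ``friction`` is in 1/ps.  Returns new positions and (half-step)
    velocities; with ``friction == 0`` no random numbers are consumed and
    the update is plain leapfrog.
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    acc = forces / (masses[:, None] * ENERGY_CONV)
    if friction > 0.0:
        gamma = friction * 1e-3  # 1/fs
        kt_md = BOLTZMANN_KCAL * temperature / ENERGY_CONV
        sigma = np.sqrt(2.0 * gamma * kt_md / (masses * dt))
        acc = acc + rng.standard_normal(positions.shape) * sigma[:, None]
        half = 0.5 * gamma * dt
        v_new = ((1.0 - half) * velocities + dt * acc) / (1.0 + half)
    else:
        v_new = velocities + dt * acc
    return positions + dt * v_new, v_new


def langevin_step(state: SubsystemState, forces: np.ndarray, topology: Topology,
                  dt: float, friction: float, temperature: float,
                  rng: np.random.Generator) -> SubsystemState:
    """One BBK Langevin step of a whole subsystem (no constraints)."""
    pos, vel = bbk_step(state.positions, state.velocities, forces,
                        topology.masses, dt, friction, temperature, rng)
    return SubsystemState(pos, vel, state.box, state.time + dt)


# ---------------------------------------------------------------------------
# constraints
#
# SHAKE is implemented in its matrix (coupled-multiplier) form: within each
# constrained fragment the Lagrange multipliers are solved together by
# Newton iteration, and fragments with identical structure (all the waters)
# are batched into one stacked linear solve.  The velocity constraints are
# linear, so RATTLE is a single exact solve.

_SOLVER_CACHE: dict = {}


class _BatchedConstraintSolver:
    """Per-fragment coupled constraint solver, batched over like fragments."""

    def __init__(self, pairs: np.ndarray, masses: np.ndarray):
        self.pairs = pairs
        # connected components of the constraint graph
        parent = {}

        def find(a):
            while parent.get(a, a) != a:
                parent[a] = parent.get(parent[a], parent[a])
                a = parent[a]
            return a

        for (i, j) in pairs:
            parent.setdefault(int(i), int(i))
            parent.setdefault(int(j), int(j))
            ri, rj = find(int(i)), find(int(j))
            if ri != rj:
                parent[ri] = rj
        comp_of = {a: find(a) for a in parent}
        comp_cons: dict[int, list[int]] = {}
        for c, (i, j) in enumerate(pairs):
            comp_cons.setdefault(comp_of[int(i)], []).append(c)

        # group components by identical local structure and masses
        batches: dict[tuple, list[list[int]]] = {}
        for cons in comp_cons.values():
            atoms = sorted({int(a) for c in cons for a in pairs[c]})
            local = {a: k for k, a in enumerate(atoms)}
            sig = (tuple((local[int(pairs[c][0])], local[int(pairs[c][1])])
                         for c in cons),
                   tuple(float(masses[a]) for a in atoms))
            batches.setdefault(sig, []).append(cons)

        self.batches = []
        for (local_pairs, local_masses), groups in batches.items():
            m = len(local_pairs)
            invm = 1.0 / np.asarray(local_masses)
            # sign of atom a in constraint c (+1 first, -1 second, 0 absent)
            n_local = len(local_masses)
            sign = np.zeros((n_local, m))
            for c, (li, lj) in enumerate(local_pairs):
                sign[li, c] = 1.0
                sign[lj, c] = -1.0
            # K[c, c']: how multiplier c' moves bond vector c (per rref unit)
            K = np.empty((m, m))
            for c, (li, lj) in enumerate(local_pairs):
                K[c] = invm[li] * sign[li] - invm[lj] * sign[lj]
            S = sign * invm[:, None]  # atom-update weights
            atom_idx = np.array([[sorted({int(a) for c in cons
                                          for a in pairs[c]})[k]
                                  for k in range(n_local)] for cons in groups])
            con_idx = np.array(groups)  # (B, m) global constraint indices
            self.batches.append((con_idx, atom_idx, K, S))

    def shake(self, positions, reference, lengths, tol, max_iter):
        pos = positions.copy()
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        for _ in range(max_iter):
            d = pos[i] - pos[j]
            dev = np.abs(np.sqrt(np.einsum("ij,ij->i", d, d)) - lengths)
            if dev.max() <= tol:
                return pos
            for con_idx, atom_idx, K, S in self.batches:
                gi = self.pairs[con_idx]          # (B, m, 2)
                rref = reference[gi[..., 0]] - reference[gi[..., 1]]
                dcur = pos[gi[..., 0]] - pos[gi[..., 1]]
                sigma = (np.einsum("bmk,bmk->bm", dcur, dcur)
                         - lengths[con_idx] ** 2)
                dots = np.einsum("bmk,bnk->bmn", dcur, rref)
                jac = 2.0 * dots * K[None, :, :]
                lam = np.linalg.solve(jac, -sigma[..., None])[..., 0]
                pos[atom_idx] += np.einsum("am,bmk->bak", S,
                                           lam[:, :, None] * rref)
        raise ConstraintError("SHAKE did not converge")

    def rattle(self, positions, velocities, tol, max_iter):
        vel = velocities.copy()
        for con_idx, atom_idx, K, S in self.batches:
            gi = self.pairs[con_idx]
            d = positions[gi[..., 0]] - positions[gi[..., 1]]
            rv = np.einsum("bmk,bmk->bm",
                           vel[gi[..., 0]] - vel[gi[..., 1]], d)
            dots = np.einsum("bmk,bnk->bmn", d, d)
            jac = dots * K[None, :, :]
            mu = np.linalg.solve(jac, -rv[..., None])[..., 0]
            vel[atom_idx] += np.einsum("am,bmk->bak", S,
                                       mu[:, :, None] * d)
        return vel


def _solver_for(pairs: np.ndarray,
                masses: np.ndarray) -> _BatchedConstraintSolver:
    key = (pairs.tobytes(), masses.tobytes())
    solver = _SOLVER_CACHE.get(key)
    if solver is None:
        solver = _BatchedConstraintSolver(pairs, masses)
        _SOLVER_CACHE[key] = solver
    return solver


def shake(positions: np.ndarray, reference: np.ndarray, pairs: np.ndarray,
          lengths: np.ndarray, masses: np.ndarray, tol: float = 1e-10,
          max_iter: int = 100) -> np.ndarray:
    """Project positions onto the constraint manifold (matrix SHAKE).

    ``reference`` supplies the pre-step bond directions along which the
    Lagrange corrections act.  Convergence is the worst absolute deviation
    |r_ij| − d_ij in Å.
    """
    if pairs.shape[0] == 0:
        return positions
    return _solver_for(pairs, masses).shake(positions, reference, lengths,
                                            tol, max_iter)


def rattle(positions: np.ndarray, velocities: np.ndarray, pairs: np.ndarray,
           masses: np.ndarray, tol: float = 1e-10,
           max_iter: int = 100) -> np.ndarray:
    """Remove velocity components along constrained bonds (exact RATTLE)."""
    if pairs.shape[0] == 0:
        return velocities
    return _solver_for(pairs, masses).rattle(positions, velocities,
                                             tol, max_iter)


def apply_constraints(state: SubsystemState, topology: Topology,
                      tol: float = 1e-10, max_iter: int = 500) -> SubsystemState:
    """SHAKE positions (self-referenced) and RATTLE velocities of a state."""
    pos = shake(state.positions, state.positions, topology.constraints,
                topology.constraint_lengths, topology.masses, tol, max_iter)
    vel = rattle(pos, state.velocities, topology.constraints,
                 topology.masses, tol, max_iter)
    return replace(state, positions=pos, velocities=vel)
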