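"""3D isotropic periodic sum (IPS) nonbonded energies and forces.

IPS replaces interactions with the remote region by interactions with
isotropic periodic images of the local region of radius ``Rc``, yielding a
purely pairwise analytic potential.  Pairwise-ness is what makes the
solute/solvent energy decomposition — and cheap recomputation of the same
conformation under several charge states — possible, which cutoff-free
lattice-sum methods (PME) cannot do without one reciprocal-space pass per
state.

The electrostatic IPS pair potential (for r ≤ Rc, zero beyond) is

    ke·qi·qj/r · (1 − 19/16·u + 35/16·u³ − 21/16·u⁵ + 5/16·u⁷),  u = r/Rc,

with zero total boundary energy under the neutral-charge assumption.  The
Lennard-Jones dispersion (−C/r⁶) and repulsion (A/r¹²) parts carry their own
IPS polynomials and the pair energy is shifted so it vanishes exactly at Rc;
a constant boundary term proportional to 4πRc³/(3V) is added to the total
energy (constant in NVT, no force).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_CONSTANT
from .topology import Topology

__all__ = [
    "NonbondedParams",
    "EnergyDecomposition",
    "NonbondedWorkspace",
    "ips_electrostatic_pair",
    "ips_lj_pair",
    "nonbonded_energy_forces",
    "multi_state_solute_energies",
]

# Electrostatic polynomial coefficients (u = r/Rc): 1 - a1 u + a3 u^3 - a5 u^5 + a7 u^7
_A1, _A3, _A5, _A7 = 19.0 / 16.0, 35.0 / 16.0, 21.0 / 16.0, 5.0 / 16.0

# Dispersion polynomial: -C/r^6 (1 + b6 u^6 + b8 u^8 + b10 u^10 + b12 u^12)
_B6, _B8, _B10, _B12 = 7.0 / 16.0, 9.0 / 14.0, -3.0 / 28.0, 6.0 / 7.0

# Repulsion polynomial: A/r^12 (1 + c12 u^12 + c16 u^16 + c20 u^20 + c24 u^24)
_C12, _C16, _C20, _C24 = 5.0 / 787.0, 9.0 / 26.0, -3.0 / 13.0, 27.0 / 26.0


@dataclass
class NonbondedParams:
    """Parameters of the IPS pair sums.

    ``lj_params`` maps unordered atom-type label pairs to ``(A, C)`` with A
    the r⁻¹² repulsion constant (kcal·Å¹²/mol) and C the r⁻⁶ dispersion
    constant (kcal·Å⁶/mol).  ``exclusions`` is a symmetric set of atom-index
    pairs removed from the pair sums.
    """

    cutoff: float
    coulomb_constant: float = COULOMB_CONSTANT
    lj_params: dict = field(default_factory=dict)
    exclusions: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff radius must be positive")
        for (i, j) in list(self.exclusions):
            self.exclusions.add((j, i))

    def lj_pair(self, type_i: str, type_j: str) -> tuple[float, float]:
        for key in ((type_i, type_j), (type_j, type_i)):
            if key in self.lj_params:
                return self.lj_params[key]
        return (0.0, 0.0)


@dataclass
class EnergyDecomposition:
    """Solute/solvent split of the nonbonded energy plus per-atom forces.

    ``e_solute`` is E_P = Σ_{a∈P} ½·(total pair energy of atom a): the full
    solute-solute term plus half of each solute-solvent cross term.
    ``e_solvent`` carries the other half of the cross terms plus all
    solvent-solvent terms, so e_solute + e_solvent is the full pair sum.
    ``e_boundary`` is the constant LJ IPS boundary energy of the box.
    """

    e_solute: float
    e_solvent: float
    e_boundary: float
    forces: np.ndarray

    @property
    def e_total(self) -> float:
        return self.e_solute + self.e_solvent + self.e_boundary


# ---------------------------------------------------------------------------
# scalar/array pair kernels (unit-strength factors)

def _ele_unit(r, rc):
    """Electrostatic energy/derivative per unit ke·qi·qj."""
    rc3, rc5, rc7 = rc**3, rc**5, rc**7
    r2 = r * r
    e = 1.0 / r - _A1 / rc + _A3 * r2 / rc3 - _A5 * r2 * r2 / rc5 + _A7 * r2 * r2 * r2 / rc7
    de = (-1.0 / r2 + 2.0 * _A3 * r / rc3 - 4.0 * _A5 * r * r2 / rc5
          + 6.0 * _A7 * r * r2 * r2 / rc7)
    return e, de


def _disp_unit(r, rc):
    """Dispersion energy/derivative per unit C (sign included)."""
    r2 = r * r
    e = -(1.0 / r**6 + _B6 / rc**6 + _B8 * r2 / rc**8
          + _B10 * r2 * r2 / rc**10 + _B12 * r2 * r2 * r2 / rc**12)
    de = -(-6.0 / r**7 + 2.0 * _B8 * r / rc**8
           + 4.0 * _B10 * r * r2 / rc**10 + 6.0 * _B12 * r * r2 * r2 / rc**12)
    return e, de


def _rep_unit(r, rc):
    """Repulsion energy/derivative per unit A."""
    r2 = r * r
    r4 = r2 * r2
    e = (1.0 / r**12 + _C12 / rc**12 + _C16 * r4 / rc**16
         + _C20 * r4 * r4 / rc**20 + _C24 * r4 * r4 * r4 / rc**24)
    de = (-12.0 / r**13 + 4.0 * _C16 * r * r2 / rc**16
          + 8.0 * _C20 * r * r2 * r4 / rc**20 + 12.0 * _C24 * r * r2 * r4 * r4 / rc**24)
    return e, de


def _disp_at_rc(rc: float) -> float:
    return -(1.0 + _B6 + _B8 + _B10 + _B12) / rc**6


def _rep_at_rc(rc: float) -> float:
    return (1.0 + _C12 + _C16 + _C20 + _C24) / rc**12


def ips_electrostatic_pair(r: float, qi: float, qj: float,
                           params: NonbondedParams) -> tuple[float, float]:
    """IPS electrostatic pair energy and radial force at separation ``r``.

    Returns ``(energy, force)`` in kcal/mol and kcal/mol/Å; the force is the
    negative radial derivative and both vanish identically beyond the
    cutoff.  Note the pair energy does *not* vanish at the cutoff — at
    r = Rc the polynomial factor equals 1 so the energy is ke·qi·qj/Rc; the
    total boundary electrostatic energy is zero only under the
    neutral-charge assumption.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    inside = r <= params.cutoff
    e, de = _ele_unit(np.where(inside, r, params.cutoff), params.cutoff)
    pref = params.coulomb_constant * qi * qj
    energy = np.where(inside, pref * e, 0.0)
    force = np.where(inside, -pref * de, 0.0)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def ips_lj_pair(r: float, A: float, C: float,
                params: NonbondedParams) -> tuple[float, float]:
    """IPS Lennard-Jones pair energy and radial force.

    The dispersion and repulsion IPS polynomials are evaluated and shifted
    by their value at Rc so the pair energy is exactly zero at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    rc = params.cutoff
    inside = r <= rc
    rs = np.where(inside, r, rc)
    ed, ded = _disp_unit(rs, rc)
    er, der = _rep_unit(rs, rc)
    energy = np.where(inside, A * (er - _rep_at_rc(rc)) + C * (ed - _disp_at_rc(rc)), 0.0)
    force = np.where(inside, -(A * der + C * ded), 0.0)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


# ---------------------------------------------------------------------------
# system-level pair sums

class NonbondedWorkspace:
    """Cached pair-sum machinery for one topology/box/parameter set.

    Precomputes the N×N Lennard-Jones parameter matrices, the exclusion
    mask and the constant LJ boundary energy; per call it builds
    minimum-image distances and evaluates the masked pair kernels with
    dense vectorized arithmetic (adequate for the few hundred atoms of the
    desk-scale systems this package targets).
    """

    def __init__(self, topology: Topology, params: NonbondedParams,
                 box: np.ndarray):
        box = np.asarray(box, dtype=float)
        if box.ndim == 0:
            box = np.repeat(box, 3)
        if np.any(box < 2.0 * params.cutoff):
            raise ValueError("every box edge must be at least 2·Rc")
        self.topology = topology
        self.params = params
        self.box = box
        n = topology.n_atoms
        self.A = np.zeros((n, n))
        self.C = np.zeros((n, n))
        labels = topology.type_labels
        uniq = sorted(set(labels))
        table = {(a, b): params.lj_pair(a, b) for a in uniq for b in uniq}
        for i in range(n):
            for j in range(n):
                self.A[i, j], self.C[i, j] = table[(labels[i], labels[j])]
        self.allowed = np.ones((n, n), dtype=bool)
        np.fill_diagonal(self.allowed, False)
        for (i, j) in params.exclusions:
            self.allowed[i, j] = False
            self.allowed[j, i] = False
        rc = params.cutoff
        # Eq-16-style boundary constant: 4πRc³/(3V) times the summed
        # per-pair boundary values over all distinct pairs (remote images
        # see every pair, so exclusions are not removed here).
        vol = float(np.prod(self.box))
        pair_mask = ~np.eye(n, dtype=bool)
        bnd_pairs = 0.5 * np.sum((self.A * _rep_at_rc(rc) + self.C * _disp_at_rc(rc))
                                 [pair_mask])
        self.e_boundary = 4.0 * np.pi * rc**3 / (3.0 * vol) * bnd_pairs
        self._sol = topology.solute_mask

    # -- geometry -----------------------------------------------------------
    def _pair_geometry(self, coords: np.ndarray):
        d = coords[:, None, :] - coords[None, :, :]
        d -= self.box * np.round(d / self.box)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        mask = self.allowed & (r2 <= self.params.cutoff**2)
        r = np.sqrt(np.where(mask, r2, 1.0))
        return d, r, mask

    def unit_electrostatic_matrix(self, coords: np.ndarray) -> np.ndarray:
        """ke·ε̂(r_ij) for every allowed pair inside the cutoff, else 0."""
        _, r, mask = self._pair_geometry(coords)
        e, _ = _ele_unit(r, self.params.cutoff)
        return np.where(mask, self.params.coulomb_constant * e, 0.0)

    def _lj_matrices(self, r, mask):
        rc = self.params.cutoff
        ed, ded = _disp_unit(r, rc)
        er, der = _rep_unit(r, rc)
        e = self.A * (er - _rep_at_rc(rc)) + self.C * (ed - _disp_at_rc(rc))
        de = self.A * der + self.C * ded
        return np.where(mask, e, 0.0), np.where(mask, de, 0.0)

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, coords: np.ndarray, charges: np.ndarray) -> EnergyDecomposition:
        """Energies (decomposed) and forces for one charge vector."""
        d, r, mask = self._pair_geometry(coords)
        rc = self.params.cutoff
        eu, deu = _ele_unit(r, rc)
        qq = charges[:, None] * charges[None, :]
        ke = self.params.coulomb_constant
        e_ele = np.where(mask, ke * qq * eu, 0.0)
        de_ele = np.where(mask, ke * qq * deu, 0.0)
        e_lj, de_lj = self._lj_matrices(r, mask)
        e_pair = e_ele + e_lj
        per_atom = e_pair.sum(axis=1)  # Σ_i ε_ai for each atom a
        e_p = 0.5 * float(per_atom[self._sol].sum())
        e_w = 0.5 * float(per_atom[~self._sol].sum())
        coef = -(de_ele + de_lj) / r          # radial force / r, masked already
        forces = np.einsum("ij,ijk->ik", coef, d)
        return EnergyDecomposition(e_solute=e_p, e_solvent=e_w,
                                   e_boundary=self.e_boundary, forces=forces)

    def solute_energies(self, coords: np.ndarray, charge_sets: np.ndarray,
                        changing_atoms: np.ndarray | None = None,
                        cross: str = "half") -> np.ndarray:
        """Per-state solute energies E_P for one shared conformation.

        The unit-charge interaction matrix and the (state-independent)
        solute LJ term are computed once and contracted against each
        state's charge vector, so adding states costs only matrix-vector
        products — the multi-state recomputation trick.

        ``cross`` selects the solute–solvent cross-term convention:
        "half" (default) assigns half of each cross pair to the solute,
        matching the solute/solvent split of :meth:`evaluate`; "full"
        charges the whole cross term to the solute, which is the
        convention the reweighting exponents and Bennett energy gaps
        need — the difference between a pure-state box and the
        mixed-charge box is the *entire* cross-term change, so half-split
        energies would halve every exponent.
        """
        if cross not in ("half", "full"):
            raise ValueError("cross must be 'half' or 'full'")
        charge_sets = np.atleast_2d(np.asarray(charge_sets, dtype=float))
        if changing_atoms is not None:
            changing = np.zeros(charge_sets.shape[1], dtype=bool)
            changing[np.asarray(changing_atoms, dtype=int)] = True
            if np.any(np.ptp(charge_sets, axis=0)[~changing] > 0):
                raise ValueError("charge sets differ outside changing_atoms")
        d, r, mask = self._pair_geometry(coords)
        ehat = np.where(mask, self.params.coulomb_constant
                        * _ele_unit(r, self.params.cutoff)[0], 0.0)
        e_lj, _ = self._lj_matrices(r, mask)
        sol = self._sol
        lj_rows = float(e_lj.sum(axis=1)[sol].sum())        # 2·ss + cross
        lj_ss = 0.5 * float(e_lj[np.ix_(sol, sol)].sum())   # ss once
        e_p_lj = 0.5 * lj_rows if cross == "half" else lj_rows - lj_ss
        out = np.empty(charge_sets.shape[0])
        ehat_ss = ehat[np.ix_(sol, sol)]
        for k, q in enumerate(charge_sets):
            rows = float((q * (ehat @ q))[sol].sum())       # 2·ss + cross
            if cross == "half":
                out[k] = e_p_lj + 0.5 * rows
            else:
                ss = 0.5 * float(q[sol] @ (ehat_ss @ q[sol]))
                out[k] = e_p_lj + rows - ss
        return out


def nonbonded_energy_forces(coords: np.ndarray, topology: Topology,
                            box, params: NonbondedParams,
                            charge_set: np.ndarray) -> EnergyDecomposition:
    """One-shot decomposition; see :class:`NonbondedWorkspace` for loops."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != topology.n_atoms:
        raise ValueError("coordinate count does not match topology")
    ws = NonbondedWorkspace(topology, params, box)
    return ws.evaluate(coords, np.asarray(charge_set, dtype=float))


def multi_state_solute_energies(coords: np.ndarray, topology: Topology,
                                box, params: NonbondedParams,
                                charge_sets: np.ndarray,
                                changing_atoms=None) -> np.ndarray:
    """Per-state E_P for a shared conformation (one-shot convenience)."""
    ws = NonbondedWorkspace(topology, params, box)
    return ws.solute_energies(np.asarray(coords, dtype=float),
                              charge_sets, changing_atoms)
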