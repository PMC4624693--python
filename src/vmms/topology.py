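"""System topology: atoms, per-state charge sets, constraints, molecules.

A :class:`Topology` is a static description of one simulation box: atom
masses and type labels, the solute membership flags, the holonomic distance
constraints that keep rigid fragments rigid, and one charge vector per
chemical state of the solute.  Solvent charges are identical across states;
only solute atoms may change charge between states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Topology", "TitrationSite"]


@dataclass
class Topology:
    """Per-atom static description of a simulation box.

    Parameters
    ----------
    masses : (N,) array
        Atomic masses in amu, strictly positive.
    type_labels : sequence of str
        Atom type labels used to look up Lennard-Jones parameters.
    charge_sets : (n_states, N) array
        One charge vector (e) per chemical state.
    solute_mask : (N,) bool array
        True for solute atoms.  Charge sets may differ only on these.
    constraints : (M, 2) int array
        Constrained atom pairs.
    constraint_lengths : (M,) array
        Target distances in Å for each constrained pair.
    molecule_ids : (N,) int array
        Molecule membership; every atom belongs to exactly one molecule.
    """

    masses: np.ndarray
    type_labels: list[str]
    charge_sets: np.ndarray
    solute_mask: np.ndarray
    constraints: np.ndarray
    constraint_lengths: np.ndarray
    molecule_ids: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.charge_sets = np.atleast_2d(np.asarray(self.charge_sets, dtype=float))
        self.solute_mask = np.asarray(self.solute_mask, dtype=bool)
        self.constraints = np.asarray(self.constraints, dtype=int).reshape(-1, 2)
        self.constraint_lengths = np.asarray(self.constraint_lengths, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        n = self.n_atoms
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if len(self.type_labels) != n:
            raise ValueError("type_labels length mismatch")
        if self.charge_sets.shape[1] != n:
            raise ValueError("charge_sets shape mismatch")
        if self.solute_mask.shape != (n,) or self.molecule_ids.shape != (n,):
            raise ValueError("per-atom array shape mismatch")
        if self.constraints.shape[0] != self.constraint_lengths.shape[0]:
            raise ValueError("constraint arrays mismatch")
        # Charges may differ between states only on solute atoms.
        if self.charge_sets.shape[0] > 1:
            spread = np.ptp(self.charge_sets, axis=0)
            if np.any(spread[~self.solute_mask] > 0):
                raise ValueError("solvent charges must be identical across states")
        # Every constrained pair must live inside one molecule.
        if self.constraints.size:
            mi = self.molecule_ids[self.constraints[:, 0]]
            mj = self.molecule_ids[self.constraints[:, 1]]
            if np.any(mi != mj):
                raise ValueError("constraints must be intramolecular")

    @property
    def n_atoms(self) -> int:
        return self.masses.shape[0]

    @property
    def n_states(self) -> int:
        return self.charge_sets.shape[0]

    @property
    def solute_indices(self) -> np.ndarray:
        return np.flatnonzero(self.solute_mask)

    @property
    def solvent_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.solute_mask)

    def solvent_constraint_selection(self) -> np.ndarray:
        """Indices of constraints whose atoms are all solvent atoms."""
        if not self.constraints.size:
            return np.zeros(0, dtype=int)
        sol = self.solute_mask
        keep = ~(sol[self.constraints[:, 0]] | sol[self.constraints[:, 1]])
        return np.flatnonzero(keep)

    def with_charge_sets(self, charge_sets: np.ndarray) -> "Topology":
        """Copy of this topology with a different stack of charge sets."""
        return Topology(
            masses=self.masses,
            type_labels=list(self.type_labels),
            charge_sets=np.atleast_2d(np.asarray(charge_sets, dtype=float)),
            solute_mask=self.solute_mask,
            constraints=self.constraints,
            constraint_lengths=self.constraint_lengths,
            molecule_ids=self.molecule_ids,
        )

    def intramolecular_exclusions(self) -> set[tuple[int, int]]:
        """All intramolecular atom pairs, as a symmetric exclusion set.

        Rigid fragments (constrained waters, rigid toy solutes) have no
        meaningful internal nonbonded terms, so every pair inside one
        molecule is excluded from the pair sums.
        """
        excl: set[tuple[int, int]] = set()
        for mol in np.unique(self.molecule_ids):
            atoms = np.flatnonzero(self.molecule_ids == mol)
            for a in range(len(atoms)):
                for b in range(a + 1, len(atoms)):
                    i, j = int(atoms[a]), int(atoms[b])
                    excl.add((i, j))
                    excl.add((j, i))
        return excl


@dataclass
class TitrationSite:
    """One two-state ionizable site on the solute.

    The deprotonated state keeps the removed proton as a zero-charge dummy
    atom so both states have identical atom counts.  ``x_deprotonated`` is
    the site's current deprotonated molar fraction; when the site is
    implicit its atoms carry the fraction-mixed charges
    ``(1-x_D)·q_H + x_D·q_D``.
    """

    site_id: str
    atom_indices: np.ndarray
    protonated_charges: np.ndarray
    deprotonated_charges: np.ndarray
    pka_ref: float
    delta_g_ref: float
    x_deprotonated: float = 0.5
    explicit: bool = True
    dummy_atom: int | None = None  # topology index of the dummy hydrogen

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.protonated_charges = np.asarray(self.protonated_charges, dtype=float)
        self.deprotonated_charges = np.asarray(self.deprotonated_charges, dtype=float)
        if self.protonated_charges.shape != self.atom_indices.shape:
            raise ValueError("protonated charge array incongruent with atoms")
        if self.deprotonated_charges.shape != self.atom_indices.shape:
            raise ValueError("deprotonated charge array incongruent with atoms")
        if not 0.0 <= self.x_deprotonated <= 1.0:
            raise ValueError("x_deprotonated must lie in [0, 1]")
        if self.dummy_atom is not None:
            pos = np.flatnonzero(self.atom_indices == self.dummy_atom)
            if pos.size != 1 or self.deprotonated_charges[pos[0]] != 0.0:
                raise ValueError("dummy hydrogen must be a member atom with zero "
                                 "charge in the deprotonated state")
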