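import numpy as np
import pytest

from vmms.nonbonded import NonbondedParams
from vmms.topology import Topology


@pytest.fixture
def two_atom_system():
    """One solute atom and one solvent atom, charges only, huge box."""
    topo = Topology(
        masses=np.array([12.0, 16.0]),
        type_labels=["A", "B"],
        charge_sets=np.array([[1.0, -0.5]]),
        solute_mask=np.array([True, False]),
        constraints=np.zeros((0, 2), dtype=int),
        constraint_lengths=np.zeros(0),
        molecule_ids=np.array([0, 1]),
    )
    params = NonbondedParams(cutoff=9.0)
    box = np.array([40.0, 40.0, 40.0])
    coords = np.array([[10.0, 10.0, 10.0], [13.0, 10.0, 10.0]])
    return topo, params, box, coords


def random_system(seed: int, n_atoms: int = 20, n_states: int = 2,
                  lj: bool = True):
    """Random unconstrained mixed solute/solvent system for oracle tests."""
    rng = np.random.default_rng(seed)
    box = np.array([18.0, 18.0, 18.0])
    coords = rng.random((n_atoms, 3)) * box
    solute = np.zeros(n_atoms, dtype=bool)
    solute[: n_atoms // 2] = True
    charges = rng.uniform(-0.8, 0.8, size=(n_states, n_atoms))
    charges[:, ~solute] = charges[0, ~solute]  # solvent identical across states
    labels = ["X" if s else "Y" for s in solute]
    topo = Topology(
        masses=np.full(n_atoms, 10.0),
        type_labels=labels,
        charge_sets=charges,
        solute_mask=solute,
        constraints=np.zeros((0, 2), dtype=int),
        constraint_lengths=np.zeros(0),
        molecule_ids=np.arange(n_atoms),
    )
    lj_params = {}
    if lj:
        lj_params = {("X", "X"): (6.0e4, 300.0), ("X", "Y"): (5.0e4, 250.0),
                     ("Y", "Y"): (4.0e4, 200.0)}
    params = NonbondedParams(cutoff=6.0, lj_params=lj_params)
    return topo, params, box, coords
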