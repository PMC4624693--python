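"""Self-contained toy systems and analytic oracles.

Every fixture is generated programmatically and seeded, so the rest of the
package is testable without external data: the charge-exaggerated
water-in-water model solution used to validate ensemble reweighting, rigid
titratable mini-solutes with one or two ionizable sites (the removed proton
kept as a zero-charge dummy so both states share an atom count), and a
two-well harmonic system whose free-energy difference has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import kT
from .free_energy import FreeEnergySamples
from .nonbonded import NonbondedParams
from .topology import TitrationSite, Topology

__all__ = [
    "ToySystemSpec",
    "HarmonicTwoState",
    "build_model_hoh_solution",
    "build_harmonic_two_state",
    "build_toy_titratable_solute",
    "WATER_OH", "WATER_HH",
]

# rigid 3-site water geometry: 0.9572 Å O-H, 104.52° H-O-H
WATER_OH = 0.9572
WATER_HH = 2.0 * WATER_OH * np.sin(np.deg2rad(104.52) / 2.0)

# TIP3P-like oxygen Lennard-Jones well (kcal/mol, Å)
_O_EPS, _O_SIGMA = 0.1521, 3.15066

MASS = {"O": 15.9994, "H": 1.008, "C": 12.011}

#: heavy-atom exclusion radius for solvent placement (Å)
PLACEMENT_EXCLUSION = 2.4


def _lj_constants(eps: float, sigma: float) -> tuple[float, float]:
    return 4.0 * eps * sigma**12, 4.0 * eps * sigma**6


def lj_table(type_params: dict[str, tuple[float, float]]) -> dict:
    """A/C table over all type pairs via Lorentz–Berthelot combination.

    ``type_params`` maps a type label to (epsilon, sigma); labels missing
    from the map get no Lennard-Jones interaction.
    """
    table = {}
    items = list(type_params.items())
    for i, (ti, (ei, si)) in enumerate(items):
        for tj, (ej, sj) in items[i:]:
            eps = np.sqrt(ei * ej)
            sig = 0.5 * (si + sj)
            table[(ti, tj)] = _lj_constants(eps, sig)
    return table


@dataclass
class ToySystemSpec:
    """A generated system: topology, coordinates, box, and parameters."""

    topology: Topology
    positions: np.ndarray
    box: np.ndarray
    params: NonbondedParams
    sites: list[TitrationSite] = field(default_factory=list)
    base_charges: np.ndarray | None = None
    note: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float) * np.ones(3)
        if self.positions.shape != (self.topology.n_atoms, 3):
            raise ValueError("coordinate count does not match topology")


# ---------------------------------------------------------------------------
# water helpers

def _water_template() -> np.ndarray:
    half = np.deg2rad(104.52) / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [WATER_OH * np.sin(half), WATER_OH * np.cos(half), 0.0],
        [-WATER_OH * np.sin(half), WATER_OH * np.cos(half), 0.0],
    ])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _min_image_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def place_waters(n_water: int, box: np.ndarray, rng: np.random.Generator,
                 fixed_heavy: np.ndarray | None = None,
                 exclusion: float = PLACEMENT_EXCLUSION,
                 max_tries: int = 20000) -> np.ndarray:
    """Random insertion of rigid waters under the heavy-atom exclusion rule.

    A trial water is rejected whenever its oxygen sits within ``exclusion``
    Å (minimum image) of any solute atom or previously placed oxygen.
    """
    box = np.asarray(box, dtype=float) * np.ones(3)
    placed_o: list[np.ndarray] = []
    coords = np.zeros((3 * n_water, 3))
    template = _water_template()
    tries = 0
    w = 0
    while w < n_water:
        tries += 1
        if tries > max_tries:
            raise ValueError("box too small for requested solvent count")
        o = rng.random(3) * box
        probes = np.vstack(placed_o) if placed_o else np.zeros((0, 3))
        if fixed_heavy is not None and fixed_heavy.size:
            probes = np.vstack([probes, fixed_heavy])
        if probes.size and np.any(_min_image_dist(o[None, :], probes, box)
                                  < exclusion):
            continue
        rot = _random_rotation(rng)
        coords[3 * w:3 * w + 3] = o + template @ rot.T
        placed_o.append(o)
        w += 1
    return coords


def _water_constraints(first_atom: int) -> tuple[np.ndarray, np.ndarray]:
    o, h1, h2 = first_atom, first_atom + 1, first_atom + 2
    pairs = np.array([[o, h1], [o, h2], [h1, h2]])
    lengths = np.array([WATER_OH, WATER_OH, WATER_HH])
    return pairs, lengths


# ---------------------------------------------------------------------------
# the model HOH solution

def build_model_hoh_solution(n_solvent: int = 10, box_edge: float = 15.55,
                             cutoff: float = 7.5, seed: int = 2024) -> ToySystemSpec:
    """One water solute in a small box of charge-scaled waters.

    The solute water carries exaggerated two-state charges — state 0:
    q_O = +2.64 e, q_H1 = 0, q_H2 = −0.64 e (net +2 e); state 1:
    q_O = −2.64 e, q_H1 = +0.64 e, q_H2 = 0 (net −2 e) — while the solvent
    charges are scaled to q_O = −0.0834 e, q_H = +0.0417 e so the two
    states have visibly distinct energy distributions at 300 K.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    box = np.array([box_edge] * 3)
    n_atoms = 3 * (1 + n_solvent)
    labels = ["OW", "HW", "HW"] * (1 + n_solvent)
    masses = np.array([MASS["O"], MASS["H"], MASS["H"]] * (1 + n_solvent))
    mol_ids = np.repeat(np.arange(1 + n_solvent), 3)
    solute_mask = np.zeros(n_atoms, dtype=bool)
    solute_mask[:3] = True

    q0 = np.empty(n_atoms)
    q1 = np.empty(n_atoms)
    q0[:3] = [2.64, 0.0, -0.64]
    q1[:3] = [-2.64, 0.64, 0.0]
    solvent_q = np.tile([-0.0834, 0.0417, 0.0417], n_solvent)
    q0[3:] = solvent_q
    q1[3:] = solvent_q

    solute_pos = 0.5 * box + _water_template() - _water_template().mean(axis=0)
    solvent_pos = place_waters(n_solvent, box, rng,
                               fixed_heavy=solute_pos)
    positions = np.vstack([solute_pos, solvent_pos])

    pairs, lengths = [], []
    for mol in range(1 + n_solvent):
        p, l = _water_constraints(3 * mol)
        pairs.append(p)
        lengths.append(l)
    topo = Topology(masses=masses, type_labels=labels,
                    charge_sets=np.vstack([q0, q1]),
                    solute_mask=solute_mask,
                    constraints=np.vstack(pairs),
                    constraint_lengths=np.concatenate(lengths),
                    molecule_ids=mol_ids)
    params = NonbondedParams(cutoff=cutoff,
                             lj_params=lj_table({"OW": (_O_EPS, _O_SIGMA)}),
                             exclusions=topo.intramolecular_exclusions())
    return ToySystemSpec(topology=topo, positions=positions, box=box,
                         params=params,
                         note="model HOH solution; exaggerated two-state "
                              "solute charges in 0.1x-charge water")


# ---------------------------------------------------------------------------
# harmonic two-state analytic system

@dataclass
class HarmonicTwoState:
    """Two isotropic harmonic wells sharing one conformation.

    State j has energy E_j = ½·k_j·|x|²; the mixed (virtual-mixture)
    distribution at fractions x is Gaussian with spring Σ x_i·k_i, so
    exact samples can be drawn and ΔG01 = (d/2)·kT·ln(k1/k0) in closed
    form.
    """

    k0: float
    k1: float
    dimensions: int = 3
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.k0 <= 0 or self.k1 <= 0:
            raise ValueError("spring constants must be positive")

    @property
    def springs(self) -> np.ndarray:
        return np.array([self.k0, self.k1])

    def exact_delta_g(self) -> float:
        return 0.5 * self.dimensions * kT(self.temperature) * np.log(self.k1 / self.k0)

    def sample_vmms(self, n_samples: int, fractions,
                    rng: np.random.Generator) -> FreeEnergySamples:
        """Exact draws from the mixture distribution at fixed fractions."""
        x = np.asarray(fractions, dtype=float)
        k_mix = float(x @ self.springs)
        sigma = np.sqrt(kT(self.temperature) / k_mix)
        conf = rng.standard_normal((n_samples, self.dimensions)) * sigma
        r2 = np.einsum("ij,ij->i", conf, conf)
        e = 0.5 * np.outer(r2, self.springs)
        return FreeEnergySamples(e_solute=e, fractions=x)

    def swapped(self) -> "HarmonicTwoState":
        return HarmonicTwoState(self.k1, self.k0, self.dimensions,
                                self.temperature)


def build_harmonic_two_state(k0: float, k1: float, dimensions: int = 3,
                             temperature: float = 300.0):
    """Harmonic two-state system plus its closed-form ΔG01."""
    sys = HarmonicTwoState(k0, k1, dimensions, temperature)
    return sys, sys.exact_delta_g()


# ---------------------------------------------------------------------------
# titratable toy solutes

def _single_site_solute():
    # 4-atom rigid acid: C-O-H(titrating) with one spectator hydrogen
    pos = np.array([
        [0.00, 0.00, 0.00],    # C
        [1.40, 0.00, 0.00],    # O
        [1.72, 0.90, 0.00],    # H (titrating; dummy when deprotonated)
        [-0.60, -0.60, 0.60],  # H (spectator)
    ])
    labels = ["CT", "OS", "HT", "HC"]
    masses = np.array([MASS["C"], MASS["O"], MASS["H"], MASS["H"]])
    q_h = np.array([0.15, -0.55, 0.40, 0.00])
    q_d = np.array([0.10, -0.90, 0.00, -0.20])
    pairs = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])
    site = dict(atoms=np.arange(4), q_h=q_h, q_d=q_d, dummy=2)
    return pos, labels, masses, [site], pairs


def _two_site_solute():
    # 5-atom rigid di-acid: central C with two O-H arms, protons lifted
    # out of plane so the 9-constraint framework is non-degenerate
    pos = np.array([
        [0.00, 0.00, 0.00],    # C
        [1.40, 0.00, 0.00],    # O1
        [1.72, 0.85, 0.30],    # H1 (site 1)
        [-0.70, 1.21, 0.00],   # O2
        [-1.02, 2.06, -0.30],  # H2 (site 2)
    ])
    labels = ["CT", "OS", "HT", "OS", "HT"]
    masses = np.array([MASS["C"], MASS["O"], MASS["H"], MASS["O"], MASS["H"]])
    sites = [
        dict(atoms=np.array([1, 2]), q_h=np.array([-0.5, 0.4]),
             q_d=np.array([-1.1, 0.0]), dummy=2),
        dict(atoms=np.array([3, 4]), q_h=np.array([-0.5, 0.4]),
             q_d=np.array([-1.1, 0.0]), dummy=4),
    ]
    pairs = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3],
                      [0, 4], [1, 4], [3, 4]])
    return pos, labels, masses, sites, pairs


def build_toy_titratable_solute(seed: int, n_solvent: int = 10,
                                assigned_pka_ref: float | list = 7.0,
                                n_sites: int = 1, box_edge: float = 15.55,
                                cutoff: float = 7.5,
                                delta_g_ref: float | list = 0.0,
                                solvent_charge_scale: float = 0.1) -> ToySystemSpec:
    """Rigid titratable mini-solute in a small box of TIP3P-like water.

    The protonated solute is neutral and each deprotonation removes one
    proton charge (net −1 e per deprotonated site), with the proton kept
    as a zero-charge dummy atom.  ``assigned_pka_ref``/``delta_g_ref``
    anchor each site's reference chemistry (scalars are broadcast).
    Solvent oxygens respect the 2.4 Å heavy-atom exclusion at build time.

    Solvent charges are scaled by ``solvent_charge_scale`` (default 0.1).
    The solvent reorganization energy of a unit charge change — and hence
    the sample size the free-energy estimators need — grows with the
    square of the solvent charges; scaling them keeps desk-scale runs of
    a whole-charge deprotonation statistically convergent while retaining
    a genuine solvation response, the same device the charge-scaled model
    HOH solution uses.
    """
    if n_sites == 1:
        pos_s, labels_s, masses_s, raw_sites, cons_s = _single_site_solute()
    elif n_sites == 2:
        pos_s, labels_s, masses_s, raw_sites, cons_s = _two_site_solute()
    else:
        raise ValueError("toy solutes support 1 or 2 sites")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    box = np.array([box_edge] * 3)
    ns = len(labels_s)
    pos_s = pos_s - pos_s.mean(axis=0) + 0.5 * box

    n_atoms = ns + 3 * n_solvent
    labels = labels_s + ["OW", "HW", "HW"] * n_solvent
    masses = np.concatenate([masses_s,
                             np.tile([MASS["O"], MASS["H"], MASS["H"]], n_solvent)])
    mol_ids = np.concatenate([np.zeros(ns, dtype=int),
                              1 + np.repeat(np.arange(n_solvent), 3)])
    solute_mask = np.zeros(n_atoms, dtype=bool)
    solute_mask[:ns] = True

    # base charges: fully protonated solute + TIP3P water
    base = np.zeros(n_atoms)
    if n_sites == 1:
        base[:ns] = raw_sites[0]["q_h"]
    else:
        base[0] = 0.2  # scaffold carbon, state-independent
        for s in raw_sites:
            base[s["atoms"]] = s["q_h"]
    base[ns:] = solvent_charge_scale * np.tile([-0.834, 0.417, 0.417],
                                               n_solvent)

    pkas = np.broadcast_to(np.asarray(assigned_pka_ref, dtype=float),
                           (n_sites,))
    grefs = np.broadcast_to(np.asarray(delta_g_ref, dtype=float), (n_sites,))
    sites = [TitrationSite(site_id=f"site{i+1}",
                           atom_indices=s["atoms"],
                           protonated_charges=s["q_h"],
                           deprotonated_charges=s["q_d"],
                           pka_ref=float(pkas[i]),
                           delta_g_ref=float(grefs[i]),
                           dummy_atom=int(s["dummy"]))
             for i, s in enumerate(raw_sites)]

    # default explicit charge sets: the full 2^n_sites ladder in bit order
    from .protonation import StateLadder
    ladder = StateLadder(sites)
    charge_sets = ladder.charge_sets(base)

    heavy = pos_s[[i for i, l in enumerate(labels_s) if not l.startswith("H")]]
    solvent_pos = place_waters(n_solvent, box, rng, fixed_heavy=pos_s)
    positions = np.vstack([pos_s, solvent_pos])

    pairs = [cons_s]
    lengths = [np.linalg.norm(pos_s[cons_s[:, 0]] - pos_s[cons_s[:, 1]], axis=1)]
    for w in range(n_solvent):
        p, l = _water_constraints(ns + 3 * w)
        pairs.append(p)
        lengths.append(l)

    topo = Topology(masses=masses, type_labels=labels,
                    charge_sets=charge_sets, solute_mask=solute_mask,
                    constraints=np.vstack(pairs),
                    constraint_lengths=np.concatenate(lengths),
                    molecule_ids=mol_ids)
    params = NonbondedParams(
        cutoff=cutoff,
        lj_params=lj_table({"OW": (_O_EPS, _O_SIGMA),
                            "OS": (_O_EPS, _O_SIGMA),
                            "CT": (0.10, 3.4)}),
        exclusions=topo.intramolecular_exclusions())
    return ToySystemSpec(topology=topo, positions=positions, box=box,
                         params=params, sites=sites, base_charges=base,
                         note=f"{n_sites}-site rigid titratable toy solute "
                              f"with {n_solvent} TIP3P-like waters")
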