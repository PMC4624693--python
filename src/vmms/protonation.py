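"""Protonation equilibrium: chemical potentials, molar fractions, pKa.

At a given pH, the standard chemical-potential difference for a
deprotonation i→j is

    Δμ⁰_ij = ΔG_ij − kT·(pH − pKa_ref)·ln10 − ΔG_ref,

anchoring the simulated free-energy difference to a model compound whose
experimental pKa and simulated deprotonation ΔG_ref absorb every
contribution (bond breaking, the proton's own chemistry) that the
classical simulation cannot provide.  Equilibrium molar fractions follow
from equal chemical potentials, μ_i = μ_i⁰ + kT·ln x_i, and pKa is read
either from the titration midpoint x_H = x_D or directly from an
equal-molar run via pKa = pKa_ref + (ΔG − ΔG_ref)/(kT·ln10).

Multi-site solutes enumerate 2^k explicit protonation microstates on a
:class:`StateLadder`; with many sites only k at a time are explicit and
the remaining sites carry fraction-mixed implicit charges
q = (1−x_D)·q_H + x_D·q_D, cycled round-robin by the VMMS-k scheduler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import logsumexp, softmax

from .constants import LN10, kT
from .free_energy import LocalAverager, FreeEnergySamples, solve_bennett
from .topology import TitrationSite

__all__ = [
    "StateLadder",
    "deprotonation_delta_mu0",
    "equilibrium_molar_fractions",
    "pka_from_fractions",
    "pka_equal_molar",
    "implicit_site_charges",
    "vmms_k_scheduler",
    "titration_curve",
    "MolarFractionController",
    "FRACTION_FLOOR",
]

#: floor applied to molar fractions before logarithms / force weights
FRACTION_FLOOR = 1e-6


def deprotonation_delta_mu0(delta_g: float, ph: float, pka_ref: float,
                            delta_g_ref: float, temperature: float) -> float:
    """Standard chemical-potential difference of one deprotonation."""
    return delta_g - kT(temperature) * (ph - pka_ref) * LN10 - delta_g_ref


def equilibrium_molar_fractions(delta_mu0_matrix: np.ndarray,
                                temperature: float,
                                antisym_tol: float = 1e-8) -> np.ndarray:
    """Molar fractions from the pairwise Δμ⁰ matrix.

    x_k = [Σ_j exp(−Δμ⁰_kj/kT)]⁻¹ / Σ_i [Σ_j exp(−Δμ⁰_ij/kT)]⁻¹, which for
    two states reduces exactly to the Boltzmann ratio
    x₁/x₀ = exp(−Δμ⁰₀₁/kT).  The matrix must be antisymmetric
    (Δμ⁰_ij = −Δμ⁰_ji) within tolerance.
    """
    m = np.asarray(delta_mu0_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("Δμ⁰ matrix must be square")
    if np.max(np.abs(m + m.T)) > antisym_tol:
        raise ValueError("Δμ⁰ matrix is not antisymmetric within tolerance")
    beta = 1.0 / kT(temperature)
    # row k: ln Σ_j exp(−β Δμ_kj); kept in log space to survive large Δμ
    log_row = logsumexp(-beta * m, axis=1)
    return softmax(-log_row)


def pka_from_fractions(ph: float, x_h: float, x_d: float,
                       floor: float = FRACTION_FLOOR) -> float:
    """pKa = pH + log₁₀(x_H/x_D) from one equilibrium composition."""
    x_h = max(float(x_h), floor)
    x_d = max(float(x_d), floor)
    return ph + np.log10(x_h / x_d)


def pka_equal_molar(delta_g: float, delta_g_ref: float, pka_ref: float,
                    temperature: float) -> float:
    """pKa from an equal-molar (x_H = x_D) VMMS free energy."""
    return pka_ref + (delta_g - delta_g_ref) / (kT(temperature) * LN10)


def implicit_site_charges(site: TitrationSite) -> np.ndarray:
    """Fraction-mixed charges (1 − x_D)·q_H + x_D·q_D for an implicit site."""
    x = site.x_deprotonated
    return (1.0 - x) * site.protonated_charges + x * site.deprotonated_charges


# ---------------------------------------------------------------------------
# explicit-state ladders

@dataclass
class StateLadder:
    """Enumeration of the 2^k protonation microstates of k explicit sites.

    State index s maps to per-site labels by its bits: bit b of s set means
    site ``explicit_sites[b]`` is deprotonated.  Enumeration order is the
    plain binary order, so it is deterministic.
    """

    explicit_sites: list[TitrationSite]
    fractions: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.fractions is None:
            self.fractions = np.full(self.n_states, 1.0 / self.n_states)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("ladder fractions must sum to 1")

    @property
    def k(self) -> int:
        return len(self.explicit_sites)

    @property
    def n_states(self) -> int:
        return 2 ** self.k

    def labels(self, state: int) -> tuple[int, ...]:
        """Per-site H/D labels of a microstate (1 = deprotonated)."""
        return tuple((state >> b) & 1 for b in range(self.k))

    def state_index(self, labels) -> int:
        return sum((1 << b) for b, lab in enumerate(labels) if lab)

    def charge_sets(self, base_charges: np.ndarray,
                    implicit_sites=()) -> np.ndarray:
        """One full charge vector per microstate.

        ``base_charges`` carries solvent and non-titrating solute charges;
        explicit sites are overwritten per microstate and implicit sites
        with their fraction-mixed charges.
        """
        base = np.asarray(base_charges, dtype=float).copy()
        for site in implicit_sites:
            base[site.atom_indices] = implicit_site_charges(site)
        out = np.tile(base, (self.n_states, 1))
        for s in range(self.n_states):
            for b, site in enumerate(self.explicit_sites):
                q = (site.deprotonated_charges if (s >> b) & 1
                     else site.protonated_charges)
                out[s, site.atom_indices] = q
        return out

    def fractions_from_sites(self) -> np.ndarray:
        """Product (independent-sites) initial fractions from per-site x_D."""
        x = np.empty(self.n_states)
        for s in range(self.n_states):
            p = 1.0
            for b, site in enumerate(self.explicit_sites):
                xd = site.x_deprotonated
                p *= xd if (s >> b) & 1 else (1.0 - xd)
            x[s] = p
        x = np.clip(x, FRACTION_FLOOR, None)
        return x / x.sum()

    def site_marginals(self, fractions: np.ndarray | None = None) -> np.ndarray:
        """Per-site deprotonated fraction marginalized over microstates."""
        f = self.fractions if fractions is None else np.asarray(fractions)
        out = np.zeros(self.k)
        for s in range(self.n_states):
            for b in range(self.k):
                if (s >> b) & 1:
                    out[b] += f[s]
        return out

    def reference_offsets(self, ph: float, temperature: float) -> np.ndarray:
        """θ_s = Σ_b bit_b(s)·(kT·(pH − pKa_ref_b)·ln10 + ΔG_ref_b).

        Pairwise Δμ⁰ between microstates assembles additively from these
        per-site terms: the reference part of Δμ⁰_ij is θ_j − θ_i.
        """
        per_site = np.array([kT(temperature) * (ph - site.pka_ref) * LN10
                             + site.delta_g_ref
                             for site in self.explicit_sites])
        theta = np.zeros(self.n_states)
        for s in range(self.n_states):
            for b in range(self.k):
                if (s >> b) & 1:
                    theta[s] += per_site[b]
        return theta


def vmms_k_scheduler(sites: list[TitrationSite], k: int, period: float,
                     equilibration: float, n_cycles: int = 1,
                     shuffle_seed: int | None = None):
    """Round-robin schedule of explicit-site subsets for a VMMS-k run.

    Yields ``(explicit_indices, ladder, equilibration, production)`` tuples;
    each subset is explicit for ``period`` ps of which ``equilibration`` ps
    are excluded from free-energy accumulation.  With ``k == len(sites)``
    the schedule is a single permanent window per cycle.  A shuffled order
    is available behind ``shuffle_seed`` for robustness testing.
    """
    m = len(sites)
    if not 1 <= k <= m:
        raise ValueError("explicit site count k out of range")
    if equilibration >= period:
        raise ValueError("equilibration must be shorter than the period")
    order = list(range(m))
    rng = None if shuffle_seed is None else np.random.default_rng(shuffle_seed)
    for _ in range(n_cycles):
        if rng is not None:
            rng.shuffle(order)
        groups = [order[i:i + k] for i in range(0, m, k)]
        for group in groups:
            explicit = [sites[i] for i in group]
            ladder = StateLadder(explicit)
            ladder.fractions = ladder.fractions_from_sites()
            yield tuple(group), ladder, equilibration, period - equilibration


def titration_curve(runs: dict):
    """pKa from a pH scan of equilibrium deprotonated fractions.

    ``runs`` maps pH → x_D (or (x_D, stderr)).  Returns a dict with the
    interpolated x_D = ½ crossing (``pka_midpoint``), a Henderson–
    Hasselbalch fit (``pka_hh``), and the curve table.  Raises if no pair
    of pH points brackets the half-deprotonation point.
    """
    ph = np.array(sorted(runs))
    vals = [runs[p] for p in ph]
    xd = np.array([v[0] if np.ndim(v) else v for v in vals], dtype=float)
    err = np.array([v[1] if np.ndim(v) else np.nan for v in vals], dtype=float)
    if ph.size < 2:
        raise ValueError("need at least two pH points")
    cross = np.nonzero(np.diff(np.sign(xd - 0.5)) != 0)[0]
    exact = np.nonzero(xd == 0.5)[0]
    if exact.size:
        pka_mid = float(ph[exact[0]])
    elif cross.size:
        i = cross[0]
        f = (0.5 - xd[i]) / (xd[i + 1] - xd[i])
        pka_mid = float(ph[i] + f * (ph[i + 1] - ph[i]))
    else:
        raise ValueError("no pH pair brackets x_D = 0.5")

    def hh(p, pka):
        return 1.0 / (1.0 + 10.0 ** (pka - p))

    popt, _ = curve_fit(hh, ph, xd, p0=[pka_mid])
    return {"pka_midpoint": pka_mid, "pka_hh": float(popt[0]),
            "ph": ph, "x_d": xd, "stderr": err}


# ---------------------------------------------------------------------------
# constant-pH molar-fraction dynamics

class MolarFractionController:
    """Updates ladder molar fractions from locally averaged free energies.

    At every update interval the controller estimates ΔG_0j for each
    microstate j against microstate 0 by the reweighted Bennett estimator
    on the interval's samples, pushes each through the exponential local
    average (window L), assembles the Δμ⁰ matrix (simulated ΔG plus the
    additive per-site reference terms) and solves for equilibrium molar
    fractions, floored at ``FRACTION_FLOOR`` and renormalized.
    """

    def __init__(self, ladder: StateLadder, ph: float, temperature: float,
                 window: int = 200, floor: float = FRACTION_FLOOR):
        self.ladder = ladder
        self.ph = ph
        self.temperature = temperature
        self.floor = floor
        self.averagers = [LocalAverager(window)
                          for _ in range(ladder.n_states - 1)]
        self.theta = ladder.reference_offsets(ph, temperature)

    def delta_g_smoothed(self) -> np.ndarray:
        """Current locally averaged ΔG_0j (j = 1..n−1); 0 for state 0."""
        return np.array([0.0] + [a.value if a.value is not None else 0.0
                                 for a in self.averagers])

    def update(self, records) -> np.ndarray:
        """Consume an interval's records; return the new molar fractions."""
        samples = FreeEnergySamples.from_records(records)
        n = self.ladder.n_states
        for j in range(1, n):
            avg = self.averagers[j - 1]
            c0 = avg.value if avg.value is not None else 0.0
            try:
                res = solve_bennett(samples, self.temperature, c01=c0,
                                    pair=(0, j))
                avg.push(res.delta_g)
            except (RuntimeError, ValueError):
                continue  # keep the previous local average
        g = self.delta_g_smoothed()
        phi = g - self.theta  # effective standard potential per microstate
        mu = phi[None, :] - phi[:, None]  # Δμ⁰_ij = φ_j − φ_i
        x = equilibrium_molar_fractions(mu, self.temperature)
        x = np.clip(x, self.floor, None)
        x = x / x.sum()
        self.ladder.fractions = x
        return x
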