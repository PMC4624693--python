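"""High-level simulation workflows.

These mirror the method's two-stage protocol: an *equal-molar* run at
fixed composition measures the deprotonation free energy (and hence the
reference ΔG of a model compound), then *constant-pH* runs let the molar
fractions evolve under the measured free energies until the titration
equilibrium emerges.  A VMMS-k driver cycles explicit-site subsets for
solutes with more titration sites than can be explicit at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import VMMSSimulation, StateEnergyRecord
from .free_energy import BennettResult, FreeEnergySamples, solve_bennett
from .protonation import (MolarFractionController, StateLadder,
                          vmms_k_scheduler)
from .toys import ToySystemSpec

__all__ = [
    "EqualMolarResult",
    "ConstantPHResult",
    "run_equal_molar",
    "run_constant_ph",
    "run_titration_scan",
    "run_vmms_k",
]


@dataclass
class EqualMolarResult:
    """ΔG estimates from a fixed-composition VMMS run."""

    bennett: dict              # state-pair -> BennettResult
    records: list
    n_steps: int

    def delta_g(self, pair=(0, 1)) -> BennettResult:
        return self.bennett[tuple(pair)]


@dataclass
class ConstantPHResult:
    """Molar-fraction dynamics of one constant-pH run."""

    fraction_history: np.ndarray    # (n_updates, n_states)
    times: np.ndarray               # fs, one per update
    ladder: StateLadder
    records: list

    def site_xd(self, burn_fraction: float = 0.5):
        """Production-average per-site deprotonated fractions and block
        standard errors (5 blocks over the production window)."""
        n = self.fraction_history.shape[0]
        start = int(burn_fraction * n)
        prod = self.fraction_history[start:]
        marg = np.array([self.ladder.site_marginals(f) for f in prod])
        mean = marg.mean(axis=0)
        blocks = np.array_split(marg, min(5, len(marg)), axis=0)
        bm = np.array([b.mean(axis=0) for b in blocks])
        se = bm.std(axis=0, ddof=1) / np.sqrt(len(blocks)) if len(blocks) > 1 \
            else np.full(mean.shape, np.nan)
        return mean, se


def _production_samples(records, burn_fraction: float) -> FreeEnergySamples:
    n = len(records)
    return FreeEnergySamples.from_records(records[int(burn_fraction * n):])


def run_equal_molar(spec: ToySystemSpec, n_steps: int,
                    temperature: float = 300.0, friction: float = 10.0,
                    dt: float = 1.0, seed: int = 0, record_every: int = 10,
                    burn_fraction: float = 0.2,
                    pairs=None) -> EqualMolarResult:
    """Fixed equal-molar VMMS run plus Bennett ΔG for the given pairs.

    Fractions stay uniform for the whole run; the first ``burn_fraction``
    of the record stream is discarded as equilibration before estimating
    ΔG (block-averaged standard errors from the remainder).
    """
    n_states = spec.topology.n_states
    x = np.full(n_states, 1.0 / n_states)
    sim = VMMSSimulation(spec.topology, spec.params, spec.box, spec.positions,
                         x, temperature=temperature, friction=friction,
                         dt=dt, seed=seed)
    records = sim.run(n_steps, record_every=record_every)
    samples = _production_samples(records, burn_fraction)
    if pairs is None:
        pairs = [(0, j) for j in range(1, n_states)]
    bennett = {tuple(p): solve_bennett(samples, temperature, pair=tuple(p))
               for p in pairs}
    return EqualMolarResult(bennett=bennett, records=records, n_steps=n_steps)


def run_constant_ph(spec: ToySystemSpec, ph: float, n_steps: int,
                    temperature: float = 300.0, friction: float = 10.0,
                    dt: float = 1.0, seed: int = 0, record_every: int = 10,
                    fraction_interval: int = 500, window: int = 200,
                    initial_fractions=None,
                    sim: VMMSSimulation | None = None,
                    controller: MolarFractionController | None = None,
                    ladder: StateLadder | None = None) -> ConstantPHResult:
    """Constant-pH VMMS run with molar-fraction dynamics.

    Every ``fraction_interval`` steps the interval's records are turned
    into Bennett ΔG estimates, locally averaged (window L), converted to
    Δμ⁰ at the given pH and solved for new equilibrium fractions that then
    reweight the solute forces.
    """
    if ladder is None:
        ladder = StateLadder(spec.sites)
    if initial_fractions is None:
        initial_fractions = np.full(ladder.n_states, 1.0 / ladder.n_states)
    if sim is None:
        sim = VMMSSimulation(spec.topology, spec.params, spec.box,
                             spec.positions, initial_fractions,
                             temperature=temperature, friction=friction,
                             dt=dt, seed=seed)
    if controller is None:
        controller = MolarFractionController(ladder, ph, temperature,
                                             window=window)
    n_updates = n_steps // fraction_interval
    history = np.empty((n_updates, ladder.n_states))
    times = np.empty(n_updates)
    all_records: list[StateEnergyRecord] = []
    for u in range(n_updates):
        recs = sim.run(fraction_interval, record_every=record_every)
        x = controller.update(recs)
        sim.set_fractions(x)
        history[u] = x
        times[u] = sim.subsystems[0].time
        all_records.extend(recs)
    return ConstantPHResult(fraction_history=history, times=times,
                            ladder=ladder, records=all_records)


def run_titration_scan(spec: ToySystemSpec, ph_values, n_steps: int,
                       seed: int = 0, site: int = 0,
                       **kwargs) -> dict:
    """Independent constant-pH runs over a pH grid.

    Returns ``{ph: (mean x_D, stderr)}`` for the selected site, suitable
    for :func:`vmms.protonation.titration_curve`.
    """
    out = {}
    for i, ph in enumerate(ph_values):
        res = run_constant_ph(spec, ph, n_steps,
                              seed=int(seed) + 1000 * (i + 1), **kwargs)
        mean, se = res.site_xd()
        out[float(ph)] = (float(mean[site]), float(se[site]))
    return out


def run_vmms_k(spec: ToySystemSpec, k: int, ph: float, period_steps: int,
               equil_steps: int, n_cycles: int, temperature: float = 300.0,
               friction: float = 10.0, dt: float = 1.0, seed: int = 0,
               record_every: int = 10, fraction_interval: int = 500,
               window: int = 200):
    """Cycled VMMS-k constant-pH run over all sites of ``spec``.

    Each scheduled segment makes one subset of k sites explicit (ladder of
    2^k subsystems, other sites carrying fraction-mixed implicit charges),
    equilibrates, then runs constant-pH fraction dynamics; on conversion
    back to implicit each explicit site freezes its marginal x_D.  The
    master conformation carries over between segments.  Returns the final
    sites and the per-site x_D history ``(site_index, time_fs, x_D)``.
    """
    sites = spec.sites
    positions = spec.positions.copy()
    history = []
    t_offset = 0.0
    segment = 0
    for group, ladder, _, _ in vmms_k_scheduler(
            sites, k, period=period_steps * dt / 1000.0,
            equilibration=equil_steps * dt / 1000.0, n_cycles=n_cycles):
        implicit = [s for i, s in enumerate(sites) if i not in group]
        charge_sets = ladder.charge_sets(spec.base_charges, implicit)
        topo = spec.topology.with_charge_sets(charge_sets)
        sim = VMMSSimulation(topo, spec.params, spec.box, positions,
                             ladder.fractions, temperature=temperature,
                             friction=friction, dt=dt,
                             seed=int(seed) + 7919 * (segment + 1))
        sim.run(equil_steps, record_every=equil_steps + 1)  # no records
        controller = MolarFractionController(ladder, ph, temperature,
                                             window=window)
        n_updates = max(1, (period_steps - equil_steps) // fraction_interval)
        for _ in range(n_updates):
            recs = sim.run(fraction_interval, record_every=record_every)
            x = controller.update(recs)
            sim.set_fractions(x)
            marg = ladder.site_marginals(x)
            for b, si in enumerate(group):
                history.append((si, t_offset + sim.subsystems[0].time,
                                float(marg[b])))
        # freeze marginals into the sites on explicit->implicit conversion
        marg = ladder.site_marginals()
        for b, si in enumerate(group):
            sites[si].x_deprotonated = float(marg[b])
        positions = sim.subsystems[0].positions.copy()
        t_offset += sim.subsystems[0].time
        segment += 1
    return sites, np.array(history, dtype=float)
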