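"""End-to-end validation studies.

Each function runs one self-contained study on the package's own toy
systems — reweighting equivalence against pure-state simulations, the
Bennett estimator against closed forms and the thermodynamic-integration
oracle, pKa self-consistency, explicit-site scheduling consistency, and
the mechanical contracts of the propagator — and returns a flat dict of
numbers.  The pytest acceptance suite and ``scripts/acceptance.py`` both
call these with sizes appropriate to their time budgets.
"""

from __future__ import annotations

import numpy as np

from . import toys
from .constants import COULOMB_CONSTANT, kT
from .core import VMMSSimulation, reweighted_average, simulate_pure_state
from .dynamics import bbk_step, kinetic_energy, subsystem_rng
from .free_energy import (ChargeInterpolatedSystem, FreeEnergySamples,
                          default_lambda_schedule, fermi, local_average,
                          solve_bennett, ti_reference_delta_g)
from .nonbonded import NonbondedParams, ips_electrostatic_pair, ips_lj_pair
from .protonation import (equilibrium_molar_fractions, pka_equal_molar,
                          pka_from_fractions, titration_curve)
from .runners import (run_constant_ph, run_equal_molar, run_titration_scan,
                      run_vmms_k)
from .topology import TitrationSite

__all__ = [
    "weighted_ks_statistic", "ks_critical",
    "reweighting_study", "harmonic_bennett_study", "bennett_vs_ti_study",
    "pka_self_consistency_study", "vmms_k_study", "mechanics_study",
    "formula_suite",
]


# ---------------------------------------------------------------------------
# statistics helpers

def weighted_ks_statistic(values: np.ndarray, weights: np.ndarray,
                          reference: np.ndarray) -> float:
    """Two-sample KS distance between a weighted and an unweighted sample."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    reference = np.asarray(reference, dtype=float)
    grid = np.sort(np.unique(np.concatenate([values, reference])))
    o = np.argsort(values)
    f1 = np.interp(grid, values[o], np.cumsum(weights[o]) / weights.sum(),
                   left=0.0)
    o2 = np.argsort(reference)
    f2 = np.interp(grid, reference[o2],
                   np.arange(1, reference.size + 1) / reference.size,
                   left=0.0)
    return float(np.abs(f1 - f2).max())


def ks_critical(n1_eff: float, n2_eff: float, alpha: float = 0.01) -> float:
    """Two-sample KS critical distance at level ``alpha``.

    Uses the asymptotic c(α)·√((n₁+n₂)/(n₁·n₂)) form with *effective*
    sample sizes, so correlated or importance-weighted streams are judged
    by the information they actually carry.
    """
    c = np.sqrt(-0.5 * np.log(alpha / 2.0))
    return float(c * np.sqrt((n1_eff + n2_eff) / (n1_eff * n2_eff)))


def _block_se(x: np.ndarray, n_blocks: int = 10) -> float:
    nb = min(n_blocks, len(x))
    if nb < 2:
        return np.inf
    means = np.array([b.mean() for b in np.array_split(x, nb)])
    return float(means.std(ddof=1) / np.sqrt(nb))


# ---------------------------------------------------------------------------
# studies

def reweighting_study(n_steps: int = 100000, seed: int = 0,
                      friction: float = 1.0, burn_fraction: float = 0.2,
                      record_every: int = 10,
                      decorrelate_every: int = 10) -> dict:
    """Reweighting equivalence on the model HOH solution.

    Runs VMMS at x = (½, ½) and one pure-state Langevin run per state,
    then compares the reweighted VMMS solute-energy distribution of each
    VMMS state against the matching pure-state distribution: weighted KS
    distance against an effective-sample-size-corrected 1% critical
    value, and reweighted means against pure means within combined
    standard errors.  ``decorrelate_every`` thins the record stream
    (records arrive every ``record_every`` steps) before the distribution
    comparison.
    """
    spec = toys.build_model_hoh_solution()
    topo = spec.topology
    sim = VMMSSimulation(topo, spec.params, spec.box, spec.positions,
                         [0.5, 0.5], friction=friction, seed=seed)
    records = sim.run(n_steps, record_every=record_every)
    burn = int(burn_fraction * len(records))
    e = np.array([r.e_solute for r in records])[burn:]
    w = np.array([r.weights for r in records])[burn:]
    out = {}
    for j in (0, 1):
        topo_j = topo.with_charge_sets(topo.charge_sets[j][None, :])
        _, energies = simulate_pure_state(
            topo_j, spec.params, spec.box, spec.positions,
            topo.charge_sets[j], n_steps, friction=friction,
            rng=subsystem_rng(seed + 1000 * (j + 1), 0),
            record_every=record_every)
        pure = np.array([x[0] for x in energies])[burn:]
        vals = e[:, j, j]
        wj = w[:, j]
        mean_rw, ess = reweighted_average(vals, wj)
        # delta-method standard error of a self-normalized importance-
        # sampling mean: weighted spread over the root effective sample
        # size (block scatter shares the weight tail and underestimates)
        wvar = float(np.sum(wj * (vals - mean_rw) ** 2) / np.sum(wj))
        se_rw = float(np.sqrt(wvar / max(ess, 1.0)))
        pure_mean = float(pure.mean())
        pure_se = _block_se(pure)
        sub = slice(None, None, decorrelate_every)
        d = weighted_ks_statistic(vals[sub], wj[sub], pure[sub])
        d_raw = weighted_ks_statistic(vals[sub], np.ones_like(vals[sub]),
                                      pure[sub])
        _, ess_sub = reweighted_average(vals[sub], wj[sub])
        crit = ks_critical(ess_sub, pure[sub].size)
        out.update({
            f"state{j}_raw_mean": float(vals.mean()),
            f"state{j}_reweighted_mean": mean_rw,
            f"state{j}_reweighted_se": se_rw,
            f"state{j}_pure_mean": pure_mean,
            f"state{j}_pure_se": pure_se,
            f"state{j}_ess": ess,
            f"state{j}_ks": d,
            f"state{j}_ks_raw": d_raw,
            f"state{j}_ks_critical_1pct": crit,
            f"state{j}_mean_sigma": abs(mean_rw - pure_mean)
            / np.hypot(se_rw, pure_se),
        })
    return out


def harmonic_bennett_study(n_samples: int = 10000, seed: int = 0) -> dict:
    """Bennett on harmonic two-state samples vs the closed form, plus
    estimator antisymmetry and three-state cycle closure.

    The sampling composition weights the *softer* well: a virtual-mixture
    sampler draws from the energy-mixed well k_mix = Σ x_i·k_i, and the
    reweighting factors to the softest state have finite variance only
    while k_mix < 2·k_min.  At the spring ratio e² an equal-molar mixture
    violates that bound and the estimator's tails dominate, so the study
    samples at x = (0.9, 0.1).
    """
    sys_, exact = toys.build_harmonic_two_state(1.0, np.e ** 2, 3, 300.0)
    samples = sys_.sample_vmms(n_samples, [0.9, 0.1],
                               np.random.default_rng(seed))
    res = solve_bennett(samples, 300.0)
    swapped = solve_bennett(
        sys_.swapped().sample_vmms(n_samples, [0.1, 0.9],
                                   np.random.default_rng(seed + 1)), 300.0)
    # three wells, composition again favouring the soft well
    springs = np.array([1.0, 2.0, 4.0])
    x = np.array([0.6, 0.25, 0.15])
    rng = np.random.default_rng(seed + 2)
    conf = rng.standard_normal((n_samples, 3)) * np.sqrt(
        kT(300.0) / float(x @ springs))
    r2 = np.einsum("ij,ij->i", conf, conf)
    cyc = FreeEnergySamples(0.5 * np.outer(r2, springs), x)
    g01 = solve_bennett(cyc, 300.0, pair=(0, 1))
    g12 = solve_bennett(cyc, 300.0, pair=(1, 2))
    g20 = solve_bennett(cyc, 300.0, pair=(2, 0))
    cycle = g01.delta_g + g12.delta_g + g20.delta_g
    cycle_se = float(np.sqrt(g01.stderr ** 2 + g12.stderr ** 2
                             + g20.stderr ** 2))
    return {
        "delta_g": res.delta_g, "stderr": res.stderr, "exact": float(exact),
        "error_sigma": abs(res.delta_g - exact) / res.stderr,
        "antisymmetry_dev": res.delta_g + swapped.delta_g,
        "antisymmetry_se": float(np.hypot(res.stderr, swapped.stderr)),
        "cycle_closure": cycle, "cycle_se": cycle_se,
    }


def bennett_vs_ti_study(n_steps: int = 80000, ti_steps: int = 6000,
                        seed: int = 0, n_solvent: int = 10) -> dict:
    """Equal-molar VMMS Bennett ΔG vs the TI oracle on the titratable toy."""
    spec = toys.build_toy_titratable_solute(seed=seed + 3,
                                            n_solvent=n_solvent)
    res = run_equal_molar(spec, n_steps, friction=10.0, seed=seed + 5)
    b = res.delta_g((0, 1))
    ti_sys = ChargeInterpolatedSystem(spec.topology, spec.params, spec.box,
                                      spec.positions, (0, 1), friction=10.0)
    dg_ti, se_ti = ti_reference_delta_g(ti_sys, default_lambda_schedule(),
                                        ti_steps, 300.0, seed + 9)
    comb = float(np.hypot(b.stderr, se_ti))
    return {
        "delta_g_bennett": b.delta_g, "stderr_bennett": b.stderr,
        "delta_g_ti": dg_ti, "stderr_ti": se_ti,
        "abs_difference": abs(b.delta_g - dg_ti),
        "combined_se": comb,
        "ess0": b.ess[0], "ess1": b.ess[1],
    }


def pka_self_consistency_study(seed: int = 0, n_ref_steps: int = 60000,
                               n_scan_steps: int = 25000,
                               pka_ref: float = 7.0,
                               ph_grid=(6.0, 6.5, 7.0, 7.5, 8.0)) -> dict:
    """Two-route pKa recovery for a toy site with an assigned reference.

    An equal-molar run defines ΔG_ref; an independent equal-molar run's
    ΔG converts through the equal-molar formula, and an independent
    constant-pH scan's titration midpoint is interpolated — both must
    land on the assigned reference pKa.
    """
    spec = toys.build_toy_titratable_solute(seed=seed + 3, n_solvent=10,
                                            assigned_pka_ref=pka_ref)
    ref = run_equal_molar(spec, n_ref_steps, friction=10.0, seed=seed + 101)
    b_ref = ref.delta_g((0, 1))
    ind = run_equal_molar(spec, n_ref_steps, friction=10.0, seed=seed + 202)
    b_ind = ind.delta_g((0, 1))
    pka_em = pka_equal_molar(b_ind.delta_g, b_ref.delta_g, pka_ref, 300.0)
    for s in spec.sites:
        s.delta_g_ref = b_ref.delta_g
    scan = run_titration_scan(spec, list(ph_grid), n_scan_steps,
                              seed=seed + 303, friction=10.0,
                              fraction_interval=250, window=20)
    curve = titration_curve(scan)
    return {
        "pka_assigned": pka_ref,
        "delta_g_ref": b_ref.delta_g, "delta_g_ref_se": b_ref.stderr,
        "delta_g_independent": b_ind.delta_g,
        "pka_equal_molar": pka_em,
        "pka_midpoint": curve["pka_midpoint"],
        "pka_hh": curve["pka_hh"],
        "equal_molar_error": abs(pka_em - pka_ref),
        "midpoint_error": abs(curve["pka_midpoint"] - pka_ref),
        "route_disagreement": abs(pka_em - curve["pka_midpoint"]),
        "scan": {p: v for p, v in scan.items()},
    }


def vmms_k_study(seed: int = 0, n_ref_steps: int = 40000,
                 n_steps: int = 30000, ph: float = 7.0,
                 period_steps: int = 2000, equil_steps: int = 500,
                 pka_refs=(6.5, 7.5)) -> dict:
    """Per-site pKas from full VMMS (k = 2) vs the VMMS-1 scheduler.

    A uniform-composition run anchors each site's ΔG_ref, then a
    constant-pH run with all 2² states explicit and a cycled one-explicit
    -site run must give consistent per-site pKas.
    """
    spec = toys.build_toy_titratable_solute(seed=seed + 11, n_solvent=10,
                                            n_sites=2,
                                            assigned_pka_ref=list(pka_refs))
    ref = run_equal_molar(spec, n_ref_steps, friction=10.0, seed=seed + 55,
                          pairs=[(0, 1), (0, 2)])
    spec.sites[0].delta_g_ref = ref.delta_g((0, 1)).delta_g
    spec.sites[1].delta_g_ref = ref.delta_g((0, 2)).delta_g

    full = run_constant_ph(spec, ph, n_steps, friction=10.0, seed=seed + 66,
                           fraction_interval=250, window=20)
    xd_full, se_full = full.site_xd()

    for s in spec.sites:
        s.x_deprotonated = 0.5
    n_cycles = max(2, n_steps // (2 * period_steps))
    _, hist = run_vmms_k(spec, k=1, ph=ph, period_steps=period_steps,
                         equil_steps=equil_steps, n_cycles=n_cycles,
                         friction=10.0, seed=seed + 77,
                         fraction_interval=250, window=10)
    out = {"ph": ph}
    for si in (0, 1):
        h = hist[hist[:, 0] == si][:, 2]
        half = h[len(h) // 2:]
        xd1 = float(half.mean())
        se1 = _block_se(half, 5)
        pka_full_si = pka_from_fractions(ph, 1 - xd_full[si], xd_full[si])
        pka_1_si = pka_from_fractions(ph, 1 - xd1, xd1)
        # propagate x_D uncertainty through the logistic link
        dpka_full = se_full[si] / (np.log(10) * max(
            xd_full[si] * (1 - xd_full[si]), 1e-3))
        dpka_1 = se1 / (np.log(10) * max(xd1 * (1 - xd1), 1e-3))
        out.update({
            f"site{si+1}_pka_full": float(pka_full_si),
            f"site{si+1}_pka_vmms1": float(pka_1_si),
            f"site{si+1}_se_full": float(dpka_full),
            f"site{si+1}_se_vmms1": float(dpka_1),
            f"site{si+1}_diff": float(abs(pka_full_si - pka_1_si)),
            f"site{si+1}_comb_se": float(np.hypot(dpka_full, dpka_1)),
        })
    return out


def mechanics_study(seed: int = 0, n_steps: int = 400,
                    nve_steps: int = 10000) -> dict:
    """Mechanical contracts of the propagator.

    Checks, on the model HOH solution: the per-record energy identity
    E^(j) − E(V_j) = E_P^(j) − Σ_i x_i E_P^(i); solute-coordinate
    identity across subsystems; the exactness of the Eq-29 solvent KE
    decrement; bit-identity of a one-state VMMS with plain Langevin; and
    the zero-friction energy drift of the integrator on a harmonic
    oscillator over ``nve_steps`` steps.
    """
    spec = toys.build_model_hoh_solution()
    topo = spec.topology
    sim = VMMSSimulation(topo, spec.params, spec.box, spec.positions,
                         [0.5, 0.5], friction=1.0, seed=seed)
    identity_dev = 0.0
    ke_dev = 0.0
    records = []
    for k in range(n_steps):
        rec = sim.step(collect=(k % 10 == 0))
        ke_dev = max(ke_dev,
                     float(np.abs(sim.last_deltas - sim.last_ke_drops).max()))
        if rec is not None:
            records.append(rec)
            lhs = rec.e_pure - rec.e_vmms
            rhs = np.diagonal(rec.e_solute) - rec.e_solute @ rec.fractions
            identity_dev = max(identity_dev, float(np.abs(lhs - rhs).max()))
    sol = topo.solute_indices
    solute_dev = float(np.abs(sim.subsystems[0].positions[sol]
                              - sim.subsystems[1].positions[sol]).max())

    topo1 = topo.with_charge_sets(topo.charge_sets[:1])
    sim1 = VMMSSimulation(topo1, spec.params, spec.box, spec.positions,
                          [1.0], friction=1.0, seed=seed + 7)
    sim1.run(n_steps, record_every=n_steps + 1)
    st, _ = simulate_pure_state(topo1, spec.params, spec.box, spec.positions,
                                topo1.charge_sets[0], n_steps, friction=1.0,
                                rng=subsystem_rng(seed + 7, 0),
                                record_every=n_steps + 1)
    bit_dev = float(max(np.abs(sim1.subsystems[0].positions - st.positions).max(),
                        np.abs(sim1.subsystems[0].velocities - st.velocities).max()))

    # zero-friction harmonic oscillator drift
    k_spring, mass = 1.0, 12.0
    pos = np.array([[1.0, 0.0, 0.0]])
    vel = np.zeros((1, 3))
    rng = np.random.default_rng(seed)
    energies = []
    for _ in range(nve_steps):
        f = -k_spring * pos
        pos, vel = bbk_step(pos, vel, f, np.array([mass]), 1.0, 0.0, 300.0,
                            rng)
        energies.append(kinetic_energy(vel, np.array([mass]))
                        + 0.5 * k_spring * float(pos[0] @ pos[0]))
    e = np.asarray(energies)
    drift = abs(e[-500:].mean() - e[:500].mean()) / e[:500].mean()

    return {
        "record_identity_max_dev": identity_dev,
        "solute_coordinate_max_dev": solute_dev,
        "ke_decrement_max_dev": ke_dev,
        "one_state_bit_identity_dev": bit_dev,
        "nve_relative_drift": float(drift),
        "weights_positive_finite": float(all(
            np.all(np.isfinite(r.weights)) and np.all(r.weights > 0)
            for r in records)),
    }


def formula_suite() -> dict:
    """Closed-form spot checks of the analytic building blocks."""
    params = NonbondedParams(cutoff=7.5)
    e_rc, _ = ips_electrostatic_pair(7.5, 1.0, 1.0, params)
    e_lj_rc, _ = ips_lj_pair(7.5, 5.0e5, 500.0, params)
    x = equilibrium_molar_fractions(np.zeros((4, 4)), 300.0)
    dm = kT(300.0) * np.log(2.0)
    two = equilibrium_molar_fractions(
        np.array([[0.0, dm], [-dm, 0.0]]), 300.0)
    site = TitrationSite(site_id="s", atom_indices=np.array([0, 1]),
                         protonated_charges=np.array([-0.5, 0.4]),
                         deprotonated_charges=np.array([-1.1, 0.0]),
                         pka_ref=7.0, delta_g_ref=0.0, x_deprotonated=0.25,
                         dummy_atom=1)
    from .protonation import implicit_site_charges
    q_mid = implicit_site_charges(site)
    impulse = 1.0
    for _ in range(10):
        impulse = local_average(impulse, 0.0, 200)
    return {
        "ips_ele_at_rc_times_rc_over_ke": e_rc * 7.5 / COULOMB_CONSTANT,
        "ips_lj_at_rc": e_lj_rc,
        "fractions_uniform_sum": float(x.sum()),
        "two_state_ratio_dev": float(two[1] / two[0] - 0.5),
        "pka_at_equal_fractions": pka_from_fractions(6.2, 0.3, 0.3),
        "implicit_charge_quarter": float(q_mid[0]),
        "impulse_response_dev": impulse - (1 - 1 / 200) ** 10,
        "fermi_at_zero": fermi(0.0),
    }
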