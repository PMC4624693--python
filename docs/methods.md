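# Methods

## The virtual mixture of multiple states (VMMS)

A solute with `n` chemical states (for constant-pH work: protonation
microstates, which differ only in atomic charges, with removed protons kept
as zero-charge dummy atoms so every state has the same atom count) is
represented by `n` simulation boxes ("subsystems"), one per state, each with
its own solvent.  All boxes share a single solute conformation.  State
populations are continuous molar fractions `x_1 … x_n` (Σx = 1), not
discrete hops: free energy differences between states are measured on the
fly and the fractions relax toward the equilibrium the measured chemical
potentials dictate.

Each box realizes the *VMMS state* `V_j`: its solvent interacts with the
**fraction-mixed** solute charge distribution `q_mix = Σ_i x_i q^(i)`.
Because solute–solvent interactions are linear in the solute charges, the
energy of a mixed-charge solute equals the fraction-weighted sum of the
per-state interaction energies, so each box's configurational density is
(to the accuracy of the force-mixing scheme below)
`∝ exp(−β(Σ_i x_i E_P^(i)(box j) + E_W^(j)))`.  The *pure* states — solute
carrying a single state's charges — are never simulated directly; they are
recovered by importance reweighting with

    w_j = exp(−β (E_P^(j) − Σ_i x_i E_P^(i)))      (all energies in box j)

so that `⟨A⟩_pure-j = ⟨A·w_j⟩_VMMS / ⟨w_j⟩_VMMS`.  Every reported
reweighted average carries a Kish effective sample size `(Σw)²/Σw²`;
consumers should treat results with small ESS as qualitative.  Exponents
are clamped at ±700 (dimensionless) with a warning.

**Solute-energy convention.**  The per-state solute energies used in the
weights and in the free-energy estimator carry the *full* solute–solvent
cross terms (`E_P = E_ss + E_cross`): the exponent above is the energy
difference between a pure-state box and the mixed box, which is the entire
cross-term change.  The `EnergyDecomposition` returned by the nonbonded
module still splits cross terms half/half between its solute and solvent
parts — that is a bookkeeping convention for box totals, selectable in
`NonbondedWorkspace.solute_energies(..., cross="half"|"full")`.

**Propagation.**  Per time step, forces in every box are evaluated with
`q_mix`.  The solute moves once — under the fraction-weighted combination
`f_a = Σ_j x_j f_a^(j)` of the per-box solute forces — in box 0, and its
coordinates/velocities are broadcast to all boxes (they agree to machine
precision at all times).  Each box's solvent moves under its own forces.
The extra work the combined solute forces do on box j,
`δ^(j) = Σ_{a∈solute} (f_a − f_a^(j))·v'_a·δt` (post-kick, pre-constraint
solute velocities), is removed from that box's solvent kinetic energy by
scaling all solvent velocities by `√(1 − δ^(j)/KE_W)`, which makes the KE
decrement exactly `δ^(j)`; a step aborts with an error if `δ ≥ KE_W`
(pathological force mismatch).  With one state, the whole machinery reduces
bit-for-bit to a plain Langevin run.

## Nonbonded interactions: 3D isotropic periodic sum (IPS)

Long-range interactions are represented by the 3D-IPS pair potentials:
remote interactions are replaced by isotropic periodic images of the local
region of radius `R_c`, giving closed-form pairwise polynomials for the
electrostatic, dispersion (−C/r⁶) and repulsion (A/r¹²) parts.  The
Lennard-Jones pair term is shifted to vanish exactly at `R_c`; a constant
boundary term `4πR_c³/(3V) × Σ_pairs (ε_disp(R_c)+ε_rep(R_c))` is added to
the box total (constant under NVT, no force).  The electrostatic boundary
energy is taken as zero under the neutral-charge assumption.  Pairwise-ness
is essential: it allows exact solute/solvent decomposition and cheap
recomputation of one conformation under many charge sets (a masked
unit-charge interaction matrix is built once per conformation and
contracted with each state's charge vector).

The repulsion polynomial's first image coefficient is implemented as 5/787;
the printed source of this coefficient is typographically ambiguous, so no
test or result relies on the repulsion polynomial's interior values — only
on the cutoff-shift contract and the analytic-derivative consistency of the
force.

Pair sums are dense O(N²) with minimum-image convention — appropriate for
the ≤ ~100-atom toys this package targets; box edges must be ≥ 2·R_c.
Exclusions: all intramolecular pairs (every fragment here is rigid, so
intramolecular nonbonded terms would be constants anyway).

Units: Å, fs, amu, elementary charge, kcal/mol;
ke = 332.0716 kcal·Å/(mol·e²), k_B = 0.0019872041 kcal/(mol·K).

## Dynamics

Leapfrog-form BBK Langevin integrator (velocities at half steps; friction
in 1/ps; zero friction reduces exactly to leapfrog, with the O((ωδt)²)
half-step energy oscillation handled in analyses by block averaging).
Holonomic constraints keep all fragments rigid: positions by matrix-SHAKE
(coupled Lagrange multipliers per fragment solved by Newton iteration,
fragments of identical structure batched into stacked 3×3/6×6/9×9 solves),
velocities by a single exact linear RATTLE solve.  Rigid three-site water:
O–H 0.9572 Å, H–O–H 104.52°, TIP3P-like oxygen Lennard-Jones
(ε = 0.1521 kcal/mol, σ = 3.15066 Å), hydrogens without LJ.  Center-of-mass
motion is not removed (Langevin noise keeps it bounded).  One RNG stream
per subsystem, keyed (master seed, subsystem index), so adding subsystems
never perturbs existing streams and runs are bit-reproducible.

## Free energies

Between two states sampled through a VMMS stream, ΔG comes from the
reweighted Bennett ratio

    ΔG01 = C01 − kT·ln [⟨f(β(ΔE₀ − C01)) w₀⟩⟨w₁⟩] / [⟨f(β(−ΔE₁ + C01)) w₁⟩⟨w₀⟩]

with `f(x) = 1/(1+eˣ)`, `ΔE_j` the state-1-minus-state-0 energy gap
evaluated on box j's configurations, and `w_j` the reweighting factors
above; all averages are computed in log space (logsumexp), so arbitrarily
large exponents are safe.  `C01` is iterated to the self-consistent point
`C01 = ΔG(C01)` (damping ½, tolerance 1e-6 kcal/mol, ≤200 iterations),
which is Bennett's minimum-variance choice.  Standard errors come from ten
contiguous blocks evaluated at the converged shift.  During a run, interval
estimates are smoothed by the exponential local average
`P̃_n = (1−1/L)·P̃_{n−1} + (1/L)·P_n`.

The independent oracle is thermodynamic integration over linearly
charge-interpolated states: `∂E/∂λ = Σ_ij q̇_i q_j(λ) ε̂_ij` sampled by
Langevin dynamics per λ window (20% of each window discarded as
equilibration, warm-started between windows), trapezoid quadrature, and
per-window block-averaged errors (trajectory samples are serially
correlated, so naive variances would be optimistic).  The default schedule
spaces windows uniformly to λ = 0.9 and five times finer beyond, where a
charging integrand curves most.  An analytic harmonic λ-system
(`(d/2)·kT·ln(k1/k0)` closed form) validates the TI machinery itself.

**Statistical regime.**  The reweighting exponent's scale is
`β·x_i·σ(ΔE)`, and `σ(ΔE) ≈ √(2·kT·λ_reorg)` is governed by the solvent
reorganization energy of the charge change — quadratic in the solvent
charges.  Estimates are reliable when `β·x·σ(ΔE) ≲ 1–2`; far beyond that
(the deliberately extreme model HOH solution reaches ≈ 5) the weights are
dominated by rare configurations, effective sample sizes collapse, and
reweighted distributions are noisy — which is why the toy systems for
*quantitative* free-energy work scale their solvent charges (see below).
A sharper, exactly analyzable form of the same phenomenon appears in the
harmonic system: sampling the energy-mixed well `k_mix = Σ x_i k_i` gives
reweighting factors to the softest state whose *second moment diverges*
once `k_mix ≥ 2·k_min`, so virtual-mixture compositions must weight soft
(broad) states heavily enough that the mixture remains broader than half
the broadest state.  Reported reweighted means carry delta-method errors
`σ_w/√ESS`, the standard formula for self-normalized importance sampling.

## Protonation equilibrium

At pH, a site's standard chemical-potential difference of deprotonation is

    Δμ⁰ = ΔG − kT·(pH − pKa_ref)·ln10 − ΔG_ref

anchored by a reference compound's experimental pKa and simulated ΔG_ref,
which absorb all contributions classical simulation cannot supply (bond
breaking, the proton's own chemistry).  Equilibrium fractions over any
state set follow from `x_k ∝ [Σ_j exp(−Δμ⁰_kj/kT)]⁻¹` (softmax in log
space), which reduces to the two-state ratio `x_D/x_H = exp(−Δμ⁰/kT)`.
pKa is read either from the titration midpoint `x_D(pH) = ½` (linear
interpolation of the scan plus a Henderson–Hasselbalch fit, both reported)
or directly from an equal-molar run via
`pKa = pKa_ref + (ΔG − ΔG_ref)/(kT·ln10)`.

Multi-site solutes enumerate `2^k` microstates on a bit-indexed ladder.
Pairwise Δμ⁰ between microstates is assembled additively from per-site
reference terms plus simulated ΔG's taken against microstate 0 (so cycle
consistency is built in); single-site flips are the primary observables.
With many sites, VMMS-k keeps k sites explicit at a time (round-robin, a
seeded shuffled order exists for robustness testing); implicit sites carry
the fraction-mixed charges `(1−x_D)q_H + x_D q_D`, and a site's `x_D`
freezes while implicit.  Between segments the master conformation carries
over, velocities are redrawn, and each segment's equilibration span is
excluded from accumulation.

During constant-pH runs the controller re-estimates ΔG from each update
interval's records (Bennett seeded with the previous smoothed value),
pushes it through the local average, and solves for new fractions, floored
at 1e-6 and renormalized before use as force-mixing weights.

### Cadences and defaults

| quantity | default | note |
| --- | --- | --- |
| temperature | 300 K | |
| time step | 1 fs | |
| friction | 10 /ps | 1 /ps for the HOH reweighting study |
| cutoff R_c | 7.5 Å | ≤ half the smallest box edge |
| weight/Fermi cadence | 10 fs | record stream |
| ΔG / fraction update | 0.5 ps | |
| local-average window L | 200 | production-scale smoothing |
| explicit-site period | 10 ps, first 2 ps equilibration | VMMS-k |

L = 200 with 0.5 ps updates implies a ~100 ps relaxation of the smoothed
ΔG — appropriate for nanosecond production runs.  The desk-scale studies
in this repository run 12–100 ps, so they shorten the update interval to
0.25 ps and the window to L = 10–20, keeping the same ~10% ratio of
smoothing time to run length.  Both are configuration parameters.

## Toy systems

* **Model HOH solution** — one water solute among 10 solvent waters in a
  15.55 Å cube, R_c = 7.5 Å.  Solute charges exaggerated to ±2.64 e sets
  (net +2 e / −2 e per state); solvent charges scaled to ∓0.0834/0.0417 e.
  Used for the reweighting-equivalence study; its exponent scale
  β·σ(u) ≈ 5 puts direct reweighting deliberately in the noise-dominated
  regime, so distribution comparisons are judged at ESS-corrected critical
  values.
* **Harmonic two-state system** — one particle in two isotropic wells,
  exact mixture sampling, closed form ΔG = (d/2)·kT·ln(k1/k0).  The
  implicit-solvent analog of the reweighting validation: here the mixture
  density is exact, so the Bennett estimator is tested free of dynamics.
* **Titratable toys** — rigid 4-atom (one site) or 5-atom (two sites)
  mini-acids, protonated form neutral, each deprotonation −1 e with the
  proton retained as a zero-charge dummy; solvated by rigid waters placed
  randomly under the 2.4 Å heavy-atom exclusion rule.  Solvent charges are
  scaled ×0.1 by default so that a whole-charge deprotonation's
  reorganization noise stays in the estimator-tractable regime at
  desk-scale run lengths (the same device the HOH model uses); the scale is
  a parameter.  Assigned pKa_ref values are arbitrary anchors — all pKa
  validations are *self*-consistency checks, not predictions of real
  compounds.

What the toys do **not** emulate: flexible solutes (no conformational
reweighting is exercised), realistic water (charge-scaled solvent
underestimates reorganization), ions/salt, tautomers, and system sizes
where cell lists or Ewald-class electrostatics would matter.  Passing
tests therefore demonstrate internal consistency of the machinery — the
estimator identities, the mechanics contracts, and the two-route pKa
agreement — not quantitative accuracy for real biomolecules.

## Numerical choices

* SHAKE tolerance 1e-10 Å, RATTLE exact; constraint fragments must be
  rigid or tree-like (the batched Newton solve requires a non-singular
  multiplier system).
* Bennett: damping 0.5, tol 1e-6 kcal/mol, max 200 iterations; 10-block
  standard errors; degenerate (all-weight-zero) intervals keep the
  previous smoothed value.
* Fraction floor 1e-6 before logarithms and force mixing.
* Titration-curve midpoint requires a bracketing pH pair; the
  Henderson–Hasselbalch fit is reported alongside.
* TI windows warm-start from the previous window and discard the first
  20% of each window.
* Trajectories are unwrapped; periodicity enters only through
  minimum-image distances.

## Validation studies and problem sizes

`scripts/acceptance.py` (and the mirrored pytest suite at smaller sizes)
runs: reweighting equivalence at 50 k steps of VMMS plus matched
pure-state runs; harmonic Bennett at 20 k samples; Bennett-vs-TI at 50 k
VMMS steps against a 15-window × 4 k-step TI; pKa self-consistency with
two independent 50 k-step equal-molar runs and a five-point constant-pH
scan at 16 k steps each; the two-site VMMS-1 vs VMMS-2 comparison at
24–25 k steps; the mechanics contracts; and the formula suite.  These
sizes were chosen so each statistical comparison has error bars several
times smaller than the quantity it checks, while a full pass completes on
one CPU core in well under half an hour.

## Known limitations

* The force-mixing scheme weights each box's solute force by its molar
  fraction; the resulting joint ensemble is canonical per box only up to
  a solute-marginal dressing from the other boxes (small for the rigid
  toys here, untested for flexible solutes).
* The IPS repulsion coefficient ambiguity above.
* Direct reweighting (and hence the HOH distribution comparison) is
  noise-dominated by construction in strongly reorganizing systems: at the
  HOH model's conditions the weights carry an effective sample size of
  order 1–10 per 10⁴–10⁵ records, so reweighted means there are reported
  but not reliable (the corresponding validation test documents this as a
  failing expectation rather than hiding it).  The Bennett ratio, whose
  Fermi functions bound the weight tails, is the quantitative tool and is
  validated against the closed-form and TI oracles.
* The equal-molar Bennett estimate samples only the mixed ensemble; its
  effective overlap with both end states degrades as β·x·σ(ΔE) grows.
* VMMS-k freezes implicit sites' fractions between explicit windows;
  strongly coupled sites may relax slowly under short periods.
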