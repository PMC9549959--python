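# Methods

This note records the models implemented in fepkit, the defaults and why
they were chosen, the numerical choices that matter, and what the toy
systems do and do not establish about production-scale calculations.

## Alchemical model

**Dual topology.** A hybrid molecule contains the union of the two
ligands' atoms. Atoms are classed `core` (present in both endpoints, two
parameter sets), `unique_old` (present only in A) and `unique_new` (only in
B). Unique atoms at their decoupled endpoint keep charge 0 and ε 0 but
retain σ, so softcore distances stay defined. Unique-new atoms are placed
by rigid least-squares (Kabsch) superposition of B's core onto A's core.
`unique_old`–`unique_new` pairs never interact. Bonded terms (harmonic
bonds) are λ-independent; bonds to dummy atoms are therefore spectators
whose contribution cancels between the two legs of the cycle but **does**
appear in single-leg endpoint energies — the endpoint-equivalence tests
account for this explicitly.

**Atom mapping.** The core is the maximum common connected induced
subgraph of the heavy-atom graphs (elements must match, bond order,
chirality and ring membership ignored), found by exact branch-and-bound;
hydrogens on mapped heavy atoms are paired afterwards in index order. Ties
between equal-size cores are broken by the smallest summed squared
inter-atom distance after superposition, then lexicographically, making
the mapping deterministic. The exact search is exponential in the worst
case but instant for lead-optimization-sized molecules; the test suite
checks it against an independent exhaustive enumeration on all catalogue
molecules.

**Softcore potentials.** Sterics:
`r_eff = σ(α(1−λ)^b + (r/σ)^c)^(1/c)`, `U = λ^a·4ε[(σ/r_eff)¹²−(σ/r_eff)⁶]`
with α=0.5, a=1, b=1, c=6. Electrostatics:
`r_eff = (β(1−λ)^e + r^f)^(1/f)`, `U = λ^d·k_e q₁q₂/r_eff` with β=0, d=1,
e=1, f=2 — at β=0 this is exactly linear scaling of the Coulomb energy, so
the system-level implementation scales per-atom effective charges
(core: q = q_A·λ_elec_delete + q_B·λ_elec_insert) and evaluates plain
Coulomb, which is equivalent and keeps the pair loop simple. Useful
closed forms: at λ=1 both reduce exactly to LJ/Coulomb; at λ=0 both vanish;
at full overlap U(r=0) = 4ελ[(α(1−λ))⁻² − (α(1−λ))⁻¹], e.g. 24ε at λ=½.

**λ-schedule.** Master λ is equally spaced over `n_windows` (default 12).
The default `two_phase` protocol switches all sterics (insert 0→1, delete
1→0) and removes the old charges over master λ ∈ [0, 0.5], then grows the
new charges over [0.5, 1]: sterics are entirely settled before the new
electrostatics switch on, and no charge ever acts on an atom without a
steric envelope. The split point is configurable; a `linear` protocol is
provided for comparison. All component trajectories are monotone and the
end states are exactly the pure molecules.

**Nonbonded conventions.** Lorentz–Berthelot combining, minimum-image
cubic periodic boxes, spherical cutoff (default 1.0 nm) with plain
truncation and no long-range or shift corrections — adequate for toy
fluids, a documented divergence from Ewald-based production setups. The
box edge must exceed twice the cutoff; construction enforces it.

## Sampling

**Langevin dynamics** uses the BAOAB splitting, chosen for its small
configurational sampling bias at large timesteps; with friction → 0 and
temperature → 0 it reduces to velocity Verlet. Units follow the GROMACS
convention (nm, ps, amu, kJ/mol) in which no unit conversion constants
enter the integrator. Default friction 1/ps (5/ps in the toy-leg driver,
where tight thermostatting shortens equilibration); the friction value is
a free parameter the reference protocol does not pin down.

**Hydrogen mass repartitioning** sets every hydrogen to 4 amu (default)
and subtracts the transferred mass from the bonded heavy atom, conserving
total mass exactly. Repartitioning refuses when a heavy atom would drop
below 1.008 amu: a methane carbon at hydrogen mass 4 would keep 0.043 amu,
which would invert the stiffest modes instead of softening them.

**Monte Carlo barostat** proposes uniform isotropic volume changes with
per-particle coordinate scaling and accepts with
min(1, exp(−β[ΔU + pΔV − N k_B T ln(V′/V)])); validated against the ideal
gas law ⟨V⟩ = (N+1)k_BT/p. Toy systems contain no rigid molecules, so
per-molecule scaling is not needed.

**Replica exchange** alternates propagation segments (one swap interval,
default 4 ps) with deterministic even/odd sweeps of neighbour swap
attempts accepted with min(1, exp(−[u_i(x_j)+u_j(x_i)−u_i(x_i)−u_j(x_j)])).
One RNG stream per state is derived from the root seed plus the state
index, and a separate stream drives swap decisions, making full runs
bitwise reproducible. Production sampling in the leg driver is NVT after
(optionally NPT) equilibration; every stored sample carries its box so the
reduced potential u = β(U + pV) is well defined per sample if a pressure
is configured.

## Estimation

**MBAR** is solved by minimizing the convex log-likelihood with L-BFGS
(analytic gradient), then polishing by self-consistent iteration to 1e-10
in f (the iteration is the convergence criterion; the optimizer is just a
good starting point). States with no samples are filled in by one-shot
reweighting. Uncertainties come from the asymptotic covariance of the
weight matrix computed in its SVD form. The overlap diagnostic is the
scalar 1 − λ₂ of the row-stochastic overlap matrix O_ij = Σ_n W_ni N_j
W_nj, which is 1 for perfectly overlapping states and 0 for a disconnected
ladder; a warning names the weakest pair below 1e-6. (The minimum
eigenvalue of O is *not* used: it approaches 0 for perfectly overlapping
states and so cannot distinguish the healthy case from the broken one.)

**BAR** solves the Bennett implicit equation
Σ_F fermi(M + w_F − Δf) = Σ_R fermi(−M + w_R + Δf), M = ln(n_F/n_R), by
bracketing root search, with w_F = u₁−u₀ on state-0 samples and
w_R = u₀−u₁ on state-1 samples. This is the exact stationarity condition
of the two-state MBAR problem, which the tests verify to 1e-8; it serves
as an independent oracle for MBAR rather than a production path.
**Zwanzig** exponential averaging is the one-sided limit, matched to
1e-10 when only one state contributes samples.

**Decorrelation** (optional, off by default in the toy driver) subsamples
each state's series by its statistical inefficiency g = 1 + 2Σc(t),
truncated at the first negative autocorrelation.

**Edges and convergence.** ΔΔG = k_BT·(Δf_complex − Δf_solvent) with
k_B = 0.0019872043 kcal/mol/K for bit-exact kcal reporting; leg
uncertainties add in quadrature. Convergence series re-estimate MBAR on
growing prefixes of the time-ordered samples (default: uniform grid, last
point = full data).

## Network analysis

Per-ligand ΔG values solve the weighted least-squares problem
min Σ w_ij (g_j − g_i − ΔΔG_ij)², w = 1/σ² (unit weights where σ is
missing), on a connected graph; the additive gauge is fixed by shifting
predictions to the mean experimental ΔG of the same ligands (predictions
are reported relative to the first ligand, with a warning, when no
experiment is supplied). Cycle-closure errors are signed sums over a
fundamental cycle basis; the per-ligand error bar is the root-sum-square
of closures of basis cycles through that ligand (zero off-cycle).
Accuracy statistics are computed per compound: MUE, RMSE, R² (squared
Pearson), Spearman ρ, and Kendall τ-b (tie-corrected, since experimental
affinities often tie after rounding). Multi-target summaries pool
compounds, not per-target averages, alongside the per-target breakdown.

## Synthetic data

The generators define the test conditions. Harmonic ladders provide exact
Gaussian samples with analytic reduced free energies f = ½ln(k/2π).
Synthetic networks draw true ΔGs uniformly on [−12, −6] kcal/mol (a
typical lead-optimization affinity range), add Gaussian edge noise, and
optionally perturb the reported experimental values (0.64 kcal/mol is a
representative experimental reproducibility). Solvated-box construction
is arithmetic only: edge = solute extent (all atoms) + 2×0.9 nm buffer,
NaCl pairs = round-half-up of c·N_A·V at 150 mM, plus exact counterions;
toy "solvent" is inert LJ beads on a lattice. Toy mutation pairs
(ethane→ethanol, bead swaps/growth, neutral→charged) come with
hand-verified mappings.

What the toys do **not** show: forcefield accuracy, protein conformational
sampling, finite-size and electrostatic artefacts of charged
transformations, or water placement — passing tests demonstrate that the
estimators, samplers and network algebra are correct, not that any
particular protein–ligand prediction is.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the
statistical checks decisive: 10,000 exact samples/state for estimator
recovery, 5,000 HREX samples/state for distributional (KS) checks, 40–50
HREX iterations × 12 windows with a 40-particle bath for alchemical round
trips, and 50-node networks for recovery. The production-scale settings
(500 ps NPT equilibration, 5 ns/window, 4 ps swap interval) remain the
config defaults. Stochastic assertions use 3σ bands throughout. MBAR
tolerance 1e-10; minimizer L-BFGS with gradient tolerances reported back;
energies at overlapping coupled particles are +inf, reported, never
masked; round-half-up for ion counts; tie-breaks in the MCS are geometric
then lexicographic.

## Known limitations

- Electrostatics are cutoff-truncated; no reaction field or Ewald. Charged
  transformations in periodic boxes therefore carry artefacts the package
  does not correct.
- MCS ignores bond order, rings and stereochemistry; chemically distinct
  but graph-identical atoms can map onto each other.
- No constraints: water is inert, bonds are harmonic, and the 4 fs
  timestep relies on HMR alone.
- The exact MCS search is exponential in the worst case (fine ≤ ~15 heavy
  atoms).
- Pairwise energies are O(N²) per evaluation; the toolkit targets hundreds
  of particles, not solvated proteins.
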