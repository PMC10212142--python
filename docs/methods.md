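# Methods

This note documents the models implemented in `llps_assembly`, the
conventions and numerical choices behind them, and what the test suite does
and does not establish.

## Model and assumptions

The system is a fixed total concentration ρ_T of one assembling species in
a solvent at two-phase coexistence: a condensate compartment of volume V_c
and a background of volume V_bg, V_r = V_c/V_bg. Assumptions inherited
from the underlying kinetic theory:

* one "average" intermediate per size n; only monomers associate or
  dissociate (no oligomer–oligomer events);
* rate constants identical in the two phases; the compartment's size and
  composition are unaffected by the subunits (dilute-client limit);
* diffusivities independent of intermediate size and of the solvation
  energy g_c;
* no malformed (off-pathway) intermediates — the monomer-starvation trap is
  the only kinetic failure mode represented;
* deterministic concentrations (no finite-number stochasticity). The
  geometry helpers show a V_r = 10⁻³ droplet in a 10 μm cell holds up to
  ~10⁶ subunits, which justifies this for typical condensates.

Units: concentrations are molar, with the standard state entering only
through the reference concentration v₀⁻¹ (default 1 M); energies are pure
numbers in k_BT (no temperature parameter — only βg ever appears); times in
seconds.

## Pathway models

**NG.** Association rate constant f (default 10⁵ M⁻¹s⁻¹, configurable;
every reported boundary concentration is independent of f). Dissociation
from sizes 2..n_nuc−1 uses g_nuc, from n_nuc..N−1 uses g_elong, from N uses
g_N (default 2·g_elong); defaults g_nuc = −4, g_elong = −17 k_BT, N = 120,
n_nuc = 3. The energy ladder G_n accumulates exactly these step energies
(so the chain's stationary distribution is Boltzmann in G_n); consequently
the pre-nucleus energy is G_n̂ = (n_nuc − 2)·g_nuc at n̂ = n_nuc − 1, the
barrier top. n_nuc = 2 means no barrier: all pre-closure steps dissociate
at the elongation rate.

**CNT.** Partial shells with G_n = n·g_sub + σ·l_n,
l_n/l₀ = 2√(πn(N−n)/N). The prefactor 2 is fixed by requiring the
half-shell rim to equal the great circle 2πR with R = l₀√(N/4π). The
continuum form gives G_1 ≠ 0 (a lone subunit is not a shell fragment); only
energy *differences* drive the kinetics, and every quantity referenced to
free monomers — the stationary distribution, the pre-nucleus concentration
in the scaling estimates — uses G_n − G_1. This convention is what makes
the CNT trap boundary land at the tens-of-μM scale; with the unreferenced
energy the defining equation has no physical root. The critical nucleus is
the discrete argmax of G_n − n·ln(ρ₁v₀) (authoritative); the continuous
stationary point n* = N/2·(1 − Γ/√(Γ²+1)) with
Γ = (ln(ρ₁v₀) − g_sub)·√(N/π)/(2σl₀) is re-derived from dG/dn = 0 and kept
as a cross-check (tests confirm it tracks the discrete argmax within ±1).

## Two-phase exchange

Finite-rate exchange uses the per-size flux of the model section with a
size-independent base rate k_exch = k_D L/V_c. The default is 300 s⁻¹,
from a monomer diffusivity of 100 μm²/s and a 1 μm compartment
(k_D L = 4πDR_c, V_c = 4πR_c³/3 ⇒ 3D/R_c² s⁻¹). At default parameters this
is ~10³ times faster than assembly, so results must be — and are, by a
regression test at 10× and 100× the default — insensitive to the choice.
The n-mer partition coefficient K_c^n is evaluated in log space; when
n·ln K_c > 600 the back flux is set to zero (one-way uptake), which is
physically indistinguishable from the true value below double precision.

The `fast_equilibrium` mode clamps the per-size partitioning
ρ_n^c/ρ_n^bg = K_c^n at every instant for **all** sizes — the exact
k_exch → ∞ limit of the flux law. Clamping only monomers would strand
intermediates in the phase where they nucleate and would not converge to
the finite-rate model. The clamp halves the state dimension and is the
default for sweeps; the finite-rate mode is used wherever kinetically
controlled partitioning could matter (e.g. the selectivity checks).

## Equilibrium theory

The two-state approximation (free subunits + complete shells, law of mass
action ρ_N = ρ₁^N e^(−Nβg_sub) in v₀ units, with ρ₁^c/ρ₁^bg = K_c) is
solved by bracketed root-finding in log ρ₁^bg; the residual scales like
ρ₁^N near the root, so linear-space tolerances would be hopeless. The
solution is verified against the analytic relation
x/(1−x)^N = N·K_eff^N·ρ_T^(N−1)e^(−Nβg_sub)(1+V_rK_c^N)/(1+V_r) at every
call. The CAC is implemented in the smooth exact form
ρ_CAC = ρ_CAC⁰/K_eff·[(1+V_r)/(1+V_rK_c^N)]^(1/N), which reduces to the
large-K_c and no-LLPS limits without a case split.

For NG parameter sets the per-subunit energy used by the two-state theory
defaults to g_sub = g_elong (configurable); the exact chain equilibrium
(`chain_equilibrium`, Boltzmann weights of the full ladder) is provided as
the oracle for small N and is what the kinetics tests compare against,
since the default mapping deliberately ignores the ~2% difference between
g_elong and G_N/N.

## Scaling estimates

τ_elong = N^α/(f·ρ₁) with α = 1 (NG) and 1/2 (CNT).
τ_1/2 = A_1/2·x_N/(Nf)·e^{G_n̂}·ρ^{−n̂}, A_1/2 = (2^n̂−1)/n̂, with x_N = 1 by
default (deep-quench limit; configurable). LLPS divides τ_1/2 by the
nucleation speedup s_nuc and sets the local elongation concentration
K_cK_effρ_T; the trap boundary ρ* solves τ_1/2 = τ_elong. Numerical
choices:

* the general ρ* is a bracketed root in log ρ on a 600-point scan grid
  (handles the discrete jumps of the CNT nucleus, solved self-consistently);
  the NG closed forms ρ*⁰ = (A_1/2x_N/N^(1+α))^(1/(n̂−1))·e^(G_n̂/(n̂−1)) and
  ρ* = ρ*⁰(K_cK_eff/s_nuc)^(1/(n_nuc−2)) are reported alongside and agree
  with the root to 10⁻⁸ where both apply;
* the two-channel elongation time weights compartment and background by the
  fraction of assemblies nucleating in each, V_rK_c^m/(V_rK_c^m+1) with
  m = n_nuc (a `capsid` weighting with m = N is available for sensitivity
  analysis);
* all optima (s*_nuc over V_r, the speedup optimum over K_c bounded by the
  trap condition, K**_c maximizing ρ*, K_c^nuc maximizing ρ*/ρ_nuc) are
  computed by bounded scalar optimization in log space; the printed
  asymptotic forms are retained only as labeled cross-checks. The K_c
  optima maximize the analytic (compartment-dominated-elongation) boundary
  for NG, which is the regime in which those optima are defined; the
  general two-channel boundary shifts the argmax upward by tens of percent;
* for CNT the critical nucleus entering the scaling formulas is evaluated
  at the relevant local concentration, and barrier energies are
  monomer-referenced (G_n̂ − G_1) as above.

The independent oracle for the trap boundary is `trap_threshold_master`:
the argmin over a concentration grid of the median assembly time measured
from full master-equation runs. With the defaults, the NG argmins land on
the grid point nearest the closed form; the CNT argmin (~52 μM) and the
self-consistent solve (~82 μM) bracket the same scale from below and above.

## Integration

`scipy.integrate.solve_ivp` with the BDF method, relative tolerance 10⁻⁸,
absolute tolerance ρ_T·10⁻¹⁴, and an explicit Jacobian sparsity pattern
(tridiagonal chain + monomer row/column + cross-phase exchange diagonal).
Output is on a log grid from 10⁻³ s to the horizon. Concentrations are not
clipped during integration — tolerances are tight instead — and are floored
at zero only on output. Total subunit mass must stay within 10⁻⁶ relative
of its initial value over every run (typically it stays within ~10⁻¹⁰);
violation raises rather than warns. Much tighter tolerances (10⁻¹⁰ with
the default atol) can stall BDF's step-size control on components near the
absolute floor and are not needed for any quantity computed here.

τ_1/2 is the first time x_N(t) reaches half its *equilibrium* value (the
two-state estimate carries x_N explicitly, so normalizing by the final
extent is the consistent reading); the lag time is the x_N = 0 intercept of
the tangent at maximum slope, the standard construction for sigmoidal
assembly curves; the peak capsid formation rate is evaluated from the exact
right-hand side at the stored states, not by differencing.

## Problem sizes used by the tests

The acceptance checks run the full N = 120 system for single trajectories
and reduced grids elsewhere: 9-point concentration grids for the
master-equation trap argmins, N = 8 chains for the Boltzmann stationarity
oracle, N = 20–30 for round-trip and convergence regressions. These sizes
were chosen so each check isolates one property at full numerical fidelity;
the scaling theory itself is size-independent, and the N = 120 defaults are
exercised end to end by the figure-level property tests.

## What the synthetic conditions do and do not show

All inputs are parameter sets, not data; the fixtures encode the reference
figure-caption conditions (N = 120, n_nuc = 3, g_nuc = −4 k_BT,
g_elong = −17 k_BT, V_r = 10⁻³, ρ_T around 0.2 μM, observation times of one
day and 10⁷ s). Within this world the tests establish internal consistency
(detailed balance, mass conservation, equilibrium limits, scaling-vs-master
agreement) and the headline phenomenology (nucleation speedup, buffering,
selectivity, trap boundaries). They do not validate the assumptions
against real systems: real condensates have finite subunit copy numbers,
crowding and excluded volume at high local concentration, malformed
intermediates, size- and g_c-dependent diffusion, and compartments whose
composition responds to uptake. The model is a controlled idealization for
mapping where those effects would matter.

## Known limitations

* The diffusion-limited floor on assembly times at very small V_r is not
  modeled; speedup predictions there are upper bounds.
* The Flory–Huggins route from microscopic interaction parameters to K_c is
  out of scope; K_c is an input.
* Equilibrium selectivity assumes capsids can exchange between phases; if
  large species cannot cross the interface, finite-time selectivity is
  kinetically controlled (the finite-rate mode with a size-dependent
  `size_scaling` can represent slower large-n exchange, but no specific
  L(n) is shipped).
* The closed-form CNT trap boundary inherits the two-state median-time
  estimate, whose combinatorial prefactor is exact only for a
  concentration-independent nucleus; the master-equation oracle is the
  arbiter where they disagree.
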