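# llps-assembly

Rate-equation models of reversible capsid self-assembly coupled to
liquid–liquid phase separation (LLPS).

Many viruses assemble their capsids inside biomolecular condensates
(viroplasms, virus factories, Negri bodies), and a growing list of cellular
structures — clathrin cages, synaptic densities, filaments — form within
phase-separated compartments. This package is for modellers and
quantitative virologists who want to ask: *by how much does a condensate
that concentrates assembly subunits speed up assembly, and when does it
backfire?*

## The model

A dilute solution of subunits at total concentration ρ_T forms shells of N
subunits through a chain of intermediates, 1 ⇌ 2 ⇌ … ⇌ N, with
single-subunit association (rate constant f) and dissociation rates tied to
the step free energies by detailed balance, v₀·bᵢ = f·exp(βgᵢ). Two rate
parameterizations are provided:

* **NG (nucleation-and-growth)** — a fixed critical nucleus n_nuc with
  piecewise energies g_nuc (uphill pre-nucleus steps), g_elong (downhill
  elongation), and g_N = 2·g_elong for shell closure;
* **CNT (classical nucleation theory)** — partial spherical shells with
  per-subunit energy g_sub and rim line tension σ = −g_sub/(2l₀), giving a
  rim length l_n = 2l₀√(πn(N−n)/N), size-dependent forward rates
  f_n = f₀·l_n/l₀, and a concentration-dependent critical nucleus.

The system contains one condensate compartment (volume fraction
V_r = V_c/V_bg of the background) into which free subunits partition with
coefficient K_c = exp(−βg_c); an n-mer partitions as K_c^n. Each species
obeys the master equation in both phases plus a diffusive exchange flux

    D_n^c = (1/V_c)·k_D L(n)·(ρ_n^bg − ρ_n^c/K_c^n),   D_n^bg = −V_r·D_n^c,

integrated with a stiff BDF solver (or, as the cheap default, the
fast-exchange limit in which every size is partitioned at quasi-equilibrium
each instant). Alongside the kinetics the package provides:

* the **two-state equilibrium** (free subunits + complete shells): yields
  x_N, the critical assembly concentration
  ρ_CAC ≈ ρ_CAC⁰/(K_c·K_eff) with K_eff = (1+V_r)/(1+K_c·V_r), and the
  equilibrium selectivity V_r·K_c^N/(V_r·K_c^N + 1);
* **scaling estimates**: elongation time τ_elong = N^α/(f·ρ₁), two-state
  median assembly time τ_1/2 = A_1/2·x_N/(N f)·exp(G_n̂)·ρ^−n̂ with
  n̂ = n_nuc − 1 and A_1/2 = (2^n̂ − 1)/n̂, the nucleation threshold ρ_nuc,
  the nucleation speedup s_nuc = K_eff^n_nuc(1 + V_r·K_c^n_nuc)/(1 + V_r),
  the monomer-starvation trap boundary ρ* (where τ_1/2 = τ_elong), the
  optimal-speedup and robustness optima over K_c, V_r.

## Worked example

Assembly of an N = 120 shell at ρ_T = 0.2 μM inside a condensate with
K_c = 36 and V_r = 10⁻³, integrated for one day:

```bash
llps-assembly simulate --rho-t 2e-7 --kc 36 --vr 1e-3 --t-end 9e4
```

prints

```json
{
  "tau_half": 1418.1014497321032,
  "tau_lag": 173.2825460125181,
  "max_rate": 1.5620373348588777e-12,
  "rho1_bg_at_max_rate": 1.6648982182711975e-07,
  "x_N_end": 0.9281864774656736,
  "x_N_eq": 0.9946737687515456,
  "selectivity_end": 1.0
}
```

Half the achievable yield forms in ~24 minutes (`tau_half`) after a ~3
minute lag; 93% of all subunits sit in complete capsids after a day, and
every one of them is inside the compartment (`selectivity_end` = 1). The
background monomer pool at peak assembly rate is still 83% of ρ_T
(`rho1_bg_at_max_rate`): the bulk acts as a buffer that feeds the
compartment. The same concentration without LLPS (`--kc 1`) gives
`tau_half` ≈ 5.7 × 10⁴ s — the condensate speeds assembly up ~40-fold here.

Other entry points:

```bash
llps-assembly theory --rho-t 2e-7 --kc 10 --vr 1e-3   # scaling estimates
llps-assembly equilibrium --rho-t 2e-7 --kc 36        # two-state yield, CAC
llps-assembly sweep --fixture fig4B --out scratch/f4b # grid sweep -> tidy CSV
llps-assembly fixtures list                           # study parameter sets
```

All CLI flags can instead come from a YAML config (`--config`), with flags
taking precedence.

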