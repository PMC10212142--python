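"""Nucleation-and-growth (NG) pathway: rate table and intermediate energies.

Assembly proceeds by single-subunit addition through a chain of sizes
1 -> 2 -> ... -> N.  The association rate constant f is size independent;
dissociation rates are set by detailed balance v0*b = f*exp(g) with a
piecewise step energy: g_nuc for pre-nucleus steps, g_elong during
elongation, and g_N for the final shell-closing subunit.  The backward rate
on the (n_nuc-1 <-> n_nuc) step is already b_elong, so the barrier top of
the chain is the pre-nucleus nhat = n_nuc - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AssemblyModelParams

__all__ = ["RateTable", "ng_rate_table", "ng_intermediate_energy"]


@dataclass
class RateTable:
    """Per-size rate constants, indexed by intermediate size.

    ``f_n[n]`` is the association rate constant (M^-1 s^-1) for the step
    n -> n+1 (valid for 1 <= n <= N-1); ``b_n[n]`` is the dissociation rate
    (s^-1) for n -> n-1 (valid for 2 <= n <= N).  Index 0 and out-of-role
    entries are zero.  Detailed balance ties the two:
    v0*b_{n+1} = f_n * exp(dG_{n+1}) with dG the step free-energy change.
    """

    N: int
    f_n: np.ndarray
    b_n: np.ndarray

    def __post_init__(self) -> None:
        f_valid = self.f_n[1 : self.N]
        b_valid = self.b_n[2 : self.N + 1]
        if not (np.all(np.isfinite(f_valid)) and np.all(f_valid > 0)):
            raise ValueError("association rates must be positive and finite")
        if not (np.all(np.isfinite(b_valid)) and np.all(b_valid > 0)):
            raise ValueError("dissociation rates must be positive and finite")


def ng_intermediate_energy(params: AssemblyModelParams, n) -> np.ndarray | float:
    """Interaction free energy G_n (k_BT) of an n-mer, G_1 = 0.

    The energy ladder accumulates the step energies of the reaction chain:
    additions forming sizes 2..n_nuc-1 contribute g_nuc each, additions
    forming sizes n_nuc..N-1 contribute g_elong each, and the final
    shell-closing addition contributes g_N.  This is exactly consistent with
    :func:`ng_rate_table` through detailed balance, so the stationary
    distribution of the chain is the Boltzmann distribution in these
    energies.  The pre-nucleus energy is G_nhat = (n_nuc - 2)*g_nuc at
    nhat = n_nuc - 1, the top of the free-energy barrier.
    """
    p = params.normalized()
    n_arr = np.asarray(n)
    if np.any(n_arr < 1) or np.any(n_arr > p.N):
        raise ValueError("size n out of range 1..N")
    nuc_steps = np.clip(n_arr - 1, 0, p.n_nuc - 2)
    elong_steps = np.clip(n_arr, p.n_nuc - 1, p.N - 1) - (p.n_nuc - 1)
    close_steps = np.where(n_arr == p.N, 1, 0)
    g = nuc_steps * p.g_nuc + elong_steps * p.g_elong + close_steps * p.g_N
    return g if g.shape else float(g)


def ng_rate_table(params: AssemblyModelParams) -> RateTable:
    """Build the NG rate table.

    f_n = f for every step.  b_n = (f/v0)*exp(g_nuc) for dissociation from
    sizes 2..n_nuc-1, (f/v0)*exp(g_elong) for n_nuc..N-1, and
    (f/v0)*exp(g_N) for the complete shell.  The statistical factor 2 on
    dimerization is applied in the master-equation right-hand side, not here.
    """
    p = params.normalized()
    if p.model_kind != "NG":
        raise ValueError("ng_rate_table requires model_kind='NG'")
    N = p.N
    f_over_v0 = p.f * p.v0_conc  # f/v0 with v0 = 1/v0_conc
    f_n = np.zeros(N + 1)
    f_n[1:N] = p.f
    b_n = np.zeros(N + 1)
    sizes = np.arange(N + 1)
    b_n[2:N] = np.where(
        sizes[2:N] <= p.n_nuc - 1,
        f_over_v0 * np.exp(p.g_nuc),
        f_over_v0 * np.exp(p.g_elong),
    )
    b_n[N] = f_over_v0 * np.exp(p.g_N)
    return RateTable(N=N, f_n=f_n, b_n=b_n)
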