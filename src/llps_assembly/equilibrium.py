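"""Equilibrium theory: two-state yield, CAC, and selectivity with LLPS.

At equilibrium, intermediates of self-limited assemblies are scarce, so the
system is well approximated by two states: free subunits and complete
capsids of size N.  In each phase the law of mass action ties the capsid
concentration to the free-subunit concentration,
rho_N = rho_1^N * exp(-N*g_sub) in v0 units, while partitioning relates the
phases: rho_1^c/rho_1^bg = K_c and rho_N^c/rho_N^bg = K_c^N.  Mass
conservation then fixes a single unknown, solved here by bracketed
root-finding (robust for any parameters); the analytic closed form is kept
as a consistency check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq

from .exchange import k_eff
from .params import AssemblyModelParams, CompartmentParams

__all__ = [
    "EquilibriumResult",
    "solve_equilibrium",
    "critical_assembly_concentration",
    "equilibrium_selectivity",
    "chain_equilibrium",
]

_EXP_CAP = 700.0


@dataclass
class EquilibriumResult:
    """Two-state equilibrium solution.

    xN_c and xN_bg are capsid mass fractions (of total subunit mass) in the
    compartment and background; xN = xN_c + xN_bg.
    """

    rho1_c: float
    rho1_bg: float
    rhoN_c: float
    rhoN_bg: float
    xN_c: float
    xN_bg: float
    xN: float
    rho_CAC: float
    selectivity: float

    def to_dict(self) -> dict:
        return asdict(self)


def _rhoN_of_rho1(rho1: float, N: int, g_sub: float, v0_conc: float) -> float:
    """Law of mass action, evaluated in log space with an overflow cap."""
    if rho1 <= 0:
        return 0.0
    expo = N * (math.log(rho1 / v0_conc) - g_sub)
    return v0_conc * math.exp(min(expo, _EXP_CAP))


def solve_equilibrium(
    rho_T: float,
    assembly: AssemblyModelParams,
    compartment: CompartmentParams,
) -> EquilibriumResult:
    """Solve the two-state mass balance for the free-subunit concentration.

    The residual is monotone in rho1_bg, so the bracketed root on
    (0, rho_T*(1+V_r)] always exists for g_sub < 0.  The solution is
    verified against the analytic closed-form relation (mass action recast
    in terms of xN) to 1e-6.
    """
    p = assembly.normalized()
    c = compartment.normalized()
    if p.g_sub >= 0:
        raise ValueError("two-state equilibrium requires g_sub < 0")
    if rho_T <= 0:
        raise ValueError("rho_T must be positive")
    N, g, v0c = p.N, p.g_sub, p.v0_conc
    K_c, V_r = c.K_c, c.V_r

    def residual(rho1_bg: float) -> float:
        rho1_c = K_c * rho1_bg
        rhoN_bg = _rhoN_of_rho1(rho1_bg, N, g, v0c)
        rhoN_c = _rhoN_of_rho1(rho1_c, N, g, v0c)
        return (
            V_r * (rho1_c + N * rhoN_c)
            + rho1_bg
            + N * rhoN_bg
            - (1.0 + V_r) * rho_T
        )

    # solve in log space: the residual varies like rho1_bg^N near the root,
    # so absolute tolerances on rho1_bg itself are far too coarse; the upper
    # endpoint is nudged past the all-monomer point to keep the sign robust
    # against exp(log(.)) rounding
    hi = math.log(rho_T * (1.0 + V_r)) + 1e-9
    lo = hi - 700.0
    u = brentq(lambda lg: residual(math.exp(lg)), lo, hi, xtol=1e-14, maxiter=300)
    rho1_bg = math.exp(u)

    rho1_c = K_c * rho1_bg
    rhoN_bg = _rhoN_of_rho1(rho1_bg, N, g, v0c)
    rhoN_c = _rhoN_of_rho1(rho1_c, N, g, v0c)
    xN_bg = N * rhoN_bg / (rho_T * (1.0 + V_r))
    xN_c = N * rhoN_c * V_r / (rho_T * (1.0 + V_r))
    xN = xN_c + xN_bg

    # closed-form consistency: x/(1-x)^N = N*Keff^N*rhoT^(N-1)*e^(-N g)*(1+Vr*Kc^N)/(1+Vr)
    if 1e-12 < xN < 1.0 - 1e-12 and K_c > 0:
        ke = k_eff(K_c, V_r)
        log_lhs = math.log(xN) - N * math.log1p(-xN)
        log_kcN_vr = N * math.log(K_c) + math.log(V_r) if V_r > 0 else -math.inf
        log_rhs = (
            math.log(N)
            + N * math.log(ke)
            + (N - 1) * math.log(rho_T / v0c)
            - N * g
            + np.logaddexp(0.0, log_kcN_vr)
            - math.log1p(V_r)
        )
        if abs(log_lhs - log_rhs) > 1e-6 * max(1.0, abs(log_rhs)):
            raise RuntimeError("two-state closed-form consistency check failed")

    cac = critical_assembly_concentration(p, c)["rho_CAC"]
    sel = equilibrium_selectivity(K_c, V_r, N)
    return EquilibriumResult(
        rho1_c=rho1_c,
        rho1_bg=rho1_bg,
        rhoN_c=rhoN_c,
        rhoN_bg=rhoN_bg,
        xN_c=xN_c,
        xN_bg=xN_bg,
        xN=xN,
        rho_CAC=cac,
        selectivity=sel,
    )


def critical_assembly_concentration(
    assembly: AssemblyModelParams, compartment: CompartmentParams
) -> dict:
    """CAC with and without LLPS, and the enhancement factor.

    rho_CAC0 = N^(-1/N)*exp(g_sub) in v0 units.  With LLPS the exact
    large-N form is rho_CAC = rho_CAC0/K_eff * [(1+V_r)/(1+V_r*K_c^N)]^(1/N),
    which reduces to rho_CAC0/(K_c*K_eff)*(V_r/(1+V_r))^(-1/N) when capsids
    reside in the compartment (K_c^N*V_r >> 1) and to rho_CAC0 when K_c = 1
    or V_r = 0.  The enhancement saturates at ~K_c for K_c*V_r << 1 and at
    ~1/V_r for K_c*V_r >> 1.
    """
    p = assembly.normalized()
    c = compartment.normalized()
    N, g, v0c = p.N, p.g_sub, p.v0_conc
    K_c, V_r = c.K_c, c.V_r
    rho_cac0 = N ** (-1.0 / N) * math.exp(g) * v0c
    if K_c <= 0:
        return {"rho_CAC": rho_cac0, "rho_CAC0": rho_cac0, "enhancement": 1.0}
    ke = k_eff(K_c, V_r)
    log_kcN_vr = N * math.log(K_c) + (math.log(V_r) if V_r > 0 else -math.inf)
    log_factor = (math.log1p(V_r) - np.logaddexp(0.0, log_kcN_vr)) / N
    rho_cac = rho_cac0 / ke * math.exp(log_factor)
    return {
        "rho_CAC": rho_cac,
        "rho_CAC0": rho_cac0,
        "enhancement": rho_cac0 / rho_cac,
    }


def equilibrium_selectivity(K_c: float, V_r: float, N: int) -> float:
    """Fraction of capsid mass in the compartment at equilibrium.

    x_selec = V_r*K_c^N / (V_r*K_c^N + 1), evaluated in log space: an
    assembled capsid carries ~N subunit-compartment contacts, so even K_c
    barely above 1 partitions capsids essentially completely.
    """
    if K_c < 0 or V_r < 0:
        raise ValueError("K_c and V_r must be nonnegative")
    if V_r == 0 or K_c == 0:
        return 0.0
    log_num = math.log(V_r) + N * math.log(K_c)
    return float(math.exp(log_num - np.logaddexp(0.0, log_num)))


def chain_equilibrium(
    rho_T: float,
    assembly: AssemblyModelParams,
    compartment: CompartmentParams,
) -> dict:
    """Full-chain equilibrium (all sizes 1..N), for small-N cross-checks.

    Uses the Boltzmann weights of the pathway's energy ladder (referenced to
    free monomers) in each phase, with per-size partitioning K_c^n, and
    solves the single mass-balance equation.  Intended for N <= ~20.
    """
    from .cnt import cnt_intermediate_energy
    from .ng import ng_intermediate_energy

    p = assembly.normalized()
    c = compartment.normalized()
    N, v0c = p.N, p.v0_conc
    K_c, V_r = c.K_c, c.V_r
    sizes = np.arange(1, N + 1)
    if p.model_kind == "NG":
        G = np.asarray(ng_intermediate_energy(p, sizes), dtype=float)
    else:
        G = np.asarray(cnt_intermediate_energy(sizes, p), dtype=float)
        G = G - G[0]  # reference the continuum energy to the monomer

    def masses(rho1_bg: float) -> tuple[np.ndarray, np.ndarray]:
        log_bg = sizes * math.log(rho1_bg / v0c) - G
        log_c = sizes * math.log(max(K_c, 1e-300) * rho1_bg / v0c) - G
        rho_bg = v0c * np.exp(np.minimum(log_bg, _EXP_CAP))
        rho_c = v0c * np.exp(np.minimum(log_c, _EXP_CAP))
        return rho_c, rho_bg

    def residual(rho1_bg: float) -> float:
        rho_c, rho_bg = masses(rho1_bg)
        return float(
            V_r * np.sum(sizes * rho_c) + np.sum(sizes * rho_bg)
        ) - (1.0 + V_r) * rho_T

    hi = math.log(rho_T * (1.0 + V_r)) + 1e-9
    rho1_bg = math.exp(
        brentq(lambda lg: residual(math.exp(lg)), hi - 700.0, hi, xtol=1e-14)
    )
    rho_c, rho_bg = masses(rho1_bg)
    xN = N * (V_r * rho_c[-1] + rho_bg[-1]) / (rho_T * (1.0 + V_r))
    return {"rho1_bg": rho1_bg, "rho_c": rho_c, "rho_bg": rho_bg, "xN": float(xN)}
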