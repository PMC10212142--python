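"""Closed-form and numeric scaling estimates for assembly timescales.

The assembly process separates into nucleation (crossing the free-energy
barrier at the critical nucleus) and elongation (adding the remaining ~N
subunits).  Treating the reaction as two-state with nucleation-order
kinetics gives the median assembly time

    tau_1/2 = A_1/2 * x_N/(N f) * exp(G_nhat) * rho^(-nhat),
    A_1/2 = (2^nhat - 1)/nhat,  nhat = n_nuc - 1,

with G_nhat the pre-nucleus interaction free energy and x_N the equilibrium
yield (default 1, the deep-quench limit).  The elongation time is
tau_elong = N^alpha/(f rho_1).  Equating the two defines the onset of the
monomer-starvation kinetic trap, rho_star, and the corresponding minimum
assembly time tau_min.  A condensate compartment rescales the picture
through the nucleation speedup s_nuc(K_c, V_r) and the local concentration
K_c*K_eff*rho_T; all optima over K_c or V_r are computed numerically, with
the asymptotic closed forms retained as labeled approximations.

For the CNT pathway the critical nucleus depends on concentration, so the
trap boundary is solved self-consistently; pre-nucleus energies are
referenced to the free monomer (G_nhat - G_1), as detailed balance of the
size chain requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .cnt import cnt_critical_nucleus, cnt_intermediate_energy
from .exchange import k_eff
from .ng import ng_intermediate_energy
from .params import AssemblyModelParams, CompartmentParams, TAU_OBS_DAY

__all__ = [
    "ScalingEstimates",
    "barrier_quantities",
    "elongation_time",
    "elongation_time_llps",
    "nucleation_time",
    "median_time",
    "nucleation_threshold",
    "nucleation_speedup",
    "trap_threshold",
    "llps_speedup",
    "robustness_optima",
    "scaling_estimates",
    "trap_threshold_master",
]


def a_half(nhat: int) -> float:
    """Combinatorial prefactor A_1/2 = (2^nhat - 1)/nhat of the two-state
    median-time estimate (log-safe for large nhat)."""
    if nhat < 1:
        raise ValueError("nhat must be >= 1")
    if nhat < 500:
        return (2.0**nhat - 1.0) / nhat
    return math.exp(nhat * math.log(2.0) - math.log(nhat))


def barrier_quantities(
    params: AssemblyModelParams, rho: Optional[float] = None
) -> tuple[int, float, float]:
    """(nhat, G_nhat, A_1/2) for the pathway model.

    NG: nhat = n_nuc - 1 and G_nhat = (nhat - 1)*g_nuc, independent of
    concentration.  CNT: the critical nucleus is the discrete free-energy
    maximum at local concentration ``rho`` (required), and the pre-nucleus
    energy is monomer-referenced, G_nhat - G_1.
    """
    p = params.normalized()
    if p.model_kind == "NG":
        nhat = p.n_nuc - 1
        G = float(ng_intermediate_energy(p, nhat))
    else:
        if rho is None:
            raise ValueError("CNT barrier quantities need a concentration")
        try:
            n_nuc = cnt_critical_nucleus(rho, p)["n_nuc_discrete"]
        except ValueError:
            n_nuc = 2  # supersaturated past the spinodal: no barrier
        nhat = max(n_nuc - 1, 1)
        G = float(cnt_intermediate_energy(nhat, p)) - float(
            cnt_intermediate_energy(1, p)
        )
    return nhat, G, a_half(nhat)


def log_s_nuc(K_c: float, V_r: float, n_nuc: int) -> float:
    """ln of the nucleation speedup, overflow-safe for huge K_c^n_nuc."""
    if K_c < 0 or V_r < 0:
        raise ValueError("K_c and V_r must be nonnegative")
    if V_r == 0 or K_c == 0:
        return 0.0
    ke = k_eff(K_c, V_r)
    log_kv = n_nuc * math.log(K_c) + math.log(V_r)
    return n_nuc * math.log(ke) + float(np.logaddexp(0.0, log_kv)) - math.log1p(V_r)


def elongation_time(rho1_local: float, params: AssemblyModelParams) -> float:
    """tau_elong = N^alpha/(f*rho_1) with the local free-subunit
    concentration (alpha = 1 NG, 1/2 CNT)."""
    p = params.normalized()
    if rho1_local <= 0:
        raise ValueError("rho1 must be positive")
    return p.N**p.alpha / (p.f * rho1_local)


def elongation_time_llps(
    rho_T: float,
    params: AssemblyModelParams,
    K_c: float = 1.0,
    V_r: float = 0.0,
    weighting: str = "nucleation",
) -> float:
    """Two-channel elongation time, weighted by where assemblies nucleate.

    tau = [w_c/tau_c + w_bg/tau_bg]^-1 with local concentrations
    rho1_c = K_c*K_eff*rho_T, rho1_bg = K_eff*rho_T.  The compartment weight
    w_c = V_r*K_c^m/(V_r*K_c^m + 1) counts the relative number of assemblies
    forming in each phase; m = n_nuc (default, nucleation-rate controlled)
    or m = N (``weighting="capsid"``, a sensitivity alternative).
    """
    p = params.normalized()
    ke = k_eff(K_c, V_r)
    rho1_bg = ke * rho_T
    rho1_c = K_c * rho1_bg
    if V_r == 0 or K_c == 1:
        return elongation_time(rho1_bg, params)
    if weighting == "nucleation":
        if p.model_kind == "NG":
            m = p.n_nuc
        else:
            m = cnt_critical_nucleus(rho1_c, p)["n_nuc_discrete"]
    elif weighting == "capsid":
        m = p.N
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    log_wc = m * math.log(K_c) + math.log(V_r)
    w_c = math.exp(log_wc - np.logaddexp(0.0, log_wc))
    inv_tau = w_c / elongation_time(rho1_c, p) + (1.0 - w_c) / elongation_time(
        rho1_bg, p
    )
    return 1.0 / inv_tau


def nucleation_time(rho: float, params: AssemblyModelParams) -> float:
    """Initial mean nucleation time tau_nuc = f^-1 exp(G_nhat) rho^-n_nuc
    (v0 units): the pre-critical nucleus is present at concentration
    ~exp(-G_nhat)*rho^nhat and gains a subunit at rate f*rho.  For
    n_nuc = 2 the barrier vanishes (G_nhat = G_1 = 0) and the formula
    reduces to 1/(f*rho^2)."""
    p = params.normalized()
    if rho <= 0:
        raise ValueError("rho must be positive")
    nhat, G, _ = barrier_quantities(p, rho)
    n_nuc = nhat + 1
    log_tau = G - math.log(p.f * p.v0_conc) - n_nuc * math.log(rho / p.v0_conc)
    return math.exp(log_tau)


def median_time(
    rho: float,
    params: AssemblyModelParams,
    K_c: float = 1.0,
    V_r: float = 0.0,
    x_N: float = 1.0,
) -> float:
    """Two-state median assembly time tau_1/2 = tau_1/2^0 / s_nuc.

    tau_1/2^0 = (A_1/2 x_N/(N f)) exp(G_nhat) rho^-nhat in v0 units; LLPS
    enters only through the nucleation speedup s_nuc(K_c, V_r).
    """
    return math.exp(min(log_median_time(rho, params, K_c, V_r, x_N), 700.0))


def log_median_time(
    rho: float,
    params: AssemblyModelParams,
    K_c: float = 1.0,
    V_r: float = 0.0,
    x_N: float = 1.0,
) -> float:
    """ln tau_1/2; overflow-safe form used by the root finders."""
    p = params.normalized()
    if rho <= 0:
        raise ValueError("rho must be positive")
    nhat, G, A = barrier_quantities(p, rho)
    log_tau0 = (
        math.log(A * x_N / p.N)
        - math.log(p.f * p.v0_conc)
        + G
        - nhat * math.log(rho / p.v0_conc)
    )
    return log_tau0 - log_s_nuc(K_c, V_r, nhat + 1)


def nucleation_threshold(
    tau_obs: float,
    params: AssemblyModelParams,
    K_c: float = 1.0,
    V_r: float = 0.0,
    x_N: float = 1.0,
) -> float:
    """Concentration below which nucleation is not observed within tau_obs.

    Inverts the median time at tau_obs.  For NG this is the closed form
    rho_nuc^0 = [A_1/2 x_N/(N f tau_obs)]^(1/nhat) exp(G_nhat/nhat), divided
    by s_nuc^(1/nhat) with LLPS; for CNT (concentration-dependent nhat) the
    inversion is numeric, which reproduces the NG closed form exactly.
    """
    if tau_obs <= 0:
        raise ValueError("tau_obs must be positive")
    p = params.normalized()
    if p.model_kind == "NG":
        nhat, G, A = barrier_quantities(p)
        log_rho = (
            math.log(A * x_N / (p.N * p.f * p.v0_conc * tau_obs)) + G
        ) / nhat - log_s_nuc(K_c, V_r, nhat + 1) / nhat
        return p.v0_conc * math.exp(log_rho)
    return _solve_median_time_equals(
        lambda rho: tau_obs, p, K_c, V_r, x_N
    )


def _solve_median_time_equals(
    target_time,
    params: AssemblyModelParams,
    K_c: float,
    V_r: float,
    x_N: float,
    lo: float = 1e-13,
    hi: float = 1.0,
) -> float:
    """Root of tau_1/2(rho) = target_time(rho) on a log-rho grid + brentq.

    ``target_time`` maps rho to the timescale to match (a constant tau_obs,
    or the elongation time for the trap boundary).  tau_1/2 falls steeply
    with rho while the target falls at most like 1/rho, so the crossing is
    unique up to the discrete jumps of the CNT critical nucleus.
    """
    p = params.normalized()

    def h(log_rho: float) -> float:
        rho = math.exp(log_rho)
        return log_median_time(rho, p, K_c, V_r, x_N) - math.log(target_time(rho))

    lo_l, hi_l = math.log(lo * p.v0_conc), math.log(hi * p.v0_conc)
    grid = np.linspace(lo_l, hi_l, 600)
    vals = np.array([h(g) for g in grid])
    sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise RuntimeError("no crossing of the median-time condition in range")
    i = sign_change[0]
    root = brentq(h, grid[i], grid[i + 1], xtol=1e-13)
    return math.exp(root)


def nucleation_speedup(K_c: float, V_r: float, n_nuc: int) -> dict:
    """Nucleation speedup s_nuc and its optimum over the volume ratio.

    s_nuc = K_eff^n_nuc * (1 + V_r K_c^n_nuc)/(1 + V_r) is the ratio of the
    total initial nucleation rate with a compartment to the homogeneous one.
    The maximizing V_r at fixed K_c (and the value there) are found
    numerically; the printed asymptote V_r* ~ K_c^-nhat serves only as an
    order-of-magnitude cross-check.
    """
    s = math.exp(log_s_nuc(K_c, V_r, n_nuc))
    if K_c <= 1.0:
        return {"s_nuc": s, "s_nuc_star": 1.0, "V_r_opt": 0.0}
    res = minimize_scalar(
        lambda lv: -log_s_nuc(K_c, math.exp(lv), n_nuc),
        bounds=(math.log(1e-12), math.log(1e3)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return {
        "s_nuc": s,
        "s_nuc_star": math.exp(-res.fun),
        "V_r_opt": math.exp(res.x),
    }


def trap_threshold(
    params: AssemblyModelParams,
    K_c: float = 1.0,
    V_r: float = 0.0,
    x_N: float = 1.0,
    weighting: str = "nucleation",
) -> dict:
    """Onset of the monomer-starvation trap: tau_1/2(rho*) = tau_elong(rho*).

    Returns the numeric root ``rho_star`` (with the two-channel elongation
    time) and the minimum assembly time tau_min = tau_elong(rho*).  For the
    NG pathway with n_nuc >= 3 the closed forms are also reported:
    rho*0 = (A_1/2 x_N/N^(1+alpha))^(1/(nhat-1)) * exp(G_nhat/(nhat-1)) and
    rho* = rho*0 * (K_c K_eff/s_nuc)^(1/(n_nuc-2)).  For CNT the solve is
    self-consistent in the concentration-dependent critical nucleus.
    """
    p = params.normalized()
    rho_star = _solve_median_time_equals(
        lambda rho: elongation_time_llps(rho, p, K_c, V_r, weighting),
        p,
        K_c,
        V_r,
        x_N,
    )
    tau_min = elongation_time_llps(rho_star, p, K_c, V_r, weighting)
    out = {"rho_star": rho_star, "tau_min": tau_min}
    if p.model_kind == "NG" and p.n_nuc >= 3:
        nhat, G, A = barrier_quantities(p)
        log_rho0 = (math.log(A * x_N) - (1.0 + p.alpha) * math.log(p.N) + G) / (
            nhat - 1
        )
        rho_star0 = p.v0_conc * math.exp(log_rho0)
        out["rho_star0_closed"] = rho_star0
        out["tau_min0_closed"] = elongation_time(rho_star0, p)
        if K_c > 0 and V_r > 0 and p.n_nuc > 2:
            log_shift = (
                math.log(K_c) + math.log(k_eff(K_c, V_r)) - log_s_nuc(K_c, V_r, p.n_nuc)
            ) / (p.n_nuc - 2)
            out["rho_star_closed"] = rho_star0 * math.exp(log_shift)
        else:
            out["rho_star_closed"] = rho_star0
    return out


def llps_speedup(
    V_r: float,
    rho_T: float,
    params: AssemblyModelParams,
    x_N: float = 1.0,
    K_c_max: float = 1e8,
) -> dict:
    """Maximum assembly speedup over the partition coefficient.

    s_LLPS = tau_1/2^0(rho_T)/min_Kc tau_1/2(K_c, V_r, rho_T), with the
    minimization bounded by the trap condition rho_T <= rho*(K_c): tau_1/2
    falls monotonically with K_c, so the optimum sits at the largest K_c
    that has not yet pushed the trap boundary below rho_T (K_c_opt).  The
    asymptotic closed form V_r^(-1/nhat)*(rho*0/rho_T)^((nhat^2-1)/nhat) is
    reported alongside.
    """
    p = params.normalized()
    base = trap_threshold(p, 1.0, 0.0, x_N)
    rho_star0 = base["rho_star"]
    if rho_T >= rho_star0:
        raise ValueError("rho_T must lie below the no-LLPS trap boundary")

    def margin(log_kc: float) -> float:
        kc = math.exp(log_kc)
        return math.log(trap_threshold(p, kc, V_r, x_N)["rho_star"]) - math.log(rho_T)

    hi = math.log(K_c_max)
    # rho*(K_c) rises then falls; find the upper crossing rho*(K_c) = rho_T
    if margin(hi) > 0:
        k_opt = K_c_max
    else:
        grid = np.linspace(0.0, hi, 80)
        vals = [margin(g) for g in grid]
        idx = [i for i in range(len(grid) - 1) if vals[i] > 0 >= vals[i + 1]]
        if not idx:
            k_opt = 1.0
        else:
            k_opt = math.exp(brentq(margin, grid[idx[-1]], grid[idx[-1] + 1]))

    tau0 = median_time(rho_T, p, 1.0, 0.0, x_N)
    tau_opt = median_time(rho_T, p, k_opt, V_r, x_N)
    nhat, _, _ = barrier_quantities(p, rho_T)
    closed = V_r ** (-1.0 / nhat) * (rho_star0 / rho_T) ** (
        (nhat**2 - 1.0) / nhat
    )
    return {
        "s_llps_numeric": tau0 / tau_opt,
        "s_llps_closed_form": closed,
        "K_c_opt": k_opt,
    }


def robustness_optima(
    V_r: float,
    params: AssemblyModelParams,
    tau_obs: float = TAU_OBS_DAY,
    x_N: float = 1.0,
) -> dict:
    """Partition coefficients maximizing trap robustness.

    K_c_starstar maximizes the trap boundary rho*(K_c) (numeric argmax;
    closed-form cross-check (1/(V_r*nhat))^(1/(nhat+1))); rho_star_ratio is
    the corresponding gain over the homogeneous boundary; window_ratio is
    the widening of the productive window rho*/rho_CAC; K_c_nuc maximizes
    the ratio of trap boundary to nucleation threshold rho*/rho_nuc.
    """
    p = params.normalized()
    if not (0 < V_r < 1):
        raise ValueError("V_r must be in (0, 1)")

    # For NG the analytic boundary rho* = rho*0*(Kc*Keff/s_nuc)^(1/(n_nuc-2))
    # is maximized (it assumes compartment-dominated elongation, as the
    # optimum formulas do); CNT falls back to the numeric trap solve.
    key = "rho_star_closed" if p.model_kind == "NG" and p.n_nuc >= 3 else "rho_star"

    def neg_log_rho_star(log_kc: float) -> float:
        return -math.log(
            trap_threshold(p, math.exp(log_kc), V_r, x_N)[key]
        )

    res = minimize_scalar(
        neg_log_rho_star,
        bounds=(0.0, math.log(1e8)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    k_ss = math.exp(res.x)
    rho_star_opt = math.exp(-res.fun)
    base = trap_threshold(p, 1.0, 0.0, x_N)
    rho_star0 = base["rho_star"]

    from .equilibrium import critical_assembly_concentration

    comp0 = CompartmentParams(K_c=1.0, V_r=0.0, rho_T=rho_star0).normalized()
    comp_ss = CompartmentParams(K_c=k_ss, V_r=V_r, rho_T=rho_star0).normalized()
    cac0 = critical_assembly_concentration(p, comp0)["rho_CAC"]
    cac_ss = critical_assembly_concentration(p, comp_ss)["rho_CAC"]

    def neg_log_window(log_kc: float) -> float:
        kc = math.exp(log_kc)
        rs = trap_threshold(p, kc, V_r, x_N)[key]
        rn = nucleation_threshold(tau_obs, p, kc, V_r, x_N)
        return -(math.log(rs) - math.log(rn))

    res_n = minimize_scalar(
        neg_log_window,
        bounds=(0.0, math.log(1e8)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    nhat, _, _ = barrier_quantities(p, rho_star0)
    return {
        "K_c_starstar": k_ss,
        "K_c_starstar_closed": (1.0 / (V_r * nhat)) ** (1.0 / (nhat + 1)),
        "rho_star_ratio": rho_star_opt / rho_star0,
        "window_ratio": (rho_star_opt / cac_ss) / (rho_star0 / cac0),
        "K_c_nuc": math.exp(res_n.x),
        "K_c_nuc_closed": (nhat / V_r) ** (1.0 / (nhat + 1)),
    }


@dataclass
class ScalingEstimates:
    """Flat bundle of the scaling quantities for one parameter set."""

    n_hat: int
    G_nhat: float
    A_half: float
    tau_elong: float
    tau_nuc: float
    tau_half: float
    rho_nuc: float
    rho_star: float
    tau_min: float
    s_nuc: float
    s_nuc_star: float
    K_c_star: float
    K_c_starstar: float
    K_c_nuc: float
    s_llps_star: float

    def to_dict(self) -> dict:
        return asdict(self)


def scaling_estimates(
    params: AssemblyModelParams,
    compartment: CompartmentParams,
    tau_obs: float = TAU_OBS_DAY,
    x_N: float = 1.0,
) -> ScalingEstimates:
    """Evaluate the full set of scaling estimates for one parameter set."""
    p = params.normalized()
    c = compartment.normalized()
    K_c, V_r, rho_T = c.K_c, c.V_r, c.rho_T
    rho1_c = K_c * k_eff(K_c, V_r) * rho_T
    nhat, G, A = barrier_quantities(p, rho1_c if p.model_kind == "CNT" else None)
    trap = trap_threshold(p, K_c, V_r, x_N)
    speed = nucleation_speedup(K_c, V_r, nhat + 1)
    if V_r > 0 and rho_T < trap_threshold(p, 1.0, 0.0, x_N)["rho_star"]:
        sp = llps_speedup(V_r, rho_T, p, x_N)
        s_star, k_star = sp["s_llps_numeric"], sp["K_c_opt"]
    else:
        s_star, k_star = 1.0, 1.0
    if 0 < V_r < 1:
        rob = robustness_optima(V_r, p, tau_obs, x_N)
        k_ss, k_nuc = rob["K_c_starstar"], rob["K_c_nuc"]
    else:
        k_ss, k_nuc = 1.0, 1.0
    return ScalingEstimates(
        n_hat=nhat,
        G_nhat=G,
        A_half=A,
        tau_elong=elongation_time_llps(rho_T, p, K_c, V_r),
        tau_nuc=nucleation_time(rho1_c, p),
        tau_half=median_time(rho_T, p, K_c, V_r, x_N),
        rho_nuc=nucleation_threshold(tau_obs, p, K_c, V_r, x_N),
        rho_star=trap["rho_star"],
        tau_min=trap["tau_min"],
        s_nuc=speed["s_nuc"],
        s_nuc_star=speed["s_nuc_star"],
        K_c_star=k_star,
        K_c_starstar=k_ss,
        K_c_nuc=k_nuc,
        s_llps_star=s_star,
    )


def trap_threshold_master(
    params: AssemblyModelParams,
    compartment: CompartmentParams,
    rho_grid: np.ndarray,
    **integrate_kwargs,
) -> dict:
    """Trap boundary from the master equation: argmin of tau_1/2 over rho.

    The independent oracle for :func:`trap_threshold`: integrates the full
    kinetics at each grid concentration and returns the concentration
    minimizing the measured median assembly time.
    """
    from dataclasses import replace

    from .kinetics import tau_half_master

    p = params.normalized()
    c = compartment.normalized()
    taus = []
    for rho in rho_grid:
        comp = replace(c, rho_T=float(rho))
        guess = median_time(float(rho), p, c.K_c, c.V_r)
        guess = min(max(guess, elongation_time_llps(float(rho), p, c.K_c, c.V_r)), 1e12)
        taus.append(tau_half_master(p, comp, guess, **integrate_kwargs))
    taus_arr = np.array([t if t is not None else np.inf for t in taus])
    i = int(np.argmin(taus_arr))
    return {
        "rho_star_master": float(rho_grid[i]),
        "tau_min_master": float(taus_arr[i]),
        "tau_half_grid": taus_arr,
    }
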