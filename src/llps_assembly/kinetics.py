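"""Two-phase master equation for assembly kinetics and its observables.

The state is the pair of size-indexed concentration vectors rho_n^c (in the
condensate compartment) and rho_n^bg (background), n = 1..N.  Within each
phase, intermediates grow and shrink by single-subunit steps with the rate
table of the chosen pathway model (rate constants are the same in both
phases); the phases communicate by the diffusive exchange fluxes of
:mod:`llps_assembly.exchange`.  Integration uses a stiff implicit method
(BDF) with an explicit Jacobian sparsity pattern (tridiagonal chain coupling
plus the monomer row/column and the exchange diagonal).

Observables: x_N(t), the mass fraction of subunits in complete capsids; the
median assembly time tau_1/2 (first time x_N reaches half its equilibrium
value); the lag time (max-slope tangent intercept); the maximum capsid
formation rate; selectivity (fraction of capsid mass inside the
compartment); and the background monomer concentration at peak rate, the
buffering diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .cnt import cnt_rate_table
from .equilibrium import solve_equilibrium
from .exchange import ExchangeSpec, clamp_partition, exchange_flux, k_eff
from .ng import RateTable, ng_rate_table
from .params import AssemblyModelParams, CompartmentParams, validate_params

__all__ = [
    "SystemState",
    "Trajectory",
    "KineticSummary",
    "initial_state",
    "assembly_rhs",
    "rhs",
    "integrate",
    "summarize",
    "tau_half_master",
]


@dataclass
class SystemState:
    """Instantaneous state: time plus the two phase concentration vectors.

    Vectors are size-indexed (index = intermediate size, entry 0 unused).
    """

    time: float
    rho_c: np.ndarray
    rho_bg: np.ndarray


def initial_state(rho_T: float, K_c: float, V_r: float, N: int) -> SystemState:
    """All mass in monomers, pre-partitioned at quasi-equilibrium:
    rho1_bg(0) = K_eff*rho_T, rho1_c(0) = K_c*K_eff*rho_T, all n > 1 empty."""
    ke = k_eff(K_c, V_r)
    rho_c = np.zeros(N + 1)
    rho_bg = np.zeros(N + 1)
    rho_bg[1] = ke * rho_T
    rho_c[1] = K_c * ke * rho_T
    return SystemState(time=0.0, rho_c=rho_c, rho_bg=rho_bg)


def rate_table_for(params: AssemblyModelParams) -> RateTable:
    p = params.normalized()
    return ng_rate_table(p) if p.model_kind == "NG" else cnt_rate_table(p)


def assembly_rhs(rho: np.ndarray, rates: RateTable) -> np.ndarray:
    """Single-phase master-equation right-hand side (no exchange).

    Implements the birth-death chain verbatim, including the statistical
    factor 2 on monomer self-association in the monomer balance (two
    monomers are consumed per dimerization, and dimer dissociation releases
    two).
    """
    N = rates.N
    if len(rho) != N + 1:
        raise ValueError("state vector length must be N+1 (size-indexed)")
    f, b = rates.f_n, rates.b_n
    rho1 = rho[1]
    J = np.zeros(N + 1)  # association flux n -> n+1
    J[1:N] = f[1:N] * rho1 * rho[1:N]
    B = np.zeros(N + 2)  # dissociation flux n -> n-1
    B[2 : N + 1] = b[2 : N + 1] * rho[2 : N + 1]
    d = np.zeros(N + 1)
    d[2:N] = J[1 : N - 1] - J[2:N] - B[2:N] + B[3 : N + 1]
    d[N] = J[N - 1] - B[N]
    d[1] = -2.0 * J[1] - np.sum(J[2:N]) + 2.0 * B[2] + np.sum(B[3 : N + 1])
    return d


def rhs(
    state: SystemState,
    rates: RateTable,
    exch: ExchangeSpec,
    K_c: float,
    V_r: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Full two-phase time derivative (finite-rate exchange mode).

    Returns (drho_c/dt, drho_bg/dt), each size-indexed.  Total subunit mass
    is conserved by construction: sum_n n*(V_r*d_c + d_bg) = 0.
    """
    a_c = assembly_rhs(state.rho_c, rates)
    a_bg = assembly_rhs(state.rho_bg, rates)
    d_c, d_bg = exchange_flux(
        np.maximum(state.rho_c, 0.0), np.maximum(state.rho_bg, 0.0), exch, K_c, V_r
    )
    return a_c + d_c, a_bg + d_bg


@dataclass
class Trajectory:
    """Integrated kinetics on a log-spaced output grid."""

    params: AssemblyModelParams
    compartment: CompartmentParams
    t: np.ndarray
    rho_c: np.ndarray  # shape (T, N+1)
    rho_bg: np.ndarray
    mass_drift: float = 0.0
    x_N_eq: Optional[float] = None  # cached equilibrium normalization

    @property
    def N(self) -> int:
        return self.params.N

    def capsid_total(self) -> np.ndarray:
        """System-wide capsid concentration (per total volume)."""
        V_r = self.compartment.V_r
        return (V_r * self.rho_c[:, self.N] + self.rho_bg[:, self.N]) / (1.0 + V_r)

    def x_N(self) -> np.ndarray:
        """Mass fraction of subunits in complete capsids."""
        return self.N * self.capsid_total() / self.compartment.rho_T

    def selectivity(self) -> np.ndarray:
        """V_c*rho_N^c / (V_c*rho_N^c + V_bg*rho_N^bg) at each output time."""
        V_r = self.compartment.V_r
        num = V_r * self.rho_c[:, self.N]
        den = num + self.rho_bg[:, self.N]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)

    def total_mass(self) -> np.ndarray:
        sizes = np.arange(self.N + 1)
        V_r = self.compartment.V_r
        return (
            V_r * self.rho_c @ sizes + self.rho_bg @ sizes
        ) / (1.0 + V_r)

    def equilibrium_x_N(self) -> float:
        if self.x_N_eq is None:
            res = solve_equilibrium(
                self.compartment.rho_T, self.params, self.compartment
            )
            self.x_N_eq = res.xN
        return self.x_N_eq


def _sparsity_two_phase(N: int) -> lil_matrix:
    M = lil_matrix((2 * N, 2 * N), dtype=np.int8)
    for off in (0, N):
        for i in range(N):
            M[off + i, off + i] = 1
            if i > 0:
                M[off + i, off + i - 1] = 1
            if i < N - 1:
                M[off + i, off + i + 1] = 1
            M[off + i, off] = 1  # everything depends on the local monomer
            M[off, off + i] = 1  # the monomer balance touches every size
        # exchange couples equal sizes across phases
    for i in range(N):
        M[i, N + i] = 1
        M[N + i, i] = 1
    return M


def _sparsity_single(N: int) -> lil_matrix:
    M = lil_matrix((N, N), dtype=np.int8)
    for i in range(N):
        M[i, i] = 1
        if i > 0:
            M[i, i - 1] = 1
        if i < N - 1:
            M[i, i + 1] = 1
        M[i, 0] = 1
        M[0, i] = 1
    return M


def integrate(
    assembly: AssemblyModelParams,
    compartment: CompartmentParams,
    t_end: float,
    rtol: float = 1e-8,
    atol: Optional[float] = None,
    n_out: int = 200,
    t_first: float = 1e-3,
    mass_tol: float = 1e-6,
) -> Trajectory:
    """Integrate the two-phase master equation from the standard initial state.

    Output is on a log-spaced grid from ``t_first`` to ``t_end`` (plus t=0).
    Negative concentrations are not clipped during integration (tolerances
    are tight instead); they are floored at zero on output.  Total subunit
    mass must be conserved to ``mass_tol`` relative over the run or a
    RuntimeError is raised.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    p, c = validate_params(assembly, compartment)
    N = p.N
    rates = rate_table_for(p)
    exch: ExchangeSpec = c.exchange
    K_c, V_r, rho_T = c.K_c, c.V_r, c.rho_T
    if atol is None:
        atol = rho_T * 1e-14

    s0 = initial_state(rho_T, K_c, V_r, N)
    t_eval = np.concatenate([[0.0], np.geomspace(t_first, t_end, n_out)])
    t_eval = t_eval[t_eval <= t_end]
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)

    if exch.mode == "fast_equilibrium":
        y0 = (V_r * s0.rho_c[1:] + s0.rho_bg[1:]) / (1.0 + V_r)

        def fun(t, y):
            tot = np.concatenate([[0.0], y])
            rc, rbg = clamp_partition(np.maximum(tot, 0.0), K_c, V_r)
            a_c = assembly_rhs(rc, rates)
            a_bg = assembly_rhs(rbg, rates)
            return (V_r * a_c[1:] + a_bg[1:]) / (1.0 + V_r)

        sparsity = _sparsity_single(N)
    else:

        def fun(t, y):
            st = SystemState(
                t,
                np.concatenate([[0.0], y[:N]]),
                np.concatenate([[0.0], y[N:]]),
            )
            d_c, d_bg = rhs(st, rates, exch, K_c, V_r)
            return np.concatenate([d_c[1:], d_bg[1:]])

        y0 = np.concatenate([s0.rho_c[1:], s0.rho_bg[1:]])
        sparsity = _sparsity_two_phase(N)

    sol = solve_ivp(
        fun,
        (0.0, t_end),
        y0,
        method="BDF",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac_sparsity=sparsity,
    )
    if not sol.success:
        raise RuntimeError(f"stiff integration failed: {sol.message}")

    T = len(sol.t)
    rho_c = np.zeros((T, N + 1))
    rho_bg = np.zeros((T, N + 1))
    if exch.mode == "fast_equilibrium":
        for i in range(T):
            tot = np.concatenate([[0.0], np.maximum(sol.y[:, i], 0.0)])
            rc, rbg = clamp_partition(tot, K_c, V_r)
            rho_c[i], rho_bg[i] = rc, rbg
    else:
        rho_c[:, 1:] = np.maximum(sol.y[:N].T, 0.0)
        rho_bg[:, 1:] = np.maximum(sol.y[N:].T, 0.0)

    traj = Trajectory(params=p, compartment=c, t=sol.t, rho_c=rho_c, rho_bg=rho_bg)
    mass = traj.total_mass()
    drift = float(np.max(np.abs(mass - rho_T)) / rho_T)
    traj.mass_drift = drift
    if drift > mass_tol:
        raise RuntimeError(
            f"mass conservation violated: relative drift {drift:.2e} > {mass_tol:.0e}"
        )
    return traj


@dataclass
class KineticSummary:
    """Scalar observables extracted from one trajectory.

    Unresolved quantities (e.g. tau_half when the run never brackets half
    completion) are ``None`` rather than extrapolated.
    """

    tau_half: Optional[float]
    tau_lag: Optional[float]
    max_rate: float
    t_max_rate: float
    rho1_bg_at_max_rate: float
    x_N_end: float
    x_N_eq: float
    selectivity_end: float
    xN_at_tau_obs: Optional[float] = None
    tau_obs: Optional[float] = None


def _capsid_rate_series(traj: Trajectory) -> np.ndarray:
    """d/dt of the system-wide capsid concentration, from exact RHS values."""
    p, c = traj.params, traj.compartment
    rates = rate_table_for(p)
    V_r, K_c = c.V_r, c.K_c
    out = np.zeros(len(traj.t))
    for i in range(len(traj.t)):
        st = SystemState(traj.t[i], traj.rho_c[i], traj.rho_bg[i])
        if c.exchange.mode == "fast_equilibrium":
            a_c = assembly_rhs(traj.rho_c[i], rates)
            a_bg = assembly_rhs(traj.rho_bg[i], rates)
            d_c, d_bg = a_c, a_bg
        else:
            d_c, d_bg = rhs(st, rates, c.exchange, K_c, V_r)
        out[i] = (V_r * d_c[p.N] + d_bg[p.N]) / (1.0 + V_r)
    return out


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> Optional[float]:
    """First time y reaches `level`, log-t interpolated; None if never."""
    above = y >= level
    if not np.any(above):
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1 = t[i - 1], t[i]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    if t0 <= 0:
        return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))
    w = (level - y0) / (y1 - y0)
    return float(np.exp(np.log(t0) + w * (np.log(t1) - np.log(t0))))


def summarize(traj: Trajectory, tau_obs: Optional[float] = None) -> KineticSummary:
    """Extract tau_1/2, lag time, peak rate, buffering and selectivity.

    tau_1/2 is referenced to the *equilibrium* extent: the first time x_N(t)
    reaches half of its equilibrium value.  The lag time is the intercept of
    the tangent at maximum dx_N/dt with x_N = 0.  The peak capsid formation
    rate is evaluated from the exact right-hand side at the stored states;
    the background monomer concentration read at that time quantifies
    buffering.
    """
    xN = traj.x_N()
    x_eq = traj.equilibrium_x_N()
    tau_half = _first_crossing(traj.t, xN, 0.5 * x_eq)

    rate = _capsid_rate_series(traj)
    i_max = int(np.argmax(rate))
    max_rate = float(rate[i_max])
    t_max = float(traj.t[i_max])
    rho1_bg = float(traj.rho_bg[i_max, 1])

    xN_rate = rate * traj.N / traj.compartment.rho_T
    tau_lag = None
    if xN_rate[i_max] > 0:
        tau_lag = float(t_max - xN[i_max] / xN_rate[i_max])

    sel = traj.selectivity()
    summary = KineticSummary(
        tau_half=tau_half,
        tau_lag=tau_lag,
        max_rate=max_rate,
        t_max_rate=t_max,
        rho1_bg_at_max_rate=rho1_bg,
        x_N_end=float(xN[-1]),
        x_N_eq=float(x_eq),
        selectivity_end=float(sel[-1]) if np.isfinite(sel[-1]) else float("nan"),
    )
    if tau_obs is not None:
        summary.tau_obs = tau_obs
        if tau_obs <= traj.t[-1]:
            summary.xN_at_tau_obs = float(np.interp(tau_obs, traj.t, xN))
    return summary


def tau_half_master(
    assembly: AssemblyModelParams,
    compartment: CompartmentParams,
    t_guess: float,
    max_expand: int = 3,
    **kwargs,
) -> Optional[float]:
    """Median assembly time from the master equation.

    Integrates to ~30x the guessed timescale and expands the horizon (up to
    ``max_expand`` times, x100 each) if half completion is not yet bracketed.
    Returns None if still unresolved.
    """
    t_end = 30.0 * t_guess
    for _ in range(max_expand + 1):
        traj = integrate(assembly, compartment, t_end, **kwargs)
        summ = summarize(traj)
        if summ.tau_half is not None:
            return summ.tau_half
        t_end *= 100.0
    return None
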