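"""Classical-nucleation-theory (CNT) shell model.

Intermediates are partial spherical shells missing a spherical cap.  The
subunits on the rim of the cap have unsatisfied contacts, producing a line
tension sigma.  All lengths are carried in units of the subunit diameter
l0 = v0^(1/3); the line-tension energy enters only through the combination
sigma*l0 (k_BT).  The critical nucleus size is concentration dependent,
which is the key qualitative difference from the NG pathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ng import RateTable
from .params import AssemblyModelParams

__all__ = [
    "CntGeometry",
    "cnt_geometry",
    "cnt_rim_length",
    "cnt_intermediate_energy",
    "cnt_critical_nucleus",
    "cnt_rate_table",
]


@dataclass
class CntGeometry:
    """Shell geometry: N = 4*pi*R^2/a0 with a0 = v0^(2/3), l0 = v0^(1/3).

    ``sigma_l0`` is the line-tension energy per rim subunit (k_BT).
    """

    N: int
    sigma_l0: float

    @property
    def shell_radius_l0(self) -> float:
        """Shell radius in units of l0, R = l0*sqrt(N/4pi)."""
        return math.sqrt(self.N / (4.0 * math.pi))


def cnt_geometry(params: AssemblyModelParams) -> CntGeometry:
    p = params.normalized()
    if p.sigma_l0 is None:
        raise ValueError("CNT geometry requires sigma_l0 (or g_sub)")
    return CntGeometry(N=p.N, sigma_l0=p.sigma_l0)


def cnt_rim_length(n, geom: CntGeometry) -> np.ndarray | float:
    """Rim length l_n of the missing spherical cap, in units of l0.

    l_n/l0 = 2*sqrt(pi*n*(N-n)/N).  The prefactor is fixed by the geometric
    requirement that the half-shell rim equals the great circle: at n = N/2,
    l_n = 2*pi*R with R = l0*sqrt(N/4pi).  l_0 = l_N = 0 (closed shell) and
    l_n = l_{N-n} by symmetry.
    """
    n_arr = np.asarray(n, dtype=float)
    N = geom.N
    if np.any(n_arr < 0) or np.any(n_arr > N):
        raise ValueError("size n out of range 0..N")
    out = 2.0 * np.sqrt(np.pi * n_arr * (N - n_arr) / N)
    return out if out.shape else float(out)


def cnt_intermediate_energy(
    n, params: AssemblyModelParams, geom: CntGeometry | None = None
) -> np.ndarray | float:
    """Total binding free energy G_n = n*g_sub + sigma*l_n (k_BT).

    Continuum form with G_0 = 0; note G_1 != 0, an artifact of describing a
    single subunit as a shell fragment.  Only differences G_{n+1} - G_n enter
    the kinetics; quantities referenced to free monomers (the stationary
    distribution, the scaling estimates) use G_n - G_1.
    """
    p = params.normalized()
    if geom is None:
        geom = cnt_geometry(p)
    n_arr = np.asarray(n, dtype=float)
    g = n_arr * p.g_sub + geom.sigma_l0 * cnt_rim_length(n_arr, geom)
    return g if g.shape else float(g)


def cnt_critical_nucleus(
    rho1: float, params: AssemblyModelParams, geom: CntGeometry | None = None
) -> dict:
    """Concentration-dependent critical nucleus size.

    The discrete value (authoritative) is the integer n in 1..N maximizing
    the total free energy of the chain, G_n - n*ln(rho1*v0); the closed form
    is the continuous stationary point of the same function,
    n* = N/2 * (1 - Gamma/sqrt(Gamma^2 + 1)) with
    Gamma = (ln(rho1*v0) - g_sub) * sqrt(N/pi) / (2*sigma_l0).

    Raises if the profile is monotonically decreasing (no barrier).
    """
    p = params.normalized()
    if geom is None:
        geom = cnt_geometry(p)
    if rho1 <= 0:
        raise ValueError("rho1 must be positive")
    log_rho = math.log(rho1 / p.v0_conc)
    ns = np.arange(1, p.N + 1)
    profile = cnt_intermediate_energy(ns, p, geom) - ns * log_rho
    i_max = int(np.argmax(profile))
    n_disc = int(ns[i_max])
    if n_disc == 1 and profile[0] >= profile[-1] and np.all(np.diff(profile) <= 0):
        raise ValueError("free-energy profile is monotonically decreasing: no barrier")
    gamma = (log_rho - p.g_sub) * math.sqrt(p.N / math.pi) / (2.0 * geom.sigma_l0)
    n_cont = 0.5 * p.N * (1.0 - gamma / math.sqrt(gamma * gamma + 1.0))
    return {"n_nuc_discrete": n_disc, "n_nuc_closed_form": n_cont}


def cnt_rate_table(
    params: AssemblyModelParams, geom: CntGeometry | None = None
) -> RateTable:
    """CNT rate table: f_n = f0*l_n/l0, b by detailed balance.

    The forward rate is proportional to the number of rim subunits; the
    dissociation rate b_{n+1} = (f_n/v0)*exp(G_{n+1} - G_n) follows from
    detailed balance.  The final addition is slow (tiny rim) but nearly
    irreversible since G_N - G_{N-1} = g_sub - sigma*l_{N-1} is strongly
    negative.
    """
    p = params.normalized()
    if p.model_kind != "CNT":
        raise ValueError("cnt_rate_table requires model_kind='CNT'")
    if geom is None:
        geom = cnt_geometry(p)
    N = p.N
    sizes = np.arange(N + 1)
    rim = cnt_rim_length(sizes, geom)
    G = cnt_intermediate_energy(sizes, p, geom)
    f_n = np.zeros(N + 1)
    f_n[1:N] = p.f * rim[1:N]
    b_n = np.zeros(N + 1)
    # b_{n} from the step (n-1 -> n): v0*b_n = f_{n-1} * exp(G_n - G_{n-1})
    b_n[2 : N + 1] = p.v0_conc * f_n[1:N] * np.exp(G[2 : N + 1] - G[1:N])
    return RateTable(N=N, f_n=f_n, b_n=b_n)
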