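"""Shared parameter types, validation, and compartment-geometry helpers.

Unit conventions used throughout the package:

* concentrations are molar (M); the standard state is expressed through a
  reference concentration ``v0_conc`` whose inverse is the standard-state
  volume v0 (default 1 M, i.e. v0 = 1/(1 M));
* energies are in units of k_BT (negative = favorable); there is no explicit
  temperature parameter because every formula only ever uses beta*g;
* times are seconds, association rate constants are M^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "AssemblyModelParams",
    "CompartmentParams",
    "CompartmentGeometry",
    "validate_params",
    "compartment_geometry",
]

#: seconds in one day; the default observation time for finite-time yields.
TAU_OBS_DAY = 9.0e4


@dataclass
class AssemblyModelParams:
    """Parameters of a single assembly pathway model.

    Two pathway models are supported.  The nucleation-and-growth (``"NG"``)
    model has a fixed critical nucleus size ``n_nuc`` and piecewise constant
    dissociation rates set by the three binding free energies ``g_nuc``
    (pre-nucleus steps), ``g_elong`` (elongation steps) and ``g_N`` (shell
    completion).  The classical-nucleation-theory (``"CNT"``) model treats
    intermediates as partial spherical shells with per-subunit energy
    ``g_sub`` and a rim line tension ``sigma_l0`` (the energy sigma*l0 in
    k_BT), giving a concentration-dependent critical nucleus.

    Parameters
    ----------
    model_kind : {"NG", "CNT"}
    N : int
        Target assembly (capsid) size in subunits.
    n_nuc : int, optional
        Critical nucleus size (NG only).
    g_nuc, g_elong, g_N : float
        NG step free energies in k_BT.  ``g_N`` defaults to ``2*g_elong``.
    g_sub : float, optional
        Per-subunit binding energy in k_BT.  Required for CNT and used by the
        two-state equilibrium theory; for NG it defaults to ``g_elong``.
    f : float
        Association rate constant (M^-1 s^-1); for CNT this is the
        single-site constant f_0.
    v0_conc : float
        Reference concentration defining the standard-state volume,
        v0 = 1/v0_conc.  Default 1 M.
    sigma_l0 : float, optional
        Line-tension energy sigma*l0 in k_BT (CNT); defaults to -g_sub/2 so
        that a rim subunit satisfies half of its contacts on average.
    alpha : float, optional
        Elongation exponent in tau_elong = N^alpha/(f rho1); defaults to 1
        for NG and 1/2 for CNT.
    """

    model_kind: str = "NG"
    N: int = 120
    n_nuc: Optional[int] = 3
    g_nuc: float = -4.0
    g_elong: float = -17.0
    g_N: Optional[float] = None
    g_sub: Optional[float] = None
    f: float = 1.0e5
    v0_conc: float = 1.0
    sigma_l0: Optional[float] = None
    alpha: Optional[float] = None

    def normalized(self) -> "AssemblyModelParams":
        """Return a copy with all derived defaults filled in (idempotent)."""
        p = replace(self)
        if p.model_kind not in ("NG", "CNT"):
            raise ValueError(f"unknown model_kind {p.model_kind!r}")
        if p.N < 3:
            raise ValueError("target size N must be >= 3")
        if p.f <= 0:
            raise ValueError("association rate constant f must be positive")
        if p.v0_conc <= 0:
            raise ValueError("reference concentration v0_conc must be positive")
        if p.model_kind == "NG":
            if p.n_nuc is None:
                raise ValueError("NG model requires n_nuc")
            if not (2 <= p.n_nuc < p.N):
                raise ValueError("NG model requires 2 <= n_nuc < N")
            if p.g_N is None:
                p.g_N = 2.0 * p.g_elong
            if p.g_sub is None:
                # single per-subunit energy used by the two-state equilibrium
                p.g_sub = p.g_elong
            if p.alpha is None:
                p.alpha = 1.0
        else:  # CNT
            if p.g_sub is None:
                raise ValueError("CNT model requires g_sub")
            if p.alpha is None:
                p.alpha = 0.5
        if p.g_sub is not None and p.sigma_l0 is None:
            p.sigma_l0 = -p.g_sub / 2.0
        return p


@dataclass
class CompartmentParams:
    """Two-phase (compartment + background) parameters.

    ``K_c`` is the equilibrium partition coefficient of free subunits into
    the compartment, related to the solvation free-energy difference by
    K_c = exp(-g_c).  ``V_r = V_c/V_bg`` is the compartment-to-background
    volume ratio.  ``V_r = 0`` or ``K_c = 1`` reduces every downstream
    computation to the homogeneous (no-LLPS) case.
    """

    K_c: float = 1.0
    V_r: float = 1.0e-3
    rho_T: float = 2.0e-7
    g_c: Optional[float] = None
    exchange: Optional[object] = None  # ExchangeSpec; default built lazily

    def normalized(self) -> "CompartmentParams":
        c = replace(self)
        if c.K_c < 0:
            raise ValueError("partition coefficient K_c must be >= 0")
        if c.V_r < 0:
            raise ValueError("volume ratio V_r must be >= 0")
        if c.rho_T <= 0:
            raise ValueError("total concentration rho_T must be positive")
        if c.g_c is None:
            if c.K_c == 0:
                c.g_c = math.inf
            else:
                c.g_c = -math.log(c.K_c)
        else:
            if c.K_c > 0 and not math.isclose(
                c.K_c, math.exp(-c.g_c), rel_tol=1e-12
            ):
                raise ValueError("inconsistent K_c and g_c: need K_c = exp(-g_c)")
        if c.exchange is None:
            from .exchange import ExchangeSpec

            c.exchange = ExchangeSpec()
        return c


def validate_params(
    assembly: AssemblyModelParams, compartment: CompartmentParams
) -> tuple[AssemblyModelParams, CompartmentParams]:
    """Normalize and cross-validate a parameter pair.

    Fills derived defaults (g_c from K_c, sigma_l0 = -g_sub/2, g_N =
    2*g_elong, alpha by model kind) and rejects inconsistent input.  The
    operation is idempotent: validating an already-validated pair returns an
    equal pair.
    """
    return assembly.normalized(), compartment.normalized()


@dataclass
class CompartmentGeometry:
    """Geometric consequences of placing one condensate droplet in a cell.

    Lengths in micrometres, volumes in nm^3 (typical protein scale).
    """

    cell_radius_um: float
    V_r: float
    subunit_volume_nm3: float
    volume_fraction: float
    compartment_radius_um: float = field(init=False)
    max_protein_count: float = field(init=False)

    def __post_init__(self) -> None:
        self.compartment_radius_um = self.cell_radius_um * (
            self.V_r / (1.0 + self.V_r)
        ) ** (1.0 / 3.0)
        vol_nm3 = (4.0 / 3.0) * math.pi * (self.compartment_radius_um * 1e3) ** 3
        self.max_protein_count = self.volume_fraction * vol_nm3 / self.subunit_volume_nm3

    def min_radius_for(self, count: float) -> float:
        """Radius (um) of the smallest droplet holding `count` subunits
        at the given volume fraction.  Scales exactly as count^(1/3)."""
        vol_nm3 = count * self.subunit_volume_nm3 / self.volume_fraction
        return (3.0 * vol_nm3 / (4.0 * math.pi)) ** (1.0 / 3.0) * 1e-3


def compartment_geometry(
    cell_radius_um: float,
    V_r: float,
    subunit_volume_nm3: float,
    volume_fraction: float,
) -> CompartmentGeometry:
    """Compartment radius, subunit capacity and minimal droplet size.

    For a cell of radius ``cell_radius_um`` containing one droplet occupying
    a fraction ``V_r/(1+V_r)`` of the cell volume, returns the droplet
    radius, the maximum number of subunits it can hold at the given packing
    ``volume_fraction``, and (via :meth:`CompartmentGeometry.min_radius_for`)
    the smallest droplet radius holding a given subunit count.
    """
    if cell_radius_um <= 0 or subunit_volume_nm3 <= 0:
        raise ValueError("lengths and volumes must be positive")
    if not (0 < V_r < 1):
        raise ValueError("V_r must be in (0, 1) for a sub-cellular droplet")
    if not (0 < volume_fraction < 1):
        raise ValueError("volume fraction must be in (0, 1)")
    return CompartmentGeometry(
        cell_radius_um, V_r, subunit_volume_nm3, volume_fraction
    )
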