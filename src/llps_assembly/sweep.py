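"""Parameter-grid sweeps with theory overlays.

A sweep integrates the master equation at every point of a (rho_T, K_c,
V_r) grid and collects the kinetic observables in a long-format tidy table,
one row per grid point per observation time.  A companion theory table
carries the equilibrium and scaling overlays (rho_CAC, rho_nuc, rho_star)
for the same grid points, so heatmap boundaries can be drawn directly from
the data.  Everything is deterministic: identical specs produce
bit-identical CSV output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .equilibrium import critical_assembly_concentration
from .exchange import ExchangeSpec
from .io import params_from_dict, params_to_dict
from .kinetics import integrate, summarize
from .params import AssemblyModelParams, CompartmentParams, TAU_OBS_DAY
from .scaling import nucleation_threshold, trap_threshold

__all__ = ["SweepSpec", "SweepResult", "run_sweep", "write_results", "read_results"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

RESULT_COLUMNS = [
    "rho_T",
    "K_c",
    "V_r",
    "tau_obs_s",
    "x_N",
    "tau_half_s",
    "tau_lag_s",
    "max_rate_M_s",
    "selectivity",
    "rho1_bg_at_max_rate_M",
    "solver_ok",
    "flag",
]

THEORY_COLUMNS = ["rho_T", "K_c", "V_r", "rho_CAC", "rho_nuc", "rho_star"]


@dataclass
class SweepSpec:
    """Declarative description of one sweep.

    Each of ``rho_T``, ``K_c`` and ``V_r`` is a sequence of values; at most
    two of them may have more than one entry.  ``tau_obs`` lists the
    observation times at which finite-time yields are read.  ``seed`` is
    recorded for provenance only — the core is deterministic.
    """

    assembly: AssemblyModelParams = field(default_factory=AssemblyModelParams)
    rho_T: Sequence[float] = (2.0e-7,)
    K_c: Sequence[float] = (1.0,)
    V_r: Sequence[float] = (1.0e-3,)
    tau_obs: Sequence[float] = (TAU_OBS_DAY,)
    exchange_mode: str = "fast_equilibrium"
    k_exch: float = 300.0
    rtol: float = 1e-8
    seed: Optional[int] = None
    note: str = ""

    def __post_init__(self) -> None:
        axes = [self.rho_T, self.K_c, self.V_r]
        if any(len(a) == 0 for a in axes) or len(self.tau_obs) == 0:
            raise ValueError("grids must be nonempty")
        if sum(len(a) > 1 for a in axes) > 2:
            raise ValueError("at most 2 swept axes per run")

    def grid(self):
        for vr in self.V_r:
            for kc in self.K_c:
                for rho in self.rho_T:
                    yield float(rho), float(kc), float(vr)

    def to_dict(self) -> dict:
        base = params_to_dict(
            self.assembly,
            CompartmentParams(
                K_c=float(self.K_c[0]),
                V_r=float(self.V_r[0]),
                rho_T=float(self.rho_T[0]),
                exchange=ExchangeSpec(mode=self.exchange_mode, k_exch=self.k_exch),
            ),
        )
        return {
            "schema_version": SCHEMA_VERSION,
            "package_version": __version__,
            "assembly": base["assembly"],
            "rho_T": [float(x) for x in self.rho_T],
            "K_c": [float(x) for x in self.K_c],
            "V_r": [float(x) for x in self.V_r],
            "tau_obs": [float(x) for x in self.tau_obs],
            "exchange_mode": self.exchange_mode,
            "k_exch": self.k_exch,
            "rtol": self.rtol,
            "seed": self.seed,
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SweepSpec":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported sweep schema: {d.get('schema_version')}")
        assembly, _ = params_from_dict(
            {
                "assembly": d["assembly"],
                "compartment": {
                    "K_c": 1.0,
                    "V_r": 0.0,
                    "rho_T": 1.0,
                    "exchange": {"mode": d["exchange_mode"], "k_exch": d["k_exch"]},
                },
            }
        )
        return cls(
            assembly=assembly,
            rho_T=d["rho_T"],
            K_c=d["K_c"],
            V_r=d["V_r"],
            tau_obs=d["tau_obs"],
            exchange_mode=d["exchange_mode"],
            k_exch=d["k_exch"],
            rtol=d["rtol"],
            seed=d.get("seed"),
            note=d.get("note", ""),
        )


@dataclass
class SweepResult:
    spec: SweepSpec
    table: pd.DataFrame
    theory: pd.DataFrame


def _theory_row(
    assembly: AssemblyModelParams, rho: float, kc: float, vr: float
) -> dict:
    comp = CompartmentParams(K_c=kc, V_r=vr, rho_T=rho).normalized()
    cac = critical_assembly_concentration(assembly, comp)["rho_CAC"]
    try:
        rho_nuc = nucleation_threshold(TAU_OBS_DAY, assembly, kc, vr)
    except (ValueError, RuntimeError):
        rho_nuc = float("nan")
    try:
        rho_star = trap_threshold(assembly, kc, vr)["rho_star"]
    except (ValueError, RuntimeError):
        rho_star = float("nan")
    return {
        "rho_T": rho,
        "K_c": kc,
        "V_r": vr,
        "rho_CAC": cac,
        "rho_nuc": rho_nuc,
        "rho_star": rho_star,
    }


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Integrate the master equation over the grid and attach theory overlays.

    Per-point solver failures are recorded in the ``flag`` column and leave
    NaNs in the observables; they are not fatal.
    """
    assembly = spec.assembly.normalized()
    rows, theory_rows = [], []
    t_end = max(spec.tau_obs)
    for rho, kc, vr in spec.grid():
        theory_rows.append(_theory_row(assembly, rho, kc, vr))
        comp = CompartmentParams(
            K_c=kc,
            V_r=vr,
            rho_T=rho,
            exchange=ExchangeSpec(mode=spec.exchange_mode, k_exch=spec.k_exch),
        )
        try:
            traj = integrate(assembly, comp, t_end, rtol=spec.rtol)
            err = ""
        except (RuntimeError, ValueError) as exc:  # recorded, not fatal
            logger.warning(
                "sweep point failed: rho_T=%g K_c=%g V_r=%g: %s", rho, kc, vr, exc
            )
            traj, err = None, str(exc)
        for tau in spec.tau_obs:
            row = {
                "rho_T": rho,
                "K_c": kc,
                "V_r": vr,
                "tau_obs_s": float(tau),
                "x_N": float("nan"),
                "tau_half_s": float("nan"),
                "tau_lag_s": float("nan"),
                "max_rate_M_s": float("nan"),
                "selectivity": float("nan"),
                "rho1_bg_at_max_rate_M": float("nan"),
                "solver_ok": traj is not None,
                "flag": err,
            }
            if traj is not None:
                s = summarize(traj, tau_obs=float(tau))
                row.update(
                    x_N=s.xN_at_tau_obs,
                    tau_half_s=s.tau_half if s.tau_half is not None else float("nan"),
                    tau_lag_s=s.tau_lag if s.tau_lag is not None else float("nan"),
                    max_rate_M_s=s.max_rate,
                    selectivity=s.selectivity_end,
                    rho1_bg_at_max_rate_M=s.rho1_bg_at_max_rate,
                )
                if s.tau_half is None:
                    row["flag"] = "tau_half_unresolved"
            logger.info(
                "point rho_T=%g K_c=%g V_r=%g tau_obs=%g: x_N=%s",
                rho,
                kc,
                vr,
                tau,
                row["x_N"],
            )
            rows.append(row)
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    theory = pd.DataFrame(theory_rows, columns=THEORY_COLUMNS)
    return SweepResult(spec=spec, table=table, theory=theory)


def write_results(result: SweepResult, path: str | Path) -> None:
    """Write ``<path>.csv``, ``<path>_theory.csv`` and the ``<path>.json``
    sidecar (full spec, package and schema versions, solver options)."""
    base = Path(path)
    result.table.to_csv(base.with_suffix(".csv"), index=False, float_format="%.17g")
    result.theory.to_csv(
        base.parent / (base.stem + "_theory.csv"), index=False, float_format="%.17g"
    )
    base.with_suffix(".json").write_text(json.dumps(result.spec.to_dict(), indent=2))


def read_results(path: str | Path) -> SweepResult:
    base = Path(path)
    spec = SweepSpec.from_dict(json.loads(base.with_suffix(".json").read_text()))
    table = pd.read_csv(base.with_suffix(".csv"), float_precision="round_trip")
    missing = set(RESULT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"result CSV missing columns {sorted(missing)}")
    table["flag"] = table["flag"].fillna("")
    for col in RESULT_COLUMNS:
        if col not in ("flag", "solver_ok"):
            table[col] = table[col].astype(float)
    theory = pd.read_csv(
        base.parent / (base.stem + "_theory.csv"), float_precision="round_trip"
    )
    missing = set(THEORY_COLUMNS) - set(theory.columns)
    if missing:
        raise ValueError(f"theory CSV missing columns {sorted(missing)}")
    theory = theory.astype({c: float for c in THEORY_COLUMNS})
    return SweepResult(spec=spec, table=table, theory=theory)
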