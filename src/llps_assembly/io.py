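"""Readers and writers for trajectories and kinetic summaries.

Trajectories are stored as tidy long-format CSV (columns ``time_s, phase,
n, concentration_M``) with a JSON sidecar carrying the parameter set, so a
trajectory can be reconstructed exactly.  Summaries are flat JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exchange import ExchangeSpec
from .kinetics import KineticSummary, Trajectory
from .params import AssemblyModelParams, CompartmentParams

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_summary",
    "read_summary",
    "params_to_dict",
    "params_from_dict",
]

_FLOAT_FMT = "%.17g"


def params_to_dict(
    assembly: AssemblyModelParams, compartment: CompartmentParams
) -> dict:
    a = asdict(assembly.normalized())
    c_norm = compartment.normalized()
    exch: ExchangeSpec = c_norm.exchange
    if exch.size_scaling is not None:
        raise ValueError("custom size_scaling callables are not serializable")
    c = {
        "K_c": c_norm.K_c,
        "V_r": c_norm.V_r,
        "rho_T": c_norm.rho_T,
        "g_c": c_norm.g_c,
        "exchange": {"mode": exch.mode, "k_exch": exch.k_exch},
    }
    return {"assembly": a, "compartment": c}


def params_from_dict(d: dict) -> tuple[AssemblyModelParams, CompartmentParams]:
    a = AssemblyModelParams(**d["assembly"])
    cd = dict(d["compartment"])
    exch = ExchangeSpec(**cd.pop("exchange"))
    c = CompartmentParams(exchange=exch, **cd)
    return a.normalized(), c.normalized()


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format view of a trajectory (one row per time, phase, size)."""
    N = traj.N
    frames = []
    for phase, arr in (("c", traj.rho_c), ("bg", traj.rho_bg)):
        t_rep = np.repeat(traj.t, N)
        n_rep = np.tile(np.arange(1, N + 1), len(traj.t))
        frames.append(
            pd.DataFrame(
                {
                    "time_s": t_rep,
                    "phase": phase,
                    "n": n_rep,
                    "concentration_M": arr[:, 1:].ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    trajectory_frame(traj).to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = params_to_dict(traj.params, traj.compartment)
    sidecar["mass_drift"] = traj.mass_drift
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "phase", "n", "concentration_M"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV missing columns {required - set(df.columns)}")
    meta = json.loads(path.with_suffix(".json").read_text())
    assembly, compartment = params_from_dict(meta)
    N = assembly.N
    t = np.sort(df["time_s"].unique())
    arrs = {}
    for phase in ("c", "bg"):
        sub = df[df["phase"] == phase].sort_values(["time_s", "n"])
        arr = np.zeros((len(t), N + 1))
        arr[:, 1:] = sub["concentration_M"].to_numpy().reshape(len(t), N)
        arrs[phase] = arr
    return Trajectory(
        params=assembly,
        compartment=compartment,
        t=t,
        rho_c=arrs["c"],
        rho_bg=arrs["bg"],
        mass_drift=meta.get("mass_drift", 0.0),
    )


def write_summary(summary: KineticSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(summary), indent=2))


def read_summary(path: str | Path) -> KineticSummary:
    return KineticSummary(**json.loads(Path(path).read_text()))
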