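"""Persistence: self-describing run containers (zarr) and CSV exports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import Grid1D
from .params import DimensionlessParams
from .state import SimulationOutput, SwarmState

__all__ = ["save_run", "load_run", "kymograph_csv", "branch_csv"]


def to_dataset(output: SimulationOutput) -> xr.Dataset:
    """Pack a run into an xarray Dataset (fields h/b/c over time x space)."""
    ds = xr.Dataset(
        {name: (("t", "x"), getattr(output, name))
         for name in ("h", "b", "c")},
        coords={"t": output.times, "x": output.grid.x},
    )
    ds.attrs["params"] = json.dumps(output.params.__dict__)
    ds.attrs["boundary_kind"] = output.grid.boundary_kind
    ds.attrs["events"] = json.dumps(output.events)
    ds.attrs["provenance"] = json.dumps(output.provenance)
    return ds


def from_dataset(ds: xr.Dataset) -> SimulationOutput:
    params = DimensionlessParams(**json.loads(ds.attrs["params"]))
    grid = Grid1D(ds["x"].values, ds.attrs.get("boundary_kind", "far_field_film"))
    times = ds["t"].values
    h, b, c = ds["h"].values, ds["b"].values, ds["c"].values
    states = [SwarmState(float(t), h[k], b[k], c[k]) for k, t in enumerate(times)]
    events = [tuple(e) for e in json.loads(ds.attrs.get("events", "[]"))]
    prov = json.loads(ds.attrs.get("provenance", "{}"))
    return SimulationOutput(times, states, params, grid, events, prov)


def save_run(output: SimulationOutput, path: str | Path) -> None:
    """Write a run container (zarr directory store)."""
    to_dataset(output).to_zarr(str(path), mode="w")


def load_run(path: str | Path) -> SimulationOutput:
    return from_dataset(xr.open_zarr(str(path)).load())


def kymograph_csv(output: SimulationOutput, path: str | Path) -> None:
    """Long-format CSV export: one row per (time, x) with h, b, c."""
    T, X = np.meshgrid(output.times, output.grid.x, indexing="ij")
    pd.DataFrame({"time": T.ravel(), "x": X.ravel(),
                  "h": output.h.ravel(), "b": output.b.ravel(),
                  "c": output.c.ravel()}).to_csv(path, index=False)


def branch_csv(branch, path: str | Path, *, sensing: float | None = None) -> None:
    """Continuation-branch CSV: arclength, V, U, L, m_ch, label, fold_flag."""
    from .metrics import m_ch as m_ch_fn

    rows = []
    fold_vols = set()
    for fv in branch.folds:
        fold_vols.add(round(fv, 6))
    for s, sol in zip(branch.arclength, branch.solutions):
        grid = sol.grid
        thr_sens = sensing if sensing is not None else sol.params.sensing
        above = np.flatnonzero(sol.profile > 0.3)
        if above.size:
            rear, front = grid.x[above[0]], grid.x[above[-1]]
            mch = m_ch_fn(sol.profile, sol.chemo, grid, rear, front, thr_sens,
                          precursor=sol.params.precursor)
        else:
            mch = np.nan
        near_fold = any(abs(sol.volume - fv) < 0.02 * max(sol.volume, 1e-9)
                        for fv in fold_vols)
        rows.append({"arclength": s, "V": sol.volume, "U": sol.speed,
                     "L": sol.length, "m_ch": mch, "label": sol.branch_label,
                     "fold_flag": near_fold})
    pd.DataFrame(rows).to_csv(path, index=False)
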