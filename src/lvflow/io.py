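"""HDF5 container for gridded fields and JSON contours.

One HDF5 file holds a whole run: grid metadata as root attributes
(``nx, ny, nz, h, origin``), per-frame groups ``frame_000`` … containing
``mask`` (int8 legend: 0 outside, 1 inside, 2 wall boundary, 3 valve
boundary), ``velocity`` (3, nx, ny, nz), ``doppler``, ``pressure`` and the
frame time.  Contours are stored as JSON lists of (x, y) points.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .fields import DopplerField, PressureField, VelocityField
from .grid_ops import MaskedDomain, StructuredGrid

__all__ = [
    "save_run",
    "load_run",
    "save_contours",
    "load_contours",
]


def _write_grid(f: h5py.File, grid: StructuredGrid) -> None:
    f.attrs["nx"], f.attrs["ny"], f.attrs["nz"] = grid.nx, grid.ny, grid.nz
    f.attrs["h"] = grid.h
    f.attrs["origin"] = np.asarray(grid.origin, dtype=float)


def _read_grid(f: h5py.File) -> StructuredGrid:
    return StructuredGrid(
        int(f.attrs["nx"]), int(f.attrs["ny"]), int(f.attrs["nz"]),
        float(f.attrs["h"]), tuple(np.asarray(f.attrs["origin"], float)),
    )


def save_run(
    path: str | Path,
    grid: StructuredGrid,
    domains: list[MaskedDomain] | None = None,
    velocities: list[VelocityField] | None = None,
    dopplers: list[DopplerField] | None = None,
    pressures: list[PressureField] | None = None,
) -> None:
    """Write masks and fields for a sequence of frames."""
    n = max(
        len(x) for x in (domains, velocities, dopplers, pressures)
        if x is not None
    )
    with h5py.File(path, "w") as f:
        _write_grid(f, grid)
        f.attrs["n_frames"] = n
        for k in range(n):
            gr = f.create_group(f"frame_{k:03d}")
            if domains is not None:
                gr.create_dataset(
                    "mask", data=domains[k].to_label_array(), dtype="int8"
                )
            if velocities is not None:
                gr.create_dataset("velocity", data=velocities[k].v)
                gr.attrs["frame_time"] = velocities[k].frame_time
            if dopplers is not None:
                d = dopplers[k]
                gr.create_dataset("doppler", data=d.values)
                gr.attrs["beam"] = d.beam
                gr.attrs["frame_time"] = d.frame_time
                gr.attrs["frame_dt"] = d.frame_dt
            if pressures is not None:
                gr.create_dataset("pressure", data=pressures[k].p)


def load_run(path: str | Path) -> dict:
    """Read a run file; returns a dict with grid and per-frame objects."""
    out: dict = {"domains": [], "velocities": [], "dopplers": [], "pressures": []}
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        out["grid"] = grid
        n = int(f.attrs["n_frames"])
        for k in range(n):
            gr = f[f"frame_{k:03d}"]
            t = float(gr.attrs.get("frame_time", 0.0))
            if "mask" in gr:
                out["domains"].append(
                    MaskedDomain.from_label_array(grid, gr["mask"][()])
                )
            if "velocity" in gr:
                out["velocities"].append(
                    VelocityField(grid, gr["velocity"][()], frame_time=t)
                )
            if "doppler" in gr:
                out["dopplers"].append(
                    DopplerField(
                        grid, gr["doppler"][()],
                        beam=np.asarray(gr.attrs["beam"], float),
                        frame_time=t,
                        frame_dt=float(gr.attrs.get("frame_dt", 0.0)),
                    )
                )
            if "pressure" in gr:
                out["pressures"].append(
                    PressureField(grid, gr["pressure"][()], frame_time=t)
                )
    for key in ("domains", "velocities", "dopplers", "pressures"):
        if not out[key]:
            out[key] = None
    return out


def save_contours(path: str | Path, contours: dict[str, list[np.ndarray]]
                  ) -> None:
    """Contour point stacks (per plane, per frame) as JSON."""
    payload = {
        plane: [np.asarray(c, float).tolist() for c in stack]
        for plane, stack in contours.items()
    }
    Path(path).write_text(json.dumps(payload))


def load_contours(path: str | Path) -> dict[str, list[np.ndarray]]:
    payload = json.loads(Path(path).read_text())
    return {
        plane: [np.asarray(c, float) for c in stack]
        for plane, stack in payload.items()
    }
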