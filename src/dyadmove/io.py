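"""Readers and writers for trajectories, rasters and flat configs.

Formats are deliberately plain text: trajectory CSV with header
``id,t,x,y`` (Movebank-minimal dialect, unit time steps), ESRI ASCII grids
for rasters (barrier cells encoded as NODATA), and flat ``key = value``
configs with stable key ordering.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .landscapes import LandscapeGrid
from .simulator import MovementKernel, ScenarioConfig, Trajectory

__all__ = [
    "FormatError",
    "OrderingError",
    "read_trajectory",
    "read_trajectories",
    "write_trajectory",
    "write_trajectories",
    "read_ascii_grid",
    "write_ascii_grid",
    "scenario_config_to_text",
    "scenario_config_from_text",
    "write_manifest",
]

NODATA = -9999.0


class FormatError(ValueError):
    """Malformed input file."""


class OrderingError(ValueError):
    """Time indices are not strictly increasing within an individual."""


def _traj_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("id", "t", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    return df


def _frame_to_traj(df: pd.DataFrame, individual_id: str) -> Trajectory:
    t = df["t"].to_numpy()
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise OrderingError(f"time indices not strictly increasing for id {individual_id!r}")
    if len(t) >= 2 and not np.all(np.diff(t) == 1):
        raise OrderingError(f"time indices must advance by 1 for id {individual_id!r}")
    return Trajectory(str(individual_id), t.astype(int), df["x"].to_numpy(float), df["y"].to_numpy(float))


def read_trajectory(path) -> Trajectory:
    """Read a single-individual trajectory CSV (header ``id,t,x,y``)."""
    df = _traj_frame(path)
    ids = df["id"].unique()
    if len(ids) != 1:
        raise FormatError(f"expected one individual in {path}, found {len(ids)}")
    return _frame_to_traj(df, ids[0])


def read_trajectories(path) -> dict[str, Trajectory]:
    """Read a trajectory CSV with one or more individuals, keyed by id."""
    df = _traj_frame(path)
    return {str(i): _frame_to_traj(g, i) for i, g in df.groupby("id", sort=False)}


def write_trajectory(traj: Trajectory, path) -> None:
    write_trajectories([traj], path)


def write_trajectories(trajs, path) -> None:
    frames = [
        pd.DataFrame({"id": tr.individual_id, "t": tr.t, "x": tr.x, "y": tr.y}) for tr in trajs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_ascii_grid(path) -> LandscapeGrid:
    """Read an ESRI ASCII grid; NODATA cells become barriers with value 0."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"missing header field {key!r} in {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", NODATA)
    try:
        data = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"bad raster body in {path}: {exc}") from None
    if data.shape != (nrows, ncols):
        raise FormatError(
            f"raster body shape {data.shape} does not match header ({nrows}, {ncols})"
        )
    values = data[::-1]  # file rows are top-to-bottom; internal origin is lower-left
    mask = values == nodata
    barrier = mask.any()
    values = np.where(mask, 0.0, values)
    return LandscapeGrid(
        values=values,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        barrier_mask=mask if barrier else None,
    )


def write_ascii_grid(grid: LandscapeGrid, path) -> None:
    """Write an ESRI ASCII grid; barrier cells are written as NODATA."""
    values = grid.values.copy()
    if grid.barrier_mask is not None:
        values[grid.barrier_mask] = NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.12g}\n")
        fh.write(f"yllcorner {grid.origin[1]:.12g}\n")
        fh.write(f"cellsize {grid.cell_size:.12g}\n")
        fh.write(f"NODATA_value {NODATA:.12g}\n")
        for row in values[::-1]:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# flat config round-trip


def scenario_config_to_text(config: ScenarioConfig) -> str:
    """Serialise a ScenarioConfig to ``key = value`` lines (stable order)."""
    items: list[tuple[str, object]] = []
    for f in dataclasses.fields(config):
        if f.name in ("landscape", "noise"):
            continue  # not flat-serialisable; regenerate from seed
        val = getattr(config, f.name)
        if f.name == "kernel":
            for kf in dataclasses.fields(val):
                items.append((f"kernel.{kf.name}", getattr(val, kf.name)))
        elif f.name == "initial_positions":
            if val is not None:
                items.append(("initial_positions", json.dumps([list(p) for p in val])))
        else:
            items.append((f.name, val))
    return "\n".join(f"{k} = {v}" for k, v in items) + "\n"


def scenario_config_from_text(text: str) -> ScenarioConfig:
    raw: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        raw[key.strip()] = val.strip()
    kernel = MovementKernel(
        kappa=float(raw.pop("kernel.kappa", 4.0)),
        gamma_shape=float(raw.pop("kernel.gamma_shape", 6.0)),
        gamma_scale=float(raw.pop("kernel.gamma_scale", 0.15)),
    )
    kwargs: dict = {"kernel": kernel}
    casts = {
        "scenario": str,
        "n_steps": int,
        "area_size": float,
        "n_grid_cells": int,
        "n_candidates": int,
        "perceptual_range": float,
        "beta_env": float,
        "beta_soc": float,
        "barrier_proportion": float,
        "seed": int,
    }
    for key, cast in casts.items():
        if key in raw:
            kwargs[key] = cast(raw[key])
    if "initial_positions" in raw:
        pos = json.loads(raw["initial_positions"])
        kwargs["initial_positions"] = tuple(tuple(p) for p in pos)
    return ScenarioConfig(**kwargs)


def write_manifest(path, *, seed: int, config_text: str | None = None, extra: dict | None = None) -> None:
    """Write a JSON run manifest (seed, config, package version, timestamp)."""
    import datetime

    from . import __version__

    manifest = {
        "package": "dyadmove",
        "version": __version__,
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    if config_text is not None:
        manifest["config"] = config_text
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
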