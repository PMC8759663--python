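"""Readers/writers for track tables, snapshots, patterns, and configs.

Canonical on-disk units are pixels and frames (matching tracking-software
exports and the pixel-valued fit residuals); conversion to mm and hours
happens at read time through a :class:`UnitContext`.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .detect import NON_MERGER
from .kinematics import Trajectory
from .sim import SimParams, SimState
from .spatial import PointPattern

__all__ = [
    "UnitContext",
    "DEFAULT_COLUMN_MAP",
    "read_tracks",
    "write_tracks",
    "read_snapshots",
    "write_snapshots",
    "write_snapshots_csv",
    "read_snapshots_csv",
    "read_point_pattern",
    "write_point_pattern",
    "load_sim_params",
]


@dataclass(frozen=True)
class UnitContext:
    """Conversion between raw (px, frame) and physical (mm, hr) units.

    The default frame interval of 0.25 hr is the 15-minute imaging
    cadence of the plate time-lapses; ``mm_per_px=1`` leaves lengths in
    pixel units.
    """

    mm_per_px: float = 1.0
    hr_per_frame: float = 0.25
    length_unit: str = "mm"
    time_unit: str = "hr"

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0 or self.hr_per_frame <= 0:
            raise ValueError("unit scales must be strictly positive")


DEFAULT_COLUMN_MAP: dict[str, str] = {
    "track_id": "track_id",
    "frame": "frame",
    "x": "x",
    "y": "y",
    "area": "area",
}


def read_tracks(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    units: UnitContext | None = None,
) -> list[Trajectory]:
    """Read a tracking CSV into unit-converted trajectories.

    ``column_map`` maps canonical names (track_id, frame, x, y, and
    optionally area) to the file's column names, absorbing whatever schema
    the tracking export used.  Rows are sorted by frame per track;
    duplicate (track, frame) rows are a data error.  Positions are scaled
    by ``mm_per_px``, areas by its square, and times are
    ``frame * hr_per_frame``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    units = units or UnitContext()
    df = pd.read_csv(path)
    for canonical in ("track_id", "frame", "x", "y"):
        if cmap[canonical] not in df.columns:
            raise ValueError(
                f"missing column {cmap[canonical]!r} (mapped from {canonical!r}) "
                f"in {path}"
            )
    has_area = cmap.get("area") in df.columns
    has_class = "merge_class" in df.columns

    trajs: list[Trajectory] = []
    for tid, sub in df.groupby(cmap["track_id"]):
        sub = sub.sort_values(cmap["frame"])
        frames = sub[cmap["frame"]].to_numpy()
        dup = pd.Series(frames).duplicated()
        if dup.any():
            row = sub.index[dup.idxmax()]
            raise ValueError(
                f"duplicate (track, frame) = ({tid}, {frames[dup.idxmax()]}) "
                f"at file row {row + 2} in {path}"
            )
        positions = sub[[cmap["x"], cmap["y"]]].to_numpy(dtype=float) * units.mm_per_px
        times = frames.astype(float) * units.hr_per_frame
        areas = (
            sub[cmap["area"]].to_numpy(dtype=float) * units.mm_per_px**2
            if has_area
            else None
        )
        merge_class = sub["merge_class"].iloc[0] if has_class else NON_MERGER
        trajs.append(
            Trajectory(
                track_id=int(tid),
                times=times,
                positions=positions,
                areas=areas,
                merge_class=merge_class,
            )
        )
    return trajs


def write_tracks(
    trajs: Sequence[Trajectory],
    path: str | Path,
    units: UnitContext | None = None,
) -> None:
    """Write trajectories to CSV in raw (px, frame) units, inverting the
    unit conversion applied by :func:`read_tracks`."""
    units = units or UnitContext()
    rows = []
    for tr in trajs:
        frames = np.round(tr.times / units.hr_per_frame).astype(int)
        for k in range(tr.n):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": frames[k],
                    "t": tr.times[k],
                    "x": tr.positions[k, 0] / units.mm_per_px,
                    "y": tr.positions[k, 1] / units.mm_per_px,
                    "area": (
                        tr.areas[k] / units.mm_per_px**2
                        if tr.areas is not None
                        else np.nan
                    ),
                    "merge_class": tr.merge_class,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_snapshots(snapshots: Sequence[SimState], path: str | Path) -> None:
    """Write simulation snapshots to HDF5, one group per snapshot."""
    with h5py.File(path, "w") as f:
        for k, snap in enumerate(snapshots):
            g = f.create_group(f"snapshot_{k:06d}")
            g.attrs["time"] = snap.time
            g.create_dataset("positions", data=snap.positions)
            g.create_dataset("states", data=snap.states)
            g.create_dataset("clocks", data=snap.clocks)
            g.create_dataset("field", data=snap.field)


def read_snapshots(path: str | Path) -> list[SimState]:
    """Read HDF5 snapshots back losslessly."""
    snaps: list[SimState] = []
    with h5py.File(path, "r") as f:
        for idx, name in enumerate(sorted(f.keys())):
            g = f[name]
            try:
                snaps.append(
                    SimState(
                        time=float(g.attrs["time"]),
                        positions=g["positions"][()],
                        states=g["states"][()],
                        clocks=g["clocks"][()],
                        field=g["field"][()],
                    )
                )
            except KeyError as err:
                raise ValueError(
                    f"corrupt snapshot group {name!r} (index {idx}) in {path}: "
                    f"missing {err}"
                ) from err
    return snaps


def write_snapshots_csv(snapshots: Sequence[SimState], path: str | Path) -> None:
    """Text export of agent data (frame, agent_id, x, y, state); the field
    grid is omitted.  Values are written with 9 significant digits."""
    rows = []
    for frame, snap in enumerate(snapshots):
        n = snap.n_agents
        rows.append(
            pd.DataFrame(
                {
                    "frame": frame,
                    "time": snap.time,
                    "agent_id": np.arange(n),
                    "x": snap.positions[:, 0],
                    "y": snap.positions[:, 1],
                    "state": snap.states,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["frame", "time", "agent_id", "x", "y", "state"]
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_snapshots_csv(path: str | Path) -> list[SimState]:
    """Parse the text export; field grids come back empty (0x0)."""
    df = pd.read_csv(path)
    snaps: list[SimState] = []
    for _, sub in df.groupby("frame"):
        sub = sub.sort_values("agent_id")
        snaps.append(
            SimState(
                time=float(sub["time"].iloc[0]),
                positions=sub[["x", "y"]].to_numpy(dtype=float),
                states=sub["state"].to_numpy(dtype=np.int8),
                clocks=np.zeros(len(sub)),
                field=np.zeros((0, 0)),
            )
        )
    return snaps


def write_point_pattern(pattern: PointPattern, path: str | Path) -> None:
    """Write a point pattern CSV with a units-bearing header comment."""
    with open(path, "w") as f:
        f.write(f"# L={pattern.L} unit={pattern.unit}\n")
        pd.DataFrame(pattern.points, columns=["x", "y"]).to_csv(f, index=False)


def read_point_pattern(path: str | Path) -> PointPattern:
    """Read a point pattern CSV written by :func:`write_point_pattern`."""
    with open(path) as f:
        header = f.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"missing units header in {path}")
        meta = dict(tok.split("=") for tok in header[1:].split())
        df = pd.read_csv(f)
    return PointPattern(
        points=df[["x", "y"]].to_numpy(dtype=float),
        L=float(meta["L"]),
        unit=meta.get("unit", "mm"),
    )


def load_sim_params(path: str | Path, **overrides) -> SimParams:
    """Load simulation parameters from TOML or plain key=value text.

    Keys mirror :class:`SimParams` field names exactly; unknown keys are a
    configuration error.  ``overrides`` (e.g. seed from the CLI) win over
    file values.
    """
    path = Path(path)
    text = path.read_text()
    try:
        raw = tomllib.loads(text)
    except tomllib.TOMLDecodeError:
        raw = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            raw[key] = val
    valid = {f.name: f.type for f in fields(SimParams)}
    kwargs = {}
    for key, val in raw.items():
        if key not in valid:
            raise ValueError(f"unknown simulation parameter {key!r} in {path}")
        if isinstance(val, str):
            if val.lower() in ("true", "false"):
                val = val.lower() == "true"
            else:
                val = float(val) if any(c in val for c in ".eE") else int(val)
        kwargs[key] = val
    kwargs.update(overrides)
    return SimParams(**kwargs)
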