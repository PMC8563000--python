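"""Table I/O, configuration, and run metadata.

Canonical in-memory units are millimetres and minutes everywhere; unit
conversion happens only at the I/O boundary.  Column names carry their units
(``x_mm``, ``t_min``) so the delimited text files are self-describing, and
every written artifact records the RNG seed and config hash that produced it
in a ``#``-comment header.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, InitVar
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TrackTable",
    "SpatialProfile",
    "RunConfig",
    "SchemaError",
    "TrackValidationError",
    "read_tracks",
    "write_tracks",
    "read_events",
    "write_events",
    "read_profile",
    "write_profile",
    "load_config",
    "EVENT_COLUMNS",
]

#: conversion factors into canonical units (mm, min)
LENGTH_FACTORS = {"mm": 1.0, "um": 1e-3, "µm": 1e-3, "micron": 1e-3, "m": 1e3}
TIME_FACTORS = {"min": 1.0, "s": 1.0 / 60.0, "sec": 1.0 / 60.0, "h": 60.0, "hr": 60.0}

EVENT_COLUMNS = [
    "cell_id",
    "t_tumble_min",
    "z_tumble_mm",
    "tau_T_min",
    "tau_R_min",
    "l_R_mm",
    "theta_R_rad",
]


class SchemaError(ValueError):
    """A table is missing required columns or declares unknown units."""


class TrackValidationError(ValueError):
    """A track table violates its invariants (e.g. non-monotone time)."""


@dataclass
class TrackTable:
    """Long-format sampled positions of many cells.

    ``data`` columns: ``cell_id``, ``t_min``, and at least one of ``x_mm``
    (lab-frame channel-axis position) or ``z_mm`` (moving-frame position);
    ``y_mm`` / ``h_mm`` transverse coordinates are optional.  ``frame``
    records whether positions are lab-frame or band (moving) frame.
    """

    data: pd.DataFrame
    frame_interval: float
    frame: str = "lab"
    meta: dict = field(default_factory=dict)
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if validate:
            self._validate()

    def _validate(self) -> None:
        cols = set(self.data.columns)
        if "cell_id" not in cols or "t_min" not in cols:
            raise SchemaError("track table needs 'cell_id' and 't_min' columns")
        if not ({"x_mm", "z_mm"} & cols):
            raise SchemaError("track table needs an 'x_mm' or 'z_mm' column")
        if not self.frame_interval > 0:
            raise TrackValidationError("frame_interval must be positive")
        t = self.data["t_min"].to_numpy()
        if len(t):
            # strictly increasing time within each cell (also rules out
            # duplicated (cell_id, t) pairs)
            cid = self.data["cell_id"].to_numpy()
            same_cell = cid[1:] == cid[:-1]
            bad = same_cell & ~(np.diff(t) > 0)
            if bad.any():
                culprit = cid[1:][bad][0]
                raise TrackValidationError(
                    f"time not strictly increasing within cell {culprit!r}"
                )

    @property
    def n_cells(self) -> int:
        return self.data["cell_id"].nunique()

    def positions(self, column: str = "z_mm") -> np.ndarray:
        return self.data[column].to_numpy()

    def groupby_cell(self):
        return self.data.groupby("cell_id", sort=False)


@dataclass
class SpatialProfile:
    """A binned quantity on the moving coordinate ``z``.

    Bins are uniform and half-open ``[edge_i, edge_{i+1})``.  ``sem`` is NaN
    where fewer than two observations fell in a bin.  ``z_mean`` (optional)
    holds the observation-weighted mean position per bin, which is a better
    abscissa than the bin center when the occupancy is uneven.
    """

    bin_edges: np.ndarray
    value: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    quantity: str = ""
    z_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        widths = np.diff(self.bin_edges)
        if len(widths) and not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")
        if len(self.value) != len(self.bin_edges) - 1:
            raise ValueError("value length must be n_bins")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def abscissa(self) -> np.ndarray:
        """Per-bin abscissa: occupancy-weighted mean position if recorded."""
        if self.z_mean is not None:
            return np.where(np.isfinite(self.z_mean), self.z_mean, self.centers)
        return self.centers


@dataclass
class RunConfig:
    """Seeded configuration: a nested parameter mapping plus the RNG seed."""

    params: dict
    seed: int

    def __post_init__(self) -> None:
        if "units" not in self.params:
            raise SchemaError("config must declare a [units] section")
        units = self.params["units"]
        if units.get("length") != "mm" or units.get("time") != "min":
            raise SchemaError("canonical config units are length='mm', time='min'")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.params, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def section(self, name: str) -> dict:
        return dict(self.params.get(name, {}))


def load_config(path: str | Path, overrides: Mapping[str, Any] | None = None,
                seed: int | None = None) -> RunConfig:
    """Read a TOML config; ``overrides`` maps dotted keys to new values."""
    with open(path, "rb") as fh:
        params = tomllib.load(fh)
    for key, val in (overrides or {}).items():
        node = params
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = val
    if seed is None:
        seed = int(params.get("seed", 0))
    return RunConfig(params=params, seed=seed)


# ---------------------------------------------------------------------------
# delimited-text readers/writers with metadata comment headers


def _meta_header(meta: Mapping[str, Any] | None) -> str:
    lines = []
    for key, val in (meta or {}).items():
        lines.append(f"# {key} = {val}\n")
    return "".join(lines)


def _read_meta(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
    return meta


def _write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, Any] | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return df, meta


def write_tracks(tracks: TrackTable, path: str | Path,
                 meta: Mapping[str, Any] | None = None) -> None:
    full_meta = {
        "kind": "tracks",
        "frame": tracks.frame,
        "frame_interval_min": repr(tracks.frame_interval),
        "units": "mm,min",
    }
    full_meta.update(tracks.meta)
    full_meta.update(meta or {})
    _write_table(tracks.data, path, full_meta)


def read_tracks(path: str | Path, dialect: Mapping[str, str] | None = None) -> TrackTable:
    """Read a delimited track table.

    ``dialect`` maps the required logical fields to the file's column names
    and declares their units, e.g.::

        {"cell_id": "id", "t": "time_s", "x": "x_um",
         "time_unit": "s", "length_unit": "um"}

    Without a dialect, canonical columns (``cell_id``, ``t_min``, ``x_mm``,
    optionally ``y_mm``/``h_mm``/``z_mm``) are expected.
    """
    df, meta = _read_table(path)
    if dialect:
        colmap = {}
        for logical, canonical in [("cell_id", "cell_id"), ("t", "t_min"),
                                   ("x", "x_mm"), ("y", "y_mm"), ("z", "z_mm")]:
            src = dialect.get(logical)
            if src is not None:
                if src not in df.columns:
                    raise SchemaError(f"column {src!r} (for {logical!r}) not in file")
                colmap[src] = canonical
        df = df.rename(columns=colmap)
        tf = TIME_FACTORS.get(dialect.get("time_unit", "min"))
        lf = LENGTH_FACTORS.get(dialect.get("length_unit", "mm"))
        if tf is None or lf is None:
            raise SchemaError("unknown unit in dialect")
        if "t_min" in df:
            df["t_min"] = df["t_min"] * tf
        for col in ("x_mm", "y_mm", "z_mm"):
            if col in df:
                df[col] = df[col] * lf
    missing = {"cell_id", "t_min"} - set(df.columns)
    if missing or not ({"x_mm", "z_mm"} & set(df.columns)):
        raise SchemaError(f"track file missing required columns: {sorted(missing) or 'x/z'}")
    fi = meta.get("frame_interval_min")
    if fi is not None:
        frame_interval = float(fi)
    else:
        dts = df.groupby("cell_id", sort=False)["t_min"].diff().dropna()
        frame_interval = float(np.median(dts)) if len(dts) else 1.0
    return TrackTable(
        data=df.reset_index(drop=True),
        frame_interval=frame_interval,
        frame=meta.get("frame", "lab"),
        meta=meta,
    )


def write_events(events: pd.DataFrame, path: str | Path,
                 meta: Mapping[str, Any] | None = None) -> None:
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise SchemaError(f"event table missing columns {sorted(missing)}")
    full_meta = {"kind": "events", "units": "mm,min,rad"}
    full_meta.update(meta or {})
    _write_table(events[EVENT_COLUMNS], path, full_meta)


def read_events(path: str | Path) -> pd.DataFrame:
    df, meta = _read_table(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"event file missing columns {sorted(missing)}")
    df.attrs["meta"] = meta
    return df


def write_profile(profile: SpatialProfile, path: str | Path,
                  meta: Mapping[str, Any] | None = None) -> None:
    df = pd.DataFrame(
        {
            "z_mm": profile.centers,
            "bin_left_mm": profile.bin_edges[:-1],
            "bin_right_mm": profile.bin_edges[1:],
            "value": profile.value,
            "sem": profile.sem,
            "n": profile.n,
        }
    )
    if profile.z_mean is not None:
        df["z_mean_mm"] = profile.z_mean
    full_meta = {"kind": "profile", "quantity": profile.quantity, "units": "mm,min"}
    full_meta.update(meta or {})
    _write_table(df, path, full_meta)


def read_profile(path: str | Path) -> SpatialProfile:
    df, meta = _read_table(path)
    edges = np.concatenate([df["bin_left_mm"].to_numpy(),
                            df["bin_right_mm"].to_numpy()[-1:]])
    return SpatialProfile(
        bin_edges=edges,
        value=df["value"].to_numpy(),
        sem=df["sem"].to_numpy(),
        n=df["n"].to_numpy(),
        quantity=meta.get("quantity", ""),
        z_mean=df["z_mean_mm"].to_numpy() if "z_mean_mm" in df else None,
    )
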