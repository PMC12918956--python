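"""Format readers/writers, run configuration, and run manifests.

All CSVs carry documented headers and are validated on read; coordinates in
CSVs are physical µm (y-up). Images and label masks are grayscale /
integer-label TIFF (y-down pixel convention), converted at this boundary.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (SchemaError, T1Event, TrajectorySet, events_from_frame,
                   events_to_frame)

EDGE_COLUMNS = ("frame", "cell_a", "cell_b", "length_um")
EVENT_COLUMNS = ("frame", "time_h", "loser_a", "loser_b", "gainer_a",
                 "gainer_b", "x_um", "y_um")
FIELD_COLUMNS = ("x_um", "y_um", "vx_um_h", "vy_um_h", "valid")


def _check_columns(df: pd.DataFrame, expected, path, optional=()) -> None:
    missing = [c for c in expected if c not in df.columns and c not in optional]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: expected columns {list(expected)}; "
            f"missing {missing}, unknown {extra}")


# -- trajectories -----------------------------------------------------------

def write_trajectory(traj: TrajectorySet, path) -> None:
    traj.to_csv(path)


def read_trajectory(path, box_size: float, periodic: bool = True) -> TrajectorySet:
    return TrajectorySet.from_csv(path, box_size=box_size, periodic=periodic)


# -- neighbor-graph edge lists ---------------------------------------------

def write_edges(graphs, path) -> None:
    rows = []
    for g in graphs:
        for (a, b) in sorted(g.edges):
            rows.append({"frame": g.frame, "cell_a": a, "cell_b": b,
                         "length_um": g.lengths.get((a, b), np.nan)})
    pd.DataFrame(rows, columns=list(EDGE_COLUMNS)).to_csv(path, index=False)


def read_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, EDGE_COLUMNS, path, optional=("length_um",))
    return df


def graphs_from_edge_frame(df: pd.DataFrame):
    from .core import NeighborGraph, canonical_edge

    graphs = []
    for frame, sub in df.groupby("frame"):
        edges = set()
        lengths = {}
        for r in sub.itertuples():
            e = canonical_edge(int(r.cell_a), int(r.cell_b))
            edges.add(e)
            if "length_um" in df.columns and np.isfinite(r.length_um):
                lengths[e] = float(r.length_um)
        graphs.append(NeighborGraph(int(frame), frozenset(edges), lengths))
    return graphs


# -- T1 events --------------------------------------------------------------

def write_events(events: list[T1Event], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events(path) -> list[T1Event]:
    df = pd.read_csv(path)
    _check_columns(df, EVENT_COLUMNS, path)
    return events_from_frame(df)


# -- velocity fields --------------------------------------------------------

def write_velocity_field(field, path) -> None:
    pos = field.node_positions()
    df = pd.DataFrame({
        "x_um": pos[..., 0].ravel(),
        "y_um": pos[..., 1].ravel(),
        "vx_um_h": field.vectors[..., 0].ravel(),
        "vy_um_h": field.vectors[..., 1].ravel(),
        "valid": field.valid.ravel().astype(int),
    })
    df.to_csv(path, index=False)


def read_velocity_field(path, time_h: float = 0.0):
    from .kinematics import VelocityField

    df = pd.read_csv(path)
    _check_columns(df, FIELD_COLUMNS, path)
    xs = np.unique(df["x_um"])
    ys = np.unique(df["y_um"])
    nx, ny = len(xs), len(ys)
    if nx * ny != len(df):
        raise SchemaError(f"{path}: velocity field is not a full grid")
    spacing = float(xs[1] - xs[0]) if nx > 1 else float(ys[1] - ys[0])
    order = np.lexsort([df["x_um"], df["y_um"]])
    vx = df["vx_um_h"].to_numpy()[order].reshape(ny, nx)
    vy = df["vy_um_h"].to_numpy()[order].reshape(ny, nx)
    valid = df["valid"].to_numpy()[order].reshape(ny, nx).astype(bool)
    return VelocityField((float(xs[0]), float(ys[0])), spacing,
                         np.stack([vx, vy], axis=-1), valid, time_h)


# -- TIFF -------------------------------------------------------------------

def write_tiff(array: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(array), photometric="minisblack")


def read_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


# -- JSON reports -----------------------------------------------------------

def write_report(payload: dict, path) -> None:
    payload = dict(payload)
    payload.setdefault("software_version", __version__)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# -- run configuration and manifest ----------------------------------------

@dataclass
class RunConfig:
    """All pipeline parameters; round-trips losslessly through YAML."""

    seed: int = 0
    um_per_px: float = 1.0
    dt_h: float = 0.25
    box_size_um: float = 500.0
    n_cells: int = 400
    mode: str = "fluid"
    speed_um_h: float = 10.0
    pack_size_um: float | None = None
    interface_t1_rate: float = 0.0
    fluid_t1_gain: float = 0.003
    n_frames: int = 48
    noise_sigma_um: float = 0.1
    piv_window_px: int = 32
    piv_overlap: float = 0.5
    persistence_frames: int = 2
    rate_bin_h: float = 3.0
    vrms_window_frames: int = 4
    n_boot: int = 2000
    junction_width_px: int = 3
    inputs: dict = dc_field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = set(cls().__dict__)
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def sha256(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=_jsonify)
        return hashlib.sha256(blob.encode()).hexdigest()


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class RunManifest:
    """Per-run provenance: config hash, input checksums, timings, warnings."""

    def __init__(self, config: RunConfig):
        self.payload = {
            "software_version": __version__,
            "config_hash": config.sha256(),
            "config": dict(config.__dict__),
            "inputs": {},
            "stages": {},
            "warnings": [],
        }

    def add_input(self, name: str, path) -> None:
        self.payload["inputs"][name] = {"path": str(path),
                                        "sha256": file_sha256(path)}

    def stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.payload["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3),
                    "ok": exc[0] is None,
                }
                return False

        return _Timer()

    def warn(self, message: str) -> None:
        self.payload["warnings"].append(message)

    def write(self, path) -> None:
        write_report(self.payload, path)
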