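"""Shared containers for monolayer dynamics data.

Physical units are micrometres and hours throughout; coordinates are y-up.
Pixel arrays (images, masks) are y-down and are converted at the I/O
boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = ("frame", "time_h", "cell_id", "x_um", "y_um")


class SchemaError(ValueError):
    """A tabular input violates the documented schema."""


def canonical_edge(a: int, b: int) -> tuple[int, int]:
    """Undirected edge as an ordered pair (a < b)."""
    if a == b:
        raise ValueError(f"self-edge on cell {a}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class NeighborGraph:
    """Cell adjacency in one frame.

    Edges are canonical (low id, high id) pairs; ``lengths`` maps each edge
    to the shared-boundary length in µm when geometry is available.
    """

    frame: int
    edges: frozenset
    lengths: dict = field(default_factory=dict, compare=False)
    boundary_cells: frozenset = frozenset()
    nodes: frozenset = frozenset()

    def __post_init__(self):
        if not self.nodes:
            node_set = frozenset(c for e in self.edges for c in e)
            object.__setattr__(self, "nodes", node_set)

    def has_edge(self, a: int, b: int) -> bool:
        return canonical_edge(a, b) in self.edges

    def adjacency(self) -> dict:
        adj: dict[int, set] = {n: set() for n in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def neighbors(self, cell: int) -> set:
        return {b if a == cell else a for a, b in self.edges if cell in (a, b)}

    def degree(self, cell: int) -> int:
        return len(self.neighbors(cell))

    def interior_cells(self) -> frozenset:
        return self.nodes - self.boundary_cells

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(*e, length_um=self.lengths.get(e, np.nan))
        return g

    def replace_edges(self, remove: Iterable, add: Iterable,
                      add_lengths: dict | None = None) -> "NeighborGraph":
        edges = set(self.edges)
        lengths = dict(self.lengths)
        for e in remove:
            edges.discard(e)
            lengths.pop(e, None)
        for e in add:
            edges.add(e)
            if add_lengths and e in add_lengths:
                lengths[e] = add_lengths[e]
        return NeighborGraph(self.frame, frozenset(edges), lengths,
                             self.boundary_cells, self.nodes)


@dataclass(frozen=True)
class T1Event:
    """One neighbor exchange: the losing pair's junction collapses and the
    gaining pair forms a new junction. ``frame``/``time_h`` mark completion
    (the first frame in which the new junction exists)."""

    frame: int
    time_h: float
    losers: tuple[int, int]
    gainers: tuple[int, int]
    centroid_um: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self):
        object.__setattr__(self, "losers", canonical_edge(*self.losers))
        object.__setattr__(self, "gainers", canonical_edge(*self.gainers))
        if set(self.losers) & set(self.gainers):
            raise ValueError("losing and gaining pairs must be disjoint")

    def key(self) -> tuple:
        return (self.frame, self.losers, self.gainers)


@dataclass
class TrajectorySet:
    """Cell-centroid trajectories with consistent ids across frames."""

    data: pd.DataFrame
    box_size: float
    periodic: bool = True

    def __post_init__(self):
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"trajectory table missing columns {missing}")
        dup = self.data.duplicated(subset=["frame", "cell_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise SchemaError(
                f"duplicate (frame, cell_id) pair at row {row}: "
                f"{tuple(self.data.iloc[row][['frame', 'cell_id']])}"
            )
        self.data = self.data.sort_values(["frame", "cell_id"]).reset_index(drop=True)

    # -- basic queries ----------------------------------------------------
    @property
    def frames(self) -> np.ndarray:
        return np.unique(self.data["frame"].to_numpy())

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.unique(self.data["cell_id"].to_numpy())

    def frame_time(self, frame: int) -> float:
        sel = self.data.loc[self.data["frame"] == frame, "time_h"]
        if sel.empty:
            raise KeyError(f"frame {frame} not present")
        return float(sel.iloc[0])

    @property
    def times(self) -> np.ndarray:
        return (self.data.drop_duplicates("frame")
                .sort_values("frame")["time_h"].to_numpy())

    def positions(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """ids (sorted) and (n, 2) xy positions for one frame."""
        sub = self.data[self.data["frame"] == frame]
        if sub.empty:
            raise KeyError(f"frame {frame} not present")
        return sub["cell_id"].to_numpy(), sub[["x_um", "y_um"]].to_numpy()

    def position_array(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(times, cell_ids, positions[n_frames, n_cells, 2]) for trajectories
        with a complete frame × cell grid (NaN where a cell is absent)."""
        piv_x = self.data.pivot(index="frame", columns="cell_id", values="x_um")
        piv_y = self.data.pivot(index="frame", columns="cell_id", values="y_um")
        pos = np.stack([piv_x.to_numpy(), piv_y.to_numpy()], axis=-1)
        return self.times, piv_x.columns.to_numpy(), pos

    # -- geometry helpers -------------------------------------------------
    def minimum_image(self, disp: np.ndarray) -> np.ndarray:
        """Wrap displacement vectors into the primary periodic image."""
        if not self.periodic:
            return disp
        L = self.box_size
        return (disp + L / 2.0) % L - L / 2.0

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, columns=list(TRAJECTORY_COLUMNS))

    @classmethod
    def from_csv(cls, path: str | Path, box_size: float,
                 periodic: bool = True) -> "TrajectorySet":
        df = pd.read_csv(path)
        extra = [c for c in df.columns if c not in TRAJECTORY_COLUMNS]
        if extra:
            raise SchemaError(f"unknown trajectory columns {extra} in {path}")
        return cls(df, box_size=box_size, periodic=periodic)


def trajectory_from_arrays(times: Sequence[float], cell_ids: Sequence[int],
                           positions: np.ndarray, box_size: float,
                           periodic: bool = True) -> TrajectorySet:
    """Build a TrajectorySet from a dense (n_frames, n_cells, 2) array."""
    positions = np.asarray(positions, dtype=float)
    n_frames, n_cells, _ = positions.shape
    frames = np.repeat(np.arange(n_frames), n_cells)
    df = pd.DataFrame(
        {
            "frame": frames,
            "time_h": np.repeat(np.asarray(times, dtype=float), n_cells),
            "cell_id": np.tile(np.asarray(cell_ids, dtype=int), n_frames),
            "x_um": positions[:, :, 0].ravel(),
            "y_um": positions[:, :, 1].ravel(),
        }
    )
    return TrajectorySet(df, box_size=box_size, periodic=periodic)


def events_to_frame(events: Iterable[T1Event]) -> pd.DataFrame:
    rows = [
        {
            "frame": e.frame,
            "time_h": e.time_h,
            "loser_a": e.losers[0],
            "loser_b": e.losers[1],
            "gainer_a": e.gainers[0],
            "gainer_b": e.gainers[1],
            "x_um": e.centroid_um[0],
            "y_um": e.centroid_um[1],
        }
        for e in events
    ]
    cols = ["frame", "time_h", "loser_a", "loser_b", "gainer_a", "gainer_b",
            "x_um", "y_um"]
    return pd.DataFrame(rows, columns=cols)


def events_from_frame(df: pd.DataFrame) -> list[T1Event]:
    return [
        T1Event(
            int(r.frame), float(r.time_h),
            (int(r.loser_a), int(r.loser_b)),
            (int(r.gainer_a), int(r.gainer_b)),
            (float(r.x_um), float(r.y_um)),
        )
        for r in df.itertuples()
    ]
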