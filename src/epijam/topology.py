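"""Neighbor topology of epithelial monolayers.

Builds cell adjacency graphs from Voronoi tessellations or label masks,
detects T1 neighbor-exchange events (the collapse of a shared junction
followed by formation of a new junction between two previously
non-neighboring cells), and computes exchange rates and per-cell shape
morphometrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Voronoi

from .core import NeighborGraph, T1Event, TrajectorySet, canonical_edge

#: default adjacency cutoff, as a fraction of the mean cell diameter; edges
#: shorter than this are treated as degenerate four-fold vertices.
EPS_EDGE_FRACTION = 0.05


# ---------------------------------------------------------------------------
# tessellation
# ---------------------------------------------------------------------------

def _tile_points(points: np.ndarray, box: float) -> np.ndarray:
    offsets = [(dx, dy) for dx in (-box, 0.0, box) for dy in (-box, 0.0, box)
               if (dx, dy) != (0.0, 0.0)]
    copies = [points] + [points + np.array(off) for off in offsets]
    return np.vstack(copies)


def voronoi_neighbor_graph(cell_ids: np.ndarray, points: np.ndarray,
                           box_size: float, periodic: bool = True,
                           frame: int = 0,
                           eps_edge: float | None = None) -> NeighborGraph:
    """Adjacency graph of the Voronoi tessellation of cell centroids.

    Cells are adjacent iff they share a Voronoi ridge of length >= eps_edge
    (default ``EPS_EDGE_FRACTION`` x mean cell diameter, with the mean cell
    area taken as box_size**2 / n_cells). In the bounded mode, cells whose
    ridge structure touches the outer hull are flagged as boundary cells.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 4:
        raise ValueError("need at least 4 cells for a tessellation")
    if eps_edge is None:
        mean_area = box_size ** 2 / n
        eps_edge = EPS_EDGE_FRACTION * 2.0 * np.sqrt(mean_area / np.pi)

    if periodic:
        vor = Voronoi(_tile_points(points % box_size, box_size))
    else:
        vor = Voronoi(points)

    lengths: dict[tuple[int, int], float] = {}
    boundary: set[int] = set()
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        a, b = int(p) % n, int(q) % n
        if periodic and p >= n and q >= n:
            continue  # ridge entirely between ghost copies
        if a == b:
            continue
        if -1 in verts:
            # unbounded ridge: only possible in bounded mode
            boundary.update((a, b))
            continue
        v0, v1 = vor.vertices[verts[0]], vor.vertices[verts[1]]
        length = float(np.hypot(*(v1 - v0)))
        e = canonical_edge(int(cell_ids[a]), int(cell_ids[b]))
        lengths[e] = max(lengths.get(e, 0.0), length)

    if not periodic:
        # cells whose polygon leaves the box are treated as boundary cells
        for i, region_idx in enumerate(vor.point_region[:n]):
            region = vor.regions[region_idx]
            if -1 in region:
                boundary.add(i)
            else:
                poly = vor.vertices[region]
                if (poly < 0).any() or (poly > box_size).any():
                    boundary.add(i)

    edges = frozenset(e for e, ln in lengths.items() if ln >= eps_edge)
    lengths = {e: lengths[e] for e in edges}
    return NeighborGraph(
        frame=frame,
        edges=edges,
        lengths=lengths,
        boundary_cells=frozenset(int(cell_ids[i]) for i in boundary),
        nodes=frozenset(int(c) for c in cell_ids),
    )


def voronoi_polygons(cell_ids: np.ndarray, points: np.ndarray,
                     box_size: float, periodic: bool = True) -> dict:
    """Shapely polygons of each Voronoi cell, clipped to the box."""
    from shapely.geometry import Polygon, box as shapely_box

    points = np.asarray(points, dtype=float)
    n = len(points)
    tiled = _tile_points(points % box_size, box_size) if periodic else points
    vor = Voronoi(tiled)
    clip = shapely_box(0.0, 0.0, box_size, box_size)
    polys: dict[int, "Polygon"] = {}
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            continue  # open cell at the hull (bounded mode border)
        poly = Polygon(vor.vertices[region])
        if not periodic:
            poly = poly.intersection(clip)
        if not poly.is_empty and poly.area > 0:
            polys[int(cell_ids[i])] = poly
    return polys


# ---------------------------------------------------------------------------
# neighbor graphs from label masks
# ---------------------------------------------------------------------------

def build_neighbor_graph(label_mask: np.ndarray, um_per_px: float = 1.0,
                         frame: int = 0,
                         eps_edge: float | None = None) -> NeighborGraph:
    """Adjacency graph from an integer label mask (background 0).

    Two cells are adjacent iff the 4-connected shared boundary between them
    is at least ``eps_edge`` µm long (default ``EPS_EDGE_FRACTION`` x mean
    equivalent cell diameter). Corner-only contacts have zero shared length
    and are never adjacent. Cells touching the image border are flagged.
    """
    label_mask = np.asarray(label_mask)
    labels = np.unique(label_mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("label mask is empty")

    # shared boundary length: count 4-neighbour pixel pairs with two
    # distinct positive labels, one pixel side each
    shared: dict[tuple[int, int], float] = {}
    for a, b in [(label_mask[:, :-1], label_mask[:, 1:]),
                 (label_mask[:-1, :], label_mask[1:, :])]:
        sel = (a != b) & (a > 0) & (b > 0)
        pairs = np.stack([a[sel], b[sel]], axis=1)
        if pairs.size:
            pairs.sort(axis=1)
            uniq, counts = np.unique(pairs, axis=0, return_counts=True)
            for (la, lb), c in zip(uniq, counts):
                e = (int(la), int(lb))
                shared[e] = shared.get(e, 0.0) + float(c) * um_per_px

    if eps_edge is None:
        areas = np.bincount(label_mask.ravel())[labels] * um_per_px ** 2
        eps_edge = EPS_EDGE_FRACTION * float(
            np.mean(2.0 * np.sqrt(areas / np.pi)))

    border = set()
    for edge_pixels in (label_mask[0], label_mask[-1],
                        label_mask[:, 0], label_mask[:, -1]):
        border.update(int(v) for v in np.unique(edge_pixels) if v > 0)

    edges = frozenset(e for e, ln in shared.items() if ln >= eps_edge)
    return NeighborGraph(
        frame=frame,
        edges=edges,
        lengths={e: shared[e] for e in edges},
        boundary_cells=frozenset(border),
        nodes=frozenset(int(v) for v in labels),
    )


# ---------------------------------------------------------------------------
# T1 detection
# ---------------------------------------------------------------------------

def _stable_before(seq: list[frozenset], t: int, edge: tuple, k: int) -> bool:
    if t - k + 1 < 0:
        return False
    return all(edge in seq[s] for s in range(t - k + 1, t + 1))


def _persists_after(seq: list[frozenset], t: int, edge: tuple, k: int) -> bool:
    if t + k > len(seq) - 1:
        return False
    return all(edge in seq[s] for s in range(t + 1, t + 1 + k))


def detect_t1(graphs: list[NeighborGraph], persistence: int = 2,
              times: np.ndarray | None = None,
              positions: dict | None = None,
              min_shared_ids: float = 0.9) -> list[T1Event]:
    """Detect T1 neighbor-exchange events in a sequence of adjacency graphs.

    For each transition between consecutive frames, a lost edge (A, B) and a
    gained edge (C, D) form an event iff the four cells are distinct, the
    four side edges A-C, A-D, B-C, B-D exist in both the pre- and
    post-transition frames (so the event is a genuine junction exchange, and
    detection is symmetric under time reversal), the old junction was stable
    for >= ``persistence`` frames up to the transition, and the new junction
    persists for >= ``persistence`` frames after it. When several lost and
    gained edges compete (rosettes), quartets are paired greedily by the lost
    junction's shared-boundary length (longest first), ties broken by lowest
    canonical cell-id pair. Each event is reported once, at the completion
    frame (the first frame containing the new junction).

    Frames whose cell-id overlap with the previous frame falls below
    ``min_shared_ids`` break tracking continuity: a warning is issued and no
    events are reported across that transition.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    n = len(graphs)
    seq = [g.edges for g in graphs]
    events: list[T1Event] = []
    for t in range(n - 1):
        g0, g1 = graphs[t], graphs[t + 1]
        common = g0.nodes & g1.nodes
        if len(g0.nodes) and len(common) / max(len(g0.nodes), len(g1.nodes)) < min_shared_ids:
            warnings.warn(
                f"tracking continuity violated at frame {t} -> {t + 1}; "
                "transition skipped", stacklevel=2)
            continue
        lost = [e for e in sorted(g0.edges - g1.edges)
                if _stable_before(seq, t, e, persistence)]
        gained = [e for e in sorted(g1.edges - g0.edges)
                  if _persists_after(seq, t, e, persistence)]
        if not lost or not gained:
            continue
        adj0, adj1 = g0.adjacency(), g1.adjacency()
        candidates = []
        for la, lb in lost:
            for ga, gb in gained:
                quartet = {la, lb, ga, gb}
                if len(quartet) != 4:
                    continue
                ok = True
                for side in [(la, ga), (la, gb), (lb, ga), (lb, gb)]:
                    u, v = side
                    if v not in adj0.get(u, ()) or v not in adj1.get(u, ()):
                        ok = False
                        break
                if ok:
                    length = g0.lengths.get((la, lb), 0.0)
                    candidates.append((-length, (la, lb), (ga, gb)))
        candidates.sort()
        used_lost: set = set()
        used_gained: set = set()
        for _, le, ge in candidates:
            if le in used_lost or ge in used_gained:
                continue
            used_lost.add(le)
            used_gained.add(ge)
            time_h = float(times[t + 1]) if times is not None else float(t + 1)
            centroid = (np.nan, np.nan)
            if positions is not None:
                pts = [positions[t + 1][c] for c in (*le, *ge)
                       if c in positions[t + 1]]
                if pts:
                    centroid = tuple(np.mean(np.asarray(pts), axis=0))
            events.append(T1Event(t + 1, time_h, le, ge, centroid))
    return events


def graphs_from_trajectory(traj: TrajectorySet,
                           eps_edge: float | None = None) -> list[NeighborGraph]:
    """Per-frame Voronoi adjacency graphs recomputed from centroids."""
    out = []
    for f in traj.frames:
        ids, pts = traj.positions(int(f))
        out.append(voronoi_neighbor_graph(ids, pts, traj.box_size,
                                          periodic=traj.periodic,
                                          frame=int(f), eps_edge=eps_edge))
    return out


# ---------------------------------------------------------------------------
# T1 rates
# ---------------------------------------------------------------------------

@dataclass
class T1RateSeries:
    """T1 exchange rate per half-open time bin, in events/cell/h."""

    bin_edges_h: np.ndarray     # len n_bins + 1
    rate: np.ndarray            # events / cell / h
    n_events: np.ndarray
    n_cells: np.ndarray         # mean interior cell count per bin

    @property
    def bin_centers_h(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_h[:-1] + self.bin_edges_h[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_start_h": self.bin_edges_h[:-1],
            "t_end_h": self.bin_edges_h[1:],
            "rate_per_cell_h": self.rate,
            "n_events": self.n_events,
            "n_cells": self.n_cells,
        })


def t1_rate(events: list[T1Event], n_cells, bin_width_h: float,
            t_start: float = 0.0, t_end: float | None = None) -> T1RateSeries:
    """Exchange events per interior cell per hour in half-open time bins.

    ``n_cells`` is either a scalar interior-cell count or a callable
    ``n_cells(bin_center_h)``.
    """
    if bin_width_h <= 0:
        raise ValueError("bin width must be positive")
    t_ev = np.array([e.time_h for e in events], dtype=float)
    if t_end is None:
        t_end = float(t_ev.max()) + bin_width_h if t_ev.size else t_start + bin_width_h
    n_bins = max(1, int(np.ceil((t_end - t_start) / bin_width_h - 1e-9)))
    edges = t_start + bin_width_h * np.arange(n_bins + 1)
    counts, _ = np.histogram(t_ev, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    denom = np.array([float(n_cells(c)) if callable(n_cells) else float(n_cells)
                      for c in centers])
    if np.any(denom <= 0):
        raise ValueError("cell-count denominator must be positive in every bin")
    rate = counts / (denom * bin_width_h)
    return T1RateSeries(edges, rate, counts.astype(int), denom)


# ---------------------------------------------------------------------------
# shape morphometrics
# ---------------------------------------------------------------------------

@dataclass
class ShapeMetrics:
    """Per-cell morphometrics for one frame."""

    cell_id: np.ndarray
    area_um2: np.ndarray
    perimeter_um: np.ndarray
    aspect_ratio: np.ndarray
    shape_index: np.ndarray          # q = P / sqrt(A) (dimensionless)
    perimeter_over_area: np.ndarray  # literal P / A (1/µm), for reference

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_id,
            "area_um2": self.area_um2,
            "perimeter_um": self.perimeter_um,
            "aspect_ratio": self.aspect_ratio,
            "shape_index": self.shape_index,
            "perimeter_over_area": self.perimeter_over_area,
        })


def _polygon_second_moments(coords: np.ndarray) -> np.ndarray:
    """Area-normalized central second moments of a simple polygon."""
    x, y = coords[:, 0], coords[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    ixx = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    iyy = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    # central, normalized by area -> covariance of the uniform lamina
    cov = np.array([
        [iyy / a - cx * cx, ixy / a - cx * cy],
        [ixy / a - cx * cy, ixx / a - cy * cy],
    ])
    return cov


def shape_metrics_polygons(polygons: dict) -> ShapeMetrics:
    """Morphometrics from shapely polygons keyed by cell id.

    shape_index is the dimensionless q = perimeter / sqrt(area); the
    printed-units perimeter/area ratio is co-reported. Aspect ratio is the
    major/minor axis ratio of the second-moment ellipse (>= 1).
    """
    ids, areas, perims, aspects = [], [], [], []
    for cid in sorted(polygons):
        poly = polygons[cid]
        if not poly.is_valid:
            raise ValueError(f"cell {cid}: polygon is not simple/valid")
        a = poly.area
        if a <= 0:
            raise ValueError(f"cell {cid}: non-positive area")
        coords = np.asarray(poly.exterior.coords)[:-1]
        cov = _polygon_second_moments(coords)
        evals = np.linalg.eigvalsh(cov)
        evals = np.clip(evals, 1e-300, None)
        ids.append(cid)
        areas.append(a)
        perims.append(poly.exterior.length)
        aspects.append(float(np.sqrt(evals[1] / evals[0])))
    areas = np.asarray(areas)
    perims = np.asarray(perims)
    return ShapeMetrics(np.asarray(ids), areas, perims, np.asarray(aspects),
                        perims / np.sqrt(areas), perims / areas)


def shape_metrics_mask(label_mask: np.ndarray, um_per_px: float = 1.0,
                       exclude_border: bool = True) -> ShapeMetrics:
    """Morphometrics from an integer label mask.

    Perimeter uses the Crofton estimate (4 directions), which converges to
    the true perimeter for smooth shapes as resolution increases.
    """
    from skimage.measure import regionprops

    border = set()
    if exclude_border:
        for edge in (label_mask[0], label_mask[-1],
                     label_mask[:, 0], label_mask[:, -1]):
            border.update(int(v) for v in np.unique(edge) if v > 0)

    ids, areas, perims, aspects = [], [], [], []
    for rp in regionprops(label_mask):
        if rp.label in border:
            continue
        minor = max(rp.axis_minor_length, 1e-12)
        ids.append(rp.label)
        areas.append(rp.area * um_per_px ** 2)
        perims.append(rp.perimeter_crofton * um_per_px)
        aspects.append(rp.axis_major_length / minor)
    areas = np.asarray(areas, dtype=float)
    perims = np.asarray(perims, dtype=float)
    return ShapeMetrics(np.asarray(ids), areas, perims,
                        np.asarray(aspects, dtype=float),
                        perims / np.sqrt(areas), perims / areas)


# ---------------------------------------------------------------------------
# T1 vs non-T1 speed comparison
# ---------------------------------------------------------------------------

@dataclass
class SpeedComparison:
    t1_speeds: np.ndarray
    neighbor_speeds: np.ndarray
    p_value: float
    statistic: float
    n_events_used: int
    n_events_excluded: int

    @property
    def median_ratio(self) -> float:
        return float(np.median(self.t1_speeds) / np.median(self.neighbor_speeds))


def instantaneous_speeds(traj: TrajectorySet, window: int = 1) -> pd.DataFrame:
    """Central-difference speed of every cell at every interior frame.

    ``window`` is the half-width in frames of the central difference.
    """
    times, ids, pos = traj.position_array()
    n_frames = len(times)
    w = window
    speeds = np.full((n_frames, len(ids)), np.nan)
    for f in range(w, n_frames - w):
        disp = traj.minimum_image(pos[f + w] - pos[f - w])
        dt = times[f + w] - times[f - w]
        speeds[f] = np.hypot(disp[:, 0], disp[:, 1]) / dt
    return pd.DataFrame(speeds, index=np.arange(n_frames), columns=ids)


def t1_speed_comparison(events: list[T1Event], traj: TrajectorySet,
                        graphs: list[NeighborGraph],
                        window: int = 1) -> SpeedComparison:
    """Instantaneous speeds of T1-quartet cells vs adjacent bystanders.

    For each event, the four participating cells' speeds at the completion
    frame are compared with those of their topological neighbors that take
    part in no event within ± ``window`` frames of it. Reports a two-sided
    Wilcoxon rank-sum p-value.
    """
    speeds = instantaneous_speeds(traj, window=window)
    participants_by_frame: dict[int, set] = {}
    for e in events:
        for f in range(e.frame - window, e.frame + window + 1):
            participants_by_frame.setdefault(f, set()).update(e.losers + e.gainers)

    t1_speeds, nb_speeds = [], []
    excluded = 0
    for e in events:
        f = e.frame
        if f not in speeds.index or not np.isfinite(speeds.loc[f]).any():
            excluded += 1
            continue
        quartet = set(e.losers + e.gainers)
        graph = graphs[f] if f < len(graphs) else graphs[-1]
        adj = graph.adjacency()
        bystanders = set()
        for c in quartet:
            bystanders |= adj.get(c, set())
        bystanders -= participants_by_frame.get(f, set())
        bystanders -= quartet
        row = speeds.loc[f]
        q_sp = [row[c] for c in quartet if c in row.index and np.isfinite(row[c])]
        b_sp = [row[c] for c in bystanders if c in row.index and np.isfinite(row[c])]
        if not q_sp or not b_sp:
            excluded += 1
            continue
        t1_speeds.extend(q_sp)
        nb_speeds.extend(b_sp)

    t1_arr = np.asarray(t1_speeds)
    nb_arr = np.asarray(nb_speeds)
    if t1_arr.size == 0 or nb_arr.size == 0:
        raise ValueError("no usable events for the speed comparison")
    stat, p = stats.ranksums(t1_arr, nb_arr)
    return SpeedComparison(t1_arr, nb_arr, float(p), float(stat),
                           n_events_used=len(events) - excluded,
                           n_events_excluded=excluded)
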