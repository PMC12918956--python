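"""Ground-truth generators for monolayer dynamics.

These generators are kinematic stand-ins with controlled statistics, not
physics engines: cell motion and neighbor topology are scripted so that
every downstream estimator (PIV, V_rms, correlation length, T1 detection,
rate-speed statistics, sigmoid/onset fits) can be validated against exact
ground truth.

Two regimes mirror the two hypotheses about how neighbor exchanges relate
to tissue motility:

* ``rigid_pack`` — cells translate in coherent clusters of size L_c; T1
  events are scripted only on junctions between clusters, at a fixed rate
  per interface cell, so the T1 rate is independent of cell speed.
* ``fluid`` — cells perform persistent random walks and T1 events are
  scripted uniformly over all junctions at a rate proportional to speed
  (``fluid_t1_gain`` x v0 per cell per hour).

Topology evolution: the frame-0 Voronoi adjacency is frozen and evolves
only through the scripted exchanges (a junction swap applied at a single
transition and persistent thereafter). Per-frame Voronoi *geometry* can
still be computed from the moving centroids when polygon shapes are needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (NeighborGraph, T1Event, TrajectorySet, canonical_edge,
                   trajectory_from_arrays)
from .topology import voronoi_neighbor_graph

#: scripted junction swaps take effect at one transition and must persist
#: this many frames to register with the matching detector setting
SWAP_PERSISTENCE = 2


@dataclass(frozen=True)
class MonolayerConfig:
    """Study conditions for a synthetic monolayer movie.

    Defaults mirror a typical long-term epithelial time-lapse: a 500 µm
    field with 400 cells imaged every 15 min. Distances in µm, times in
    hours, speeds in µm/h.
    """

    n_cells: int = 400
    box_size: float = 500.0
    mode: str = "fluid"                  # rigid_pack | fluid | static
    pack_size: float | None = None       # L_c (rigid_pack only)
    speed: float = 10.0                  # v0
    interface_t1_rate: float = 0.0       # events / interface cell / h
    fluid_t1_gain: float = 0.003         # (events/cell/h) per (µm/h)
    n_frames: int = 48
    dt: float = 0.25
    noise_sigma: float = 0.1             # centroid jitter, µm
    periodic: bool = True
    persistence_time: float = 2.0        # heading persistence, h
    t1_speed_factor: float = 1.0         # speed multiplier for event quartets
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 4:
            raise ValueError("n_cells must be >= 4")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.mode not in ("rigid_pack", "fluid", "static"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "rigid_pack":
            if self.pack_size is None:
                raise ValueError("rigid_pack mode requires pack_size (L_c)")
            if self.pack_size > self.box_size:
                raise ValueError("pack_size L_c cannot exceed box_size")


@dataclass
class MonolayerRun:
    """One generated movie: trajectories, per-frame adjacency, ground truth."""

    traj: TrajectorySet
    graphs: list[NeighborGraph]
    events: list[T1Event]
    config: MonolayerConfig
    pack_of: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.traj.times


# ---------------------------------------------------------------------------
# initial condition and motion
# ---------------------------------------------------------------------------

def _initial_positions(cfg: MonolayerConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered-lattice seeding: near-confluent without overlapping centroids."""
    m = int(np.ceil(np.sqrt(cfg.n_cells)))
    spacing = cfg.box_size / m
    jj, ii = np.meshgrid(np.arange(m), np.arange(m))
    sites = np.stack([(jj.ravel() + 0.5), (ii.ravel() + 0.5)], axis=1) * spacing
    idx = rng.choice(len(sites), size=cfg.n_cells, replace=False)
    pos = sites[idx] + rng.normal(0.0, 0.18 * spacing, size=(cfg.n_cells, 2))
    return pos % cfg.box_size


def _heading_walk(n_steps: int, n_walkers: int, dt: float, tau: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit headings of persistent random walkers, shape (n_steps, n_walkers, 2)."""
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n_walkers)
    if tau > 0:
        dtheta = rng.normal(0.0, np.sqrt(2.0 * dt / tau),
                            size=(n_steps, n_walkers))
    else:
        dtheta = rng.uniform(-np.pi, np.pi, size=(n_steps, n_walkers))
    theta = theta0[None, :] + np.concatenate(
        [np.zeros((1, n_walkers)), np.cumsum(dtheta, axis=0)[:-1]], axis=0)
    return np.stack([np.cos(theta), np.sin(theta)], axis=-1)


# ---------------------------------------------------------------------------
# scripted T1 exchanges
# ---------------------------------------------------------------------------

def _script_events(graph0: NeighborGraph, times: np.ndarray,
                   total_rate_per_h: float, rng: np.random.Generator,
                   allowed_edge, allowed_quartet=None,
                   k: int = SWAP_PERSISTENCE):
    """Sample a Poisson number of junction swaps and apply them to the
    frozen topology.

    Returns (per-transition swap schedule, event list skeleton). Raises if
    the requested rate is too high for non-overlapping quartets within the
    persistence window.
    """
    n_frames = len(times)
    duration = float(times[-1] - times[0]) if n_frames > 1 else 0.0
    n_events = rng.poisson(total_rate_per_h * duration)
    lo, hi = k - 1, n_frames - 1 - k  # inclusive transition range
    if n_events and lo > hi:
        raise ValueError(
            "movie too short to script T1 events with the persistence "
            f"window k={k}; need n_frames >= {2 * k + 1}")
    transitions = np.sort(rng.integers(lo, hi + 1, size=n_events))

    import heapq

    current = graph0
    busy_until: dict[int, int] = {}
    schedule: dict[int, list] = {}
    events: list[tuple[int, tuple, tuple]] = []
    max_defer = 8  # transitions an event may slip when quartets are congested
    queue = [(int(t), 0) for t in transitions]
    heapq.heapify(queue)
    while queue:
        t, deferred = heapq.heappop(queue)
        adj = current.adjacency()
        placed = False
        edges = sorted(e for e in current.edges if allowed_edge(e))
        order = rng.permutation(len(edges))
        for pick in order:
            a, b = edges[pick]
            if busy_until.get(a, -(10**9)) >= t - k or busy_until.get(b, -(10**9)) >= t - k:
                continue
            common = sorted(adj[a] & adj[b])
            common = [c for c in common
                      if busy_until.get(c, -(10**9)) < t - k]
            # keep the tessellation realistic: losers keep >= 3 neighbors,
            # gainers stay below 10 (real cell-neighbor counts)
            if len(adj[a]) <= 3 or len(adj[b]) <= 3:
                continue
            pairs = [(c, d) for i, c in enumerate(common)
                     for d in common[i + 1:]
                     if canonical_edge(c, d) not in current.edges
                     and len(adj[c]) < 9 and len(adj[d]) < 9
                     and (allowed_quartet is None
                          or allowed_quartet(a, b, c, d))]
            if not pairs:
                continue
            c, d = pairs[rng.integers(len(pairs))]
            lost = canonical_edge(a, b)
            gained = canonical_edge(c, d)
            mean_len = (np.mean(list(current.lengths.values()))
                        if current.lengths else 1.0)
            current = current.replace_edges([lost], [gained],
                                            {gained: float(mean_len)})
            adj = current.adjacency()
            for cell in (a, b, c, d):
                busy_until[cell] = t + k
            schedule.setdefault(t, []).append((lost, gained))
            events.append((t + 1, lost, gained))
            placed = True
            break
        if not placed:
            if deferred < max_defer and t + 1 <= hi:
                heapq.heappush(queue, (t + 1, deferred + 1))
                continue
            raise ValueError(
                "T1 rate too high: could not place a non-overlapping quartet "
                f"at transition {t} within the persistence window (k={k}); "
                "reduce the rate or lengthen the movie")
    events.sort()
    return schedule, events


def _materialize_graphs(graph0: NeighborGraph, n_frames: int,
                        schedule: dict) -> list[NeighborGraph]:
    graphs = []
    current = graph0
    for f in range(n_frames):
        if f > 0 and (f - 1) in schedule:
            for lost, gained in schedule[f - 1]:
                mean_len = (np.mean(list(current.lengths.values()))
                            if current.lengths else 1.0)
                current = current.replace_edges([lost], [gained],
                                                {gained: float(mean_len)})
        graphs.append(NeighborGraph(f, current.edges, current.lengths,
                                    current.boundary_cells, current.nodes))
    return graphs


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_monolayer(cfg: MonolayerConfig) -> MonolayerRun:
    """Dispatch on ``cfg.mode``."""
    if cfg.mode == "rigid_pack":
        return generate_rigid_pack(cfg)
    if cfg.mode == "fluid":
        return generate_fluid(cfg)
    return generate_static(cfg)


def generate_static(cfg: MonolayerConfig) -> MonolayerRun:
    rng = np.random.default_rng(cfg.seed)
    pos0 = _initial_positions(cfg, rng)
    times = cfg.dt * np.arange(cfg.n_frames)
    pos = np.broadcast_to(pos0, (cfg.n_frames, cfg.n_cells, 2)).copy()
    if cfg.noise_sigma > 0:
        pos = pos + rng.normal(0.0, cfg.noise_sigma, size=pos.shape)
        pos %= cfg.box_size
    ids = np.arange(1, cfg.n_cells + 1)
    graph0 = voronoi_neighbor_graph(ids, pos0, cfg.box_size, cfg.periodic)
    graphs = _materialize_graphs(graph0, cfg.n_frames, {})
    traj = trajectory_from_arrays(times, ids, pos, cfg.box_size, cfg.periodic)
    return MonolayerRun(traj, graphs, [], cfg)


def generate_rigid_pack(cfg: MonolayerConfig) -> MonolayerRun:
    """Coherent clusters of diameter ~ L_c sharing one velocity per frame.

    Scripted exchanges occur only on junctions between cells of different
    packs, at ``interface_t1_rate`` events per interface cell per hour, so
    that the total T1 rate is set by the interface geometry and not by v0.
    """
    if cfg.mode != "rigid_pack":
        cfg = replace(cfg, mode="rigid_pack")
    cfg.__post_init__()
    rng = np.random.default_rng(cfg.seed)
    pos0 = _initial_positions(cfg, rng)
    times = cfg.dt * np.arange(cfg.n_frames)
    ids = np.arange(1, cfg.n_cells + 1)

    n_side = max(1, int(round(cfg.box_size / cfg.pack_size)))
    cell_pack = (np.floor(pos0[:, 0] / cfg.box_size * n_side).astype(int)
                 * n_side
                 + np.floor(pos0[:, 1] / cfg.box_size * n_side).astype(int))
    packs = np.unique(cell_pack)
    pack_index = {p: i for i, p in enumerate(packs)}
    pack_of = {int(ids[i]): int(cell_pack[i]) for i in range(cfg.n_cells)}

    headings = _heading_walk(cfg.n_frames - 1, len(packs), cfg.dt,
                             cfg.persistence_time, rng)
    pack_steps = cfg.speed * cfg.dt * headings        # (n-1, n_packs, 2)
    pack_disp = np.concatenate(
        [np.zeros((1, len(packs), 2)), np.cumsum(pack_steps, axis=0)], axis=0)
    idx = np.array([pack_index[p] for p in cell_pack])
    pos = pos0[None, :, :] + pack_disp[:, idx, :]
    if cfg.noise_sigma > 0:
        pos = pos + rng.normal(0.0, cfg.noise_sigma, size=pos.shape)
    pos %= cfg.box_size

    graph0 = voronoi_neighbor_graph(ids, pos0, cfg.box_size, cfg.periodic)
    interface_cells = {a for a, b in graph0.edges if pack_of[a] != pack_of[b]}
    interface_cells |= {b for a, b in graph0.edges if pack_of[a] != pack_of[b]}
    total_rate = cfg.interface_t1_rate * len(interface_cells)

    # junctions flip back and forth at pack interfaces: the losing junction
    # must join two interface cells and the quartet must span two packs
    def allowed(edge):
        return edge[0] in interface_cells and edge[1] in interface_cells

    def allowed_quartet(a, b, c, d):
        return len({pack_of[x] for x in (a, b, c, d)}) >= 2

    schedule, raw_events = ({}, []) if total_rate == 0 else _script_events(
        graph0, times, total_rate, rng, allowed, allowed_quartet)
    graphs = _materialize_graphs(graph0, cfg.n_frames, schedule)
    traj = trajectory_from_arrays(times, ids, pos, cfg.box_size, cfg.periodic)
    events = _finalize_events(raw_events, times, traj)
    return MonolayerRun(traj, graphs, events, cfg, pack_of)


def generate_fluid(cfg: MonolayerConfig,
                   speed_schedule=None) -> MonolayerRun:
    """Persistent random motion at mean speed ~ v0 with distributed T1s.

    ``speed_schedule`` optionally maps time (h) to speed, overriding the
    constant v0 (used by the crowding generator).
    """
    if cfg.mode != "fluid":
        cfg = replace(cfg, mode="fluid")
    rng = np.random.default_rng(cfg.seed)
    pos0 = _initial_positions(cfg, rng)
    times = cfg.dt * np.arange(cfg.n_frames)
    ids = np.arange(1, cfg.n_cells + 1)

    graph0 = voronoi_neighbor_graph(ids, pos0, cfg.box_size, cfg.periodic)
    interior = graph0.interior_cells()
    mean_speed = (cfg.speed if speed_schedule is None
                  else float(np.mean([speed_schedule(t) for t in times[:-1]])))
    total_rate = cfg.fluid_t1_gain * mean_speed * len(interior)

    def allowed(edge):
        return edge[0] in interior and edge[1] in interior

    schedule, raw_events = ({}, []) if total_rate == 0 else _script_events(
        graph0, times, total_rate, rng, allowed)

    headings = _heading_walk(cfg.n_frames - 1, cfg.n_cells, cfg.dt,
                             cfg.persistence_time, rng)
    if speed_schedule is None:
        speeds = np.full((cfg.n_frames - 1, cfg.n_cells), cfg.speed)
    else:
        per_frame = np.array([speed_schedule(t) for t in times[:-1]])
        speeds = np.broadcast_to(per_frame[:, None],
                                 (cfg.n_frames - 1, cfg.n_cells)).copy()
    if cfg.t1_speed_factor != 1.0 and raw_events:
        id_col = {int(c): j for j, c in enumerate(ids)}
        for frame, lost, gained in raw_events:
            f0 = max(0, frame - 1 - SWAP_PERSISTENCE)
            f1 = min(cfg.n_frames - 1, frame + SWAP_PERSISTENCE)
            for cell in (*lost, *gained):
                speeds[f0:f1, id_col[cell]] *= cfg.t1_speed_factor

    steps = speeds[:, :, None] * cfg.dt * headings
    pos = pos0[None, :, :] + np.concatenate(
        [np.zeros((1, cfg.n_cells, 2)), np.cumsum(steps, axis=0)], axis=0)
    if cfg.noise_sigma > 0:
        pos = pos + rng.normal(0.0, cfg.noise_sigma, size=pos.shape)
    pos %= cfg.box_size

    graphs = _materialize_graphs(graph0, cfg.n_frames, schedule)
    traj = trajectory_from_arrays(times, ids, pos, cfg.box_size, cfg.periodic)
    events = _finalize_events(raw_events, times, traj)
    return MonolayerRun(traj, graphs, events, cfg)


def _finalize_events(raw_events, times, traj: TrajectorySet) -> list[T1Event]:
    events = []
    for frame, lost, gained in raw_events:
        ids, pts = traj.positions(frame)
        lookup = {int(c): pts[i] for i, c in enumerate(ids)}
        quartet = np.array([lookup[c] for c in (*lost, *gained)])
        ref = quartet[0]
        centered = ref + traj.minimum_image(quartet - ref)
        centroid = tuple(np.mean(centered, axis=0) % traj.box_size)
        events.append(T1Event(frame, float(times[frame]), lost, gained,
                              centroid))
    events.sort(key=lambda e: e.key())
    return events


# ---------------------------------------------------------------------------
# crowding time course
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrowdingEpoch:
    t_start_h: float
    speed: float                 # v0 for this epoch, µm/h
    density_per_mm2: float | None = None


def make_speed_schedule(epochs: list[CrowdingEpoch]):
    """Piecewise schedule; between listed epochs the speed interpolates
    linearly (a step is two epochs with equal start times a frame apart)."""
    ts = np.array([e.t_start_h for e in epochs])
    vs = np.array([e.speed for e in epochs])
    order = np.argsort(ts)
    ts, vs = ts[order], vs[order]

    def schedule(t: float) -> float:
        return float(np.interp(t, ts, vs))

    return schedule


def generate_crowding_timecourse(cfg: MonolayerConfig,
                                 epochs: list[CrowdingEpoch],
                                 seed: int | None = None) -> TrajectorySet:
    """Long trajectory whose windowed V_rms follows the epoch speed schedule
    (decay-then-plateau when the schedule does), for onset-detection tests."""
    speeds = [e.speed for e in sorted(epochs, key=lambda e: e.t_start_h)]
    if any(b > a + 1e-12 for a, b in zip(speeds, speeds[1:])):
        warnings.warn("crowding speed schedule is not monotone non-increasing",
                      stacklevel=2)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    # no scripted exchanges: this generator feeds kinematics-only analyses
    cfg = replace(cfg, mode="fluid", fluid_t1_gain=0.0)
    run = generate_fluid(cfg, speed_schedule=make_speed_schedule(epochs))
    return run.traj


# ---------------------------------------------------------------------------
# sigmoidal marker series
# ---------------------------------------------------------------------------

def four_param_logistic(t, bottom: float, top: float, logec50: float,
                        hill: float):
    """4PL on a log10 time axis: y = bottom + (top-bottom)/(1+(EC50/t)^hill).

    ``logec50`` is log10 of the half-maximal time EC50 (hours); ``hill`` is
    the dimensionless slope. Monotone increasing from bottom to top for
    hill > 0, with y(EC50) = (bottom + top)/2.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("the 4PL on log-time requires strictly positive times")
    ec50 = 10.0 ** logec50
    return bottom + (top - bottom) / (1.0 + (ec50 / t) ** hill)


@dataclass
class SigmoidSeries:
    """Noisy marker time course with known generating parameters."""

    times_h: np.ndarray
    values: np.ndarray
    bottom: float
    top: float
    logec50: float
    hill: float
    noise_sigma: float
    seed: int

    @property
    def ec50_h(self) -> float:
        return 10.0 ** self.logec50


def generate_sigmoid_series(bottom: float, top: float, logec50: float,
                            hill: float, times_h: np.ndarray,
                            noise_sigma: float = 0.0,
                            seed: int = 0) -> SigmoidSeries:
    if hill == 0:
        raise ValueError("hill slope must be nonzero")
    times_h = np.sort(np.asarray(times_h, dtype=float))
    rng = np.random.default_rng(seed)
    values = four_param_logistic(times_h, bottom, top, logec50, hill)
    if noise_sigma > 0:
        values = values + rng.normal(0.0, noise_sigma, size=times_h.shape)
    return SigmoidSeries(times_h, values, bottom, top, logec50, hill,
                         noise_sigma, seed)


# ---------------------------------------------------------------------------
# correlated velocity fields (for correlation-length validation)
# ---------------------------------------------------------------------------

def correlated_velocity_field(n_grid: int, spacing_um: float, xi_um: float,
                              rms: float = 1.0, seed: int = 0,
                              time_h: float = 0.0):
    """Gaussian random velocity field with exponential spatial correlation.

    Each component is sampled by circulant embedding on the periodic grid so
    that the lattice covariance is exactly exp(-d/xi) in the torus metric;
    for separations below half the domain this equals the Euclidean
    exponential correlation. The 1/e crossing of the correlation profile is
    therefore xi_um by construction.
    """
    from .kinematics import VelocityField

    rng = np.random.default_rng(seed)
    n = n_grid
    ax = spacing_um * np.minimum(np.arange(n), n - np.arange(n))
    dist = np.hypot(ax[:, None], ax[None, :])
    eigen = np.fft.fft2(np.exp(-dist / xi_um)).real
    eigen = np.clip(eigen, 0.0, None)

    def sample_component():
        white = rng.normal(size=(n, n))
        f = np.fft.fft2(white) * np.sqrt(eigen)
        comp = np.fft.ifft2(f).real
        return comp / np.sqrt(np.mean(comp ** 2)) * rms / np.sqrt(2.0)

    vx, vy = sample_component(), sample_component()
    vectors = np.stack([vx, vy], axis=-1)
    return VelocityField(origin_um=(0.0, 0.0), spacing_um=spacing_um,
                         vectors=vectors,
                         valid=np.ones((n, n), dtype=bool), time_h=time_h)
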