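"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plainly as possible (explicit loops, no
shared helpers with the package) so it can serve as a reference
implementation in equivalence tests.
"""

from __future__ import annotations

import numpy as np


def brute_force_t1(graphs, k):
    """Naive T1 detection: adjacency-set differences with the persistence
    rule applied by explicit scanning. Returns (frame, losers, gainers)."""
    n = len(graphs)
    out = []
    for t in range(n - 1):
        e0, e1 = graphs[t].edges, graphs[t + 1].edges

        lost = []
        for e in sorted(e0 - e1):
            if t - k + 1 < 0:
                continue
            if all(e in graphs[s].edges for s in range(t - k + 1, t + 1)):
                lost.append(e)
        gained = []
        for e in sorted(e1 - e0):
            if t + k > n - 1:
                continue
            if all(e in graphs[s].edges for s in range(t + 1, t + 1 + k)):
                gained.append(e)

        candidates = []
        for (a, b) in lost:
            for (c, d) in gained:
                if len({a, b, c, d}) != 4:
                    continue
                sides_ok = True
                for (u, v) in ((a, c), (a, d), (b, c), (b, d)):
                    e = (u, v) if u < v else (v, u)
                    if e not in e0 or e not in e1:
                        sides_ok = False
                        break
                if sides_ok:
                    length = graphs[t].lengths.get((a, b), 0.0)
                    candidates.append((-length, (a, b), (c, d)))
        candidates.sort()
        used_lost, used_gained = set(), set()
        for _, le, ge in candidates:
            if le in used_lost or ge in used_gained:
                continue
            used_lost.add(le)
            used_gained.add(ge)
            out.append((t + 1, le, ge))
    return out


def brute_force_correlation(points, dv, edges):
    """All-ordered-pairs (including self) binned correlation sums."""
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    n = len(points)
    for i in range(n):
        for j in range(n):
            d = np.hypot(points[i, 0] - points[j, 0],
                         points[i, 1] - points[j, 1])
            for b in range(n_bins):
                if edges[b] <= d < edges[b + 1]:
                    sums[b] += dv[i, 0] * dv[j, 0] + dv[i, 1] * dv[j, 1]
                    counts[b] += 1
                    break
    return sums, counts


def pixel_adjacency_oracle(label_mask, um_per_px, eps_edge):
    """Shared-boundary lengths by scanning every 4-neighbour pixel pair."""
    shared = {}
    h, w = label_mask.shape
    for i in range(h):
        for j in range(w):
            a = int(label_mask[i, j])
            if a <= 0:
                continue
            for di, dj in ((0, 1), (1, 0)):
                if i + di >= h or j + dj >= w:
                    continue
                b = int(label_mask[i + di, j + dj])
                if b <= 0 or b == a:
                    continue
                e = (a, b) if a < b else (b, a)
                shared[e] = shared.get(e, 0.0) + um_per_px
    return {e for e, ln in shared.items() if ln >= eps_edge}


def random_t1_sequences(n_sequences, rng):
    """Random adjacency-graph sequences with scripted quartet flips and
    single-frame flicker noise, for detector/oracle equivalence checks."""
    from epijam.core import NeighborGraph, canonical_edge
    from epijam.topology import voronoi_neighbor_graph

    sequences = []
    for _ in range(n_sequences):
        n_cells = int(rng.integers(12, 31))
        n_frames = int(rng.integers(8, 31))
        pts = rng.uniform(0, 100, size=(n_cells, 2))
        ids = np.arange(1, n_cells + 1)
        g0 = voronoi_neighbor_graph(ids, pts, 100.0, periodic=True)
        frames = [set(g0.edges) for _ in range(n_frames)]

        # scripted persistent quartet flips
        for _ in range(int(rng.integers(1, 6))):
            t = int(rng.integers(1, max(2, n_frames - 2)))
            edges_now = sorted(frames[t])
            if not edges_now:
                continue
            a, b = edges_now[rng.integers(len(edges_now))]
            nbrs_a = {x for e in frames[t] for x in e if a in e} - {a}
            nbrs_b = {x for e in frames[t] for x in e if b in e} - {b}
            common = sorted((nbrs_a & nbrs_b) - {a, b})
            pairs = [(c, d) for i, c in enumerate(common)
                     for d in common[i + 1:]
                     if canonical_edge(c, d) not in frames[t]]
            if not pairs:
                continue
            c, d = pairs[rng.integers(len(pairs))]
            for s in range(t + 1, n_frames):
                frames[s].discard(canonical_edge(a, b))
                frames[s].add(canonical_edge(c, d))

        # single-frame flicker (should be filtered by persistence >= 2)
        for _ in range(int(rng.integers(0, 8))):
            t = int(rng.integers(0, n_frames))
            edges_now = sorted(frames[t])
            if edges_now and rng.random() < 0.5:
                frames[t].discard(edges_now[rng.integers(len(edges_now))])
            else:
                u, v = rng.choice(n_cells, size=2, replace=False) + 1
                frames[t].add(canonical_edge(int(u), int(v)))

        graphs = [NeighborGraph(f, frozenset(frames[f]),
                                {e: g0.lengths.get(e, 1.0) for e in frames[f]},
                                nodes=frozenset(int(i) for i in ids))
                  for f in range(n_frames)]
        sequences.append(graphs)
    return sequences
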