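"""Neighbor graphs, T1 detection, exchange rates, and shape morphometrics."""

import numpy as np
import pytest

from epijam.core import NeighborGraph, T1Event
from epijam.synthetic import MonolayerConfig, generate_fluid
from epijam.topology import (build_neighbor_graph, detect_t1, shape_metrics_mask,
                             shape_metrics_polygons, t1_rate,
                             t1_speed_comparison, voronoi_neighbor_graph,
                             voronoi_polygons)

from oracles import brute_force_t1, pixel_adjacency_oracle, random_t1_sequences


def graph_from_edges(frame, edges, lengths=None):
    return NeighborGraph(frame, frozenset(edges), dict(lengths or {}))


class TestBuildNeighborGraph:
    def test_corner_contact_is_not_adjacency(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[:10, :10] = 1
        mask[:10, 10:] = 2
        mask[10:, :10] = 3
        mask[10:, 10:] = 4
        g = build_neighbor_graph(mask)
        assert g.has_edge(1, 2) and g.has_edge(1, 3)
        assert not g.has_edge(1, 4) and not g.has_edge(2, 3)

    def test_honeycomb_center_has_degree_six(self):
        # rasterized Voronoi of a hexagonal lattice: 7 hexagonal cells
        d = 30.0
        angles = np.arange(6) * np.pi / 3
        centers = np.vstack([[0.0, 0.0],
                             np.column_stack([d * np.cos(angles),
                                              d * np.sin(angles)])])
        centers += 60.0
        yy, xx = np.mgrid[0:120, 0:120]
        dist = (yy[..., None] - centers[:, 1]) ** 2 + (xx[..., None] - centers[:, 0]) ** 2
        mask = np.argmin(dist, axis=-1) + 1
        g = build_neighbor_graph(mask)
        assert g.degree(1) == 6

    def test_matches_pixel_adjacency_oracle(self, rng):
        pts = rng.uniform(0, 60, size=(50, 2))
        yy, xx = np.mgrid[0:60, 0:60]
        dist = (yy[..., None] - pts[:, 1]) ** 2 + (xx[..., None] - pts[:, 0]) ** 2
        mask = np.argmin(dist, axis=-1) + 1
        g = build_neighbor_graph(mask, um_per_px=1.0)
        areas = np.bincount(mask.ravel())[1:]
        eps = 0.05 * float(np.mean(2 * np.sqrt(areas / np.pi)))
        assert set(g.edges) == pixel_adjacency_oracle(mask, 1.0, eps)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_neighbor_graph(np.zeros((10, 10), dtype=int))

    def test_border_cells_flagged(self):
        mask = np.zeros((30, 30), dtype=int)
        mask[:15] = 1
        mask[15:] = 2
        g = build_neighbor_graph(mask)
        assert g.boundary_cells == frozenset({1, 2})


class TestDetectT1:
    @staticmethod
    def quad_flip_sequence(k=2, n=8, flip_at=3):
        """Canonical T1: A=1,B=2 adjacent, C=3,D=4 gain the junction."""
        sides = [(1, 3), (1, 4), (2, 3), (2, 4)]
        before = set(sides) | {(1, 2)}
        after = set(sides) | {(3, 4)}
        return [graph_from_edges(f, before if f < flip_at else after)
                for f in range(n)]

    def test_single_quad_flip_detected_once(self):
        events = detect_t1(self.quad_flip_sequence(), persistence=2)
        assert len(events) == 1
        ev = events[0]
        assert ev.losers == (1, 2) and ev.gainers == (3, 4)
        assert ev.frame == 3

    def test_static_sequence_has_no_events(self):
        g = self.quad_flip_sequence(flip_at=100, n=10)
        assert detect_t1(g, persistence=2) == []

    def test_flicker_suppressed_by_persistence(self):
        graphs = self.quad_flip_sequence(flip_at=3, n=8)
        # revert immediately after one frame: no persistent exchange
        graphs = graphs[:3] + [graphs[3]] + graphs[:4] + graphs[:1]
        events = detect_t1(graphs, persistence=2)
        assert events == []

    def test_generator_ground_truth_recovered(self, rigid_run):
        detected = detect_t1(rigid_run.graphs, persistence=2,
                             times=rigid_run.times)
        gt = {e.key() for e in rigid_run.events}
        dd = {e.key() for e in detected}
        assert len(gt & dd) / len(dd) >= 0.95  # precision
        assert len(gt & dd) / len(gt) >= 0.95  # recall

    def test_matches_brute_force_oracle(self, rng):
        for graphs in random_t1_sequences(20, rng):
            fast = [(e.frame, e.losers, e.gainers)
                    for e in detect_t1(graphs, persistence=2)]
            assert fast == brute_force_t1(graphs, 2)

    def test_relabeling_invariance(self, rng):
        graphs = random_t1_sequences(1, rng)[0]
        nodes = sorted(graphs[0].nodes)
        relabel = {c: 1000 + i for i, c in enumerate(rng.permutation(nodes))}

        def map_graph(g):
            return NeighborGraph(
                g.frame,
                frozenset(tuple(sorted((relabel[a], relabel[b])))
                          for a, b in g.edges),
                {tuple(sorted((relabel[a], relabel[b]))): ln
                 for (a, b), ln in g.lengths.items()},
                nodes=frozenset(relabel[c] for c in g.nodes))

        base = {(e.frame, tuple(sorted(relabel[c] for c in e.losers)),
                 tuple(sorted(relabel[c] for c in e.gainers)))
                for e in detect_t1(graphs, persistence=2)}
        mapped = {(e.frame, e.losers, e.gainers)
                  for e in detect_t1([map_graph(g) for g in graphs],
                                     persistence=2)}
        assert base == mapped

    def test_time_reversal_swaps_losers_and_gainers(self, rng):
        for graphs in random_t1_sequences(5, rng):
            fwd = detect_t1(graphs, persistence=2)
            rev = detect_t1(list(reversed(graphs)), persistence=2)
            fwd_pairs = sorted((e.losers, e.gainers) for e in fwd)
            rev_pairs = sorted((e.gainers, e.losers) for e in rev)
            assert fwd_pairs == rev_pairs

    def test_tracking_discontinuity_warns_and_skips(self):
        graphs = self.quad_flip_sequence()
        other = graph_from_edges(4, {(101, 102), (102, 103), (101, 103),
                                     (103, 104), (101, 104), (102, 104)})
        with pytest.warns(UserWarning, match="tracking continuity"):
            detect_t1(graphs[:4] + [other] + graphs[4:], persistence=1)

    def test_persistence_below_one_rejected(self):
        with pytest.raises(ValueError, match="persistence"):
            detect_t1(self.quad_flip_sequence(), persistence=0)


class TestT1Rate:
    @staticmethod
    def make_events(times):
        return [T1Event(i + 2, t, (1, 2), (3, 4)) for i, t in enumerate(times)]

    def test_twelve_events_hundred_cells_three_hours(self):
        events = self.make_events(np.linspace(0.1, 2.9, 12))
        series = t1_rate(events, 100, 3.0, t_end=3.0)
        assert series.rate[0] == pytest.approx(0.04)

    def test_no_events_gives_zero(self):
        series = t1_rate([], 100, 3.0, t_end=6.0)
        assert np.all(series.rate == 0.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            t1_rate(self.make_events([1.0]), 0, 3.0)

    def test_denominator_scales_rate_not_events(self):
        events = self.make_events(np.linspace(0.1, 2.9, 12))
        all_cells = t1_rate(events, 100, 3.0, t_end=3.0)
        interior = t1_rate(events, 80, 3.0, t_end=3.0)
        assert np.array_equal(all_cells.n_events, interior.n_events)
        assert interior.rate[0] == pytest.approx(all_cells.rate[0] * 100 / 80)


class TestShapeMetrics:
    def test_unit_square(self):
        from shapely.geometry import Polygon

        sm = shape_metrics_polygons({1: Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])})
        assert sm.shape_index[0] == pytest.approx(4.0, abs=1e-12)
        assert sm.aspect_ratio[0] == pytest.approx(1.0, abs=1e-9)
        assert sm.perimeter_over_area[0] == pytest.approx(4.0, abs=1e-12)

    def test_regular_hexagon(self):
        from shapely.geometry import Polygon

        ang = np.pi / 3 * np.arange(6)
        hexagon = Polygon(np.column_stack([np.cos(ang), np.sin(ang)]))
        sm = shape_metrics_polygons({1: hexagon})
        expected = 6.0 / np.sqrt(3 * np.sqrt(3) / 2)
        assert sm.shape_index[0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(3.7224, abs=1e-4)

    def test_two_one_rectangle(self):
        from shapely.geometry import Polygon

        rect = Polygon([(0, 0), (2, 0), (2, 1), (0, 1)])
        sm = shape_metrics_polygons({1: rect})
        assert sm.aspect_ratio[0] == pytest.approx(2.0, abs=1e-9)
        assert sm.shape_index[0] == pytest.approx(6.0 / np.sqrt(2), abs=1e-12)

    def test_shape_index_bounded_below_by_disk(self, rng):
        pts = rng.uniform(0, 200, size=(40, 2))
        polys = voronoi_polygons(np.arange(1, 41), pts, 200.0, periodic=True)
        sm = shape_metrics_polygons(polys)
        assert np.all(sm.shape_index >= 2 * np.sqrt(np.pi) - 1e-9)
        assert np.all(sm.aspect_ratio >= 1.0 - 1e-12)

    def test_rasterized_disk_converges_to_circle_bound(self):
        q_err = []
        for radius in (5, 20, 120):
            n = 2 * radius + 9
            yy, xx = np.mgrid[0:n, 0:n]
            mask = (((yy - n / 2) ** 2 + (xx - n / 2) ** 2)
                    <= radius ** 2).astype(int)
            sm = shape_metrics_mask(mask, exclude_border=False)
            q_err.append(abs(sm.shape_index[0] - 2 * np.sqrt(np.pi)))
        assert q_err[0] > q_err[1] > q_err[2]
        assert q_err[2] < 0.02

    def test_invalid_polygon_rejected(self):
        from shapely.geometry import Polygon

        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError, match="valid"):
            shape_metrics_polygons({1: bowtie})

    def test_mask_border_cells_excluded(self):
        mask = np.zeros((30, 30), dtype=int)
        mask[:15] = 1
        mask[20:28, 5:25] = 2
        sm = shape_metrics_mask(mask, exclude_border=True)
        assert list(sm.cell_id) == [2]


class TestT1SpeedComparison:
    def test_shared_speed_is_non_significant(self, fluid_run):
        events = fluid_run.events
        comp = t1_speed_comparison(events, fluid_run.traj, fluid_run.graphs,
                                   window=1)
        assert comp.p_value > 0.01
        assert abs(comp.median_ratio - 1.0) < 0.1

    def test_boosted_quartets_detected(self):
        pvals = []
        for seed in range(3):
            cfg = MonolayerConfig(n_cells=144, box_size=300.0, mode="fluid",
                                  speed=8.0, fluid_t1_gain=0.003,
                                  n_frames=121, t1_speed_factor=2.0,
                                  seed=seed)
            run = generate_fluid(cfg)
            assert len(run.events) >= 50
            comp = t1_speed_comparison(run.events, run.traj, run.graphs,
                                       window=1)
            assert comp.median_ratio > 1.5
            pvals.append(comp.p_value)
        assert all(p < 0.01 for p in pvals)

    def test_no_events_rejected(self, fluid_run):
        with pytest.raises(ValueError, match="no usable events"):
            t1_speed_comparison([], fluid_run.traj, fluid_run.graphs)


class TestVoronoiGraph:
    def test_periodic_graph_has_no_boundary_cells(self, rng):
        pts = rng.uniform(0, 100, size=(30, 2))
        g = voronoi_neighbor_graph(np.arange(1, 31), pts, 100.0, periodic=True)
        assert g.boundary_cells == frozenset()

    def test_bounded_graph_flags_hull_cells(self, rng):
        pts = rng.uniform(0, 100, size=(30, 2))
        g = voronoi_neighbor_graph(np.arange(1, 31), pts, 100.0,
                                   periodic=False)
        assert len(g.boundary_cells) > 0
        assert g.interior_cells() == g.nodes - g.boundary_cells

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            voronoi_neighbor_graph(np.array([1, 2, 3]),
                                   np.zeros((3, 2)), 10.0)
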