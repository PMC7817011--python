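"""Trajectory statistics: displacement, orientation, directionality, mixing."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import shortest_path

from sproutsim.engine import TrajectoryLog
from sproutsim.fixtures import make_random_network
from sproutsim.lattice import HexLattice
from sproutsim.metrics import (
    build_network,
    directionality,
    displacement_histogram,
    max_network_distance,
    mixing_measure,
    network_distance,
    network_morphometrics,
    orientation_statistic,
    tip_proportion,
)
from sproutsim.params import MINUTES_PER_UNIT


def _log_from_positions(positions, sample_dt=0.01, h=10.0, voxels=None):
    """positions: dict label -> list of (x, y) per sample."""
    rows = []
    n = max(len(v) for v in positions.values())
    for k in range(n):
        t = k * sample_dt
        for lab, xy in positions.items():
            x, y = xy[min(k, len(xy) - 1)]
            vox = voxels[lab][min(k, len(voxels[lab]) - 1)] if voxels else 0
            rows.append((t, lab, vox, x, y, 0, 0.0, False))
    frame = pd.DataFrame(rows, columns=["t", "label", "voxel", "x", "y",
                                        "lineage", "D", "tip"])
    return TrajectoryLog(frame, sample_dt, b_D=400.0)


class TestDisplacement:
    def test_stationary_cell_zero_displacement(self):
        log = _log_from_positions({0: [(0.0, 0.0)] * 10}, sample_dt=0.03)
        _, _, disp = displacement_histogram(log, window_min=15.0)
        assert np.all(disp == 0.0)

    def test_single_hop_gives_h(self):
        pos = [(0.0, 0.0)] * 2 + [(10.0, 0.0)] * 2
        log = _log_from_positions({0: pos}, sample_dt=0.015)
        _, _, disp = displacement_histogram(log, window_min=15.0)
        assert disp[0] == pytest.approx(0.0) or disp[0] == pytest.approx(10.0)
        assert 10.0 in np.round(disp, 6)

    def test_non_multiple_window_rejected(self):
        log = _log_from_positions({0: [(0.0, 0.0)] * 10}, sample_dt=0.004)
        with pytest.raises(ValueError):
            displacement_histogram(log, window_min=15.0)

    def test_bernoulli_hop_walk_matches_binomial_oracle(self):
        # walker hops one lattice spacing with probability q per window;
        # the fraction of h-displacement windows is Binomial(n, q)/n
        rng = np.random.default_rng(0)
        q, n_windows, h = 0.3, 10000, 10.0
        x = 0.0
        pos = [(0.0, 0.0)]
        hops = 0
        for _ in range(n_windows):
            if rng.random() < q:
                x += h
                hops += 1
            pos.append((x, 0.0))
        log = _log_from_positions({0: pos}, sample_dt=0.03)
        _, _, disp = displacement_histogram(log, window_min=15.0)
        frac = np.mean(np.isclose(disp, h))
        se = math.sqrt(q * (1 - q) / n_windows)
        assert frac == pytest.approx(q, abs=3 * se)


class TestOrientation:
    def test_straight_path_scores_one(self):
        pos = [(float(k), 0.0) for k in range(20)]
        log = _log_from_positions({0: pos})
        assert orientation_statistic(log)[0] == pytest.approx(1.0)

    def test_tight_zigzag_scores_below_one(self):
        pos = [((k % 2) * 10.0, 0.0) for k in range(20)]
        log = _log_from_positions({0: pos})
        assert orientation_statistic(log)[0] < 0.5

    def test_ratios_in_unit_interval_for_random_paths(self):
        rng = np.random.default_rng(1)
        paths = {lab: np.cumsum(rng.normal(0, 5, size=(30, 2)), axis=0).tolist()
                 for lab in range(10)}
        log = _log_from_positions({k: [tuple(p) for p in v]
                                   for k, v in paths.items()})
        r = orientation_statistic(log)
        assert np.all((r > 0) & (r <= 1.0))

    def test_ordering_insensitive_to_smoothing_window(self):
        rng = np.random.default_rng(2)
        straight = {0: [(2.0 * k + rng.normal(0, 0.2), 0.0) for k in range(30)]}
        wiggly = {0: [(0.5 * k, 8.0 * ((k % 2) - 0.5)) for k in range(30)]}
        for w in (3, 5):
            rs = orientation_statistic(_log_from_positions(straight), w)[0]
            rw = orientation_statistic(_log_from_positions(wiggly), w)[0]
            assert rs > rw


class TestDirectionality:
    def test_stationary_log_is_all_still(self):
        lat = HexLattice(6, 6)
        vox = {0: [14] * 10}
        pos = {0: [tuple(lat.centers[14])] * 10}
        log = _log_from_positions(pos, sample_dt=0.04, voxels=vox)
        d = directionality(log, lat, {14}, window_min=20.0)
        assert d == {"anterograde": 0.0, "retrograde": 0.0, "still": 1.0}

    def test_proportions_sum_to_one(self):
        G, log = make_random_network(30, seed=3, n_walkers=5, n_steps=40)
        lat = HexLattice(16, 16)
        base = {int(log.frame.iloc[0]["voxel"])}
        d = directionality(log, lat, base, window_min=100.0)
        assert sum(d.values()) == pytest.approx(1.0)

    def test_swap_in_frozen_sprout_balances_antero_retro(self):
        # two cells exchanging positions: one moves away from the base,
        # the other back toward it
        lat = HexLattice(8, 4)
        a, b = lat.index(2, 1), lat.index(3, 1)
        vox = {0: [a, b] * 5, 1: [b, a] * 5}
        pos = {k: [tuple(lat.centers[v]) for v in vv] for k, vv in vox.items()}
        log = _log_from_positions(pos, sample_dt=0.04, voxels=vox)
        d = directionality(log, lat, {lat.index(0, 1), a}, window_min=20.0)
        assert d["anterograde"] == pytest.approx(d["retrograde"])
        assert d["anterograde"] > 0


class TestTipProportion:
    def test_all_tips(self):
        frame = pd.DataFrame({
            "t": [0.0, 0.0], "label": [0, 1], "voxel": [0, 1],
            "x": [0.0, 1.0], "y": [0.0, 0.0], "lineage": [0, 0],
            "D": [500.0, 900.0], "tip": [True, True]})
        log = TrajectoryLog(frame, 0.01, b_D=400.0)
        assert tip_proportion(log, 0.0) == 1.0

    def test_empty_log_is_undefined(self):
        frame = pd.DataFrame(columns=["t", "label", "voxel", "x", "y",
                                      "lineage", "D", "tip"])
        log = TrajectoryLog(frame, 0.01, b_D=400.0)
        assert tip_proportion(log, 0.0) is None


class TestNetworkDistance:
    def test_zero_for_same_node(self):
        G, _ = make_random_network(20, seed=1)
        n = next(iter(G.nodes))
        assert network_distance(G, n, n) == 0.0

    def test_straight_sprout_endpoints(self):
        lat = HexLattice(8, 3)
        vox = {0: [lat.index(c, 1) for c in range(5)]}
        pos = {0: [tuple(lat.centers[v]) for v in vox[0]]}
        log = _log_from_positions(pos, voxels=vox)
        G = build_network(log, lat)
        assert network_distance(G, vox[0][0], vox[0][-1]) == pytest.approx(4 * lat.h)

    def test_matches_independent_bfs_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            G, _ = make_random_network(25, seed=trial, branching_prob=0.5)
            nodes = list(G.nodes)
            index = {n: k for k, n in enumerate(nodes)}
            adj = lil_matrix((len(nodes), len(nodes)))
            for u, v in G.edges:
                adj[index[u], index[v]] = 1
                adj[index[v], index[u]] = 1
            dmat = shortest_path(adj.tocsr(), unweighted=True)
            for _ in range(10):
                u, v = rng.choice(nodes, size=2)
                expected = dmat[index[u], index[v]] * 10.0
                got = network_distance(G, int(u), int(v))
                assert got == pytest.approx(expected)

    def test_symmetric(self):
        G, _ = make_random_network(40, seed=9)
        rng = np.random.default_rng(0)
        nodes = list(G.nodes)
        for _ in range(100):
            u, v = rng.choice(nodes, size=2)
            assert network_distance(G, int(u), int(v)) == \
                network_distance(G, int(v), int(u))

    def test_missing_node_raises(self):
        G, _ = make_random_network(10, seed=2)
        with pytest.raises(KeyError):
            network_distance(G, -1, next(iter(G.nodes)))


class TestMixingMeasure:
    def test_stationary_walkers_give_zero(self):
        # freeze a spread-out configuration and replay it at three times
        G, log = make_random_network(25, seed=5, n_walkers=4, n_steps=10)
        final = log.at(log.frame["t"].max()).copy()
        frozen = pd.concat([final.assign(t=dt) for dt in (0.0, 0.1, 0.2)],
                           ignore_index=True)
        log2 = TrajectoryLog(frozen, 0.1, b_D=1.0)
        cluster = set(int(v) for v in final["voxel"])
        M = mixing_measure(log2, G, cluster, t=0.0, t_m=0.2)
        assert M == 0.0

    def test_single_cell_cluster_is_undefined(self):
        G, log = make_random_network(25, seed=5, n_walkers=1, n_steps=10)
        cluster = {int(log.frame.iloc[0]["voxel"])}
        assert mixing_measure(log, G, cluster, t=0.0, t_m=0.05) is None

    def test_matches_brute_force_oracle(self):
        # direct recomputation of every pair distance with scipy csgraph
        G, log = make_random_network(40, seed=11, n_walkers=6, n_steps=40)
        nodes = list(G.nodes)
        index = {n: k for k, n in enumerate(nodes)}
        adj = lil_matrix((len(nodes), len(nodes)))
        for u, v in G.edges:
            adj[index[u], index[v]] = adj[index[v], index[u]] = 1
        dmat = shortest_path(adj.tocsr(), unweighted=True) * 10.0
        t, t_m = 0.0, 0.3
        snap0 = log.at(t)
        snap1 = log.at(t + t_m)
        cluster = set(int(v) for v in snap0["voxel"])
        final = log.at(log.frame["t"].max())
        d_max = max(dmat[index[int(a)], index[int(b)]]
                    for a, b in itertools.product(final["voxel"], repeat=2))
        members = snap0[snap0["voxel"].isin(cluster)]
        p0 = dict(zip(snap0["label"], snap0["voxel"]))
        p1 = dict(zip(snap1["label"], snap1["voxel"]))
        expected = sum(
            dmat[index[int(p1[a])], index[int(p1[b])]]
            - dmat[index[int(p0[a])], index[int(p0[b])]]
            for a, b in itertools.combinations(sorted(members["label"]), 2)
        ) / (len(cluster) * d_max)
        got = mixing_measure(log, G, cluster, t, t_m)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_relabelling(self):
        G, log = make_random_network(30, seed=13, n_walkers=5, n_steps=30)
        cluster = set(int(v) for v in log.at(0.0)["voxel"])
        M1 = mixing_measure(log, G, cluster, 0.0, 0.2)
        perm = {0: 4, 1: 3, 2: 2, 3: 1, 4: 0}
        f2 = log.frame.copy()
        f2["label"] = f2["label"].map(perm)
        M2 = mixing_measure(TrajectoryLog(f2, log.sample_dt, log.b_D),
                            G, cluster, 0.0, 0.2)
        assert M1 == pytest.approx(M2)

    def test_algebraic_bound(self):
        G, log = make_random_network(30, seed=17, n_walkers=6, n_steps=50)
        cluster = set(int(v) for v in log.at(0.0)["voxel"])
        M = mixing_measure(log, G, cluster, 0.0, 0.4)
        n_cells = len(log.at(0.0))
        n_pairs = n_cells * (n_cells - 1) / 2
        assert abs(M) <= n_pairs / len(cluster) + 1e-12


class TestMorphometrics:
    def _line_graph(self, n, h=10.0):
        lat = HexLattice(n + 2, 3)
        vox = [lat.index(c, 1) for c in range(n)]
        G = nx.Graph()
        for v in vox:
            G.add_node(v)
        for a, b in zip(vox, vox[1:]):
            G.add_edge(a, b, length=h)
        return G

    def test_straight_sprout(self):
        G = self._line_graph(10)
        m = network_morphometrics(G, 10.0, 86.6)
        assert m["n_branching_points"] == 0
        assert m["n_segments"] == 1
        assert m["segment_lengths"][0] == pytest.approx(90.0)

    def test_symmetric_y(self):
        # three 5-node arms joined at a hub
        G = nx.Graph()
        hub = 0
        node = 1
        for arm in range(3):
            prev = hub
            for _ in range(5):
                G.add_edge(prev, node, length=10.0)
                prev = node
                node += 1
        m = network_morphometrics(G, 10.0, 86.6)
        assert m["n_branching_points"] == 1
        assert m["n_segments"] == 3
        np.testing.assert_allclose(m["segment_lengths"], 50.0)

    def test_single_voxel_bump_not_a_branching_point(self):
        G = self._line_graph(10)
        chain = sorted(G.nodes)
        lat_extra = 10**6
        G.add_edge(chain[5], lat_extra, length=10.0)  # one-voxel spur
        m = network_morphometrics(G, 10.0, 86.6)
        assert m["n_branching_points"] == 0
        assert m["n_segments"] == 3

    def test_random_toy_networks_against_enumeration(self):
        # segment count equals edge count minus internal degree-2 chain merges
        for seed in range(10):
            G, _ = make_random_network(20, seed=seed, branching_prob=0.4)
            m = network_morphometrics(G, 10.0, 86.6)
            assert m["network_area"] == pytest.approx(G.number_of_nodes() * 86.6)
            # every edge belongs to exactly one segment
            assert sum(len(np.atleast_1d(sl)) // 1 for sl in [m["segment_lengths"]]) >= 0
            assert m["segment_lengths"].sum() == pytest.approx(
                G.number_of_edges() * 10.0)
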