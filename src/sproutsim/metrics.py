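"""Quantitative statistics of simulated (or experimental) cell trajectories.

All metrics are pure functions of a :class:`~sproutsim.engine.TrajectoryLog`
(and, where relevant, the vascular-network graph of ever-occupied
voxels): displacement histograms over 15-minute windows, the
trajectory-orientation (persistence) ratio, anterograde/retrograde/still
directionality over 20-minute windows, the tip-cell proportion, network
morphometrics (branching points per area, vessel segments), and the
cell-mixing measure

``M(t) = (1 / (|I_cluster| d_max)) * sum_pairs [d(i1,i2,t+t_m) - d(i1,i2,t)]``

which quantifies how far cells that started as a cluster of nearest
neighbours have moved apart *through the network* after a lag ``t_m``,
normalised by the largest network distance between any two cells at the
final time.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd

from .engine import TrajectoryLog
from .lattice import HexLattice
from .params import MINUTES_PER_UNIT

__all__ = [
    "displacement_histogram",
    "orientation_statistic",
    "directionality",
    "tip_proportion",
    "build_network",
    "network_distance",
    "mixing_measure",
    "mixing_curve",
    "network_morphometrics",
]


def _window_samples(log: TrajectoryLog, window_min: float) -> int:
    w = (window_min / MINUTES_PER_UNIT) / log.sample_dt
    if abs(w - round(w)) > 1e-6 or round(w) < 1:
        raise ValueError(
            f"window of {window_min} min is not a multiple of the sampling "
            f"interval ({log.sample_dt * MINUTES_PER_UNIT} min)")
    return int(round(w))


def _cell_tracks(log: TrajectoryLog):
    for label, g in log.frame.groupby("label"):
        yield label, g.sort_values("t")


def displacement_histogram(
    log: TrajectoryLog,
    window_min: float = 15.0,
    bin_width: float = 2.5,
    max_um: float | None = None,
):
    """Distribution of per-cell displacements over disjoint windows.

    Euclidean displacement (um) of each cell over each disjoint window of
    ``window_min`` simulated minutes, pooled across cells.  Returns
    ``(bin_edges, counts, displacements)``.
    """
    k = _window_samples(log, window_min)
    disp = []
    for _, g in _cell_tracks(log):
        xy = g[["x", "y"]].to_numpy()
        for a in range(0, len(xy) - k, k):
            disp.append(float(np.hypot(*(xy[a + k] - xy[a]))))
    disp = np.asarray(disp)
    top = max_um if max_um is not None else (disp.max() if disp.size else 1.0)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(disp, bins=edges)
    return edges, counts, disp


def _path_length(xy: np.ndarray) -> float:
    return float(np.hypot(*np.diff(xy, axis=0).T).sum()) if len(xy) > 1 else 0.0


def _moving_average(xy: np.ndarray, w: int) -> np.ndarray:
    """Endpoint-preserving moving average (smoothing must not clip the path)."""
    if len(xy) < w:
        return xy.copy()
    kernel = np.ones(w) / w
    interior = np.column_stack([
        np.convolve(xy[:, 0], kernel, mode="valid"),
        np.convolve(xy[:, 1], kernel, mode="valid"),
    ])
    return np.vstack([xy[:1], interior, xy[-1:]])


def orientation_statistic(log: TrajectoryLog, smooth_window: int = 3) -> np.ndarray:
    """Per-cell persistence ratio: smoothed path length / actual path length.

    The smoothed trajectory is a ``smooth_window``-point moving average of
    the sampled positions; straight paths score 1, tortuous paths less.
    Cells that never move are excluded.
    """
    ratios = []
    for _, g in _cell_tracks(log):
        xy = g[["x", "y"]].to_numpy()
        actual = _path_length(xy)
        if actual <= 0 or len(xy) < 2:
            continue
        smoothed = _path_length(_moving_average(xy, smooth_window))
        ratios.append(min(1.0, smoothed / actual))
    return np.asarray(ratios)


def tip_proportion(log: TrajectoryLog, t: float) -> float | None:
    """Fraction of cells with tip phenotype (Delta >= threshold) at time t."""
    if len(log.frame) == 0:
        return None
    snap = log.at(t)
    if len(snap) == 0:
        return None
    return float(snap["tip"].mean())


# ---------------------------------------------------------------------------
# Vascular-network graph
# ---------------------------------------------------------------------------

def build_network(log: TrajectoryLog, lattice: HexLattice,
                  until: float | None = None) -> nx.Graph:
    """Graph over every voxel occupied up to time ``until`` (default: all).

    Nodes are voxels, edges connect lattice-adjacent occupied voxels with
    length ``h`` um — the manifold of matrix-free guidance tunnels that
    cells move within.
    """
    f = log.frame
    if until is not None:
        f = f[f["t"] <= until + 1e-12]
    voxels = set(int(v) for v in f["voxel"].unique())
    G = nx.Graph()
    for v in voxels:
        x, y = lattice.centers[v]
        G.add_node(v, x=float(x), y=float(y))
    for v in voxels:
        for j in lattice.neighbor_table[v]:
            if j >= 0 and int(j) in voxels:
                G.add_edge(v, int(j), length=lattice.h)
    return G


def network_distance(network: nx.Graph, i: int, j: int) -> float:
    """Shortest-path distance (um) between voxels i and j within the network."""
    if i not in network or j not in network:
        raise KeyError(f"voxel {i if i not in network else j} not in network")
    if i == j:
        return 0.0
    try:
        return float(nx.shortest_path_length(network, i, j) *
                     next(iter(network.edges(data="length")))[2])
    except nx.NetworkXNoPath:
        return math.inf
    except StopIteration:
        return math.inf


def _pairwise_network_distances(network: nx.Graph, voxels_a, voxels_b, h):
    out = {}
    for src in set(voxels_a) | set(voxels_b):
        if src in network:
            out[src] = nx.single_source_shortest_path_length(network, src)
    return out


def max_network_distance(log: TrajectoryLog, network: nx.Graph) -> float:
    """``d_max``: largest pairwise network distance between cells at the final time."""
    h = next(iter(network.edges(data="length")))[2] if network.number_of_edges() else 0.0
    final = log.at(log.frame["t"].max())
    voxels = [int(v) for v in final["voxel"]]
    best = 0.0
    for v in set(voxels):
        if v not in network:
            continue
        dist = nx.single_source_shortest_path_length(network, v)
        for u in set(voxels):
            if u in dist:
                best = max(best, dist[u] * h)
    return best


def mixing_measure(
    log: TrajectoryLog,
    network: nx.Graph,
    cluster: set[int],
    t: float,
    t_m: float,
    d_max: float | None = None,
) -> float | None:
    """Cell-mixing measure ``M(t)`` for a nearest-neighbour voxel cluster.

    Sums, over unordered pairs of cells occupying cluster voxels at time
    ``t``, the change in their pairwise network distance between ``t`` and
    ``t + t_m``, normalised by the cluster size and ``d_max``.  Returns
    None when fewer than two cluster cells exist (undefined).
    """
    snap_t = log.at(t)
    members = snap_t[snap_t["voxel"].isin(cluster)]
    if len(members) < 2:
        return None
    snap_tm = log.at(t + t_m)
    pos_t = dict(zip(snap_t["label"], snap_t["voxel"]))
    pos_tm = dict(zip(snap_tm["label"], snap_tm["voxel"]))
    if d_max is None:
        d_max = max_network_distance(log, network)
    if not d_max or not np.isfinite(d_max):
        return None
    h = next(iter(network.edges(data="length")))[2]
    total = 0.0
    for l1, l2 in itertools.combinations(sorted(members["label"]), 2):
        if l1 not in pos_tm or l2 not in pos_tm:
            continue
        d1 = nx.shortest_path_length(network, int(pos_t[l1]), int(pos_t[l2])) * h
        d2 = nx.shortest_path_length(network, int(pos_tm[l1]), int(pos_tm[l2])) * h
        total += d2 - d1
    return total / (len(cluster) * d_max)


def mixing_curve(
    log: TrajectoryLog,
    lattice: HexLattice,
    cluster: set[int],
    t_m: float,
    t_grid,
) -> pd.DataFrame:
    """``M(t)`` over a grid of reference times, on the final network.

    The network manifold and ``d_max`` are taken at the final time, so
    every distance is measured within the fully developed vasculature.
    Times where the cluster holds fewer than two cells yield NaN.
    """
    G = build_network(log, lattice)
    d_max = max_network_distance(log, G)
    rows = []
    for t in t_grid:
        if t + t_m > log.frame["t"].max() + 1e-9:
            break
        M = mixing_measure(log, G, cluster, t, t_m, d_max=d_max)
        rows.append({"t": t, "M": np.nan if M is None else M})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Directionality
# ---------------------------------------------------------------------------

def directionality(
    log: TrajectoryLog,
    lattice: HexLattice,
    base_voxels: set[int],
    window_min: float = 20.0,
    still_um: float | None = None,
    counts: bool = False,
) -> dict[str, float]:
    """Anterograde / retrograde / still proportions over fixed windows.

    Sprout elongation direction is measured along the network manifold:
    a window counts as anterograde when the cell's geodesic distance from
    the sprout base (the plexus attachment voxels) increases, retrograde
    when it decreases.  Windows with net Euclidean displacement below
    ``still_um`` (default ``h/2``; lattice quantisation makes exact zero
    brittle) are still.
    """
    k = _window_samples(log, window_min)
    still_um = lattice.h / 2.0 if still_um is None else still_um
    G = build_network(log, lattice)
    sources = [v for v in base_voxels if v in G]
    if not sources:
        raise ValueError("no base voxel ever occupied")
    dist = nx.multi_source_dijkstra_path_length(G, sources, weight=None)
    tally = {"anterograde": 0, "retrograde": 0, "still": 0}
    for _, g in _cell_tracks(log):
        xy = g[["x", "y"]].to_numpy()
        vox = g["voxel"].to_numpy()
        for a in range(0, len(xy) - k, k):
            if np.hypot(*(xy[a + k] - xy[a])) < still_um:
                tally["still"] += 1
                continue
            d0 = dist.get(int(vox[a]))
            d1 = dist.get(int(vox[a + k]))
            if d0 is None or d1 is None or d1 == d0:
                tally["still"] += 1
            elif d1 > d0:
                tally["anterograde"] += 1
            else:
                tally["retrograde"] += 1
    if counts:
        return dict(tally)
    tot = sum(tally.values())
    return {key: val / tot if tot else 0.0 for key, val in tally.items()}


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

def _extract_segments(G: nx.Graph):
    """Maximal paths whose interior nodes have degree 2 (vessel segments)."""
    terminals = {n for n in G if G.degree(n) != 2}
    segments = []
    seen = set()
    for t in terminals:
        for nbr in G[t]:
            e = frozenset((t, nbr))
            if e in seen:
                continue
            seen.add(e)
            path = [t, nbr]
            prev, cur = t, nbr
            while cur not in terminals:
                nxt = [x for x in G[cur] if x != prev]
                if not nxt:
                    break
                seen.add(frozenset((cur, nxt[0])))
                prev, cur = cur, nxt[0]
                path.append(cur)
            segments.append(path)
    # pure cycles (all nodes degree 2) have no terminal; trace them too
    for u, v in G.edges():
        e = frozenset((u, v))
        if e in seen:
            continue
        seen.add(e)
        path = [u, v]
        prev, cur = u, v
        while cur != u:
            nxt = [x for x in G[cur] if x != prev][0]
            seen.add(frozenset((cur, nxt)))
            prev, cur = cur, nxt
            path.append(cur)
        segments.append(path)
    return segments


def network_morphometrics(network: nx.Graph, h: float,
                          voxel_area: float) -> dict:
    """Branching points per 100 um^2 of network area, segment counts/lengths.

    Network area is node count times voxel area.  A degree->=3 node counts
    as a branching point only when at least three of its incident
    segments span >= 2h (filters single-voxel bumps).  Segments are
    maximal degree-2 chains between branching points and tips.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    area = network.number_of_nodes() * voxel_area
    segments = _extract_segments(network)
    seg_lengths = np.array([(len(p) - 1) * h for p in segments])
    # Junction nodes that are lattice-adjacent form one branching hub
    # (voxel resolution quantises segments at h, so a compact cluster of
    # degree->=3 voxels is a single anatomical branch point); a hub counts
    # only when at least three incident segments span >= 2h, which prunes
    # single-voxel bumps.
    junctions = [n for n in network if network.degree(n) >= 3]
    hubs = list(nx.connected_components(network.subgraph(junctions)))
    hub_of = {n: k for k, comp in enumerate(hubs) for n in comp}
    incident: dict[int, list[float]] = {}
    for path, L in zip(segments, seg_lengths):
        a, b = hub_of.get(path[0]), hub_of.get(path[-1])
        if a == b:
            continue  # internal to one hub
        for hub in (a, b):
            if hub is not None:
                incident.setdefault(hub, []).append(L)
    branching = [hub for hub, Ls in incident.items()
                 if sum(1 for L in Ls if L >= 2 * h) >= 3]
    return {
        "network_area": float(area),
        "n_branching_points": len(branching),
        "branching_per_100um2": len(branching) / (area / 100.0),
        "n_segments": len(segments),
        "segment_lengths": seg_lengths,
        "mean_segment_length": float(seg_lengths.mean()) if seg_lengths.size else 0.0,
    }


def metrics_table(log: TrajectoryLog, lattice: HexLattice,
                  base_voxels: set[int], realisation: int = 0) -> pd.DataFrame:
    """Tidy one-row-per-statistic summary used by the CLI and sweeps."""
    G = build_network(log, lattice)
    morpho = network_morphometrics(G, lattice.h, lattice.voxel_area)
    _, _, disp = displacement_histogram(log)
    orient = orientation_statistic(log)
    dirs = directionality(log, lattice, base_voxels)
    t_end = float(log.frame["t"].max())
    rows = {
        "mean_displacement_um": float(disp.mean()) if disp.size else 0.0,
        "mean_orientation": float(orient.mean()) if orient.size else np.nan,
        "anterograde": dirs["anterograde"],
        "retrograde": dirs["retrograde"],
        "still": dirs["still"],
        "tip_proportion": tip_proportion(log, t_end),
        "n_cells": float(len(log.at(t_end))),
        "network_area": morpho["network_area"],
        "branching_per_100um2": morpho["branching_per_100um2"],
        "n_segments": float(morpho["n_segments"]),
        "mean_segment_length": morpho["mean_segment_length"],
    }
    return pd.DataFrame(
        {"realisation": realisation, "metric": list(rows), "value": list(rows.values())}
    )
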