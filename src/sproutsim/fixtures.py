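"""Small-instance generators for tests and focused numerical experiments.

Each generator returns a ready-to-run :class:`~sproutsim.engine.Simulation`
(or a synthetic network/trajectory pair) representing one isolated piece
of the coupled system, with freeze flags so individual scales can be
studied on their own: a frozen-occupancy monolayer exercises pure
juxtacrine signalling, a matrix-walled linear sprout exercises pure cell
shuffling, and random lattice networks with labelled walkers exercise the
trajectory metrics.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .engine import Simulation, TrajectoryLog
from .lattice import HexLattice
from .params import LineageOverride, ParameterSet

__all__ = ["make_monolayer", "make_linear_sprout", "make_random_network"]


def make_monolayer(
    n_x: int,
    n_y: int,
    params: ParameterSet | None = None,
    seed: int = 0,
    V: float = 5.0,
    freeze_migration: bool = True,
    lineage: LineageOverride | None = None,
) -> Simulation:
    """Fully occupied monolayer with frozen occupancy, for patterning studies.

    Every voxel holds one cell whose initial protein levels fluctuate by
    the fraction ``xi`` around the activated-cell steady state; with
    migration frozen the only dynamics are the signalling reactions, so
    the lattice settles into the alternating tip/stalk pattern of lateral
    inhibition.
    """
    if n_x < 2 or n_y < 2:
        raise ValueError("monolayer needs at least a 2x2 lattice")
    lat = HexLattice(n_x, n_y)
    sim = Simulation(
        lat,
        params or ParameterSet(),
        lineages=[lineage] if lineage else None,
        V=V,
        freeze_migration=freeze_migration,
        freeze_fields=True,
    )
    rng = np.random.default_rng(seed)
    for v in range(lat.n_voxels):
        sim.place_cell(v, 0, rng=rng)
    return sim


def make_linear_sprout(
    length: int,
    width: int = 2,
    lineages: Sequence[LineageOverride] | None = None,
    mix: Sequence[float] | None = None,
    params: ParameterSet | None = None,
    seed: int = 0,
    V: float = 5.0,
    pad: int = 2,
) -> tuple[Simulation, list[int], list[int]]:
    """Matrix-walled linear sprout for proteolysis-free shuffling assays.

    A ``width x length`` strip of matrix-free voxels holds the cells.
    The surroundings carry ECM at exactly ``c_max`` — impenetrable, since
    motility is gated on the density of the voxel being entered — and
    field dynamics are frozen, so cells can only shuffle and overtake
    within the sprout.  Cell lineages are drawn independently
    with probabilities ``mix`` (default uniform).

    Returns ``(simulation, strip_voxels, leading_positions)`` where the
    leading positions are the voxels of the distal (rightmost) column.
    """
    if length < 2:
        raise ValueError("sprout length must be >= 2")
    params = params or ParameterSet()
    # the strip spans the full lattice width: its ends are lattice
    # boundaries, so the sprout cannot elongate past the distal column
    lat = HexLattice(length, width + 2 * pad)
    # fibrils initially aligned along the sprout axis (Delta_init = 1 in r)
    l0 = np.zeros((lat.n_voxels, 6))
    l0[:, 0] = 1.0
    sim = Simulation(
        lat,
        params,
        lineages=lineages,
        V=V,
        c_init=params.migration.c_max,
        l_init=l0,
        freeze_fields=True,
    )
    rows = range(pad, pad + width)
    cols = range(0, length)
    strip = [lat.index(c, r) for r in rows for c in cols]
    sim.c[strip] = 0.0
    n_lin = len(sim.lineages)
    probs = np.asarray(mix if mix is not None else np.full(n_lin, 1.0 / n_lin))
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    for v in strip:
        sim.place_cell(v, int(rng.choice(n_lin, p=probs)), rng=rng)
    leading = [lat.index(length - 1, r) for r in rows]
    return sim, strip, leading


def make_random_network(
    n_nodes: int,
    branching_prob: float = 0.3,
    seed: int = 0,
    n_walkers: int = 4,
    n_steps: int = 50,
    h: float = 10.0,
) -> tuple[nx.Graph, TrajectoryLog]:
    """Random tree-like lattice subgraph plus labelled random walks on it.

    Grows a connected subgraph of a hexagonal lattice from a central voxel
    by random frontier expansion (each accepted voxel branches with
    probability ``branching_prob``), then runs ``n_walkers`` independent
    random walks on the subgraph and packages them as a synthetic
    trajectory log for metric testing.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(2 * np.sqrt(n_nodes))) + 4
    lat = HexLattice(side, side)
    start = lat.index(side // 2, side // 2)
    nodes = {start}
    frontier = [start]
    while len(nodes) < n_nodes and frontier:
        v = frontier.pop(int(rng.integers(len(frontier))))
        nbrs = [int(j) for j in lat.neighbor_table[v] if j >= 0 and j not in nodes]
        rng.shuffle(nbrs)
        n_new = 1 + int(rng.random() < branching_prob)
        for j in nbrs[:n_new]:
            if len(nodes) >= n_nodes:
                break
            nodes.add(j)
            frontier.append(j)
        if not frontier and len(nodes) < n_nodes:
            frontier = [v for v in nodes
                        if any(int(j) >= 0 and int(j) not in nodes
                               for j in lat.neighbor_table[v])]
    G = nx.Graph()
    scale = h / lat.h
    for v in nodes:
        x, y = lat.centers[v]
        G.add_node(v, x=x * scale, y=y * scale)
    for v in nodes:
        for j in lat.neighbor_table[v]:
            if j >= 0 and int(j) in nodes:
                G.add_edge(v, int(j), length=h)

    rows = []
    pos = {w: start for w in range(n_walkers)}
    for k in range(n_steps + 1):
        t = 0.01 * k
        for w in range(n_walkers):
            if k > 0:
                options = list(G[pos[w]])
                pos[w] = int(options[rng.integers(len(options))]) if options else pos[w]
            x, y = lat.centers[pos[w]]
            rows.append((t, w, pos[w], x * scale, y * scale, 0, 0.0))
    frame = pd.DataFrame(rows, columns=["t", "label", "voxel", "x", "y",
                                        "lineage", "D"])
    frame["tip"] = False
    return G, TrajectoryLog(frame, 0.01, b_D=1.0)
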