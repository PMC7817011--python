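"""Simulation state assembly and the next-subvolume event loop driver.

:class:`Simulation` owns all lattice-indexed state (occupancy, per-cell
protein copy numbers, ECM/BM fields, orientation landscape) plus the
event schedule, and drives the compiled core in :mod:`sproutsim._core`.
Runs are resumable: :meth:`Simulation.run` advances the clock to a target
time and returns the trajectory samples collected on the way, so callers
can interleave running with field snapshots.

Two runs constructed with the same configuration and seed produce
identical event streams and logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _core
from .lattice import HexLattice, weights_csr
from .params import (
    HOURS_PER_UNIT,
    MINUTES_PER_UNIT,
    LineageOverride,
    ParameterSet,
    SubcellularParams,
)
from .subcellular import steady_states

__all__ = ["Simulation", "TrajectoryLog", "build_dependencies"]

SAMPLE_DT_DEFAULT = 0.01  # 5 simulated minutes

_QUIESCENT_CACHE: dict[SubcellularParams, tuple] = {}
_ACTIVATED_CACHE: dict[SubcellularParams, tuple] = {}


def _activated_state(p: SubcellularParams) -> tuple:
    """Isolated-cell stable state with the highest Delta (memoised)."""
    if p not in _ACTIVATED_CACHE:
        stable = [y for y, st in steady_states(p, 0.0) if st]
        _ACTIVATED_CACHE[p] = tuple(max(stable, key=lambda y: y[1]))
    return _ACTIVATED_CACHE[p]


def _quiescent_state(p: SubcellularParams) -> tuple:
    """Laterally-inhibited (stalk-branch) cell state, memoised per parameter set.

    Cells inside an established vessel receive trans-Delta from their
    neighbours, so fresh cells start on the low-Delta branch evaluated at
    the midpoint of the bistable window of external Delta (or, when the
    circuit is monostable, at zero input).  Exposed cells then escape to
    the tip state as their neighbourhood signal drops.
    """
    if p not in _QUIESCENT_CACHE:
        lo = hi = 0.0
        if p.k_t > 0:
            from .subcellular import bifurcation_scan
            scan = bifurcation_scan(p, np.linspace(0.0, 4000.0, 33))
            iv = scan.bistable_interval
            if iv is not None:
                lo, hi = iv
        ref = 0.5 * (lo + hi)
        stable = [y for y, st in steady_states(p, ref) if st]
        _QUIESCENT_CACHE[p] = tuple(min(stable, key=lambda y: y[1]))
    return _QUIESCENT_CACHE[p]


def build_dependencies(lattice: HexLattice, R_s: float, R_c: float):
    """Per-voxel dependency sets of the event engine, in CSR form.

    The set of voxel ``i`` contains every voxel whose propensities depend
    on ``i``'s state: the (inverted) signalling neighbourhood at ``R_s``,
    the (inverted) occupancy neighbourhood at ``R_c``, the six lattice
    neighbours, and ``i`` itself.  Overlap neighbourhoods are symmetric,
    so the inversion is the neighbourhood itself.
    """
    ai, aj, _ = weights_csr(lattice, R_s)
    pi, pj, _ = weights_csr(lattice, R_c)
    nb = lattice.neighbor_table
    indptr = np.zeros(lattice.n_voxels + 1, dtype=np.int64)
    idx: list[int] = []
    for v in range(lattice.n_voxels):
        dep = {v}
        dep.update(aj[ai[v]:ai[v + 1]].tolist())
        dep.update(pj[pi[v]:pi[v + 1]].tolist())
        dep.update(int(j) for j in nb[v] if j >= 0)
        idx.extend(sorted(dep))
        indptr[v + 1] = len(idx)
    return indptr, np.asarray(idx, dtype=np.int64)


def _subcellular_row(p: SubcellularParams) -> np.ndarray:
    """Pack a lineage's subcellular parameters, converted to per-unit rates."""
    r = np.empty(_core.NSP)
    r[_core.SP_BN] = p.b_N * HOURS_PER_UNIT
    r[_core.SP_BD] = p.b_D * HOURS_PER_UNIT
    r[_core.SP_BR2] = p.b_R2 * HOURS_PER_UNIT
    r[_core.SP_GAMMA] = p.gamma * HOURS_PER_UNIT
    r[_core.SP_GAMMAE] = p.gamma_e * HOURS_PER_UNIT
    r[_core.SP_KT] = p.k_t * HOURS_PER_UNIT
    r[_core.SP_KC] = p.k_c * HOURS_PER_UNIT
    r[_core.SP_KV] = p.k_v * HOURS_PER_UNIT
    r[_core.SP_ETA] = p.eta
    r[_core.SP_I0] = p.I0
    r[_core.SP_LIN] = p.lam_I_N
    r[_core.SP_NN] = p.n_N
    r[_core.SP_R2S0] = p.R2s0
    r[_core.SP_LRD] = p.lam_R2s_D
    r[_core.SP_ND] = p.n_D
    r[_core.SP_LIR2] = p.lam_I_R2
    r[_core.SP_NR2] = p.n_R2
    return r


def _global_vector(ps: ParameterSet, xi: float,
                   freeze_migration: bool, freeze_fields: bool) -> np.ndarray:
    mg, ts = ps.migration, ps.tissue
    G = np.zeros(_core.NG)
    G[_core.G_DW] = mg.D_omega * MINUTES_PER_UNIT / ps.h**2
    G[_core.G_CMAX] = mg.c_max
    G[_core.G_EF1] = mg.E_F1
    G[_core.G_EF2] = mg.E_F2
    G[_core.G_SF1] = mg.s_F1
    G[_core.G_SF2] = mg.s_F2
    G[_core.G_PMAX] = mg.p_max
    G[_core.G_SP] = mg.s_p
    G[_core.G_DP] = mg.D_p
    G[_core.G_K] = mg.K
    G[_core.G_KM] = mg.k_m
    G[_core.G_KD] = mg.k_D
    G[_core.G_AH] = mg.a_H
    G[_core.G_NH] = mg.n_H
    G[_core.G_ETAMAX] = ts.eta_max * HOURS_PER_UNIT
    G[_core.G_SC] = ts.s_c
    G[_core.G_DC] = ts.D_c
    G[_core.G_GMAX] = ts.gamma_max * HOURS_PER_UNIT
    G[_core.G_SM] = ts.s_m
    G[_core.G_DM] = ts.D_m
    G[_core.G_DL] = ts.Delta_l
    G[_core.G_ETAL] = ts.eta_l * HOURS_PER_UNIT
    G[_core.G_OMEGA] = ps.subcellular.Omega
    G[_core.G_XI] = xi
    G[_core.G_FREEZE_MIG] = 1.0 if freeze_migration else 0.0
    G[_core.G_FREEZE_FIELDS] = 1.0 if freeze_fields else 0.0
    G[_core.G_BD_THRESH] = ps.subcellular.b_D
    G[_core.G_WNB] = ts.w_reach
    return G


@dataclass
class TrajectoryLog:
    """Time-stamped per-cell samples, sufficient for every metric.

    ``frame`` has columns ``t`` (simulation units), ``label``, ``voxel``,
    ``x``/``y`` (um), ``lineage`` (variant index), ``D`` (Delta on the
    concentration scale) and ``tip`` (phenotype by the Delta threshold).
    """

    frame: pd.DataFrame
    sample_dt: float
    b_D: float
    lineage_names: tuple[str, ...] = ("WT",)

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.frame["t"].to_numpy())

    def at(self, t: float) -> pd.DataFrame:
        ts = self.times
        tnear = ts[np.argmin(np.abs(ts - t))]
        return self.frame[self.frame["t"] == tnear]

    def concat(self, other: "TrajectoryLog") -> "TrajectoryLog":
        f2 = other.frame[other.frame["t"] > self.frame["t"].max() + 1e-12]
        return TrajectoryLog(
            pd.concat([self.frame, f2], ignore_index=True),
            self.sample_dt, self.b_D, self.lineage_names,
        )


class Simulation:
    """A configured multiscale simulation on a hexagonal lattice.

    Parameters
    ----------
    lattice : HexLattice
    params : ParameterSet
        Baseline parameters (the first lineage variant).
    lineages : sequence of LineageOverride
        The cell-lineage variants present; per-cell ``lineage`` indices
        refer to this list.  Default: wild type only.
    V : float or array
        External VEGF concentration (ng/ml), uniform or per voxel.
    c_init, m_init : float or array
        Initial ECM density and BM concentration fields.
    plexus : sequence of voxel indices
        Boundary voxels refilled with a fresh cell whenever vacated
        (constant EC supply from the vascular plexus).
    freeze_migration, freeze_fields : bool
        Disable cell movement (pure signalling runs) or ECM/BM dynamics
        (proteolysis-free assays).
    """

    def __init__(
        self,
        lattice: HexLattice,
        params: ParameterSet | None = None,
        lineages: Sequence[LineageOverride] | None = None,
        V: float | np.ndarray = 5.0,
        c_init: float | np.ndarray = 0.0,
        m_init: float | np.ndarray = 0.0,
        l_init: float | np.ndarray = 0.0,
        plexus: Sequence[int] = (),
        plexus_lineage: int | Sequence[int] = 0,
        freeze_migration: bool = False,
        freeze_fields: bool = False,
        xi: float = 0.1,
        init_state: str = "quiescent",
    ) -> None:
        self.lattice = lattice
        self.params = params or ParameterSet()
        self.lineages = tuple(lineages) if lineages else (LineageOverride(),)
        if init_state not in ("quiescent", "activated"):
            raise ValueError("init_state must be 'quiescent' or 'activated'")
        self.init_state = init_state
        n = lattice.n_voxels

        self.SP = np.stack([
            _subcellular_row(self.params.for_lineage(ov)) for ov in self.lineages
        ])
        self.G = _global_vector(self.params, xi, freeze_migration, freeze_fields)

        self.a_indptr, self.a_idx, self.a_w = weights_csr(lattice, self.params.R_s)
        self.p_indptr, self.p_idx, self.p_w = weights_csr(lattice, self.params.R_c)
        self.a_wsum = np.array([
            self.a_w[self.a_indptr[i]:self.a_indptr[i + 1]].sum() for i in range(n)
        ])
        self.p_wsum = np.array([
            self.p_w[self.p_indptr[i]:self.p_indptr[i + 1]].sum() for i in range(n)
        ])
        self.d_indptr, self.d_idx = build_dependencies(
            lattice, self.params.R_s, self.params.R_c)

        self.E = np.zeros(n, dtype=np.int8)
        self.lin = np.zeros(n, dtype=np.int64)
        self.label = np.full(n, -1, dtype=np.int64)
        self.X = np.zeros((n, 5), dtype=np.int64)
        self.c = np.broadcast_to(np.asarray(c_init, float), (n,)).copy()
        self.m = np.broadcast_to(np.asarray(m_init, float), (n,)).copy()
        if np.ndim(l_init) == 0:
            self.l = np.full((n, 6), float(l_init))
        else:
            self.l = np.array(l_init, dtype=float).reshape(n, 6).copy()
        self.t_field = np.zeros(n)
        self.V = np.broadcast_to(np.asarray(V, float), (n,)).copy()

        self.Dbar_num = np.zeros(n)
        self.Nbar_num = np.zeros(n)
        self.EN_num = np.zeros(n)
        self.masses = np.full((n, 6), 1.0 / 6.0)
        self.prop = np.zeros((n, _core.N_CH))
        self.ptot = np.zeros(n)
        self.tnext = np.full(n, np.inf)

        self.is_plexus = np.zeros(n, dtype=np.int8)
        self.spawn_lin = np.zeros(n, dtype=np.int64)
        for v in plexus:
            self.is_plexus[v] = 1
        if np.ndim(plexus_lineage) == 0:
            self.spawn_lin[:] = int(plexus_lineage)
        else:
            for v, li in zip(plexus, plexus_lineage):
                self.spawn_lin[v] = int(li)

        self.init_mean = self._initial_means()
        self.clock = 0.0
        self._next_label = 0
        self._segment = 0

    # -- construction helpers ----------------------------------------------
    def _initial_means(self) -> np.ndarray:
        """Mean initial copy numbers per lineage: the quiescent cell state.

        Cells start (and enter through the plexus) on the laterally
        inhibited low-Delta branch at each lineage's VEGF level, scaled to
        copy numbers by Omega; activation to the tip state then happens
        where the neighbourhood Delta signal permits it.
        """
        state_of = (_activated_state if self.init_state == "activated"
                    else _quiescent_state)
        out = np.zeros((len(self.lineages), 5))
        W = self.params.subcellular.Omega
        for k, ov in enumerate(self.lineages):
            out[k] = W * np.asarray(state_of(self.params.for_lineage(ov)))
        return out

    def place_cell(self, voxel: int, lineage: int = 0,
                   proteins: np.ndarray | None = None,
                   rng: np.random.Generator | None = None) -> None:
        """Put a cell into an empty voxel, with initial fluctuated protein levels."""
        if self.E[voxel]:
            raise ValueError(f"voxel {voxel} already occupied")
        self.E[voxel] = 1
        self.lin[voxel] = lineage
        self.label[voxel] = self._next_label
        self._next_label += 1
        if proteins is not None:
            self.X[voxel] = np.asarray(proteins, dtype=np.int64)
        else:
            rng = rng or np.random.default_rng(0)
            xi = self.G[_core.G_XI]
            u = rng.uniform(-1.0, 1.0, size=5)
            self.X[voxel] = np.maximum(
                0, np.round(self.init_mean[lineage] * (1.0 + xi * u))
            ).astype(np.int64)

    @property
    def n_cells(self) -> int:
        return int(self.E.sum())

    @property
    def D_conc(self) -> np.ndarray:
        """Per-voxel Delta level on the concentration scale."""
        return self.X[:, 1] / self.params.subcellular.Omega

    def tip_mask(self) -> np.ndarray:
        return (self.E == 1) & (self.D_conc >= self.params.subcellular.b_D)

    # -- propensity bookkeeping (oracle hooks) ------------------------------
    def refresh_all(self) -> None:
        """From-scratch recomputation of neighbourhood sums, masses and rates."""
        _core.full_refresh(
            self.clock, self.E, self.lin, self.X, self.c, self.m, self.l,
            self.t_field, self.Dbar_num, self.Nbar_num, self.EN_num,
            self.masses, self.prop, self.ptot, self.tnext,
            self.lattice.neighbor_table, self.a_indptr, self.a_idx, self.a_w,
            self.a_wsum, self.p_indptr, self.p_idx, self.p_w, self.p_wsum,
            self.SP, self.V, self.G)

    def propensities(self) -> np.ndarray:
        return self.prop.copy()

    # -- running -------------------------------------------------------------
    def run(
        self,
        t_end: float,
        seed: int,
        sample_dt: float = SAMPLE_DT_DEFAULT,
        max_events: int = 2**62,
        record_events: int = 0,
    ) -> TrajectoryLog:
        """Advance the simulation to ``t_end`` and return the trajectory log.

        ``seed`` controls the whole event stream of this call; ``sample_dt``
        is the trajectory sampling interval (default 0.01 units = 5 min).
        With ``record_events > 0`` the per-event records (time, voxel,
        channel) are kept on ``self.last_events``.
        """
        n = self.lattice.n_voxels
        if t_end < self.clock:
            raise ValueError("t_end before current clock")
        n_samples = int(np.floor((t_end - self.clock) / sample_dt + 1e-9)) + 2
        cap = n_samples * max(1, n)
        samp_t = np.empty(cap)
        samp_vox = np.empty(cap, dtype=np.int64)
        samp_label = np.empty(cap, dtype=np.int64)
        samp_lin = np.empty(cap, dtype=np.int64)
        samp_D = np.empty(cap, dtype=np.int64)
        samp_count = np.zeros(1, dtype=np.int64)
        nev = max(record_events, 1)
        ev_t = np.empty(nev)
        ev_vox = np.empty(nev, dtype=np.int64)
        ev_ch = np.empty(nev, dtype=np.int64)
        ev_count = np.zeros(1, dtype=np.int64)
        next_label_arr = np.array([self._next_label], dtype=np.int64)

        sub_seed = int(np.random.SeedSequence([seed, self._segment]).generate_state(1)[0] % (2**31 - 1))
        self.clock = _core.run_core(
            self.clock, t_end, sub_seed,
            self.E, self.lin, self.label, self.X, self.c, self.m, self.l,
            self.t_field, self.Dbar_num, self.Nbar_num, self.EN_num,
            self.masses, self.prop, self.ptot, self.tnext,
            self.lattice.neighbor_table, self.a_indptr, self.a_idx, self.a_w,
            self.a_wsum, self.p_indptr, self.p_idx, self.p_w, self.p_wsum,
            self.d_indptr, self.d_idx, self.SP, self.V, self.G,
            self.is_plexus, self.spawn_lin, self.init_mean,
            sample_dt, samp_t, samp_vox, samp_label, samp_lin, samp_D,
            samp_count, next_label_arr, max_events,
            ev_t, ev_vox, ev_ch, ev_count)
        self._next_label = int(next_label_arr[0])
        self._segment += 1

        k = int(samp_count[0])
        W = self.params.subcellular.Omega
        centers = self.lattice.centers
        frame = pd.DataFrame({
            "t": samp_t[:k],
            "label": samp_label[:k],
            "voxel": samp_vox[:k],
            "x": centers[samp_vox[:k], 0],
            "y": centers[samp_vox[:k], 1],
            "lineage": samp_lin[:k],
            "D": samp_D[:k] / W,
        })
        frame["tip"] = frame["D"] >= self.params.subcellular.b_D
        self.last_events = pd.DataFrame({
            "t": ev_t[:int(ev_count[0])],
            "voxel": ev_vox[:int(ev_count[0])],
            "channel": ev_ch[:int(ev_count[0])],
        })
        return TrajectoryLog(
            frame, sample_dt, self.params.subcellular.b_D,
            tuple(ov.lineage + ("+DAPT" if ov.dapt else "") for ov in self.lineages),
        )

    def step(self, seed: int) -> tuple[float, int, int]:
        """Fire a single event; returns (time, voxel, channel).

        Channel indices 0-11 are the signalling reactions (order of
        :data:`sproutsim.subcellular.STOICHIOMETRY`), 12-17 the migration
        directions.  Raises StopIteration when no channel is active.
        """
        before = self.clock
        horizon = self.clock + 1.0e6
        self.run(horizon, seed=seed, sample_dt=2.0e6, max_events=1,
                 record_events=1)
        if len(self.last_events) == 0:
            self.clock = before
            raise StopIteration("all propensities zero")
        row = self.last_events.iloc[0]
        self.clock = float(row["t"])
        return self.clock, int(row["voxel"]), int(row["channel"])
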