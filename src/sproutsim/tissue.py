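"""Tissue-scale fields: ECM density, basement membrane, fibril orientation.

Three per-voxel fields shape cell migration:

* ``c`` — extracellular-matrix (collagen) density in ``[0, c_max]``,
  degraded by cell-driven proteolysis at a rate that rises sigmoidally
  with the resident cell's Delta level (tip cells are strongly
  proteolytic).  Degradation carves the matrix-free guidance tunnels that
  sprouts elongate into.
* ``m`` — basement-membrane concentration in ``[0, 1]``, deposited by
  cells at a Delta-dependent rate; accumulated BM raises the polarity
  concentration ``kappa`` and so locks cells into the sprout direction.
  BM decay is neglected on the simulated timescale.
* ``l`` — the orientation landscape: one non-negative component per
  migration direction representing aligned ECM fibrils.  Each cell move
  stretches the component of the traversed direction in both the source
  and target voxel by ``Delta_l * D_i`` (tip cells drag more fibrils),
  while all components relax exponentially at rate ``eta_l``.

Between stochastic events the Delta levels are constant, so ``c`` and
``m`` follow clamped linear-in-time solutions and ``l`` an exact
exponential decay — no ODE solver is involved.
"""

from __future__ import annotations

import math

import numpy as np

from .params import TissueParams

__all__ = [
    "proteolysis_rate",
    "bm_deposition_rate",
    "advance_fields",
    "stretch_orientation",
    "relax_orientation",
]


def proteolysis_rate(D: float, p: TissueParams) -> float:
    """ECM degradation rate ``eta_c(D)``, logistic in Delta with ceiling ``eta_max``."""
    if D < 0:
        raise ValueError("Delta level must be non-negative")
    return p.eta_max / (1.0 + math.exp(-p.s_c * (D - p.D_c)))


def bm_deposition_rate(D: float, p: TissueParams) -> float:
    """BM deposition rate ``gamma_m(D)``, logistic in Delta with ceiling ``gamma_max``."""
    if D < 0:
        raise ValueError("Delta level must be non-negative")
    return p.gamma_max / (1.0 + math.exp(-p.s_m * (D - p.D_m)))


def advance_fields(
    c: np.ndarray,
    m: np.ndarray,
    D: np.ndarray,
    occupied: np.ndarray,
    tau: float,
    p: TissueParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance ECM and BM fields over a waiting time ``tau`` (exact, clamped).

    Only occupied voxels evolve: the rates are functions of the resident
    cell's Delta level, which is constant between events, so the update is
    the exact piecewise-linear solution ``c <- max(0, c - eta_c(D) tau)``
    and ``m <- min(1, m + gamma_m(D) tau)``.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    c = np.array(c, dtype=float, copy=True)
    m = np.array(m, dtype=float, copy=True)
    occ = np.asarray(occupied, dtype=bool)
    for i in np.flatnonzero(occ):
        c[i] = max(0.0, c[i] - proteolysis_rate(D[i], p) * tau)
        m[i] = min(1.0, m[i] + bm_deposition_rate(D[i], p) * tau)
    return c, m


def stretch_orientation(
    l: np.ndarray,
    i: int,
    j: int,
    s: int,
    D_i: float,
    Delta_l: float,
) -> np.ndarray:
    """Record a move ``i -> j`` in direction ``s`` on the orientation landscape.

    Both the vacated and the entered voxel gain ``Delta_l * D_i`` in the
    traversed direction's component — the migrating cell pulls fibrils
    into alignment along its path, in proportion to its Delta level.
    """
    l = np.array(l, dtype=float, copy=True)
    l[i, s] += Delta_l * D_i
    l[j, s] += Delta_l * D_i
    return l


def relax_orientation(l: np.ndarray, tau: float, eta_l: float) -> np.ndarray:
    """Exponential relaxation ``l <- l exp(-eta_l tau)`` of every component."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return np.asarray(l, dtype=float) * math.exp(-eta_l * tau)
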