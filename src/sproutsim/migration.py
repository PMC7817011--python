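"""The persistent-random-walk migration rate and its component factors.

A cell hops from voxel ``i`` to a neighbouring voxel ``j`` (direction
``s``) at rate

``omega(i->j) = (D_omega/h^2) E_i S(c_j) F(E_i^N) rho_ij(D_i) P_i(s)``

where ``E_i`` is occupancy, ``S`` gates motility on the extracellular-
matrix density of the voxel being entered (fully saturated matrix is
impenetrable; invasion proceeds as resident cells degrade their own
voxel, opening it to followers), ``F`` is the cell-cell adhesion
(neighbourhood) function, ``rho_ij`` the overtaking probability (1 into
empty voxels, an increasing sigmoid of the mover's Delta into occupied
ones), and ``P_i(s)`` the probability that a von Mises-distributed
polarity angle falls inside the ``pi/3`` window of direction ``s``.  The
polarity mean comes from the local fibril orientation landscape; its
concentration ``kappa`` falls with Delta (tip cells explore) and rises
with deposited basement membrane.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.integrate import quad

from .lattice import DIRECTIONS, Direction, angle_interval, as_direction
from .params import MigrationParams

__all__ = [
    "ecm_speed_factor",
    "neighbourhood_function",
    "switching_probability",
    "overtaking_probability",
    "exploratoriness",
    "mean_polarisation",
    "direction_mass",
    "direction_masses",
    "migration_rate",
]


def ecm_speed_factor(c: float, c_max: float) -> float:
    """Motility factor ``S(c) = 1 - c/c_max`` for ``c < c_max``, else 0."""
    if c < 0:
        raise ValueError("ECM density must be non-negative")
    return max(0.0, 1.0 - c / c_max) if c < c_max else 0.0


def neighbourhood_function(E_N: float, p: MigrationParams) -> float:
    """Cell-cell adhesion factor ``F`` of the weighted neighbour occupancy.

    Rises once the occupancy passes the contact-loss threshold ``E_F1``
    (isolated cells halt) and falls past the crowding threshold ``E_F2``;
    the positive part keeps it non-negative.
    """
    up = 1.0 / (1.0 + math.exp(-p.s_F1 * (E_N - p.E_F1)))
    down = 1.0 / (1.0 + math.exp(p.s_F2 * (E_N - p.E_F2)))
    return max(0.0, up + down - 1.0)


def switching_probability(D: float, p: MigrationParams) -> float:
    """Overtaking (position-switch) probability, logistic in the mover's Delta."""
    return p.p_max / (1.0 + math.exp(-p.s_p * (D - p.D_p)))


def overtaking_probability(D_mover: float, target_occupied: bool, p: MigrationParams) -> float:
    """``rho_ij``: 1 into an empty voxel, ``p_switch(D_mover)`` into an occupied one.

    When an occupied-target move fires, the two cells exchange voxels (the
    overtaken cell performs the retrograde displacement).
    """
    return switching_probability(D_mover, p) if target_occupied else 1.0


def exploratoriness(D: float, m: float, p: MigrationParams) -> float:
    """Polarity concentration ``kappa = K exp(k_m m - k_D D)``.

    High Delta (tip phenotype) lowers ``kappa`` — exploratory, near-isotropic
    polarity; deposited basement membrane raises it — movement confined to
    the established sprout direction.
    """
    return p.K * math.exp(p.k_m * m - p.k_D * D)


def hill_saturation(x, a: float, n: float):
    """Plain Hill saturation ``x^n / (a^n + x^n)`` used to read the landscape."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    r = (x[nz] / a) ** n
    out[nz] = r / (1.0 + r)
    return out if out.ndim else float(out)


def mean_polarisation(l_i: np.ndarray, a_H: float, n_H: float) -> float | None:
    """Mean polarity angle from the orientation landscape of one voxel.

    Saturates each of the six direction components with a Hill function and
    takes the principal argument of their vector resultant; returns None
    when the resultant vanishes (isotropic landscape) so callers can fall
    back to an unpolarised (kappa = 0) cell.
    """
    l_i = np.asarray(l_i, dtype=float)
    if l_i.shape != (6,) or np.any(l_i < 0):
        raise ValueError("orientation landscape must be 6 non-negative components")
    w = hill_saturation(l_i, a_H, n_H)
    px = sum(w[s] * math.cos(DIRECTIONS[s].angle) for s in range(6))
    py = sum(w[s] * math.sin(DIRECTIONS[s].angle) for s in range(6))
    if math.hypot(px, py) < 1e-12:
        return None
    return math.atan2(py, px)


def _vm_unnorm(phi, mu, kappa):
    return np.exp(kappa * (np.cos(phi - mu) - 1.0))


def direction_mass(mu: float | None, kappa: float, s: Direction | int | str) -> float:
    """Probability that a von Mises polarity angle falls in direction ``s``'s window.

    Integrates the von Mises density with mean ``mu`` and concentration
    ``kappa`` over the ``pi/3`` interval of ``s``; the six masses are
    normalised by their sum (the intervals partition the circle), so they
    add to 1 exactly.  ``mu is None`` (undefined polarity) means ``kappa = 0``:
    every direction gets 1/6.
    """
    return direction_masses(mu, kappa)[as_direction(s).index]


def direction_masses(mu: float | None, kappa: float) -> np.ndarray:
    if mu is None or kappa == 0.0:
        return np.full(6, 1.0 / 6.0)
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    parts = np.empty(6)
    for s in range(6):
        lo, hi = angle_interval(s)
        val, _ = quad(_vm_unnorm, lo, hi, args=(mu, kappa), epsabs=1e-12, epsrel=1e-10)
        parts[s] = val
    return parts / parts.sum()


# Fixed Gauss-Legendre rule used by the event engine (same quantity as
# direction_masses, accurate to ~1e-10 for the kappa range encountered).
_GL_NODES, _GL_WTS = leggauss(24)


def direction_masses_gl(mu: float, kappa: float) -> np.ndarray:
    parts = np.empty(6)
    for s in range(6):
        lo, hi = angle_interval(s)
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        phi = mid + half * _GL_NODES
        parts[s] = half * np.sum(_GL_WTS * _vm_unnorm(phi, mu, kappa))
    return parts / parts.sum()


def migration_rate(
    i_occupied: bool,
    c_target: float,
    E_N: float,
    D_mover: float,
    m_mover: float,
    l_mover: np.ndarray,
    target_occupied: bool,
    s: Direction | int | str,
    p: MigrationParams,
    h: float,
) -> float:
    """Full transition rate ``omega(i->j)`` in events per minute.

    Zero for an empty source voxel; otherwise the product of the diffusive
    scale ``D_omega/h^2``, the target-voxel ECM gate, the adhesion factor,
    the overtaking probability and the windowed von Mises direction mass.
    """
    if not i_occupied:
        return 0.0
    s = as_direction(s)
    mu = mean_polarisation(l_mover, p.a_H, p.n_H)
    kappa = 0.0 if mu is None else exploratoriness(D_mover, m_mover, p)
    mass = direction_mass(mu, kappa, s)
    return (
        (p.D_omega / h**2)
        * ecm_speed_factor(c_target, p.c_max)
        * neighbourhood_function(E_N, p)
        * overtaking_probability(D_mover, target_occupied, p)
        * mass
    )
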