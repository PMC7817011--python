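"""Stochastic VEGF-Delta-Notch kinetics and its mean-field limit.

Each cell carries five molecular species: Notch receptor ``N``, Delta
ligand ``D``, Notch intracellular domain ``I`` (the cleaved active
signal), VEGFR2 ``R2`` and VEGF-bound VEGFR2 ``R2*``.  Lateral inhibition
arises because a cell's Delta trans-activates its neighbours' Notch, whose
NICD represses their VEGFR2 and hence (via reduced VEGF signalling) their
Delta.  The circuit is bistable in the external Delta input: low input
selects the exploratory high-Delta *tip* state, high input the quiescent
low-Delta *stalk* state, and intermediate inputs support both.

The stochastic representation uses integer copy numbers; the system size
``Omega`` (copies per concentration unit) controls the intrinsic noise
that drives phenotype switching.  The twelve elementary reaction channels
are defined in :data:`STOICHIOMETRY` / :func:`reaction_propensities`, and
their mean-field expectation reproduces :func:`mean_field_rhs` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, fsolve

from .params import SubcellularParams

__all__ = [
    "N_SPECIES",
    "N_REACTIONS",
    "STOICHIOMETRY",
    "shifted_hill",
    "reaction_propensities",
    "mean_field_rhs",
    "classify_phenotype",
    "external_signals",
    "steady_states",
    "bifurcation_scan",
    "BifurcationScan",
    "ssa_trajectory",
]

N_SPECIES = 5  # (N, D, I, R2, R2s)
N_REACTIONS = 12

# Stoichiometry matrix, one row per channel, columns (N, D, I, R2, R2s).
STOICHIOMETRY = np.array(
    [
        [1, 0, 0, 0, 0],    # 0  production of N, rate b_N * H+(I)
        [0, 1, 0, 0, 0],    # 1  production of D, rate b_D * H+(R2*)
        [0, 0, 0, 1, 0],    # 2  production of R2, rate b_R2 * H-(I)
        [-1, 0, 0, 0, 0],   # 3  decay of N, rate gamma
        [0, -1, 0, 0, 0],   # 4  decay of D, rate gamma
        [0, 0, 0, -1, 0],   # 5  decay of R2, rate gamma
        [0, 0, -1, 0, 0],   # 6  decay of I, rate gamma_e
        [0, 0, 0, 0, -1],   # 7  decay of R2*, rate gamma_e
        [-1, 0, 1, 0, 0],   # 8  trans-activation N + D_ext -> I, rate k_t D_ext N
        [0, -1, 0, 0, 0],   # 9  trans-consumption of D by N_ext, rate eta k_t N_ext D
        [-1, -1, 0, 0, 0],  # 10 cis-inhibition N + D -> 0, rate k_c N D
        [0, 0, 0, -1, 1],   # 11 VEGF activation R2 -> R2*, rate k_v V R2
    ],
    dtype=np.int64,
)


def shifted_hill(X: float, X0: float, lam: float, n: float) -> float:
    """Shifted Hill factor ``(1 + lam (X/X0)^n) / (1 + (X/X0)^n)``.

    Equals 1 at ``X = 0`` and tends to ``lam`` as ``X -> inf``; ``lam > 1``
    is transcriptional activation, ``lam < 1`` repression.
    """
    if X0 <= 0 or lam <= 0 or n <= 0:
        raise ValueError("X0, lam and n must be positive")
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    r = (X / X0) ** n
    out = (1.0 + lam * r) / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def reaction_propensities(
    counts: np.ndarray,
    Dext: float,
    Next: float,
    p: SubcellularParams,
) -> np.ndarray:
    """Propensities (per hour) of the 12 channels for one cell.

    ``counts`` holds the integer copy numbers (N, D, I, R2, R2s); ``Dext``
    and ``Next`` are the neighbourhood-averaged Delta and Notch on the
    concentration scale.  Production rates carry a factor ``Omega`` and
    bimolecular rate constants a factor ``1/Omega`` so the law of large
    numbers recovers the concentration-scale mean field.
    """
    N, D, I, R2, R2s = (float(x) for x in counts)
    if min(N, D, I, R2, R2s) < 0:
        raise ValueError("negative copy number")
    W = p.Omega
    a = np.empty(N_REACTIONS)
    a[0] = W * p.b_N * shifted_hill(I / W, p.I0, p.lam_I_N, p.n_N)
    a[1] = W * p.b_D * shifted_hill(R2s / W, p.R2s0, p.lam_R2s_D, p.n_D)
    a[2] = W * p.b_R2 * shifted_hill(I / W, p.I0, p.lam_I_R2, p.n_R2)
    a[3] = p.gamma * N
    a[4] = p.gamma * D
    a[5] = p.gamma * R2
    a[6] = p.gamma_e * I
    a[7] = p.gamma_e * R2s
    a[8] = p.k_t * Dext * N
    a[9] = p.eta * p.k_t * Next * D
    a[10] = (p.k_c / W) * N * D
    a[11] = p.k_v * p.V * R2
    return a


def mean_field_rhs(
    y: np.ndarray,
    Dext: float,
    Next: float,
    p: SubcellularParams,
) -> np.ndarray:
    """Deterministic right-hand side for concentrations ``y = (N, D, I, R2, R2s)``.

    For the individual-cell system ``Dext`` and ``Next`` are constant
    inputs; in the multicellular system they are the overlap-weighted
    neighbourhood averages of :func:`external_signals`.
    """
    N, D, I, R2, R2s = y
    dN = p.b_N * shifted_hill(max(I, 0.0), p.I0, p.lam_I_N, p.n_N) \
        - p.gamma * N - p.k_t * Dext * N - p.k_c * N * D
    dD = p.b_D * shifted_hill(max(R2s, 0.0), p.R2s0, p.lam_R2s_D, p.n_D) \
        - p.gamma * D - p.eta * p.k_t * Next * D - p.k_c * N * D
    dI = p.k_t * Dext * N - p.gamma_e * I
    dR2 = p.b_R2 * shifted_hill(max(I, 0.0), p.I0, p.lam_I_R2, p.n_R2) \
        - p.gamma * R2 - p.k_v * p.V * R2
    dR2s = p.k_v * p.V * R2 - p.gamma_e * R2s
    return np.array([dN, dD, dI, dR2, dR2s])


def classify_phenotype(D: float, b_D: float) -> str:
    """Tip/stalk classification by the Delta proxy: tip iff ``D >= b_D``."""
    if D < 0:
        raise ValueError("Delta level must be non-negative")
    return "tip" if D >= b_D else "stalk"


def external_signals(proteins: np.ndarray, indptr, indices, weights, wsum=None):
    """Neighbourhood-averaged Delta and Notch per voxel.

    ``proteins`` is (n_voxels, >=2) with columns (N, D, ...); the CSR triplet
    describes the self-excluded overlap neighbourhood at radius ``R_s``
    (see :func:`sproutsim.lattice.weights_csr`).  The denominator is the
    total overlap weight of the neighbourhood, so empty voxels dilute the
    signal — a cell with a single distant neighbour sees only the
    overlap-weighted fraction of that neighbour's ligand.
    """
    n = len(indptr) - 1
    Dbar = np.zeros(n)
    Nbar = np.zeros(n)
    if wsum is None:
        wsum = np.array([weights[indptr[i]:indptr[i + 1]].sum() for i in range(n)])
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        if hi == lo or wsum[i] <= 0:
            continue
        js = indices[lo:hi]
        w = weights[lo:hi]
        Nbar[i] = (w * proteins[js, 0]).sum() / wsum[i]
        Dbar[i] = (w * proteins[js, 1]).sum() / wsum[i]
    return Dbar, Nbar


# ---------------------------------------------------------------------------
# Steady states and bifurcation structure of the individual-cell system
# ---------------------------------------------------------------------------

def _reduced_fixed_point_residual(I: float, Dext: float, Next: float,
                                  p: SubcellularParams) -> float:
    """Residual of the 1-D fixed-point problem in the NICD level.

    At a fixed point the four fast variables are explicit functions of
    ``I``:  R2, R2*, then D and N, leaving one scalar consistency equation
    ``k_t Dext N(I) - gamma_e I = 0``.
    """
    R2 = p.b_R2 * shifted_hill(I, p.I0, p.lam_I_R2, p.n_R2) / (p.gamma + p.k_v * p.V)
    R2s = p.k_v * p.V * R2 / p.gamma_e
    # N and D solve a 2x2 nonlinear system through the cis term; iterate.
    prodN = p.b_N * shifted_hill(I, p.I0, p.lam_I_N, p.n_N)
    prodD = p.b_D * shifted_hill(R2s, p.R2s0, p.lam_R2s_D, p.n_D)
    N, D = prodN / p.gamma, prodD / p.gamma
    for _ in range(500):
        N_new = prodN / (p.gamma + p.k_t * Dext + p.k_c * D)
        D_new = prodD / (p.gamma + p.eta * p.k_t * Next + p.k_c * N_new)
        if abs(N_new - N) + abs(D_new - D) < 1e-12 * (1 + N + D):
            N, D = N_new, D_new
            break
        N, D = N_new, D_new
    return p.k_t * Dext * N - p.gamma_e * I


def _fixed_point_from_I(I: float, Dext: float, Next: float, p: SubcellularParams):
    R2 = p.b_R2 * shifted_hill(I, p.I0, p.lam_I_R2, p.n_R2) / (p.gamma + p.k_v * p.V)
    R2s = p.k_v * p.V * R2 / p.gamma_e
    prodN = p.b_N * shifted_hill(I, p.I0, p.lam_I_N, p.n_N)
    prodD = p.b_D * shifted_hill(R2s, p.R2s0, p.lam_R2s_D, p.n_D)
    N, D = prodN / p.gamma, prodD / p.gamma
    for _ in range(500):
        N = prodN / (p.gamma + p.k_t * Dext + p.k_c * D)
        D = prodD / (p.gamma + p.eta * p.k_t * Next + p.k_c * N)
    return np.array([N, D, I, R2, R2s])


def _jacobian(y, Dext, Next, p, eps=1e-6):
    J = np.empty((5, 5))
    f0 = mean_field_rhs(y, Dext, Next, p)
    for k in range(5):
        dy = np.array(y, dtype=float)
        step = eps * max(1.0, abs(y[k]))
        dy[k] += step
        J[:, k] = (mean_field_rhs(dy, Dext, Next, p) - f0) / step
    return J


def steady_states(p: SubcellularParams, Dext: float, Next: float = 0.0,
                  n_starts: int = 20, rng=None, tol: float = 1e-9):
    """All fixed points of the individual-cell system at a given ``Dext``.

    Roots of the reduced 1-D problem in ``I`` are bracketed on a log-spaced
    grid and polished with a full 5-D Newton solve; stability comes from
    the eigenvalues of a finite-difference Jacobian.  Returns a list of
    ``(y, stable)`` pairs sorted by the Notch coordinate.
    """
    if p.k_t * Dext == 0.0:
        roots = [0.0]
    else:
        grid = np.concatenate([[0.0], np.logspace(-3, 6, 200)])
        vals = [_reduced_fixed_point_residual(I, Dext, Next, p) for I in grid]
        roots = []
        for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
            if fa == 0.0:
                roots.append(a)
            elif fa * fb < 0:
                roots.append(brentq(_reduced_fixed_point_residual, a, b,
                                    args=(Dext, Next, p), xtol=1e-12, rtol=1e-14))
    out = []
    for I in roots:
        y0 = _fixed_point_from_I(I, Dext, Next, p)
        y, info, ier, _ = fsolve(mean_field_rhs, y0, args=(Dext, Next, p),
                                 full_output=True, xtol=1e-13)
        if ier != 1 or np.any(y < -1e-6):
            continue
        y = np.clip(y, 0.0, None)
        if np.max(np.abs(mean_field_rhs(y, Dext, Next, p))) > tol:
            continue
        if any(np.max(np.abs(y - z)) < 1e-6 * (1 + np.max(np.abs(z))) for z, _ in out):
            continue
        lam = np.linalg.eigvals(_jacobian(y, Dext, Next, p))
        out.append((y, bool(np.max(lam.real) < 0)))
    if not out:
        raise RuntimeError(f"no fixed point found at Dext={Dext}")
    out.sort(key=lambda t: t[0][0])
    return out


@dataclass
class BifurcationScan:
    """Result of a steady-state scan over external Delta."""

    Dext: np.ndarray
    branches: list          # per grid point: list of (y, stable)
    bistable_mask: np.ndarray

    @property
    def bistable_interval(self) -> tuple[float, float] | None:
        idx = np.flatnonzero(self.bistable_mask)
        if idx.size == 0:
            return None
        return (float(self.Dext[idx[0]]), float(self.Dext[idx[-1]]))

    @property
    def bistable_width(self) -> float:
        iv = self.bistable_interval
        return 0.0 if iv is None else iv[1] - iv[0]


def bifurcation_scan(p: SubcellularParams, Dext_grid, Next: float = 0.0) -> BifurcationScan:
    """Scan the stable steady-state structure of the circuit over ``Dext``.

    For each grid value, all fixed points are located and classified;
    points supporting two stable states (coexisting tip and stalk) form
    the bistable interval.
    """
    Dext_grid = np.asarray(Dext_grid, dtype=float)
    branches = []
    mask = np.zeros(Dext_grid.size, dtype=bool)
    for k, Dx in enumerate(Dext_grid):
        fps = steady_states(p, Dx, Next)
        branches.append(fps)
        mask[k] = sum(1 for _, st in fps if st) >= 2
    return BifurcationScan(Dext_grid, branches, mask)


# ---------------------------------------------------------------------------
# Reference SSA for a single cell with frozen external inputs
# ---------------------------------------------------------------------------

def ssa_trajectory(p: SubcellularParams, Dext: float, Next: float,
                   t_end: float, x0=None, rng=None, max_events: int = 5_000_000):
    """Direct-method Gillespie simulation of one cell (time in hours).

    Used as the independent oracle for the compartment engine; returns
    (times, states) with the state after each event.
    """
    rng = np.random.default_rng(rng)
    x = np.zeros(N_SPECIES, dtype=np.int64) if x0 is None else np.array(x0, np.int64)
    t = 0.0
    times = [0.0]
    states = [x.copy()]
    for _ in range(max_events):
        a = reaction_propensities(x, Dext, Next, p)
        a0 = a.sum()
        if a0 <= 0:
            break
        t += rng.exponential(1.0 / a0)
        if t >= t_end:
            break
        j = np.searchsorted(np.cumsum(a), rng.uniform(0, a0), side="right")
        x += STOICHIOMETRY[j]
        times.append(t)
        states.append(x.copy())
    return np.asarray(times), np.asarray(states)
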