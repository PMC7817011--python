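"""Canned simulation setups and the quantitative assays built on them.

Four study configurations are provided:

* ``setup1_plexus`` — sprouting from a vascular plexus (a supplied bottom
  row of cells plus short seed sprouts) into uniform VEGF; the workhorse
  for calibration metrics, network morphometrics and cell mixing.
* ``setup2_gradient`` — an initial vessel in a linear VEGF ramp; produces
  the brush-border effect (denser branching toward high VEGF).
* ``setup3_bead`` — a central cell bead embedded in matrix of varying
  density under a VEGF gradient; reproduces the collagen-density
  "sweet spot" of sprouting morphology.
* ``setup4_sprout`` — a matrix-walled linear sprout of two mixed cell
  lineages shuffling without proteolysis; the leading-position
  competition assay.

Lineage overrides (VEGFR2+/-, VEGFR1+/-, DAPT) are defined in
:mod:`sproutsim.params`; the competition and one-at-a-time sensitivity
protocols live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .engine import Simulation, TrajectoryLog
from .fixtures import make_linear_sprout
from .lattice import HexLattice
from .metrics import metrics_table
from .params import (
    LineageOverride,
    MigrationParams,
    ParameterSet,
    SubcellularParams,
    TissueParams,
)

__all__ = [
    "SetupSpec",
    "SETUP_NAMES",
    "make_setup",
    "build_simulation",
    "run_setup",
    "competition_experiment",
    "sensitivity_sweep",
]

SETUP_NAMES = ("setup1_plexus", "setup2_gradient", "setup3_bead", "setup4_sprout")




@dataclass
class SetupSpec:
    """Declarative description of one simulation experiment."""

    name: str
    n_x: int
    n_y: int
    plexus: list[int]
    initial_cells: list[int]
    c_init: np.ndarray
    m_init: np.ndarray
    V: np.ndarray
    T_max: float
    lineages: list[LineageOverride]
    lineage_mix: list[float]
    freeze_fields: bool = False
    init_state: str = "quiescent"
    l_init: np.ndarray | float = 0.0
    params: ParameterSet = field(default_factory=ParameterSet)
    leading_positions: list[int] = field(default_factory=list)
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.initial_cells) != len(set(self.initial_cells)):
            raise ValueError("initial cells must occupy distinct voxels")
        if np.any(self.V < 0):
            raise ValueError("VEGF field must be non-negative")


def _vegf_column(sub: SubcellularParams, V_ref: float) -> SubcellularParams:
    # the lineage steady states used for initial conditions refer to V_ref
    return replace(sub, V=V_ref)


def make_setup(
    name: str,
    vegf: float = 5.0,
    c_max: float | None = None,
    n_x: int | None = None,
    n_y: int | None = None,
    T_max: float | None = None,
    lineages: Sequence[LineageOverride] | None = None,
    params: ParameterSet | None = None,
    sprout_length: int = 12,
) -> SetupSpec:
    """Build one of the four canned study configurations.

    ``vegf`` is the uniform concentration (setup 1/4) or the ramp maximum
    (setups 2/3 ramp linearly from 0 at y = 0).  ``c_max`` overrides the
    matrix density ceiling (and initial density) for setup 3.  Lattice
    dimensions and final times default to reduced study sizes suited to a
    single workstation run; the structure (plexus row, seed sprouts, bead
    geometry, sprout strip) follows the corresponding experiment.
    """
    if name not in SETUP_NAMES:
        raise ValueError(f"unknown setup {name!r}; choose from {SETUP_NAMES}")
    params = params or ParameterSet()
    if c_max is not None:
        params = replace(params, migration=replace(params.migration, c_max=c_max))
    cm = params.migration.c_max
    lineages = list(lineages) if lineages else [LineageOverride()]

    if name == "setup4_sprout":
        # geometry handled by the linear-sprout fixture at build time
        nx_, ny_ = sprout_length + 4, 2 + 4
        lat = HexLattice(nx_, ny_)
        params = replace(params, subcellular=_vegf_column(params.subcellular, vegf))
        spec = SetupSpec(
            name=name, n_x=nx_, n_y=ny_, plexus=[], initial_cells=[],
            c_init=np.full(lat.n_voxels, cm), m_init=np.zeros(lat.n_voxels),
            V=np.full(lat.n_voxels, vegf),
            T_max=T_max if T_max is not None else 50.0,
            lineages=lineages if len(lineages) == 2 else
            [LineageOverride(), LineageOverride()],
            lineage_mix=[0.5, 0.5], freeze_fields=True, params=params,
            options={"sprout_length": sprout_length},
        )
        return spec

    if name == "setup3_bead":
        nx_ = n_x or 21
        ny_ = n_y or 15
        lat = HexLattice(nx_, ny_)
        centre = lat.index(nx_ // 2, ny_ // 2)
        bead = {centre}
        for j in lat.neighbor_table[centre]:
            if j >= 0:
                bead.add(int(j))
        for v in list(bead):
            for j in lat.neighbor_table[v]:
                if j >= 0:
                    bead.add(int(j))
        c_init = np.full(lat.n_voxels, cm)
        m_init = np.zeros(lat.n_voxels)
        c_init[list(bead)] = 0.0
        m_init[list(bead)] = 1.0   # basement-membrane shell around the bead
        y = lat.centers[:, 1]
        V_field = vegf * np.clip(y / 125.0, 0.0, 1.0)
        # initial activation refers to the VEGF the bead actually sees
        V_bead = float(V_field[sorted(bead)].mean())
        params = replace(params, subcellular=_vegf_column(params.subcellular, V_bead))
        # bead explants are VEGF-stimulated before embedding: cells start
        # on the activated (tip) branch and pattern in place
        return SetupSpec(
            name=name, n_x=nx_, n_y=ny_, plexus=[],
            initial_cells=sorted(bead), c_init=c_init, m_init=m_init,
            V=V_field, T_max=T_max if T_max is not None else 1.0,
            lineages=lineages, lineage_mix=[1.0], params=params,
            init_state="activated",
        )

    # setups 1 and 2: plexus row at the bottom plus short seed sprouts
    nx_ = n_x or 25
    ny_ = n_y or 25
    lat = HexLattice(nx_, ny_)
    plexus = [lat.index(c, 0) for c in range(nx_)]
    cells = list(plexus)
    stubs: list[int] = []
    for c in range(nx_ // 6, nx_, max(1, nx_ // 3)):
        for r in (1, 2, 3):
            stubs.append(lat.index(c, r))
    cells += stubs
    c_init = np.full(lat.n_voxels, cm)
    c_init[cells] = 0.0
    m_init = np.zeros(lat.n_voxels)
    if name == "setup2_gradient":
        y = lat.centers[:, 1]
        V_field = vegf * y / y.max()
        V_ref = vegf
    else:
        V_field = np.full(lat.n_voxels, vegf)
        V_ref = vegf
    params = replace(params, subcellular=_vegf_column(params.subcellular, V_ref))
    # virgin matrix carries no fibril alignment: polarity self-organises
    # through the stretching feedback as cells move
    return SetupSpec(
        name=name, n_x=nx_, n_y=ny_, plexus=plexus, initial_cells=cells,
        c_init=c_init, m_init=m_init, V=V_field, l_init=0.0,
        T_max=T_max if T_max is not None else 2.5,
        lineages=lineages, lineage_mix=[1.0] * len(lineages),
        params=params, options={"stubs": stubs},
    )


def build_simulation(spec: SetupSpec, seed: int) -> Simulation:
    """Instantiate the simulation state for a setup (cells placed, fields set)."""
    rng = np.random.default_rng(seed)
    if spec.name == "setup4_sprout":
        sim, strip, leading = make_linear_sprout(
            spec.options["sprout_length"], width=2, lineages=spec.lineages,
            params=spec.params, seed=seed, V=float(spec.V[0]),
        )
        spec.leading_positions = leading
        spec.initial_cells = strip
        return sim
    lat = HexLattice(spec.n_x, spec.n_y)
    sim = Simulation(
        lat, spec.params, lineages=spec.lineages, V=spec.V,
        c_init=spec.c_init, m_init=spec.m_init, l_init=spec.l_init,
        plexus=spec.plexus, freeze_fields=spec.freeze_fields,
        init_state=spec.init_state,
    )
    probs = np.asarray(spec.lineage_mix, dtype=float)
    probs = probs / probs.sum()
    for v in spec.initial_cells:
        sim.place_cell(v, int(rng.choice(len(probs), p=probs)), rng=rng)
    return sim


def run_setup(spec: SetupSpec, seed: int, sample_dt: float = 0.01,
              T_max: float | None = None) -> tuple[Simulation, TrajectoryLog]:
    sim = build_simulation(spec, seed)
    log = sim.run(T_max if T_max is not None else spec.T_max,
                  seed=seed + 7919, sample_dt=sample_dt)
    return sim, log


# ---------------------------------------------------------------------------
# Leading-position competition (linear-sprout assay)
# ---------------------------------------------------------------------------

def competition_experiment(
    pair: Sequence[LineageOverride],
    n_realisations: int = 20,
    seed: int = 0,
    T_max: float = 10.0,
    burn_in: float = 2.0,
    sprout_length: int = 12,
    params: ParameterSet | None = None,
    vegf: float = 5.0,
    sample_dt: float = 0.02,
) -> pd.DataFrame:
    """Occupancy of the two leading sprout positions by each lineage.

    For every realisation a width-2 matrix-walled sprout is initialised
    with the two lineages mixed 1:1 and left to shuffle; the fraction of
    simulated time (after ``burn_in``, which lets the tip/stalk pattern
    establish) that each lineage occupies each distal voxel is recorded.
    Returns a tidy frame with one row per (realisation, position).
    """
    if len(pair) != 2:
        raise ValueError("competition needs exactly two lineages")
    rows = []
    for r in range(n_realisations):
        spec = make_setup("setup4_sprout", vegf=vegf, T_max=T_max,
                          lineages=list(pair), params=params,
                          sprout_length=sprout_length)
        sim, log = run_setup(spec, seed=seed * 100003 + r, sample_dt=sample_dt)
        f = log.frame
        f = f[f["t"] >= burn_in]
        for k, pos in enumerate(spec.leading_positions):
            at_pos = f[f["voxel"] == pos]
            occ0 = float((at_pos["lineage"] == 0).mean()) if len(at_pos) else np.nan
            rows.append({"realisation": r, "position": k + 1,
                         "occupancy_lineage1": occ0,
                         "occupancy_lineage2": 1.0 - occ0})
    return pd.DataFrame(rows)


def summarise_competition(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +- standard deviation of lineage-1 occupancy per leading position."""
    out = (table.groupby("position")["occupancy_lineage1"]
           .agg(["mean", "std"]).reset_index())
    out["mean_pct"] = 100.0 * out["mean"]
    out["std_pct"] = 100.0 * out["std"]
    return out


# ---------------------------------------------------------------------------
# One-at-a-time sensitivity sweep
# ---------------------------------------------------------------------------

_SWEEPABLE = {
    "D_omega": ("migration", "D_omega"), "c_max": ("migration", "c_max"),
    "E_F1": ("migration", "E_F1"), "E_F2": ("migration", "E_F2"),
    "s_F1": ("migration", "s_F1"), "s_F2": ("migration", "s_F2"),
    "p_max": ("migration", "p_max"), "s_p": ("migration", "s_p"),
    "D_p": ("migration", "D_p"), "K": ("migration", "K"),
    "k_m": ("migration", "k_m"), "k_D": ("migration", "k_D"),
    "eta_max": ("tissue", "eta_max"), "s_c": ("tissue", "s_c"),
    "D_c": ("tissue", "D_c"), "gamma_max": ("tissue", "gamma_max"),
    "s_m": ("tissue", "s_m"), "D_m": ("tissue", "D_m"),
    "Delta_l": ("tissue", "Delta_l"), "eta_l": ("tissue", "eta_l"),
}

DEFAULT_DELTAS = (-0.20, -0.15, -0.10, -0.05, -0.01, -0.001,
                  0.001, 0.01, 0.05, 0.10, 0.15, 0.20)


def _perturb(params: ParameterSet, name: str, frac: float) -> ParameterSet:
    if name not in _SWEEPABLE:
        raise ValueError(f"unknown cellular/tissue parameter {name!r}")
    group, attr = _SWEEPABLE[name]
    sub = getattr(params, group)
    sub2 = replace(sub, **{attr: getattr(sub, attr) * (1.0 + frac)})
    return replace(params, **{group: sub2})


def sensitivity_sweep(
    param_name: str,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    n_realisations: int = 5,
    seed: int = 0,
    vegf: float = 5.0,
    n_x: int = 25,
    n_y: int = 25,
    T_max: float = 2.5,
    base_params: ParameterSet | None = None,
) -> pd.DataFrame:
    """One-at-a-time perturbation of a cellular/tissue parameter.

    Runs the plexus setup for each perturbed value and tabulates the six
    summary metrics (anterograde proportion, orientation, displacement,
    branching points per area, segment count, segment length) plus cell
    number and network area, one row per (delta, realisation, metric).
    """
    base_params = base_params or ParameterSet()
    frames = []
    for frac in deltas:
        params = _perturb(base_params, param_name, frac)
        for r in range(n_realisations):
            spec = make_setup("setup1_plexus", vegf=vegf, n_x=n_x, n_y=n_y,
                              T_max=T_max, params=params)
            sim, log = run_setup(spec, seed=seed * 7919 + r)
            tab = metrics_table(log, sim.lattice, set(spec.plexus), realisation=r)
            tab["param"] = param_name
            tab["delta"] = frac
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)
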