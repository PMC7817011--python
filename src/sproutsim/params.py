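"""Model parameters.

Conventions
-----------
* One simulation time unit corresponds to 500 minutes of real time (the
  calibration anchor: a final time of 2.5 units is 1250 min).  Kinetic rate
  constants are stored **per hour** for readability; the engine converts
  them with :data:`HOURS_PER_UNIT` when assembling propensities.
* Subcellular copy numbers are related to the concentration scale (the
  scale on which thresholds such as ``D_p = 1500`` are expressed) by the
  system size ``Omega`` (copies per concentration unit).  ``Omega`` sets
  the intrinsic noise level: smaller values mean fewer molecules and more
  frequent stochastic phenotype switching.
* Lengths are in um; the voxel width ``h`` defaults to 10 um, roughly one
  endothelial nucleus diameter.

The shape parameters of the migration factors (``K``, ``k_m``, ``k_D``,
``E_F1``, ``E_F2``, ``s_F1``, ``s_F2``, ``p_max``, ``s_p``, ``D_p``) and the
interaction radius ``R_c = 1.5 h`` are fixed published values; the
remaining rate constants are this package's own calibration, chosen so the
signalling system is bistable in the external Delta input, monolayers
pattern into alternating tip/stalk states, and mutant competition assays
reproduce the known ordering (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Any

import yaml

__all__ = [
    "HOURS_PER_UNIT",
    "MINUTES_PER_UNIT",
    "LINEAGES",
    "SubcellularParams",
    "MigrationParams",
    "TissueParams",
    "LineageOverride",
    "ParameterSet",
    "lineage_params",
]

MINUTES_PER_UNIT = 500.0
HOURS_PER_UNIT = MINUTES_PER_UNIT / 60.0

LINEAGES = ("WT", "VEGFR2het", "VEGFR1het")


@dataclass(frozen=True)
class SubcellularParams:
    """Rate constants of the VEGF-Delta-Notch circuit (per hour, concentration scale).

    The circuit: external Delta trans-activates Notch releasing NICD (``k_t``);
    NICD up-regulates Notch production (fold ``lam_I_N``) and represses VEGFR2
    production (fold ``lam_I_R2 < 1``); VEGF-activated VEGFR2 up-regulates
    Delta production (fold ``lam_R2s_D``); Delta and Notch of the same cell
    annihilate by cis-inhibition (``k_c``).
    """

    b_N: float = 875.0        # baseline Notch production
    b_D: float = 1000.0       # baseline Delta production; also the tip/stalk threshold
    b_R2: float = 2500.0      # baseline VEGFR2 production
    gamma: float = 0.25       # dilution/degradation of N, D, R2
    gamma_e: float = 1.25     # degradation of NICD and activated VEGFR2
    k_t: float = 3.75e-4      # trans-binding rate (per conc per hour)
    k_c: float = 1.25e-3      # cis-inhibition rate (per conc per hour)
    k_v: float = 0.01         # VEGF binding rate (per (ng/ml) per hour)
    eta: float = 0.5          # fraction of trans-bound Delta consumed
    V: float = 5.0            # external VEGF concentration (ng/ml)
    # Shifted-Hill parameters: H(X) = (1 + lam (X/X0)^n) / (1 + (X/X0)^n)
    I0: float = 250.0
    lam_I_N: float = 4.0      # NICD -> Notch production (activation)
    n_N: float = 2.0
    R2s0: float = 250.0
    lam_R2s_D: float = 3.5    # VEGFR2* -> Delta production (activation)
    n_D: float = 2.0
    lam_I_R2: float = 0.05    # NICD -> VEGFR2 production (repression)
    n_R2: float = 4.0
    Omega: float = 0.05       # copies per concentration unit (noise knob)


@dataclass(frozen=True)
class MigrationParams:
    """Shape of the persistent-random-walk transition rate."""

    D_omega: float = 50.0     # macroscale EC diffusion coefficient (um^2/min)
    c_max: float = 1.0        # ECM density at which motility vanishes
    E_F1: float = 0.15        # neighbourhood function: contact-loss threshold
    E_F2: float = 0.6         # neighbourhood function: crowding threshold
    s_F1: float = 30.0
    s_F2: float = 10.0
    p_max: float = 0.26       # overtaking probability ceiling
    s_p: float = 0.0015
    D_p: float = 1500.0       # Delta level at half-maximal overtaking
    K: float = 13.6           # exploratoriness scale
    k_m: float = 2.2          # BM sensitivity of kappa
    k_D: float = 2.0e-4       # Delta sensitivity of kappa
    a_H: float = 1.0          # Hill saturation of orientation-landscape readout
    n_H: float = 2.0
    R_c_factor: float = 1.5   # cellular interaction radius, in units of h
    R_s_factor: float = 1.5   # subcellular interaction radius, in units of h


@dataclass(frozen=True)
class TissueParams:
    """ECM proteolysis, BM deposition and orientation-landscape dynamics (per hour)."""

    eta_max: float = 4.0      # max ECM degradation rate
    s_c: float = 0.002
    D_c: float = 6000.0       # Delta threshold for proteolysis initiation
    gamma_max: float = 0.8    # max BM deposition rate
    s_m: float = 0.002
    D_m: float = 6000.0       # Delta threshold for BM assembly
    w_reach: float = 0.3      # proteolysis weight on adjacent voxels (filopodia)
    Delta_l: float = 0.001    # orientation stretch increment per move (per conc unit)
    eta_l: float = 0.6        # orientation landscape relaxation rate


@dataclass(frozen=True)
class LineageOverride:
    """Cell-lineage parameter override (mutants, gamma-secretase inhibition).

    ``VEGFR2het`` halves the VEGFR2 production rate.  ``VEGFR1het`` models the
    halved decoy receptor as increased VEGF availability to VEGFR2 (a
    multiplier on the ``k_v V`` channel).  ``dapt`` abolishes Notch signalling
    by zeroing the trans-activation channel.
    """

    lineage: str = "WT"
    dapt: bool = False
    r1_vegf_multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}; choose from {LINEAGES}")


def lineage_params(base: SubcellularParams, override: LineageOverride) -> SubcellularParams:
    """Apply a lineage/DAPT override to a baseline subcellular parameter set."""
    p = base
    if override.lineage == "VEGFR2het":
        p = replace(p, b_R2=0.5 * p.b_R2)
    elif override.lineage == "VEGFR1het":
        p = replace(p, k_v=override.r1_vegf_multiplier * p.k_v)
    if override.dapt:
        p = replace(p, k_t=0.0)
    return p


@dataclass(frozen=True)
class ParameterSet:
    """Complete parameterisation of a simulation."""

    subcellular: SubcellularParams = field(default_factory=SubcellularParams)
    migration: MigrationParams = field(default_factory=MigrationParams)
    tissue: TissueParams = field(default_factory=TissueParams)
    h: float = 10.0           # voxel width (um)

    @property
    def R_s(self) -> float:
        return self.migration.R_s_factor * self.h

    @property
    def R_c(self) -> float:
        return self.migration.R_c_factor * self.h

    def for_lineage(self, override: LineageOverride) -> SubcellularParams:
        return lineage_params(self.subcellular, override)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ParameterSet":
        return cls(
            subcellular=SubcellularParams(**d.get("subcellular", {})),
            migration=MigrationParams(**d.get("migration", {})),
            tissue=TissueParams(**d.get("tissue", {})),
            h=d.get("h", 10.0),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
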