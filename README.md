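# sproutsim

A hybrid stochastic multiscale simulator of early sprouting
angiogenesis — the process by which endothelial cells (ECs) leave an
existing vessel, invade the extracellular matrix (ECM) and build a
branched vascular network.  It is aimed at quantitative/systems
biologists who want a mechanistic, reproducible sandbox for questions
about tip/stalk selection, cell rearrangement ("mixing"), mutant
competition and network morphology.

## The model

Three coupled scales on a hexagonal lattice (voxel width `h = 10 um`,
at most one cell nucleus per voxel):

* **Subcellular** — stochastic VEGF–Delta–Notch kinetics per cell
  (copy numbers of Notch `N`, Delta `D`, NICD `I`, VEGFR2 `R2`,
  activated VEGFR2 `R2*`; twelve elementary reactions with shifted-Hill
  transcriptional regulation).  The circuit is bistable in the
  neighbourhood Delta signal: low input selects the exploratory,
  proteolytic **tip** phenotype (high `D`), high input the quiescent
  **stalk** phenotype.  Cells classify as tip when `D >= b_D`.
* **Cellular** — an on-lattice persistent random walk with rate

  `omega(i -> j) = (D_omega / h^2) * E_i * S(c_j) * F(E_i^N) * rho_ij(D_i) * P_i(s)`

  combining occupancy, the ECM gate `S(c) = (1 - c/c_max)^+` of the
  voxel entered, the cell–cell adhesion function `F` (isolated and
  over-crowded cells halt), the Delta-dependent overtaking probability
  `rho` (moves into occupied voxels exchange the two cells), and the
  probability `P_i(s)` that a von Mises-distributed polarity angle —
  mean set by the local ECM fibril alignment, concentration
  `kappa = K exp(k_m m - k_D D)` — falls in the direction's `pi/3`
  window.
* **Tissue** — ECM density `c` degraded by Delta-dependent proteolysis,
  basement membrane `m` deposited by active cells (raising `kappa`),
  and a per-direction fibril orientation landscape stretched by every
  move and relaxing exponentially.

Events are executed with a next-subvolume stochastic simulation
algorithm (per-voxel propensities and exponential clocks); the
deterministic fields are integrated exactly between events.  Branching,
chemotactic sensitivity to VEGF and tip-cell overtaking are emergent,
not hard-wired.  See `docs/methods.md` for the full formulation,
parameter provenance and numerical choices.

## A worked example

`examples/competition_assay.py` runs the leading-position competition:
two cell lineages mixed 1:1 shuffle inside a matrix-walled sprout of
2 x 12 voxels, and the fraction of time each lineage occupies the two
distal voxels is recorded:

```
$ python examples/competition_assay.py
WT vs VEGFR2+/- (6 realisations, reduced run):
 position  mean_pct  std_pct
        1      93.6      2.2
        2      95.7      2.4

mean_pct is the WT share of time at each leading position; the
VEGFR2+/- mutant, with halved receptor production, rarely acquires the
tip phenotype and is excluded from the front.
```

Wild-type cells hold the leading positions ~93% of the time against the
VEGFR2⁺ᐟ⁻ mutant: the mutant's weakened VEGF signalling loses the
lateral-inhibition contest, its Delta stays low, and low-Delta cells
rarely overtake.  Against VEGFR1⁺ᐟ⁻ (more free VEGF, higher Delta) the
wild type is itself excluded (~20%).  The other scripts in `examples/`
demonstrate the bistability scan, monolayer patterning, plexus
sprouting with an ASCII network picture, and bead invasion versus
collagen density.

A thin CLI wraps the same functionality:

```bash
sproutsim run --setup setup1_plexus --vegf 5 --tmax 2.5 --seed 1 --out out/
sproutsim experiment --name competition --lineages WT:VEGFR2het --replicates 10 --out comp.csv
sproutsim scan --vegf 5 --out scan.csv
sproutsim metrics --log out/trajectory.csv --nx 25 --ny 25 --out metrics.csv
```

## Layout

```
src/sproutsim/
  lattice.py      hexagonal geometry, overlap weights
  params.py       parameter tables, lineage/DAPT overrides
  subcellular.py  reaction propensities, mean field, bifurcation scan
  migration.py    migration-rate factors, von Mises polarity
  tissue.py       ECM/BM fields, orientation landscape
  engine.py       simulation state and event loop (numba core in _core.py)
  metrics.py      displacement, orientation, directionality, mixing, morphometrics
  experiments.py  canned setups, competition assay, sensitivity sweep
  fixtures.py     toy-scenario generators
  cli.py          command-line interface
```
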