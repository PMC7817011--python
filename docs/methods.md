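# Methods

## Model overview

`sproutsim` simulates early sprouting angiogenesis as a hybrid stochastic
multiscale system on a two-dimensional hexagonal lattice of voxels of
width `h = 10 um` (roughly one endothelial nucleus diameter; the hexagon
edge is `a = h/sqrt(3)`). Three scales are coupled:

* **Subcellular.** Each cell carries integer copy numbers of Notch (`N`),
  Delta (`D`), NICD (`I`), VEGFR2 (`R2`) and VEGF-bound VEGFR2 (`R2*`),
  evolving through twelve elementary reactions: Hill-regulated production
  of `N`, `D`, `R2`; linear decay of all five species; trans-activation
  of Notch by neighbourhood Delta (producing NICD); trans-consumption of
  Delta by neighbourhood Notch; cis-inhibition (`N + D -> 0`); and VEGF
  activation of VEGFR2.  Production rates are transcriptionally shifted
  Hill factors `H(X) = (1 + lam (X/X0)^n)/(1 + (X/X0)^n)`: NICD
  up-regulates Notch and represses VEGFR2; activated VEGFR2 up-regulates
  Delta.  Cells with Delta at or above the baseline production rate `b_D`
  are classified *tip*, otherwise *stalk*.
* **Cellular.** Cells perform an on-lattice persistent random walk with
  transition rate
  `omega(i->j) = (D_omega/h^2) E_i S(c_j) F(E_i^N) rho_ij(D_i) P_i(s)`:
  occupancy gate, ECM gate of the entered voxel, cell-cell adhesion
  factor, overtaking probability, and the windowed von Mises polarity
  mass.  Moves into occupied voxels exchange the two cells (overtaking).
* **Tissue.** Per-voxel ECM density `c` (degraded by resident and
  adjacent cells at a Delta-dependent sigmoidal rate), basement-membrane
  concentration `m` (deposited by resident cells, raising the polarity
  concentration `kappa`), and a six-component fibril orientation
  landscape `l` stretched along each executed move by `Delta_l * D_i` and
  relaxing exponentially at rate `eta_l`.

Interactions are non-local: a cell signals to (and senses occupancy of)
every voxel whose hexagon overlaps a disc of radius `R_s` (`R_c`) centred
on its voxel, weighted by the overlapped area fraction.  The
neighbourhood Delta/Notch averages divide by the total neighbourhood
weight, so empty surroundings dilute the signal.

One simulation time unit corresponds to 500 minutes (a final time of 2.5
units is 1250 min).  Copy numbers relate to the concentration scale of
the published thresholds (e.g. `D_p = 1500`) through the system size
`Omega` (copies per concentration unit); bimolecular propensities scale
as `1/Omega`, productions as `Omega`, so the mean field is
`Omega`-independent while intrinsic noise grows as `Omega` shrinks.

## Event engine

The coupled jump process is executed with a next-subvolume scheme: every
voxel carries 18 channels (12 reactions + 6 migration directions), a
total propensity and an exponential next-event time; the earliest voxel
fires, one channel is selected proportionally to propensity, and the
dependency set of the event (the overlap neighbourhoods of the changed
voxels, which contain the lattice neighbours) is refreshed with redrawn
clocks — statistically exact by memorylessness.  The deterministic
fields are advanced lazily: each voxel stores the time it was last
materialised, and the exact clamped-linear (for `c`, `m`) or exponential
(for `l`) solution is applied on read.  Because every voxel in a
proteolytic footprint is materialised *before* any contributing Delta
level changes, the piecewise-constant integration is exact.  Two
deliberate piecewise-frozen approximations remain: cached von Mises
masses are refreshed when the owning cell's Delta, landscape or position
changes (they lag the slow continuous BM growth and the global landscape
decay between refreshes), and migration rates read the ECM gate at the
last refresh of the moving voxel's schedule entry.  The von Mises window
masses are computed by 24-point Gauss-Legendre quadrature per `pi/3`
interval and normalised by their sum, so the six masses add to one
exactly; the public `direction_mass` uses adaptive quadrature
(tolerance 1e-10) and the two agree to better than 1e-8 over the
`kappa` range reached in simulations.

## Parameter provenance and calibration

Fixed published values (figure-caption constants): `K = 13.6`,
`k_m = 2.2`, `k_D = 2e-4`; `E_F1 = 0.15`, `E_F2 = 0.6`, `s_F1 = 30`,
`s_F2 = 10`; `p_max = 0.26`, `s_p = 0.0015`, `D_p = 1500`;
`R_c = 1.5 h`; initial-condition fluctuation `xi = 0.1` and landscape
increment `Delta_init = 1`; the experiment geometry, VEGF levels
(0/5/50 ng/ml uniform, 0->5 ng/ml over 125 um gradients), collagen
ladder `c_max in {0.1, 1, 1.7, 3}` and final times.

All remaining rate constants were calibrated by us, once, against the
qualitative behaviours the model must reproduce (in this order):

1. **Bistability** of the single-cell circuit in the external Delta
   input at VEGF = 5 ng/ml, with the bistable window shrinking
   monotonically as VEGF falls (vanishing near 0.5 ng/ml).
2. **Patterning geometry**: the lower fold of the bistable window lies
   above the Delta level a stalk-surrounded cell receives (so uniform
   stalk states destabilise into alternating patterns), and the upper
   fold lies below the signal delivered by a tip-rich neighbourhood (so
   uniform tip states collapse).
3. **Lineage ordering**: each mutant's fold ceiling orders with the wild
   type's Delta delivery, so VEGFR2+/- tips are suppressed by WT
   neighbours while VEGFR1+/- tips survive them; all lineages' pure-tip
   Delta exceeds ~3500 so that the overtaking probability saturates and
   gamma-secretase inhibition (DAPT: `k_t = 0`) restores parity.
4. **Timescales**: protein turnover `gamma = 0.25 /h` makes phenotype
   patterning settle within ~1 time unit, commensurate with the
   simulated windows.

The resulting subcellular set (per hour, concentration scale):
`b_N = 875`, `b_D = 1000`, `b_R2 = 2500`, `gamma = 0.25`,
`gamma_e = 1.25`, `k_t = 3.75e-4`, `k_c = 1.25e-3`, `k_v = 0.01`,
`I0 = 250`, `lam_I_N = 4`, `n_N = 2`, `R2s0 = 250`, `lam_R2s_D = 3.5`,
`n_D = 2`, `lam_I_R2 = 0.05`, `n_R2 = 4`, and `Omega = 0.05` (tip cells
hold ~350 Delta copies; the noise level makes tip/stalk contests re-run
on the timescale of sprout rearrangement).  Note that a uniform rescale
of all kinetic constants changes no steady state or fold location, only
the clock; the set above is such a rescale of a slower calibration.

Cellular/tissue choices: `D_omega = 50 um^2/min` (free-cell hop attempt
every few simulated minutes; realised displacements are far smaller
because of the adhesion, matrix and polarity gates), `c_max = 1`
baseline, `a_H = 1`, `n_H = 2` for the landscape readout,
`eta_max = 1.0 /h`, `gamma_max = 0.8 /h`, sigmoid midpoints
`D_c = D_m = 5500` with slopes `s_c = s_m = 0.002` (placed between the
quiescent Delta level (~300-1100, no proteolysis: VEGF = 0 gives no
elongation) and the tip levels of the bead (~4000, slow graded erosion
that resolves the collagen-density ladder within 500 min) and plexus
experiments (~6500-9700, fast erosion)),
`Delta_l = 1e-3`, `eta_l = 0.6 /h`, proteolytic reach weight 0.3 on the
six adjacent voxels (filopodia extend beyond the nucleus voxel; without
any reach, own-voxel proteolysis could never open matrix standing at
`c_max`), and `R_s = 1.5 h`.

The VEGFR2+/- mutant halves `b_R2`; the VEGFR1+/- mutant multiplies the
VEGF-activation channel by 1.5 (halved decoy receptor leaves more VEGF
available to VEGFR2); DAPT sets `k_t = 0`.  In the competition sprout the
fibril landscape starts aligned along the axis (`Delta_init = 1` in the
distal direction), which makes tip-cell overtaking strongly
forward-directed and is what lets wild-type cells exclude VEGFR2+/-
mutants from (and be excluded by VEGFR1+/- mutants at) the leading
positions at the reported magnitudes.

## ECM gating and invasion

The prose description of the migration rate reads the ECM density "in
the voxel where the nucleus is situated"; we gate on the voxel being
*entered* instead.  A source-evaluated gate makes dense matrix absorbing
(cells enter at full speed and then freeze), which floods the domain,
irreversibly biases VEGF = 0 directionality anterograde, and lets cells
escape the competition sprout.  A target-evaluated gate reproduces the
reported behaviours: saturated matrix is impenetrable, invasion proceeds
step-by-step as resident and adjacent cells degrade voxels below
`c_max`, VEGF = 0 cells stay confined to the existing vasculature with
anterograde and retrograde moves exactly balanced by overtaking, and the
matrix walls of the shuffling assay are absolute.

## Study configurations

* **Plexus sprouting (setup 1)** — a bottom-row plexus (refilled with a
  fresh quiescent cell whenever vacated: constant-supply boundary) plus
  three short seed sprouts, matrix at `c_max` elsewhere, uniform VEGF.
  Default reduced lattice 25x25 (directionality runs use 21x32 so that
  high-VEGF elongation is not domain-capped).
* **VEGF gradient (setup 2)** — the same vasculature in a linear 0->5
  ng/ml ramp; branching concentrates toward high VEGF (brush border).
* **Cell bead (setup 3)** — a 19-cell hexagonal bead with a basement
  membrane shell in matrix of density `c_max in {0.1, 1, 1.7, 3}`, VEGF
  ramp 0->5 ng/ml over 125 um, final time 1.0 (500 min).  Invasion
  depth decreases monotonically with `c_max`.
* **Linear-sprout competition (setup 4)** — a 2x12 matrix-walled,
  matrix-free sprout spanning the lattice (its distal column abuts the
  boundary, so the sprout cannot elongate), two lineages mixed 1:1,
  ECM/BM dynamics frozen (proteolysis-free shuffling), VEGF 5 ng/ml.
  The occupancy of the two distal voxels by each lineage is integrated
  over time after a burn-in that lets the tip/stalk pattern establish.

Initial protein levels are drawn with `xi = 0.1` relative fluctuation
around the *quiescent* (laterally inhibited) state of each lineage —
the low-Delta branch at the midpoint of the bistable window — so tips
emerge where the neighbourhood signal permits rather than being imposed.

## Metrics

Displacement (Euclidean, disjoint 15-min windows), orientation
(endpoint-preserving 3-point moving-average smoothed path length over
actual path length), directionality (per 20-min window: still if the net
displacement is below `h/2` — lattice quantisation makes exact zero
brittle — otherwise anterograde/retrograde by the change of geodesic
distance from the plexus within the network of ever-occupied voxels),
tip proportion, network morphometrics (node count times voxel area;
maximal degree-2 chains as vessel segments; degree->=3 nodes count as
branching points only when at least three incident segments span
`>= 2h`), and the mixing measure

`M(t) = (1/(|I_cluster| d_max)) sum_pairs [d(i1,i2,t+t_m) - d(i1,i2,t)]`

over unordered pairs of cells occupying a nearest-neighbour voxel
cluster at time `t`, with `d` the shortest-path distance within the
final network and `d_max` the largest pairwise cell distance at the
final time.  The default cluster is a seed-sprout base voxel and its six
neighbours; the default lag is `t_m = 200 min` (0.4 units), a value we
expose in run metadata because the published analysis does not print it.

## What the generators emulate — and what they do not

The synthetic configurations reproduce the *in vitro* geometries
(plexus explant, bead assay, isolated sprout) at reduced lattice sizes
and durations chosen so a complete study runs on one workstation core.
They do not emulate image noise, cell shape, proliferation or death,
lumen formation, 3D geometry, or VEGF transport (the VEGF field is
static by assumption).  Passing tests therefore demonstrate the
internal consistency of the model and the reproducibility of its
emergent behaviours — branching, chemotactic sensitivity, mutant
competition — not agreement with any particular wet-lab image.

## Numerical choices and degenerate inputs

* Exact clamped integration of `c` and `m` between events (no solver);
  the clamp boundaries 0 and 1 are reached exactly and are sticky.
* Undefined polarity (zero landscape resultant) falls back to an
  isotropic cell (`kappa = 0`, all six masses 1/6).
* Fixed-point scans bracket roots of a reduced one-dimensional problem
  in the NICD level on a log grid, polish with a full Newton solve
  (residual tolerance 1e-9), and classify stability by the eigenvalues
  of a finite-difference Jacobian (step 1e-6 relative).
* Empty neighbourhoods give zero external signal; an empty lattice ends
  the simulation (all propensities vanish).
* The random stream is a single seeded generator consumed in event
  order; runs are bit-reproducible given (configuration, seed), and
  resumed segments derive their seeds from the user seed and segment
  index.

## Reduced problem sizes

Test and acceptance runs use deliberately reduced sizes, chosen as the
smallest that keep the qualitative contrasts stable across seeds:
competition 2x12 sprout, 12 realisations (20 for the WT:WT control) of
7 time units with a 2-unit burn-in (the occupancy fractions equilibrate
after ~2 units); monolayer 10x12 for
2 units; plexus runs 17x20 to 21x32 for 1.5-2.5 units with 3-5
realisations; bead 21x15 for 1 unit.  The published study used 100
realisations of larger domains over up to 50 units; quantities that are
noisy per realisation (competition occupancies) therefore carry larger
standard errors here, and the tests assert bands rather than the
printed standard deviations.

## Known limitations

* The supplementary parameter tables of the source study were not
  available; the rate constants are this package's own calibration (see
  above), so agreement with printed *quantitative* values beyond the
  competition table should not be over-interpreted.
* Networks grown at high VEGF are denser than the published figures,
  and the morphometric branching count on such dense regions is
  conservative (the degree->=3 rule with segment-length pruning reports
  few branch points inside compact mats).
* Under DAPT the model retains a ~10-point deviation from parity at the
  leading positions: with an aligned landscape the exploratoriness
  function couples each lineage's (all-tip) Delta level to its
  forward-directed overtaking, favouring the lower-Delta lineage.
  Removing the alignment restores exact parity but destroys the
  mutant-exclusion magnitudes; we document the deviation rather than
  trade it away.
* The two-state Markov reduction and continuum limits discussed as
  future work in the source study are out of scope, as are
  proliferation, lumen formation and pericytes.
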