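"""Cell invasion from a bead into matrices of increasing collagen density.

Reproduces the collagen 'sweet spot': free dispersal in sparse matrix,
sprout-like invasion at intermediate density, and near-total confinement
in dense matrix.  Invasion depth is the distance beyond the initial bead.
"""
import numpy as np
from sproutsim.experiments import make_setup, run_setup

for cm in (0.1, 1.0, 1.7, 3.0):
    spec = make_setup("setup3_bead", c_max=cm)
    sim, log = run_setup(spec, seed=1)
    lat = sim.lattice
    centre = lat.centers[lat.index(spec.n_x // 2, spec.n_y // 2)]
    last = log.at(spec.T_max)
    r = np.hypot(last["x"] - centre[0], last["y"] - centre[1])
    depth = np.maximum(0.0, r - 2 * lat.h)
    print(f"c_max = {cm:3}: mean invasion depth {depth.mean():5.1f} um "
          f"(max {depth.max():4.0f} um)")
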