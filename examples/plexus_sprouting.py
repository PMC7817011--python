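"""Sprouting from a vascular plexus into uniform VEGF.

Runs the full multiscale system (signalling + migration + matrix
remodelling) from a bottom-row plexus with cell influx, then prints the
trajectory metrics and an ASCII picture of the grown network
('#' = cell, '.' = matrix-free tunnel).
"""
from sproutsim.experiments import make_setup, run_setup
from sproutsim.metrics import build_network, directionality, network_morphometrics

spec = make_setup("setup1_plexus", vegf=5.0, T_max=2.0)
sim, log = run_setup(spec, seed=1)
lat = sim.lattice
d = directionality(log, lat, set(spec.plexus))
G = build_network(log, lat)
m = network_morphometrics(G, lat.h, lat.voxel_area)
print(f"cells at T: {sim.n_cells}   tip fraction: {float(log.at(2.0)['tip'].mean()):.2f}")
print(f"directionality: anterograde {d['anterograde']:.2f}, "
      f"retrograde {d['retrograde']:.2f}, still {d['still']:.2f}")
print(f"network area {m['network_area']:.0f} um^2, "
      f"{m['n_branching_points']} branching points, "
      f"{m['n_segments']} segments (mean {m['mean_segment_length']:.0f} um)\n")
ever = set(int(v) for v in log.frame["voxel"].unique())
occ = set(int(v) for v in log.at(2.0)["voxel"])
for r in range(spec.n_y - 1, -1, -1):
    cells = "".join("#" if lat.index(c, r) in occ else
                    ("." if lat.index(c, r) in ever else " ")
                    for c in range(spec.n_x))
    print((" " if r % 2 else "") + " ".join(cells))
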