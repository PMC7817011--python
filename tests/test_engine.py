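"""Event-engine correctness: scheduling, bookkeeping, conservation, influx."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from sproutsim.engine import Simulation, build_dependencies
from sproutsim.lattice import HexLattice, weights_csr
from sproutsim.params import LineageOverride, ParameterSet, SubcellularParams, TissueParams
from sproutsim.subcellular import STOICHIOMETRY, reaction_propensities
from sproutsim.params import HOURS_PER_UNIT


def _frozen_tissue() -> ParameterSet:
    # no landscape relaxation so cached rates stay exact between events
    return ParameterSet(tissue=TissueParams(eta_l=0.0))


class TestDependencies:
    def test_every_voxel_depends_on_itself(self):
        lat = HexLattice(8, 8)
        indptr, idx = build_dependencies(lat, 15.0, 15.0)
        for v in range(lat.n_voxels):
            assert v in idx[indptr[v]:indptr[v + 1]]

    def test_symmetric_for_equal_radii(self):
        lat = HexLattice(8, 8)
        indptr, idx = build_dependencies(lat, 15.0, 15.0)
        dep = [set(idx[indptr[v]:indptr[v + 1]]) for v in range(lat.n_voxels)]
        for v in range(lat.n_voxels):
            for u in dep[v]:
                assert v in dep[u]

    def test_contains_lattice_neighbours(self):
        lat = HexLattice(8, 8)
        indptr, idx = build_dependencies(lat, 12.0, 12.0)
        for v in range(lat.n_voxels):
            dep = set(idx[indptr[v]:indptr[v + 1]])
            for j in lat.neighbor_table[v]:
                if j >= 0:
                    assert int(j) in dep


class TestDeterminism:
    def _make(self):
        sim = Simulation(HexLattice(5, 5), _frozen_tissue(), V=5.0,
                         freeze_fields=True)
        rng = np.random.default_rng(0)
        for v in range(sim.lattice.n_voxels):
            sim.place_cell(v, rng=rng)
        return sim

    def test_same_seed_identical_logs(self):
        logs = [self._make().run(0.2, seed=17) for _ in range(2)]
        assert logs[0].frame.equals(logs[1].frame)

    def test_zero_final_time_logs_initial_state_only(self):
        sim = self._make()
        log = sim.run(0.0, seed=1)
        assert set(log.frame["t"]) == {0.0}
        assert len(log.frame) == sim.lattice.n_voxels


class TestIncrementalBookkeeping:
    def test_from_scratch_recomputation_matches(self):
        # ~1000 events on a 6x6 lattice with signalling and migration
        ps = _frozen_tissue()
        sim = Simulation(HexLattice(6, 6), ps, V=5.0, freeze_fields=True)
        rng = np.random.default_rng(2)
        for v in range(0, sim.lattice.n_voxels, 2):
            sim.place_cell(v, rng=rng)
        sim.run(10.0, seed=5, max_events=1000)
        incremental = sim.propensities()
        inc_Dbar = sim.Dbar_num.copy()
        inc_EN = sim.EN_num.copy()
        sim.refresh_all()
        np.testing.assert_allclose(sim.Dbar_num, inc_Dbar, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(sim.EN_num, inc_EN, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(sim.propensities(), incremental,
                                   rtol=1e-9, atol=1e-12)

    def test_engine_propensities_match_reference_implementation(self):
        # voxel-local reaction propensities agree with the pure-Python
        # definitions used throughout the subcellular module
        ps = _frozen_tissue()
        sim = Simulation(HexLattice(5, 5), ps, V=5.0, freeze_fields=True,
                         freeze_migration=True)
        rng = np.random.default_rng(3)
        for v in range(sim.lattice.n_voxels):
            sim.place_cell(v, rng=rng)
        sim.run(0.5, seed=9)
        sim.refresh_all()
        p = ps.subcellular
        indptr, idx, w = weights_csr(sim.lattice, ps.R_s)
        for v in [0, 7, 12, 18, 24]:
            lo, hi = indptr[v], indptr[v + 1]
            wsum = w[lo:hi].sum()
            Dbar = (w[lo:hi] * sim.X[idx[lo:hi], 1]).sum() / wsum / p.Omega
            Nbar = (w[lo:hi] * sim.X[idx[lo:hi], 0]).sum() / wsum / p.Omega
            ref = reaction_propensities(sim.X[v], Dbar, Nbar, p) * HOURS_PER_UNIT
            np.testing.assert_allclose(sim.prop[v, :12], ref, rtol=1e-9)


class TestEventStatistics:
    def test_first_event_of_empty_cell_is_production(self):
        # a lone cell with zero proteins and V=0 can only produce N, D or R2
        for seed in range(5):
            ps = _frozen_tissue()
            sim = Simulation(HexLattice(3, 3), ps, V=0.0, freeze_fields=True,
                             freeze_migration=True)
            sim.place_cell(4, proteins=np.zeros(5, dtype=int))
            _, voxel, channel = sim.step(seed=seed)
            assert voxel == 4
            assert channel in (0, 1, 2)

    def test_first_event_channel_frequencies_match_propensities(self):
        # multinomial oracle: channel choice is proportional to propensity
        ps = _frozen_tissue()
        counts = np.zeros(3)
        n = 300
        for seed in range(n):
            sim = Simulation(HexLattice(3, 3), ps, V=0.0, freeze_fields=True,
                             freeze_migration=True)
            sim.place_cell(4, proteins=np.zeros(5, dtype=int))
            _, _, ch = sim.step(seed=seed)
            counts[ch] += 1
        p = ps.subcellular
        expected = np.array([p.b_N, p.b_D, p.b_R2])
        expected = expected / expected.sum()
        for k in range(3):
            se = np.sqrt(expected[k] * (1 - expected[k]) / n)
            assert counts[k] / n == pytest.approx(expected[k], abs=3.5 * se)

    def test_first_event_time_is_exponential(self):
        # NSV scheduling vs the direct-method waiting time Exp(total rate)
        ps = _frozen_tissue()
        times = []
        total = None
        for seed in range(400):
            sim = Simulation(HexLattice(3, 3), ps, V=0.0, freeze_fields=True,
                             freeze_migration=True)
            for v in range(9):
                sim.place_cell(v, proteins=np.zeros(5, dtype=int))
            if total is None:
                sim.refresh_all()
                total = sim.ptot.sum()
            t, _, _ = sim.step(seed=seed)
            times.append(t)
        res = stats.kstest(times, "expon", args=(0, 1.0 / total))
        assert res.pvalue > 0.01

    def test_terminal_state_raises(self):
        sim = Simulation(HexLattice(3, 3), _frozen_tissue(), V=0.0,
                         freeze_fields=True, freeze_migration=True)
        with pytest.raises(StopIteration):
            sim.step(seed=0)


class TestConservationAndInflux:
    def test_migration_conserves_cells_and_labels(self):
        ps = _frozen_tissue()
        sim = Simulation(HexLattice(8, 8), ps, V=5.0, c_init=0.0,
                         freeze_fields=True)
        rng = np.random.default_rng(4)
        chosen = rng.choice(64, size=20, replace=False)
        for v in chosen:
            sim.place_cell(int(v), rng=rng)
        log = sim.run(1.0, seed=21)
        f = log.frame
        for t, snap in f.groupby("t"):
            assert len(snap) == 20
            assert set(snap["label"]) == set(range(20))

    def test_plexus_refilled_on_vacancy(self):
        ps = _frozen_tissue()
        lat = HexLattice(6, 6)
        plexus = [lat.index(c, 0) for c in range(6)]
        sim = Simulation(lat, ps, V=5.0, c_init=0.0, plexus=plexus,
                         freeze_fields=True)
        rng = np.random.default_rng(5)
        for v in plexus:
            sim.place_cell(v, rng=rng)
        log = sim.run(1.5, seed=33)
        f = log.frame
        # plexus voxels occupied at every sample; cell count = initial + influx
        for t, snap in f.groupby("t"):
            assert set(plexus) <= set(snap["voxel"])
            n_spawned = (snap["label"] >= len(plexus)).sum()
            assert len(snap) == len(plexus) + n_spawned
        counts = f.groupby("t")["label"].count()
        assert (np.diff(counts.to_numpy()) >= 0).all()

    def test_non_plexus_voxels_never_refilled(self):
        # without a plexus the total count stays frozen even as cells wander
        ps = _frozen_tissue()
        sim = Simulation(HexLattice(6, 6), ps, V=5.0, c_init=0.0,
                         freeze_fields=True)
        rng = np.random.default_rng(6)
        for v in range(0, 36, 3):
            sim.place_cell(v, rng=rng)
        log = sim.run(1.0, seed=8)
        assert (log.frame.groupby("t")["label"].count() == 12).all()
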