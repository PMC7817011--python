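"""VEGF-Delta-Notch kinetics: propensities, mean field, bistability."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sproutsim.params import SubcellularParams
from sproutsim.subcellular import (
    N_REACTIONS,
    STOICHIOMETRY,
    bifurcation_scan,
    classify_phenotype,
    external_signals,
    mean_field_rhs,
    reaction_propensities,
    shifted_hill,
    ssa_trajectory,
    steady_states,
)


@pytest.fixture(scope="module")
def p():
    return SubcellularParams()


class TestShiftedHill:
    def test_zero_input_gives_one(self):
        assert shifted_hill(0.0, 100.0, 5.0, 2.0) == 1.0

    def test_midpoint(self):
        assert shifted_hill(100.0, 100.0, 5.0, 2.0) == pytest.approx(3.0)

    @pytest.mark.parametrize("lam", [0.05, 0.5, 2.0, 10.0])
    def test_asymptote_is_fold_change(self, lam):
        assert shifted_hill(1e6 * 50.0, 50.0, lam, 2.0) == pytest.approx(lam, abs=1e-3)

    def test_monotone(self):
        x = np.linspace(0, 1000, 200)
        act = shifted_hill(x, 100.0, 4.0, 2.0)
        rep = shifted_hill(x, 100.0, 0.1, 2.0)
        assert np.all(np.diff(act) >= 0)
        assert np.all(np.diff(rep) <= 0)


class TestPropensities:
    def test_empty_cell_only_production(self, p):
        a = reaction_propensities(np.zeros(5, dtype=int), 0.0, 0.0, p)
        assert np.all(a[:3] > 0)
        assert np.all(a[3:] == 0)

    def test_no_vegf_no_activation(self, p):
        x = np.array([10, 10, 10, 10, 10])
        a = reaction_propensities(x, 100.0, 100.0, replace(p, V=0.0))
        assert a[11] == 0.0

    def test_consuming_channels_vanish_with_reactant(self, p):
        # no reaction can drive a copy number negative
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 50, size=5)
            x[rng.integers(5)] = 0
            a = reaction_propensities(x, 200.0, 200.0, p)
            for ch in range(N_REACTIONS):
                consumed = np.flatnonzero(STOICHIOMETRY[ch] < 0)
                if any(x[sp] == 0 for sp in consumed):
                    assert a[ch] == 0.0

    def test_negative_copy_number_rejected(self, p):
        with pytest.raises(ValueError):
            reaction_propensities(np.array([-1, 0, 0, 0, 0]), 0.0, 0.0, p)

    def test_mean_field_consistency(self, p):
        # propensity-weighted stoichiometry, rescaled by Omega, reproduces
        # the deterministic right-hand side exactly
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 800, size=5)
            Dext, Next = rng.uniform(0, 3000, size=2)
            a = reaction_propensities(x, Dext, Next, p)
            drift = (a[:, None] * STOICHIOMETRY).sum(axis=0) / p.Omega
            rhs = mean_field_rhs(x / p.Omega, Dext, Next, p)
            np.testing.assert_allclose(drift, rhs, rtol=1e-12)


class TestPhenotype:
    def test_threshold_inclusive(self, p):
        assert classify_phenotype(p.b_D, p.b_D) == "tip"

    def test_zero_is_stalk(self, p):
        assert classify_phenotype(0.0, p.b_D) == "stalk"

    def test_monotone(self, p):
        tips = [D for D in np.linspace(0, 2 * p.b_D, 41)
                if classify_phenotype(D, p.b_D) == "tip"]
        assert tips == sorted(tips)
        assert min(tips) >= p.b_D


class TestExternalSignals:
    def _csr(self, weights_by_voxel, n):
        indptr = [0]
        idx, w = [], []
        for i in range(n):
            for j, wij in weights_by_voxel.get(i, {}).items():
                idx.append(j)
                w.append(wij)
            indptr.append(len(idx))
        return np.array(indptr), np.array(idx), np.array(w, dtype=float)

    def test_isolated_cell_sees_nothing(self):
        indptr, idx, w = self._csr({}, 1)
        prot = np.array([[5.0, 7.0]])
        Dbar, Nbar = external_signals(prot, indptr, idx, w)
        assert Dbar[0] == 0.0 and Nbar[0] == 0.0

    def test_single_neighbour_weighted_average(self):
        # printed formula: Dbar = alpha*D / total weight over H(i)
        indptr, idx, w = self._csr({0: {1: 0.4, 2: 0.6}}, 3)
        prot = np.array([[0.0, 0.0], [10.0, 20.0], [0.0, 0.0]])
        Dbar, Nbar = external_signals(prot, indptr, idx, w)
        assert Dbar[0] == pytest.approx(0.4 * 20.0 / 1.0)
        assert Nbar[0] == pytest.approx(0.4 * 10.0 / 1.0)

    def test_uniform_monolayer_average_is_constant(self):
        from sproutsim.lattice import HexLattice, weights_csr
        lat = HexLattice(10, 12)
        indptr, idx, w = weights_csr(lat, 15.0)
        prot = np.full((lat.n_voxels, 2), 3.0)
        prot[:, 1] = 11.0
        Dbar, _ = external_signals(prot, indptr, idx, w)
        assert Dbar[lat.index(5, 6)] == pytest.approx(11.0, rel=1e-9)


class TestSteadyStates:
    def test_fixed_points_have_tiny_residual(self, p):
        for Dx in (0.0, 1000.0, 3000.0):
            for y, _ in steady_states(p, Dx):
                assert np.max(np.abs(mean_field_rhs(y, Dx, 0.0, p))) < 1e-9

    def test_tip_at_low_input_stalk_at_high_input(self, p):
        lo = [y for y, s in steady_states(p, 0.0) if s]
        hi = [y for y, s in steady_states(p, 4000.0) if s]
        assert len(lo) == 1 and len(hi) == 1
        assert classify_phenotype(lo[0][1], p.b_D) == "tip"
        assert classify_phenotype(hi[0][1], p.b_D) == "stalk"
        assert hi[0][0] > lo[0][0]  # stalk has high Notch

    def test_bistable_interval_exists_and_shrinks_with_vegf(self, p):
        grid = np.linspace(0, 4000, 41)
        widths = []
        for V in (5.0, 2.0, 0.5):
            widths.append(bifurcation_scan(replace(p, V=V), grid).bistable_width)
        assert widths[0] > 0
        assert widths[0] > widths[1] > widths[2] or widths[2] == 0.0


class TestStochasticMeanAgreement:
    def test_ssa_mean_tracks_ode(self, p):
        # law-of-large-numbers oracle: ensemble mean of the jump process
        # follows the deterministic solution within 3 standard errors
        pp = replace(p, Omega=0.5)
        Dext, Next, t_end = 800.0, 500.0, 4.0
        n_runs = 60
        finals = np.empty((n_runs, 5))
        for r in range(n_runs):
            _, states = ssa_trajectory(pp, Dext, Next, t_end, rng=r)
            finals[r] = states[-1] / pp.Omega
        sol = solve_ivp(
            lambda t, y: mean_field_rhs(y, Dext, Next, pp),
            (0, t_end), np.zeros(5), rtol=1e-9, atol=1e-9)
        mean = finals.mean(axis=0)
        se = finals.std(axis=0, ddof=1) / np.sqrt(n_runs)
        for sp in range(5):
            tol = 3 * se[sp] + 1e-9
            assert abs(mean[sp] - sol.y[sp, -1]) < tol + 0.05 * abs(sol.y[sp, -1])
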