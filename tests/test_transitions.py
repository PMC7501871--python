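"""Transition maps, hotspots, and the dual-landscape master equation."""

import numpy as np
import pytest
import scipy.sparse as sp

from cryoscape import (
    GridSpec,
    OccupancyGrid,
    RateModel,
    build_rate_model,
    energy_from_occupancy,
    find_hotspots,
    initial_flux,
    integrate_master_equation,
    stationary_distribution,
    transition_map,
)
from cryoscape.transitions import TransitionMap


def _occ(counts, condition="minus"):
    counts = np.asarray(counts)
    return OccupancyGrid(condition, GridSpec(*counts.shape), counts)


class TestTransitionMap:
    def test_matching_deltas(self):
        tm = transition_map(_occ([[4, 0], [0, 0]]), _occ([[9, 0], [0, 0]], "plus"))
        assert tm.t[0, 0] == 1.0
        assert tm.t.sum() == pytest.approx(1.0)

    def test_uniform_over_k_cells(self):
        tm = transition_map(_occ([[2, 2], [2, 2]]), _occ([[3, 3], [3, 3]], "plus"))
        np.testing.assert_allclose(tm.t, 0.25)

    def test_hand_arithmetic_example(self):
        tm = transition_map(_occ([[2, 0], [1, 1]]), _occ([[1, 1], [0, 2]], "plus"))
        np.testing.assert_allclose(tm.t, [[0.5, 0.0], [0.0, 0.5]])

    def test_disjoint_supports_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            transition_map(_occ([[5, 0], [0, 0]]), _occ([[0, 0], [0, 5]], "plus"))

    def test_argmax_matches_product_argmax(self):
        rng = np.random.default_rng(0)
        nm = rng.integers(0, 50, (6, 6))
        npl = rng.integers(0, 50, (6, 6))
        nm[0, 0] += 1  # ensure nonzero overlap
        npl[0, 0] += 1
        tm = transition_map(_occ(nm), _occ(npl, "plus"))
        prod = (nm / nm.sum()) * (npl / npl.sum())
        assert tm.argmax_cell == tuple(np.unravel_index(np.argmax(prod), prod.shape))


class TestFindHotspots:
    def test_single_peak(self):
        t = np.zeros((4, 4))
        t[2, 1] = 1.0
        spots = find_hotspots(TransitionMap(GridSpec(4, 4), t))
        assert spots == [(2, 1)]

    def test_two_equal_peaks_row_major_tie(self):
        t = np.zeros((4, 4))
        t[1, 1] = 0.5
        t[3, 3] = 0.5
        spots = find_hotspots(TransitionMap(GridSpec(4, 4), t))
        assert spots == [(1, 1), (3, 3)]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        t = rng.random((10, 10))
        t /= t.sum()
        tm = TransitionMap(GridSpec(10, 10), t)
        got = set(find_hotspots(tm, rel_threshold=0.3))
        expected = set()
        for i in range(10):
            for j in range(10):
                neigh = [
                    t[a, b]
                    for a in range(max(0, i - 1), min(10, i + 2))
                    for b in range(max(0, j - 1), min(10, j + 2))
                    if (a, b) != (i, j)
                ]
                if t[i, j] >= max(neigh) and t[i, j] >= 0.3 * t.max():
                    expected.add((i, j))
        assert got == expected


def _flat_landscapes(n=3, counts=5):
    occ_m = _occ(np.full((n, n), counts))
    occ_p = _occ(np.full((n, n), counts), "plus")
    return energy_from_occupancy(occ_m), energy_from_occupancy(occ_p)


class TestBuildRateModel:
    def test_flat_landscape_gives_uniform_rates(self):
        em, ep = _flat_landscapes()
        model = build_rate_model(em, ep, ligand_conc=1.0, prefactor=2.5)
        rates = model.w_mm.data
        assert len(rates) > 0
        np.testing.assert_allclose(rates, 2.5)

    def test_metropolis_asymmetry_for_kt_ln2_step(self):
        counts = np.array([[20, 10], [20, 10]])  # E diff = kT ln 2 along axis 1
        em = energy_from_occupancy(_occ(counts), kT=1.0)
        ep = energy_from_occupancy(_occ(counts, "plus"), kT=1.0)
        model = build_rate_model(em, ep, prefactor=1.0, kT=1.0)
        w = model.w_mm.toarray()
        lo, hi = 0, 1  # cell (0,0) -> (0,1) is uphill by ln 2
        assert w[hi, lo] == pytest.approx(0.5)
        assert w[lo, hi] == pytest.approx(1.0)

    def test_association_rate_proportional_to_plus_spectrum(self):
        rng = np.random.default_rng(1)
        counts_p = rng.integers(1, 100, (4, 4))
        em = energy_from_occupancy(_occ(np.full((4, 4), 10)))
        ep = energy_from_occupancy(_occ(counts_p, "plus"))
        model = build_rate_model(em, ep, ligand_conc=2.0, prefactor=3.0)
        w = model.w_assoc.reshape(4, 4)
        ratio = w / counts_p
        np.testing.assert_allclose(ratio, ratio[0, 0], rtol=1e-10)

    def test_masked_cells_carry_zero_rates(self):
        counts = np.array([[10, 0], [10, 10]])
        em = energy_from_occupancy(_occ(counts))
        ep = energy_from_occupancy(_occ(counts, "plus"))
        model = build_rate_model(em, ep)
        dead = 0 * 2 + 1  # row-major index of the masked cell
        assert model.w_mm[:, dead].sum() == 0
        assert model.w_mm[dead, :].sum() == 0
        assert model.w_assoc[dead] == 0

    def test_invalid_args(self):
        em, ep = _flat_landscapes()
        with pytest.raises(ValueError):
            build_rate_model(em, ep, ligand_conc=-1)
        with pytest.raises(ValueError):
            build_rate_model(em, ep, dissociation="sometimes")


class TestIntegrateMasterEquation:
    def _zero_model(self, n=2):
        grid = GridSpec(n, n)
        z = sp.csr_matrix((n * n, n * n))
        return RateModel(
            grid=grid, w_mm=z, w_pp=z, w_assoc=np.zeros(n * n),
            w_dissoc=np.zeros(n * n), ligand_conc=0.0, prefactor=1.0, kT=1.0,
        )

    def test_zero_rates_freeze_the_distribution(self):
        model = self._zero_model()
        p0 = np.zeros(8)
        p0[0] = 0.4
        p0[5] = 0.6
        traj = integrate_master_equation(model, p0, np.array([0.0, 1.0, 10.0]))
        np.testing.assert_allclose(traj, np.tile(p0, (3, 1)), atol=1e-12)

    def test_symmetric_two_state_relaxes_to_half_half(self):
        grid = GridSpec(2, 2)
        w = sp.lil_matrix((4, 4))
        w[0, 1] = 1.0
        w[1, 0] = 1.0
        model = RateModel(
            grid=grid, w_mm=w.tocsr(), w_pp=sp.csr_matrix((4, 4)),
            w_assoc=np.zeros(4), w_dissoc=np.zeros(4),
            ligand_conc=0.0, prefactor=1.0, kT=1.0,
        )
        p0 = np.zeros(8)
        p0[0] = 1.0
        traj = integrate_master_equation(model, p0, np.array([50.0]))
        assert traj[0, 0] == pytest.approx(0.5, abs=1e-6)
        assert traj[0, 1] == pytest.approx(0.5, abs=1e-6)

    def test_probability_conserved_and_nonnegative(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 60, (5, 5))
        em = energy_from_occupancy(_occ(counts))
        ep = energy_from_occupancy(_occ(rng.integers(1, 60, (5, 5)), "plus"))
        model = build_rate_model(em, ep, ligand_conc=0.5)
        p0 = np.zeros(50)
        p0[:25] = (counts / counts.sum()).ravel()
        traj = integrate_master_equation(model, p0, np.linspace(0, 5, 6))
        np.testing.assert_allclose(traj.sum(axis=1), 1.0, atol=1e-8)
        assert traj.min() > -1e-8

    def test_invalid_p0(self):
        model = self._zero_model()
        with pytest.raises(ValueError):
            integrate_master_equation(model, np.ones(8), [0.0])


class TestStationarity:
    def test_metropolis_stationary_state_is_boltzmann(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(1, 200, (12, 12))
        em = energy_from_occupancy(_occ(counts), kT=1.0)
        ep = energy_from_occupancy(_occ(counts, "plus"), kT=1.0)
        model = build_rate_model(em, ep, ligand_conc=0.0)
        pi = stationary_distribution(model.w_mm)
        boltz = counts / counts.sum()
        tv = 0.5 * np.abs(pi - boltz.ravel()).sum()
        assert tv < 1e-6


class TestInitialFlux:
    def test_uniform_association_makes_flux_proportional_to_spectrum(self):
        em, ep = _flat_landscapes(3)
        model = build_rate_model(em, ep, ligand_conc=1.0, prefactor=1.0)
        p_minus = np.arange(1.0, 10.0)
        p_minus /= p_minus.sum()
        flux = initial_flux(model, p_minus)
        np.testing.assert_allclose(flux / flux.sum(), p_minus, rtol=1e-12)

    def test_delta_spectrum_gives_single_cell_flux(self):
        em, ep = _flat_landscapes(2)
        model = build_rate_model(em, ep)
        p = np.zeros(4)
        p[2] = 1.0
        flux = initial_flux(model, p)
        assert np.count_nonzero(flux) == 1

    def test_normalized_flux_equals_transition_map(self):
        rng = np.random.default_rng(11)
        nm = rng.integers(1, 80, (6, 6))
        npl = rng.integers(1, 80, (6, 6))
        occ_m, occ_p = _occ(nm), _occ(npl, "plus")
        em = energy_from_occupancy(occ_m)
        ep = energy_from_occupancy(occ_p)
        model = build_rate_model(em, ep, ligand_conc=0.7, prefactor=2.0)
        flux = initial_flux(model, occ_m.probabilities.ravel())
        tm = transition_map(occ_m, occ_p)
        np.testing.assert_allclose(
            flux / flux.sum(), tm.t.ravel(), atol=1e-13, rtol=1e-12
        )
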