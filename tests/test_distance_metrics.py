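import numpy as np
import pytest
from scipy.integrate import solve_ivp

import garnettrack as gt
from garnettrack.core_io import ClassCode
from garnettrack.distance_metrics import (contact_distance_map,
                                          fit_distance_porosity,
                                          garnet_lifetime,
                                          matric_potential_for_diameter,
                                          particle_vs_bulk,
                                          turnover_trajectory)

from _oracles import nearest_distance_bruteforce


def labelvol(labels, voxel_size=8.0):
    return gt.LabelVolume(np.asarray(labels, dtype=np.uint8), voxel_size=voxel_size)


class TestContactDistanceMap:
    def test_face_adjacent_voxel_is_one_voxel_away(self):
        labels = np.full((4, 4, 4), ClassCode.MATRIX, dtype=np.uint8)
        labels[0] = ClassCode.PORE_CONNECTED
        cd = contact_distance_map(labelvol(labels))
        assert cd.distance[1, 2, 2] == pytest.approx(8.0)

    def test_far_corner_of_cube_with_corner_pore(self):
        labels = np.full((10, 10, 10), ClassCode.MATRIX, dtype=np.uint8)
        labels[0, 0, 0] = ClassCode.PORE_CONNECTED
        cd = contact_distance_map(labelvol(labels))
        assert cd.distance[9, 9, 9] == pytest.approx(np.sqrt(3) * 9 * 8.0)

    def test_matches_exhaustive_search_on_random_volumes(self, rng):
        for _ in range(3):
            pore = rng.random((12, 12, 12)) < 0.25
            if not pore.any():
                continue
            labels = np.where(pore, np.uint8(ClassCode.PORE_CONNECTED),
                              np.uint8(ClassCode.MATRIX))
            cd = contact_distance_map(labelvol(labels, voxel_size=1.0))
            oracle = nearest_distance_bruteforce(pore)
            np.testing.assert_allclose(cd.distance, oracle, atol=1e-9)

    def test_zero_exactly_on_connected_pores(self, coated_phantom):
        _, truth, _ = coated_phantom
        cd = contact_distance_map(truth.labels)
        pore = truth.labels.labels == ClassCode.PORE_CONNECTED
        assert (cd.distance[pore] == 0).all()
        assert (cd.distance[~pore] > 0).all()

    def test_mean_consistent_with_histogram(self, coated_phantom):
        _, truth, _ = coated_phantom
        cd = contact_distance_map(truth.labels)
        mids = (cd.bin_edges[:-1] + cd.bin_edges[1:]) / 2
        hist_mean = (mids * cd.hist_bulk).sum() / cd.hist_bulk.sum()
        assert hist_mean == pytest.approx(cd.mean_bulk, rel=0.05)

    def test_no_connected_pore_rejected(self):
        labels = np.full((4, 4, 4), ClassCode.MATRIX, dtype=np.uint8)
        with pytest.raises(ValueError):
            contact_distance_map(labelvol(labels))

    def test_carving_pore_never_increases_distances(self, rng):
        """Monotone coupling: adding a connected-pore voxel only shrinks D."""
        pore = rng.random((14, 14, 14)) < 0.1
        pore[0, 0, 0] = True
        labels = np.where(pore, np.uint8(ClassCode.PORE_CONNECTED),
                          np.uint8(ClassCode.MATRIX))
        d0 = contact_distance_map(labelvol(labels, 1.0)).distance
        solid = np.argwhere(~pore)
        for z, y, x in solid[rng.choice(len(solid), 5, replace=False)]:
            labels2 = labels.copy()
            labels2[z, y, x] = ClassCode.PORE_CONNECTED
            d1 = contact_distance_map(labelvol(labels2, 1.0)).distance
            assert (d1 <= d0 + 1e-9).all()


class TestParticleVsBulk:
    def test_fresh_coat_particles_sit_near_pores(self, coated_phantom):
        _, truth, _ = coated_phantom
        cd = contact_distance_map(truth.labels)
        ds, dp, delta = particle_vs_bulk(cd)
        assert dp < ds and delta > 0

    def test_equal_means_give_zero_divergence(self):
        r = gt.ContactDistanceResult(
            distance=np.zeros((1, 1, 1)), voxel_size=8.0,
            bin_edges=np.array([0.0, 8.0]), hist_bulk=np.array([1]),
            hist_particle=np.array([1]), mean_bulk=40.0, mean_particle=40.0,
            mean_matrix=40.0, porosity=0.3)
        assert particle_vs_bulk(r)[2] == pytest.approx(0.0)

    def test_no_particles_rejected(self):
        r = gt.ContactDistanceResult(
            distance=np.zeros((1, 1, 1)), voxel_size=8.0,
            bin_edges=np.array([0.0, 8.0]), hist_bulk=np.array([1]),
            hist_particle=np.array([0]), mean_bulk=40.0, mean_particle=None,
            mean_matrix=40.0, porosity=0.3)
        with pytest.raises(ValueError):
            particle_vs_bulk(r)

    def test_random_matrix_placement_matches_matrix_mean(self, coated_phantom, rng):
        """Uniform random placement in the matrix sits on the 1:1 line."""
        _, truth, _ = coated_phantom
        cd = contact_distance_map(truth.labels)
        matrix = truth.labels.labels == ClassCode.MATRIX
        dvals = cd.distance[matrix]
        deltas = []
        for _ in range(5):
            sample = rng.choice(dvals.size, size=2000, replace=False)
            deltas.append(1.0 - dvals[sample].mean() / cd.mean_matrix)
        mean = np.mean(deltas)
        sem = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(mean) <= max(3 * sem, 0.02)


class TestTurnoverTrajectory:
    def _result(self, ds, dp):
        return gt.ContactDistanceResult(
            distance=np.zeros((1, 1, 1)), voxel_size=8.0,
            bin_edges=np.array([0.0, 8.0]), hist_bulk=np.array([1]),
            hist_particle=np.array([1]), mean_bulk=ds, mean_particle=dp,
            mean_matrix=ds, porosity=0.3)

    def test_identical_states_give_zero_decay(self):
        traj = turnover_trajectory([self._result(40, 20)] * 3)
        assert traj.decay_rate == pytest.approx(0.0)

    def test_decaying_divergence_recovers_rate(self):
        states = [self._result(40.0, 40.0 * (1 - 0.5 * np.exp(-0.3 * t)))
                  for t in range(5)]
        traj = turnover_trajectory(states)
        assert traj.decay_rate == pytest.approx(0.3, rel=1e-6)

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            turnover_trajectory([self._result(40, 20)])


class TestFitDistancePorosity:
    def test_parameter_recovery_under_mild_noise(self, rng):
        phi = np.linspace(0.05, 0.45, 12)
        d = 400.0 * np.exp(-12.0 * phi) * (1 + rng.normal(0, 0.01, phi.size))
        a, b = fit_distance_porosity(np.column_stack([phi, d]))
        assert a == pytest.approx(400, rel=0.05)
        assert b == pytest.approx(12, rel=0.10)

    def test_two_points_interpolated_exactly(self):
        a, b = fit_distance_porosity([(0.1, 100.0), (0.3, 50.0)])
        assert a * np.exp(-b * 0.1) == pytest.approx(100.0)
        assert a * np.exp(-b * 0.3) == pytest.approx(50.0)

    def test_constant_porosity_rejected(self):
        with pytest.raises(ValueError):
            fit_distance_porosity([(0.2, 10.0), (0.2, 20.0), (0.2, 30.0)])

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            fit_distance_porosity([(0.1, 10.0), (0.2, 0.0), (0.3, 5.0)])


class TestPhysicalHelpers:
    def test_young_laplace_reference_point(self):
        """Resolved pores (8 um) drain at -375 hPa with sigma=0.075, theta=0."""
        assert matric_potential_for_diameter(8.0) == pytest.approx(-375.0)

    def test_large_pores_drain_near_zero(self):
        assert abs(matric_potential_for_diameter(1e6)) < 0.01

    def test_halving_diameter_doubles_magnitude(self):
        assert matric_potential_for_diameter(4.0) == pytest.approx(
            2 * matric_potential_for_diameter(8.0))

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            matric_potential_for_diameter(0.0)

    def test_zero_shrinkage_takes_no_time(self):
        assert garnet_lifetime(50.0, 50.0) == 0.0

    def test_doubling_rate_halves_lifetime(self):
        assert garnet_lifetime(50, 25, rate=1e-6) == pytest.approx(
            garnet_lifetime(50, 25, rate=5e-7) / 2)

    def test_closed_form_matches_numeric_shrinking_sphere(self):
        rate, rho = 5e-7, 4.3
        t_closed = garnet_lifetime(50.0, 25.0, rate=rate, density=rho)

        def dddt(t, d):  # d in mm; dm/dt = -rate * area
            return [-2 * rate / rho]

        def hit(t, d):
            return d[0] - 25e-3
        hit.terminal = True
        sol = solve_ivp(dddt, (0, 1e7), [50e-3], events=hit, max_step=1e4)
        assert sol.t_events[0][0] == pytest.approx(t_closed, rel=1e-3)

    def test_invalid_diameters_rejected(self):
        with pytest.raises(ValueError):
            garnet_lifetime(25.0, 50.0)
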