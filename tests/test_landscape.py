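"""Averaged force, fixed points, string method, effective potential."""

import numpy as np
import pytest

from switchbead import binding
from switchbead import landscape as L
from switchbead.forces import UNBOUND, total_drift
from switchbead.params import preset
from switchbead.system import BeadSystem, SingleStateSystem

from conftest import equilateral


class TestAveragedForce:
    def test_alpha_invariance(self, sys3, rng):
        """<v> is unchanged when the rate matrix is scaled by any alpha > 0."""
        x = rng.normal(size=6)
        base = sys3.averaged_drift(x)
        for alpha in (0.1, 10.0):
            sys_a = BeadSystem(sys3.params.with_(timescale=alpha))
            # the generator carries no timescale factor by construction;
            # scale it explicitly and recompute the stationary weighting
            S = alpha * sys3.generator(x)
            r = binding.stationary_distribution(S)
            v = r @ sys3.drifts(x)
            assert np.abs(v - base).max() < 1e-12
            assert np.abs(sys_a.averaged_drift(x) - base).max() < 1e-12

    def test_matches_frozen_ctmc_time_average(self, sys3):
        """<v> agrees with the empirical time average of v(x; s(t)).

        The chain is sampled exactly (exponential holding times from the
        generator), positions frozen.
        """
        rng = np.random.default_rng(5)
        x = equilateral(0.9).reshape(-1) + 0.05 * rng.normal(size=6)
        S = sys3.generator(x)
        drifts = sys3.drifts(x)
        n_states = 4
        occ = np.zeros(n_states)
        s = 0
        # exact CTMC simulation via Gillespie
        for _ in range(200_000):
            rates = S[:, s].copy()
            rates[s] = 0.0
            total = rates.sum()
            dt_hold = rng.exponential(1.0 / total)
            occ[s] += dt_hold
            s = rng.choice(n_states, p=rates / total)
        occ /= occ.sum()
        v_emp = occ @ drifts
        v = sys3.averaged_drift(x)
        assert np.linalg.norm(v_emp - v) / np.linalg.norm(v) < 0.01

    def test_centered_symmetry(self, sys3):
        v = sys3.averaged_drift(equilateral(1.0).reshape(-1)).reshape(3, 2)
        assert np.abs(v.sum(axis=0)).max() < 1e-12

    def test_batch_matches_single(self, sys3, rng):
        X = rng.normal(size=(7, 6))
        V = sys3.averaged_drift_batch(X)
        for k in range(7):
            assert np.allclose(V[k], sys3.averaged_drift(X[k]), atol=1e-13)

    def test_average_of_state_drifts(self, sys3, rng):
        """<v> is the stationary-weighted sum of the per-state drifts."""
        x = rng.normal(size=6)
        r = sys3.stationary(x)
        drifts = sys3.drifts(x)
        assert np.allclose(sys3.averaged_drift(x), r @ drifts, atol=1e-13)
        # per-state drifts equal the force module's drift for that matching
        states = sys3.states
        for s in states:
            v_forces = total_drift(
                x.reshape(3, 2), s.partner_array(), sys3.params
            )
            assert np.allclose(drifts[s.index], v_forces, atol=1e-13)


class TestFixedPoints:
    def test_recovers_all_cluster_states(self, sys3):
        fps = L.find_fixed_points(sys3)
        labels = {f.label for f in fps if f.is_minimum}
        assert {L.UNBOUND_TRIANGLE, L.TWO_BEAD, L.THREE_BEAD} <= labels
        for f in fps:
            assert f.residual < 1e-8

    def test_two_bead_orbit_is_threefold_degenerate(self, sys3, minima):
        """The three 2-bead clusters are bead permutations of one another."""
        two = minima[L.TWO_BEAD]
        d_ref = two.sorted_distances()
        seeds = [two.positions[perm] for perm in ([1, 2, 0], [2, 0, 1])]
        for f in L.find_fixed_points(sys3, seeds=seeds):
            assert f.label == L.TWO_BEAD
            assert np.allclose(f.sorted_distances(), d_ref, atol=1e-8)

    def test_two_bead_distance_against_reduced_oracle(self, sys3, minima):
        """1-d root find on the symmetric two-bound-one-far manifold.

        With the pair superimposed at p = -u E / eta and the third bead at
        z = 2 u E / eta (u = z - p along one axis), stationarity reduces to a
        scalar equation for the separation d; the full fixed point must agree.
        """
        from scipy.optimize import brentq

        params = sys3.params

        def radial(d):
            z = np.array([2 * d / 3.0, 0.0])
            pp = np.array([-d / 3.0, 0.0])
            pos = np.array([pp, pp, z])
            v = sys3.averaged_drift(pos.reshape(-1)).reshape(3, 2)
            return v[2, 0]

        d_star = brentq(radial, 0.8 * params.affinity_midpoint * 2,
                        3.0 * params.affinity_midpoint)
        two = minima[L.TWO_BEAD]
        assert two.sorted_distances()[1] == pytest.approx(d_star, rel=1e-6)


class TestStringMethod:
    def test_quadratic_potential_gives_straight_line(self):
        """Isotropic quadratic: the converged string is the straight chord."""

        def force(X):
            return -X

        a = np.array([0.0, 0.0])
        b = np.array([2.0, 1.0])
        w = np.linspace(0, 1, 32)[:, None]
        init = (1 - w) * a + w * b
        init[:, 1] += 0.5 * np.sin(np.pi * w[:, 0])  # bend it first
        path = L.string_method(a, b, force, n_images=32, step_size=0.05,
                               tol=1e-13, max_iter=50000, init=init)
        chord = (1 - w) * a + w * b
        assert np.abs(path.images - chord).max() < 1e-6

    def test_double_well_path_and_barrier(self, double_well):
        """U = (z^2-1)^2 + y^2: MEP is the z-axis segment, barrier exactly 1."""
        init = np.stack([
            np.linspace(-1, 1, 64),
            0.3 * np.sin(np.pi * np.linspace(0, 1, 64)),  # bent start
        ], axis=1)
        path = L.string_method(
            np.array([-1.0, 0.0]), np.array([1.0, 0.0]),
            double_well.averaged_drift_batch, n_images=64,
            step_size=5e-3, tol=1e-10, max_iter=100000, init=init,
        )
        assert path.converged
        assert np.abs(path.images[:, 1]).max() < 1e-6   # on the z-axis
        prof = L.effective_potential_along_path(path, double_well)
        assert prof.barrier == pytest.approx(1.0, rel=5e-3)

    def test_collapse_detected(self, double_well):
        with pytest.raises((L.StringCollapseError, ValueError)):
            L.string_method(np.array([1.0, 0.0]), np.array([1.0, 0.0]),
                            double_well.averaged_drift_batch)

    def test_equal_arclength_spacing(self, path22):
        path, _ = path22
        seg = path.segment_lengths()
        assert seg.std() / seg.mean() < 1e-3

    def test_endpoints_and_saddle_are_critical(self, sys3, path22):
        path, saddle = path22
        scale = sys3.params.kappa
        assert np.linalg.norm(sys3.averaged_drift(path.images[0])) < 1e-6 * scale
        assert np.linalg.norm(sys3.averaged_drift(path.images[-1])) < 1e-6 * scale
        assert saddle.n_unstable == 1
        assert saddle.label == L.SADDLE_COLLINEAR


class TestEffectivePotential:
    def test_single_state_profile_equals_potential_difference(self, double_well):
        """For a gradient field the line integral reproduces U exactly."""
        z = np.linspace(-1, 1, 64)
        images = np.stack([z, np.zeros_like(z)], axis=1)
        path = L.TransitionPath(images, np.linspace(0, 1, 64), True, 0, 0.0)
        prof = L.effective_potential_along_path(path, double_well)
        exact = (z**2 - 1) ** 2
        assert np.abs(prof.values - exact).max() < 2e-3   # O(1/n^2) quadrature

    def test_quadrature_convergence(self, sys3, minima):
        """Doubling the image count changes the barrier by < 0.5%."""
        p64, _ = L.transition_path(sys3, "2bead-2bead", minima=minima,
                                   n_images=64)
        p128, _ = L.transition_path(sys3, "2bead-2bead", minima=minima,
                                    n_images=128)
        b64 = L.effective_potential_along_path(p64, sys3).barrier
        b128 = L.effective_potential_along_path(p128, sys3).barrier
        assert abs(b128 - b64) / b64 < 5e-3

    def test_loop_residual_reported_nonzero(self, sys3, path22):
        """<v> is not a gradient: a closed loop integral need not vanish.

        The residual is computed and reported on the profile rather than
        silently discarded; for a gradient field it vanishes.
        """
        path, _ = path22
        prof = L.effective_potential_along_path(path, sys3,
                                                return_loop_residual=True)
        assert np.isfinite(prof.loop_residual)
        # gradient single-state control: loop residual ~ quadrature error
        z = np.linspace(-1, 1, 64)
        images = np.stack([z, 0.1 * np.sin(np.pi * z)], axis=1)
        gpath = L.TransitionPath(images, np.linspace(0, 1, 64), True, 0, 0.0)

        def drift(x):
            return np.array([-4 * x[0] * (x[0] ** 2 - 1), -2 * x[1]])

        gsys = SingleStateSystem(drift, 2)
        gprof = L.effective_potential_along_path(gpath, gsys,
                                                 return_loop_residual=True)
        assert abs(gprof.loop_residual) < 1e-3

    def test_barrier_ordering_rearrangement_vs_exit(self, sys3, minima):
        """Leaving the 3-bead cluster costs more than rearranging within it."""
        exit_path, _ = L.transition_path(sys3, "3bead-2bead", minima=minima)
        rearr_path, _ = L.transition_path(sys3, "3bead-collinear",
                                          minima=minima)
        b_exit = L.effective_potential_along_path(exit_path, sys3).barrier
        b_rearr = L.effective_potential_along_path(rearr_path, sys3).barrier
        assert b_exit > b_rearr
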