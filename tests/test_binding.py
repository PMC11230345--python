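"""Binding-state enumeration, rate matrices, stationarity, event sampling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from switchbead import binding
from switchbead.binding import (
    BindingState,
    EnumerationInfeasibleError,
    RateResolutionWarning,
    affinity,
    enumerate_states,
    sample_events,
    stationary_distribution,
    transition_rate_matrix,
)
from switchbead.forces import UNBOUND
from switchbead.params import preset

from conftest import equilateral


def brute_force_state_count(n: int) -> int:
    """Count valid matchings by checking every partner array (oracle)."""
    count = 0
    for partner in itertools.product(range(-1, n), repeat=n):
        ok = all(
            p == -1 or (p != i and 0 <= p < n and partner[p] == i)
            for i, p in enumerate(partner)
        )
        count += ok
    return count


class TestEnumeration:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 2), (3, 4)])
    def test_small_counts(self, n, expected):
        assert len(enumerate_states(n)) == expected

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_counts_match_brute_force_oracle(self, n):
        assert len(enumerate_states(n)) == brute_force_state_count(n)
        assert binding.count_states(n) == brute_force_state_count(n)

    def test_three_bead_state_order(self):
        states = enumerate_states(3)
        assert states[0].bonds == ()          # all unbound first
        assert states[1].bonds == ((0, 1),)
        assert states[2].bonds == ((0, 2),)
        assert states[3].bonds == ((1, 2),)
        assert [s.index for s in states] == [0, 1, 2, 3]

    def test_states_are_valid_unique_matchings(self):
        states = enumerate_states(6)
        seen = set()
        for s in states:
            BindingState(s.partner)  # validates the involution
            assert s.partner not in seen
            seen.add(s.partner)
        assert len(states) == 76  # telephone number T(6)

    def test_cap_raises_directing_to_simulation(self):
        with pytest.raises(EnumerationInfeasibleError, match="simulation"):
            enumerate_states(9)


class TestAffinity:
    def test_midpoint_and_limits(self):
        for name in ("table1-3bead", "table1-361"):
            p = preset(name)
            assert affinity(p.affinity_midpoint, p) == pytest.approx(1.0)
            assert affinity(0.0, p) == pytest.approx(p.affinity_amplitude, rel=1e-6)
            assert affinity(100 * p.affinity_midpoint, p) < 1e-12

    def test_direct_evaluation(self):
        p = preset("table1-3bead")
        assert affinity(1.0, p) == pytest.approx(2.0 / (1.0 + np.e**5), rel=1e-12)

    def test_strictly_decreasing(self):
        p = preset("table1-3bead")
        r = np.linspace(0, 3, 200)
        a = affinity(r, p)
        assert np.all(np.diff(a) < 0)

    def test_negative_separation_rejected(self):
        with pytest.raises(ValueError):
            affinity(-0.1, preset("table1-3bead"))


class TestRateMatrix:
    def test_three_bead_structure(self, rng):
        """The 4x4 generator has the published symbolic structure."""
        p = preset("table1-3bead")
        pos = rng.normal(size=(3, 2))
        S = transition_rate_matrix(pos, p, include_timescale=False)
        a01 = affinity(np.linalg.norm(pos[0] - pos[1]), p)
        a02 = affinity(np.linalg.norm(pos[0] - pos[2]), p)
        a12 = affinity(np.linalg.norm(pos[1] - pos[2]), p)
        c = p.c_break
        expect = np.array([
            [-(a01 + a02 + a12), c, c, c],
            [a01, -c, 0, 0],
            [a02, 0, -c, 0],
            [a12, 0, 0, -c],
        ])
        assert np.allclose(S, expect, atol=1e-14)

    def test_columns_sum_to_zero_and_timescale(self, rng):
        p = preset("table1-3bead", timescale=7.0)
        pos = rng.normal(size=(3, 2))
        S = transition_rate_matrix(pos, p)
        assert np.abs(S.sum(axis=0)).max() < 1e-12
        S1 = transition_rate_matrix(pos, p.with_(timescale=1.0))
        assert np.allclose(S, 7.0 * S1)

    def test_equilateral_symmetry(self):
        p = preset("table1-3bead")
        pos = equilateral(1.0)
        S = transition_rate_matrix(pos, p, include_timescale=False)
        a = affinity(1.0, p)
        assert np.allclose(S[1:, 0], a)

    def test_five_bead_generator_is_valid(self, rng):
        p = preset("table1-3bead", n_beads=5)
        pos = rng.normal(size=(5, 2))
        S = transition_rate_matrix(pos, p)
        assert S.shape == (26, 26)
        off = S - np.diag(np.diag(S))
        assert off.min() >= 0
        assert np.abs(S.sum(axis=0)).max() < 1e-12


class TestStationary:
    def test_equilateral_closed_form(self):
        p = preset("table1-3bead")
        ell = 1.0
        S = transition_rate_matrix(equilateral(ell), p)
        a, c = affinity(ell, p), p.c_break
        r = stationary_distribution(S)
        assert np.allclose(r, np.array([c, a, a, a]) / (c + 3 * a), atol=1e-10)
        assert np.abs(S @ r).max() < 1e-10
        assert r.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.1, 1.0, 10.0])
    def test_scaling_invariance(self, alpha, rng):
        p = preset("table1-3bead")
        S = transition_rate_matrix(rng.normal(size=(3, 2)), p)
        r1 = stationary_distribution(S)
        r2 = stationary_distribution(alpha * S)
        assert np.abs(r1 - r2).max() < 1e-12

    def test_two_state_detailed_balance(self):
        k12, k21 = 0.3, 1.7   # rate out of 1, rate out of 2
        S = np.array([[-k12, k21], [k12, -k21]])
        r = stationary_distribution(S)
        assert np.allclose(r, [k21 / (k12 + k21), k12 / (k12 + k21)])

    def test_degenerate_generator_rejected(self):
        # two disconnected 2-state chains: two stationary directions
        S = np.zeros((4, 4))
        S[0, 1] = S[1, 0] = 1.0
        S[2, 3] = S[3, 2] = 1.0
        S -= np.diag(S.sum(axis=0))
        with pytest.raises(ValueError):
            stationary_distribution(S)


class TestSampleEvents:
    def test_zero_rates_leave_state_unchanged(self, rng):
        p = preset("table1-3bead").with_(affinity_amplitude=0.0, c_break=0.0)
        pos = np.zeros((3, 2))
        partner = np.array([1, 0, UNBOUND])
        out = sample_events(pos, partner, p, dt=0.01, rng=rng)
        assert np.array_equal(out, partner)

    def test_distant_beads_never_bind(self, rng):
        p = preset("table1-3bead")
        pos = 100.0 * np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        partner = np.full(3, UNBOUND)
        for _ in range(200):
            partner = sample_events(pos, partner, p, dt=0.01, rng=rng)
        assert np.all(partner == UNBOUND)

    def test_break_times_exponential_ks(self, rng):
        """Single-bond lifetimes follow Exponential(R c) (KS test)."""
        p = preset("table1-3bead", n_beads=2, timescale=2.0, epsilon=0.5,
                   scaling_exponent=1).with_(affinity_amplitude=0.0)
        R = p.rate_multiplier           # 4.0
        rate = R * p.c_break            # 2.0
        dt = 0.02                       # rate*dt = 0.04
        pos = np.zeros((2, 2))
        n = 3000
        lifetimes = []
        partner = np.array([1, 0])
        steps = 0
        while len(lifetimes) < n:
            steps += 1
            out = sample_events(pos, partner, p, dt, rng)
            if out[0] == UNBOUND:
                lifetimes.append(steps * dt)
                partner = np.array([1, 0])
                steps = 0
        stat, _ = stats.kstest(lifetimes, "expon", args=(0, 1 / rate))
        # thinning discretizes the exponential to a geometric on a dt grid;
        # its KS distance from the exponential is ~rate*dt/2
        assert stat < 0.05

    def test_result_is_valid_matching(self, rng):
        p = preset("table1-3bead", n_beads=6, timescale=10.0, epsilon=1.0,
                   scaling_exponent=0)
        pos = 0.05 * rng.normal(size=(6, 2))
        partner = np.full(6, UNBOUND)
        ever_bound = False
        for _ in range(100):
            partner = sample_events(pos, partner, p, dt=0.01, rng=rng)
            BindingState(tuple(int(v) for v in partner))  # validates
            ever_bound = ever_bound or np.any(partner != UNBOUND)
        # beads this close at these rates must bind at some point
        assert ever_bound

    def test_rate_resolution_warning(self, rng):
        p = preset("table1-3bead", timescale=100.0, scaling_exponent=0)
        pos = np.zeros((3, 2))
        with pytest.warns(RateResolutionWarning):
            sample_events(pos, np.full(3, UNBOUND), p, dt=0.1, rng=rng)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matching_validity_property(self, seed):
        rng = np.random.default_rng(seed)
        p = preset("table1-3bead", n_beads=5, timescale=5.0, epsilon=1.0,
                   scaling_exponent=0)
        pos = 0.2 * rng.normal(size=(5, 2))
        partner = np.full(5, UNBOUND)
        for _ in range(20):
            partner = sample_events(pos, partner, p, dt=5e-3, rng=rng)
        BindingState(tuple(int(v) for v in partner))


class TestOccupationFractions:
    def test_frozen_positions_ctmc_converges_to_stationary(self):
        """Occupation fractions of a long frozen-bead chain match the null vector.

        Positions are frozen by zeroing all forces and making thermal motion
        negligible; ~1e6 binding/unbinding events are sampled through the
        compiled simulator.
        """
        from switchbead.simulate import simulate

        p = preset("table1-3bead", timescale=5.0, epsilon=1e-12,
                   scaling_exponent=0).with_(eta=0.0, a_ev=0.0, kappa=0.0)
        pos = equilateral(0.8)
        S = transition_rate_matrix(pos, p)
        r_exact = stationary_distribution(S)
        traj = simulate(p, T=2e5, dt=0.01, seed=2024, initial=pos,
                        record_every=10)
        idx = traj.state_indices()
        occupancy = np.bincount(idx, minlength=4) / idx.size
        tv = 0.5 * np.abs(occupancy - r_exact).sum()
        assert tv < 0.02
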