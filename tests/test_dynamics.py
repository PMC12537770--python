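"""Derivative fields, batch integration and serial-transfer protocols."""

import numpy as np
import pytest

from lvtrio import (
    CommunityState,
    InteractionMatrix,
    SpeciesParams,
    derivatives_classic,
    derivatives_freqdep,
    doublings_per_cycle,
    integrate_batch,
    simulate_invasion,
    simulate_serial_transfer,
    total_generations,
)
from lvtrio.growth import logistic


def hand_rates(N, r, K, A, freqdep):
    """Independent scalar evaluation of the model equations.

    Written directly from the per-species formulas, one term at a time,
    as a cross-check on the vectorized implementation.
    """
    out = []
    total = sum(N)
    for i in range(3):
        crowd = N[i]
        for j in range(3):
            if j == i:
                continue
            if freqdep:
                weight = N[j] / total if total > 0 else 0.0
                crowd += A[i][j] * weight * N[j]
            else:
                crowd += A[i][j] * N[j]
        out.append(N[i] * r[i] * (1.0 - crowd / K[i]))
    return np.array(out)


UNIFORM_HALF = [[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]


class TestDerivatives:
    def test_classic_logistic_limit(self, community):
        # all alpha = 0 and N_E = K_E/2 gives the logistic maximum r*K/4
        state = CommunityState(0.0, 5e8, 0.0, 0.0)
        rates = derivatives_classic(state, community, InteractionMatrix())
        assert rates[0] == pytest.approx(0.7 * 1e9 / 4)
        assert rates[1] == 0.0 and rates[2] == 0.0

    def test_classic_equilibrium_at_K(self, community):
        state = CommunityState(0.0, 1e9, 0.0, 0.0)
        rates = derivatives_classic(state, community, InteractionMatrix())
        assert rates[0] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("freqdep", [False, True])
    def test_matches_hand_evaluation(self, community, freqdep):
        """Vectorized rates equal a term-by-term scalar evaluation."""
        alphas = InteractionMatrix(
            alpha_EY=0.5, alpha_EB=0.5, alpha_YE=0.5,
            alpha_YB=0.5, alpha_BE=0.5, alpha_BY=0.5,
        )
        state = CommunityState(0.0, 1e7, 1e7, 1e7)
        fn = derivatives_freqdep if freqdep else derivatives_classic
        got = fn(state, community, alphas)
        want = hand_rates(
            [1e7, 1e7, 1e7], [0.7, 0.35, 0.6], [1e9, 1e8, 1e9],
            UNIFORM_HALF, freqdep,
        )
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_freqdep_frozen_point(self, community):
        """Frozen values from an independent symbolic evaluation."""
        alphas = InteractionMatrix(
            alpha_EY=0.5, alpha_EB=0.5, alpha_YE=0.5,
            alpha_YB=0.5, alpha_BE=0.5, alpha_BY=0.5,
        )
        state = CommunityState(0.0, 1e7, 1e7, 1e7)
        got = derivatives_freqdep(state, community, alphas)
        # dE = 1e7*0.7*(1 - (1e7 + 2*(1/3)*0.5*1e7)/1e9), etc.
        np.testing.assert_allclose(
            got, [6906666.666666667, 3033333.3333333333, 5920000.0], rtol=1e-12
        )
        got_c = derivatives_classic(state, community, alphas)
        np.testing.assert_allclose(got_c, [6860000.0, 2800000.0, 5880000.0], rtol=1e-12)

    def test_models_coincide_at_zero_alpha(self, community):
        state = CommunityState(0.0, 3e6, 8e6, 1e5)
        a0 = InteractionMatrix()
        np.testing.assert_allclose(
            derivatives_classic(state, community, a0),
            derivatives_freqdep(state, community, a0),
        )

    def test_freqdep_reduces_to_pair_when_B_absent(self, community):
        """With N_B = 0 the E and Y equations lose every B term."""
        alphas = InteractionMatrix(
            alpha_EY=0.3, alpha_EB=2.5, alpha_YE=0.2,
            alpha_YB=2.5, alpha_BE=2.5, alpha_BY=2.5,
        )
        no_b_terms = InteractionMatrix(alpha_EY=0.3, alpha_YE=0.2)
        state = CommunityState(0.0, 4e6, 2e6, 0.0)
        np.testing.assert_allclose(
            derivatives_freqdep(state, community, alphas),
            derivatives_freqdep(state, community, no_b_terms),
        )

    def test_zero_total_population_rates_are_zero(self, community):
        state = CommunityState(0.0, 0.0, 0.0, 0.0)
        alphas = InteractionMatrix(alpha_EY=1.0)
        assert derivatives_freqdep(state, community, alphas).tolist() == [0, 0, 0]


def rk4_endpoint(model, params, alphas, t_end, dt=0.001):
    """Fixed-step fourth-order Runge-Kutta oracle, independent of scipy."""
    from lvtrio.dynamics import _RHS, _unpack

    r, K = _unpack(params)
    A = alphas.as_matrix()
    rhs = _RHS[model]
    order = {p.role: p for p in params}
    y = np.array([order[s].N0 for s in ("E", "Y", "B")], dtype=float)
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        k1 = rhs(y, r, K, A)
        k2 = rhs(y + 0.5 * dt * k1, r, K, A)
        k3 = rhs(y + 0.5 * dt * k2, r, K, A)
        k4 = rhs(y + dt * k3, r, K, A)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


class TestIntegrateBatch:
    def test_closed_form_logistic_at_zero_alpha(self, community):
        traj = integrate_batch("classic", community, InteractionMatrix(), 24.0)
        end = traj.populations[-1]
        for i, (r, K, N0) in enumerate([(0.7, 1e9, 1e7), (0.35, 1e8, 1e7), (0.6, 1e9, 1e7)]):
            expected = logistic(24.0, K, r, N0)
            assert end[i] == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("model", ["classic", "freqdep"])
    def test_agrees_with_rk4_oracle(self, community, model):
        alphas = InteractionMatrix(
            alpha_EY=0.8, alpha_EB=0.2, alpha_YE=1.5,
            alpha_YB=0.7, alpha_BE=0.4, alpha_BY=0.1,
        )
        traj = integrate_batch(model, community, alphas, 24.0)
        oracle = rk4_endpoint(model, community, alphas, 24.0)
        np.testing.assert_allclose(
            traj.populations[-1], oracle, rtol=1e-4, atol=1e-3
        )

    def test_rk4_oracle_battery(self, rng):
        """Endpoint equivalence on a seeded random parameter battery."""
        for _ in range(5):
            params = tuple(
                SpeciesParams(
                    role=s,
                    r=float(rng.uniform(0.2, 1.0)),
                    K=float(rng.uniform(5e7, 2e9)),
                    N0=float(rng.uniform(1e5, 5e7)),
                )
                for s in ("E", "Y", "B")
            )
            alphas = InteractionMatrix(
                **{k: float(rng.uniform(0, 2)) for k in (
                    "alpha_EY", "alpha_EB", "alpha_YE",
                    "alpha_YB", "alpha_BE", "alpha_BY",
                )}
            )
            traj = integrate_batch("freqdep", params, alphas, 24.0)
            oracle = rk4_endpoint("freqdep", params, alphas, 24.0)
            np.testing.assert_allclose(
                traj.populations[-1], oracle, rtol=1e-4,
                atol=1e-6 * max(p.K for p in params),
            )

    def test_absent_species_stays_absent(self):
        params = tuple(
            SpeciesParams(role=s, r=r, K=1e9, N0=n0)
            for s, r, n0 in [("E", 0.7, 1e7), ("Y", 0.35, 1e7), ("B", 0.6, 0.0)]
        )
        alphas = InteractionMatrix(alpha_BE=0.01, alpha_BY=0.01)
        traj = integrate_batch("freqdep", params, alphas, 24.0)
        assert (traj.populations[:, 2] == 0.0).all()

    def test_nonnegativity_and_boundedness(self, community):
        """Competition only depresses growth: 0 <= N <= max(N0, K)."""
        alphas = InteractionMatrix(
            alpha_EY=3.0, alpha_EB=3.0, alpha_YE=3.0,
            alpha_YB=3.0, alpha_BE=3.0, alpha_BY=3.0,
        )
        traj = integrate_batch("freqdep", community, alphas, 24.0)
        assert (traj.populations >= 0).all()
        caps = np.array([max(p.N0, p.K) for p in traj.params])
        assert (traj.populations <= caps * (1 + 1e-6)).all()

    def test_rejects_bad_inputs(self, community):
        with pytest.raises(ValueError):
            integrate_batch("classic", community, InteractionMatrix(), t_end=-1.0)
        with pytest.raises(ValueError):
            integrate_batch("gompertz", community, InteractionMatrix(), 24.0)


class TestSerialTransfer:
    def test_single_species_regrows_to_K_each_cycle(self):
        params = tuple(
            SpeciesParams(role=s, r=r, K=K, N0=n0)
            for s, r, K, n0 in [("E", 0.7, 1e9, 1e7), ("Y", 0.35, 1e8, 0.0), ("B", 0.6, 1e9, 0.0)]
        )
        trajs = simulate_serial_transfer(
            "classic", params, InteractionMatrix(), n_cycles=3
        )
        for traj in trajs:
            assert traj.populations[-1, 0] == pytest.approx(1e9, rel=1e-3)

    def test_dilution_conservation(self, community, weak_alphas):
        trajs = simulate_serial_transfer(
            "freqdep", community, weak_alphas, n_cycles=3, dilution_factor=2**-10
        )
        for prev, nxt in zip(trajs, trajs[1:]):
            np.testing.assert_array_equal(
                prev.populations[-1] * 2**-10, nxt.populations[0]
            )

    def test_no_dilution_is_continuous(self, community, weak_alphas):
        trajs = simulate_serial_transfer(
            "freqdep", community, weak_alphas, n_cycles=2, dilution_factor=1.0
        )
        np.testing.assert_array_equal(
            trajs[0].populations[-1], trajs[1].populations[0]
        )

    def test_equilibrium_frequency_independent_of_starting_ratio(self):
        """E-Y pairs started 1:10 and 10:1 converge to the same frequency.

        Mutual invasibility from rare: with weak interactions both species
        reach the same stable equilibrium frequency regardless of
        inoculation ratio, within 1% after at most 7 daily cycles.
        """
        def pair(n_e, n_y):
            return tuple(
                SpeciesParams(role=s, r=r, K=K, N0=n0)
                for s, r, K, n0 in [
                    ("E", 0.7, 1e9, n_e), ("Y", 0.35, 1e8, n_y), ("B", 0.6, 1e9, 0.0),
                ]
            )

        alphas = InteractionMatrix(alpha_EY=0.01, alpha_YE=0.01)
        freqs = []
        for n_e, n_y in [(1e6, 1e7), (1e7, 1e6)]:
            trajs = simulate_serial_transfer(
                "freqdep", pair(n_e, n_y), alphas, n_cycles=7
            )
            end = trajs[-1].populations[-1]
            freqs.append(end[0] / (end[0] + end[1]))
        assert abs(freqs[0] - freqs[1]) < 0.01

    def test_generation_arithmetic(self):
        assert doublings_per_cycle(2**-10) == pytest.approx(10.0)
        assert total_generations(7, 2**-10) == pytest.approx(70.0)


class TestInvasion:
    def test_zero_density_invasion_matches_pair_transfer(self, community, weak_alphas):
        pair = tuple(p for p in community if p.role in ("E", "Y"))
        invader = next(p for p in community if p.role == "B")
        result = simulate_invasion(
            "freqdep", pair, weak_alphas, invader,
            equilibration_cycles=3, total_cycles=6, invader_density=0.0,
        )
        from dataclasses import replace

        params = tuple(
            replace(p, N0=0.0) if p.role == "B" else p for p in community
        )
        ref = simulate_serial_transfer(
            "freqdep", params, weak_alphas, n_cycles=6
        )
        for a, b in zip(result.cycles, ref):
            np.testing.assert_allclose(a.populations, b.populations, rtol=1e-8)

    def test_no_equilibration_equals_three_species_transfer(self, community, weak_alphas):
        pair = tuple(p for p in community if p.role in ("E", "Y"))
        invader = next(p for p in community if p.role == "B")
        result = simulate_invasion(
            "freqdep", pair, weak_alphas, invader,
            equilibration_cycles=0, total_cycles=3, invader_density=invader.N0,
        )
        ref = simulate_serial_transfer("freqdep", community, weak_alphas, n_cycles=3)
        assert result.introduction_cycle == 0
        for a, b in zip(result.cycles, ref):
            np.testing.assert_allclose(a.populations, b.populations, rtol=1e-10)

    def test_strongly_suppressed_invader_goes_extinct(self, community):
        """alpha_BE = 3 (E suppresses B): invader extinct within 2 cycles."""
        from lvtrio import classify_simulation

        alphas = InteractionMatrix(
            alpha_EY=0.01, alpha_EB=0.01, alpha_YE=0.01,
            alpha_YB=0.01, alpha_BE=3.0, alpha_BY=0.01,
        )
        pair = tuple(p for p in community if p.role in ("E", "Y"))
        invader = next(p for p in community if p.role == "B")
        result = simulate_invasion(
            "freqdep", pair, alphas, invader,
            equilibration_cycles=3, total_cycles=6,
        )
        post = result.cycles[result.introduction_cycle + 1]
        label = classify_simulation(post.end_state)
        assert "B" in label.extinct_set
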