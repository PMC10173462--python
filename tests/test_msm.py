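import numpy as np
import pytest

from permcycle.msm import (
    build_msm,
    chapman_kolmogorov,
    count_transitions,
    net_fluxes,
    spectral_analysis,
    stationary_distribution,
    transition_matrix,
)
from permcycle.occupancy import StateTrajectory
from permcycle.synthetic import generate_markov_sequence

A, B, C = "00K0KW", "0CK0KW", "0KK0KW"  # shorthand codes


def _traj(codes, dt=20.0, jumps=None):
    return StateTrajectory(states=codes, frame_interval=dt, jumps=jumps)


class TestCounting:
    def test_sliding_window_lag1(self):
        Cm, states = count_transitions(_traj([A, B, A, B]), 20.0)
        assert states == [A, B]
        assert Cm.tolist() == [[0, 2], [1, 0]]

    def test_lag2(self):
        Cm, _ = count_transitions(_traj([A, B, A, B]), 40.0)
        assert Cm.tolist() == [[1, 0], [0, 1]]

    def test_pooling_adds(self):
        t = _traj([A, B, A, B])
        C1, _ = count_transitions(t, 20.0)
        C2, _ = count_transitions([t, t], 20.0)
        assert np.array_equal(C2, 2 * C1)

    def test_non_multiple_lag_raises(self):
        with pytest.raises(ValueError, match="multiple"):
            count_transitions(_traj([A, B]), 30.0)

    def test_short_trajectory_warns(self):
        with pytest.warns(UserWarning, match="shorter"):
            Cm, _ = count_transitions(_traj([A, B]), 60.0)
        assert Cm.sum() == 0


class TestTransitionMatrix:
    def test_row_normalization(self):
        model = transition_matrix(np.array([[8, 2], [1, 9]]), [A, B])
        assert np.allclose(model.transition_matrix, [[0.8, 0.2], [0.1, 0.9]])
        assert np.allclose(model.transition_matrix.sum(axis=1), 1.0)

    def test_zero_row_pruned(self):
        Cm = np.array([[5, 5, 1], [10, 0, 2], [0, 0, 0]])
        with pytest.warns(UserWarning, match="pruning"):
            model = transition_matrix(Cm, [A, B, C])
        assert model.states == [A, B]
        assert np.allclose(model.transition_matrix.sum(axis=1), 1.0)

    def test_all_pruned_raises(self):
        with pytest.raises(ValueError, match="pruning|no states"), \
                pytest.warns(UserWarning):
            transition_matrix(np.zeros((2, 2), dtype=int), [A, B])


class TestSpectral:
    def test_identity_all_infinite(self):
        lam, times = spectral_analysis(np.eye(2), 20.0)
        assert np.allclose(np.abs(lam), 1.0)
        assert np.all(np.isinf(times))

    def test_two_state_closed_form(self):
        lam, times = spectral_analysis([[0.7, 0.3], [0.3, 0.7]], 20.0)
        assert lam[1].real == pytest.approx(0.4, abs=1e-12)
        assert times[1] == pytest.approx(-20.0 / np.log(0.4), rel=1e-12)

    def test_cyclic_permutation_norm_rule(self):
        # 3-cycle: complex eigenvalues on the unit circle -> infinite times
        T = np.roll(np.eye(3), 1, axis=1)
        lam, times = spectral_analysis(T, 20.0)
        assert np.allclose(np.abs(lam), 1.0)
        assert np.all(np.isinf(times))
        assert np.iscomplex(lam).any()

    def test_rejects_non_stochastic(self):
        with pytest.raises(ValueError, match="stochastic"):
            spectral_analysis([[0.5, 0.4], [0.3, 0.7]], 20.0)


class TestStationary:
    def test_symmetric_chain_uniform(self):
        rho = stationary_distribution([[0.7, 0.3], [0.3, 0.7]])
        assert np.allclose(rho, [0.5, 0.5])

    def test_hand_solved_example(self):
        rho = stationary_distribution([[0.9, 0.1], [0.5, 0.5]])
        assert np.allclose(rho, [5 / 6, 1 / 6])

    def test_reducible_raises_with_classes(self):
        T = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="communicating classes"):
            stationary_distribution(T)

    def test_agrees_with_left_eigenvector(self, rng):
        from conftest import random_stochastic

        T = random_stochastic(rng, 5)
        rho = stationary_distribution(T)
        assert np.allclose(rho @ T, rho, atol=1e-9)
        assert rho.sum() == pytest.approx(1.0)


class TestNetFluxes:
    def test_antisymmetry(self, rng):
        from conftest import random_stochastic

        T = random_stochastic(rng, 4)
        F = net_fluxes(T, stationary_distribution(T))
        assert np.allclose(F + F.T, 0.0, atol=1e-15)
        assert np.allclose(np.diag(F), 0.0)

    def test_detailed_balance_zero(self):
        # birth-death chains are reversible
        T = np.array([[0.5, 0.5, 0.0], [0.25, 0.5, 0.25], [0.0, 0.5, 0.5]])
        F = net_fluxes(T, stationary_distribution(T))
        assert np.allclose(F, 0.0, atol=1e-12)

    def test_forced_cycle_constant_flux(self):
        T = np.roll(np.eye(3), 1, axis=1)
        rho = np.full(3, 1 / 3)
        F = net_fluxes(T, rho)
        for i in range(3):
            assert F[i, (i + 1) % 3] == pytest.approx(1 / 3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="match"):
            net_fluxes(np.eye(2), np.ones(3) / 3)


class TestChapmanKolmogorov:
    def test_markovian_data_small_deviation(self, rng):
        from conftest import random_stochastic

        T = random_stochastic(rng, 4)
        traj = generate_markov_sequence(T, 50_000, seed=5)
        res = chapman_kolmogorov(traj, 20.0, [2, 3])
        assert all(d < 0.02 for d in res.deviations)
        assert res.curves  # self-transition curves available for plotting

    def test_lumped_chain_fails(self):
        # deterministic 3-cycle observed through a 2-state lens: strongly
        # non-Markovian at the observed level
        codes = {0: A, 1: B, 2: B}
        seq = [codes[t % 3] for t in range(3000)]
        res = chapman_kolmogorov(_traj(seq), 20.0, [2], count_floor=50)
        assert res.deviations[0] > 0.05

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            chapman_kolmogorov(_traj([A, B] * 100), 20.0, [1])


def test_parameter_recovery_six_state(rng):
    from conftest import random_stochastic

    T = random_stochastic(rng, 6)
    traj = generate_markov_sequence(T, 100_000, seed=7)
    model = build_msm(traj, 20.0)
    assert np.abs(model.transition_matrix - T).max() < 0.02
    assert np.abs(model.stationary - stationary_distribution(T)).max() < 0.01


def test_implied_timescale_lag_stability(rng):
    """On Markovian data t_2 estimated at tau and 2 tau must agree."""
    from conftest import random_stochastic

    T = random_stochastic(rng, 4)
    traj = generate_markov_sequence(T, 100_000, seed=9)
    m1 = build_msm(traj, 20.0)
    m2 = build_msm(traj, 40.0)
    t2_1, t2_2 = m1.relaxation_times[1], m2.relaxation_times[1]
    assert abs(t2_1 - t2_2) / t2_1 < 0.15


def test_model_json_roundtrip(tmp_path, rng):
    from conftest import random_stochastic
    from permcycle.msm import TransitionModel

    T = random_stochastic(rng, 3)
    traj = generate_markov_sequence(T, 5000, seed=1)
    model = build_msm(traj, 20.0)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = TransitionModel.from_json(path)
    assert back.states == model.states
    assert np.allclose(back.transition_matrix, model.transition_matrix)
    assert np.allclose(back.stationary, model.stationary)
    assert np.allclose(back.eigenvalues, model.eigenvalues)
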