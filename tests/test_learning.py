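"""Objective, analytic gradients and the training schedule."""

import numpy as np
import pytest

from emnet import (
    LearningConfig,
    NetworkParams,
    StimulusModel,
    calibrate_normalization,
    default_schedule,
    gradients,
    init_feedforward_tonotopic,
    jacobian_chi,
    objective,
    run_schedule,
    sigmoid_attenuation,
    spectral_radius,
    steady_state_newton,
    train_phase,
)
from conftest import make_random_network


def finite_difference_directions(params, x, config, eps=1e-5, tol=1e-13):
    """Central finite differences of the objective: the gradient oracle."""
    fd = {}
    for name, arr in (("W", params.W), ("K", params.K), ("T", params.T)):
        grad = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            fp, _, _ = objective(params, x, config, newton_tol=tol)
            arr[idx] = orig - eps
            fm, _, _ = objective(params, x, config, newton_tol=tol)
            arr[idx] = orig
            grad[idx] = -(fp - fm) / (2 * eps)  # descent direction
        fd[name] = grad
    return fd


class TestJacobian:
    def test_no_recurrence_reduces_to_gain_times_w(self):
        params, x = make_random_network(0)
        params.K[:] = 0.0
        steady = steady_state_newton(params, x, tol=1e-13)
        chi, phi = jacobian_chi(params, steady)
        np.testing.assert_allclose(phi, np.diag(steady.gain), atol=1e-14)
        np.testing.assert_allclose(chi, np.diag(steady.gain) @ params.W, atol=1e-14)

    def test_scalar_network_closed_form(self):
        w, k = 0.8, 1.5
        params = NetworkParams(np.array([[w]]), np.array([[k]]), np.zeros(1))
        x = np.array([0.2])
        steady = steady_state_newton(params, x, tol=1e-14)
        chi, _ = jacobian_chi(params, steady)
        g1 = steady.gain[0]
        assert chi[0, 0] == pytest.approx(g1 * w / (1 - g1 * k), rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_chi_matches_steady_state_sensitivity(self, seed):
        # chi_ij must equal the finite-difference derivative ds_i/dx_j
        params, x = make_random_network(seed, m=4, n=8)
        steady = steady_state_newton(params, x, tol=1e-14)
        chi, _ = jacobian_chi(params, steady)
        eps = 1e-6
        for j in range(4):
            dx = np.zeros(4)
            dx[j] = eps
            sp = steady_state_newton(params, x + dx, tol=1e-14).s
            sm = steady_state_newton(params, x - dx, tol=1e-14).s
            np.testing.assert_allclose(chi[:, j], (sp - sm) / (2 * eps), atol=1e-6)


class TestObjective:
    def test_scalar_closed_form(self):
        # 1x1 net at the sigmoid midpoint: chi = 1/4, entropy term = -log(1/4)
        params = NetworkParams(np.array([[1.0]]), np.zeros((1, 1)), np.zeros(1))
        config = LearningConfig(lambda_w=0.0, lambda_k=0.0)
        total, ent, (reg_w, reg_k) = objective(params, np.array([[0.0]]), config)
        assert ent == pytest.approx(1.3862943611198906, rel=1e-12)
        assert reg_w == 0.0 and reg_k == 0.0
        assert total == ent

    def test_regularization_terms_match_norms(self):
        params, x = make_random_network(1)
        config = LearningConfig(lambda_w=0.01, lambda_k=0.05, ff_norm="l1", rec_norm="l2")
        _, _, (reg_w, reg_k) = objective(params, x, config)
        assert reg_w == pytest.approx(0.01 * np.abs(params.W).sum())
        assert reg_k == pytest.approx(0.025 * (params.K**2).sum())

    def test_entropy_term_decreases_toward_criticality(self):
        # balanced Mexican-hat recurrence, as training produces: the
        # susceptibility grows as the scale approaches critical while the
        # gains stay put, so the entropy term falls monotonically
        n = 12
        idx = np.arange(n)
        dist = np.minimum(np.abs(idx[:, None] - idx[None, :]), n - np.abs(idx[:, None] - idx[None, :]))
        K = np.exp(-dist**2 / 8.0) - 0.5 * np.exp(-dist**2 / 50.0)
        np.fill_diagonal(K, 0.0)
        K /= spectral_radius(K)
        rng = np.random.default_rng(2)
        params = NetworkParams(rng.normal(0, 0.5, (n, 4)), K, np.zeros(n))
        x = rng.uniform(0, 0.5, 4)
        config = LearningConfig(lambda_w=0.0, lambda_k=0.0)
        ents = []
        for sigma in (0.5, 2.0, 3.5):
            scaled = params.copy()
            scaled.K = sigma * K
            _, ent, _ = objective(scaled, x, config)
            ents.append(ent)
        assert ents[0] > ents[1] > ents[2]


class TestGradients:
    @pytest.mark.parametrize("norms", [("l1", "l2"), ("l2", "l1")])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_match_finite_differences(self, seed, norms):
        params, x = make_random_network(seed, m=3, n=6)
        config = LearningConfig(
            eta=1.0, lambda_w=0.01, lambda_k=0.05,
            ff_norm=norms[0], rec_norm=norms[1], newton_tol=1e-13,
        )
        steady = steady_state_newton(params, x, tol=1e-13)
        bundle = gradients(params, x, steady, config)
        fd = finite_difference_directions(params.copy(), x, config)
        for name, analytic in (("W", bundle.dW), ("K", bundle.dK), ("T", bundle.dT)):
            err = np.max(np.abs(analytic - fd[name])) / np.max(np.abs(analytic))
            assert err < 1e-5, f"{name} gradient mismatch: {err}"

    def test_symmetric_state_has_zero_y_and_dT(self):
        # all net inputs at 0 make g'' vanish, so y = 0 and dT = 0
        n = 6
        W = np.random.default_rng(0).normal(size=(n, 2))
        params = NetworkParams(W, np.zeros((n, n)), np.zeros(n))
        steady = steady_state_newton(params, np.zeros(2), tol=1e-14)
        config = LearningConfig(lambda_w=0.0, lambda_k=0.0)
        bundle = gradients(params, np.zeros(2), steady, config)
        np.testing.assert_allclose(bundle.y, 0.0, atol=1e-12)
        np.testing.assert_allclose(bundle.dT, 0.0, atol=1e-12)

    def test_entropy_free_recurrent_direction_is_weight_decay(self):
        params, x = make_random_network(4)
        config = LearningConfig(lambda_w=0.0, lambda_k=0.3, rec_norm="l2")
        steady = steady_state_newton(params, x, tol=1e-13)
        bundle = gradients(params, x, steady, config, include_entropy=False)
        np.testing.assert_allclose(bundle.dK, -0.3 * params.K, atol=1e-14)


class TestTonotopicInit:
    def test_zero_amplitude_gives_zero_weights(self):
        W, _ = init_feedforward_tonotopic(10, 40, amplitude=0.0)
        assert np.all(W == 0.0)

    def test_centers_ordered_and_peaks_aligned(self):
        W, T = init_feedforward_tonotopic(10, 40, amplitude=0.5, width=1.0)
        peaks = np.argmax(W, axis=1)
        assert np.all(np.diff(peaks) >= 0)
        centers = np.arange(1, 41) * 10 / 40
        channels = np.arange(1, 11, dtype=float)
        # nearest channel to each row's center, ties toward the lower channel
        expected = np.argmin(np.abs(channels[None, :] - centers[:, None]), axis=1)
        np.testing.assert_array_equal(peaks, expected)
        assert np.all(T == 0.0)

    def test_undercomplete_rejected(self):
        with pytest.raises(ValueError):
            init_feedforward_tonotopic(10, 5)


@pytest.fixture(scope="module")
def tiny_stimuli():
    model = StimulusModel(n_channels=6)
    return calibrate_normalization(model, 500, np.random.default_rng(0))


class TestTrainPhase:
    def test_all_frozen_config_rejected(self):
        with pytest.raises(ValueError):
            LearningConfig(train_W=False, train_K=False, train_T=False)

    def test_autapses_stay_zero(self, tiny_stimuli):
        params, _ = make_random_network(0, m=6, n=12, rho=1.0)
        config = LearningConfig(eta=0.01, lambda_k=0.1, n_iterations=50, trace_every=0)
        trained, _ = train_phase(params, config, tiny_stimuli, np.random.default_rng(1))
        np.testing.assert_array_equal(np.diag(trained.K), np.zeros(12))

    def test_frozen_matrices_untouched(self, tiny_stimuli):
        params, _ = make_random_network(1, m=6, n=12, rho=1.0)
        config = LearningConfig(eta=0.01, n_iterations=20, train_K=True, trace_every=0)
        trained, _ = train_phase(params, config, tiny_stimuli, np.random.default_rng(2))
        np.testing.assert_array_equal(trained.W, params.W)
        np.testing.assert_array_equal(trained.T, params.T)
        assert not np.array_equal(trained.K, params.K)

    def test_objective_settles_during_recurrent_training(self, tiny_stimuli):
        # smoothed single-sample objective over the last half of training is
        # no worse than over the second quarter (convergence, not divergence)
        W, T = init_feedforward_tonotopic(6, 24, amplitude=1.5, width=1.0)
        params = NetworkParams(W, np.zeros((24, 24)), T)
        config = LearningConfig(eta=0.005, lambda_k=0.1, n_iterations=6000, trace_every=50)
        trained, trace = train_phase(params, config, tiny_stimuli, np.random.default_rng(3))
        vals = trace["objective"].to_numpy()
        q = len(vals) // 4
        assert np.mean(vals[-2 * q:]) <= np.mean(vals[q:2 * q]) + 0.05

    def test_l1_recurrent_regularization_keeps_connectivity_sparse(self, tiny_stimuli):
        W, T = init_feedforward_tonotopic(6, 24, amplitude=1.5, width=1.0)
        params = NetworkParams(W, np.zeros((24, 24)), T)
        config = LearningConfig(
            eta=0.005, lambda_k=0.1, rec_norm="l1", n_iterations=4000, trace_every=0
        )
        trained, _ = train_phase(params, config, tiny_stimuli, np.random.default_rng(4))
        off_diag = trained.K[~np.eye(24, dtype=bool)]
        # subgradient descent keeps most weights oscillating within one step
        # of zero: "sparse" up to the step size eta * lambda_k
        near_zero = np.abs(off_diag) <= config.eta * config.lambda_k * 2
        assert near_zero.mean() > 0.9


class TestSchedule:
    def test_empty_schedule_returns_initial(self, tiny_stimuli):
        params, _ = make_random_network(5, m=6, n=12)
        out = run_schedule([], params, tiny_stimuli, np.random.default_rng(0))
        assert len(out) == 1
        np.testing.assert_array_equal(out[0][0].K, params.K)

    def test_phase1_keeps_recurrence_zero(self, tiny_stimuli):
        att = sigmoid_attenuation(3.0, 10.0, 6)
        schedule = default_schedule(att, phase1_iters=30, phase2_iters=10, phase3_iters=10)
        W, T = init_feedforward_tonotopic(6, 12)
        params = NetworkParams(W, np.zeros((12, 12)), T)
        out = run_schedule(schedule, params, tiny_stimuli, np.random.default_rng(1))
        assert len(out) == 3
        phase1 = out[0][0]
        assert np.all(phase1.K == 0.0)
        assert not np.array_equal(phase1.W, params.W)

    def test_no_pretraining_variant_has_two_phases(self):
        att = sigmoid_attenuation(3.0, 10.0, 6)
        schedule = default_schedule(att, include_phase2=False)
        assert [p.name for p in schedule] == ["phase1_feedforward", "phase3_deprived"]
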