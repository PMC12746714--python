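"""Core tPC network: energy, inference, learning and recall.

The numerical oracles here are independent of the implementation path:
hand-computed scalar cases, closed-form linear solves, and central finite
differences of the energy.
"""

import numpy as np
import pytest

from neural_asm import tpc
from neural_asm._kernels import settle_hidden, settle_hidden_np


def _net(n_obs, n_hidden, activation="tanh", seed=0, **kw):
    cfg = tpc.TPCConfig(n_obs=n_obs, n_hidden=n_hidden, activation=activation,
                        seed=seed, **kw)
    return tpc.TPCNetwork.init(cfg)


def _manual_net(W_H, W_F, activation="linear"):
    W_H = np.atleast_2d(np.asarray(W_H, dtype=float))
    W_F = np.atleast_2d(np.asarray(W_F, dtype=float))
    cfg = tpc.TPCConfig(n_obs=W_F.shape[0], n_hidden=W_H.shape[0],
                        activation=activation)
    return tpc.TPCNetwork(W_H=W_H, W_F=W_F, config=cfg)


def _energy_of(net, z, z_prev, x):
    return tpc.energy(tpc.StepState.compute(z, z_prev, x, net), net)


class TestEnergy:
    def test_zero_when_both_errors_vanish(self, small_net):
        z_prev = np.array([0.3, -0.2, 0.1, 0.5])
        z = small_net.W_H @ np.tanh(z_prev)
        x = small_net.W_F @ np.tanh(z)
        assert _energy_of(small_net, z, z_prev, x) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_linear_hand_case(self):
        # 1-d linear, W_H=W_F=1, z_prev=0, z=0.5, x=1: (0.5)^2 + (0.5)^2 = 0.5
        net = _manual_net([[1.0]], [[1.0]])
        val = _energy_of(net, np.array([0.5]), np.array([0.0]), np.array([1.0]))
        assert val == pytest.approx(0.5)

    def test_quadratic_scaling_of_errors(self, small_net):
        z_prev = np.array([0.4, 0.1, -0.3, 0.2])
        pred_z = small_net.W_H @ np.tanh(z_prev)
        z = pred_z + np.array([0.1, -0.2, 0.3, 0.05])
        pred_x = small_net.W_F @ np.tanh(z)
        x = pred_x + np.array([0.2, -0.1, 0.4])
        e1 = _energy_of(small_net, z, z_prev, x)
        # doubling both error vectors while holding predictions fixed
        st = tpc.StepState.compute(z, z_prev, x, small_net)
        e2_expected = 4 * e1
        e2 = float(2 * st.eps_z @ (2 * st.eps_z) + 2 * st.eps_x @ (2 * st.eps_x))
        assert e2 == pytest.approx(e2_expected)

    def test_shape_mismatch_raises(self, small_net):
        with pytest.raises(ValueError):
            tpc.energy(
                tpc.StepState(z=np.zeros(5), z_prev=np.zeros(4), x=np.zeros(3),
                              eps_z=np.zeros(5), eps_x=np.zeros(3), energy=0.0),
                small_net,
            )


class TestInferHidden:
    def test_zero_topdown_weights_keep_temporal_prediction(self):
        cfg = tpc.TPCConfig(n_obs=3, n_hidden=4, seed=2)
        net = tpc.TPCNetwork.init(cfg)
        net = tpc.TPCNetwork(W_H=net.W_H, W_F=np.zeros((3, 4)), config=cfg)
        z_prev = np.array([0.2, -0.4, 0.3, 0.1])
        z, _ = tpc.infer_hidden(np.ones(3), z_prev, net)
        np.testing.assert_allclose(z, net.W_H @ np.tanh(z_prev), atol=1e-12)

    def test_linear_matches_closed_form_solve(self, rng):
        # stationary point of the dynamics: (I + W_F^T W_F) z = W_H z_prev + W_F^T x
        cfg = tpc.TPCConfig(n_obs=3, n_hidden=4, activation="linear", seed=3)
        net = tpc.TPCNetwork.init(cfg)
        x = rng.normal(size=3)
        z_prev = rng.normal(size=4)
        z, _ = tpc.infer_hidden(x, z_prev, net, iters=5000, lr=0.05)
        expected = np.linalg.solve(
            np.eye(4) + net.W_F.T @ net.W_F, net.W_H @ z_prev + net.W_F.T @ x
        )
        np.testing.assert_allclose(z, expected, atol=1e-6)

    def test_update_direction_matches_finite_difference_gradient(self, small_net, rng):
        x = rng.normal(size=3)
        z_prev = rng.normal(size=4)
        z = rng.normal(size=4) * 0.5
        # analytic update direction: -eps_z + f'(z) * W_F^T eps_x = -grad F / 2
        st = tpc.StepState.compute(z, z_prev, x, small_net)
        analytic = -st.eps_z + (1 - np.tanh(z) ** 2) * (small_net.W_F.T @ st.eps_x)
        h = 1e-6
        fd = np.empty(4)
        for i in range(4):
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] -= h
            fd[i] = (_energy_of(small_net, zp, z_prev, x)
                     - _energy_of(small_net, zm, z_prev, x)) / (2 * h)
        np.testing.assert_allclose(analytic, -fd / 2, rtol=1e-4)

    def test_energy_non_increasing_within_inference(self, rng):
        for seed in range(3):
            net = _net(3, 6, seed=seed)
            x = rng.normal(size=3)
            z_prev = rng.normal(size=6)
            _, energies = tpc.infer_hidden(x, z_prev, net, iters=200, lr=1e-2)
            assert np.all(np.diff(energies) <= 1e-10)
            assert energies[-1] <= energies[0]

    def test_numba_and_numpy_engines_agree(self, small_net, rng):
        x = rng.normal(size=3)
        z_prev = rng.normal(size=4)
        z1, e1 = tpc.infer_hidden(x, z_prev, small_net, iters=50, engine="numba")
        z2, e2 = tpc.infer_hidden(x, z_prev, small_net, iters=50, engine="numpy")
        np.testing.assert_allclose(z1, z2, atol=1e-12)
        np.testing.assert_allclose(e1, e2, atol=1e-12)

    def test_divergent_lr_raises_naming_iteration(self, small_net):
        with pytest.raises(tpc.DivergenceError, match="iteration"):
            tpc.infer_hidden(np.full(3, 1e3), np.zeros(4), small_net,
                             iters=500, lr=50.0)


class TestUpdateWeights:
    def test_zero_errors_leave_weights_unchanged(self, small_net):
        z_prev = np.array([0.3, -0.2, 0.1, 0.5])
        z = small_net.W_H @ np.tanh(z_prev)
        x = small_net.W_F @ np.tanh(z)
        st = tpc.StepState.compute(z, z_prev, x, small_net)
        out = tpc.update_weights(st, small_net, lr=0.1)
        np.testing.assert_array_equal(out.W_H, small_net.W_H)
        np.testing.assert_array_equal(out.W_F, small_net.W_F)

    def test_scalar_outer_product_hand_case(self):
        # eps_z=0.5, f(z_prev)=0, eps_x=0.5, f(z)=0.5, lr=0.1:
        # dW_H = 0.1*0.5*0 = 0 ; dW_F = 0.1*0.5*0.5 = 0.025
        net = _manual_net([[1.0]], [[0.5]])
        z_prev = np.array([0.0])
        z = np.array([0.5])           # eps_z = 0.5 - 1*0 = 0.5
        x = np.array([0.75])          # eps_x = 0.75 - 0.5*0.5 = 0.5
        st = tpc.StepState.compute(z, z_prev, x, net)
        out = tpc.update_weights(st, net, lr=0.1)
        assert out.W_H[0, 0] == pytest.approx(1.0)
        assert out.W_F[0, 0] == pytest.approx(0.525)

    def test_update_equals_negative_weight_gradient(self, small_net, rng):
        x = rng.normal(size=3)
        z_prev = rng.normal(size=4)
        z = rng.normal(size=4) * 0.5
        st = tpc.StepState.compute(z, z_prev, x, small_net)
        lr = 1.0
        out = tpc.update_weights(st, small_net, lr=lr)
        h = 1e-6
        for W_name, delta in (("W_H", out.W_H - small_net.W_H),
                              ("W_F", out.W_F - small_net.W_F)):
            W = getattr(small_net, W_name)
            fd = np.empty_like(W)
            for i in range(W.shape[0]):
                for j in range(W.shape[1]):
                    for s, tgt in ((+h, "p"), (-h, "m")):
                        Wmod = W.copy()
                        Wmod[i, j] += s
                        net2 = tpc.TPCNetwork(
                            W_H=Wmod if W_name == "W_H" else small_net.W_H,
                            W_F=Wmod if W_name == "W_F" else small_net.W_F,
                            config=small_net.config)
                        val = _energy_of(net2, z, z_prev, x)
                        if tgt == "p":
                            fp = val
                        else:
                            fm = val
                    fd[i, j] = (fp - fm) / (2 * h)
            np.testing.assert_allclose(delta, -fd / 2, rtol=1e-4, atol=1e-9)


class TestMemorise:
    def test_zero_epochs_returns_model_unchanged(self, small_net):
        seqs = [np.zeros((4, 3))]
        out, curve = tpc.memorise(seqs, small_net, epochs=0)
        np.testing.assert_array_equal(out.W_H, small_net.W_H)
        assert curve.size == 0

    def test_empty_input_rejected(self, small_net):
        with pytest.raises(ValueError):
            tpc.memorise([], small_net)

    def test_constant_sequence_energy_non_increasing(self):
        cfg = tpc.TPCConfig(n_obs=3, n_hidden=8, activation="linear", seed=4)
        net = tpc.TPCNetwork.init(cfg)
        seq = np.tile(np.array([0.5, -0.3, 0.8]), (6, 1))
        _, curve = tpc.memorise([seq], net, epochs=50)
        assert np.all(np.diff(curve) <= 1e-9)

    def test_single_short_sequence_is_recallable(self, rng):
        # a 5-step sequence is memorised and reproduced from a 1-step cue
        seq = rng.normal(size=(5, 4))
        seq = (seq - seq.mean(0)) / seq.std(0)
        cfg = tpc.TPCConfig(n_obs=4, n_hidden=64, seed=5, weight_lr=1e-3)
        net = tpc.TPCNetwork.init(cfg)
        net, curve = tpc.memorise([seq], net, epochs=2000)
        assert curve[-1] < curve[0]
        res = tpc.offline_recall(net, seq[:1], 5)
        per_channel = ((res.predicted - seq) ** 2).mean(axis=0)
        assert np.all(per_channel < 0.1)


class TestRecall:
    def test_zero_weights_recall_zero(self):
        cfg = tpc.TPCConfig(n_obs=3, n_hidden=4)
        net = tpc.TPCNetwork(W_H=np.zeros((4, 4)), W_F=np.zeros((3, 4)), config=cfg)
        res = tpc.offline_recall(net, np.ones((1, 3)), 4)
        np.testing.assert_allclose(res.predicted, 0.0, atol=1e-12)

    def test_cue_length_must_be_shorter_than_horizon(self, small_net):
        with pytest.raises(ValueError):
            tpc.offline_recall(small_net, np.ones((4, 3)), 4)

    def test_cue_selects_matching_skill(self, rng):
        t_steps = 6
        base = np.linspace(0, 2 * np.pi, t_steps)
        skill_a = np.stack([np.sin(base), np.cos(base), base / 4 - 0.7], axis=1)
        skill_b = -skill_a[::-1]
        cfg = tpc.TPCConfig(n_obs=3, n_hidden=64, seed=6)
        net = tpc.TPCNetwork.init(cfg)
        net, _ = tpc.memorise([skill_a, skill_b], net, epochs=800)
        res = tpc.offline_recall(net, skill_a[:2], t_steps)
        mse_a = ((res.predicted - skill_a) ** 2).mean()
        mse_b = ((res.predicted - skill_b) ** 2).mean()
        assert mse_a < mse_b

    def test_online_recall_emits_one_prediction_for_two_steps(self, small_net):
        res = tpc.online_recall(small_net, np.ones((2, 3)) * 0.1)
        assert res.predicted.shape == (1, 3)
        assert res.energies.shape == (2,)

    def test_online_energies_match_recomputed_step_states(self, small_net, rng):
        obs = rng.normal(size=(5, 3)) * 0.5
        res = tpc.online_recall(small_net, obs)
        recomputed = [tpc.energy(st, small_net) for st in res.states]
        np.testing.assert_allclose(res.energies, recomputed, rtol=1e-10)

    def test_memorised_sequence_has_lower_energy_than_permuted(self, rng):
        seq = rng.normal(size=(8, 4))
        seq = (seq - seq.mean(0)) / seq.std(0)
        cfg = tpc.TPCConfig(n_obs=4, n_hidden=64, seed=7)
        net = tpc.TPCNetwork.init(cfg)
        net, _ = tpc.memorise([seq], net, epochs=500)
        e_train = tpc.online_recall(net, seq).energies[1:].mean()
        e_perm = tpc.online_recall(net, seq[:, [2, 0, 3, 1]]).energies[1:].mean()
        assert e_train < e_perm


class TestSerialisation:
    def test_round_trip_is_bit_exact(self, tmp_path, small_net):
        path = tmp_path / "net.npz"
        small_net.save(path, channels=["a", "b", "c"])
        loaded, channels = tpc.TPCNetwork.load(path)
        np.testing.assert_array_equal(loaded.W_H, small_net.W_H)
        np.testing.assert_array_equal(loaded.W_F, small_net.W_F)
        assert loaded.config == small_net.config
        assert channels == ["a", "b", "c"]

    def test_seeded_init_is_reproducible(self):
        a = _net(5, 7, seed=42)
        b = _net(5, 7, seed=42)
        np.testing.assert_array_equal(a.W_H, b.W_H)
        np.testing.assert_array_equal(a.W_F, b.W_F)


class TestKernels:
    def test_compiled_and_reference_settling_agree(self, rng):
        for act in (0, 1):
            a = rng.normal(size=6)
            W_F = rng.normal(size=(4, 6)) * 0.4
            x = rng.normal(size=4)
            z1, e1 = settle_hidden(a, W_F, np.ascontiguousarray(W_F.T), x, 40, 1e-2, act)
            z2, e2 = settle_hidden_np(a, W_F, x, 40, 1e-2, act)
            np.testing.assert_allclose(z1, z2, atol=1e-13)
            np.testing.assert_allclose(e1, e2, atol=1e-13)
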