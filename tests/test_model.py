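"""GCN layer, LSTM cell, full forward pass, gradients and training."""

import numpy as np
import pytest

from dynfcnet.graph_features import GraphSequence
from dynfcnet.model import (
    ModelConfig,
    TrainConfig,
    forward,
    gcn_layer_forward,
    init_params,
    load_checkpoint,
    loss_and_grads,
    lstm_cell_forward,
    predict,
    save_checkpoint,
    stratified_split,
    train,
)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def lstm_oracle(h_prev, c_prev, x, Wx, Wh, b):
    """Step-by-step independent evaluation of the gate equations."""
    H = h_prev.shape[-1]
    z = x @ Wx + h_prev @ Wh + b
    f = _sigmoid(z[..., :H])
    i = _sigmoid(z[..., H : 2 * H])
    g = np.tanh(z[..., 2 * H : 3 * H])
    o = _sigmoid(z[..., 3 * H :])
    c = f * c_prev + i * g
    return o * np.tanh(c), c


def _random_batch(rng, B=2, K=3, R=6, dtype=np.float64):
    adj = rng.random((B, K, R, R))
    adj = (adj + adj.transpose(0, 1, 3, 2)) / 2
    feats = rng.random((B, K, R))
    return adj.astype(dtype), feats.astype(dtype)


class TestGcnLayer:
    def test_identity_propagation(self, rng):
        H = rng.random((5, 3))
        out = gcn_layer_forward(H, np.eye(5), np.eye(3))
        np.testing.assert_allclose(out, H)

    def test_zero_features_give_zero(self, rng):
        out = gcn_layer_forward(np.zeros((4, 2)), rng.random((4, 4)), rng.random((2, 3)))
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            adj = rng.standard_normal((5, 5))
            H = rng.standard_normal((5, 3))
            W = rng.standard_normal((3, 4))
            expected = np.zeros((5, 4))
            for r in range(5):
                for o in range(4):
                    acc = 0.0
                    for j in range(5):
                        for d in range(3):
                            acc += adj[r, j] * H[j, d] * W[d, o]
                    expected[r, o] = max(acc, 0.0)
            np.testing.assert_allclose(gcn_layer_forward(H, adj, W), expected, atol=1e-10)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            gcn_layer_forward(rng.random((5, 3)), rng.random((4, 4)), rng.random((3, 2)))


class TestLstmCell:
    def test_all_zero_parameters(self):
        H, D = 4, 3
        h, c = lstm_cell_forward(
            np.zeros(H), np.zeros(H), np.zeros(D),
            np.zeros((D, 4 * H)), np.zeros((H, 4 * H)), np.zeros(4 * H),
        )
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)
        # gates sit at sigmoid(0) = 0.5: with C_prev = 1, C = f*1 + i*0 = 0.5
        h1, c1 = lstm_cell_forward(
            np.zeros(H), np.ones(H), np.zeros(D),
            np.zeros((D, 4 * H)), np.zeros((H, 4 * H)), np.zeros(4 * H),
        )
        np.testing.assert_allclose(c1, 0.5)
        np.testing.assert_allclose(h1, 0.5 * np.tanh(0.5))

    def test_saturated_forget_gate_keeps_cell_state(self, rng):
        H, D = 3, 2
        Wx = rng.standard_normal((D, 4 * H)) * 0.1
        Wh = rng.standard_normal((H, 4 * H)) * 0.1
        b = np.zeros(4 * H)
        b[:H] = 20.0  # forget gate ~ 1
        c_prev = rng.standard_normal(H)
        x = rng.standard_normal(D)
        h_prev = rng.standard_normal(H) * 0.1
        _, c = lstm_cell_forward(h_prev, c_prev, x, Wx, Wh, b)
        z = x @ Wx + h_prev @ Wh + b
        i = _sigmoid(z[H : 2 * H])
        g = np.tanh(z[2 * H : 3 * H])
        np.testing.assert_allclose(c, c_prev + i * g, atol=1e-6)

    def test_matches_independent_oracle(self, rng):
        for _ in range(10):
            H, D, B = 5, 4, 3
            Wx = rng.standard_normal((D, 4 * H))
            Wh = rng.standard_normal((H, 4 * H))
            b = rng.standard_normal(4 * H)
            h_prev = rng.standard_normal((B, H))
            c_prev = rng.standard_normal((B, H))
            x = rng.standard_normal((B, D))
            h, c = lstm_cell_forward(h_prev, c_prev, x, Wx, Wh, b)
            h_exp, c_exp = lstm_oracle(h_prev, c_prev, x, Wx, Wh, b)
            np.testing.assert_allclose(h, h_exp, atol=1e-12)
            np.testing.assert_allclose(c, c_exp, atol=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            lstm_cell_forward(
                np.zeros(3), np.zeros(3), np.zeros(2),
                np.zeros((5, 12)), np.zeros((3, 12)), np.zeros(12),
            )


class TestForward:
    def test_deterministic_inference(self, rng):
        cfg = ModelConfig(n_regions=6, gcn_widths=(1, 4, 1), lstm_hidden=5)
        params = init_params(cfg, seed=1)
        adj, feats = _random_batch(rng, dtype=np.float32)
        np.testing.assert_array_equal(
            forward(params, cfg, adj, feats), forward(params, cfg, adj, feats)
        )

    def test_identical_subjects_identical_scores(self, rng):
        cfg = ModelConfig(n_regions=6, gcn_widths=(1, 4, 1), lstm_hidden=5)
        params = init_params(cfg, seed=1)
        adj, feats = _random_batch(rng, B=1)
        both_adj = np.concatenate([adj, adj])
        both_feats = np.concatenate([feats, feats])
        logits = forward(params, cfg, both_adj, both_feats)
        np.testing.assert_array_equal(logits[0], logits[1])

    def test_window_order_matters(self, rng):
        cfg = ModelConfig(n_regions=6, gcn_widths=(1, 4, 1), lstm_hidden=5)
        params = init_params(cfg, seed=1)
        # keep the width-1 GCN output alive for generic positive inputs
        params["gcn.1.W"] = np.abs(params["gcn.1.W"])
        adj, feats = _random_batch(rng, B=1, K=5)
        base = forward(params, cfg, adj, feats)
        perm = [3, 1, 4, 0, 2]
        permuted = forward(params, cfg, adj[:, perm], feats[:, perm])
        assert not np.allclose(base, permuted)

    def test_zero_input_collapses_to_lstm_zero_trajectory(self, rng):
        """All-zero features and adjacencies: the GCN emits zeros, so the
        score must equal the head applied to the LSTM's closed-loop
        zero-input trajectory, reconstructed with the cell oracle."""
        K, R = 4, 6
        cfg = ModelConfig(n_regions=R, gcn_widths=(1, 4, 1), lstm_hidden=5,
                          lstm_layers=3)
        params = {k: v.astype(np.float64) for k, v in init_params(cfg, seed=2).items()}
        adj = np.zeros((1, K, R, R))
        feats = np.zeros((1, K, R))
        logits = forward(params, cfg, adj, feats)
        x_seq = np.zeros((K, R))
        for l in range(cfg.lstm_layers):
            h = np.zeros(cfg.lstm_hidden)
            c = np.zeros(cfg.lstm_hidden)
            outs = []
            for k in range(K):
                h, c = lstm_oracle(
                    h, c, x_seq[k],
                    params[f"lstm.{l}.Wx"], params[f"lstm.{l}.Wh"], params[f"lstm.{l}.b"],
                )
                outs.append(h)
            x_seq = np.stack(outs)
        expected = x_seq[-1] @ params["head.W"] + params["head.b"]
        np.testing.assert_allclose(logits[0], expected, atol=1e-9)

    def test_empty_sequence_rejected(self, rng):
        cfg = ModelConfig(n_regions=6, gcn_widths=(1, 4, 1), lstm_hidden=5)
        params = init_params(cfg, seed=1)
        with pytest.raises(ValueError, match="empty"):
            forward(params, cfg, np.zeros((1, 0, 6, 6)), np.zeros((1, 0, 6)))


class TestGradients:
    @pytest.mark.parametrize("share", [True, False])
    def test_numeric_vs_analytic(self, rng, share):
        """Analytic backprop matches central differences to 1e-4 relative
        (with an absolute floor for zero-gradient entries)."""
        B, K, R = 2, 3, 6
        cfg = ModelConfig(
            n_regions=R, gcn_widths=(1, 4, 1), lstm_hidden=5, lstm_layers=3,
            share_gcn_weights=share, n_windows=K,
        )
        params = init_params(cfg, seed=0, dtype=np.float64)
        adj, feats = _random_batch(rng, B=B, K=K, R=R)
        y = np.array([0, 1])
        _, grads, _ = loss_and_grads(params, cfg, adj, feats, y, l2_weight=1e-3)
        eps = 1e-6
        for key, value in params.items():
            flat = value.ravel()
            idx = rng.choice(flat.size, size=min(10, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp, _, _ = loss_and_grads(params, cfg, adj, feats, y, l2_weight=1e-3)
                flat[i] = orig - eps
                lm, _, _ = loss_and_grads(params, cfg, adj, feats, y, l2_weight=1e-3)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key].ravel()[i]
                assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana), 1e-4), (
                    f"{key}[{i}]: numeric {num}, analytic {ana}"
                )


def _separable_dataset(rng, n=24, K=4, R=8):
    """Two classes with clearly different feature scales."""
    seqs, labels = [], []
    for i in range(n):
        label = i % 2
        feats = rng.random((K, R)) * (0.2 + 0.7 * label)
        adj = np.tile(np.eye(R), (K, 1, 1))
        seqs.append(GraphSequence(f"s{i}", feats, adj))
        labels.append(label)
    return seqs, np.array(labels)


class TestTraining:
    def test_loss_decreases_and_separates(self, rng):
        seqs, labels = _separable_dataset(rng)
        cfg = TrainConfig(seed=3, epochs=100, patience=100, batch_size=8,
                          dropout_rate=0.0)
        mcfg = ModelConfig(n_regions=8, gcn_widths=(1, 4, 1), lstm_hidden=8)
        model = train(seqs, labels, cfg, mcfg)
        losses = [h["train_loss"] for h in model.history]
        assert np.mean(losses[-5:]) < np.mean(losses[:5])
        assert model.history[-1]["val_acc"] >= 0.75

    def test_training_deterministic(self, rng):
        seqs, labels = _separable_dataset(rng, n=16)
        cfg = TrainConfig(seed=5, epochs=8, patience=8, batch_size=8)
        mcfg = ModelConfig(n_regions=8, gcn_widths=(1, 4, 1), lstm_hidden=8)
        m1 = train(seqs, labels, cfg, mcfg)
        m2 = train(seqs, labels, cfg, mcfg)
        assert m1.history == m2.history
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_single_class_rejected(self, rng):
        seqs, labels = _separable_dataset(rng, n=8)
        with pytest.raises(ValueError, match="both classes"):
            train(seqs, np.zeros(8, dtype=int), TrainConfig(seed=0))

    def test_checkpoint_round_trip(self, rng, tmp_path):
        seqs, labels = _separable_dataset(rng, n=16)
        cfg = TrainConfig(seed=5, epochs=4, patience=4, batch_size=8)
        mcfg = ModelConfig(n_regions=8, gcn_widths=(1, 4, 1), lstm_hidden=8)
        model = train(seqs, labels, cfg, mcfg)
        save_checkpoint(model, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        np.testing.assert_array_equal(predict(model, seqs), predict(loaded, seqs))
        assert loaded.model_config == mcfg


class TestSplit:
    def test_fractions_and_stratification(self):
        labels = np.array([0] * 40 + [1] * 60)
        tr, va, te = stratified_split(labels, (0.7, 0.15, 0.15), seed=1)
        assert len(tr) + len(va) + len(te) == 100
        assert set(tr) | set(va) | set(te) == set(range(100))
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))
        # each fold keeps both classes in roughly the right proportion
        for fold in (tr, va, te):
            frac_pos = labels[fold].mean()
            assert 0.4 <= frac_pos <= 0.75

    def test_deterministic(self):
        labels = np.array([0, 1] * 20)
        a = stratified_split(labels, (0.6, 0.2, 0.2), seed=9)
        b = stratified_split(labels, (0.6, 0.2, 0.2), seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
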