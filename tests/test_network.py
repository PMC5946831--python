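"""Network architecture, BN-LSTM semantics, CTC loss and training."""

import numpy as np
import pytest

from conftest import brute_force_ctc, random_prob_matrix, reference_lstm_step
from squigglecall import labeling, sim
from squigglecall.autodiff import Tensor
from squigglecall.network import (BnLstmParams, ModelCheckpoint, Network,
                                  NetworkConfig, bn_lstm_step, ctc_loss,
                                  ctc_loss_grad, required_length, train)

TINY = NetworkConfig(n_conv_layers=2, conv_channels=8, n_rnn_layers=1,
                     rnn_hidden=6, segment_lengths=(40,), batch_size=4)


class TestConfig:
    def test_defaults_match_published_architecture(self):
        cfg = NetworkConfig()
        assert cfg.n_conv_layers == 5
        assert cfg.conv_channels == 256
        assert cfg.conv_kernel == 3
        assert cfg.n_rnn_layers == 3
        assert cfg.rnn_hidden == 200
        assert cfg.learning_rate == 0.001
        assert cfg.segment_lengths == (200, 400, 1000)

    def test_alphabet_is_fixed(self):
        with pytest.raises(ValueError):
            NetworkConfig(alphabet_size=4)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_conv_layers=0)


class TestResidualBlock:
    def test_length_preserved(self):
        net = Network(TINY, seed=0)
        x = Tensor(np.random.default_rng(0).standard_normal((1, 300, 1)))
        out = net.conv_blocks[0](x, training=False)
        assert out.shape == (1, 300, TINY.conv_channels)

    def test_zero_input_zero_output_in_inference(self):
        # fresh running stats: mean 0 / var 1; ReLU(BN(0)) stays 0
        net = Network(TINY, seed=0)
        out = net.conv_blocks[0](Tensor(np.zeros((1, 10, 1))), training=False)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_channel_mismatch_rejected(self):
        net = Network(TINY, seed=0)
        with pytest.raises(ValueError):
            net.conv_blocks[1](Tensor(np.zeros((1, 10, 3))), training=False)


class TestBnLstmStep:
    def _identity_params(self, D, H, seed):
        p = BnLstmParams(D, H, np.random.default_rng(seed))
        for t in (p.gamma_h, p.gamma_x, p.gamma_c):
            t.data[...] = 1.0
        p.beta_c.data[...] = 0.0
        p.eps = 0.0  # running stats default to mean 0 / var 1
        return p

    def test_identity_bn_reduces_to_plain_lstm(self):
        rng = np.random.default_rng(4)
        D, H = 5, 7
        p = self._identity_params(D, H, seed=4)
        x_t = rng.standard_normal((3, D))
        h0 = rng.standard_normal((3, H))
        c0 = rng.standard_normal((3, H))
        h, c = bn_lstm_step(x_t, h0, c0, p, training=False)
        h_ref, c_ref = reference_lstm_step(x_t, h0, c0, p.W_x.data,
                                           p.W_h.data, p.b.data, H)
        np.testing.assert_allclose(h, h_ref, atol=1e-9)
        np.testing.assert_allclose(c, c_ref, atol=1e-9)

    def test_zero_weights_closed_form(self):
        rng = np.random.default_rng(5)
        D, H = 3, 4
        p = self._identity_params(D, H, seed=5)
        p.W_x.data[...] = 0.0
        p.W_h.data[...] = 0.0
        p.b.data[...] = 0.0
        c0 = rng.standard_normal((2, H))
        h, c = bn_lstm_step(np.zeros((2, D)), np.zeros((2, H)), c0, p,
                            training=False)
        sig0 = 0.5
        c_expected = sig0 * c0  # sigmoid(0)*c0 + sigmoid(0)*tanh(0)
        np.testing.assert_allclose(c, c_expected, atol=1e-12)
        np.testing.assert_allclose(h, sig0 * np.tanh(c_expected), atol=1e-12)

    def test_recurrent_bn_shifts_fixed_at_zero_after_training(self):
        """The recurrent/input BN shifts are structurally zero, not params."""
        net = Network(TINY, seed=0)
        segs = _toy_segments(n=8)
        train(segs, TINY, epochs=1, seed=0, network=net)
        for fwd, bwd in net.rnn_layers:
            for p in (fwd, bwd):
                assert p.beta_h == 0.0 and p.beta_x == 0.0
                assert "beta_h" not in p.trainables()
                assert "beta_x" not in p.trainables()

    def test_dimension_mismatch(self):
        p = BnLstmParams(3, 4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            bn_lstm_step(np.zeros((1, 5)), np.zeros((1, 4)),
                         np.zeros((1, 4)), p)


class TestForward:
    @pytest.mark.parametrize("T", [1, 40, 73])
    def test_length_preservation_and_row_sums(self, T):
        net = Network(TINY, seed=1)
        probs = net.predict(np.random.default_rng(T).standard_normal((2, T)))
        assert probs.shape == (2, T, 5)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_parameter_count_closed_form(self):
        cfg = TINY
        C, H, K = cfg.conv_channels, cfg.rnn_hidden, cfg.conv_kernel
        conv = 0
        c_in = 1
        for _ in range(cfg.n_conv_layers):
            weights = c_in * C + c_in * C + K * C * C + C * C
            conv += weights + 4 * 2 * C  # four BNs, gamma+beta each
            c_in = C
        rnn = 0
        in_size = C
        for _ in range(cfg.n_rnn_layers):
            per_dir = (in_size * 4 * H + H * 4 * H + 4 * H  # W_x, W_h, b
                       + 4 * H + 4 * H + H + H)  # gamma_x, gamma_h, gamma_c, beta_c
            rnn += 2 * per_dir
            in_size = 2 * H
        fc = in_size * cfg.alphabet_size
        assert Network(cfg, seed=0).n_parameters() == conv + rnn + fc

    def test_inference_deterministic(self):
        net = Network(TINY, seed=2)
        x = np.random.default_rng(0).standard_normal((1, 50))
        np.testing.assert_array_equal(net.predict(x), net.predict(x))


class TestCtcLoss:
    def test_single_timestep_single_base(self):
        rng = np.random.default_rng(0)
        probs = random_prob_matrix(rng, 1)
        assert ctc_loss(probs, "A") == pytest.approx(-np.log(probs[0, 0]))

    def test_matches_brute_force_t4(self):
        rng = np.random.default_rng(1)
        probs = random_prob_matrix(rng, 4)
        expected = brute_force_ctc(probs, "AG")
        assert np.exp(-ctc_loss(probs, "AG")) == pytest.approx(expected,
                                                               abs=1e-6)

    def test_infeasible_label(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            ctc_loss(random_prob_matrix(rng, 1), "AG")

    def test_repeat_needs_separating_blank(self):
        assert required_length("AA") == 3
        assert required_length("AG") == 2
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            ctc_loss(random_prob_matrix(rng, 2), "AA")

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(4)
        logits = rng.standard_normal((2, 5, 5))
        labels = [[0, 2], [1]]
        loss, grad = ctc_loss_grad(logits, labels)
        eps = 1e-6
        for idx in [(0, 0, 0), (0, 3, 4), (1, 2, 1), (1, 4, 3)]:
            lp = logits.copy()
            lp[idx] += eps
            lm = logits.copy()
            lm[idx] -= eps
            fd = (ctc_loss_grad(lp, labels)[0]
                  - ctc_loss_grad(lm, labels)[0]) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, abs=1e-6)


def _toy_segments(n=8, length=40, seed=0):
    model = sim.generate_pore_model(1, seed=seed)
    rng = np.random.default_rng(seed)
    segs = []
    while len(segs) < n:
        seq = sim.random_sequence(8, int(rng.integers(0, 2**31)))
        read = sim.simulate_read(seq, model, dwell_range=(5, 5),
                                 noise_sd=0.01, seed=int(rng.integers(0, 2**31)))
        segs.extend(labeling.cut_segments(read, length, length))
    return segs[:n]


class TestTraining:
    def test_zero_epochs_leaves_weights_at_initialization(self):
        segs = _toy_segments()
        fresh = Network(TINY, seed=3)
        before = {k: v.data.copy() for k, v in fresh.trainables().items()}
        ckpt = train(segs, TINY, epochs=0, seed=3, network=fresh)
        for k, v in ckpt.network.trainables().items():
            np.testing.assert_array_equal(v.data, before[k])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TINY, epochs=1, seed=0)

    def test_inconsistent_segment_length_rejected(self):
        segs = _toy_segments(length=40)
        cfg = NetworkConfig(n_conv_layers=1, conv_channels=4, n_rnn_layers=1,
                            rnn_hidden=4, segment_lengths=(20,))
        with pytest.raises(ValueError):
            train(segs, cfg, epochs=1, seed=0)

    def test_training_is_seed_reproducible(self):
        segs = _toy_segments()
        a = train(segs, TINY, epochs=1, seed=9)
        b = train(segs, TINY, epochs=1, seed=9)
        for (ka, va), (kb, vb) in zip(a.network.trainables().items(),
                                      b.network.trainables().items()):
            assert ka == kb
            np.testing.assert_array_equal(va.data, vb.data)

    def test_loss_curve_has_one_entry_per_epoch(self):
        segs = _toy_segments()
        ckpt = train(segs, TINY, epochs=2, seed=0)
        assert len(ckpt.loss_curve) == 2


class TestCheckpoint:
    def test_round_trip_bit_identical_forward(self, tmp_path):
        segs = _toy_segments()
        ckpt = train(segs, TINY, epochs=1, seed=1)
        path = ckpt.save(tmp_path / "model.npz")
        loaded = ModelCheckpoint.load(path)
        x = np.random.default_rng(7).standard_normal((1, 40))
        np.testing.assert_array_equal(ckpt.network.predict(x),
                                      loaded.network.predict(x))
        assert loaded.epochs == 1
        assert loaded.loss_curve == ckpt.loss_curve
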