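"""Decoder architecture, gradients, training and prediction contracts."""

import numpy as np
import pytest

import topodecode as td
from topodecode import nn
from topodecode.cnn3d import ArchitectureError
from topodecode.nn import _im2col


def _tiny_net(dtype=np.float64, seed=0):
    rng = np.random.default_rng(seed)
    return nn.Sequential(
        [
            nn.Conv3d(1, 2, (2, 2, 3), pad=(1, 1, 0), rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.BatchNorm(2, dtype=dtype),
            nn.MaxPool3d((1, 1, 2)),
            nn.Conv3d(2, 3, (2, 1, 3), rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.BatchNorm(3, dtype=dtype),
            nn.MaxPool3d((2, 1, 2)),
            nn.Flatten(),
            nn.Dense(24, 2, rng=rng, dtype=dtype),
        ]
    )


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Central finite differences on a tiny float64 model."""
        net = _tiny_net()
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 1, 4, 3, 12))
        y = np.array([0, 1, 0, 1])

        def loss():
            return nn.cross_entropy(net.forward(x, train=True), y)

        _, d = loss()
        net.backward(d)
        worst = 0.0
        for layer, key in net.parameters():
            grad = layer.grads[key].copy()
            p = layer.params[key]
            it = np.nditer(p, flags=["multi_index"])
            for _ in range(min(p.size, 5)):
                idx = it.multi_index
                eps, old = 1e-6, p[idx]
                p[idx] = old + eps
                lp, _ = loss()
                p[idx] = old - eps
                lm, _ = loss()
                p[idx] = old
                fd = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(fd) + abs(grad[idx]))
                worst = max(worst, abs(fd - grad[idx]) / denom)
                it.iternext()
        assert worst < 1e-4

    def test_direct_kernels_agree_with_im2col_reference(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 4, 6, 5, 9)).astype(np.float32)
        conv = nn.Conv3d(4, 5, (3, 2, 4), rng=rng)
        out = conv.forward(x)
        cols = _im2col(x, (3, 2, 4))
        wm = conv.params["W"].reshape(5, -1)
        ref = (cols @ wm.T + conv.params["b"]).transpose(0, 4, 1, 2, 3)
        assert np.allclose(out, ref, atol=1e-4)


class TestArchitecture:
    def test_five_learnable_layers_and_kernels(self):
        arch = td.ArchitectureSpec()
        model = td.build_model(arch, input_T=125, K=2, seed=0)
        assert model.n_learnable_layers == 5
        convs = [l for l in model.net.layers if isinstance(l, nn.Conv3d)]
        dense = [l for l in model.net.layers if isinstance(l, nn.Dense)]
        assert len(convs) == 4 and len(dense) == 1
        assert [c.kernel for c in convs[:3]] == [(3, 4, 5)] * 3
        assert convs[3].kernel == (3, 1, 5)  # 2-D kernel (3, 5) across columns
        assert arch.kernels == [(3, 4, 5)] * 3 + [(3, 5)]

    @pytest.mark.parametrize("T", [125, 250, 500])
    def test_supported_epoch_lengths(self, T):
        model = td.build_model(td.ArchitectureSpec(), input_T=T, K=4, seed=0)
        x = np.zeros((2, 1, 13, 9, T), dtype=np.float32)
        assert model.net.forward(x, train=False).shape == (2, 4)

    def test_collapsing_temporal_dimension_names_layer(self):
        with pytest.raises(ArchitectureError, match="conv"):
            td.build_model(td.ArchitectureSpec(), input_T=16, K=2, seed=0)

    def test_same_seed_same_initial_parameters(self):
        m1 = td.build_model(td.ArchitectureSpec(), 125, 2, seed=9)
        m2 = td.build_model(td.ArchitectureSpec(), 125, 2, seed=9)
        for (l1, k1), (l2, k2) in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(l1.params[k1], l2.params[k2])

    def test_cam_resolution_keeps_finer_time_axis(self):
        coarse = td.build_model(td.ArchitectureSpec(), 125, 2, seed=0)
        fine = td.build_model(
            td.ArchitectureSpec(cam_resolution=True), 125, 2, seed=0
        )
        x = np.zeros((1, 1, 13, 9, 125), dtype=np.float32)
        for m in (coarse, fine):
            m.net.forward(x, train=False)
        t_coarse = coarse.net.activation(coarse.cam_layer_index).shape[-1]
        t_fine = fine.net.activation(fine.cam_layer_index).shape[-1]
        assert t_fine > 2 * t_coarse


class TestTrainingAndPrediction:
    def test_defaults_match_training_protocol(self):
        cfg = td.TrainingConfig()
        assert cfg.learning_rate == 1e-3
        assert cfg.batch_size == 64
        assert cfg.epochs == 60

    def test_loss_decreases_on_separable_data(self, tiny_tensorset):
        model = td.build_model(
            td.ArchitectureSpec(conv3d_filters=(2, 4, 4), conv2d_filters=8),
            125, 2, seed=0,
        )
        cfg = td.TrainingConfig(epochs=4, batch_size=16, seed=0)
        model = td.train(model, tiny_tensorset, cfg)
        assert model.history[-1] < model.history[0]

    def test_training_is_bit_deterministic(self, tiny_tensorset):
        arch = td.ArchitectureSpec(conv3d_filters=(2, 2, 2), conv2d_filters=4)
        cfg = td.TrainingConfig(epochs=2, batch_size=16, seed=3)
        runs = []
        for _ in range(2):
            m = td.build_model(arch, 125, 2, seed=3)
            td.train(m, tiny_tensorset, cfg)
            runs.append(m.net.state())
        for a, b in zip(*runs):
            assert np.array_equal(a, b)

    def test_single_class_training_rejected(self, tiny_tensorset):
        import dataclasses

        ds = dataclasses.replace(
            tiny_tensorset, labels=np.zeros(len(tiny_tensorset), int)
        )
        model = td.build_model(td.ArchitectureSpec(), 125, 2, seed=0)
        with pytest.raises(ValueError, match="2 classes"):
            td.train(model, ds, td.TrainingConfig(epochs=1))

    def test_probability_rows_normalized_and_deterministic(self, tiny_tensorset):
        model = td.build_model(
            td.ArchitectureSpec(conv3d_filters=(2, 2, 2), conv2d_filters=4),
            125, 2, seed=1,
        )
        proba1, labels1 = td.predict(model, tiny_tensorset)
        proba2, _ = td.predict(model, tiny_tensorset)
        assert proba1.shape == (len(tiny_tensorset), 2)
        assert np.all(proba1 >= 0)
        assert np.abs(proba1.sum(axis=1) - 1).max() < 1e-6
        assert np.array_equal(proba1, proba2)
        assert np.array_equal(labels1, proba1.argmax(axis=1))

    def test_shape_mismatch_rejected(self, tiny_tensorset):
        model = td.build_model(td.ArchitectureSpec(), input_T=250, K=2, seed=0)
        with pytest.raises(ValueError, match="T="):
            td.predict(model, tiny_tensorset)

    def test_memorizes_random_labels(self, mapping):
        """Capacity check: the default decoder drives 64 random-label
        trials to >= 99% training accuracy within 60 epochs."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(64, 13, 9, 125)).astype(np.float32)
        y = rng.integers(0, 2, 64)
        ds = td.TopoTensorSet(x, y, mapping, 250.0, class_names=("a", "b"))
        model = td.build_model(td.ArchitectureSpec(), 125, 2, seed=0)
        cfg = td.TrainingConfig(
            epochs=60, batch_size=64, seed=0, early_stop_accuracy=0.99
        )
        td.train(model, ds, cfg)
        _, pred = td.predict(model, ds)
        assert np.mean(pred == y) >= 0.99
        assert len(model.history) <= 60

    def test_balanced_classes_have_uniform_recall(self, tiny_tensorset):
        """On well-separated balanced data the per-class recalls agree
        to within 10 percentage points."""
        model = td.build_model(
            td.ArchitectureSpec(conv3d_filters=(2, 4, 4), conv2d_filters=8),
            125, 2, seed=0,
        )
        td.train(model, tiny_tensorset, td.TrainingConfig(epochs=6, batch_size=16, seed=0))
        _, pred = td.predict(model, tiny_tensorset)
        conf, _, _ = td.metrics(tiny_tensorset.labels, pred, K=2)
        recalls = conf.diagonal()
        assert abs(recalls[0] - recalls[1]) < 10.0

    def test_2d_baseline_builds_and_predicts(self):
        model = td.build_model_2d(117, 125, K=2, filters=(2, 2, 2, 4), seed=0)
        x = np.zeros((3, 117, 1, 125), dtype=np.float32)
        proba, _ = td.predict(model, x)
        assert proba.shape == (3, 2)
        assert np.abs(proba.sum(axis=1) - 1).max() < 1e-6
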