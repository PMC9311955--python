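"""Residual classifier: structure, residual gradient identity, training."""

import numpy as np
import pytest

from suturevision.age_cnn import (
    AgeRangeCNN,
    NetworkSpec,
    TrainConfig,
    _ResidualBlock,
    build_network,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)
from suturevision.nn import BatchNorm2d


def _images(n, seed=0):
    return np.random.default_rng(seed).integers(0, 256, size=(n, 50, 200), dtype=np.uint8)


class TestStructure:
    def test_output_is_probability_vector(self):
        model = build_network(NetworkSpec.small(), seed=1)
        probs = model.predict_proba(_images(3))
        assert probs.shape == (3, 5)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_zeroed_head_gives_uniform_fifth(self):
        model = build_network(NetworkSpec.small(), seed=1)
        model.fc.w.value[:] = 0.0
        model.fc.b.value[:] = 0.0
        probs = model.predict_proba(_images(2))
        np.testing.assert_allclose(probs, 0.2, atol=1e-12)

    def test_zeroed_residual_branches_leave_identity_chain(self):
        """With F == 0 every unit reduces to ReLU(x) = x on non-negative input."""
        spec = NetworkSpec(stage_blocks=(3,), base_width=8, bottleneck=False, stem_kernel=3)
        model = build_network(spec, seed=2)
        for blk in model.stages[0].layers:
            final_bn = blk.branch.layers[-1]
            final_bn.gamma.value[:] = 0.0
            final_bn.beta.value[:] = 0.0
        model.set_train(False)
        x = AgeRangeCNN.prepare(_images(2))
        stem_out = model.stem.forward(x)
        stage_out = model.stages[0].forward(stem_out)
        np.testing.assert_allclose(stage_out, stem_out, atol=1e-12)

    def test_canonical_50_layer_parameter_count(self):
        """Arithmetic oracle over the (3,4,6,3) bottleneck layout, 1-ch/5-cls."""
        spec = NetworkSpec.resnet50()
        model = build_network(spec, seed=0)

        def bn(c):
            return 2 * c

        total = 64 * 1 * 7 * 7 + bn(64)  # stem conv (no bias) + BN
        c_in = 64
        for s, blocks in enumerate((3, 4, 6, 3)):
            w = 64 * 2**s
            for b in range(blocks):
                total += c_in * w + bn(w)          # 1x1 reduce
                total += w * w * 9 + bn(w)         # 3x3
                total += w * 4 * w + bn(4 * w)     # 1x1 expand
                if b == 0:                         # projection shortcut
                    total += c_in * 4 * w + bn(4 * w)
                c_in = 4 * w
        total += 2048 * 5 + 5  # fully connected head
        assert model.n_parameters() == total
        assert model.n_weight_layers() == 50

    def test_resnet50_forward_shapes(self):
        model = build_network(NetworkSpec.resnet50(), seed=0)
        probs = model.predict_proba(_images(1))
        assert probs.shape == (1, 5)
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-6)
        assert model._feature.shape[1] == 2048  # stage-4 channels


class TestResidualGradient:
    def test_backward_carries_additive_identity_term(self):
        """d loss / d x_l = upstream * (1 + dF/dx): finite-difference check
        on a 2-block chain, plus exact identity when the branch is zeroed."""
        rng = np.random.default_rng(3)
        blocks = [
            _ResidualBlock(4, 4, 1, bottleneck=False, rng=rng) for _ in range(2)
        ]
        for blk in blocks:
            blk.set_train(False)
        x = np.abs(rng.normal(size=(1, 4, 3, 3))) + 0.1  # in the ReLU-linear region

        def forward(z):
            h = z
            for blk in blocks:
                h = blk.forward(h)
            return h

        up = rng.normal(size=(1, 4, 3, 3))
        forward(x)
        dy = up
        for blk in reversed(blocks):
            dy = blk.backward(dy)
        analytic = dy

        h = 1e-6
        numeric = np.zeros_like(x)
        for k in range(x.size):
            e = np.zeros_like(x).ravel()
            e[k] = h
            e = e.reshape(x.shape)
            numeric.ravel()[k] = ((forward(x + e) - forward(x - e)) * up).sum() / (2 * h)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-4, atol=1e-6)

        # zero both branches: gradient passes through untouched (pure identity)
        for blk in blocks:
            bn_last = blk.branch.layers[-1]
            bn_last.gamma.value[:] = 0.0
            bn_last.beta.value[:] = 0.0
        forward(x)
        dy = up
        for blk in reversed(blocks):
            dy = blk.backward(dy)
        np.testing.assert_allclose(dy, up, atol=1e-12)


class TestTraining:
    def test_memorizes_ten_images_within_200_steps(self):
        x = _images(10, seed=5)
        y = np.arange(10) % 5
        model = build_network(NetworkSpec.small(), seed=0)
        cfg = TrainConfig(learning_rate=0.02, max_steps=200, checkpoint_every=200, seed=0)
        history = train(model, (x, y), None, cfg)
        assert history[-1]["train_acc"] == 1.0

    def test_zero_learning_rate_freezes_parameters(self):
        x = _images(8, seed=6)
        y = np.arange(8) % 5
        model = build_network(NetworkSpec.small(), seed=0)
        before = [p.value.copy() for p in model.params()]
        cfg = TrainConfig(learning_rate=0.0, weight_decay=0.0, max_steps=5, checkpoint_every=5, seed=0)
        history = train(model, (x, y), None, cfg)
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)
        assert np.isfinite(history[-1]["loss"])

    def test_lr_schedule_exponential_with_floor(self):
        cfg = TrainConfig(learning_rate=0.1, decay_rate=0.5, decay_steps=100, end_learning_rate=0.03)
        assert cfg.lr_at(0) == pytest.approx(0.1)
        assert cfg.lr_at(100) == pytest.approx(0.05)
        assert cfg.lr_at(1000) == pytest.approx(0.03)  # floored

    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path):
        x = _images(4, seed=8)
        model = build_network(NetworkSpec.small(), seed=3)
        cfg = TrainConfig(learning_rate=0.02, max_steps=10, checkpoint_every=10, seed=0)
        train(model, (x, np.arange(4) % 5), None, cfg)
        path = save_checkpoint(model, cfg, tmp_path / "ck.npz")
        model2, cfg2 = load_checkpoint(path)
        np.testing.assert_allclose(
            model.predict_proba(x), model2.predict_proba(x), atol=1e-12
        )
        assert cfg2.learning_rate == cfg.learning_rate

    def test_empty_training_set_rejected(self):
        model = build_network(NetworkSpec.small(), seed=0)
        with pytest.raises(ValueError):
            train(model, (np.empty((0, 50, 200)), np.empty(0, dtype=int)), None, TrainConfig())


class TestPredict:
    def test_batch_rows_sum_to_one_and_labels_in_range(self):
        model = build_network(NetworkSpec.small(), seed=0)
        probs, labels = predict(model, _images(12))
        assert probs.shape == (12, 5)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(labels) <= set(range(5))

    def test_wrong_shape_rejected(self):
        model = build_network(NetworkSpec.small(), seed=0)
        with pytest.raises(ValueError, match="expected"):
            predict(model, np.zeros((60, 100), dtype=np.uint8))
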