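"""Three-subnetwork model: shapes, dataflow, gradients, loss."""

import numpy as np
import pytest

from pamrestore import nn
from pamrestore.mtrdn import (
    MTRDN,
    RDN,
    RDNConfig,
    load_checkpoint,
    multitask_loss,
    save_checkpoint,
)

TINY = dict(n_blocks=2, convs_per_block=2, growth=4, base_channels=8)


class TestRDNConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            RDNConfig(n_blocks=0)
        with pytest.raises(ValueError):
            RDNConfig(scale=3)

    @pytest.mark.parametrize(
        "cfg",
        [
            RDNConfig(**TINY, scale=2),
            RDNConfig(**TINY, scale=1, in_channels=2),
            RDNConfig(n_blocks=4, convs_per_block=4, growth=16, base_channels=32, scale=4),
        ],
    )
    def test_parameter_count_closed_form(self, cfg):
        net = RDN(cfg, np.random.default_rng(0))
        assert net.n_parameters() == cfg.n_parameters()


class TestRDNForward:
    @pytest.mark.parametrize("scale, size, expected", [(2, 50, 100), (4, 50, 200), (1, 16, 16)])
    def test_scale_contract(self, scale, size, expected):
        net = RDN(RDNConfig(**TINY, scale=scale), np.random.default_rng(1))
        x = nn.Tensor(np.random.default_rng(0).random((1, size, size, 1), dtype=np.float32))
        assert net(x).data.shape == (1, expected, expected, 1)

    def test_finite_output_for_random_input(self, rng):
        net = RDN(RDNConfig(**TINY, scale=2), np.random.default_rng(2))
        x = nn.Tensor(rng.random((2, 16, 16, 1)).astype(np.float32))
        assert np.isfinite(net(x).data).all()

    def test_too_small_input_rejected(self):
        net = RDN(RDNConfig(**TINY, scale=1), np.random.default_rng(0))
        with pytest.raises(ValueError):
            net(nn.Tensor(np.zeros((1, 4, 4, 1), np.float32)))


@pytest.fixture(scope="module")
def model():
    return MTRDN(scale=2, **TINY, seed=3)


class TestMTRDNForward:
    def test_output_shapes(self, model, rng):
        o1, o2, o3 = model.forward(rng.random((16, 16)), rng.random((16, 16)))
        assert o1.shape == o2.shape == o3.shape == (32, 32)

    def test_dataflow_isolation(self, model, rng):
        i1, i2 = rng.random((16, 16)), rng.random((16, 16))
        o1a, o2a, o3a = model.forward(i1, i2)
        o1b, o2b, o3b = model.forward(i1, i2 + 0.1)
        np.testing.assert_array_equal(o1a, o1b)  # branch 1 never sees input 2
        assert not np.array_equal(o2a, o2b)
        assert not np.array_equal(o3a, o3b)  # fusion sees both branches

    def test_forward_deterministic(self, model, rng):
        i1, i2 = rng.random((16, 16)), rng.random((16, 16))
        a = model.forward(i1, i2)
        b = model.forward(i1, i2)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            model.forward(np.zeros((16, 16)), np.zeros((16, 18)))


class TestMultitaskLoss:
    def test_zero_when_outputs_match(self, rng):
        t = tuple(rng.random((8, 8)) for _ in range(3))
        assert multitask_loss(t, t, (0.25, 0.25, 0.5)) == 0.0

    def test_single_branch_reduction(self, rng):
        outs = tuple(rng.random((8, 8)) for _ in range(3))
        gts = tuple(rng.random((8, 8)) for _ in range(3))
        expected = np.abs(outs[0] - gts[0]).mean()
        assert multitask_loss(outs, gts, (1, 0, 0)) == pytest.approx(expected)

    def test_constant_residual_hand_arithmetic(self):
        outs = tuple(np.full((4, 4), 0.6) for _ in range(3))
        gts = tuple(np.full((4, 4), 0.5) for _ in range(3))
        # 0.25*0.1 + 0.25*0.1 + 0.5*0.1 = 0.1
        assert multitask_loss(outs, gts, (0.25, 0.25, 0.5)) == pytest.approx(0.1)

    def test_weights_normalized_before_use(self, rng):
        outs = tuple(rng.random((8, 8)) for _ in range(3))
        gts = tuple(rng.random((8, 8)) for _ in range(3))
        assert multitask_loss(outs, gts, (1, 1, 2)) == pytest.approx(
            multitask_loss(outs, gts, (0.25, 0.25, 0.5))
        )

    def test_all_zero_weights_rejected(self, rng):
        t = tuple(rng.random((4, 4)) for _ in range(3))
        with pytest.raises(ValueError):
            multitask_loss(t, t, (0, 0, 0))


class TestGradients:
    def test_conv_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        x = nn.Tensor(rng.random((1, 8, 8, 2)).astype(np.float32))
        w1 = nn.Tensor(rng.normal(0, 0.3, (3, 3, 2, 3)).astype(np.float32), requires_grad=True)
        b1 = nn.Tensor(np.zeros(3, np.float32), requires_grad=True)
        w2 = nn.Tensor(rng.normal(0, 0.3, (1, 1, 3, 4)).astype(np.float32), requires_grad=True)
        tgt = rng.random((1, 16, 16, 1)).astype(np.float32)

        def loss_fn():
            h = nn.relu(nn.conv2d(x, w1, b1))
            return nn.mae(nn.pixel_shuffle(nn.conv2d(h, w2), 2), tgt)

        loss = loss_fn()
        loss.backward()
        for p in (w1, b1, w2):
            grad = p.grad.copy()
            for _ in range(4):
                ix = tuple(rng.integers(0, s) for s in p.data.shape)
                eps = 1e-2
                orig = p.data[ix]
                p.data[ix] = orig + eps
                lp = float(loss_fn().data)
                p.data[ix] = orig - eps
                lm = float(loss_fn().data)
                p.data[ix] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grad[ix]) <= 0.05 * abs(fd) + 1e-4

    def test_multisupervision_reaches_every_subnetwork(self, rng):
        model = MTRDN(scale=2, **TINY, seed=5)
        t1 = nn.Tensor(rng.random((2, 8, 8, 1)).astype(np.float32))
        t2 = nn.Tensor(rng.random((2, 8, 8, 1)).astype(np.float32))
        outs = model.forward_tensors(t1, t2)
        gts = tuple(rng.random((2, 16, 16, 1)).astype(np.float32) for _ in range(3))
        loss = model.loss_tensor(outs, gts)
        loss.backward()
        for net in (model.subnet1, model.subnet2, model.subnet3):
            grads = [p.grad for p in net.parameters()]
            assert all(g is not None for g in grads)
            assert any(np.abs(g).max() > 0 for g in grads)


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, rng):
        model = MTRDN(scale=2, **TINY, seed=7, loss_weights=(0.2, 0.3, 0.5))
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.get_config() == model.get_config()
        i1, i2 = rng.random((16, 16)), rng.random((16, 16))
        for a, b in zip(model.forward(i1, i2), loaded.forward(i1, i2)):
            np.testing.assert_array_equal(a, b)
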