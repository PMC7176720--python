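"""Autograd correctness, U-Net variants, loss, training and inference."""

import numpy as np
import pytest

from simrestore import nn, prep
from simrestore.nn.autograd import Tensor, concat, conv2d, conv_transpose2d, maxpool2


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestAutograd:
    def test_conv2d_gradients_match_numeric(self, rng):
        x = Tensor(rng.standard_normal((2, 3, 6, 6)), requires_grad=True)
        w = Tensor(rng.standard_normal((4, 3, 3, 3)) * 0.2, requires_grad=True)
        b = Tensor(rng.standard_normal(4) * 0.1, requires_grad=True)
        conv2d(x, w, b).relu().square().sum().backward()

        def f():
            return float(conv2d(x, w, b).relu().square().sum().data)

        for t in (x, w, b):
            ng = numeric_grad(f, t.data)
            assert np.abs(ng - t.grad).max() <= 1e-6 * max(np.abs(ng).max(), 1)

    def test_conv_transpose_gradients_match_numeric(self, rng):
        x = Tensor(rng.standard_normal((1, 2, 4, 4)), requires_grad=True)
        w = Tensor(rng.standard_normal((2, 3, 2, 2)) * 0.3, requires_grad=True)
        b = Tensor(np.zeros(3), requires_grad=True)
        conv_transpose2d(x, w, b).square().sum().backward()

        def f():
            return float(conv_transpose2d(x, w, b).square().sum().data)

        for t in (x, w):
            ng = numeric_grad(f, t.data)
            assert np.abs(ng - t.grad).max() <= 1e-6 * np.abs(ng).max()

    def test_maxpool_routes_gradient_to_argmax(self, rng):
        x = Tensor(rng.standard_normal((1, 2, 4, 4)), requires_grad=True)
        maxpool2(x).sum().backward()
        assert x.grad.sum() == pytest.approx(8.0)   # one unit per pooled cell
        assert set(np.unique(x.grad)) <= {0.0, 1.0}

    def test_concat_splits_gradient(self, rng):
        a = Tensor(rng.standard_normal((1, 2, 4, 4)), requires_grad=True)
        b = Tensor(rng.standard_normal((1, 3, 4, 4)), requires_grad=True)
        (concat([a, b]) * 2.0).sum().backward()
        assert np.all(a.grad == 2.0) and np.all(b.grad == 2.0)

    def test_abs_and_square_chain(self, rng):
        x = Tensor(rng.standard_normal((5, 5)), requires_grad=True)
        (x.abs() + 5.0 * x.square()).mean().backward()
        expect = (np.sign(x.data) + 10 * x.data) / 25.0
        assert np.allclose(x.grad, expect)


class TestUNetShapes:
    @pytest.mark.parametrize(
        "name,size",
        [("sim15", 64), ("sim3", 64), ("snr", 32), ("srrf5", 32)],
    )
    def test_named_variants_preserve_spatial_shape(self, name, size):
        net = nn.build_named(name, depth=2, base_features=4)
        c_in, c_out = nn.NAMED_CHANNELS[name]
        y = net(Tensor(np.zeros((1, c_in, size, size))))
        assert y.shape == (1, c_out, size, size)

    def test_indivisible_input_rejected(self):
        net = nn.build_unet(nn.NetworkConfig("unet", 3, 1, depth=3, base_features=4))
        with pytest.raises(ValueError, match="divisible"):
            net(Tensor(np.zeros((1, 3, 36, 36))))

    def test_seeded_init_reproducible(self):
        cfg = nn.NetworkConfig("unet", 15, 1, 2, 4, seed=3)
        a, b = nn.build_unet(cfg), nn.build_unet(cfg)
        for k in a.parameters():
            assert np.array_equal(a.parameters()[k].data, b.parameters()[k].data)

    def test_param_count_deterministic_function_of_config(self):
        n1 = nn.build_unet(nn.NetworkConfig("unet", 15, 1, 2, 4, seed=0)).n_parameters()
        n2 = nn.build_unet(nn.NetworkConfig("unet", 15, 1, 2, 4, seed=99)).n_parameters()
        assert n1 == n2
        wider = nn.build_unet(nn.NetworkConfig("unet", 15, 1, 2, 8)).n_parameters()
        assert wider > n1


class TestSCUNet:
    def test_stacked_forward_shape(self):
        net = nn.build_scunet(nn.NetworkConfig("scunet", 15, 1, 2, 4))
        y = net(Tensor(np.zeros((1, 15, 32, 32))))
        assert y.shape == (1, 1, 32, 32)

    def test_cross_skips_add_parameters(self):
        with_skips = nn.build_scunet(nn.NetworkConfig("scunet", 15, 1, 2, 4))
        without = nn.build_scunet(
            nn.NetworkConfig("scunet", 15, 1, 2, 4, cross_skips=False)
        )
        assert without.n_parameters() < with_skips.n_parameters()

    def test_eval_forward_deterministic(self, rng):
        net = nn.build_scunet(nn.NetworkConfig("scunet", 15, 1, 2, 4))
        x = rng.random((1, 15, 32, 32))
        a = net(Tensor(x)).data
        b = net(Tensor(x)).data
        assert np.array_equal(a, b)


class TestLoss:
    def test_zero_residual_both_variants(self, rng):
        u = rng.random((16, 16))
        for variant in ("as_printed", "l1_l2"):
            assert float(nn.loss(u, u.copy(), variant).data) == 0.0

    def test_hand_values_constant_residual(self):
        u = np.zeros((8, 8))
        # residual +0.1: 0.1 + 5*0.01 = 0.15/px in both variants
        assert float(nn.loss(u + 0.1, u, "as_printed").data) == pytest.approx(0.15)
        assert float(nn.loss(u + 0.1, u, "l1_l2").data) == pytest.approx(0.15)
        # residual -0.1 exposes the signed first term: -0.1 + 0.05 = -0.05
        assert float(nn.loss(u - 0.1, u, "as_printed").data) == pytest.approx(-0.05)
        assert float(nn.loss(u - 0.1, u, "l1_l2").data) == pytest.approx(0.15)

    def test_variants_agree_when_residual_nonnegative(self, rng):
        u = rng.random((12, 12))
        v = u - rng.random((12, 12))   # U >= V pixelwise
        a = float(nn.loss(u, v, "as_printed").data)
        b = float(nn.loss(u, v, "l1_l2").data)
        assert a == pytest.approx(b, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            nn.loss(np.zeros((4, 4)), np.zeros((5, 5)))


def _tiny_pairs(rng, n=3, c_in=3, size=16):
    pairs = []
    for i in range(n):
        x = rng.random((c_in, size, size))
        y = rng.random((1, size, size)) * 0.5
        pairs.append(prep.PatchPair(x, y, f"s{i}", (0, 0), (1.0, 1.0)))
    return pairs


class TestTraining:
    def test_single_sample_overfit(self, rng):
        # memorizing one pair must drive the loss far below its start
        pairs = _tiny_pairs(rng, n=1)
        split = prep.DatasetSplit([0], [], [])
        net = nn.build_unet(nn.NetworkConfig("unet", 3, 1, 2, 8, seed=0))
        cfg = nn.TrainingConfig(epochs=500, batch_size=1, learning_rate=3e-3, seed=0)
        hist = nn.train(net, pairs, split, cfg)
        assert hist.train_loss[-1] < 0.01 * hist.train_loss[0]

    def test_training_deterministic_under_seed(self, rng):
        pairs = _tiny_pairs(rng)
        split = prep.DatasetSplit([0, 1], [2], [])
        losses = []
        for _ in range(2):
            net = nn.build_unet(nn.NetworkConfig("unet", 3, 1, 2, 4, seed=1))
            cfg = nn.TrainingConfig(epochs=2, batch_size=2, learning_rate=1e-3, seed=5)
            hist = nn.train(net, pairs, split, cfg)
            losses.append((hist.train_loss, hist.val_loss))
        assert losses[0] == losses[1]

    def test_empty_training_split_rejected(self, rng):
        pairs = _tiny_pairs(rng)
        with pytest.raises(ValueError, match="empty"):
            nn.train(pairs=pairs, net=nn.build_unet(nn.NetworkConfig("unet", 3, 1, 1, 2)),
                     split=prep.DatasetSplit([], [0], []), config=nn.TrainingConfig(1))

    def test_history_length_matches_epochs(self, rng):
        pairs = _tiny_pairs(rng)
        split = prep.DatasetSplit([0, 1], [2], [])
        net = nn.build_unet(nn.NetworkConfig("unet", 3, 1, 1, 2, seed=0))
        hist = nn.train(net, pairs, split, nn.TrainingConfig(epochs=3, batch_size=2))
        assert len(hist.train_loss) == 3 and len(hist.val_loss) == 3


class TestTransferInit:
    def test_parameters_copied_exactly(self):
        cfg = nn.NetworkConfig("unet", 3, 1, 2, 4, seed=1)
        src = nn.build_unet(cfg)
        dst = nn.build_unet(nn.NetworkConfig("unet", 3, 1, 2, 4, seed=9))
        nn.transfer_init(dst, src.state_dict())
        for k in src.parameters():
            assert np.array_equal(dst.parameters()[k].data, src.parameters()[k].data)

    def test_channel_mismatch_lists_layers(self):
        src = nn.build_unet(nn.NetworkConfig("unet", 15, 1, 2, 4))
        dst = nn.build_unet(nn.NetworkConfig("unet", 3, 1, 2, 4))
        with pytest.raises(ValueError, match="enc0.conv1.w"):
            nn.transfer_init(dst, src.state_dict())

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = nn.build_unet(nn.NetworkConfig("unet", 3, 1, 2, 4, seed=2))
        path = tmp_path / "model.npz"
        nn.save_checkpoint(path, net, normalization=(123.0, 456.0), training_seed=7)
        ck = nn.load_checkpoint(path)
        assert ck["normalization"] == (123.0, 456.0)
        x = rng.random((1, 3, 16, 16))
        assert np.array_equal(ck["net"](Tensor(x)).data, net(Tensor(x)).data)


class TestPredict:
    def test_single_tile_pass_through(self, rng):
        net = nn.build_unet(nn.NetworkConfig("unet", 3, 1, 2, 4, seed=0))
        stack = rng.random((3, 16, 16))
        full = nn.predict(net, stack, (1.0, 1.0), upsample=False)
        direct = np.clip(net(Tensor(stack[None])).data[0], 0, None)
        assert np.array_equal(full, direct)

    def test_tiled_matches_single_tile_closely(self, rng):
        net = nn.build_unet(nn.NetworkConfig("unet", 3, 1, 2, 4, seed=0))
        stack = rng.random((3, 32, 32))
        full = nn.predict(net, stack, (1.0, 1.0), upsample=False)
        tiled = nn.predict(net, stack, (1.0, 1.0), tile=24, overlap=8, upsample=False)
        # feathered blending of overlapping tiles stays close to the
        # single-shot prediction away from tile-boundary effects
        assert np.median(np.abs(tiled - full)) < 0.1 * full.max()

    def test_upsampling_doubles_grid(self, rng):
        net = nn.build_unet(nn.NetworkConfig("unet", 3, 1, 2, 4, seed=0))
        out = nn.predict(net, rng.random((3, 16, 16)), (1.0, 1.0), upsample=True)
        assert out.shape == (1, 32, 32)

    def test_missing_normalization_rejected(self, rng):
        net = nn.build_unet(nn.NetworkConfig("unet", 3, 1, 1, 2))
        with pytest.raises(ValueError, match="normalization"):
            nn.predict(net, rng.random((3, 16, 16)), None)
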