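"""Network building blocks: activation values, shape contracts, attention
semantics, lightweight-convolution structure."""

import numpy as np
import pytest

from kyolo import nn
from kyolo.autodiff import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(3)


class TestActivations:
    def test_hardswish_printed_values(self):
        assert nn.hardswish(-3.0) == 0.0
        assert nn.hardswish(3.0) == 3.0
        assert nn.hardswish(1.0) == pytest.approx(2 / 3)
        assert nn.hardswish(-1.5) == pytest.approx(-0.375)  # global minimum
        assert nn.hardswish(-10.0) == 0.0 and nn.hardswish(10.0) == 10.0

    def test_hardswish_continuous_at_kinks(self):
        eps = 1e-8
        assert nn.hardswish(-3 + eps) == pytest.approx(0.0, abs=1e-7)
        assert nn.hardswish(3 - eps) == pytest.approx(3.0, abs=1e-7)

    def test_hardswish_nonmonotonic_dip(self):
        xs = np.linspace(-3, -1.5, 50)
        vals = nn.hardswish(xs)
        assert np.all(np.diff(vals) < 0)  # decreasing into the minimum
        xs2 = np.linspace(-1.5, 5, 50)
        assert np.all(np.diff(nn.hardswish(xs2)) > 0)

    def test_swish_values_and_relu_limit(self):
        assert nn.swish(0.0) == 0.0
        assert nn.swish(1.0, beta=1.0) == pytest.approx(0.7310585786300049)
        x = np.array([-2.0, -0.5, 0.5, 2.0])
        big = nn.swish(x, beta=500.0)
        np.testing.assert_allclose(big, np.maximum(x, 0), atol=1e-6)
        with pytest.raises(ValueError):
            nn.swish(1.0, beta=0.0)

    def test_tensor_and_array_paths_agree(self, rng):
        x = rng.normal(0, 2, 40)
        np.testing.assert_allclose(nn.hardswish(Tensor(x)).data, nn.hardswish(x),
                                   rtol=1e-6)
        np.testing.assert_allclose(nn.swish(Tensor(x), 1.3).data, nn.swish(x, 1.3),
                                   rtol=1e-5)


class TestChannelAttention:
    def test_output_shape_and_range(self, rng):
        with nn.init_seed(0):
            ca = nn.ChannelAttention(32, reduction=16)
        x = Tensor(rng.normal(0, 1, (2, 32, 8, 8)).astype(np.float32))
        w = ca(x)
        assert w.shape == (2, 32, 1, 1)
        assert np.all((w.data > 0) & (w.data < 1))

    def test_constant_input_pools_agree(self):
        with nn.init_seed(0):
            ca = nn.ChannelAttention(8, reduction=4)
        const = Tensor(np.tile(np.arange(8, dtype=np.float32).reshape(1, 8, 1, 1),
                               (1, 1, 5, 5)))
        # max pool == avg pool for per-channel-constant input, so the two
        # branch outputs are identical; attention = sigmoid(2 * branch)
        avg = const.data.mean(axis=(2, 3))
        h1 = nn.Module.__call__(ca.fc1, Tensor(avg))
        branch = ca.fc2(ca.act(h1)).data
        expect = 1 / (1 + np.exp(-2 * branch))
        np.testing.assert_allclose(ca(const).data.reshape(1, 8), expect, rtol=1e-5)

    def test_zero_bottleneck_gives_half(self):
        with nn.init_seed(0):
            ca = nn.ChannelAttention(16)
        ca.fc1.weight.data[...] = 0
        ca.fc2.weight.data[...] = 0
        x = Tensor(np.random.default_rng(0).normal(0, 1, (3, 16, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(ca(x).data, 0.5, atol=1e-7)


class TestSpatialAttention:
    def test_improved_branch_range_and_shape(self, rng):
        with nn.init_seed(1):
            sa = nn.SpatialAttention(7, improved=True)
        sa.train(False)
        x = Tensor(rng.normal(0, 3, (2, 16, 10, 10)).astype(np.float32))
        out = sa(x)
        assert out.shape == (2, 1, 10, 10)
        assert out.data.min() >= -0.375 - 1e-6  # Hardswish lower bound

    def test_improved_maps_very_negative_preactivation_to_zero(self):
        with nn.init_seed(1):
            sa = nn.SpatialAttention(7, improved=True)
        sa.train(False)
        sa.bn.beta.data[...] = -10.0  # force pre-activation <= -3
        x = Tensor(np.zeros((1, 4, 6, 6), np.float32))
        assert np.all(sa(x).data == 0.0)

    def test_classic_branch_is_sigmoid_bounded(self, rng):
        with nn.init_seed(1):
            sa = nn.SpatialAttention(7, improved=False)
        x = Tensor(rng.normal(0, 3, (2, 16, 10, 10)).astype(np.float32))
        out = sa(x).data
        assert np.all((out > 0) & (out < 1))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            nn.SpatialAttention(6)


class TestCBAMVariants:
    @pytest.mark.parametrize("cls", [nn.CBAM, nn.ICBAM])
    def test_shape_preserved_and_swappable(self, cls, rng):
        with nn.init_seed(2):
            m = cls(64)
        m.train(False)
        x = Tensor(rng.normal(0, 1, (2, 64, 40, 40)).astype(np.float32))
        assert m(x).shape == x.shape

    def test_zero_input_zero_output(self):
        with nn.init_seed(2):
            m = nn.ICBAM(16)
        m.train(False)
        x = Tensor(np.zeros((1, 16, 8, 8), np.float32))
        assert np.all(m(x).data == 0.0)  # multiplicative gating

    def test_gradient_reaches_both_attention_branches(self, rng):
        with nn.init_seed(2):
            m = nn.ICBAM(8, reduction=4)
        m.train(False)
        x = Tensor(rng.normal(0, 1, (1, 8, 6, 6)).astype(np.float64), requires_grad=True)
        m(x).sum().backward()
        assert x.grad is not None and np.abs(x.grad).max() > 0
        for p in (m.ca.fc1.weight, m.sa.conv.weight):
            p.grad = None
        out = m(x)
        out.sum().backward()
        assert np.abs(m.ca.fc1.weight.grad).max() > 0
        assert np.abs(m.sa.conv.weight.grad).max() > 0

    def test_icbam_gradcheck_wrt_input(self, rng):
        """Finite differences through the full attention block."""
        with nn.init_seed(4):
            m = nn.ICBAM(4, reduction=2, kernel=3)
        m.train(False)
        x = rng.normal(0, 1, (1, 4, 3, 3))
        xt = Tensor(x, requires_grad=True)
        m(xt).sum().backward()
        eps = 1e-5
        flat_idx = [(0, c, i, j) for c in range(4) for i in range(3) for j in range(3)]
        for idx in flat_idx[::7]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fd = (float(m(Tensor(xp)).data.sum()) - float(m(Tensor(xm)).data.sum())) / (2 * eps)
            assert xt.grad[idx] == pytest.approx(fd, rel=1e-3, abs=1e-6)


class TestLightweightConvs:
    def test_channel_shuffle_interleaves_and_is_bijective(self):
        x = Tensor(np.arange(4, dtype=np.float32).reshape(1, 4, 1, 1))
        out = nn.channel_shuffle(x, 2).data.reshape(4)
        np.testing.assert_array_equal(out, [0, 2, 1, 3])  # [a,b,c,d] -> [a,c,b,d]
        big = Tensor(np.random.default_rng(0).normal(0, 1, (2, 16, 3, 3)).astype(np.float32))
        shuffled = nn.channel_shuffle(big, 2).data
        assert sorted(map(tuple, shuffled.reshape(2, 16, -1)[0])) == \
               sorted(map(tuple, big.data.reshape(2, 16, -1)[0]))

    @pytest.mark.parametrize("cls", [nn.GSConv, nn.GhostConv])
    def test_output_channels_and_shapes(self, cls, rng):
        with nn.init_seed(0):
            m = cls(32, 64, k=3, s=2)
        m.train(False)
        x = Tensor(rng.normal(0, 1, (1, 32, 80, 80)).astype(np.float32))
        out = m(x)
        assert out.shape == (1, 64, 40, 40)
        with pytest.raises(ValueError):
            cls(32, 63)

    @pytest.mark.parametrize("cls", [nn.GSConv, nn.GhostConv])
    def test_fewer_parameters_than_dense_conv(self, cls):
        c1, c2, k = 64, 128, 3
        with nn.init_seed(0):
            m = cls(c1, c2, k=k)
        n_params = sum(p.size for p in m.parameters())
        dense = nn.conv_param_count(c1, c2, k) + 2 * c2  # conv + BN affine
        assert n_params < dense

    def test_gsconv_flops_below_dense(self):
        # closed-form MAC comparison at equal configuration
        c1, c2, k, hw = 64, 128, 3, 40 * 40
        dense_macs = k * k * c1 * c2 * hw
        gs_macs = k * k * c1 * (c2 // 2) * hw + 25 * (c2 // 2) * hw
        assert gs_macs < dense_macs


class TestCompositeBlocks:
    def test_cbs_c3_shapes(self, rng):
        with nn.init_seed(0):
            cbs = nn.ConvBNAct(16, 32, 3, 2)
            c3 = nn.C3(32, 32, n=1, shortcut=True)
        for m in (cbs, c3):
            m.train(False)
        x = Tensor(rng.normal(0, 1, (2, 16, 16, 16)).astype(np.float32))
        y = cbs(x)
        assert y.shape == (2, 32, 8, 8)
        assert c3(y).shape == y.shape  # identical in/out channels, shortcut on

    def test_sppf_equals_spp_5_9_13(self, rng):
        """Chained 5-pools reproduce parallel {5, 9, 13} receptive fields."""
        with nn.init_seed(7):
            sppf = nn.SPPF(32, 32, k=5)
        with nn.init_seed(7):
            spp = nn.SPP(32, 32, ks=(5, 9, 13))
        sppf.train(False)
        spp.train(False)
        # same weights by identical init seed and layout
        x = Tensor(rng.normal(0, 1, (1, 32, 12, 12)).astype(np.float32))
        np.testing.assert_allclose(sppf(x).data, spp(x).data, atol=1e-5)

    def test_sppf_channel_and_spatial_contract(self, rng):
        with nn.init_seed(0):
            sppf = nn.SPPF(64, 48, k=5)
        sppf.train(False)
        x = Tensor(rng.normal(0, 1, (2, 64, 10, 10)).astype(np.float32))
        assert sppf(x).shape == (2, 48, 10, 10)

    def test_batch_dimension_preserved_on_random_shapes(self, rng):
        for _ in range(5):
            b = int(rng.integers(1, 4))
            hw = int(rng.integers(4, 12)) * 2
            with nn.init_seed(0):
                blocks = [nn.ConvBNAct(8, 16, 3, 1), nn.C3(16, 16, 1),
                          nn.GSConv(16, 16), nn.ICBAM(16)]
            x = Tensor(rng.normal(0, 1, (b, 8, hw, hw)).astype(np.float32))
            y = blocks[0](x)
            for m in blocks[1:]:
                m.train(False)
                y = m(y)
            assert y.shape[0] == b


class TestBlockSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            nn.BlockSpec(kind="gsconv", c_in=8, c_out=7)
        with pytest.raises(ValueError):
            nn.BlockSpec(kind="cbs", c_in=0, c_out=8)
        with pytest.raises(ValueError):
            nn.ActivationSpec(kind="gelu")
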