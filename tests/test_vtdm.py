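"""Trajectory-descriptor module: convolution, grid, sampler, and pipeline
oracle checks against brute-force implementations."""

import numpy as np
import pytest

from viqa import nn
from viqa.errors import InvalidArgumentError
from viqa.vtdm import (
    VTDM,
    LocalisationNet,
    TemporalAggregation,
    affine_grid,
    bilinear_sample,
    make_sampling_grid,
    normalize_0_255,
    trajectory_descriptor,
)

rng = np.random.default_rng(42)


def brute_force_conv(clip, phi, bias=0.0):
    """Naive sliding-window temporal-aggregation convolution (zero pad 1)."""
    h, w, T = clip.shape
    padded = np.zeros((h + 2, w + 2, T))
    padded[1:-1, 1:-1] = clip
    out = np.full((h, w), bias, dtype=np.float64)
    for y in range(h):
        for x in range(w):
            out[y, x] += np.sum(padded[y : y + 3, x : x + 3] * phi)
    return out


def brute_force_bilinear(desc, gx, gy):
    """Direct bilinear interpolation of one normalized source point."""
    h, w = desc.shape
    px = (gx + 1) / 2 * (w - 1)
    py = (gy + 1) / 2 * (h - 1)
    x0, y0 = int(np.floor(px)), int(np.floor(py))
    val = 0.0
    for yy, wy in ((y0, 1 - (py - y0)), (y0 + 1, py - y0)):
        for xx, wx in ((x0, 1 - (px - x0)), (x0 + 1, px - x0)):
            if 0 <= yy < h and 0 <= xx < w:
                val += desc[yy, xx] * wy * wx
    return val


class TestTrajectoryDescriptor:
    def test_zero_clip_zero_bias_gives_zero(self):
        out = trajectory_descriptor(np.zeros((8, 8, 4)), rng.standard_normal((3, 3, 4)))
        assert np.all(out == 0)

    def test_center_tap_identity_sums_over_time(self):
        """Phi with only the center weight set to 1 per temporal channel
        reduces the convolution to a plain temporal sum."""
        clip = rng.random((8, 8, 4))
        phi = np.zeros((3, 3, 4))
        phi[1, 1, :] = 1.0
        out = trajectory_descriptor(clip, phi)
        assert np.abs(out - clip.sum(axis=2)).max() < 1e-5

    def test_matches_brute_force_on_random_instances(self):
        for _ in range(30):
            h = int(rng.integers(4, 17))
            T = int(rng.integers(1, 9))
            clip = rng.standard_normal((h, h, T))
            phi = rng.standard_normal((3, 3, T))
            b = float(rng.standard_normal())
            got = trajectory_descriptor(clip, phi, b)
            want = brute_force_conv(clip, phi, b)
            assert np.abs(got - want).max() < 1e-5

    def test_channel_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            trajectory_descriptor(np.zeros((8, 8, 4)), np.zeros((3, 3, 5)))

    def test_module_applies_bn_relu_and_is_trainable(self):
        mod = TemporalAggregation(T=4, rng=np.random.default_rng(0))
        x = nn.Tensor(rng.random((2, 4, 8, 8)).astype(np.float32), requires_grad=False)
        out = mod(x)
        assert out.data.shape == (2, 1, 8, 8)
        assert np.all(out.data >= 0)  # ReLU
        nn.backward(out.mean())
        assert mod.conv.weight.grad is not None


class TestSamplingGrid:
    def test_identity_theta_reproduces_general_grid(self):
        from viqa.vtdm import _base_grid

        g = make_sampling_grid(np.eye(2), (7, 5))
        assert np.array_equal(g, _base_grid((7, 5)).astype(np.float64))

    def test_quarter_rotation_maps_x_axis_to_y_axis(self):
        theta = np.array([[0.0, -1.0], [1.0, 0.0]])
        g = make_sampling_grid(theta, (3, 3))
        # output grid point (x=1, y=0) is at row 1 (y=0), col 2 (x=1)
        assert np.allclose(g[1, 2], [0.0, 1.0])

    def test_scalar_theta_doubles_every_coordinate(self):
        g1 = make_sampling_grid(np.eye(2), (9, 9))
        g2 = make_sampling_grid(2.0 * np.eye(2), (9, 9))
        assert np.allclose(g2, 2.0 * g1)

    def test_affine_grid_gradient_flows_to_theta(self):
        theta = nn.Tensor(np.eye(2, dtype=np.float32)[None], requires_grad=True)
        grid = affine_grid(theta, (4, 4))
        nn.backward(grid.mean())
        assert theta.grad is not None and theta.grad.shape == (1, 2, 2)


class TestBilinearSample:
    def test_identity_grid_is_exact(self):
        from viqa.vtdm import _base_grid

        d = rng.standard_normal((8, 8))
        out = bilinear_sample(d, _base_grid((8, 8)))
        assert np.abs(out - d).max() < 1e-6

    def test_midpoint_of_2x2_neighborhood(self):
        d = np.array([[0.0, 0.0], [1.0, 1.0]])
        grid = np.zeros((1, 1, 2))  # center of the 2x2 map
        assert bilinear_sample(d, grid)[0, 0] == pytest.approx(0.5)

    def test_matches_brute_force_at_random_points(self):
        d = rng.standard_normal((5, 5))
        for _ in range(20):
            gx, gy = rng.uniform(-0.95, 0.95, 2)
            got = bilinear_sample(d, np.array([[[gx, gy]]]))[0, 0]
            assert got == pytest.approx(brute_force_bilinear(d, gx, gy), abs=1e-6)

    def test_out_of_bounds_contributes_zero(self):
        d = np.ones((4, 4))
        out = bilinear_sample(d, np.full((2, 2, 2), 5.0))
        assert np.all(out == 0)


class TestLocalisationNet:
    def test_identity_initialization_returns_identity_theta(self):
        net = LocalisationNet(16, rng=np.random.default_rng(0))
        x = nn.Tensor(rng.random((3, 1, 16, 16)).astype(np.float32))
        theta = net(x)
        assert theta.data.shape == (3, 2, 2)
        assert np.allclose(theta.data, np.eye(2), atol=1e-7)

    def test_too_small_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            LocalisationNet(8)

    def test_theta_gradient_matches_finite_differences(self):
        """Gradient of a theta component w.r.t. single input pixels."""
        net = LocalisationNet(16, rng=np.random.default_rng(3))
        # move off the identity init so gradients are non-trivial
        net.fc2.weight.data[...] = 0.01 * np.random.default_rng(4).standard_normal(
            net.fc2.weight.data.shape)
        x = nn.Tensor(rng.random((1, 1, 16, 16)).astype(np.float32), requires_grad=True)
        theta = net(x)
        nn.backward(theta.reshape(4).mean())
        got = x.grad
        eps = 1e-2
        for (py, px) in [(3, 4), (8, 8), (12, 2)]:
            orig = x.data[0, 0, py, px]
            x.data[0, 0, py, px] = orig + eps
            fp = float(net(nn.Tensor(x.data)).data.reshape(4).mean())
            x.data[0, 0, py, px] = orig - eps
            fm = float(net(nn.Tensor(x.data)).data.reshape(4).mean())
            x.data[0, 0, py, px] = orig
            fd = (fp - fm) / (2 * eps)
            if abs(fd) > 1e-6:
                assert got[0, 0, py, px] == pytest.approx(fd, rel=1e-2, abs=1e-5)


class TestVTDMForward:
    def _clips(self, n=1, t=4, size=16):
        return nn.Tensor(rng.random((n, 15, t, size, size)).astype(np.float32))

    def test_all_zero_clips_give_all_zero_descriptor(self):
        v = VTDM(T=4, map_size=16, rng=np.random.default_rng(0))
        v.eval()
        out = v(nn.Tensor(np.zeros((1, 15, 4, 16, 16), np.float32)))
        assert np.all(out.data == 0)

    def test_stn_disabled_equals_identity_init_at_initialization(self):
        clips = self._clips()
        a = VTDM(T=4, map_size=16, stn_enabled=True, rng=np.random.default_rng(1))
        b = VTDM(T=4, map_size=16, stn_enabled=False, rng=np.random.default_rng(1))
        a.eval(), b.eval()
        assert np.abs(a(clips).data - b(clips).data).max() < 1e-3

    def test_channel_j_equals_single_joint_pipeline(self):
        """Stacking is per-joint independent: channel j of the batch output
        equals running the same pipeline on joint j's clip alone."""
        clips = self._clips()
        v = VTDM(T=4, map_size=16, rng=np.random.default_rng(2))
        v.eval()
        full = v(clips).data
        for j in (0, 7, 14):
            solo = np.repeat(clips.data[:, j : j + 1], 15, axis=1)
            out = v(nn.Tensor(solo)).data
            assert np.abs(full[0, j] - out[0, j]).max() < 1e-5

    def test_wrong_joint_count_rejected(self):
        v = VTDM(T=4, map_size=16)
        with pytest.raises(InvalidArgumentError):
            v(nn.Tensor(np.zeros((1, 10, 4, 16, 16), np.float32)))

    def test_gradients_reach_phi_and_localisation_weights(self):
        v = VTDM(T=4, map_size=16, rng=np.random.default_rng(5))
        v.train()
        out = v(self._clips(n=2))
        nn.backward(out.mean())
        for name, p in v.named_parameters():
            assert p.grad is not None, f"no gradient reached {name}"

    def test_normalize_0_255_scales_channels_independently(self):
        x = nn.Tensor(np.stack([np.zeros((4, 4), np.float32),
                                np.linspace(0, 2, 16, dtype=np.float32).reshape(4, 4)])[None])
        out = normalize_0_255(x)
        assert np.all(out.data[0, 0] == 0)  # constant channel -> zeros
        assert out.data[0, 1].max() == pytest.approx(255.0)
        assert out.data[0, 1].min() == pytest.approx(0.0)


def test_affine_consistency_warp_then_sample_recovers_original():
    """For a smooth descriptor and moderate theta, sampling the
    theta-warped image with grid(theta) recovers the original away from
    borders (dense inverse-warp oracle via scikit-image)."""
    from skimage.transform import AffineTransform, warp

    size = 33
    yy, xx = np.mgrid[0:size, 0:size]
    desc = np.exp(-(((xx - 16) / 6.0) ** 2 + ((yy - 13) / 4.0) ** 2))
    rng_local = np.random.default_rng(0)
    successes = []
    for _ in range(10):
        ang = rng_local.uniform(-45, 45)
        sc = rng_local.uniform(0.8, 1.25)
        r = np.deg2rad(ang)
        theta = sc * np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
        # build the warped image W such that sampling W at grid(theta)
        # returns the original: W(p) = desc(theta^{-1} p) in centered coords
        c = (size - 1) / 2
        Ainv = np.linalg.inv(theta)
        tf = AffineTransform(matrix=np.array([
            [Ainv[0, 0], Ainv[0, 1], c - Ainv[0, 0] * c - Ainv[0, 1] * c],
            [Ainv[1, 0], Ainv[1, 1], c - Ainv[1, 0] * c - Ainv[1, 1] * c],
            [0, 0, 1]]))
        warped = warp(desc, tf, order=3)
        grid = make_sampling_grid(theta, (size, size))
        recovered = bilinear_sample(warped, grid)
        inner = (slice(6, -6), slice(6, -6))
        a, b = recovered[inner].ravel(), desc[inner].ravel()
        ncc = np.corrcoef(a, b)[0, 1]
        successes.append(ncc)
    assert np.min(successes) >= 0.95
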