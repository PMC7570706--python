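"""View-invariant trajectory descriptor module (VTDM).

Stages, applied per joint with weights shared across joints:

1. *Temporal aggregation*: a single 3x3 2D convolution with T input
   channels (one per clip frame), stride 1, zero padding 1, followed by
   batch-norm and ReLU, collapses the ``W x H x T`` heatmap stack of one
   joint into a single-channel trajectory descriptor -- an image tracing
   where that joint's probability mass travelled over the clip.
2. *Localisation network*: conv(5x5) x10 -> maxpool2 -> ReLU ->
   conv(5x5, ch 10) x10 -> maxpool2 -> ReLU -> FC(32) -> ReLU -> FC(4),
   regressing the four entries of a 2x2 affine matrix theta per joint.
   The final layer starts at the identity transform (zero weights, bias
   (1, 0, 0, 1)) so training departs smoothly from "no warp".
3. *Affine resampling*: a sampling grid built from theta over normalized
   pixel-center coordinates in [-1, 1]^2 (origin at the map center; the
   4-parameter transform has no translation, so rotation/scale/shear act
   about the center), then bilinear interpolation with zeros outside the
   input -- the descriptor background is zero, so out-of-view samples are
   genuinely empty.

The J=15 view-normalized descriptors, each rescaled to the 0..255 image
intensity range, are stacked channel-wise into the global descriptor the
score classifier consumes.  The whole module is differentiable end to end.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import InvalidArgumentError, InvalidDataError
from .pose_heatmaps import N_JOINTS

__all__ = [
    "TemporalAggregation",
    "LocalisationNet",
    "affine_grid",
    "make_sampling_grid",
    "bilinear_sample",
    "trajectory_descriptor",
    "normalize_0_255",
    "VTDM",
]


class TemporalAggregation(nn.Module):
    """Learned temporal-aggregation convolution: (N, T, H, W) -> (N, 1, H, W)."""

    def __init__(self, T: int = 16, rng: np.random.Generator | None = None):
        super().__init__()
        self.T = T
        self.conv = nn.Conv2d(T, 1, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(1)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.data.ndim != 4 or x.data.shape[1] != self.T:
            raise InvalidArgumentError(
                f"expected (N, {self.T}, H, W) clip stack, got {x.data.shape}")
        return nn.relu(self.bn(self.conv(x)))


class LocalisationNet(nn.Module):
    """Regresses the 2x2 affine matrix from a trajectory descriptor."""

    def __init__(self, map_size: int, rng: np.random.Generator | None = None):
        super().__init__()
        if map_size < 16:
            raise InvalidArgumentError(
                f"localisation needs at least 16x16 input (two 2x2 poolings), got {map_size}")
        self.map_size = map_size
        self.conv1 = nn.Conv2d(1, 10, 5, padding=2, rng=rng)
        self.conv2 = nn.Conv2d(10, 10, 5, padding=2, rng=rng)
        feat = 10 * (map_size // 2 // 2) ** 2
        self.fc1 = nn.Linear(feat, 32, rng=rng)
        self.fc2 = nn.Linear(32, 4, rng=rng)
        # identity-transform initialization
        self.fc2.weight.data[...] = 0.0
        self.fc2.bias.data[...] = np.array([1.0, 0.0, 0.0, 1.0], dtype=np.float32)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """(N, 1, H, W) -> theta as (N, 2, 2)."""
        if x.data.shape[2] != self.map_size or x.data.shape[3] != self.map_size:
            raise InvalidArgumentError(
                f"descriptor is {x.data.shape[2:]} but net was built for "
                f"{self.map_size}x{self.map_size}")
        h = nn.relu(nn.max_pool2d(self.conv1(x), 2))
        h = nn.relu(nn.max_pool2d(self.conv2(h), 2))
        h = h.reshape(h.data.shape[0], -1)
        h = nn.relu(self.fc1(h))
        theta = self.fc2(h)
        return theta.reshape(-1, 2, 2)


def _base_grid(out_size: tuple[int, int]) -> np.ndarray:
    """General grid G: normalized pixel-center coordinates, shape (H', W', 2).

    x runs over columns, y over rows, both in [-1, 1] with -1/+1 at the
    border pixel centers and the origin at the map center.
    """
    wo, ho = int(out_size[0]), int(out_size[1])
    if wo < 1 or ho < 1:
        raise InvalidArgumentError(f"output size must be positive, got {out_size}")
    xs = np.linspace(-1.0, 1.0, wo, dtype=np.float32) if wo > 1 else np.zeros(1, np.float32)
    ys = np.linspace(-1.0, 1.0, ho, dtype=np.float32) if ho > 1 else np.zeros(1, np.float32)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    return np.stack([gx, gy], axis=-1)


def affine_grid(theta: nn.Tensor, out_size: tuple[int, int]) -> nn.Tensor:
    """Differentiable sampling grid: source_i = theta @ (x_i^g, y_i^g)^T.

    ``theta``: (N, 2, 2); returns (N, H', W', 2) source coordinates in the
    same normalized units.  No translation term -- the transform is the
    4-parameter rotation/scale/shear about the map center.
    """
    g = _base_grid(out_size)  # (H', W', 2)
    src = np.einsum("nij,hwj->nhwi", theta.data, g)
    out = nn.Tensor(src, theta.requires_grad)
    out._parents = (theta,)

    def bwd(grad):
        if theta.requires_grad:
            theta._accumulate(np.einsum("nhwi,hwj->nij", grad, g))

    out._backward = bwd
    return out


def make_sampling_grid(theta, out_size: tuple[int, int]) -> np.ndarray:
    """Array-level grid builder for a single 2x2 theta (oracle-friendly)."""
    th = np.asarray(theta, dtype=np.float64).reshape(2, 2)
    g = _base_grid(out_size).astype(np.float64)
    return np.einsum("ij,hwj->hwi", th, g)


def bilinear_sample(desc: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Sample a single-channel map at normalized grid points (array level).

    ``desc``: (H, W); ``grid``: (H', W', 2) with (x, y) in [-1, 1] under the
    align-corners convention.  Points outside [-1, 1]^2 contribute zero.
    Float64 throughout, so sampling at the identity grid reproduces the
    input to full precision; the float32 in-graph equivalent is
    :func:`viqa.nn.grid_sample`.
    """
    desc = np.asarray(desc, dtype=np.float64)
    grid = np.asarray(grid, dtype=np.float64)
    if not np.all(np.isfinite(grid)):
        raise InvalidDataError("sampling grid contains NaN or Inf")
    h, w = desc.shape
    gx = (grid[..., 0] + 1) * 0.5 * (w - 1)
    gy = (grid[..., 1] + 1) * 0.5 * (h - 1)
    x0 = np.floor(gx).astype(np.int64)
    y0 = np.floor(gy).astype(np.int64)
    wx1, wy1 = gx - x0, gy - y0
    out = np.zeros(grid.shape[:-1], dtype=np.float64)
    for dy, wy in ((0, 1.0 - wy1), (1, wy1)):
        for dx, wx in ((0, 1.0 - wx1), (1, wx1)):
            yy, xx = y0 + dy, x0 + dx
            valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
            vals = desc[np.clip(yy, 0, h - 1), np.clip(xx, 0, w - 1)]
            out += np.where(valid, vals * wy * wx, 0.0)
    return out


def trajectory_descriptor(clip: np.ndarray, phi: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Pre-activation temporal-aggregation convolution at the array level.

    ``clip``: (H, W, T) heatmap stack; ``phi``: (3, 3, T) kernel.  Returns
    the (H, W) convolution output (stride 1, zero padding 1) before
    batch-norm/ReLU -- the form the brute-force oracle checks.
    """
    clip = np.asarray(clip, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if clip.ndim != 3 or phi.ndim != 3 or clip.shape[2] != phi.shape[2]:
        raise InvalidArgumentError(
            f"temporal-channel mismatch: clip {clip.shape}, phi {phi.shape}")
    x = nn.Tensor(clip.transpose(2, 0, 1)[None])          # (1, T, H, W)
    w = nn.Tensor(phi.transpose(2, 0, 1)[None])           # (1, T, 3, 3)
    b = nn.Tensor(np.array([bias]))
    return nn.conv2d(x, w, b, padding=1).data[0, 0].astype(np.float64)


def normalize_0_255(x: nn.Tensor) -> nn.Tensor:
    """Per-sample, per-channel affine rescale to [0, 255] inside the graph.

    The min/max scale factors are computed from the current values and
    treated as constants in the backward pass (a straight-through affine),
    so gradients keep the plain rescale form.  All-constant channels map
    to zero, matching the zero-signal semantics of a fully occluded joint.
    """
    d = x.data
    lo = d.min(axis=(2, 3), keepdims=True)
    hi = d.max(axis=(2, 3), keepdims=True)
    span = hi - lo
    scale = np.where(span > 0, 255.0 / np.where(span > 0, span, 1.0), 0.0)
    y = (d - lo) * scale
    out = nn.Tensor(y, x.requires_grad)
    out._parents = (x,)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * scale)

    out._backward = bwd
    return out


class VTDM(nn.Module):
    """Full per-joint pipeline producing the J-channel global descriptor.

    Input: (N, J, T, H, W) heatmap clip stacks; output: (N, J, H, W).
    The temporal-aggregation kernel and the localisation weights are shared
    across joints (joints are folded into the batch); theta is regressed
    per joint.  ``stn_enabled=False`` skips the transformer stage (ablation)
    so the descriptor is just the normalized aggregation output.
    """

    def __init__(self, T: int = 16, map_size: int = 56, stn_enabled: bool = True,
                 normalize: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.T, self.map_size = T, map_size
        self.stn_enabled = stn_enabled
        self.normalize = normalize
        self.temporal = TemporalAggregation(T, rng)
        self.loc = LocalisationNet(map_size, rng)

    def forward(self, clips: nn.Tensor, return_theta: bool = False):
        n, j, t, h, w = clips.data.shape
        if j != N_JOINTS:
            raise InvalidArgumentError(f"expected {N_JOINTS} joint clips, got {j}")
        x = clips.reshape(n * j, t, h, w)
        lam = self.temporal(x)                      # (N*J, 1, H, W)
        theta = None
        if self.stn_enabled:
            theta = self.loc(lam)                   # (N*J, 2, 2)
            grid = affine_grid(theta, (w, h))
            lam = nn.grid_sample(lam, grid)
        if self.normalize:
            lam = normalize_0_255(lam)
        out = lam.reshape(n, j, h, w)
        if return_theta:
            return out, theta
        return out
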