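"""Movement score module (MSM): classifiers over the global descriptor.

The score classifier is an ordinary image CNN whose first convolution is
re-channeled to accept the J=15 descriptor channels and whose final FC layer
emits S+1 logits, one per integer quality score.  Three families:

``tiny``
    Three conv blocks + global average pooling + two FC layers.  Small
    enough to train on one CPU core; the default for desk-scale work.
``vgg19_adapted``
    The 16-conv/3-FC stack with the first layer replaced by a 3x3, J-channel
    convolution (+ batch-norm + ReLU) and the last FC re-sized to S+1.
``resnext50_adapted``
    The 4-stage aggregated-residual bottleneck network (cardinality 32,
    width 4), first layer replaced by a 7x7, J-channel convolution followed
    by 3x3 max pooling, last FC re-sized to S+1.

Middle layers of the adapted families follow the standard architectures.
Pretrained 3-channel first-layer weights, when available as an ``.npz``
checkpoint, are re-channeled with :func:`init_first_layer`; otherwise the
adapted families start from random initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import CheckpointError, InvalidArgumentError, InvalidDataError
from .pose_heatmaps import N_JOINTS

__all__ = [
    "BackboneConfig",
    "TinyBackbone",
    "VGG19Adapted",
    "ResNeXt50Adapted",
    "adapt_backbone",
    "init_first_layer",
    "forward_score",
    "resize_bilinear",
]

FAMILIES = ("tiny", "vgg19_adapted", "resnext50_adapted")


@dataclass
class BackboneConfig:
    family: str = "tiny"
    J: int = N_JOINTS
    S: int = 4
    pretrained_source: str | None = None
    input_size: int | None = None  # None: family default (tiny native, others 224)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidArgumentError(f"unknown backbone family {self.family!r}")
        if self.J < 1 or self.S < 1:
            raise InvalidArgumentError("J and S must be positive")


def init_first_layer(pretrained_w: np.ndarray, J: int) -> np.ndarray:
    """Re-channel 3-channel first-layer weights to J input channels.

    The three pretrained channel slices are tiled cyclically to J channels
    and all weights are scaled by 3/J, so the layer's response to a
    constant input is preserved (exactly so when J is a multiple of 3, as
    with the J=15 joint channels used here).
    ``pretrained_w``: (C_out, 3, k, k) -> (C_out, J, k, k).
    """
    if J < 1:
        raise InvalidArgumentError(f"J must be >= 1, got {J}")
    w = np.asarray(pretrained_w)
    if w.ndim != 4 or w.shape[1] != 3:
        raise CheckpointError(f"expected (C_out, 3, k, k) weights, got {w.shape}")
    reps = int(np.ceil(J / 3))
    tiled = np.tile(w, (1, reps, 1, 1))[:, :J]
    return (tiled * (3.0 / J)).astype(w.dtype)


class _ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, k, stride=1, padding=0, groups=1, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride, padding, groups, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return nn.relu(self.bn(self.conv(x)))


class TinyBackbone(nn.Module):
    """Three conv blocks + coarse 4x4 spatial pooling + two FC layers.

    The head pools to a 4x4 grid rather than a single global average:
    trajectory descriptors carry most of their score information in coarse
    spatial layout (horizontal extent of the trace, left/right asymmetry),
    which a linear readout of pooled maps can exploit from the first
    gradient steps.
    """

    input_size = None  # operates at the native descriptor size

    def __init__(self, J: int = N_JOINTS, S: int = 4, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.J, self.S = J, S
        self.block1 = _ConvBNReLU(J, 16, 3, padding=1, rng=rng)
        self.block2 = _ConvBNReLU(16, 32, 3, padding=1, rng=rng)
        self.block3 = _ConvBNReLU(32, 32, 3, padding=1, rng=rng)
        self.fc1 = nn.Linear(32 * 4 * 4, 64, rng=rng)
        self.fc2 = nn.Linear(64, S + 1, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = nn.max_pool2d(self.block1(x), 2)
        h = nn.max_pool2d(self.block2(h), 2)
        h = self.block3(h)
        h = nn.adaptive_avg_pool2d(h, (4, 4))
        h = h.reshape(h.data.shape[0], -1)
        h = nn.relu(self.fc1(h))
        return self.fc2(h)


_VGG19_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
              512, 512, 512, 512, "M", 512, 512, 512, 512, "M"]


class VGG19Adapted(nn.Module):
    """VGG-19 stack with a J-channel 3x3 first layer and an S+1 final FC."""

    input_size = 224

    def __init__(self, J: int = N_JOINTS, S: int = 4, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.J, self.S = J, S
        self.features: list[nn.Module] = []
        self._plan: list[int | str] = []  # conv index or "M" pool marker
        cin = J
        for v in _VGG19_CFG:
            if v == "M":
                self._plan.append("M")
            else:
                # first entry is the replaced J-channel 3x3 layer
                self._plan.append(len(self.features))
                self.features.append(_ConvBNReLU(cin, v, 3, padding=1, rng=rng))
                cin = v
        self.fc1 = nn.Linear(512 * 7 * 7, 4096, rng=rng)
        self.fc2 = nn.Linear(4096, 4096, rng=rng)
        self.fc3 = nn.Linear(4096, S + 1, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        for step in self._plan:
            if step == "M":
                x = nn.max_pool2d(x, 2)
            else:
                x = self.features[step](x)
        x = nn.adaptive_avg_pool2d(x, (7, 7))
        x = x.reshape(x.data.shape[0], -1)
        x = nn.relu(self.fc1(x))
        x = nn.relu(self.fc2(x))
        return self.fc3(x)


class _Bottleneck(nn.Module):
    """Aggregated-residual bottleneck: 1x1 -> grouped 3x3 -> 1x1 + shortcut."""

    def __init__(self, cin, width, cout, stride, cardinality, rng=None):
        super().__init__()
        self.reduce = _ConvBNReLU(cin, width, 1, rng=rng)
        self.grouped = _ConvBNReLU(width, width, 3, stride=stride, padding=1,
                                   groups=cardinality, rng=rng)
        self.expand_conv = nn.Conv2d(width, cout, 1, bias=False, rng=rng)
        self.expand_bn = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(cout)
        else:
            self.down_conv = None

    def forward(self, x):
        h = self.reduce(x)
        h = self.grouped(h)
        h = self.expand_bn(self.expand_conv(h))
        sc = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return nn.relu(h + sc)


class ResNeXt50Adapted(nn.Module):
    """ResNeXt-50 (32x4d) with a J-channel 7x7 stem and an S+1 final FC."""

    input_size = 224

    def __init__(self, J: int = N_JOINTS, S: int = 4, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.J, self.S = J, S
        self.stem = _ConvBNReLU(J, 64, 7, stride=2, padding=3, rng=rng)
        blocks = []
        cin = 64
        for stage, (n_blocks, width, cout) in enumerate(
                [(3, 128, 256), (4, 256, 512), (6, 512, 1024), (3, 1024, 2048)]):
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage > 0) else 1
                blocks.append(_Bottleneck(cin, width, cout, stride, 32, rng=rng))
                cin = cout
        self.blocks = blocks
        self.fc = nn.Linear(2048, S + 1, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.stem(x)
        h = nn.max_pool2d(h, 3, stride=2, padding=1)
        for blk in self.blocks:
            h = blk(h)
        h = nn.global_avg_pool2d(h)
        return self.fc(h)


def adapt_backbone(cfg: BackboneConfig, rng: np.random.Generator | None = None) -> nn.Module:
    """Build a score classifier per the config, loading pretrained first-layer
    weights (re-channeled to J) when a checkpoint path is given."""
    cls = {"tiny": TinyBackbone, "vgg19_adapted": VGG19Adapted,
           "resnext50_adapted": ResNeXt50Adapted}[cfg.family]
    model = cls(cfg.J, cfg.S, rng=rng)
    if cfg.input_size is not None:
        model.input_size = cfg.input_size
    if cfg.pretrained_source is not None:
        try:
            ckpt = np.load(cfg.pretrained_source)
            w3 = ckpt["first_layer_weight"]
        except Exception as e:  # noqa: BLE001 - surfaced as a checkpoint error
            raise CheckpointError(f"cannot read pretrained weights: {e}") from e
        wj = init_first_layer(w3, cfg.J)
        if cfg.family == "tiny":
            target = model.block1.conv.weight
        elif cfg.family == "vgg19_adapted":
            target = model.features[0].conv.weight
        else:
            target = model.stem.conv.weight
        if target.data.shape != wj.shape:
            raise CheckpointError(
                f"pretrained first layer {wj.shape} incompatible with "
                f"{cfg.family} first layer {target.data.shape}")
        target.data[...] = wj.astype(np.float32)
    return model


def resize_bilinear(x: nn.Tensor, size: int) -> nn.Tensor:
    """Differentiable bilinear resize via identity-grid sampling."""
    n = x.data.shape[0]
    ys = np.linspace(-1, 1, size, dtype=np.float32)
    gy, gx = np.meshgrid(ys, ys, indexing="ij")
    grid = np.broadcast_to(np.stack([gx, gy], -1)[None], (n, size, size, 2)).copy()
    return nn.grid_sample(x, nn.Tensor(grid))


def forward_score(model: nn.Module, desc: nn.Tensor) -> nn.Tensor:
    """Run the classifier on a (N, J, H, W) global descriptor -> (N, S+1) logits."""
    if not np.all(np.isfinite(desc.data)):
        raise InvalidDataError("descriptor contains NaN or Inf")
    size = getattr(model, "input_size", None)
    if size is not None and desc.data.shape[2] != size:
        desc = resize_bilinear(desc, size)
    return model(desc)
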