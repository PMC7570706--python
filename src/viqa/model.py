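"""End-to-end network: trajectory descriptor module + score classifier.

Takes the (N, J, T, H, W) per-joint heatmap clip stacks, produces the
view-normalized J-channel global descriptor, and classifies it into S+1
quality-score logits.  Trained end to end: gradients flow from the
cross-entropy loss back through the classifier, the bilinear sampler, the
localisation network and the temporal-aggregation convolution.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .errors import CheckpointError
from .msm import BackboneConfig, adapt_backbone, forward_score
from .pose_heatmaps import N_JOINTS
from .vtdm import VTDM

__all__ = ["MovementQualityNet", "save_checkpoint", "load_checkpoint"]


class MovementQualityNet(nn.Module):
    """Clip heatmaps in, score logits out."""

    def __init__(self, S: int = 4, T: int = 16, map_size: int = 56,
                 backbone: str = "tiny", stn_enabled: bool = True,
                 input_size: int | None = None, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.S, self.T, self.map_size = S, T, map_size
        self.backbone_family = backbone
        self.stn_enabled = stn_enabled
        self.seed = seed
        self.vtdm = VTDM(T=T, map_size=map_size, stn_enabled=stn_enabled, rng=rng)
        self.msm = adapt_backbone(
            BackboneConfig(family=backbone, J=N_JOINTS, S=S, input_size=input_size), rng=rng)

    def forward(self, clips: nn.Tensor) -> nn.Tensor:
        desc = self.vtdm(clips)
        return forward_score(self.msm, desc)

    def config(self) -> dict:
        return {
            "J": N_JOINTS, "T": self.T, "W": self.map_size, "H": self.map_size,
            "S": self.S, "backbone": self.backbone_family,
            "stn_enabled": self.stn_enabled, "seed": self.seed,
            "input_size": getattr(self.msm, "input_size", None),
        }


def save_checkpoint(model: MovementQualityNet, path) -> None:
    """Write weights as a single ``.npz`` archive with a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path, **model.state_dict())
    side = path.with_suffix(".json")
    side.write_text(json.dumps(model.config(), indent=2))


def load_checkpoint(path) -> MovementQualityNet:
    path = Path(path)
    side = path.with_suffix(".json")
    if not side.exists():
        raise CheckpointError(f"missing sidecar {side}")
    cfg = json.loads(side.read_text())
    model = MovementQualityNet(S=cfg["S"], T=cfg["T"], map_size=cfg["W"],
                               backbone=cfg["backbone"], stn_enabled=cfg["stn_enabled"],
                               input_size=cfg.get("input_size"), seed=cfg.get("seed", 0))
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as d:
        try:
            model.load_state_dict({k: d[k] for k in d.files})
        except (KeyError, ValueError) as e:
            raise CheckpointError(f"incompatible checkpoint: {e}") from e
    return model
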