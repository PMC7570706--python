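import numpy as np
import pytest

from viqa.pose_heatmaps import PoseSequence, VideoMeta
from viqa.synthetic import DatasetConfig, MovementSpec, generate_dataset, make_views, simulate_skeleton


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numerical_gradient(f, x, eps=1e-3):
    """Central finite differences of scalar f() w.r.t. array x (in place)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture
def walk_sequence():
    """A moderately impaired canonical walk, 64 frames."""
    return simulate_skeleton(MovementSpec.for_score("walk", 2, 4, duration=64, seed=7))


@pytest.fixture
def normal_walk():
    return simulate_skeleton(MovementSpec.for_score("walk", 0, 4, duration=64, seed=7))


@pytest.fixture
def tiny_dataset():
    """2 subjects x 2 views x scores 0..2, walk, 48 frames."""
    cfg = DatasetConfig(n_subjects=2, views=make_views(2, seed=3), actions=("walk",),
                        S=2, per_score_count=1, duration=48, seed=5)
    return generate_dataset(cfg)


@pytest.fixture
def still_sequence():
    """A stationary figure (all frames identical), 20 frames, full confidence."""
    base = simulate_skeleton(MovementSpec.for_score("walk", 0, 4, duration=20, seed=1))
    joints = np.repeat(base.joints[:1], 20, axis=0)
    return PoseSequence(joints, base.frame_size, VideoMeta(video_id="still"))
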