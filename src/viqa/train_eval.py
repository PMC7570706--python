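"""Clip construction, loss, training, video scoring, and evaluation protocols.

Videos are divided into non-overlapping T=16-frame clips; each clip carries
its video's integer quality score as a class label.  Training samples clips
uniformly from the pooled training videos and minimizes the softmax
cross-entropy with plain SGD (defaults: learning rate 0.001, batch size 5,
20 epochs, one network per movement type trained from scratch).  At test
time every clip of a video is scored and the video's predicted score is the
argmax over classes of the clip-averaged logits of the final FC layer.
Agreement with ground truth over a test set is summarized by Spearman's
rank correlation.

Evaluation protocols: cross-subject k-fold (k = number of distinct scores,
subject sets disjoint across folds), cross-view single (train on one camera
view, test on all others), cross-view pair (train on one frontal + one side
view), and a plain stratified holdout.  Class imbalance is handled by
subsampling normal (score 0) videos to a fixed count and augmenting
minority scores with random temporal crops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .errors import (
    EmptyDatasetError,
    EmptyVideoError,
    LabelError,
    SplitError,
    TooShortError,
    TrainingFailure,
    UndefinedCorrelationError,
)
from .model import MovementQualityNet
from .pose_heatmaps import PoseSequence, render_sequence_heatmaps

T_DEFAULT = 16

__all__ = [
    "ClipIndex",
    "TrainConfig",
    "SplitPlan",
    "VideoScore",
    "split_clips",
    "cross_entropy",
    "sample_training_clips",
    "render_clip_tensor",
    "train",
    "score_video",
    "spearman_rho",
    "balance_dataset",
    "make_splits",
    "run_experiment",
]


@dataclass(frozen=True)
class ClipIndex:
    """One non-overlapping T-frame window of a video, with its score label."""

    video_id: str
    clip_index: int
    frame_start: int
    frame_end: int  # half-open
    score: int


@dataclass
class TrainConfig:
    """Optimization protocol: SGD, lr 0.001, batch 5, 20 epochs."""

    lr: float = 0.001
    batch_size: int = 5
    epochs: int = 20
    seed: int = 0
    stn_enabled: bool = True
    T: int = T_DEFAULT
    map_size: int = 56
    sigma: float = 2.0

    def __post_init__(self):
        if self.lr < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("hyperparameters must be positive")


@dataclass
class SplitPlan:
    protocol: str
    folds: list[tuple[list[str], list[str]]]  # (train video_ids, test video_ids)
    k: int


@dataclass
class VideoScore:
    video_id: str
    score: int
    mean_logits: np.ndarray


def split_clips(video: PoseSequence, T: int = T_DEFAULT) -> list[ClipIndex]:
    """Divide a video into ⌊n/T⌋ disjoint, ordered T-frame clips.

    Trailing frames beyond the last full clip are discarded.
    """
    n = video.n_frames
    if n < T:
        raise TooShortError(f"video {video.meta.video_id!r} has {n} < {T} frames")
    return [
        ClipIndex(video.meta.video_id, m, m * T, (m + 1) * T, video.meta.score)
        for m in range(n // T)
    ]


def cross_entropy(f, s: int) -> float:
    """``-log softmax(f)[s]`` for one S+1-dim logit vector and label ``s``."""
    f = np.asarray(f, dtype=np.float64).reshape(-1)
    if not 0 <= s < f.size:
        raise LabelError(f"label {s} outside 0..{f.size - 1}")
    m = f.max()
    return float(m + np.log(np.exp(f - m).sum()) - f[s])


def sample_training_clips(pool: list, batch_size: int, rng: np.random.Generator) -> list:
    """Uniform draw (with replacement) over the global clip pool."""
    if not pool:
        raise EmptyDatasetError("no clips to sample from")
    idx = rng.integers(0, len(pool), size=batch_size)
    return [pool[i] for i in idx]


def render_clip_tensor(seq: PoseSequence, clip: ClipIndex, map_size: int,
                       sigma: float = 2.0) -> np.ndarray:
    """Heatmap stack for one clip: (J, T, H, W) float32."""
    maps = render_sequence_heatmaps(
        seq, sigma=sigma, map_size=map_size)[clip.frame_start : clip.frame_end]
    return np.ascontiguousarray(maps.transpose(1, 0, 2, 3), dtype=np.float32)


def _build_pool(videos: list[PoseSequence], cfg: TrainConfig):
    """All training clips, pre-rendered once; returns (tensors, labels)."""
    tensors, labels = [], []
    for v in videos:
        full = render_sequence_heatmaps(v, sigma=cfg.sigma, map_size=cfg.map_size)
        for c in split_clips(v, cfg.T):
            t = full[c.frame_start : c.frame_end].transpose(1, 0, 2, 3)
            tensors.append(np.asarray(t, dtype=np.float16))  # pool cache
            labels.append(c.score)
    return tensors, np.asarray(labels)


def train(model: MovementQualityNet, videos: list[PoseSequence],
          cfg: TrainConfig) -> tuple[MovementQualityNet, list[float]]:
    """SGD training over the pooled clips; returns the model and the
    per-epoch mean loss trace.  Deterministic given ``cfg.seed`` and the
    model's own initialization seed."""
    if not videos:
        raise EmptyDatasetError("empty training set")
    tensors, labels = _build_pool(videos, cfg)
    n_clips = len(tensors)
    steps_per_epoch = int(np.ceil(n_clips / cfg.batch_size))
    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(model.parameters(), lr=cfg.lr)
    model.train()
    trace: list[float] = []
    step = 0
    for _epoch in range(cfg.epochs):
        losses = []
        for _ in range(steps_per_epoch):
            idx = rng.integers(0, n_clips, size=cfg.batch_size)
            x = nn.Tensor(np.stack([tensors[i] for i in idx]).astype(np.float32))
            y = labels[idx]
            logits = model(x)
            loss = nn.softmax_cross_entropy(logits, y)
            if not np.isfinite(loss.data):
                raise TrainingFailure("loss diverged (NaN/Inf)", step)
            opt.zero_grad()
            nn.backward(loss)
            opt.step()
            losses.append(float(loss.data))
            step += 1
        trace.append(float(np.mean(losses)))
    return model, trace


def score_video(model: MovementQualityNet, seq: PoseSequence, cfg: TrainConfig,
                aggregate: str = "mean_logits") -> VideoScore:
    """Predict a video's score from all of its clips.

    ``mean_logits`` (default): argmax over classes of the clip-averaged
    final-FC outputs, ties broken toward the lowest score.
    ``max_clip_score``: the maximum of the per-clip argmax scores (the
    alternative aggregation; kept behind this flag).
    """
    clips = split_clips(seq, cfg.T)
    if not clips:
        raise EmptyVideoError(f"video {seq.meta.video_id!r} yields no clips")
    full = render_sequence_heatmaps(seq, sigma=cfg.sigma, map_size=cfg.map_size)
    xs = np.stack([
        full[c.frame_start : c.frame_end].transpose(1, 0, 2, 3) for c in clips
    ]).astype(np.float32)
    model.eval()
    logits = model(nn.Tensor(xs)).data  # (M, S+1)
    mean = logits.mean(axis=0)
    if aggregate == "mean_logits":
        s = int(np.argmax(mean))  # np.argmax takes the first (lowest) maximum
    elif aggregate == "max_clip_score":
        s = int(np.max(np.argmax(logits, axis=1)))
    else:
        raise ValueError(f"unknown aggregation {aggregate!r}")
    return VideoScore(seq.meta.video_id, s, mean)


def spearman_rho(predicted, truth) -> float:
    """Spearman rank correlation with average ranks for ties."""
    predicted = np.asarray(predicted, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if predicted.size != truth.size or predicted.size < 2:
        raise UndefinedCorrelationError("need >= 2 paired scores")
    if np.all(truth == truth[0]):
        raise UndefinedCorrelationError("true scores are constant; rho undefined")
    if np.all(predicted == predicted[0]):
        return 0.0
    return float(stats.spearmanr(predicted, truth).statistic)


# ---------------------------------------------------------------------------
# balancing and splits
# ---------------------------------------------------------------------------


def _temporal_crop(seq: PoseSequence, rng: np.random.Generator, T: int,
                   suffix: str) -> PoseSequence:
    """Random contiguous subsequence, length in [max(T, n/2), n]."""
    n = seq.n_frames
    lo = max(T, n // 2)
    length = int(rng.integers(lo, n + 1))
    start = int(rng.integers(0, n - length + 1))
    out = seq.copy()
    out.joints = out.joints[start : start + length]
    out.meta.video_id = f"{seq.meta.video_id}{suffix}"
    return out


def balance_dataset(videos: list[PoseSequence], rng: np.random.Generator,
                    n_normal: int = 15, max_ratio: float = 2.0,
                    T: int = T_DEFAULT) -> list[PoseSequence]:
    """Subsample normals and augment minority scores by temporal cropping.

    Score-0 videos are randomly subsampled to ``n_normal`` (use 4 for the
    high-resolution sit-stand scale, 15 otherwise) and are exempt from
    augmentation -- their count is exactly what was configured.  Abnormal
    scores whose counts fall below ``max_count / max_ratio`` (max over
    abnormal scores) gain random temporal crops of existing videos of that
    score until the per-score count ratio bound holds.  A score class with
    zero videos is reported, not fabricated.
    """
    by_score: dict[int, list[PoseSequence]] = {}
    for v in videos:
        by_score.setdefault(v.meta.score, []).append(v)
    out: list[PoseSequence] = []
    if 0 in by_score and len(by_score[0]) > n_normal:
        keep = rng.choice(len(by_score[0]), size=n_normal, replace=False)
        by_score[0] = [by_score[0][i] for i in sorted(keep)]
    missing = [s for s, vs in by_score.items() if not vs]
    if missing:
        raise EmptyDatasetError(f"score classes with zero sequences: {missing}")
    abnormal = [s for s in by_score if s != 0]
    max_count = max((len(by_score[s]) for s in abnormal),
                    default=len(by_score.get(0, [])))
    target = int(np.ceil(max_count / max_ratio))
    for s in sorted(by_score):
        vs = list(by_score[s])
        k = 0
        while s != 0 and len(vs) < target:
            src = vs[k % len(by_score[s])]
            vs.append(_temporal_crop(src, rng, T, suffix=f"_crop{k:02d}"))
            k += 1
        out.extend(vs)
    return out


def make_splits(manifest: pd.DataFrame, protocol: str, *, train_view: int | None = None,
                train_views: tuple[int, int] | None = None, k: int | None = None,
                test_fraction: float = 0.3, seed: int = 0) -> SplitPlan:
    """Build train/test folds of video ids under an evaluation protocol.

    ``cross_subject_kfold``: subjects partitioned into k folds (k defaults
    to the number of distinct scores); every fold's test subjects are
    disjoint from its train subjects.  ``cross_view_single``: train on one
    view, test on all others.  ``cross_view_pair``: train on a (frontal,
    side) pair of views.  ``holdout``: stratified-by-score video holdout.
    Every test fold must contain at least two distinct scores.
    """
    rng = np.random.default_rng(seed)
    ids = manifest["video_id"].to_numpy()
    folds: list[tuple[list[str], list[str]]] = []
    if protocol == "cross_subject_kfold":
        subjects = np.sort(manifest["subject"].unique())
        kk = k or manifest["score"].nunique()
        if len(subjects) < kk:
            raise SplitError(f"{len(subjects)} subjects cannot form {kk} folds")
        perm = rng.permutation(subjects)
        groups = np.array_split(perm, kk)
        for grp in groups:
            test_mask = manifest["subject"].isin(grp)
            folds.append((list(ids[~test_mask]), list(ids[test_mask])))
    elif protocol == "cross_view_single":
        views = np.sort(manifest["view"].unique())
        if len(views) < 2:
            raise SplitError("cross-view requires >= 2 views")
        if train_view is None:
            raise SplitError("cross_view_single needs train_view")
        if train_view not in views:
            raise SplitError(f"view {train_view} not in dataset views {list(views)}")
        mask = manifest["view"] == train_view
        folds.append((list(ids[mask]), list(ids[~mask])))
        kk = 1
    elif protocol == "cross_view_pair":
        views = np.sort(manifest["view"].unique())
        if train_views is None or len(train_views) != 2:
            raise SplitError("cross_view_pair needs a (frontal, side) view pair")
        if len(views) < 3:
            raise SplitError("cross_view_pair requires >= 3 views")
        for v in train_views:
            if v not in views:
                raise SplitError(f"view {v} not in dataset views {list(views)}")
        mask = manifest["view"].isin(train_views)
        folds.append((list(ids[mask]), list(ids[~mask])))
        kk = 1
    elif protocol == "holdout":
        test_ids: list[str] = []
        for _s, grp in manifest.groupby("score"):
            gids = grp["video_id"].to_numpy()
            n_test = max(1, int(round(test_fraction * len(gids))))
            pick = rng.choice(len(gids), size=n_test, replace=False)
            test_ids.extend(gids[pick])
        test_set = set(test_ids)
        folds.append(([i for i in ids if i not in test_set],
                      [i for i in ids if i in test_set]))
        kk = 1
    else:
        raise SplitError(f"unknown protocol {protocol!r}")
    if protocol == "cross_subject_kfold":
        kk = len(folds)
    score_of = dict(zip(manifest["video_id"], manifest["score"]))
    for train_ids, test_ids in folds:
        if not train_ids or not test_ids:
            raise SplitError("a fold has an empty train or test set")
        if len({score_of[i] for i in test_ids}) < 2:
            raise SplitError("a test fold contains fewer than 2 distinct scores")
    return SplitPlan(protocol, folds, kk)


def run_experiment(videos: list[PoseSequence], plan: SplitPlan, cfg: TrainConfig,
                   S: int, backbone: str = "tiny",
                   balance: bool = False, n_normal: int = 15) -> pd.DataFrame:
    """Train per fold from scratch and report per-fold Spearman rho.

    Per-fold initialization is freshly seeded with ``cfg.seed + fold``.
    A fold whose training fails is recorded with ``rho = NaN`` and the
    experiment continues.  Returns a report with one row per fold.
    """
    by_id = {v.meta.video_id: v for v in videos}
    rows = []
    for fold, (train_ids, test_ids) in enumerate(plan.folds):
        train_videos = [by_id[i] for i in train_ids]
        test_videos = [by_id[i] for i in test_ids]
        if balance:
            train_videos = balance_dataset(
                train_videos, np.random.default_rng(cfg.seed + fold),
                n_normal=n_normal, T=cfg.T)
        model = MovementQualityNet(S=S, T=cfg.T, map_size=cfg.map_size,
                                   backbone=backbone, stn_enabled=cfg.stn_enabled,
                                   seed=cfg.seed + fold)
        fold_cfg = TrainConfig(lr=cfg.lr, batch_size=cfg.batch_size, epochs=cfg.epochs,
                               seed=cfg.seed + fold, stn_enabled=cfg.stn_enabled,
                               T=cfg.T, map_size=cfg.map_size, sigma=cfg.sigma)
        row = {"fold": fold, "protocol": plan.protocol,
               "stn_flag": cfg.stn_enabled, "n_test_videos": len(test_ids)}
        try:
            model, trace = train(model, train_videos, fold_cfg)
            preds = [score_video(model, v, fold_cfg).score for v in test_videos]
            truth = [v.meta.score for v in test_videos]
            row["rho"] = spearman_rho(preds, truth)
            row["final_loss"] = trace[-1]
        except (TrainingFailure, UndefinedCorrelationError) as e:
            row["rho"] = np.nan
            row["error"] = str(e)
        rows.append(row)
    return pd.DataFrame(rows)
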