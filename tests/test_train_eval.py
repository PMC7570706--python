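"""Clip division, loss values, scoring aggregation, rank correlation,
balancing, split protocols, and training determinism."""

import numpy as np
import pandas as pd
import pytest

from viqa.errors import (
    EmptyDatasetError,
    LabelError,
    SplitError,
    TooShortError,
    UndefinedCorrelationError,
)
from viqa.model import MovementQualityNet
from viqa.pose_heatmaps import VideoMeta
from viqa.synthetic import MovementSpec, simulate_skeleton
from viqa.train_eval import (
    TrainConfig,
    balance_dataset,
    cross_entropy,
    make_splits,
    sample_training_clips,
    score_video,
    spearman_rho,
    split_clips,
    train,
)


def _video(n_frames, score=0, video_id="v", subject=0, view=1):
    seq = simulate_skeleton(MovementSpec.for_score("walk", 0, 4, duration=max(n_frames, 16), seed=1))
    seq.joints = seq.joints[:n_frames]
    seq.meta = VideoMeta(video_id=video_id, subject=subject, view=view,
                         action="synthetic-walk", score=score)
    return seq


class TestSplitClips:
    def test_35_frames_give_two_clips(self):
        clips = split_clips(_video(35), T=16)
        assert [(c.frame_start, c.frame_end) for c in clips] == [(0, 16), (16, 32)]

    def test_exactly_16_frames_give_one_clip(self):
        assert len(split_clips(_video(16), T=16)) == 1

    def test_160_frames_cover_disjointly(self):
        clips = split_clips(_video(160), T=16)
        assert len(clips) == 10
        covered = sorted((c.frame_start, c.frame_end) for c in clips)
        assert covered[0][0] == 0 and covered[-1][1] == 160
        for (a, b), (c, d) in zip(covered, covered[1:]):
            assert b == c  # contiguous, disjoint

    def test_clips_inherit_video_score(self):
        clips = split_clips(_video(48, score=3), T=16)
        assert all(c.score == 3 for c in clips)

    def test_too_short_video_rejected(self):
        with pytest.raises(TooShortError):
            split_clips(_video(15), T=16)


class TestCrossEntropy:
    def test_uniform_logits_give_log_k(self):
        assert cross_entropy(np.zeros(5), 0) == pytest.approx(np.log(5), abs=1e-12)

    def test_saturated_correct_class_near_zero(self):
        f = np.zeros(5)
        f[2] = 20.0
        assert cross_entropy(f, 2) < 1e-8

    def test_reference_fixture(self):
        # -ln(e^3 / (e^1 + e^2 + e^3))
        assert cross_entropy([1.0, 2.0, 3.0], 2) == pytest.approx(0.40760596, abs=1e-6)

    def test_nonnegative_everywhere(self, rng):
        for _ in range(50):
            f = rng.standard_normal(6)
            assert cross_entropy(f, int(rng.integers(0, 6))) >= 0

    def test_out_of_range_label_rejected(self):
        with pytest.raises(LabelError):
            cross_entropy(np.zeros(5), 5)


class TestScoreVideo:
    def _model_with_logits(self, logit_rows):
        """A stand-in scorer that returns canned per-clip logits."""

        class Stub:
            stn_enabled = False

            def __init__(self, rows):
                self.rows = np.asarray(rows, dtype=np.float64)

            def eval(self):
                return self

            def __call__(self, x):
                import viqa.nn as vnn

                return vnn.Tensor(self.rows[: x.data.shape[0]])

        return Stub(logit_rows)

    def test_single_clip_argmax(self):
        model = self._model_with_logits([[0.1, 0.9, 0.2]])
        vs = score_video(model, _video(16), TrainConfig(map_size=32))
        assert vs.score == 1

    def test_hand_computed_average_then_argmax(self):
        # clips (2,0) and (0,1): means (1, 0.5) -> score 0
        model = self._model_with_logits([[2.0, 0.0], [0.0, 1.0]])
        vs = score_video(model, _video(32), TrainConfig(map_size=32))
        assert vs.score == 0
        assert np.allclose(vs.mean_logits, [1.0, 0.5])

    def test_tied_mean_logits_break_to_lowest_score(self):
        model = self._model_with_logits([[1.0, 1.0], [1.0, 1.0]])
        vs = score_video(model, _video(32), TrainConfig(map_size=32))
        assert vs.score == 0

    def test_max_clip_score_variant(self):
        # per-clip argmax: 1 and 0 -> max rule gives 1; mean rule gives 0
        model = self._model_with_logits([[0.0, 3.0], [4.0, 0.0]])
        cfg = TrainConfig(map_size=32)
        assert score_video(model, _video(32), cfg, aggregate="max_clip_score").score == 1
        assert score_video(model, _video(32), cfg, aggregate="mean_logits").score == 0

    def test_random_fixtures_match_hand_rule(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 6))
            rows = rng.standard_normal((m, 5))
            model = self._model_with_logits(rows)
            vs = score_video(model, _video(16 * m), TrainConfig(map_size=32))
            assert vs.score == int(np.argmax(rows.mean(axis=0)))


class TestSpearman:
    def test_perfect_agreement(self):
        assert spearman_rho([0, 1, 2, 3], [0, 1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert spearman_rho([3, 2, 1, 0], [0, 1, 2, 3]) == pytest.approx(-1.0)

    def test_matches_brute_force_rank_then_pearson(self, rng):
        def brute(p, t):
            def avg_ranks(v):
                v = np.asarray(v, dtype=float)
                order = np.argsort(v, kind="stable")
                ranks = np.empty(len(v))
                i = 0
                sv = v[order]
                while i < len(v):
                    j = i
                    while j < len(v) and sv[j] == sv[i]:
                        j += 1
                    ranks[order[i:j]] = (i + j - 1) / 2 + 1
                    i = j
                return ranks

            rp, rt = avg_ranks(p), avg_ranks(t)
            rp -= rp.mean()
            rt -= rt.mean()
            return float((rp * rt).sum() / np.sqrt((rp**2).sum() * (rt**2).sum()))

        assert spearman_rho([1, 2, 3, 5], [1, 2, 4, 3]) == pytest.approx(
            brute([1, 2, 3, 5], [1, 2, 4, 3]), abs=1e-9)
        for _ in range(100):
            n = int(rng.integers(3, 20))
            p = rng.integers(0, 5, n)
            t = rng.integers(0, 5, n)
            if np.all(t == t[0]):
                continue
            assert spearman_rho(p, t) == pytest.approx(brute(p, t), abs=1e-9)

    def test_constant_truth_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1, 2, 3], [2, 2, 2])


class TestSampling:
    def test_batch_within_pool(self, rng):
        pool = list(range(10))
        batch = sample_training_clips(pool, 5, rng)
        assert len(batch) == 5 and all(b in pool for b in batch)

    def test_fixed_seed_reproducible(self):
        pool = list(range(10))
        a = sample_training_clips(pool, 5, np.random.default_rng(3))
        b = sample_training_clips(pool, 5, np.random.default_rng(3))
        assert a == b

    def test_empirical_frequencies_uniform(self):
        """10k draws from a 4-clip pool stay within 3 sigma of uniform."""
        pool = [0, 1, 2, 3]
        rng = np.random.default_rng(0)
        draws = np.concatenate([sample_training_clips(pool, 10, rng) for _ in range(1000)])
        counts = np.bincount(draws, minlength=4)
        n, p = len(draws), 0.25
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 3 * sigma)

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(EmptyDatasetError):
            sample_training_clips([], 5, rng)


class TestBalanceDataset:
    def _videos(self, counts, n_frames=64):
        out = []
        for score, n in counts.items():
            for i in range(n):
                out.append(_video(n_frames, score=score, video_id=f"s{score}_{i}"))
        return out

    def test_normals_subsampled_to_target(self, rng):
        vids = self._videos({0: 41, 1: 12, 2: 10})
        out = balance_dataset(vids, rng, n_normal=15)
        assert sum(1 for v in out if v.meta.score == 0) == 15

    def test_crop_lengths_within_bounds(self, rng):
        vids = self._videos({0: 2, 1: 12, 2: 3}, n_frames=100)
        out = balance_dataset(vids, rng, n_normal=15, max_ratio=2.0)
        crops = [v for v in out if "_crop" in v.meta.video_id]
        assert crops, "augmentation expected for the minority score"
        for c in crops:
            assert 50 <= c.n_frames <= 100 and c.n_frames >= 16

    def test_post_balance_ratio_bound(self, rng):
        vids = self._videos({0: 30, 1: 3, 2: 9, 3: 2})
        out = balance_dataset(vids, rng, n_normal=8, max_ratio=1.5)
        counts = {}
        for v in out:
            counts[v.meta.score] = counts.get(v.meta.score, 0) + 1
        assert counts[0] == 8  # normals: exactly the configured count
        abnormal = [c for s, c in counts.items() if s != 0]
        assert max(abnormal) / min(abnormal) <= 1.5 + 1e-9

    def test_missing_score_class_reported(self, rng):
        vids = self._videos({0: 3, 2: 3})
        vids.append(_video(16, score=1, video_id="ghost"))
        vids = [v for v in vids if v.meta.video_id != "ghost"]
        # class 1 absent entirely is fine (only classes present are balanced);
        # an explicitly empty class list is an error
        out = balance_dataset(vids, rng, n_normal=3)
        assert {v.meta.score for v in out} == {0, 2}


class TestMakeSplits:
    def _manifest(self, n_subjects=10, n_views=6, scores=(0, 1, 2, 3, 4)):
        rows = []
        for s in range(n_subjects):
            for v in range(1, n_views + 1):
                for q in scores:
                    rows.append({"video_id": f"s{s}v{v}q{q}", "subject": s,
                                 "view": v, "action": "synthetic-walk",
                                 "score": q, "n_frames": 64})
        return pd.DataFrame(rows)

    def test_cross_subject_kfold_disjoint_and_exhaustive(self):
        man = self._manifest()
        plan = make_splits(man, "cross_subject_kfold", seed=1)
        assert plan.k == 5  # number of distinct scores
        sub = dict(zip(man.video_id, man.subject))
        seen = set()
        for tr, te in plan.folds:
            tr_s = {sub[i] for i in tr}
            te_s = {sub[i] for i in te}
            assert not tr_s & te_s
            seen |= te_s
        assert seen == set(range(10))

    def test_cross_view_single_tests_all_other_views(self):
        man = self._manifest()
        plan = make_splits(man, "cross_view_single", train_view=2)
        view = dict(zip(man.video_id, man.view))
        tr, te = plan.folds[0]
        assert {view[i] for i in tr} == {2}
        assert {view[i] for i in te} == {1, 3, 4, 5, 6}

    def test_cross_view_pair_tests_remaining_views(self):
        man = self._manifest()
        plan = make_splits(man, "cross_view_pair", train_views=(2, 5))
        view = dict(zip(man.video_id, man.view))
        tr, te = plan.folds[0]
        assert {view[i] for i in tr} == {2, 5}
        assert {view[i] for i in te} == {1, 3, 4, 6}

    def test_single_view_dataset_unsplittable(self):
        man = self._manifest(n_views=1)
        with pytest.raises(SplitError):
            make_splits(man, "cross_view_single", train_view=1)

    def test_every_test_fold_has_two_scores(self):
        man = self._manifest()
        for protocol, kw in [("cross_subject_kfold", {}),
                             ("cross_view_single", {"train_view": 1}),
                             ("holdout", {})]:
            plan = make_splits(man, protocol, seed=0, **kw)
            score = dict(zip(man.video_id, man.score))
            for _tr, te in plan.folds:
                assert len({score[i] for i in te}) >= 2


class TestTrain:
    def test_zero_learning_rate_leaves_weights_unchanged(self, tiny_dataset):
        model = MovementQualityNet(S=2, map_size=32, backbone="tiny", seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items() if not k.startswith("buf")}
        cfg = TrainConfig(lr=0.0, epochs=1, seed=0, map_size=32)
        model, _ = train(model, tiny_dataset[:2], cfg)
        after = model.state_dict()
        for k, v in before.items():
            assert np.array_equal(v, after[k]), k

    def test_same_seed_identical_final_loss(self, tiny_dataset):
        traces = []
        for _ in range(2):
            model = MovementQualityNet(S=2, map_size=32, backbone="tiny", seed=1)
            cfg = TrainConfig(epochs=2, seed=5, map_size=32)
            _, trace = train(model, tiny_dataset, cfg)
            traces.append(trace)
        assert abs(traces[0][-1] - traces[1][-1]) < 1e-6

    def test_loss_trace_length_and_empty_dataset(self, tiny_dataset):
        model = MovementQualityNet(S=2, map_size=32, backbone="tiny", seed=0)
        cfg = TrainConfig(epochs=3, seed=0, map_size=32)
        _, trace = train(model, tiny_dataset, cfg)
        assert len(trace) == 3
        with pytest.raises(EmptyDatasetError):
            train(model, [], cfg)
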