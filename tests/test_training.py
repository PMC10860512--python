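"""Dice loss, subject splits, training-loop contracts, prediction."""

import numpy as np
import pytest

from gtvseg.estimator import AttentionUNetSegmenter
from gtvseg.imaging import window_normalize
from gtvseg.nn.unet import AttentionUNet, NetworkConfig
from gtvseg.phantom import generate_cohort, generate_subject
from gtvseg.training import (
    Checkpoint,
    TrainConfig,
    cohort_to_arrays,
    dice_loss,
    fine_tune,
    fit_network,
    predict_volume,
    preprocess_subject,
    split_subjects,
    train,
)


class TestDiceLoss:
    def test_perfect_prediction_goes_to_zero(self, rng):
        t = (rng.random((8, 8)) > 0.5).astype(float)
        assert dice_loss(t, t, smooth=1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_masks_go_to_one(self):
        p = np.zeros((4, 4))
        t = np.zeros((4, 4))
        p[0, 0] = 1.0
        t[3, 3] = 1.0
        assert dice_loss(p, t, smooth=1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_half_coverage_hand_computation(self):
        """p = 0.5 everywhere, target covers half the image, smooth -> 0:
        Dice = |T| / (0.5N + 0.5N) = 0.5, loss 0.5."""
        n = 16
        t = np.zeros((n, n))
        t[: n // 2] = 1.0
        p = np.full((n, n), 0.5)
        assert dice_loss(p, t, smooth=0.0) == pytest.approx(0.5)

    def test_bounded_and_symmetric_on_binary(self, rng):
        for _ in range(200):
            p = rng.random((6, 6))
            t = (rng.random((6, 6)) > 0.5).astype(float)
            val = dice_loss(p, t)
            assert 0.0 <= val <= 1.0
        pb = (rng.random((6, 6)) > 0.5).astype(float)
        assert dice_loss(pb, t) == pytest.approx(dice_loss(t, pb))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestSplitSubjects:
    def test_ten_percent_of_twenty(self, source_spec):
        cohort = generate_cohort(source_spec, 20, seed=0)
        tr, va = split_subjects(cohort, 0.1, seed=1)
        assert (len(tr), len(va)) == (18, 2)

    def test_partition_properties(self, source_spec):
        cohort = generate_cohort(source_spec, 9, seed=0)
        tr, va = split_subjects(cohort, 0.2, seed=3)
        ids = {s.id for s in tr} | {s.id for s in va}
        assert ids == {s.id for s in cohort}
        assert not ({s.id for s in tr} & {s.id for s in va})

    def test_deterministic(self, source_spec):
        cohort = generate_cohort(source_spec, 9, seed=0)
        a = split_subjects(cohort, 0.2, seed=3)
        b = split_subjects(cohort, 0.2, seed=3)
        assert [s.id for s in a[1]] == [s.id for s in b[1]]

    def test_too_small_cohort(self, source_spec):
        cohort = generate_cohort(source_spec, 1, seed=0)
        with pytest.raises(ValueError):
            split_subjects(cohort, 0.1, seed=0)


def _one_subject_arrays(source_spec, seed=15):
    sub = preprocess_subject(generate_subject(source_spec, seed))
    from gtvseg.imaging import to_slices

    pairs = to_slices(sub.volume, sub.truth_mask, sub.id, include_empty=False)
    X = np.stack([p.image for p in pairs]).astype(np.float32)
    y = np.stack([p.mask for p in pairs]).astype(np.float32)
    return X, y, sub


class TestFitNetwork:
    def test_zero_learning_rate_keeps_weights_and_loss(self, source_spec):
        X, y, _ = _one_subject_arrays(source_spec)
        net = AttentionUNet(NetworkConfig(input_size=64, depth=2, base_channels=2, seed=0))
        before = {k: v.copy() for k, v in net.parameters().items()}
        cfg = TrainConfig(epochs_max=3, batch_size=len(X), learning_rate=0.0, seed=0)
        hist = fit_network(net, X, y, cfg)
        after = net.parameters()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        # constant up to float32 batch-statistics summation order
        assert np.ptp(hist.train_loss) < 1e-6

    def test_same_seed_reproduces_loss_trajectory(self, source_spec):
        X, y, _ = _one_subject_arrays(source_spec)
        cfg = TrainConfig(epochs_max=3, batch_size=2, learning_rate=1e-3, seed=4)
        hists = []
        for _ in range(2):
            net = AttentionUNet(NetworkConfig(input_size=64, depth=2, base_channels=2, seed=9))
            hists.append(fit_network(net, X, y, cfg))
        assert hists[0].train_loss == hists[1].train_loss

    def test_empty_training_set_raises(self):
        net = AttentionUNet(NetworkConfig(input_size=16, depth=2, base_channels=1))
        with pytest.raises(ValueError):
            fit_network(net, np.zeros((0, 16, 16)), np.zeros((0, 16, 16)), TrainConfig(epochs_max=1))


class TestFineTune:
    def test_zero_epochs_is_identity(self, source_spec):
        cohort = generate_cohort(source_spec, 3, seed=2)
        net = AttentionUNet(NetworkConfig(input_size=64, depth=2, base_channels=2, seed=0))
        ckpt = Checkpoint.from_net(net, {"cohort": "source"})
        ckpt2, hist = fine_tune(ckpt, cohort, TrainConfig(epochs_max=0, seed=1))
        assert all(np.array_equal(ckpt.state[k], ckpt2.state[k]) for k in ckpt.state)
        assert hist.train_loss == []

    def test_incompatible_checkpoint_rejected(self, tiny_net_cfg):
        net = AttentionUNet(tiny_net_cfg)
        state = net.state_dict()
        other = AttentionUNet(NetworkConfig(input_size=16, depth=2, base_channels=3))
        with pytest.raises(ValueError):
            other.load_state_dict(state)


class TestPredictVolume:
    def _ckpt(self):
        net = AttentionUNet(NetworkConfig(input_size=64, depth=2, base_channels=2, seed=0))
        return Checkpoint.from_net(net)

    def test_threshold_above_one_gives_empty_mask(self, source_spec):
        sub = preprocess_subject(generate_subject(source_spec, 5))
        mask = predict_volume(self._ckpt(), sub.volume, threshold=1.0 + 1e-6)
        assert mask.sum() == 0

    def test_shape_preserved(self, source_spec):
        sub = preprocess_subject(generate_subject(source_spec, 5))
        mask = predict_volume(self._ckpt(), sub.volume)
        assert mask.shape == sub.volume.shape

    def test_requires_normalized_volume(self, source_spec):
        sub = generate_subject(source_spec, 5)
        with pytest.raises(ValueError):
            predict_volume(self._ckpt(), sub.volume)


class TestCohortToArrays:
    def test_empty_slice_cap(self, source_spec):
        cohort = generate_cohort(source_spec, 3, seed=1)
        X_all, y_all = cohort_to_arrays(cohort, include_empty=True)
        X_cap, y_cap = cohort_to_arrays(cohort, include_empty=True, max_empty_ratio=0.5, seed=0)
        n_pos = int((y_all.sum(axis=(1, 2)) > 0).sum())
        n_empty_cap = int((y_cap.sum(axis=(1, 2)) == 0).sum())
        assert n_empty_cap == min(len(X_all) - n_pos, round(0.5 * n_pos))
        assert int((y_cap.sum(axis=(1, 2)) > 0).sum()) == n_pos


class TestEstimator:
    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = AttentionUNetSegmenter(depth=2, base_channels=2, epochs=1)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            AttentionUNetSegmenter().predict_proba(np.zeros((1, 64, 64)))

    def test_fit_predict_shapes_and_warm_start(self, source_spec):
        X, y, _ = _one_subject_arrays(source_spec)
        est = AttentionUNetSegmenter(input_size=64, depth=2, base_channels=2,
                                     epochs=2, learning_rate=1e-3, warm_start=True,
                                     random_state=0)
        est.fit(X, y)
        w_first = {k: v.copy() for k, v in est.model_.parameters().items()}
        proba = est.predict_proba(X)
        assert proba.shape == X.shape and np.all((proba > 0) & (proba < 1))
        assert est.predict(X).dtype == np.uint8
        est.fit(X, y)  # continues training rather than re-initializing
        assert any(not np.array_equal(w_first[k], v) for k, v in est.model_.parameters().items())

    def test_rejects_unnormalized_input(self):
        est = AttentionUNetSegmenter(input_size=16, depth=2, base_channels=1, epochs=1)
        with pytest.raises(ValueError):
            est.fit(np.full((2, 16, 16), 7.0), np.zeros((2, 16, 16)))
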