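"""Segmentation, training mechanics and the cross-validation protocol."""

import numpy as np
import pytest

from tonosyl.core_io import EventTable, FeatureMatrix, SyllableInventory
from tonosyl.decoder import (CVResult, SegmentSpec, StackedRecurrentConfig,
                             TrainConfig, TrialSegment, confusion,
                             cross_validate_10fold, downsample_features,
                             extract_segments, focal_loss, mixup_batch,
                             one_hot, repetition_curve, segments_to_arrays,
                             train_decoder)
from tonosyl.core_io import ValidationError


@pytest.fixture(scope="module")
def features_and_events(rng=None):
    rng = np.random.default_rng(3)
    import pandas as pd
    fm = FeatureMatrix(rng.standard_normal((600, 5)), 100.0,
                       np.arange(600) / 100.0)
    df = pd.DataFrame({
        "trial_id": [0, 1, 2],
        "onset_s": [0.1, 2.0, 4.5],
        "syllable": ["ma", "shi", "ma"],
        "tone": [1, 3, 4],
        "character": ["马", "是", "骂"],
        "task": "char",
    })
    return fm, EventTable(df), SyllableInventory(["ma", "shi"])


class TestSegmentation:
    def test_segment_has_100_frames(self, features_and_events):
        fm, ev, inv = features_and_events
        segs = extract_segments(fm, ev, inv, SegmentSpec())
        assert all(s.features.shape == (100, 5) for s in segs)

    def test_event_too_early_dropped(self, features_and_events, caplog):
        fm, ev, inv = features_and_events
        with caplog.at_level("INFO"):
            segs = extract_segments(fm, ev, inv, SegmentSpec())
        assert len(segs) == 2           # t=0.1 s lacks the 300-ms pre window
        assert {s.trial_id for s in segs} == {1, 2}

    def test_content_matches_brute_force_slice(self, features_and_events):
        fm, ev, inv = features_and_events
        segs = extract_segments(fm, ev, inv, SegmentSpec())
        s = segs[0]                     # onset at 2.0 s
        lo = round((2.0 - 0.3) * 100)
        np.testing.assert_array_equal(s.features, fm.data[lo: lo + 100])

    def test_labels_carried(self, features_and_events):
        fm, ev, inv = features_and_events
        segs = extract_segments(fm, ev, inv, SegmentSpec())
        assert segs[0].label_syllable == inv.index("shi")
        assert segs[0].label_tone == 3

    def test_downsample_averages_groups(self):
        data = np.arange(8, dtype=float)[:, None]
        fm = FeatureMatrix(data, 400.0, np.arange(8) / 400.0)
        out = downsample_features(fm, 100.0)
        np.testing.assert_allclose(out.data[:, 0], [1.5, 5.5])
        assert out.frame_rate_hz == 100.0


class TestMixupAndLosses:
    def test_lambda_one_is_identity(self, rng):
        x, y = rng.standard_normal((4, 5)), one_hot(np.array([0, 1, 2, 3]), 4)
        xm, ym = mixup_batch(x, y, rng.standard_normal((4, 5)),
                             one_hot(np.array([3, 2, 1, 0]), 4), 1.0)
        np.testing.assert_array_equal(xm, x)
        np.testing.assert_array_equal(ym, y)

    def test_half_mix_of_constants(self):
        x0, x1 = np.zeros((2, 3)), np.full((2, 3), 2.0)
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        xm, ym = mixup_batch(x0, y, x1, y[::-1], 0.5)
        np.testing.assert_array_equal(xm, np.ones((2, 3)))
        np.testing.assert_allclose(ym.sum(axis=1), 1.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            mixup_batch(np.zeros((2, 3)), np.zeros((2, 2)),
                        np.zeros((3, 3)), np.zeros((3, 2)), 0.5)

    def test_focal_scalar_hand_value(self):
        p = np.array([[0.5, 0.5]])
        y = np.array([[1.0, 0.0]])
        assert focal_loss(p, y, 2.0) == pytest.approx(0.25 * np.log(2))


def _toy_segments(rng, n_per_class=6, n_classes=3, T=12, C=4, sep=2.0):
    """Feature-level segments with class-dependent channel means."""
    segs = []
    for c in range(n_classes):
        for _ in range(n_per_class):
            x = rng.standard_normal((T, C))
            x[:, c % C] += sep
            segs.append(TrialSegment(x, c, (c % 4) + 1))
    return segs


@pytest.fixture(scope="module")
def toy_trained():
    rng = np.random.default_rng(5)
    segs = _toy_segments(rng)
    cfg = TrainConfig(seed=2, max_epochs=30, batch_size=8, mixup_alpha=0.2)
    model = train_decoder(segs, "syllable",
                          StackedRecurrentConfig(hidden1=4, hidden2=3),
                          cfg, n_classes=3)
    return segs, model


class TestTraining:
    def test_separable_data_learned(self, toy_trained):
        segs, model = toy_trained
        X, y = segments_to_arrays(segs, "syllable")
        assert (model.predict_batch(X).argmax(axis=1) == y).mean() >= 0.9

    def test_fixed_seed_reproduces_weights(self):
        rng = np.random.default_rng(5)
        segs = _toy_segments(rng)
        cfg = TrainConfig(seed=2, max_epochs=5, batch_size=8)
        kw = dict(model_cfg=StackedRecurrentConfig(hidden1=4, hidden2=3),
                  train_cfg=cfg, n_classes=3)
        m1 = train_decoder(segs, "syllable", **kw)
        m2 = train_decoder(segs, "syllable", **kw)
        for k, v in m1.net.named_params().items():
            np.testing.assert_array_equal(v, m2.net.named_params()[k])

    def test_single_class_rejected(self, rng):
        segs = [TrialSegment(rng.standard_normal((10, 3)), 0, 1)
                for _ in range(6)]
        with pytest.raises(ValidationError):
            train_decoder(segs, "syllable")

    def test_history_records_epochs(self, toy_trained):
        _, model = toy_trained
        h = model.history
        assert len(h["train_loss"]) == len(h["val_acc"]) == len(h["lr"])
        assert len(h["train_loss"]) >= 1

    def test_predict_probs_on_simplex_and_deterministic(self, toy_trained):
        segs, model = toy_trained
        p1 = model.predict_probs(segs[0])
        p2 = model.predict_probs(segs[0])
        np.testing.assert_array_equal(p1, p2)
        assert p1.sum() == pytest.approx(1.0, abs=1e-6)

    def test_probs_equal_mean_of_per_timestep_softmax(self, toy_trained):
        segs, model = toy_trained
        x = segs[0].features[None]
        probs, caches = model.net.forward(x)
        per_t = caches[-1]              # per-timestep distributions
        np.testing.assert_allclose(probs, per_t.mean(axis=1), atol=1e-12)


class TestCrossValidation:
    def test_fold_bookkeeping_and_ci(self):
        rng = np.random.default_rng(6)
        segs = _toy_segments(rng, n_per_class=10, n_classes=3)
        cv = cross_validate_10fold(
            segs, "syllable", StackedRecurrentConfig(hidden1=3, hidden2=2),
            TrainConfig(seed=0, max_epochs=3, batch_size=16),
            n_folds=5, n_bootstrap=200)
        assert cv.fold_accuracies.size == 5
        assert cv.ci99[0] <= cv.median <= cv.ci99[1]

    def test_split_proportions(self):
        """90% remainder splits 70/30: with 100 trials, 63 train / 27 val."""
        rest = 90
        n_val = int(round(0.3 * rest))
        assert (rest - n_val, n_val) == (63, 27)

    def test_vocab_curve_subsets_are_seeded(self):
        from tonosyl.decoder import vocab_curve
        rng = np.random.default_rng(8)
        segs = _toy_segments(rng, n_per_class=8, n_classes=4)
        kw = dict(model_cfg=StackedRecurrentConfig(hidden1=3, hidden2=2),
                  train_cfg=TrainConfig(seed=0, max_epochs=2, batch_size=16),
                  n_folds=3, n_bootstrap=50)
        a = vocab_curve(segs, "syllable", sizes=(2,), n_repeats=2, seed=1, **kw)
        b = vocab_curve(segs, "syllable", sizes=(2,), n_repeats=2, seed=1, **kw)
        assert len(a[2]) == 2
        np.testing.assert_array_equal(a[2][0].fold_accuracies,
                                      b[2][0].fold_accuracies)

    def test_repetition_curve_uses_all_when_short(self, caplog):
        rng = np.random.default_rng(7)
        segs = _toy_segments(rng, n_per_class=3, n_classes=3)
        with caplog.at_level("INFO"):
            out = repetition_curve(
                segs, "syllable", reps_list=(5,),
                model_cfg=StackedRecurrentConfig(hidden1=3, hidden2=2),
                train_cfg=TrainConfig(seed=0, max_epochs=2, batch_size=16),
                n_folds=3, n_bootstrap=50)
        assert isinstance(out[5], CVResult)


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 0, 1, 2, 2, 2])
        m = confusion(y, y, 3)
        assert np.array_equal(np.diag(m), [2, 1, 3])
        assert m.sum() == 6 and np.triu(m, 1).sum() + np.tril(m, -1).sum() == 0

    def test_total_is_conserved(self, rng):
        truth = rng.integers(0, 4, 50)
        pred = rng.integers(0, 4, 50)
        assert confusion(pred, truth, 4).sum() == 50
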