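"""Dual-stream syllable/tone decoding: segments, training, evaluation.

A trial is a 1000-ms window of 100-Hz high-gamma features from -300 to
+700 ms around speech onset (100 frames x good channels). Two stacked
bidirectional recurrent classifiers share this input: the syllable stream
(cross-entropy) and the tone stream (focal loss, since tone proportions are
imbalanced). Both use mixup augmentation, Adam with a plateau learning-rate
schedule, and keep the best-validation-accuracy checkpoint. Per-timestep
class distributions are averaged over the segment to give the trial
probability vector.

Evaluation follows the offline protocol: 10 disjoint test folds of 10% each,
with the remaining 90% split 70/30 into training (63% of total) and
validation (27%), plus learning curves over repetitions per syllable and
inventory size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import EventTable, FeatureMatrix, SyllableInventory, ValidationError
from . import nn

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentSpec:
    pre_onset_ms: float = 300.0
    post_onset_ms: float = 700.0
    frame_rate_hz: float = 100.0

    @property
    def n_frames(self) -> int:
        return int(round((self.pre_onset_ms + self.post_onset_ms) / 1000
                         * self.frame_rate_hz))


@dataclass
class TrialSegment:
    features: np.ndarray            # (n_frames, n_channels)
    label_syllable: int             # class index into the inventory
    label_tone: int                 # 1..4
    trial_id: int = -1
    character: str = ""
    onset_s: float = np.nan
    sentence_id: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.features).all():
            raise ValidationError("segment contains NaN")


def downsample_features(fm: FeatureMatrix, target_hz: float = 100.0) -> FeatureMatrix:
    """Average consecutive frame groups to reach an integer-divisor rate."""
    factor = fm.frame_rate_hz / target_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValidationError("target rate must divide the frame rate")
    f = int(round(factor))
    if f == 1:
        return fm
    n = (fm.n_frames // f) * f
    data = fm.data[:n].reshape(n // f, f, fm.n_channels).mean(axis=1)
    times = fm.frame_times_s[f - 1: n: f]   # right edge of each group
    return FeatureMatrix(data, target_hz, times, zscored=fm.zscored,
                         norm_mean=fm.norm_mean, norm_sd=fm.norm_sd,
                         channel_ids=fm.channel_ids)


def extract_segments(features: FeatureMatrix, events: EventTable,
                     inventory: SyllableInventory,
                     spec: SegmentSpec | None = None,
                     onsets_s: np.ndarray | None = None) -> list[TrialSegment]:
    """One segment per event, dropped (with a logged count) at session edges.

    ``onsets_s`` overrides the annotated onsets with detected ones (same
    ordering) for closed-loop evaluation.
    """
    spec = spec or SegmentSpec(frame_rate_hz=features.frame_rate_hz)
    rate = features.frame_rate_hz
    pre = int(round(spec.pre_onset_ms / 1000 * rate))
    n_frames = spec.n_frames
    onsets = events.onsets_s if onsets_s is None else np.asarray(onsets_s)
    t0 = features.frame_times_s[0]
    segments = []
    dropped = 0
    for i, (_, row) in enumerate(events.df.iterrows()):
        onset_idx = int(round((onsets[i] - t0) * rate))
        lo = onset_idx - pre
        if lo < 0 or lo + n_frames > features.n_frames:
            dropped += 1
            continue
        sid = row["sentence_id"]
        segments.append(TrialSegment(
            features.data[lo: lo + n_frames].copy(),
            inventory.index(row["syllable"]), int(row["tone"]),
            trial_id=int(row["trial_id"]), character=str(row["character"]),
            onset_s=float(onsets[i]),
            sentence_id=None if pd.isna(sid) else int(sid)))
    if dropped:
        logger.info("dropped %d event(s) too close to session edges", dropped)
    return segments


def segments_to_arrays(segments: list[TrialSegment],
                       stream: str) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.features for s in segments])
    if stream == "syllable":
        y = np.array([s.label_syllable for s in segments])
    elif stream == "tone":
        y = np.array([s.label_tone - 1 for s in segments])
    else:
        raise ValueError("stream must be 'syllable' or 'tone'")
    return X, y


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class StackedRecurrentConfig:
    hidden1: int = 250      # per direction; block output 500
    hidden2: int = 100      # per direction; block output 200
    dropout: float = 0.3


@dataclass
class TrainConfig:
    lr: float = 1e-2
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 12              # early stop on stale validation accuracy
    lr_patience: int = 4
    mixup_alpha: float = 0.2        # 0 disables mixup
    focal_gamma: float = 2.0        # tone stream only
    val_fraction: float = 0.3
    stop_at_val_acc: float | None = 0.999   # early exit; None trains to patience
    seed: int = 0


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


def mixup_batch(x_a, y_a, x_b, y_b, lam: float):
    """Convex combination of two batches and their (soft) labels."""
    if x_a.shape != x_b.shape or y_a.shape != y_b.shape:
        raise ValidationError("mixup shape mismatch")
    if not 0.0 <= lam <= 1.0:
        raise ValidationError("lambda must lie in [0,1]")
    return lam * x_a + (1 - lam) * x_b, lam * y_a + (1 - lam) * y_b


def focal_loss(probs: np.ndarray, targets: np.ndarray, gamma: float = 2.0) -> float:
    """Batch-mean focal loss on probability vectors (scalar value)."""
    return nn.focal_loss(probs, targets, gamma)[0]


@dataclass
class DecoderModel:
    """A trained stream decoder with its class map and training history."""

    net: nn.StackedBiLSTM
    stream: str                                 # 'syllable' | 'tone'
    class_names: list[str]
    history: dict[str, list] = field(default_factory=dict)

    def predict_probs(self, segment: TrialSegment | np.ndarray) -> np.ndarray:
        x = segment.features if isinstance(segment, TrialSegment) else segment
        return self.net.predict_proba(x[None])[0]

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(X)


def train_decoder(segments: list[TrialSegment], stream: str,
                  model_cfg: StackedRecurrentConfig | None = None,
                  train_cfg: TrainConfig | None = None,
                  class_names: list[str] | None = None,
                  val_segments: list[TrialSegment] | None = None,
                  warm_start: DecoderModel | None = None,
                  n_classes: int | None = None) -> DecoderModel:
    """Train one stream's decoder; returns the best-validation checkpoint.

    With ``warm_start`` this is fine-tuning: training continues from the
    given weights at a tenth of the configured learning rate.
    """
    model_cfg = model_cfg or StackedRecurrentConfig()
    cfg = train_cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    X, y = segments_to_arrays(segments, stream)
    if n_classes is None:
        n_classes = 4 if stream == "tone" else int(y.max()) + 1
    if np.unique(y).size < 2:
        raise ValidationError("need >=2 classes to train")

    if val_segments is not None:
        Xv, yv = segments_to_arrays(val_segments, stream)
    else:
        order = rng.permutation(len(y))
        n_val = max(1, int(round(cfg.val_fraction * len(y))))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        X, Xv = X[tr_idx], X[val_idx]
        y, yv = y[tr_idx], y[val_idx]
    Y = one_hot(y, n_classes)

    if warm_start is not None:
        net = warm_start.net
        lr = cfg.lr * 0.1
    else:
        net = nn.StackedBiLSTM(X.shape[2], n_classes, model_cfg.hidden1,
                               model_cfg.hidden2, model_cfg.dropout,
                               seed=cfg.seed)
        lr = cfg.lr
    opt = nn.Adam(net, lr=lr)
    sched = nn.ReduceLROnPlateau(opt, patience=cfg.lr_patience)
    gamma = cfg.focal_gamma if stream == "tone" else 0.0

    history = {"train_loss": [], "val_loss": [], "val_acc": [], "lr": []}
    best_key, best_w, stale = (-1.0, -np.inf), net.get_weights(), 0
    n = len(y)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            if cfg.mixup_alpha > 0:
                lam = float(rng.beta(cfg.mixup_alpha, cfg.mixup_alpha))
                perm = rng.permutation(len(idx))
                xb, yb = mixup_batch(xb, yb, xb[perm], yb[perm], lam)
            probs, caches = net.forward(xb, train=True, rng=rng)
            loss, dprobs = nn.focal_loss(probs, yb, gamma) if gamma > 0 \
                else nn.cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: check inputs/lr")
            net.backward(dprobs, caches)
            opt.step()
            losses.append(loss)
        pv = net.predict_proba(Xv)
        val_loss = nn.cross_entropy(pv, one_hot(yv, n_classes))[0]
        val_acc = float((pv.argmax(axis=1) == yv).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)
        sched.step(val_loss)
        key = (val_acc, -val_loss)      # best accuracy, ties to sharper model
        if key > best_key:
            best_w = net.get_weights()
            stale = 0 if val_acc > best_key[0] else stale + 1
            best_key = key
        else:
            stale += 1
        if stale > cfg.patience:
            break
        if cfg.stop_at_val_acc is not None and best_key[0] >= cfg.stop_at_val_acc \
                and epoch >= 2:
            break
    net.set_weights(best_w)
    best_acc = best_key[0]
    if class_names is None:
        class_names = (["1", "2", "3", "4"] if stream == "tone"
                       else [str(i) for i in range(n_classes)])
    return DecoderModel(net, stream, class_names, history)


def fine_tune(model: DecoderModel, segments: list[TrialSegment],
              train_cfg: TrainConfig | None = None) -> DecoderModel:
    """Continue training on (sentence-task) segments at a reduced rate."""
    return train_decoder(segments, model.stream, train_cfg=train_cfg,
                         class_names=model.class_names, warm_start=model,
                         n_classes=model.net.n_classes)


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    median: float
    ci99: tuple[float, float]


def cross_validate_10fold(segments: list[TrialSegment], stream: str,
                          model_cfg: StackedRecurrentConfig | None = None,
                          train_cfg: TrainConfig | None = None,
                          n_folds: int = 10, seed: int = 0,
                          n_bootstrap: int = 1000) -> CVResult:
    """Disjoint 10-fold CV with the 63/27/10 train/validation/test split.

    Each fold holds out 10% as the test set; the remaining 90% is split 70/30
    into training and validation. Reports per-fold test accuracy, the median,
    and a 99% bootstrap CI (1000 resamples of the fold accuracies).
    """
    if len(segments) < n_folds:
        raise ValidationError("need at least one trial per fold")
    rng = np.random.default_rng(seed)
    cfg = train_cfg or TrainConfig()
    order = rng.permutation(len(segments))
    folds = np.array_split(order, n_folds)
    _, y_all = segments_to_arrays(segments, stream)
    n_classes = 4 if stream == "tone" else int(y_all.max()) + 1
    accs = []
    for k, test_idx in enumerate(folds):
        rest = np.concatenate([f for j, f in enumerate(folds) if j != k])
        rest = rng.permutation(rest)
        n_val = int(round(0.3 * len(rest)))
        val_idx, tr_idx = rest[:n_val], rest[n_val:]
        tr = [segments[i] for i in tr_idx]
        _, ytr = segments_to_arrays(tr, stream)
        if np.unique(ytr).size < n_classes:
            warnings.warn(f"fold {k}: class absent from training split")
        model = train_decoder(tr, stream, model_cfg,
                              train_cfg=cfg,
                              val_segments=[segments[i] for i in val_idx],
                              n_classes=n_classes)
        Xte, yte = segments_to_arrays([segments[i] for i in test_idx], stream)
        accs.append(float((model.predict_batch(Xte).argmax(axis=1) == yte).mean()))
    accs = np.array(accs)
    boot = np.array([np.median(rng.choice(accs, size=accs.size))
                     for _ in range(n_bootstrap)])
    return CVResult(accs, float(np.median(accs)),
                    (float(np.percentile(boot, 0.5)),
                     float(np.percentile(boot, 99.5))))


def repetition_curve(segments: list[TrialSegment], stream: str,
                     reps_list=(5, 10, 15, 20), seed: int = 0,
                     **cv_kwargs) -> dict[int, CVResult]:
    """CV accuracy as a function of repetitions per syllable.

    Subsamples without replacement per syllable; syllables with fewer trials
    than the target contribute all their trials (logged).
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for i, s in enumerate(segments):
        by_class.setdefault(s.label_syllable, []).append(i)
    out = {}
    for reps in reps_list:
        idx = []
        for c, members in sorted(by_class.items()):
            if len(members) <= reps:
                if len(members) < reps:
                    logger.info("class %d has %d < %d trials; using all",
                                c, len(members), reps)
                idx.extend(members)
            else:
                idx.extend(rng.choice(members, size=reps, replace=False))
        out[reps] = cross_validate_10fold([segments[i] for i in idx], stream,
                                          seed=seed, **cv_kwargs)
    return out


def vocab_curve(segments: list[TrialSegment], stream: str,
                sizes=(50, 100, 150, 200, 250, 300, 350), n_repeats: int = 10,
                seed: int = 0, **cv_kwargs) -> dict[int, list[CVResult]]:
    """CV accuracy as a function of inventory size, repeated subsampling.

    Picks random syllable subsets of each size (``n_repeats`` independent
    draws), relabels classes within the subset, and runs the CV protocol.
    """
    rng = np.random.default_rng(seed)
    classes = sorted({s.label_syllable for s in segments})
    out: dict[int, list[CVResult]] = {}
    for size in sizes:
        if size > len(classes):
            raise ValidationError(f"size {size} exceeds {len(classes)} classes")
        reps = 1 if size == len(classes) else n_repeats
        results = []
        for _ in range(reps):
            subset = set(rng.choice(classes, size=size, replace=False).tolist())
            remap = {c: i for i, c in enumerate(sorted(subset))}
            sub = [TrialSegment(s.features, remap[s.label_syllable], s.label_tone,
                                s.trial_id, s.character, s.onset_s, s.sentence_id)
                   for s in segments if s.label_syllable in subset]
            results.append(cross_validate_10fold(sub, stream, seed=seed,
                                                 **cv_kwargs))
        out[size] = results
    return out


def confusion(predictions: np.ndarray, truths: np.ndarray,
              n_classes: int) -> np.ndarray:
    """Confusion-count matrix, rows = truth, columns = prediction."""
    m = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(m, (np.asarray(truths), np.asarray(predictions)), 1)
    return m
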