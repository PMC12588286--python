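"""Speech-onset detection from audio power and from neural features.

Two detectors, as deployed in practice:

* **Audio**: short-time power over a 25-ms sliding window, moving-average
  smoothed, thresholded at 1.6x the mean smoothed power, with a refractory
  period between declared onsets.

* **Neural**: a 15-frame (150 ms) bidirectional contextual feature vector is
  built around each 100-Hz high-gamma frame, reduced to its top 50 principal
  components, and scored by a two-class linear discriminant that outputs a
  continuous onset probability. The probability trace is smoothed over 2
  frames and an onset is declared when it exceeds 0.45 for 14 consecutive
  frames. The declared onset time is the *start* of the qualifying run; the
  detector's fixed algorithmic latency is the 70-ms future context plus the
  140-ms consecutive-window rule = 210 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core_io import EventTable, FeatureMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class OnsetEvent:
    time_s: float
    score: float
    source: str                 # 'audio' | 'neural'
    latency_ms: float = 0.0     # fixed pipeline delay before declaration


# ---------------------------------------------------------------------------
# Audio detector
# ---------------------------------------------------------------------------

@dataclass
class AudioOnsetConfig:
    power_window_ms: float = 25.0
    smooth_ms: float = 50.0
    threshold_factor: float = 1.6
    refractory_s: float = 0.5

    def __post_init__(self) -> None:
        if self.power_window_ms <= 0 or self.threshold_factor <= 0:
            raise ValidationError("window and threshold factor must be positive")


def _causal_moving_average(x: np.ndarray, n: int) -> np.ndarray:
    return signal.lfilter(np.full(n, 1.0 / n), [1.0], x)


def audio_detect(waveform: np.ndarray, rate_hz: float,
                 cfg: AudioOnsetConfig | None = None) -> list[OnsetEvent]:
    """Onsets at upward crossings of smoothed short-time power."""
    cfg = cfg or AudioOnsetConfig()
    x = np.asarray(waveform, dtype=float)
    if x.size == 0 or not np.abs(x).max() > 0:
        return []
    n_pow = max(1, int(round(cfg.power_window_ms / 1000 * rate_hz)))
    n_smooth = max(1, int(round(cfg.smooth_ms / 1000 * rate_hz)))
    power = _causal_moving_average(x * x, n_pow)
    smoothed = _causal_moving_average(power, n_smooth)
    thresh = cfg.threshold_factor * smoothed.mean()
    above = smoothed > thresh
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    events: list[OnsetEvent] = []
    last = -np.inf
    for idx in crossings:
        t = idx / rate_hz
        if t - last >= cfg.refractory_s:
            events.append(OnsetEvent(t, float(smoothed[idx]), "audio"))
            last = t
    return events


# ---------------------------------------------------------------------------
# Neural detector
# ---------------------------------------------------------------------------

@dataclass
class NeuralOnsetConfig:
    context_halfwidth: int = 7          # frames of past AND future context
    pca_components: int = 50
    prob_smooth_frames: int = 2
    threshold: float = 0.45
    consecutive_required: int = 14
    refractory_s: float = 0.6
    # training labels: frames in [-pre, +post] ms around a true onset are
    # positive. The post margin must comfortably exceed the consecutive-
    # window rule's duration (140 ms), otherwise the probability trace
    # cannot stay high long enough for any onset to be declared.
    label_margin_pre_ms: float = 30.0
    label_margin_post_ms: float = 300.0
    guard_ms: float = 380.0             # exclusion zone around positives


def build_context(features: FeatureMatrix, t: int,
                  halfwidth: int = 7) -> np.ndarray:
    """Bidirectional contextual vector for frame t, channel-major order.

    Concatenates frames t-hw .. t+hw: for each channel its 2*hw+1 time points
    are contiguous in the output.
    """
    if t < halfwidth or t > features.n_frames - halfwidth - 1:
        raise ValidationError(f"frame {t} lacks +-{halfwidth} frames of context")
    return features.data[t - halfwidth: t + halfwidth + 1].T.ravel()


def _context_matrix(data: np.ndarray, halfwidth: int) -> tuple[np.ndarray, np.ndarray]:
    """All valid contextual vectors at once; returns (X, frame_indices)."""
    n, c = data.shape
    w = 2 * halfwidth + 1
    if n < w:
        return np.zeros((0, w * c)), np.zeros(0, dtype=int)
    sw = np.lib.stride_tricks.sliding_window_view(data, w, axis=0)  # (n-w+1, c, w)
    X = sw.reshape(n - w + 1, c * w)
    return X, np.arange(halfwidth, n - halfwidth)


@dataclass
class NeuralOnsetModel:
    """PCA -> LDA onset-probability model plus the streaming decision rule."""

    pca: PCA
    lda: LinearDiscriminantAnalysis
    cfg: NeuralOnsetConfig
    frame_rate_hz: float = 100.0

    @property
    def latency_ms(self) -> float:
        """Fixed algorithmic detection latency of the real-time detector.

        Future context of the bidirectional window plus the duration of the
        consecutive-window decision rule (e.g. 70 + 140 = 210 ms).
        """
        frame_ms = 1000.0 / self.frame_rate_hz
        return (self.cfg.context_halfwidth
                + self.cfg.consecutive_required) * frame_ms

    def frame_probs(self, features: FeatureMatrix) -> np.ndarray:
        """Onset probability per frame (edge frames without context get 0)."""
        X, idx = _context_matrix(features.data, self.cfg.context_halfwidth)
        probs = np.zeros(features.n_frames)
        if len(idx):
            scores = self.pca.transform(X)
            probs[idx] = self.lda.predict_proba(scores)[:, 1]
        return probs


def train_neural_onset(features: FeatureMatrix, events: EventTable,
                       cfg: NeuralOnsetConfig | None = None,
                       seed: int = 0) -> NeuralOnsetModel:
    """Fit the PCA+LDA onset model from ground-truth annotations.

    Frames inside the onset label window are positives; frames inside the
    surrounding guard band are excluded from the negatives so boundary
    frames do not inject label noise.
    """
    cfg = cfg or NeuralOnsetConfig()
    X, idx = _context_matrix(features.data, cfg.context_halfwidth)
    times = features.frame_times_s[idx]
    onsets = events.onsets_s
    if len(onsets) == 0:
        raise ValidationError("no events to label")
    delta = times[:, None] - onsets[None, :]            # signed, per onset
    pos = ((delta >= -cfg.label_margin_pre_ms / 1000)
           & (delta <= cfg.label_margin_post_ms / 1000)).any(axis=1)
    neg = (np.abs(delta) > cfg.guard_ms / 1000).all(axis=1)
    keep = pos | neg
    y = pos[keep].astype(int)
    if y.min() == y.max():
        raise ValidationError("labeling produced a single class")
    n_comp = min(cfg.pca_components, X.shape[1], int(keep.sum()) - 1)
    if n_comp < cfg.pca_components:
        logger.info("PCA reduced to %d components (feature dim limit)", n_comp)
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(X[keep])
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores, y)
    return NeuralOnsetModel(pca, lda, cfg, features.frame_rate_hz)


def smooth_probs(probs: np.ndarray, n: int) -> np.ndarray:
    """Causal moving average over the trailing n frames."""
    return _causal_moving_average(probs, n)


def neural_detect_stream(model: NeuralOnsetModel,
                         features: FeatureMatrix | None = None,
                         probs: np.ndarray | None = None,
                         frame_times_s: np.ndarray | None = None
                         ) -> list[OnsetEvent]:
    """Apply the consecutive-window decision rule to a probability trace.

    Either pass ``features`` (probabilities computed internally) or a raw
    ``probs`` trace. Declares an onset once the smoothed probability exceeds
    the threshold for ``consecutive_required`` frames; the event time is the
    first frame of the qualifying run and the fixed latency is recorded on
    the event. The detector re-arms after the refractory period.
    """
    cfg = model.cfg
    if probs is None:
        probs = model.frame_probs(features)
        frame_times_s = features.frame_times_s
    if frame_times_s is None:
        frame_times_s = np.arange(probs.size) / model.frame_rate_hz
    sm = smooth_probs(np.asarray(probs, dtype=float), cfg.prob_smooth_frames)
    events: list[OnsetEvent] = []
    run = 0
    run_start = 0
    rearm_time = -np.inf
    for k, v in enumerate(sm):
        if frame_times_s[k] < rearm_time:
            run = 0
            continue
        if v > cfg.threshold:
            if run == 0:
                run_start = k
            run += 1
            if run == cfg.consecutive_required:
                t0 = float(frame_times_s[run_start])
                score = float(sm[run_start: k + 1].max())
                events.append(OnsetEvent(t0, score, "neural", model.latency_ms))
                rearm_time = t0 + cfg.refractory_s
                run = 0
        else:
            run = 0
    return events


# ---------------------------------------------------------------------------
# Evaluation / tuning
# ---------------------------------------------------------------------------

def match_onsets(detected_s: np.ndarray, true_s: np.ndarray,
                 tol_s: float = 0.15) -> tuple[int, int, int]:
    """Greedy one-to-one matching; returns (tp, fp, fn)."""
    detected = sorted(detected_s)
    used = np.zeros(len(true_s), dtype=bool)
    tp = 0
    for d in detected:
        diffs = np.abs(np.asarray(true_s) - d)
        diffs[used] = np.inf
        if diffs.size and diffs.min() <= tol_s:
            used[int(np.argmin(diffs))] = True
            tp += 1
    return tp, len(detected) - tp, len(true_s) - tp


def onset_f1(detected_s, true_s, tol_s: float = 0.15) -> float:
    tp, fp, fn = match_onsets(np.asarray(detected_s), np.asarray(true_s), tol_s)
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def tune_onset(dev_features: FeatureMatrix, dev_events: EventTable,
               search_space: dict[str, list], n_draws: int, seed: int = 0,
               base_cfg: NeuralOnsetConfig | None = None,
               match_tol_s: float = 0.15) -> tuple[NeuralOnsetConfig, float]:
    """Random search over detector parameters maximizing onset F1.

    ``search_space`` maps NeuralOnsetConfig field names to candidate lists.
    Ties go to the earlier draw. The development set must be disjoint from
    any evaluation data.
    """
    if not search_space or n_draws < 1:
        raise ValidationError("empty search space")
    rng = np.random.default_rng(seed)
    base = base_cfg or NeuralOnsetConfig()
    best_cfg, best_f1 = None, -1.0
    for _ in range(n_draws):
        draw = {k: v[int(rng.integers(len(v)))] for k, v in search_space.items()}
        cfg = replace(base, **draw)
        model = train_neural_onset(dev_features, dev_events, cfg, seed=seed)
        det = neural_detect_stream(model, dev_features)
        f1 = onset_f1([e.time_s for e in det], dev_events.onsets_s, match_tol_s)
        if f1 > best_f1:
            best_cfg, best_f1 = cfg, f1
    return best_cfg, best_f1
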