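"""End-to-end real-time simulation and offline evaluation orchestration.

``run_realtime`` replays a raw session chunk-by-chunk through the causal
feature extractor, detects speech onsets (audio power or the neural PCA+LDA
detector), assembles a 1000-ms segment per onset once +700 ms of features
exist, runs both decoders, maps the probability pair to character candidates
and beam-decodes each sentence with and without the language model on the
identical onset set. The report carries per-onset decodes, per-sentence CAR
with/without LM, session CPM, onset F1 against ground truth, and a latency
account (streaming group delay, onset decision latency, post-onset wait).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import CharacterDict, EventTable, RawRecording, SyllableInventory
from .decoder import DecoderModel, SegmentSpec, TrialSegment, extract_segments
from .fusion import NGram3LM, beam_decode, car, char_candidates, cpm
from .onset import (AudioOnsetConfig, NeuralOnsetModel, audio_detect,
                    neural_detect_stream, onset_f1)
from .preprocess import StreamConfig, stream_init

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    stream_cfg: StreamConfig
    inventory: SyllableInventory
    chardict: CharacterDict
    syllable_model: DecoderModel
    tone_model: DecoderModel
    lm: NGram3LM | None = None
    lm_lambda: float = 1.0
    beam_width: int = 10
    top_k: int = 10
    onset_source: str = "audio"                 # 'audio' | 'neural'
    audio_cfg: AudioOnsetConfig = field(default_factory=AudioOnsetConfig)
    neural_onset: NeuralOnsetModel | None = None
    segment_spec: SegmentSpec = field(default_factory=SegmentSpec)
    chunk_ms: float = 10.0
    match_tol_s: float = 0.2


@dataclass
class SentenceDecode:
    sentence_id: int
    truth: str
    decoded_lm: str
    decoded_nolm: str
    car_lm: float
    car_nolm: float


@dataclass
class SessionReport:
    sentences: list[SentenceDecode]
    onset_f1: float
    n_onsets_detected: int
    n_events_true: int
    car_lm: float                   # session-level, pooled over characters
    car_nolm: float
    cpm: float
    lm_lambda: float
    onset_source: str
    latency_ms: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), ensure_ascii=False, indent=1)


def run_realtime(raw: RawRecording, audio: np.ndarray, events: EventTable,
                 cfg: PipelineConfig) -> SessionReport:
    """Replay one session through the streaming stack and score it."""
    n_good = raw.channels.good_indices.size
    if cfg.syllable_model.net.n_inputs != n_good:
        raise ValueError("decoder input dimension does not match good channels")

    # causal feature extraction in strict chunk order
    state = stream_init(cfg.stream_cfg, raw.channels, raw.rate_hz)
    chunk = int(round(cfg.chunk_ms / 1000 * raw.rate_hz))
    frames, times = [], []
    for lo in range(0, raw.n_samples, chunk):
        f, t = state.process(raw.data[lo: lo + chunk])
        if f.size:
            frames.append(f)
            times.append(t)
    feats = np.vstack(frames)
    ftimes = np.concatenate(times) + raw.t0_s
    from .core_io import FeatureMatrix
    fm = FeatureMatrix(feats, state.frame_rate_hz, ftimes, zscored=True,
                       norm_mean=state.norm_mean, norm_sd=state.norm_sd,
                       channel_ids=raw.channels.good_indices)

    # onset detection
    if cfg.onset_source == "audio":
        det = audio_detect(audio, raw.rate_hz, cfg.audio_cfg)
        onset_latency = 0.0
    elif cfg.onset_source == "neural":
        if cfg.neural_onset is None:
            raise ValueError("neural onset model required")
        det = neural_detect_stream(cfg.neural_onset, fm)
        onset_latency = cfg.neural_onset.latency_ms
    else:
        raise ValueError(f"unknown onset source {cfg.onset_source!r}")
    det_times = np.array([e.time_s for e in det])
    f1 = onset_f1(det_times, events.onsets_s, cfg.match_tol_s)

    # match detections to true events so sentence grouping is defined
    spec = cfg.segment_spec
    true_times = events.onsets_s
    matched: dict[int, float] = {}
    used = np.zeros(len(det_times), dtype=bool)
    for i, t in enumerate(true_times):
        if det_times.size == 0:
            break
        d = np.abs(det_times - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= cfg.match_tol_s:
            matched[i] = det_times[j]
            used[j] = True

    # per-onset dual-stream decode + candidates
    per_event: dict[int, list] = {}
    rate = fm.frame_rate_hz
    pre = int(round(spec.pre_onset_ms / 1000 * rate))
    for i, t_on in matched.items():
        idx = int(round((t_on - fm.frame_times_s[0]) * rate))
        lo = idx - pre
        if lo < 0 or lo + spec.n_frames > fm.n_frames:
            continue
        seg = fm.data[lo: lo + spec.n_frames]
        p_s = cfg.syllable_model.predict_batch(seg[None])[0]
        p_t = cfg.tone_model.predict_batch(seg[None])[0]
        per_event[i] = char_candidates(p_s, p_t, cfg.chardict, cfg.inventory,
                                       cfg.top_k)

    # sentence-level fusion on identical onset sets with and without the LM
    df = events.df
    sent_ids = sorted({int(s) for s in df["sentence_id"].dropna().unique()}) \
        if df["sentence_id"].notna().any() else [0]
    sentences = []
    n_correct_lm = n_correct_nolm = n_truth = 0
    for sid in sent_ids:
        rows = df.index[df["sentence_id"] == sid].tolist() \
            if df["sentence_id"].notna().any() else df.index.tolist()
        truth = "".join(df.loc[rows, "character"])
        cands = [per_event[i] for i in rows if i in per_event]
        if cands:
            dec_lm, _ = beam_decode(cands, cfg.lm, cfg.lm_lambda, cfg.beam_width)
            dec_no, _ = beam_decode(cands, None, 0.0, cfg.beam_width)
        else:
            dec_lm = dec_no = ""
        c_lm = car(dec_lm, truth) if truth else 0.0
        c_no = car(dec_no, truth) if truth else 0.0
        sentences.append(SentenceDecode(sid, truth, dec_lm, dec_no, c_lm, c_no))
        n_truth += len(truth)
        n_correct_lm += round(c_lm * len(truth) / 100)
        n_correct_nolm += round(c_no * len(truth) / 100)

    elapsed = raw.duration_s
    n_decoded = sum(len(s.decoded_lm) for s in sentences)
    report = SessionReport(
        sentences=sentences,
        onset_f1=f1,
        n_onsets_detected=len(det),
        n_events_true=len(events),
        car_lm=100.0 * n_correct_lm / max(1, n_truth),
        car_nolm=100.0 * n_correct_nolm / max(1, n_truth),
        cpm=cpm(n_decoded, elapsed),
        lm_lambda=cfg.lm_lambda,
        onset_source=cfg.onset_source,
        latency_ms={
            "stream_group_delay": state.group_delay_s * 1000,
            "onset_decision": onset_latency,
            "post_onset_wait": spec.post_onset_ms,
        },
    )
    return report


def run_offline_eval(segments: list[TrialSegment], inventory: SyllableInventory,
                     streams=("syllable", "tone"), seed: int = 0,
                     **cv_kwargs) -> dict:
    """Offline evaluation bundle: per-stream cross-validation metrics."""
    from .decoder import cross_validate_10fold

    bundle = {}
    for stream in streams:
        cv = cross_validate_10fold(segments, stream, seed=seed, **cv_kwargs)
        bundle[stream] = {
            "fold_accuracies": cv.fold_accuracies.tolist(),
            "median": cv.median,
            "ci99": list(cv.ci99),
        }
    return bundle
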