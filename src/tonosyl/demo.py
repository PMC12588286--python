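"""Self-contained end-to-end demonstration on a synthetic participant.

Builds a small syllable inventory, renders a character-reading training
session and a sentence-reading evaluation session from the same activation
templates, trains both decoder streams on streaming features, fits a trigram
language model on a matched corpus, and replays the evaluation session
through the real-time pipeline. Used by the CLI ``demo`` command and as the
canonical identifiability check: with no noise and unique homophones the
decoded characters reproduce the ground truth exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import RawRecording
from .decoder import (SegmentSpec, StackedRecurrentConfig, TrainConfig,
                      extract_segments, train_decoder)
from .fusion import train_3gram
from .onset import AudioOnsetConfig
from .pipeline import PipelineConfig, SessionReport, run_realtime
from .preprocess import StreamConfig, fit_normalization, stream_preprocess
from .synth import (SynthConfig, Templates, events_from_sentences,
                    make_char_events, make_inventory, make_corpus,
                    make_templates, render_session)


def fit_stream_normalization(raw: RawRecording,
                             cfg: StreamConfig) -> tuple[np.ndarray, np.ndarray]:
    """Fixed z-score parameters from a session's un-normalized envelope frames."""
    n_good = raw.channels.good_indices.size
    probe = dataclasses.replace(cfg, norm_mean=np.zeros(n_good),
                                norm_sd=np.ones(n_good))
    fm = stream_preprocess(raw, probe)
    return fit_normalization([fm.data])


def stream_features_and_norm(raw: RawRecording, cfg: StreamConfig,
                             chunk_ms: float = 1000.0):
    """Stream once with unit normalization, fit z-score parameters, rescale.

    z-scoring is the final (affine) stage of the streaming chain, so fitting
    on the raw envelope frames and rescaling is identical to re-streaming
    with the fitted parameters. Returns (features, configured StreamConfig).
    """
    from .core_io import FeatureMatrix

    n_good = raw.channels.good_indices.size
    probe = dataclasses.replace(cfg, norm_mean=np.zeros(n_good),
                                norm_sd=np.ones(n_good))
    fm = stream_preprocess(raw, probe, chunk_ms=chunk_ms)
    mu, sd = fit_normalization([fm.data])
    out = FeatureMatrix((fm.data - mu) / sd, fm.frame_rate_hz, fm.frame_times_s,
                        zscored=True, norm_mean=mu, norm_sd=sd,
                        channel_ids=fm.channel_ids)
    return out, dataclasses.replace(cfg, norm_mean=mu, norm_sd=sd)


def parameter_recovery_dataset(seed: int = 0, n_syllables: int = 20,
                               trials_per_syllable: int = 30):
    """Character-task segments at the parameter-recovery study scale.

    20 base syllables x 4 tones, 30 trials per syllable, moderate noise
    (generator defaults), streamed through the causal feature extractor.
    Returns (segments, inventory).
    """
    cfg = SynthConfig(inventory_size=n_syllables,
                      trials_per_syllable=trials_per_syllable, seed=seed)
    inventory, chardict = make_inventory(n_syllables, 4,
                                         cfg.homophones_per_tonal_syllable, seed)
    templates = make_templates(cfg, inventory)
    rng = np.random.default_rng(seed + 1)
    events = make_char_events(cfg, inventory, chardict, rng)
    raw, _, _, _ = render_session(cfg, templates, inventory, events, rng)
    fm, _ = stream_features_and_norm(raw, StreamConfig())
    return extract_segments(fm, events, inventory, SegmentSpec()), inventory


def recovery_train_cfg(seed: int = 0) -> TrainConfig:
    """Reduced-size training settings used for cross-validated recovery runs."""
    return TrainConfig(seed=seed, max_epochs=25, patience=8)


def recovery_model_cfg() -> StackedRecurrentConfig:
    return StackedRecurrentConfig(hidden1=16, hidden2=8)


def lm_benefit_experiment(seed: int = 0, n_noise_seeds: int = 10,
                          logit_noise_sd: float = 2.0,
                          **demo_kwargs) -> list[tuple[float, float]]:
    """CAR with vs. without the language model under noisy decoders.

    Trains one system (as in :func:`run_demo`), then for each noise seed
    perturbs the per-trial syllable/tone log-probabilities with Gaussian
    noise — decoders that are informative but unreliable — and decodes every
    sentence with ``lambda=1`` and ``lambda=0`` on the identical candidate
    lattices. Returns ``[(car_lm, car_nolm), ...]`` pooled over characters.
    """
    from .fusion import beam_decode, car, char_candidates

    sys_ = build_demo_system(seed=seed, **demo_kwargs)
    probs = []          # (sentence_id, truth_char, p_syll, p_tone)
    for seg in sys_["eval_segments"]:
        p_s = sys_["syllable_model"].predict_probs(seg)
        p_t = sys_["tone_model"].predict_probs(seg)
        probs.append((seg.sentence_id, seg.character, p_s, p_t))
    sent_ids = sorted({p[0] for p in probs})
    out = []
    for k in range(n_noise_seeds):
        rng = np.random.default_rng(seed * 1000 + k)
        n_ok_lm = n_ok_no = n_all = 0
        for sid in sent_ids:
            rows = [p for p in probs if p[0] == sid]
            truth = "".join(r[1] for r in rows)
            cands = []
            for _, _, p_s, p_t in rows:
                ps = _perturb(p_s, rng, logit_noise_sd)
                pt = _perturb(p_t, rng, logit_noise_sd)
                cands.append(char_candidates(ps, pt, sys_["chardict"],
                                             sys_["inventory"], 10))
            dec_lm, _ = beam_decode(cands, sys_["lm"], 1.0, 10)
            dec_no, _ = beam_decode(cands, None, 0.0, 10)
            n_ok_lm += round(car(dec_lm, truth) * len(truth) / 100)
            n_ok_no += round(car(dec_no, truth) * len(truth) / 100)
            n_all += len(truth)
        out.append((100.0 * n_ok_lm / n_all, 100.0 * n_ok_no / n_all))
    return out


def _perturb(p: np.ndarray, rng: np.random.Generator, sd: float) -> np.ndarray:
    z = np.log(np.clip(p, 1e-12, None)) + sd * rng.standard_normal(p.size)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def fine_tune_model(model, segments, train_cfg):
    """Continue training on sentence segments, tracking training-set accuracy."""
    return train_decoder(segments, model.stream, train_cfg=train_cfg,
                         class_names=model.class_names, warm_start=model,
                         n_classes=model.net.n_classes, val_segments=segments)


def build_demo_system(seed: int = 0, n_syllables: int = 6, n_channels: int = 16,
                      trials_per_syllable: int = 8, noise_sd: float = 0.0,
                      line_noise_amp: float = 0.0, homophones: int = 1,
                      n_sentences: int = 5,
                      hidden: tuple[int, int] = (16, 8),
                      fine_tune_sentences: bool = True) -> dict:
    """Train the full system on synthetic sessions; return all components."""
    cfg = SynthConfig(n_channels=n_channels, grid_cols=4,
                      inventory_size=n_syllables,
                      trials_per_syllable=trials_per_syllable,
                      noise_sd=noise_sd, line_noise_amp=line_noise_amp,
                      homophones_per_tonal_syllable=homophones, seed=seed)
    inventory, chardict = make_inventory(n_syllables, 4, homophones, seed)
    templates = make_templates(cfg, inventory)
    rng = np.random.default_rng(seed + 1)

    # --- training session (character task) ---
    ev_train = make_char_events(cfg, inventory, chardict, rng)
    raw_tr, _, _, _ = render_session(cfg, templates, inventory, ev_train, rng)
    fm_tr, scfg = stream_features_and_norm(raw_tr, StreamConfig())
    spec = SegmentSpec()
    segs = extract_segments(fm_tr, ev_train, inventory, spec)

    mcfg = StackedRecurrentConfig(hidden1=hidden[0], hidden2=hidden[1])
    tcfg = TrainConfig(seed=seed, max_epochs=40, mixup_alpha=0.0)
    syl_model = train_decoder(segs, "syllable", mcfg, tcfg,
                              class_names=inventory.base_syllables,
                              n_classes=inventory.size)
    tone_model = train_decoder(segs, "tone", mcfg, tcfg)

    # --- language model on a matched corpus ---
    corpus = make_corpus(chardict, n_sentences=60, len_range=(2, 5), seed=seed)
    lm = train_3gram(corpus)

    # --- evaluation session (sentences drawn from the same corpus) ---
    rng_eval = np.random.default_rng(seed + 2)
    sentences = [corpus[i] for i in
                 rng_eval.choice(len(corpus), size=n_sentences, replace=False)]
    ev_eval = events_from_sentences(cfg, inventory, chardict, sentences, rng_eval)
    raw_ev, audio, _, _ = render_session(cfg, templates, inventory, ev_eval,
                                         rng_eval)
    fm_ev = stream_preprocess(raw_ev, scfg)
    segs_ev = extract_segments(fm_ev, ev_eval, inventory, spec)

    # fine-tune both streams on the sentence task (reduced learning rate),
    # mirroring the deployment protocol
    if fine_tune_sentences:
        ft_cfg = dataclasses.replace(tcfg, max_epochs=40, patience=40,
                                     stop_at_val_acc=None)
        syl_model = fine_tune_model(syl_model, segs_ev, ft_cfg)
        tone_model = fine_tune_model(tone_model, segs_ev, ft_cfg)

    return {"cfg": cfg, "inventory": inventory, "chardict": chardict,
            "templates": templates, "stream_cfg": scfg, "spec": spec,
            "syllable_model": syl_model, "tone_model": tone_model,
            "lm": lm, "corpus": corpus, "train_segments": segs,
            "eval_raw": raw_ev, "eval_audio": audio, "eval_events": ev_eval,
            "eval_segments": segs_ev}


def run_demo(seed: int = 0, lm_lambda: float = 1.0,
             decoder_noise_sd: float = 0.0, **kwargs) -> SessionReport:
    """Train on a character session, decode a sentence session in real time.

    ``decoder_noise_sd`` adds seeded Gaussian noise to the evaluation
    session's raw signal before replay, emulating degraded decoders.
    """
    sys_ = build_demo_system(seed=seed, **kwargs)
    raw_ev, audio, ev_eval = sys_["eval_raw"], sys_["eval_audio"], sys_["eval_events"]
    if decoder_noise_sd > 0:
        raw_ev = RawRecording(
            raw_ev.data + decoder_noise_sd
            * np.random.default_rng(seed + 3).standard_normal(raw_ev.data.shape)
            * raw_ev.data.std(),
            raw_ev.rate_hz, raw_ev.channels, raw_ev.t0_s)

    pcfg = PipelineConfig(
        stream_cfg=sys_["stream_cfg"], inventory=sys_["inventory"],
        chardict=sys_["chardict"], syllable_model=sys_["syllable_model"],
        tone_model=sys_["tone_model"], lm=sys_["lm"], lm_lambda=lm_lambda,
        onset_source="audio", audio_cfg=AudioOnsetConfig(),
        segment_spec=sys_["spec"])
    return run_realtime(raw_ev, audio, ev_eval, pcfg)
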