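"""Synthetic sessions with known ground truth.

The generator emulates what makes overt Mandarin syllable production
decodable from sensorimotor cortex: each base syllable drives a distinct
spatial pattern of high-gamma amplitude over a subset of electrodes with a
syllable-specific temporal kernel, and each lexical tone modulates a
partially distinct electrode subset with a pitch-like temporal ramp (level /
rising / dipping / falling for tones 1-4). The carrier is amplitude-modulated
band-limited (70-150 Hz) Gaussian noise, so the Hilbert envelope of the
preprocessed signal recovers the injected modulation — the extraction math is
exercised, not just the labels. White noise, an optional 50-Hz line
component, homophone-rich character dictionaries and trigram-structured
sentence corpora complete the study conditions.

Audio is an envelope-only proxy (noise bursts at the true onsets), sufficient
for power-threshold onset detection; no acoustics are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core_io import (CharacterDict, ChannelTable, EventTable, RawRecording,
                      SyllableInventory, ValidationError)

# pinyin-like CV grammar; initials align with the articulatory-feature table
INITIALS = ["b", "p", "m", "f", "d", "t", "n", "l", "g", "k", "h",
            "z", "c", "s", "zh", "ch", "sh", "r", "j", "q", "x"]
FINALS = ["a", "o", "e", "i", "u", "v", "ai", "ei", "ao", "ou", "an", "en",
          "ang", "eng", "ong", "ia", "ie", "iao", "iu", "ian", "in", "iang",
          "ing", "ua", "uo", "uai", "ui", "uan", "un", "uang", "ueng"]

MANNER = {**{c: "plosive" for c in ["b", "p", "d", "t", "g", "k"]},
          **{c: "fricative" for c in ["f", "h", "s", "sh", "r", "x"]},
          **{c: "affricate" for c in ["z", "c", "zh", "ch", "j", "q"]},
          **{c: "nasal" for c in ["m", "n"]},
          "l": "lateral"}
PLACE = {c: ("labial" if c in ("b", "p", "m", "f") else "lingual")
         for c in INITIALS}


def initial_of(syllable: str) -> str:
    """Initial consonant of a CV syllable (longest-match digraphs first)."""
    for two in ("zh", "ch", "sh"):
        if syllable.startswith(two):
            return two
    return syllable[0]


def manner_of(syllable: str) -> str:
    return MANNER[initial_of(syllable)]


def place_of(syllable: str) -> str:
    return PLACE[initial_of(syllable)]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic participant/session family."""

    n_channels: int = 64                 # 8x8 grid at desk scale
    grid_cols: int = 8
    raw_rate_hz: float = 1000.0
    inventory_size: int = 20
    n_tones: int = 4
    trials_per_syllable: int = 10
    template_channel_fraction: float = 0.3
    tone_channel_fraction: float = 0.2
    template_duration_s: float = 0.6
    neural_lead_s: float = 0.12     # motor activation precedes the acoustics
    response_gain: float = 3.0
    tone_gain: float = 2.0
    noise_sd: float = 0.3
    line_noise_amp: float = 0.5
    homophones_per_tonal_syllable: int = 2
    pitch_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.raw_rate_hz < 400:
            raise ValidationError("raw rate must be >=400 Hz to host the 70-150 Hz band")
        for f in (self.template_channel_fraction, self.tone_channel_fraction):
            if not 0 < f <= 1:
                raise ValidationError("channel fractions must be in (0,1]")
        if min(self.n_channels, self.inventory_size, self.trials_per_syllable) < 1:
            raise ValidationError("counts must be positive")


def make_inventory(size: int, n_tones: int = 4,
                   homophones_per_tonal_syllable: int = 2,
                   seed: int = 0) -> tuple[SyllableInventory, CharacterDict]:
    """Sample a synthetic base-syllable inventory and homophone dictionary.

    Syllables are unique CV strings over a pinyin-like alphabet; every tonal
    syllable maps to ``homophones_per_tonal_syllable`` unique CJK characters
    with Dirichlet-drawn prior weights.
    """
    if size < 2:
        raise ValidationError("inventory size must be >=2")
    combos = [i + f for i in INITIALS for f in FINALS]
    if size > len(combos):
        raise ValidationError(f"at most {len(combos)} CV syllables representable")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(combos), size=size, replace=False)
    inventory = SyllableInventory([combos[i] for i in picks], n_tones)

    n_chars = size * n_tones * homophones_per_tonal_syllable
    chars = [chr(0x4E00 + int(i)) for i in rng.permutation(n_chars)]
    mapping = {}
    it = iter(chars)
    for base in inventory.base_syllables:
        for tone in range(1, n_tones + 1):
            weights = rng.dirichlet(np.ones(homophones_per_tonal_syllable))
            mapping[(base, tone)] = [(next(it), float(w)) for w in weights]
    return inventory, CharacterDict(mapping)


@dataclass
class Templates:
    """Per-syllable and per-tone activation structure (the ground truth)."""

    syllable_weights: np.ndarray      # (n_syll, n_ch), max 1 on support
    kernel_ab: np.ndarray             # (n_syll, 2) beta-shape parameters
    tone_weights: np.ndarray          # (n_tones, n_ch)
    duration_s: float

    def kernel(self, syll_idx: int, u: np.ndarray) -> np.ndarray:
        a, b = self.kernel_ab[syll_idx]
        k = np.clip(u, 1e-12, 1 - 1e-12) ** (a - 1) * \
            np.clip(1 - u, 1e-12, 1 - 1e-12) ** (b - 1)
        return k / k.max()

    def kernel_peak_s(self, syll_idx: int) -> float:
        a, b = self.kernel_ab[syll_idx]
        return float((a - 1) / (a + b - 2) * self.duration_s)

    @staticmethod
    def tone_ramp(tone: int, u: np.ndarray) -> np.ndarray:
        if tone == 1:
            r = np.ones_like(u)
        elif tone == 2:
            r = 0.4 + 1.2 * u
        elif tone == 3:
            r = 0.4 + 1.2 * (2 * u - 1) ** 2
        elif tone == 4:
            r = 1.6 - 1.2 * u
        else:
            raise ValidationError(f"tone {tone} outside 1-4")
        taper = np.clip(np.minimum(u / 0.1, (1 - u) / 0.1), 0, 1)
        return r * taper


def make_templates(cfg: SynthConfig, inventory: SyllableInventory,
                   seed: int | None = None) -> Templates:
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_ch, n_s = cfg.n_channels, inventory.size
    m = max(1, round(cfg.template_channel_fraction * n_ch))
    w_s = np.zeros((n_s, n_ch))
    for s in range(n_s):
        sup = rng.choice(n_ch, size=m, replace=False)
        w_s[s, sup] = rng.uniform(0.5, 1.0, size=m)
        w_s[s] /= w_s[s].max()
    ab = rng.uniform(1.5, 4.0, size=(n_s, 2))

    mt = max(1, round(cfg.tone_channel_fraction * n_ch))
    pool = rng.choice(n_ch, size=min(n_ch, 2 * mt), replace=False)
    w_t = np.zeros((cfg.n_tones, n_ch))
    for t in range(cfg.n_tones):
        sup = rng.choice(pool, size=mt, replace=False)
        w_t[t, sup] = rng.uniform(0.5, 1.0, size=mt)
        w_t[t] /= w_t[t].max()
    return Templates(w_s, ab, w_t, cfg.template_duration_s)


@dataclass
class GroundTruth:
    events: EventTable
    templates: Templates
    inventory: SyllableInventory


# minimum quiet gap after a response so the next trial's (-700,-500) ms
# baseline never overlaps it
_POST_GAP_S = 0.4


def _draw_char(chardict: CharacterDict, base: str, tone: int,
               rng: np.random.Generator) -> str:
    entries = chardict.mapping[(base, tone)]
    probs = np.array([w for _, w in entries])
    return entries[rng.choice(len(entries), p=probs / probs.sum())][0]


def make_char_events(cfg: SynthConfig, inventory: SyllableInventory,
                     chardict: CharacterDict, rng: np.random.Generator,
                     trials_per_syllable: int | None = None,
                     start_s: float = 1.0) -> EventTable:
    """Single-character reading task: every syllable repeated, random tones."""
    reps = trials_per_syllable or cfg.trials_per_syllable
    labels = [(s, int(rng.integers(1, cfg.n_tones + 1)))
              for s in range(inventory.size) for _ in range(reps)]
    rng.shuffle(labels)
    return _events_from_labels(cfg, inventory, chardict, labels, rng,
                               start_s, task="char")


def events_from_sentences(cfg: SynthConfig, inventory: SyllableInventory,
                          chardict: CharacterDict, sentences: list[str],
                          rng: np.random.Generator,
                          start_s: float = 1.0) -> EventTable:
    """Word-by-word sentence reading with deliberate pauses between characters."""
    inv_map = chardict.char_to_tonal()
    rows = []
    t = start_s
    for sid, sent in enumerate(sentences):
        for ch in sent:
            base, tone = inv_map[ch]
            rows.append((t, inventory.index(base), tone, ch, sid))
            t += cfg.template_duration_s + _POST_GAP_S + 0.3 + rng.uniform(0, 0.2)
        t += 1.0
    df = pd.DataFrame({
        "trial_id": np.arange(len(rows)),
        "onset_s": [_align(r[0], cfg.raw_rate_hz) for r in rows],
        "syllable": [inventory.base_syllables[r[1]] for r in rows],
        "tone": [r[2] for r in rows],
        "character": [r[3] for r in rows],
        "task": "sentence",
        "sentence_id": [r[4] for r in rows],
    })
    return EventTable(df)


def _align(t: float, rate: float) -> float:
    return round(t * rate) / rate


def _events_from_labels(cfg, inventory, chardict, labels, rng, start_s, task):
    rows = []
    t = start_s
    for s_idx, tone in labels:
        base = inventory.base_syllables[s_idx]
        rows.append((t, base, tone, _draw_char(chardict, base, tone, rng)))
        t += cfg.template_duration_s + _POST_GAP_S + 0.3 + rng.uniform(0, 0.2)
    df = pd.DataFrame({
        "trial_id": np.arange(len(rows)),
        "onset_s": [_align(r[0], cfg.raw_rate_hz) for r in rows],
        "syllable": [r[1] for r in rows],
        "tone": [r[2] for r in rows],
        "character": [r[3] for r in rows],
        "task": task,
        "sentence_id": pd.array([pd.NA] * len(rows), dtype="Int64"),
    })
    return EventTable(df)


def render_session(cfg: SynthConfig, templates: Templates,
                   inventory: SyllableInventory, events: EventTable,
                   rng: np.random.Generator
                   ) -> tuple[RawRecording, np.ndarray, EventTable, GroundTruth]:
    """Render raw neural data + proxy audio for a given event list.

    Per channel: ``raw = A(t) * carrier + noise + line``, where the carrier is
    unit-mean-envelope 70-150 Hz Gaussian noise and ``A`` is 1 plus the
    syllable/tone activation templates at each trial.
    """
    rate = cfg.raw_rate_hz
    dur = float(events.onsets_s[-1]) + cfg.template_duration_s + 1.0 if len(events) else 2.0
    n = int(round(dur * rate))
    n_ch = cfg.n_channels

    sos = signal.butter(4, (70.0, 150.0), btype="bandpass", fs=rate, output="sos")
    carrier = signal.sosfilt(sos, rng.standard_normal((n, n_ch)), axis=0)
    carrier /= carrier.std(axis=0) * np.sqrt(np.pi / 2)  # mean envelope ~ 1

    amp = np.ones((n, n_ch))
    tpl_n = int(round(cfg.template_duration_s * rate))
    u = np.arange(tpl_n) / tpl_n
    lead = int(round(cfg.neural_lead_s * rate))
    for _, row in events.df.iterrows():
        s = inventory.index(row["syllable"])
        lo = max(0, int(round(row["onset_s"] * rate)) - lead)
        hi = min(lo + tpl_n, n)
        k = templates.kernel(s, u[: hi - lo])
        r = Templates.tone_ramp(int(row["tone"]), u[: hi - lo])
        amp[lo:hi] += (cfg.response_gain * k[:, None] * templates.syllable_weights[s]
                       + cfg.tone_gain * r[:, None] * templates.tone_weights[row["tone"] - 1])

    raw = amp * carrier
    if cfg.noise_sd > 0:
        raw = raw + cfg.noise_sd * rng.standard_normal((n, n_ch))
    if cfg.line_noise_amp > 0:
        t = np.arange(n) / rate
        raw = raw + cfg.line_noise_amp * np.sin(2 * np.pi * 50.0 * t)[:, None]

    audio = np.zeros(n)
    ramp = max(1, int(round(0.01 * rate)))      # fast attack, as in overt speech
    for onset in events.onsets_s:
        lo = int(round(onset * rate))
        hi = min(lo + tpl_n, n)
        win = signal.windows.tukey(hi - lo, alpha=2 * ramp / max(1, hi - lo))
        audio[lo:hi] = 0.9 * rng.uniform(-1, 1, size=hi - lo) * win

    n_rows = cfg.n_channels // cfg.grid_cols + (cfg.n_channels % cfg.grid_cols > 0)
    table = ChannelTable.from_grid(n_rows, cfg.grid_cols, cfg.pitch_mm)
    table = ChannelTable(np.arange(n_ch), table.name[:n_ch], table.grid_row[:n_ch],
                         table.grid_col[:n_ch], cfg.pitch_mm)
    rec = RawRecording(raw, rate, table)
    return rec, audio, events, GroundTruth(events, templates, inventory)


def simulate_recording(cfg: SynthConfig, events_per_session: int | None = None,
                       inventory: SyllableInventory | None = None,
                       chardict: CharacterDict | None = None,
                       templates: Templates | None = None,
                       events: EventTable | None = None,
                       ) -> tuple[RawRecording, np.ndarray, EventTable, GroundTruth]:
    """One-call session simulator; every output is a pure function of (cfg, seed).

    With ``events_per_session`` the character task uses
    ``ceil(events/inventory)`` repetitions; by default every syllable is
    repeated ``cfg.trials_per_syllable`` times.
    """
    rng = np.random.default_rng(cfg.seed)
    if inventory is None or chardict is None:
        inventory, chardict = make_inventory(cfg.inventory_size, cfg.n_tones,
                                             cfg.homophones_per_tonal_syllable,
                                             cfg.seed)
    if templates is None:
        templates = make_templates(cfg, inventory)
    if events is None:
        reps = (int(np.ceil(events_per_session / inventory.size))
                if events_per_session else cfg.trials_per_syllable)
        events = make_char_events(cfg, inventory, chardict, rng,
                                  trials_per_syllable=reps)
        if events_per_session:
            events = EventTable(events.df.iloc[:events_per_session])
    return render_session(cfg, templates, inventory, events, rng)


def make_corpus(chardict: CharacterDict, n_sentences: int,
                len_range: tuple[int, int] = (2, 11),
                seed: int = 0) -> list[str]:
    """Sentences from a seeded generator-Markov process over the dictionary image.

    Successor preferences are sparse (three favored continuations per
    character), so a fitted trigram model has structure to exploit.
    """
    chars = chardict.characters()
    if not chars:
        raise ValidationError("empty dictionary")
    rng = np.random.default_rng(seed)
    n_c = len(chars)
    fav = {c: rng.choice(n_c, size=min(3, n_c), replace=False) for c in chars}
    start_pool = rng.choice(n_c, size=min(5, n_c), replace=False)
    sentences = []
    for _ in range(n_sentences):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        cur = chars[int(rng.choice(start_pool))]
        sent = [cur]
        for _ in range(length - 1):
            if rng.uniform() < 0.75:
                cur = chars[int(rng.choice(fav[cur]))]
            else:
                cur = chars[int(rng.integers(n_c))]
            sent.append(cur)
        sentences.append("".join(sent))
    return sentences
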