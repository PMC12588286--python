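"""Shared data model and readers/writers for the decoding pipeline.

The pipeline's containers are deliberately thin: numpy arrays plus a little
metadata, with validation at construction. Timestamps are always seconds from
session start; event onsets are aligned to the nearest raw sample when they
are consumed, never at storage time.

External formats: WAV audio (PCM or float, via :mod:`scipy.io.wavfile`),
tab-separated event tables (UTF-8, one header line), read-only Praat TextGrid
interval tiers, HDF5 feature containers, and JSON for syllable inventories
and character dictionaries.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["trial_id", "onset_s", "syllable", "tone", "character", "task"]


class SchemaError(ValueError):
    """A file is parseable but does not match the expected schema."""


class ValidationError(ValueError):
    """In-memory data violates a container invariant."""


# ---------------------------------------------------------------------------
# Channel geometry
# ---------------------------------------------------------------------------

@dataclass
class ChannelTable:
    """Electrode bookkeeping: identity, rectangular-grid position, quality.

    ``pitch_mm`` is the center-to-center interelectrode spacing used by the
    electrode-statistics module to build the spatial adjacency matrix.
    """

    channel_id: np.ndarray          # int, contiguous from 0
    name: list[str]
    grid_row: np.ndarray
    grid_col: np.ndarray
    pitch_mm: float = 3.0
    is_good: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel_id = np.asarray(self.channel_id, dtype=int)
        self.grid_row = np.asarray(self.grid_row, dtype=int)
        self.grid_col = np.asarray(self.grid_col, dtype=int)
        n = self.channel_id.size
        if self.is_good is None:
            self.is_good = np.ones(n, dtype=bool)
        self.is_good = np.asarray(self.is_good, dtype=bool)
        if not np.array_equal(self.channel_id, np.arange(n)):
            raise ValidationError("channel_ids must be contiguous from 0")
        pos = set(zip(self.grid_row.tolist(), self.grid_col.tolist()))
        if len(pos) != n:
            raise ValidationError("(grid_row, grid_col) must be unique per channel")
        if not self.pitch_mm > 0:
            raise ValidationError("pitch_mm must be positive")

    @property
    def n_channels(self) -> int:
        return self.channel_id.size

    @property
    def good_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_good)

    def positions_mm(self) -> np.ndarray:
        """(n_channels, 2) physical electrode positions."""
        return np.column_stack([self.grid_row, self.grid_col]) * self.pitch_mm

    def with_good(self, is_good: np.ndarray) -> "ChannelTable":
        return replace(self, is_good=np.asarray(is_good, dtype=bool).copy())

    @classmethod
    def from_grid(cls, n_rows: int, n_cols: int, pitch_mm: float = 3.0) -> "ChannelTable":
        rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
        names = [f"ch{r}_{c}" for r, c in zip(rows, cols)]
        return cls(np.arange(n_rows * n_cols), names, rows, cols, pitch_mm)


@dataclass
class RawRecording:
    """samples x channels cortical time series in arbitrary units."""

    data: np.ndarray
    rate_hz: float
    channels: ChannelTable
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be samples x channels")
        if self.data.shape[1] != self.channels.n_channels:
            raise ValidationError(
                f"data has {self.data.shape[1]} columns but channel table has "
                f"{self.channels.n_channels} channels"
            )
        if not self.rate_hz > 0:
            raise ValidationError("rate_hz must be positive")
        if not np.isfinite(self.data).all():
            raise ValidationError("raw data contains NaN/inf")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class FeatureMatrix:
    """frames x channels high-gamma analytic-amplitude features.

    ``frame_rate_hz`` is 100 for the streaming pipeline (50-ms windows stepped
    10 ms) and 400 for the offline pipeline. ``channel_ids`` maps columns back
    to the originating electrodes (bad channels are dropped upstream).
    """

    data: np.ndarray
    frame_rate_hz: float
    frame_times_s: np.ndarray
    zscored: bool = False
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None
    channel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.data.ndim != 2 or self.frame_times_s.size != self.data.shape[0]:
            raise ValidationError("frame_times_s must have one entry per frame")
        if self.frame_times_s.size > 1:
            dt = np.diff(self.frame_times_s)
            if not (dt > 0).all():
                raise ValidationError("frame_times_s must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.frame_rate_hz, rtol=1e-6, atol=1e-9):
                raise ValidationError("frame spacing must equal 1/frame_rate_hz")
        if self.zscored:
            if self.norm_sd is None or not (np.asarray(self.norm_sd) > 0).all():
                raise ValidationError("zscored features require positive norm_sd")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.data.shape[1])
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Linguistic containers
# ---------------------------------------------------------------------------

@dataclass
class SyllableInventory:
    """Ordered list of base syllables; class index = list position."""

    base_syllables: list[str]
    n_tones: int = 4

    def __post_init__(self) -> None:
        if len(set(self.base_syllables)) != len(self.base_syllables):
            raise ValidationError("base syllables must be unique")

    @property
    def size(self) -> int:
        return len(self.base_syllables)

    @property
    def n_tonal(self) -> int:
        return self.size * self.n_tones

    def index(self, base: str) -> int:
        return self.base_syllables.index(base)

    def chance_level_pct(self) -> float:
        """Chance classification accuracy for base syllables, in percent."""
        return 100.0 / self.size

    def tone_chance_pct(self) -> float:
        return 100.0 / self.n_tones

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"base_syllables": self.base_syllables, "n_tones": self.n_tones},
                      fh, ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyllableInventory":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(d["base_syllables"], d["n_tones"])


@dataclass
class CharacterDict:
    """(base syllable, tone) -> homophone characters with prior weights.

    Priors are normalized to sum to one within each tonal syllable at
    construction. Characters are opaque UTF-8 strings (no normalization
    beyond what the producer applied): logographic identity must be exact.
    """

    mapping: dict[tuple[str, int], list[tuple[str, float]]]

    def __post_init__(self) -> None:
        norm: dict[tuple[str, int], list[tuple[str, float]]] = {}
        for key, entries in self.mapping.items():
            if not entries:
                raise ValidationError(f"tonal syllable {key} has no characters")
            total = sum(w for _, w in entries)
            if total <= 0 or any(w < 0 for _, w in entries):
                raise ValidationError(f"priors for {key} must be nonnegative, sum > 0")
            norm[(key[0], int(key[1]))] = [(c, w / total) for c, w in entries]
        self.mapping = norm

    def characters(self) -> list[str]:
        """Sorted image of the dictionary: every character it can emit."""
        return sorted({c for entries in self.mapping.values() for c, _ in entries})

    def char_to_tonal(self) -> dict[str, tuple[str, int]]:
        """Inverse map; well-defined only when characters are unambiguous."""
        inv: dict[str, tuple[str, int]] = {}
        for key, entries in self.mapping.items():
            for c, _ in entries:
                inv.setdefault(c, key)
        return inv

    def to_json(self, path) -> None:
        payload = {f"{b}	{t}": [[c, w] for c, w in v]
                   for (b, t), v in self.mapping.items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=0)

    @classmethod
    def from_json(cls, path) -> "CharacterDict":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        mapping = {}
        for key, entries in payload.items():
            b, t = key.split("\t")
            mapping[(b, int(t))] = [(c, float(w)) for c, w in entries]
        return cls(mapping)


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    """Per-trial annotations: onset, base syllable, tone, character, task."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=EVENT_COLUMNS + ["sentence_id"]))

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in EVENT_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"event table missing column '{col}'")
        if "sentence_id" not in df.columns:
            df["sentence_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
        if len(df):
            df["tone"] = df["tone"].astype(int)
            bad = ~df["tone"].isin([1, 2, 3, 4])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"row {row}: tone {df['tone'].iloc[row]} outside 1-4")
            ons = df["onset_s"].to_numpy(dtype=float)
            if (ons < 0).any():
                raise ValidationError("onset_s must be nonnegative")
            if (np.diff(ons) < 0).any():
                raise ValidationError("onsets must be nondecreasing")
            if not df["task"].isin(["char", "sentence"]).all():
                raise ValidationError("task must be 'char' or 'sentence'")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def onsets_s(self) -> np.ndarray:
        return self.df["onset_s"].to_numpy(dtype=float)

    def equals(self, other: "EventTable") -> bool:
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        for col in EVENT_COLUMNS:
            if col == "onset_s":
                if not np.allclose(a[col].to_numpy(float), b[col].to_numpy(float)):
                    return False
            elif not (a[col].to_numpy() == b[col].to_numpy()).all():
                return False
        return True


def read_events(path, dialect: str = "tsv") -> EventTable:
    """Read a per-trial event table from TSV or a Praat TextGrid.

    The TextGrid convention is a single interval tier whose non-empty labels
    encode ``syllable+tone+character`` (e.g. ``ma3+X``); interval start times
    become onsets.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"syllable": str, "character": str})
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"TSV missing column(s): {', '.join(missing)}")
        return EventTable(df)
    if dialect == "textgrid":
        return _read_textgrid_events(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_events(events: EventTable, path, dialect: str = "tsv") -> None:
    if dialect != "tsv":
        raise ValueError("only TSV writing is supported")
    cols = EVENT_COLUMNS + ["sentence_id"]
    events.df[cols].to_csv(path, sep="\t", index=False, encoding="utf-8")


_TG_NUM = re.compile(r"(xmin|xmax)\s*=\s*([0-9.eE+-]+)")
_TG_TEXT = re.compile(r'text\s*=\s*"(.*)"')


def _read_textgrid_events(path) -> EventTable:
    """Minimal read-only parser for Praat TextGrid interval tiers.

    Point tiers are ignored; intervals with empty labels are skipped. Labels
    follow the convention ``<base><tone digit>+<character>``.
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    rows = []
    trial = 0
    # split into tier blocks; keep only IntervalTier blocks
    for block in re.split(r'item\s*\[\d+\]\s*:', text)[1:]:
        if '"IntervalTier"' not in block:
            continue
        for iv in re.split(r'intervals\s*\[\d+\]\s*:', block)[1:]:
            mtext = _TG_TEXT.search(iv)
            nums = _TG_NUM.findall(iv)
            if mtext is None or not nums:
                continue
            label = mtext.group(1).strip()
            if not label:
                continue
            xmin = float(dict(nums)["xmin"])
            m = re.match(r"([a-zA-Z]+)([1-4])\+(.+)", label)
            if m is None:
                raise SchemaError(f"TextGrid label {label!r} not of form syll+tone+char")
            rows.append({"trial_id": trial, "onset_s": xmin, "syllable": m.group(1),
                         "tone": int(m.group(2)), "character": m.group(3),
                         "task": "char"})
            trial += 1
    return EventTable(pd.DataFrame(rows, columns=EVENT_COLUMNS) if rows
                      else pd.DataFrame(columns=EVENT_COLUMNS))


# ---------------------------------------------------------------------------
# Audio and feature containers
# ---------------------------------------------------------------------------

def read_audio(path, normalize: bool = True) -> tuple[np.ndarray, float, bool]:
    """Read a WAV file to a float vector.

    Returns ``(waveform, rate_hz, silent)``. Stereo input is averaged to mono
    with a warning. With ``normalize=True`` the waveform is peak-normalized to
    [-1, 1]; an all-zero file returns zeros and ``silent=True``.
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if data.ndim == 2:
        logger.warning("stereo WAV %s averaged to mono", path)
        data = data.mean(axis=1)
    peak = np.abs(data).max() if data.size else 0.0
    silent = peak == 0.0
    if normalize:
        if silent:
            return np.zeros_like(data), float(rate), True
        return data / peak, float(rate), False
    return data, float(rate), silent


def write_audio(path, waveform: np.ndarray, rate_hz: float) -> None:
    from scipy.io import wavfile

    wavfile.write(path, int(rate_hz), np.asarray(waveform, dtype=np.float32))


class FormatError(ValueError):
    """An on-disk container is corrupt or missing required attributes."""


def save_features(fm: FeatureMatrix, path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("data", data=fm.data)
        h5.create_dataset("frame_times_s", data=fm.frame_times_s)
        h5.create_dataset("channel_ids", data=fm.channel_ids)
        h5.attrs["frame_rate_hz"] = fm.frame_rate_hz
        h5.attrs["zscored"] = fm.zscored
        if fm.norm_mean is not None:
            h5.create_dataset("norm_mean", data=fm.norm_mean)
            h5.create_dataset("norm_sd", data=fm.norm_sd)


def load_features(path) -> FeatureMatrix:
    import h5py

    try:
        with h5py.File(path, "r") as h5:
            if "frame_rate_hz" not in h5.attrs:
                raise FormatError(f"{path}: missing frame_rate_hz attribute")
            return FeatureMatrix(
                data=h5["data"][()],
                frame_rate_hz=float(h5.attrs["frame_rate_hz"]),
                frame_times_s=h5["frame_times_s"][()],
                zscored=bool(h5.attrs["zscored"]),
                norm_mean=h5["norm_mean"][()] if "norm_mean" in h5 else None,
                norm_sd=h5["norm_sd"][()] if "norm_sd" in h5 else None,
                channel_ids=h5["channel_ids"][()],
            )
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5 container ({exc})") from exc
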