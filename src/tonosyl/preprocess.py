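"""High-gamma feature extraction: offline pipeline, causal streaming twin, SNR.

Two deliberately different pipelines coexist, mirroring common practice for
cortical speech decoding:

* **Offline** (analysis-grade): bad-channel drop -> common average reference
  -> polyphase downsampling to 400 Hz -> zero-phase notch at 50 Hz and all
  harmonics below Nyquist -> Gaussian band-pass 70-150 Hz -> Hilbert analytic
  amplitude -> per-channel z-score over time. Zero-phase filtering keeps event
  latencies unbiased; the output frame rate equals the downsampled rate.

* **Streaming** (decoding-grade): every filter is causal and keeps internal
  state so that processing a session in chunks of any size reproduces the
  one-shot output sample-for-sample. The analytic envelope uses a causal FIR
  Hilbert transformer with group-delay compensation (a true Hilbert transform
  is non-causal); the envelope is averaged over a 50-ms window stepped every
  10 ms, giving 100-Hz feature frames, then z-scored with *fixed* per-channel
  parameters estimated from earlier sessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .core_io import ChannelTable, FeatureMatrix, RawRecording, ValidationError

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Offline pipeline
# ---------------------------------------------------------------------------

@dataclass
class OfflineConfig:
    notch_base_hz: float = 50.0
    downsample_to_hz: float = 400.0
    hg_band_hz: tuple[float, float] = (70.0, 150.0)
    notch_q: float = 30.0
    zscore: bool = True

    def __post_init__(self) -> None:
        nyq = self.downsample_to_hz / 2
        if not self.hg_band_hz[1] < nyq:
            raise ValidationError("band edge must lie below downsampled Nyquist")


def common_average_reference(data: np.ndarray, good: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean of the good channels from every channel."""
    return data - data[:, good].mean(axis=1, keepdims=True)


def notch_zero_phase(data: np.ndarray, rate_hz: float, base_hz: float,
                     q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``base_hz`` and every harmonic below Nyquist."""
    out = data
    for k in range(1, int(np.floor((rate_hz / 2 - 1e-9) / base_hz)) + 1):
        b, a = signal.iirnotch(k * base_hz, q, fs=rate_hz)
        out = signal.filtfilt(b, a, out, axis=0)
    return out


def gaussian_bandpass(data: np.ndarray, rate_hz: float,
                      band_hz: tuple[float, float]) -> np.ndarray:
    """Zero-phase band-pass with a Gaussian magnitude response.

    The window is centered on the band and its sigma is a quarter of the
    bandwidth, so the nominal edges sit at two sigma (~ -17 dB).
    """
    n = data.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    fc = 0.5 * (band_hz[0] + band_hz[1])
    sigma = (band_hz[1] - band_hz[0]) / 4.0
    win = np.exp(-0.5 * ((freqs - fc) / sigma) ** 2)
    return np.fft.irfft(np.fft.rfft(data, axis=0) * win[:, None], n=n, axis=0)


def analytic_amplitude(data: np.ndarray) -> np.ndarray:
    return np.abs(signal.hilbert(data, axis=0))


def zscore_over_time(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = data.mean(axis=0)
    sd = np.maximum(data.std(axis=0), SD_FLOOR)
    return (data - mu) / sd, mu, sd


def offline_preprocess(raw: RawRecording, cfg: OfflineConfig | None = None) -> FeatureMatrix:
    """Analysis-grade high-gamma features at the downsampled (400 Hz) rate.

    Output columns correspond to the good channels only (``channel_ids``
    records the mapping). Steps run in the fixed order documented above.
    """
    cfg = cfg or OfflineConfig()
    if raw.rate_hz < cfg.downsample_to_hz:
        raise ValidationError("raw rate below target feature rate")
    good = raw.channels.good_indices
    if good.size < 2:
        raise ValidationError("need >=2 good channels for common average referencing")
    data = common_average_reference(raw.data, good)[:, good]

    frac = Fraction(cfg.downsample_to_hz / raw.rate_hz).limit_denominator(10000)
    data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=0)
    rate = raw.rate_hz * frac.numerator / frac.denominator

    data = notch_zero_phase(data, rate, cfg.notch_base_hz, cfg.notch_q)
    data = gaussian_bandpass(data, rate, cfg.hg_band_hz)
    env = analytic_amplitude(data)
    norm_mean = norm_sd = None
    if cfg.zscore:
        env, norm_mean, norm_sd = zscore_over_time(env)
    times = raw.t0_s + np.arange(env.shape[0]) / rate
    return FeatureMatrix(env, rate, times, zscored=cfg.zscore,
                         norm_mean=norm_mean, norm_sd=norm_sd, channel_ids=good)


# ---------------------------------------------------------------------------
# Streaming pipeline
# ---------------------------------------------------------------------------

@dataclass
class StreamConfig:
    chunk_ms: float = 10.0
    notch_base_hz: float = 50.0
    notch_q: float = 30.0
    band_hz: tuple[float, float] = (70.0, 170.0)
    butterworth_order: int = 3
    envelope_window_ms: float = 50.0
    step_ms: float = 10.0
    hilbert_taps_s: float = 0.063     # FIR Hilbert transformer length in seconds
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.envelope_window_ms < self.step_ms:
            raise ValidationError("envelope window must cover at least one step")
        ratio = self.chunk_ms / self.step_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError("step must divide the chunk duration")


def fir_hilbert_taps(rate_hz: float, length_s: float) -> tuple[np.ndarray, int]:
    """Hamming-windowed type-III FIR Hilbert transformer and its group delay."""
    n = int(round(length_s * rate_hz))
    if n % 2 == 0:
        n += 1
    m = (n - 1) // 2
    k = np.arange(-m, m + 1)
    h = np.zeros(n)
    odd = k % 2 != 0
    h[odd] = 2.0 / (np.pi * k[odd])
    h *= np.hamming(n)
    return h, m


class StreamState:
    """Causal per-session state for the streaming feature extractor.

    Holds IIR filter memories, the FIR Hilbert delay lines, and a ring buffer
    of envelope samples covering one averaging window. The contract: feeding a
    signal in chunks of any partition yields exactly the frames of one-shot
    processing.
    """

    def __init__(self, cfg: StreamConfig, channels: ChannelTable, rate_hz: float):
        good = channels.good_indices
        if good.size < 2:
            raise ValidationError("need >=2 good channels")
        if cfg.norm_mean is None or cfg.norm_sd is None:
            raise ValidationError("streaming requires fixed normalization parameters")
        if np.asarray(cfg.norm_mean).size != good.size:
            raise ValidationError("normalization parameters do not match good channels")
        nyq = rate_hz / 2
        if cfg.band_hz[1] >= nyq:
            raise ValidationError("band edge above Nyquist")
        step = cfg.step_ms / 1000 * rate_hz
        win = cfg.envelope_window_ms / 1000 * rate_hz
        if abs(step - round(step)) > 1e-9 or abs(win - round(win)) > 1e-9:
            raise ValidationError("step and window must be whole samples at this rate")
        self.cfg = cfg
        self.rate_hz = rate_hz
        self.good = good
        self.n_good = good.size
        self.step = int(round(step))
        self.win = int(round(win))
        self.frame_rate_hz = 1000.0 / cfg.step_ms

        self._sos = []
        self._zi = []
        for k in range(1, int(np.floor((nyq - 1e-9) / cfg.notch_base_hz)) + 1):
            b, a = signal.iirnotch(k * cfg.notch_base_hz, cfg.notch_q, fs=rate_hz)
            sos = signal.tf2sos(b, a)
            self._sos.append(sos)
            self._zi.append(np.zeros((sos.shape[0], 2, self.n_good)))
        sos = signal.butter(cfg.butterworth_order, cfg.band_hz, btype="bandpass",
                            fs=rate_hz, output="sos")
        self._sos.append(sos)
        self._zi.append(np.zeros((sos.shape[0], 2, self.n_good)))

        self._htaps, self._hdelay = fir_hilbert_taps(rate_hz, cfg.hilbert_taps_s)
        self._htaps_rev = self._htaps[::-1].copy()
        # input history for the FIR convolution (bitwise chunk-invariant:
        # each output sample sums the same fixed-length window)
        self._xhist = np.zeros((self._htaps.size - 1, self.n_good))
        self._dbuf = np.zeros((self._hdelay, self.n_good))  # group-delay line

        self._env = np.zeros((0, self.n_good))   # envelope ring buffer
        self._env_start = 0                      # absolute index of _env[0]
        self.frames_emitted = 0
        self.flagged_frames: list[int] = []

        self.norm_mean = np.asarray(cfg.norm_mean, dtype=float)
        self.norm_sd = np.maximum(np.asarray(cfg.norm_sd, dtype=float), SD_FLOOR)

    @property
    def group_delay_s(self) -> float:
        """Latency added by the causal Hilbert approximation."""
        return self._hdelay / self.rate_hz

    def process(self, chunk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Feed one chunk (samples x all channels); return (frames, frame_times).

        Frames are emitted once a full 50-ms window of envelope samples is
        available, timestamped at the window's right edge. NaN samples flag
        the affected frames (recorded in ``flagged_frames``) rather than
        propagating silently.
        """
        chunk = np.asarray(chunk, dtype=float)
        if chunk.ndim != 2 or chunk.shape[1] < self.good.max() + 1:
            raise ValidationError("chunk channel count does not match state")
        x = chunk[:, self.good]
        nanmask = ~np.isfinite(x)
        if nanmask.any():
            x = np.where(nanmask, 0.0, x)
        x = x - x.mean(axis=1, keepdims=True)  # CAR over good channels, per sample
        for i, sos in enumerate(self._sos):
            x, self._zi[i] = signal.sosfilt(sos, x, axis=0, zi=self._zi[i])
        # causal analytic envelope: quadrature via FIR Hilbert, in-phase via delay
        xext = np.vstack([self._xhist, x])
        sw = np.lib.stride_tricks.sliding_window_view(xext, self._htaps.size,
                                                      axis=0)  # (L, ch, taps)
        q = (sw * self._htaps_rev).sum(axis=-1)
        self._xhist = xext[-(self._htaps.size - 1):]
        stacked = np.vstack([self._dbuf, x])
        delayed = stacked[: x.shape[0]]
        self._dbuf = stacked[x.shape[0]:][-self._hdelay:] if self._hdelay else self._dbuf
        env = np.hypot(delayed, q)
        if nanmask.any():
            env[nanmask.any(axis=1)] = np.nan

        self._env = np.vstack([self._env, env])
        frames, times = [], []
        total = self._env_start + self._env.shape[0]
        while True:
            right = self.win + self.frames_emitted * self.step
            if right > total:
                break
            lo = right - self.win - self._env_start
            w = self._env[lo: lo + self.win]
            frame = w.mean(axis=0)
            if not np.isfinite(frame).all():
                self.flagged_frames.append(self.frames_emitted)
            frames.append((frame - self.norm_mean) / self.norm_sd)
            times.append(right / self.rate_hz)
            self.frames_emitted += 1
        # trim buffer to what the next window still needs
        next_lo = self.win + self.frames_emitted * self.step - self.win
        drop = max(0, next_lo - self._env_start)
        if drop:
            self._env = self._env[drop:]
            self._env_start += drop
        if frames:
            return np.array(frames), np.array(times)
        return np.zeros((0, self.n_good)), np.zeros(0)


def stream_init(cfg: StreamConfig, channels: ChannelTable,
                rate_hz: float) -> StreamState:
    return StreamState(cfg, channels, rate_hz)


def stream_preprocess(raw: RawRecording, cfg: StreamConfig,
                      chunk_ms: float | None = None) -> FeatureMatrix:
    """Run the causal streaming pipeline over a whole recording."""
    state = stream_init(cfg, raw.channels, raw.rate_hz)
    chunk = int(round((chunk_ms or cfg.chunk_ms) / 1000 * raw.rate_hz))
    frames, times = [], []
    for lo in range(0, raw.n_samples, chunk):
        f, t = state.process(raw.data[lo: lo + chunk])
        if f.size:
            frames.append(f)
            times.append(t)
    data = np.vstack(frames) if frames else np.zeros((0, state.n_good))
    tvec = raw.t0_s + (np.concatenate(times) if times else np.zeros(0))
    return FeatureMatrix(data, state.frame_rate_hz, tvec, zscored=True,
                         norm_mean=state.norm_mean, norm_sd=state.norm_sd,
                         channel_ids=raw.channels.good_indices)


def fit_normalization(feature_runs: list[np.ndarray],
                      min_frames: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Fixed per-channel z-score parameters pooled over earlier sessions.

    ``feature_runs`` are un-z-scored envelope frame matrices (frames x
    channels) from the character-reading sessions that precede the session to
    be decoded. SD is floored at 1e-8 so degenerate channels stay finite.
    """
    pooled = np.vstack(feature_runs)
    if pooled.shape[0] < min_frames:
        logger.warning("normalization fitted on only %d frames", pooled.shape[0])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    if (sd < SD_FLOOR).any():
        logger.warning("constant channel(s) %s: sd floored",
                       np.flatnonzero(sd < SD_FLOOR).tolist())
    return mu, np.maximum(sd, SD_FLOOR)


# ---------------------------------------------------------------------------
# SNR quality metric
# ---------------------------------------------------------------------------

@dataclass
class SnrConfig:
    window_s: float = 60.0
    step_s: float = 30.0
    band_hz: tuple[float, float] = (1.5, 250.0)
    bin_ms: float = 100.0
    min_high_run_bins: int = 4


def snr_from_envelope(env: np.ndarray, rate_hz: float, cfg: SnrConfig) -> float:
    """SNR (dB) of one window given its Hilbert envelope.

    Envelope samples are averaged into 100-ms bins; bins above the window's
    mean envelope amplitude are "high activity". Signal = peak-to-peak of the
    envelope within contiguous high runs of >= ``min_high_run_bins`` bins;
    noise = RMS of the envelope over contiguous low periods.
    SNR = 20 log10(mean run PP / mean low-period RMS); NaN if no run
    qualifies.
    """
    bin_n = int(round(cfg.bin_ms / 1000 * rate_hz))
    n_bins = env.shape[0] // bin_n
    if n_bins == 0:
        return np.nan
    env = env[: n_bins * bin_n]
    bins = env.reshape(n_bins, bin_n).mean(axis=1)
    high = bins > env.mean()

    pps, rmss = [], []
    i = 0
    while i < n_bins:
        j = i
        while j < n_bins and high[j] == high[i]:
            j += 1
        seg = env[i * bin_n: j * bin_n]
        if high[i]:
            if j - i >= cfg.min_high_run_bins:
                pps.append(seg.max() - seg.min())
        else:
            rmss.append(np.sqrt(np.mean(seg ** 2)))
        i = j
    if not pps or not rmss:
        return np.nan
    return 20.0 * np.log10(np.mean(pps) / np.mean(rmss))


def compute_snr(x: np.ndarray, rate_hz: float,
                cfg: SnrConfig | None = None) -> np.ndarray:
    """Per-window SNR values (dB) for one already-notch-filtered channel.

    Windows without a qualifying high-activity run are reported as NaN,
    never as zero.
    """
    cfg = cfg or SnrConfig()
    sos = signal.butter(4, cfg.band_hz, btype="bandpass", fs=rate_hz, output="sos")
    win = int(round(cfg.window_s * rate_hz))
    step = int(round(cfg.step_s * rate_hz))
    if win > x.shape[0]:
        raise ValidationError("window longer than signal")
    out = []
    for lo in range(0, x.shape[0] - win + 1, step):
        seg = signal.sosfiltfilt(sos, x[lo: lo + win])
        env = np.abs(signal.hilbert(seg))
        out.append(snr_from_envelope(env, rate_hz, cfg))
    return np.array(out)


# ---------------------------------------------------------------------------
# Bad channels
# ---------------------------------------------------------------------------

def detect_bad_channels(raw: RawRecording, k: float = 5.0,
                        flat_floor: float = 1e-10) -> ChannelTable:
    """Flag flat channels and broadband-RMS outliers (|dev| > k * scaled MAD)."""
    if raw.duration_s < 1.0:
        raise ValidationError("need >=1 s of data")
    sd = raw.data.std(axis=0)
    rms = np.sqrt(np.mean(raw.data ** 2, axis=0))
    med = np.median(rms)
    mad = 1.4826 * np.median(np.abs(rms - med))
    good = sd > flat_floor
    if mad > 0:
        good &= np.abs(rms - med) <= k * mad
    n_bad = int((~good).sum())
    if n_bad:
        logger.info("flagged %d bad channel(s): %s", n_bad,
                    np.flatnonzero(~good).tolist())
    return raw.channels.with_good(good & raw.channels.is_good)
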