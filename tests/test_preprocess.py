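"""Feature-extraction contracts: offline pipeline, causal streaming twin, SNR."""

import dataclasses

import numpy as np
import pytest
from scipy import signal

from tonosyl.core_io import ChannelTable, RawRecording, ValidationError
from tonosyl.preprocess import (OfflineConfig, SnrConfig, StreamConfig,
                                compute_snr, detect_bad_channels,
                                fir_hilbert_taps, fit_normalization,
                                notch_zero_phase, offline_preprocess,
                                snr_from_envelope, stream_init,
                                stream_preprocess)


def _raw(data, rate=1000.0, cols=None):
    n_ch = data.shape[1]
    table = ChannelTable.from_grid(1, n_ch) if cols is None else cols
    return RawRecording(data, rate, table)


class TestOffline:
    def test_sinusoid_envelope_flat(self, rng):
        """An in-band tone of amplitude a has a near-constant analytic
        amplitude (120 Hz: inside 70-150, clear of the notch harmonics)."""
        t = np.arange(4000) / 1000.0
        a = 3.0
        data = np.column_stack([a * np.sin(2 * np.pi * 120 * t),
                                0.01 * rng.standard_normal(4000),
                                0.01 * rng.standard_normal(4000)])
        fm = offline_preprocess(_raw(data), OfflineConfig(zscore=False))
        env = fm.data[200:-200, 0]         # exclude filter edge effects
        assert np.ptp(env) / env.mean() < 0.10

    def test_notch_suppresses_line_by_20db(self, rng):
        t = np.arange(8000) / 1000.0
        x = np.sin(2 * np.pi * 50 * t) + 0.1 * rng.standard_normal(8000)
        y = notch_zero_phase(x[:, None], 1000.0, 50.0)[:, 0]
        f, p = signal.periodogram(x, fs=1000.0)
        _, p2 = signal.periodogram(y, fs=1000.0)
        i = np.argmin(np.abs(f - 50))
        assert 10 * np.log10(p[i] / p2[i]) >= 20

    def test_zscore_exact(self, rng):
        data = rng.standard_normal((4000, 4))
        fm = offline_preprocess(_raw(data))
        np.testing.assert_allclose(fm.data.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(fm.data.std(axis=0), 1, atol=1e-6)

    def test_bad_channels_dropped_from_output(self, rng):
        table = ChannelTable.from_grid(1, 4)
        table.is_good[2] = False
        fm = offline_preprocess(_raw(rng.standard_normal((2000, 4)), cols=table))
        assert fm.n_channels == 3
        assert 2 not in fm.channel_ids

    def test_too_few_good_channels_errors(self, rng):
        table = ChannelTable.from_grid(1, 3)
        table.is_good[:] = [True, False, False]
        with pytest.raises(ValidationError):
            offline_preprocess(_raw(rng.standard_normal((1000, 3)), cols=table))


class TestStreaming:
    @pytest.fixture()
    def setup(self, rng):
        x = rng.standard_normal((2000, 6))
        ch = ChannelTable.from_grid(2, 3)
        cfg = StreamConfig(norm_mean=np.zeros(6), norm_sd=np.ones(6))
        return x, ch, cfg

    def _run(self, x, ch, cfg, partition):
        state = stream_init(cfg, ch, 1000.0)
        frames, times = [], []
        lo = 0
        for n in partition:
            f, t = state.process(x[lo: lo + n])
            lo += n
            if f.size:
                frames.append(f)
                times.append(t)
        return np.vstack(frames), np.concatenate(times)

    @pytest.mark.parametrize("partition", [
        [10] * 200, [5, 15] * 100, [2000], [7] * 285 + [5], [1] * 100 + [1900],
    ])
    def test_chunk_partition_invariance_exact(self, setup, partition):
        x, ch, cfg = setup
        ref, tref = self._run(x, ch, cfg, [10] * 200)
        out, tout = self._run(x, ch, cfg, partition)
        assert np.array_equal(ref, out)
        assert np.array_equal(tref, tout)

    def test_no_frames_before_window_fills(self, setup):
        x, ch, cfg = setup
        state = stream_init(cfg, ch, 1000.0)
        f, _ = state.process(x[:40])
        assert f.shape[0] == 0
        f, t = state.process(x[40:60])
        assert f.shape[0] == 2
        np.testing.assert_allclose(t, [0.05, 0.06])

    def test_brute_force_causal_oracle(self, setup):
        """Independent one-shot causal implementation agrees to 1e-9."""
        x, ch, cfg = setup
        out, _ = self._run(x, ch, cfg, [10] * 200)
        xc = x - x.mean(axis=1, keepdims=True)
        y = xc
        for k in range(1, 10):
            b, a = signal.iirnotch(50 * k, 30, fs=1000)
            y = signal.lfilter(b, a, y, axis=0)
        sos = signal.butter(3, (70, 170), btype="bandpass", fs=1000,
                            output="sos")
        y = signal.sosfilt(sos, y, axis=0)
        taps, delay = fir_hilbert_taps(1000, 0.063)
        q = signal.lfilter(taps, [1.0], y, axis=0)
        d = np.vstack([np.zeros((delay, 6)), y])[:2000]
        env = np.hypot(d, q)
        frames = np.array([env[r - 50: r].mean(axis=0)
                           for r in range(50, 2001, 10)])
        assert np.abs(frames - out).max() < 1e-9

    def test_zero_input_yields_neg_mean_over_sd(self, ch_table_6=None):
        ch = ChannelTable.from_grid(2, 3)
        mu, sd = np.full(6, 2.0), np.full(6, 4.0)
        cfg = StreamConfig(norm_mean=mu, norm_sd=sd)
        state = stream_init(cfg, ch, 1000.0)
        f, _ = state.process(np.zeros((100, 6)))
        np.testing.assert_allclose(f, -0.5)

    def test_missing_norm_params_is_config_error(self):
        ch = ChannelTable.from_grid(2, 3)
        with pytest.raises(ValidationError):
            stream_init(StreamConfig(), ch, 1000.0)

    def test_step_must_divide_chunk(self):
        with pytest.raises(ValidationError):
            StreamConfig(step_ms=7.0, norm_mean=np.zeros(2),
                         norm_sd=np.ones(2))

    def test_nan_chunk_flags_frames(self, setup):
        x, ch, cfg = setup
        x = x.copy()
        x[100, 0] = np.nan
        state = stream_init(cfg, ch, 1000.0)
        state.process(x[:500])
        assert state.flagged_frames  # affected windows are marked, not hidden

    def test_offline_and_stream_agree_on_burst_location(self, clean_session):
        """Both pipelines locate a high-gamma burst at the same time."""
        raw = clean_session["raw"]
        events = clean_session["events"]
        tpl = clean_session["truth"].templates
        inv = clean_session["inventory"]
        fm_off = offline_preprocess(raw)
        n_good = raw.channels.good_indices.size
        cfg = StreamConfig(norm_mean=np.zeros(n_good), norm_sd=np.ones(n_good))
        fm_str = stream_preprocess(raw, cfg, chunk_ms=100)
        row = events.df.iloc[0]
        s = inv.index(row["syllable"])
        ch = int(np.argmax(tpl.syllable_weights[s]))
        t0, t1 = row["onset_s"], row["onset_s"] + 0.6

        def peak_time(fm):
            sel = (fm.frame_times_s >= t0) & (fm.frame_times_s <= t1)
            seg = fm.data[sel, ch]
            k = max(1, int(0.05 * fm.frame_rate_hz))
            sm = np.convolve(seg, np.ones(k) / k, mode="same")
            return fm.frame_times_s[sel][np.argmax(sm)]

        # one 100-Hz frame of slack plus the causal group delay
        slack = 0.01 + 2 * 0.0315
        assert abs(peak_time(fm_off) - peak_time(fm_str)) <= 0.05 + slack


class TestNormalization:
    def test_split_vs_joint_identical(self, rng):
        a, b = rng.standard_normal((300, 4)), rng.standard_normal((200, 4))
        mu1, sd1 = fit_normalization([a, b])
        mu2, sd2 = fit_normalization([np.vstack([a, b])])
        np.testing.assert_array_equal(mu1, mu2)
        np.testing.assert_array_equal(sd1, sd2)

    def test_known_moments_recovered(self, rng):
        x = rng.standard_normal((5000, 3)) * np.array([1, 2, 3]) + [5, -1, 0]
        mu, sd = fit_normalization([x])
        np.testing.assert_allclose(mu, x.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(sd, x.std(axis=0), atol=1e-12)

    def test_constant_channel_floored(self, caplog):
        x = np.ones((500, 2))
        x[:, 1] = np.linspace(0, 1, 500)
        with caplog.at_level("WARNING"):
            _, sd = fit_normalization([x])
        assert sd[0] == 1e-8


class TestSnr:
    def _cfg(self):
        return SnrConfig(window_s=4.0, step_s=2.0, bin_ms=100.0)

    def test_closed_form_20db(self):
        """High runs with PP=10 over a floor of RMS=1 give exactly 20 dB.

        Each run oscillates 7 +- 5 with one full period per 100-ms bin, so
        every run bin sits above the window mean and the run's peak-to-peak
        is exactly 10, while the low-activity floor has RMS exactly 1."""
        rate, cfg = 1000.0, self._cfg()
        env = np.ones(4000)
        wave = 7.0 + 5.0 * np.sin(2 * np.pi * np.arange(500) / 100)
        for start in (500, 2000, 3300):
            env[start: start + 500] = wave
        assert snr_from_envelope(env, rate, cfg) == pytest.approx(20.0)

    def test_zero_db_when_pools_equal(self):
        rate, cfg = 1000.0, self._cfg()
        env = np.ones(4000)
        env[1000:1500] = 2.0 + 0.5 * np.sin(2 * np.pi * np.arange(500) / 100)
        assert snr_from_envelope(env, rate, cfg) == pytest.approx(0.0)

    def test_no_qualifying_run_is_missing(self):
        env = np.ones(4000)
        env[1000:1200] = 5.0                      # only 2 high bins < 4
        assert np.isnan(snr_from_envelope(env, 1000.0, self._cfg()))

    def test_scale_covariance(self, rng):
        x = rng.standard_normal(8000)
        x[2000:4000] *= 8.0
        a = compute_snr(x, 1000.0, self._cfg())
        b = compute_snr(3.7 * x, 1000.0, self._cfg())
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_matches_literal_formula_transcription(self, rng):
        """Randomized burst signal vs. an independent step-by-step oracle."""
        rate, cfg = 1000.0, self._cfg()
        x = 0.2 * rng.standard_normal(4000)
        for start in (800, 2200):
            x[start: start + 600] += 4 * rng.standard_normal(600)
        got = compute_snr(x, rate, cfg)[0]
        # oracle: literal transcription
        sos = signal.butter(4, (1.5, 250), btype="bandpass", fs=rate,
                            output="sos")
        env = np.abs(signal.hilbert(signal.sosfiltfilt(sos, x[:4000])))
        bins = env.reshape(40, 100).mean(axis=1)
        high = bins > env.mean()
        runs, lows, i = [], [], 0
        while i < 40:
            j = i
            while j < 40 and high[j] == high[i]:
                j += 1
            seg = env[i * 100: j * 100]
            if high[i] and j - i >= 4:
                runs.append(seg.max() - seg.min())
            if not high[i]:
                lows.append(np.sqrt(np.mean(seg ** 2)))
            i = j
        expected = 20 * np.log10(np.mean(runs) / np.mean(lows))
        assert got == pytest.approx(expected, abs=1e-9)


class TestBadChannels:
    def test_zeroed_channel_flagged(self, rng):
        data = rng.standard_normal((2000, 5))
        data[:, 3] = 0.0
        table = detect_bad_channels(_raw(data))
        assert not table.is_good[3] and table.is_good.sum() == 4

    def test_scaled_channel_flagged_by_mad_rule(self, rng):
        data = rng.standard_normal((2000, 8))
        data[:, 2] *= 100.0
        rms = np.sqrt((data ** 2).mean(axis=0))
        med = np.median(rms)
        mad = 1.4826 * np.median(np.abs(rms - med))
        assert np.abs(rms[2] - med) > 5 * mad     # the rule applied by hand
        assert not detect_bad_channels(_raw(data)).is_good[2]

    def test_homogeneous_channels_untouched(self, rng):
        data = rng.standard_normal((2000, 6))
        assert detect_bad_channels(_raw(data)).is_good.all()
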