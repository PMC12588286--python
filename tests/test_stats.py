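"""Electrode statistics: responsiveness, discriminability, saliency."""

import numpy as np
import pandas as pd
import pytest

from tonosyl.core_io import ChannelTable, EventTable, FeatureMatrix, \
    SyllableInventory
from tonosyl.decoder import DecoderModel, TrialSegment
from tonosyl.stats import (ElectrodeStatsConfig, channel_adjacency,
                           cumulative_mask, discriminative_electrodes,
                           gradient_saliency, speech_responsive,
                           _cluster_labels, _f_oneway_stat)
from tonosyl import nn

RATE = 400.0


def _features_events(rng, syllables, n_trials, effect, n_channels=8,
                     effect_channels=(0, 1), effect_window=(0.05, 0.35),
                     tones=None):
    """400-Hz feature session; `effect[label]` adds a mean shift on
    `effect_channels` inside `effect_window` after each onset."""
    spacing = 2.0
    n_frames = int((n_trials * spacing + 2) * RATE)
    data = rng.standard_normal((n_frames, n_channels))
    onsets, labels = [], []
    rows = []
    for i in range(n_trials):
        t = 1.0 + i * spacing
        lab = syllables[i % len(syllables)]
        lo = int((t + effect_window[0]) * RATE)
        hi = int((t + effect_window[1]) * RATE)
        for ch in effect_channels:
            data[lo:hi, ch] += effect(lab)
        onsets.append(t)
        tone = tones[i % len(tones)] if tones else (i % 4) + 1
        rows.append((i, t, lab, tone, "x", "char"))
    fm = FeatureMatrix(data, RATE, np.arange(n_frames) / RATE)
    ev = EventTable(pd.DataFrame(
        rows, columns=["trial_id", "onset_s", "syllable", "tone",
                       "character", "task"]))
    return fm, ev


@pytest.fixture()
def cfg200():
    return ElectrodeStatsConfig(n_permutations=200, balanced_n=1000, seed=0)


class TestSpeechResponsive:
    def test_template_channel_detected_noise_not(self, cfg200):
        rng = np.random.default_rng(1)
        fm, ev = _features_events(rng, ["ma"], 40, lambda s: 3.0,
                                  effect_channels=(2,),
                                  effect_window=(-0.1, 0.25))
        res = speech_responsive(fm, ev, cfg200)
        assert res.responsive[2]
        assert not res.responsive[[0, 1, 3, 4, 5, 6, 7]].any()

    def test_short_response_fails_duration_rule(self, cfg200):
        rng = np.random.default_rng(2)
        fm, ev = _features_events(rng, ["ma"], 40, lambda s: 3.0,
                                  effect_channels=(2,),
                                  effect_window=(0.0, 0.1))   # 100 ms only
        res = speech_responsive(fm, ev, cfg200)
        assert not res.responsive[2]

    def test_duration_rule_is_80_points_at_400hz(self, cfg200):
        assert cfg200.min_run_frames(400.0) == 80
        assert cfg200.min_run_frames(100.0) == 20


class TestDiscriminative:
    def _run(self, factor, syllables, effect, tones=None, seed=3,
             channels=(0, 1), n_trials=60):
        rng = np.random.default_rng(seed)
        fm, ev = _features_events(rng, syllables, n_trials, effect,
                                  effect_channels=channels, tones=tones)
        table = ChannelTable.from_grid(2, 4)
        inv = SyllableInventory(sorted(set(syllables)))
        cfg = ElectrodeStatsConfig(n_permutations=200, seed=0)
        return discriminative_electrodes(fm, ev, factor, table, inv, cfg)

    def test_syllable_channels_recovered(self):
        effects = {"ba": 0.0, "da": 2.0, "ka": 4.0}
        res = self._run("syllable", list(effects), lambda s: effects[s])
        assert res.discriminative[0] and res.discriminative[1]
        assert not res.discriminative[2:].any()

    def test_tone_channels_recovered(self):
        rng = np.random.default_rng(4)
        fm, ev = _features_events(rng, ["ma"], 80, lambda s: 0.0,
                                  effect_channels=(), tones=[1, 2, 3, 4])
        for i, (_, row) in enumerate(ev.df.iterrows()):
            lo = int((row["onset_s"] + 0.05) * RATE)
            hi = int((row["onset_s"] + 0.35) * RATE)
            fm.data[lo:hi, 3] += row["tone"] * 1.5
        table = ChannelTable.from_grid(2, 4)
        inv = SyllableInventory(["ma"])
        cfg = ElectrodeStatsConfig(n_permutations=200, seed=0)
        out = discriminative_electrodes(fm, ev, "tone", table, inv, cfg)
        assert out.discriminative[3]
        assert not out.discriminative[[0, 1, 2, 4, 5, 6, 7]].any()

    def test_place_two_group_contrast(self):
        effects = {"ba": 2.0, "ma": 2.0, "da": 0.0, "ga": 0.0}
        res = self._run("place", list(effects), lambda s: effects[s],
                        channels=(5,), n_trials=80)
        assert res.discriminative[5]

    def test_cluster_masses_match_mne_oracle(self):
        """Suprathreshold spatiotemporal cluster masses vs. MNE-Python."""
        mne = pytest.importorskip("mne")
        from scipy import sparse
        rng = np.random.default_rng(7)
        n_per, T, E = 15, 40, 6
        X = [rng.standard_normal((n_per, T, E)) for _ in range(3)]
        X[1][:, 10:20, 2] += 1.5
        table = ChannelTable.from_grid(2, 3)
        adj = channel_adjacency(table)
        data = np.concatenate(X)
        labels = np.repeat([0, 1, 2], n_per)
        groups = [np.flatnonzero(labels == i) for i in range(3)]
        f = _f_oneway_stat(data, groups)
        adj_pairs = np.column_stack(sparse.triu(adj, k=1).nonzero())
        lab, n = _cluster_labels(f > 3.0, adj_pairs)
        mine = sorted(float(f[lab == c].sum()) for c in range(n))
        _, clusters, _, _ = mne.stats.spatio_temporal_cluster_test(
            X, threshold=3.0, n_permutations=5, adjacency=adj, seed=0,
            out_type="mask", verbose="error")
        f_mne = mne.stats.f_oneway(*X)
        theirs = sorted(float(f_mne[m].sum()) for m in clusters)
        assert len(mine) == len(theirs)
        np.testing.assert_allclose(mine, theirs, rtol=1e-8)


class TestSaliency:
    def test_model_reading_single_electrode(self, rng):
        net = nn.StackedBiLSTM(6, 3, hidden1=3, hidden2=2, dropout=0.0, seed=0)
        for direction in (net.layers[0].fwd, net.layers[0].bwd):
            direction.Wx[:, :] = 0.0
            direction.Wx[4, :] = 0.5        # only electrode 4 reaches the net
        model = DecoderModel(net, "syllable", ["a", "b", "c"])
        segs = [TrialSegment(rng.standard_normal((10, 6)), i % 3, 1)
                for i in range(6)]
        res = gradient_saliency(model, segs)
        assert res.scores[4] == pytest.approx(1.0)
        others = np.delete(res.scores, 4)
        assert (others < 1e-10).all()
        assert list(np.flatnonzero(res.mask90)) == [4]

    def test_invariant_to_trial_order(self, rng):
        net = nn.StackedBiLSTM(4, 2, hidden1=2, hidden2=2, dropout=0.0, seed=1)
        model = DecoderModel(net, "syllable", ["a", "b"])
        segs = [TrialSegment(rng.standard_normal((8, 4)), i % 2, 1)
                for i in range(5)]
        a = gradient_saliency(model, segs).scores
        b = gradient_saliency(model, segs[::-1]).scores
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_cumulative_mask_hand_case(self):
        scores = np.array([1.0, 0.05, 0.04])
        mask = cumulative_mask(scores, 0.9)
        assert list(np.flatnonzero(mask)) == [0]
        # needs two once the top electrode covers less than 90%
        mask2 = cumulative_mask(np.array([1.0, 0.5, 0.01]), 0.9)
        assert mask2[:2].all() and not mask2[2]


class TestAdjacency:
    def test_grid_four_connectivity(self):
        table = ChannelTable.from_grid(3, 3, pitch_mm=3.0)
        adj = channel_adjacency(table)
        center = 4
        neighbors = sorted(adj[center].nonzero()[1].tolist())
        assert neighbors == [1, 3, 5, 7]
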