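"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from tonosyl.core_io import ChannelTable, EventTable, FeatureMatrix
from tonosyl.synth import SynthConfig, make_inventory, make_templates, \
    make_char_events, render_session


@pytest.fixture(scope="session")
def small_session():
    """Tiny noisy session: 16 channels, 4 syllables x 3 trials."""
    cfg = SynthConfig(n_channels=16, grid_cols=4, inventory_size=4,
                      trials_per_syllable=3, seed=7)
    inventory, chardict = make_inventory(4, 4, 2, 7)
    templates = make_templates(cfg, inventory)
    rng = np.random.default_rng(8)
    events = make_char_events(cfg, inventory, chardict, rng)
    raw, audio, events, truth = render_session(cfg, templates, inventory,
                                               events, rng)
    return {"cfg": cfg, "inventory": inventory, "chardict": chardict,
            "raw": raw, "audio": audio, "events": events, "truth": truth}


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free session for identifiability-style checks."""
    cfg = SynthConfig(n_channels=16, grid_cols=4, inventory_size=4,
                      trials_per_syllable=6, noise_sd=0.0, line_noise_amp=0.0,
                      seed=11)
    inventory, chardict = make_inventory(4, 4, 1, 11)
    templates = make_templates(cfg, inventory)
    rng = np.random.default_rng(12)
    events = make_char_events(cfg, inventory, chardict, rng)
    raw, audio, events, truth = render_session(cfg, templates, inventory,
                                               events, rng)
    return {"cfg": cfg, "inventory": inventory, "chardict": chardict,
            "raw": raw, "audio": audio, "events": events, "truth": truth}


def synthetic_feature_matrix(rng, n_frames=400, n_channels=8,
                             frame_rate_hz=400.0):
    data = rng.standard_normal((n_frames, n_channels))
    times = np.arange(n_frames) / frame_rate_hz
    return FeatureMatrix(data, frame_rate_hz, times)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
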