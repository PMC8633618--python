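"""Shared fixtures: scaled synthetic recordings with ground truth.

All fixtures are generated programmatically; the expensive ones are
session-scoped so multiple test modules can reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from hepsleep.synthpsg import SynthConfig, synthesize_recording


@pytest.fixture(scope="session")
def small_psg():
    """A ~630 s recording at 256 Hz with 10 segments per state."""
    cfg = SynthConfig(fs=256.0, n_segments_per_state=10, seed=3)
    rec, truth = synthesize_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def noise_free_psg():
    """Noise-free render: only injected structure (HEP, EMs, ECG)."""
    cfg = SynthConfig(fs=256.0, n_segments_per_state=6, seed=5)
    cfg.noise_spec.eeg_rms_uv = 0.0
    cfg.noise_spec.eog_rms_uv = 0.0
    cfg.noise_spec.ecg_rms_uv = 0.0
    for k in cfg.band_power_spec.alpha_high_uv:
        cfg.band_power_spec.alpha_high_uv[k] = 0.0
        cfg.band_power_spec.beta_uv[k] = 0.0
    cfg.ecg_leak_fraction = 0.0
    cfg.eog_leak_gain = 0.0  # keep EM bursts but no cross-channel mixing
    rec, truth = synthesize_recording(cfg)
    return cfg, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
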