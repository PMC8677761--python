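"""Shared fixtures: seeded synthetic recordings at several scales.

The expensive end-to-end fixtures are session-scoped so the parameter-
recovery, reporting, and acceptance tests share a single simulation run.
"""

from __future__ import annotations

import numpy as np
import pytest

from swarmtone.audio_core import compute_spectrogram
from swarmtone.playback_synthesis import classify_periods, make_schedule, render
from swarmtone.stats_report import analyze_recording
from swarmtone.swarm_synth import mixed_config, simulate
from swarmtone.tone_tracking import Band


@pytest.fixture(scope="session")
def mixed_run():
    """Full 1-h mixed-sex swarm with 100 interaction events at the standard
    criteria margins (+50 Hz, +15 dB, rapid FM), analyzed end to end."""
    cfg = mixed_config(
        seed=7,
        n_events=100,
        interaction_df_hz=(50.0, 50.0),
        interaction_da_db=(15.0, 15.0),
    )
    clip, truth = simulate(cfg)
    result = analyze_recording(clip)
    return {"config": cfg, "truth": truth, "result": result}


@pytest.fixture(scope="session")
def short_mixed_run():
    """2-min mixed-sex swarm with 5 events for fast unit-level checks."""
    cfg = mixed_config(
        seed=11,
        n_events=5,
        interaction_df_hz=(50.0, 50.0),
        interaction_da_db=(15.0, 15.0),
    )
    clip, truth = simulate(cfg, duration_s=120.0)
    return {"config": cfg, "clip": clip, "truth": truth}


@pytest.fixture(scope="session")
def playback_roundtrip():
    """Standard female playback stimulus rendered and re-analyzed."""
    schedule = make_schedule(Band.FEMALE)
    clip = render(schedule, sample_rate=44100)
    spec = compute_spectrogram(clip, overlap=0.0, fmax=700.0)
    table = classify_periods(spec, schedule)
    return {"schedule": schedule, "table": table}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
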