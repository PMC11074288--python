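"""Shared fixtures: small simulated sessions and hand-built waveforms."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dcpot import (
    AverageWaveform,
    EventTable,
    Recording,
    SimConfig,
)

FS = 500.0
WINDOW_MS = (-500.0, 1000.0)
N_EPOCH = 750


def make_waveform(
    values: np.ndarray,
    corrected: bool = True,
    tone: str = "rewarded",
    channel: str = "frontal",
    subject: str = "S01",
    session: str = "conditioning4",
    n_trials: int = 150,
) -> AverageWaveform:
    """An AverageWaveform over the standard epoch window from raw samples."""
    values = np.asarray(values, dtype=float)
    assert len(values) == N_EPOCH
    return AverageWaveform(
        values=values,
        fs=FS,
        window_ms=WINDOW_MS,
        n_trials_averaged=n_trials,
        baseline_corrected=corrected,
        subject_id=subject,
        session_id=session,
        tone=tone,
        channel=channel,
    )


def waveform_from_post(post: np.ndarray, **kwargs) -> AverageWaveform:
    """Waveform that is zero in the baseline and ``post`` (500 samples,
    0..1000 ms) afterwards — the natural shape of event-locked kernels."""
    values = np.concatenate([np.zeros(250), np.asarray(post, dtype=float)])
    return make_waveform(values, **kwargs)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A cheap cohort: 3 clean subjects, 12 trials/tone, frontal only."""
    return SimConfig(
        n_subjects=3,
        include_noisy_subject=False,
        n_trials_per_tone=12,
        channels=("frontal",),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_session(tiny_config):
    """One simulated conditioning session (recording, events, artifact log)."""
    from dcpot import simulate_session

    return simulate_session(tiny_config, "conditioning3", "S01")


@pytest.fixture()
def flat_recording() -> tuple[Recording, EventTable]:
    """A constant 10-uV recording with three well-separated events."""
    rec = Recording(
        channels=["frontal"],
        fs=FS,
        data=np.full((1, int(20 * FS)), 10.0),
        subject_id="S01",
        session_id="independent",
    )
    events = EventTable(
        pd.DataFrame(
            {
                "onset": [2.0, 8.0, 14.0],
                "tone": ["rewarded", "unrewarded", "rewarded"],
                "session_day": "independent",
                "stim_followed": False,
            }
        )
    )
    return rec, events
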