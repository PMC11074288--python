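"""Epoch extraction, artifact rejection, averaging and baseline correction.

Continuous recordings are cut into fixed windows of −500 ms to +1000 ms
around each tone onset (half-open in samples: 750 samples at 500 Hz), any
epoch whose peak-to-peak amplitude exceeds a movement-artifact threshold is
rejected, accepted epochs are averaged per tone and channel, and the mean of
the 500 ms pre-stimulus baseline is subtracted from the average.

Averaging precedes baseline correction: the baseline of the *averaged*
waveform is subtracted (per-trial correction is available as an option but
is not the default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import EventTable, Recording, ValidationError

__all__ = [
    "EpochSet",
    "AverageWaveform",
    "RejectionReport",
    "EmptyAverageError",
    "extract_epochs",
    "reject_epochs",
    "average_epochs",
    "baseline_correct",
    "DEFAULT_WINDOW_MS",
    "DEFAULT_P2P_THRESHOLD_UV",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_MS: tuple[float, float] = (-500.0, 1000.0)
#: Peak-to-peak rejection threshold for "marked movement noise" (uV).
DEFAULT_P2P_THRESHOLD_UV: float = 300.0


class EmptyAverageError(ValueError):
    """No accepted epochs remain in the requested stratum."""


@dataclass
class EpochSet:
    """Per-trial epochs of shape ``(n_trials, n_channels, n_samples)``.

    ``trial_index`` maps each epoch row back to its row in the originating
    event table; ``n_edge_excluded`` counts events dropped because their
    window did not fit inside the recording, so that
    ``accepted + rejected + edge-excluded`` always equals the number of
    events presented.
    """

    data: np.ndarray
    fs: float
    window_ms: tuple[float, float]
    channels: list[str]
    labels: np.ndarray  # tone per trial
    trial_index: np.ndarray
    accepted_mask: np.ndarray
    n_edge_excluded: int = 0
    subject_id: str = "unknown"
    session_id: str = "unknown"

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.trial_index) == len(self.accepted_mask) == n):
            raise ValidationError("per-trial arrays disagree in length")
        expected = int(round((self.window_ms[1] - self.window_ms[0]) / 1000.0 * self.fs))
        if self.data.shape[2] != expected:
            raise ValidationError(
                f"epoch length {self.data.shape[2]} != window * fs = {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times relative to tone onset (half-open window)."""
        n = self.data.shape[2]
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.fs

    def counts(self) -> dict[str, int]:
        acc = int(self.accepted_mask.sum())
        return {
            "accepted": acc,
            "rejected": self.n_trials - acc,
            "edge_excluded": self.n_edge_excluded,
            "total_events": self.n_trials + self.n_edge_excluded,
        }


@dataclass
class AverageWaveform:
    """Per-channel average of accepted epochs for one stratum."""

    values: np.ndarray  # uV per sample over the epoch window
    fs: float
    window_ms: tuple[float, float]
    n_trials_averaged: int
    baseline_corrected: bool = False
    subject_id: str = "unknown"
    session_id: str = "unknown"
    tone: str = "unknown"
    channel: str = "unknown"

    @property
    def times_ms(self) -> np.ndarray:
        return self.window_ms[0] + np.arange(len(self.values)) * 1000.0 / self.fs

    def value_at(self, t_ms: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the waveform at arbitrary epoch times."""
        return np.interp(t_ms, self.times_ms, self.values)

    def window_slice(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Samples with onset-relative time in ``[start_ms, end_ms)``."""
        t = self.times_ms
        if start_ms < t[0] - 1e-9 or end_ms > self.window_ms[1] + 1e-9:
            raise ValueError(
                f"window [{start_ms}, {end_ms}) ms outside epoch "
                f"[{t[0]}, {self.window_ms[1]}) ms"
            )
        return self.values[(t >= start_ms - 1e-9) & (t < end_ms - 1e-9)]


@dataclass
class RejectionReport:
    """Per-trial peak-to-peak values and decisions of artifact screening."""

    table: pd.DataFrame  # columns: trial_index, tone, p2p_uv, rejected
    threshold_uv: float

    @property
    def rejection_rate(self) -> float:
        if len(self.table) == 0:
            return 0.0
        return float(self.table["rejected"].mean())

    @property
    def rejected_trials(self) -> set[int]:
        return set(self.table.loc[self.table["rejected"], "trial_index"])


def extract_epochs(
    recording: Recording,
    events: EventTable,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> EpochSet:
    """Cut one epoch per event from the continuous recording.

    The onset sample is the nearest sample at-or-after the event time, and
    the window is half-open ``[onset + w0, onset + w1)`` in samples. Events
    whose window does not fit inside the recording are excluded with a
    logged warning rather than raising.
    """
    events.check_within(recording)
    fs = recording.fs
    w0 = int(round(window_ms[0] / 1000.0 * fs))
    w1 = int(round(window_ms[1] / 1000.0 * fs))
    n_win = w1 - w0
    onset_samples = np.ceil(events.onsets * fs - 1e-9).astype(int)

    keep, dropped = [], []
    for i, s0 in enumerate(onset_samples):
        if s0 + w0 < 0 or s0 + w1 > recording.n_samples:
            dropped.append(i)
        else:
            keep.append(i)
    if dropped:
        logger.warning(
            "%d/%d events too close to a recording edge were excluded "
            "(first at %.3f s)",
            len(dropped),
            len(events),
            events.onsets[dropped[0]],
        )
    data = np.empty((len(keep), len(recording.channels), n_win))
    for row, i in enumerate(keep):
        s0 = onset_samples[i]
        data[row] = recording.data[:, s0 + w0 : s0 + w1]
    return EpochSet(
        data=data,
        fs=fs,
        window_ms=window_ms,
        channels=list(recording.channels),
        labels=events.df["tone"].to_numpy()[keep],
        trial_index=np.asarray(keep, dtype=int),
        accepted_mask=np.ones(len(keep), dtype=bool),
        n_edge_excluded=len(dropped),
        subject_id=recording.subject_id,
        session_id=recording.session_id,
    )


def reject_epochs(
    epochs: EpochSet, threshold_uv: float = DEFAULT_P2P_THRESHOLD_UV
) -> tuple[EpochSet, RejectionReport]:
    """Flag epochs whose peak-to-peak amplitude exceeds ``threshold_uv``.

    An epoch is rejected iff max − min within the epoch, on *any* channel,
    exceeds the threshold. Returns a new EpochSet (with an updated
    ``accepted_mask``) and a per-trial report.
    """
    if not threshold_uv > 0:
        raise ValidationError("rejection threshold must be positive")
    p2p = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (trials, channels)
    worst = p2p.max(axis=1) if p2p.size else np.zeros(0)
    rejected = worst > threshold_uv
    report = RejectionReport(
        table=pd.DataFrame(
            {
                "trial_index": epochs.trial_index,
                "tone": epochs.labels,
                "p2p_uv": worst,
                "rejected": rejected,
            }
        ),
        threshold_uv=threshold_uv,
    )
    updated = replace(epochs, accepted_mask=epochs.accepted_mask & ~rejected)
    return updated, report


def average_epochs(
    epochs: EpochSet, tone: str, per_trial_baseline: bool = False
) -> dict[str, AverageWaveform]:
    """Pointwise mean across accepted epochs of one tone, per channel.

    With ``per_trial_baseline`` each epoch has its own pre-stimulus mean
    subtracted before averaging (an alternative to correcting the average).
    """
    sel = epochs.accepted_mask & (epochs.labels == tone)
    n = int(sel.sum())
    if n == 0:
        raise EmptyAverageError(
            f"no accepted epochs for tone={tone!r} "
            f"(subject={epochs.subject_id}, session={epochs.session_id})"
        )
    data = epochs.data[sel]
    if per_trial_baseline:
        t = epochs.times_ms
        base = (t >= epochs.window_ms[0]) & (t < 0)
        data = data - data[:, :, base].mean(axis=2, keepdims=True)
    mean = data.mean(axis=0)  # (channels, samples)
    return {
        ch: AverageWaveform(
            values=mean[ci],
            fs=epochs.fs,
            window_ms=epochs.window_ms,
            n_trials_averaged=n,
            baseline_corrected=per_trial_baseline,
            subject_id=epochs.subject_id,
            session_id=epochs.session_id,
            tone=tone,
            channel=ch,
        )
        for ci, ch in enumerate(epochs.channels)
    }


def baseline_correct(avg: AverageWaveform) -> AverageWaveform:
    """Subtract the mean of the [−500, 0) ms baseline from every sample.

    Idempotent: correcting an already-corrected waveform changes nothing
    (its baseline mean is already zero).
    """
    if avg.baseline_corrected:
        return avg  # already zero-mean baseline; nothing to subtract
    t = avg.times_ms
    base = (t >= avg.window_ms[0]) & (t < 0)
    if not np.any(base):
        raise ValidationError("epoch window contains no pre-stimulus baseline")
    shift = avg.values[base].mean()
    return replace(
        avg, values=avg.values - shift, baseline_corrected=True
    )
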