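"""DC-potential statistics computed from averaged, baseline-corrected waveforms.

Metrics
-------
* ``mean_dc_amplitude`` — mean amplitude over a post-tone window, by default
  [600, 1000) ms where tone discrimination is expressed.
* ``integrated_area_difference`` — the discrimination statistic: the
  absolute sum of trapezoidal area differences between the rewarded and
  unrewarded averages every 1 ms from 300 to 999 ms (uV*ms). The native
  500 Hz grid (2 ms) is linearly interpolated onto the 1-ms grid.
* ``windowed_dc_areas`` — signed trapezoidal areas over [300, 600] and
  [600, 1000] ms (the two "area" factor levels of the statistical design).
* ``relative_dc_profile`` — per-subject waveform values at 300..1000 ms
  (100-ms steps) expressed relative to the cohort grand mean at 300 ms over
  both tones, removing inter-subject AEP-amplitude offsets.
* ``dc_ratios`` — values at 600 and 1000 ms divided by the value at 300 ms,
  with an epsilon guard on the denominator.
* ``classify_profile`` — labels a waveform "sustained" (negative shift held
  through 1000 ms), "reduced" (returning toward baseline) or "flat".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import AverageWaveform

__all__ = [
    "mean_dc_amplitude",
    "integrated_area_difference",
    "windowed_dc_areas",
    "relative_dc_profile",
    "dc_ratios",
    "classify_profile",
    "RelativeDCTable",
    "RELATIVE_TIMEPOINTS_MS",
]

logger = logging.getLogger(__name__)

RELATIVE_TIMEPOINTS_MS: tuple[int, ...] = tuple(range(300, 1001, 100))


def _require_corrected(avg: AverageWaveform) -> None:
    if not avg.baseline_corrected:
        raise ValueError(
            f"waveform (subject={avg.subject_id}, session={avg.session_id}, "
            f"tone={avg.tone}, channel={avg.channel}) is not baseline-corrected"
        )


def mean_dc_amplitude(
    avg: AverageWaveform, window_ms: tuple[float, float] = (600.0, 1000.0)
) -> float:
    """Arithmetic mean amplitude (uV) over ``[start, end)`` ms post-tone."""
    _require_corrected(avg)
    return float(avg.window_slice(*window_ms).mean())


def _ms_grid(avg: AverageWaveform, t0: float, t1: float) -> np.ndarray:
    """Waveform resampled to a 1-ms grid covering t0..t1 inclusive.

    Grid points past the last sample (the half-open window ends one sample
    short of ``window_ms[1]``) take the final sample's value.
    """
    if t0 < avg.window_ms[0] or t1 > avg.window_ms[1] + 1e-9:
        raise ValueError(f"grid [{t0}, {t1}] ms outside epoch window {avg.window_ms}")
    return avg.value_at(np.arange(t0, t1 + 0.5))


def integrated_area_difference(
    avg_rewarded: AverageWaveform,
    avg_unrewarded: AverageWaveform,
    t0_ms: float = 300.0,
    t1_ms: float = 999.0,
) -> float:
    """Absolute sum of 1-ms trapezoidal area differences (uV*ms).

    Both waveforms are interpolated onto a 1-ms grid from ``t0_ms`` to
    ``t1_ms``; the statistic is the sum over each 1-ms interval of the
    absolute trapezoidal area of the rewarded-minus-unrewarded difference —
    symmetric in its arguments, non-negative, and zero only when the
    difference vanishes on the grid.
    """
    for a, b, what in (
        (avg_rewarded.channel, avg_unrewarded.channel, "channel"),
        (avg_rewarded.session_id, avg_unrewarded.session_id, "session"),
        (avg_rewarded.subject_id, avg_unrewarded.subject_id, "subject"),
    ):
        if a != b:
            raise KeyError(f"waveforms disagree on {what}: {a!r} vs {b!r}")
    _require_corrected(avg_rewarded)
    _require_corrected(avg_unrewarded)
    d = _ms_grid(avg_rewarded, t0_ms, t1_ms) - _ms_grid(avg_unrewarded, t0_ms, t1_ms)
    # |trapezoid| over each 1-ms interval: 0.5 * |d[i] + d[i+1]| * 1 ms
    return float(np.sum(np.abs(0.5 * (d[:-1] + d[1:]))))


def windowed_dc_areas(
    avg: AverageWaveform,
    windows_ms: tuple[tuple[float, float], ...] = ((300.0, 600.0), (600.0, 1000.0)),
) -> tuple[float, ...]:
    """Signed trapezoidal integrals (uV*ms) over each window on the 1-ms grid."""
    _require_corrected(avg)
    out = []
    for w0, w1 in windows_ms:
        y = _ms_grid(avg, w0, w1)
        out.append(float(np.trapezoid(y, dx=1.0)))
    return tuple(out)


@dataclass
class RelativeDCTable:
    """Long-format relative DC values plus the per-stratum reference."""

    table: pd.DataFrame  # subject, session, tone, channel, timepoint_ms, relative_value
    reference_value: float
    session_id: str
    channel: str


def relative_dc_profile(
    cohort_averages: list[AverageWaveform],
    timepoints_ms: tuple[int, ...] = RELATIVE_TIMEPOINTS_MS,
) -> RelativeDCTable:
    """Relative DC profile for one (session, channel) across a cohort.

    The reference is the grand mean of the waveform values at 300 ms across
    all subjects and both tones; every (subject, tone, timepoint) value is
    the waveform value minus that reference. Subjects missing either tone
    are excluded with a warning. By construction the 300-ms column has
    stratum mean exactly zero.
    """
    sessions = {w.session_id for w in cohort_averages}
    channels = {w.channel for w in cohort_averages}
    if len(sessions) != 1 or len(channels) != 1:
        raise KeyError(
            f"cohort averages must share one session and channel, got "
            f"sessions={sorted(sessions)} channels={sorted(channels)}"
        )
    by_subject: dict[str, dict[str, AverageWaveform]] = {}
    for w in cohort_averages:
        _require_corrected(w)
        by_subject.setdefault(w.subject_id, {})[w.tone] = w
    complete = {
        s: tones
        for s, tones in by_subject.items()
        if {"rewarded", "unrewarded"} <= set(tones)
    }
    for s in set(by_subject) - set(complete):
        logger.warning("subject %s lacks one tone average; excluded from profile", s)
    if len(complete) < 2:
        raise ValueError("relative DC profile needs at least 2 complete subjects")

    waves = [w for tones in complete.values() for w in tones.values()]
    reference = float(np.mean([w.value_at(timepoints_ms[0]) for w in waves]))
    rows = []
    for s, tones in sorted(complete.items()):
        for tone, w in sorted(tones.items()):
            for tp in timepoints_ms:
                rows.append(
                    {
                        "subject": s,
                        "session": w.session_id,
                        "tone": tone,
                        "channel": w.channel,
                        "timepoint_ms": tp,
                        "relative_value": float(w.value_at(tp)) - reference,
                    }
                )
    return RelativeDCTable(
        table=pd.DataFrame(rows),
        reference_value=reference,
        session_id=sessions.pop(),
        channel=channels.pop(),
    )


def dc_ratios(
    avg: AverageWaveform | None = None,
    *,
    v300: float | None = None,
    v600: float | None = None,
    v1000: float | None = None,
    epsilon_uv: float = 1.0,
) -> tuple[float, float]:
    """Ratios of the 600-ms and 1000-ms values to the 300-ms value.

    Operates on a baseline-corrected average by default (pass ``avg``), or
    on explicit values — e.g. relative DC values — via keywords. When the
    300-ms denominator is smaller in magnitude than ``epsilon_uv`` the
    ratios are undefined and returned as NaN (never +/-inf).
    """
    if avg is not None:
        _require_corrected(avg)
        v300 = float(avg.value_at(300.0))
        v600 = float(avg.value_at(600.0))
        v1000 = float(avg.value_at(1000.0))  # clamps to the final sample
    if v300 is None or v600 is None or v1000 is None:
        raise ValueError("provide either avg or all of v300, v600, v1000")
    if abs(v300) < epsilon_uv:
        return (float("nan"), float("nan"))
    return (v600 / v300, v1000 / v300)


def classify_profile(
    avg: AverageWaveform,
    mid_ms: float = 600.0,
    end_ms: float = 1000.0,
    flat_threshold_uv: float = 10.0,
    retain_fraction: float = 0.7,
) -> str:
    """Label the post-tone DC response "sustained", "reduced" or "flat".

    Let ``m`` be the mean over [mid-50, mid+50] ms and ``e`` the mean over
    [end-100, end) ms. The response is "flat" when |m| is below
    ``flat_threshold_uv``; otherwise "sustained" when the late window
    retains at least ``retain_fraction`` of |m| with the same sign, and
    "reduced" when it has returned toward baseline.
    """
    _require_corrected(avg)
    m = float(avg.window_slice(mid_ms - 50.0, mid_ms + 50.0).mean())
    e = float(avg.window_slice(end_ms - 100.0, end_ms).mean())
    if abs(m) < flat_threshold_uv:
        return "flat"
    if abs(e) >= retain_fraction * abs(m) and np.sign(e) == np.sign(m):
        return "sustained"
    return "reduced"
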