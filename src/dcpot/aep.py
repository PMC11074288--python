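"""Detection of auditory-evoked-potential components P1, N1 and P2.

P1 is the first positive inflection after tone onset (searched in
[20, 80) ms), N1 the first negative deflection after P1 (up to 150 ms), and
P2 the next positive peak after N1 (up to 300 ms). The P1 amplitude is the
peak value relative to the (zero) baseline of a corrected average; the N1
and P2 amplitudes are peak-to-peak magnitudes (P1-to-N1 and N1-to-P2).
Latencies are measured from tone onset in seconds.

The averaged waveform is lightly smoothed (Savitzky–Golay, 5-point window,
quadratic) before peak picking; a quadratic-preserving filter leaves the
curvature of smooth evoked lobes essentially untouched while suppressing
sample-to-sample noise that would otherwise jitter the argmax. Components
whose extremum sits on a search-window edge (no sign-appropriate interior
peak) are reported with a low-confidence flag rather than dropped, keeping
cohort tables rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .epochs import AverageWaveform

__all__ = ["AEPComponents", "AEPWindows", "detect_aep_components"]


@dataclass(frozen=True)
class AEPWindows:
    """Search windows (ms from tone onset) for the sequential peak search."""

    p1_ms: tuple[float, float] = (20.0, 80.0)
    n1_end_ms: float = 150.0
    p2_end_ms: float = 300.0


@dataclass
class AEPComponents:
    """Latencies (s from tone onset), amplitudes (uV) and confidence flags."""

    p1_latency_s: float
    n1_latency_s: float
    p2_latency_s: float
    p1_amp_uv: float  # peak value minus (zero) baseline
    n1_amp_uv: float  # P1-to-N1 peak-to-peak, >= 0
    p2_amp_uv: float  # N1-to-P2 peak-to-peak, >= 0
    low_confidence: dict[str, bool] = field(
        default_factory=lambda: {"p1": False, "n1": False, "p2": False}
    )
    windows: AEPWindows = field(default_factory=AEPWindows)

    def as_metric_rows(self) -> dict[str, float]:
        return {
            "p1_amp": self.p1_amp_uv,
            "n1_amp": self.n1_amp_uv,
            "p2_amp": self.p2_amp_uv,
            "p1_lat": self.p1_latency_s,
            "n1_lat": self.n1_latency_s,
            "p2_lat": self.p2_latency_s,
        }


def _search(
    t_ms: np.ndarray,
    y: np.ndarray,
    lo_ms: float,
    hi_ms: float,
    sign: float,
) -> tuple[float, float, bool]:
    """Extremum of ``sign * y`` in [lo_ms, hi_ms); ties broken earliest.

    Returns (latency_ms, value, low_confidence); low confidence means the
    extremum sits on the window edge or the window is degenerate.
    """
    mask = (t_ms >= lo_ms - 1e-9) & (t_ms < hi_ms - 1e-9)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return (lo_ms, 0.0, True)
    seg = sign * y[idx]
    k = int(np.argmax(seg))  # argmax returns the earliest maximal sample
    flagged = k == 0 or k == len(idx) - 1
    return (float(t_ms[idx[k]]), float(y[idx[k]]), flagged)


def detect_aep_components(
    avg: AverageWaveform,
    windows: AEPWindows = AEPWindows(),
    smooth: bool = True,
) -> AEPComponents:
    """Sequential constrained P1 → N1 → P2 search on a corrected average."""
    if not avg.baseline_corrected:
        raise ValueError("AEP detection requires a baseline-corrected average")
    t_ms = avg.times_ms
    y = avg.values
    if smooth and len(y) >= 5:
        y = savgol_filter(y, window_length=5, polyorder=2)

    half_step = 500.0 / avg.fs  # half a sample, to keep searches strictly after
    p1_lat, p1_val, p1_flag = _search(t_ms, y, *windows.p1_ms, sign=+1.0)
    n1_lat, n1_val, n1_flag = _search(
        t_ms, y, p1_lat + half_step, windows.n1_end_ms, sign=-1.0
    )
    p2_lat, p2_val, p2_flag = _search(
        t_ms, y, n1_lat + half_step, windows.p2_end_ms, sign=+1.0
    )
    return AEPComponents(
        p1_latency_s=p1_lat / 1000.0,
        n1_latency_s=n1_lat / 1000.0,
        p2_latency_s=p2_lat / 1000.0,
        p1_amp_uv=p1_val,
        n1_amp_uv=abs(p1_val - n1_val),
        p2_amp_uv=abs(p2_val - n1_val),
        low_confidence={"p1": p1_flag, "n1": n1_flag, "p2": p2_flag},
        windows=windows,
    )
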