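"""Synthetic cohorts of DC-EEG recordings for the two-tone reward paradigm.

The generator emulates the study design the analysis assumes: an 11-session
schedule (one independent baseline day, five daily conditioning sessions,
five daily extinction sessions) in which two tones are presented randomly
with an equal ratio — 150 times each in a full session — at a mean
inter-trial interval of 12 s (range 10–14 s) during independent/conditioning
days and 4 s during extinction. During conditioning, the rewarded tone is
followed 1000 ms later by a medial-forebrain-bundle stimulation burst, which
appears in the signal as a saturating pulse-train artifact.

Each channel's continuous signal is built by superposition:

    pink noise + slow drift
    + per event: AEP kernel + slow-shift kernel (scaled per channel)
    + movement artifacts + (rewarded, conditioning) stimulation artifact

The slow-shift kernel is zero until ``onset_ms``, ramps linearly to its
plateau amplitude ``A`` at ``plateau_ms``, and then either holds ``A``
("sustained") or decays exponentially toward baseline ("reduced") — the two
response profiles that distinguish rewarded from unrewarded tones once
discrimination is learned. The per-day amplitudes grow over conditioning,
peak on day 4, diverge between tones from day 3, and collapse to equality by
extinction day 2.

Everything is deterministic given ``(config, rng_seed)``; a noise-free mode
(``noise_sd=0, drift_amp_uv=0, artifact_rate_per_min=0``) exposes the pure
kernel superposition for oracle tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventTable, Recording, SessionMeta, ValidationError, SESSION_DAYS

__all__ = [
    "AEPKernelParams",
    "ShiftEntry",
    "ShiftSchedule",
    "SimConfig",
    "build_effect_schedule",
    "aep_kernel",
    "slow_shift_kernel",
    "pink_noise",
    "simulate_session",
    "inject_artifacts",
    "trials_hit_by_artifacts",
]


# ---------------------------------------------------------------------------
# Kernel parameter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AEPKernelParams:
    """Three-lobe auditory-evoked-potential kernel (P1 +, N1 -, P2 +).

    Each lobe is a raised-cosine (Hann) deflection ``amp * cos^2`` centred on
    its latency with compact support ``latency +/- width``; the lobes do not
    overlap with the default timings, so peak amplitudes and latencies are
    recovered exactly by superposition. Latency/amplitude defaults sit in the
    regime reported for epidural rat recordings (P1 near 47 ms; P1 amplitude
    of a few tens of microvolts).
    """

    p1_latency_ms: float = 47.0
    p1_amp_uv: float = 40.0
    p1_width_ms: float = 20.0
    n1_latency_ms: float = 90.0
    n1_amp_uv: float = -92.0
    n1_width_ms: float = 22.0
    p2_latency_ms: float = 170.0
    p2_amp_uv: float = 20.0
    p2_width_ms: float = 16.0

    def __post_init__(self) -> None:
        if not (self.p1_latency_ms < self.n1_latency_ms < self.p2_latency_ms):
            raise ValidationError(
                "AEP latencies must be ordered P1 < N1 < P2, got "
                f"{self.p1_latency_ms}, {self.n1_latency_ms}, {self.p2_latency_ms}"
            )
        for name in ("p1_width_ms", "n1_width_ms", "p2_width_ms"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def lobes(self) -> tuple[tuple[float, float, float], ...]:
        return (
            (self.p1_latency_ms, self.p1_amp_uv, self.p1_width_ms),
            (self.n1_latency_ms, self.n1_amp_uv, self.n1_width_ms),
            (self.p2_latency_ms, self.p2_amp_uv, self.p2_width_ms),
        )


@dataclass(frozen=True)
class ShiftEntry:
    """Slow-shift kernel parameters for one (session_day, tone) pair."""

    amp_uv: float  # plateau amplitude A (negative for a negative shift)
    profile: str = "sustained"  # or "reduced"
    onset_ms: float = 300.0
    plateau_ms: float = 600.0
    decay_tau_ms: float = 400.0  # time constant of the "reduced" decay

    def __post_init__(self) -> None:
        if self.profile not in ("sustained", "reduced"):
            raise ValidationError(f"unknown profile {self.profile!r}")
        if not (0 <= self.onset_ms < self.plateau_ms < 1000.0):
            raise ValidationError(
                f"require 0 <= onset ({self.onset_ms}) < plateau "
                f"({self.plateau_ms}) < 1000 ms"
            )
        if self.decay_tau_ms <= 0:
            raise ValidationError("decay_tau_ms must be positive")


@dataclass
class ShiftSchedule:
    """Per (session_day, tone) slow-shift kernels covering all 11 sessions."""

    entries: dict[tuple[str, str], ShiftEntry]
    no_difference_tol_uv: float = 5.0

    def __post_init__(self) -> None:
        expected = {(d, t) for d in SESSION_DAYS for t in ("rewarded", "unrewarded")}
        if set(self.entries) != expected:
            missing = expected - set(self.entries)
            extra = set(self.entries) - expected
            raise ValidationError(
                f"schedule must cover all 22 (session, tone) pairs; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        ind_r = self.entries[("independent", "rewarded")]
        ind_u = self.entries[("independent", "unrewarded")]
        if ind_r != ind_u:
            raise ValidationError("independent-day kernels must be tone-identical")
        cond = {
            d: (
                abs(self.entries[(f"conditioning{d}", "rewarded")].amp_uv),
                abs(self.entries[(f"conditioning{d}", "unrewarded")].amp_uv),
            )
            for d in range(1, 6)
        }
        for d in range(3, 6):
            if cond[d][0] < cond[d][1]:
                raise ValidationError(
                    f"|A(rewarded)| must be >= |A(unrewarded)| from the "
                    f"divergence day on; violated on conditioning day {d}"
                )
        for tone_idx in (0, 1):
            if max(cond[d][tone_idx] for d in range(1, 6)) != cond[4][tone_idx]:
                raise ValidationError("|A| must peak on conditioning day 4")

    def __getitem__(self, key: tuple[str, str]) -> ShiftEntry:
        return self.entries[key]


# Default per-day plateau amplitudes (uV) and profiles. Negative shifts grow
# over conditioning, peak on day 4, diverge between tones from day 3
# ("sustained" rewarded vs "reduced" unrewarded), stay separated on
# extinction day 1 and are equal again from extinction day 2 onward.
_DEFAULT_SHIFTS: dict[str, tuple[tuple[float, str], tuple[float, str]]] = {
    #  session:        (rewarded),          (unrewarded)
    "independent": ((-15.0, "sustained"), (-15.0, "sustained")),
    "conditioning1": ((-25.0, "sustained"), (-25.0, "sustained")),
    "conditioning2": ((-35.0, "sustained"), (-35.0, "sustained")),
    "conditioning3": ((-50.0, "sustained"), (-35.0, "reduced")),
    "conditioning4": ((-60.0, "sustained"), (-38.0, "reduced")),
    "conditioning5": ((-55.0, "sustained"), (-36.0, "reduced")),
    "extinction1": ((-35.0, "sustained"), (-25.0, "reduced")),
    "extinction2": ((-20.0, "reduced"), (-20.0, "reduced")),
    "extinction3": ((-17.0, "reduced"), (-17.0, "reduced")),
    "extinction4": ((-16.0, "reduced"), (-16.0, "reduced")),
    "extinction5": ((-15.0, "reduced"), (-15.0, "reduced")),
}

_DEFAULT_AEP: dict[str, AEPKernelParams] = {
    # P1-N1 peak-to-peak ~132 uV frontal, ~108 parietal, ~78 temporal;
    # temporal P1 ~40 uV — the magnitude regime of epidural rat AEPs.
    "frontal": AEPKernelParams(p1_amp_uv=30.0, n1_amp_uv=-102.0, p2_amp_uv=20.0),
    "parietal": AEPKernelParams(p1_amp_uv=35.0, n1_amp_uv=-73.0, p2_amp_uv=25.0),
    "temporal": AEPKernelParams(p1_amp_uv=40.0, n1_amp_uv=-37.0, p2_amp_uv=20.0),
}


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    The defaults describe the full study conditions: 7 subjects of which the
    last is planted as a high-noise animal (for exclusion-rule testing),
    500 Hz sampling, three channels with a frontal-dominant slow-shift
    scaling, 150 trials per tone per session. ``noise_sd`` is the standard
    deviation of the 1/f background in microvolts; trial-averaged residual
    noise then falls as 1/sqrt(N).
    """

    n_subjects: int = 7
    include_noisy_subject: bool = True
    noisy_subject_factor: float = 10.0
    fs: float = 500.0
    channels: tuple[str, ...] = ("frontal", "parietal", "temporal")
    channel_scales: dict[str, float] = field(
        default_factory=lambda: {"frontal": 1.0, "parietal": 0.6, "temporal": 0.4}
    )
    noise_sd: float = 20.0
    pink_noise_exponent: float = 1.0
    drift_amp_uv: float = 15.0
    drift_period_s: float = 120.0
    artifact_rate_per_min: float = 0.5
    artifact_amp_uv: float = 500.0
    artifact_duration_ms: float = 200.0
    n_trials_per_tone: int = 150
    #: optional (lo, hi) override of the session's inter-trial interval, a
    #: problem-size knob for reduced simulations (the tone schedule itself
    #: carries no signal).
    iti_override: tuple[float, float] | None = None
    subject_scale_sd: float = 0.1
    stim_amp_uv: float = 2000.0
    aep_params: dict[str, AEPKernelParams] = field(
        default_factory=lambda: dict(_DEFAULT_AEP)
    )
    shift_overrides: dict[str, tuple[tuple[float, str], tuple[float, str]]] = field(
        default_factory=dict
    )
    shift_onset_ms: float = 300.0
    shift_plateau_ms: float = 600.0
    shift_decay_tau_ms: float = 400.0
    no_difference_tol_uv: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.artifact_rate_per_min < 0:
            raise ValidationError("artifact_rate_per_min must be >= 0")
        missing = [c for c in self.channels if c not in self.channel_scales]
        if missing:
            raise ValidationError(f"channel_scales missing entries for {missing}")
        missing = [c for c in self.channels if c not in self.aep_params]
        if missing:
            raise ValidationError(f"aep_params missing entries for {missing}")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def null(cls, **kwargs) -> "SimConfig":
        """A configuration in which both tones share identical kernels on
        every session — the generator's null hypothesis for the condition
        factor."""
        overrides = {
            day: ((-20.0, "sustained"), (-20.0, "sustained")) for day in SESSION_DAYS
        }
        kwargs.setdefault("shift_overrides", overrides)
        return cls(**kwargs)

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def noisy_subject_id(self) -> str | None:
        if self.include_noisy_subject and self.n_subjects >= 2:
            return self.subject_ids()[-1]
        return None


def build_effect_schedule(config: SimConfig) -> ShiftSchedule:
    """Construct the 22-entry (session, tone) slow-shift schedule."""
    table = dict(_DEFAULT_SHIFTS)
    table.update(config.shift_overrides)
    entries = {}
    for day in SESSION_DAYS:
        (amp_r, prof_r), (amp_u, prof_u) = table[day]
        for tone, amp, prof in (
            ("rewarded", amp_r, prof_r),
            ("unrewarded", amp_u, prof_u),
        ):
            entries[(day, tone)] = ShiftEntry(
                amp_uv=amp,
                profile=prof,
                onset_ms=config.shift_onset_ms,
                plateau_ms=config.shift_plateau_ms,
                decay_tau_ms=config.shift_decay_tau_ms,
            )
    return ShiftSchedule(entries, no_difference_tol_uv=config.no_difference_tol_uv)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def aep_kernel(params: AEPKernelParams, fs: float) -> np.ndarray:
    """Deterministic AEP waveform over [0, 1000) ms (length ``fs`` samples).

    Superposition of three raised-cosine lobes; zero at t = 0 and wherever no
    lobe has support, so the kernel never leaks into the pre-stimulus
    baseline.
    """
    n = int(round(fs))  # 1000 ms worth of samples
    t_ms = np.arange(n) * 1000.0 / fs
    out = np.zeros(n)
    for latency, amp, width in params.lobes:
        z = (t_ms - latency) / width
        mask = np.abs(z) < 1.0
        out[mask] += amp * np.cos(0.5 * np.pi * z[mask]) ** 2
    return out


def slow_shift_kernel(entry: ShiftEntry, fs: float) -> np.ndarray:
    """Slow negative-shift waveform over [0, 1000) ms.

    Zero before ``onset_ms``; linear ramp to ``amp_uv`` at ``plateau_ms``;
    then either held ("sustained") or decaying as ``A * exp(-dt/tau)``
    ("reduced").
    """
    n = int(round(fs))
    t_ms = np.arange(n) * 1000.0 / fs
    out = np.zeros(n)
    ramp = (t_ms >= entry.onset_ms) & (t_ms < entry.plateau_ms)
    out[ramp] = (
        entry.amp_uv
        * (t_ms[ramp] - entry.onset_ms)
        / (entry.plateau_ms - entry.onset_ms)
    )
    after = t_ms >= entry.plateau_ms
    if entry.profile == "sustained":
        out[after] = entry.amp_uv
    else:
        out[after] = entry.amp_uv * np.exp(
            -(t_ms[after] - entry.plateau_ms) / entry.decay_tau_ms
        )
    return out


def pink_noise(
    n: int, sd: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f^exponent noise of length ``n`` with sample standard deviation ``sd``.

    Generated by shaping white Gaussian noise in the frequency domain; the DC
    bin is zeroed and the trace rescaled to the requested SD, so the output
    is zero-mean by construction.
    """
    if sd == 0 or n == 0:
        return np.zeros(n)
    from scipy.fft import irfft, next_fast_len, rfft

    # Pad to a fast FFT length and truncate; keeps arbitrary session
    # durations away from Bluestein-sized transforms.
    n_fft = next_fast_len(n)
    white = rng.standard_normal(n_fft)
    spec = rfft(white)
    freqs = np.fft.rfftfreq(n_fft)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = irfft(spec * shaping, n_fft)[:n]
    return shaped * (sd / shaped.std())


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

_PAD_START_S = 2.0  # silence before the first tone (room for the baseline window)
_PAD_END_S = 3.0  # silence after the last tone (room for epoch + stimulation)


def _session_seed(config: SimConfig, session_day: str, subject_id: str) -> np.random.SeedSequence:
    subj_idx = config.subject_ids().index(subject_id) if subject_id in config.subject_ids() else abs(hash(subject_id)) % (2**16)
    day_idx = SESSION_DAYS.index(session_day)
    return np.random.SeedSequence([config.rng_seed, day_idx, subj_idx])


def _subject_scale(config: SimConfig, subject_id: str) -> float:
    """Per-subject multiplicative gain on event-locked kernels (stable across
    sessions), emulating inter-animal amplitude variability."""
    if config.subject_scale_sd == 0:
        return 1.0
    subj_idx = (
        config.subject_ids().index(subject_id)
        if subject_id in config.subject_ids()
        else abs(hash(subject_id)) % (2**16)
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 9999, subj_idx]))
    return float(max(0.2, 1.0 + config.subject_scale_sd * rng.standard_normal()))


def simulate_session(
    config: SimConfig,
    session_day: str,
    subject_id: str,
    rng_seed: int | None = None,
) -> tuple[Recording, EventTable, pd.DataFrame]:
    """Simulate one subject-session.

    Returns ``(recording, events, artifact_log)``; the artifact log has
    columns ``onset`` (s), ``duration_s`` and ``amp_uv`` and provides the
    ground truth for artifact-rejection tests. Fully reproducible from
    ``(config, session_day, subject_id)`` (or an explicit ``rng_seed``).
    """
    if session_day not in SESSION_DAYS:
        raise KeyError(f"unknown session_day {session_day!r}")
    meta = SessionMeta.from_label(session_day, config.n_trials_per_tone)
    if rng_seed is not None:
        seed_seq = np.random.SeedSequence([int(rng_seed)])
    else:
        seed_seq = _session_seed(config, session_day, subject_id)
    rng_events, rng_noise, rng_artifacts = [
        np.random.default_rng(s) for s in seed_seq.spawn(3)
    ]
    fs = config.fs

    # --- event schedule: equal-ratio random tone order, uniform ITIs -------
    n_total = 2 * meta.n_trials_per_tone
    tones = np.array(
        ["rewarded"] * meta.n_trials_per_tone + ["unrewarded"] * meta.n_trials_per_tone
    )
    rng_events.shuffle(tones)
    lo, hi = config.iti_override or meta.iti_range_s
    # Gaps are rounded to ms so that on-disk event times (ms precision) are
    # identical to the in-memory ones.
    gaps = np.round(rng_events.uniform(lo, hi, size=n_total), 3)
    onsets = np.round(_PAD_START_S + np.cumsum(gaps) - gaps[0], 3)
    stim = (tones == "rewarded") & (meta.session_kind == "conditioning")
    events = EventTable(
        pd.DataFrame(
            {
                "onset": onsets,
                "tone": tones,
                "session_day": session_day,
                "stim_followed": stim,
            }
        )
    )

    n_samples = int(np.ceil((onsets[-1] + _PAD_END_S) * fs))
    schedule = build_effect_schedule(config)
    subj_scale = _subject_scale(config, subject_id)
    noise_sd = config.noise_sd
    if subject_id == config.noisy_subject_id():
        noise_sd *= config.noisy_subject_factor

    data = np.zeros((len(config.channels), n_samples))
    onset_samples = np.ceil(events.onsets * fs - 1e-9).astype(int)
    kernel_len = int(round(fs))  # 1000 ms

    for ci, channel in enumerate(config.channels):
        kernels = {
            tone: aep_kernel(config.aep_params[channel], fs)
            + config.channel_scales[channel]
            * slow_shift_kernel(schedule[(session_day, tone)], fs)
            for tone in ("rewarded", "unrewarded")
        }
        sig = pink_noise(n_samples, noise_sd, config.pink_noise_exponent, rng_noise)
        if config.drift_amp_uv > 0:
            t = np.arange(n_samples) / fs
            phase = rng_noise.uniform(0, 2 * np.pi)
            sig += config.drift_amp_uv * np.sin(
                2 * np.pi * t / config.drift_period_s + phase
            )
        for s0, tone in zip(onset_samples, tones):
            seg = slice(s0, min(s0 + kernel_len, n_samples))
            sig[seg] += subj_scale * kernels[tone][: seg.stop - seg.start]
        data[ci] = sig

    # --- MFB stimulation artifact: 20 pulses, 10 ms on / 20 ms spacing,
    # starting 1000 ms after each rewarded tone of a conditioning session ---
    if meta.session_kind == "conditioning":
        pulse_len = int(round(0.010 * fs))
        spacing = int(round(0.020 * fs))
        for s0 in onset_samples[stim]:
            burst0 = s0 + kernel_len
            for p in range(20):
                a = burst0 + p * spacing
                b = min(a + pulse_len, n_samples)
                if a >= n_samples:
                    break
                sign = 1.0 if p % 2 == 0 else -1.0
                data[:, a:b] = sign * config.stim_amp_uv  # amplifier saturation

    recording = Recording(
        channels=list(config.channels),
        fs=fs,
        data=data,
        subject_id=subject_id,
        session_id=session_day,
    )
    recording, artifact_log = inject_artifacts(
        recording,
        config.artifact_rate_per_min,
        config.artifact_amp_uv,
        rng_artifacts,
        duration_ms=config.artifact_duration_ms,
    )
    return recording, events, artifact_log


def inject_artifacts(
    recording: Recording,
    rate_per_min: float,
    amp_uv: float,
    rng: np.random.Generator,
    duration_ms: float = 200.0,
) -> tuple[Recording, pd.DataFrame]:
    """Add movement-artifact deflections at Poisson-distributed times.

    Each artifact is a square deflection of random sign, ``duration_ms``
    long and ``amp_uv`` high, applied to all channels (movement moves every
    electrode). Returns the modified recording and a sorted log
    (``onset`` s, ``duration_s``, ``amp_uv``) for ground-truth rejection
    tests.
    """
    log_cols = {"onset": [], "duration_s": [], "amp_uv": []}
    if rate_per_min > 0:
        if amp_uv <= 0:
            raise ValidationError("artifact amp_uv must be positive")
        minutes = recording.duration_s / 60.0
        count = rng.poisson(rate_per_min * minutes)
        times = np.sort(rng.uniform(0, recording.duration_s, size=count))
        dur_s = duration_ms / 1000.0
        n_dur = max(1, int(round(dur_s * recording.fs)))
        data = recording.data.copy()
        for t in times:
            a = int(t * recording.fs)
            b = min(a + n_dur, recording.n_samples)
            sign = rng.choice([-1.0, 1.0])
            data[:, a:b] += sign * amp_uv
            log_cols["onset"].append(a / recording.fs)
            log_cols["duration_s"].append((b - a) / recording.fs)
            log_cols["amp_uv"].append(sign * amp_uv)
        recording = Recording(
            channels=recording.channels,
            fs=recording.fs,
            data=data,
            start_time=recording.start_time,
            subject_id=recording.subject_id,
            session_id=recording.session_id,
        )
    return recording, pd.DataFrame(log_cols)


def trials_hit_by_artifacts(
    events: EventTable,
    artifact_log: pd.DataFrame,
    fs: float,
    window_ms: tuple[float, float] = (-500.0, 1000.0),
) -> set[int]:
    """Indices of events whose epoch window overlaps a logged artifact.

    Overlap is computed on the sample grid, matching how epochs are cut, so
    the returned set is the exact ground truth for peak-to-peak rejection.
    """
    hit: set[int] = set()
    if len(artifact_log) == 0:
        return hit
    onset_samples = np.ceil(events.onsets * fs - 1e-9).astype(int)
    w0 = int(round(window_ms[0] / 1000.0 * fs))
    w1 = int(round(window_ms[1] / 1000.0 * fs))
    art_a = (artifact_log["onset"].to_numpy() * fs).astype(int)
    art_b = art_a + np.maximum(
        1, np.round(artifact_log["duration_s"].to_numpy() * fs).astype(int)
    )
    for i, s0 in enumerate(onset_samples):
        e_a, e_b = s0 + w0, s0 + w1
        if np.any((art_a < e_b) & (art_b > e_a)):
            hit.add(i)
    return hit
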