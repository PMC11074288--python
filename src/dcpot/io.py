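"""Reading and writing of continuous DC-EEG recordings and stimulus event tables.

Recordings are continuous multichannel signals in microvolts sampled at a
fixed rate (500 Hz by default, matching a DC-coupled acquisition chain).
Two on-disk containers are supported:

* ``.h5`` — an HDF5 layout (float64, lossless) used by the pipeline;
* ``.edf`` — 16-bit European Data Format for interoperability with standard
  EEG viewers. EDF quantizes amplitudes; the writer guarantees a step of at
  most 0.1 uV and refuses signals whose dynamic range would exceed that.

Event tables are BIDS-style tab-separated files with columns
``onset`` (seconds from recording start, ms precision), ``tone``
(``rewarded`` / ``unrewarded``), ``session_day`` and ``stim_followed``.

Time convention: seconds from recording start; tone onset defines t = 0 for
all epoch-relative quantities, and every epoch window is half-open in
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Recording",
    "EventTable",
    "SessionMeta",
    "ValidationError",
    "SESSION_DAYS",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "load_yaml_config",
    "save_yaml_config",
]


class ValidationError(ValueError):
    """An input object violates one of its declared invariants."""


#: The 11-session schedule: one independent baseline day, five daily
#: conditioning sessions, five daily extinction sessions.
SESSION_DAYS: tuple[str, ...] = (
    "independent",
    *(f"conditioning{d}" for d in range(1, 6)),
    *(f"extinction{d}" for d in range(1, 6)),
)

_TONES = ("rewarded", "unrewarded")


@dataclass
class Recording:
    """Continuous multichannel signal in microvolts.

    Parameters
    ----------
    channels
        Channel labels (typically ``frontal``, ``parietal``, ``temporal``).
    fs
        Sampling rate in Hz (> 0; 500 by default).
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    start_time
        Recording start in seconds (an offset only; events are expressed
        relative to it).
    subject_id, session_id
        Identifiers propagated into every derived table.
    """

    channels: list[str]
    fs: float
    data: np.ndarray
    start_time: float = 0.0
    subject_id: str = "unknown"
    session_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = list(self.channels)
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValidationError(
                "data must be 2-D (n_channels, n_samples); for ragged channel "
                "lists all channels must have equal length"
            )
        if self.data.shape[0] != len(self.channels):
            raise ValidationError(
                f"{len(self.channels)} channel labels but data has "
                f"{self.data.shape[0]} rows"
            )
        for label, row in zip(self.channels, self.data):
            if not np.all(np.isfinite(row)):
                raise ValidationError(
                    f"channel {label!r} contains non-finite amplitudes"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"no channel {label!r}; available: {self.channels}"
            ) from None
        return self.data[idx]

    @classmethod
    def from_channel_dict(
        cls, signals: dict[str, Sequence[float]], fs: float, **kwargs
    ) -> "Recording":
        labels = list(signals)
        lengths = {label: len(np.asarray(signals[label])) for label in labels}
        if len(set(lengths.values())) > 1:
            raise ValidationError(f"channels have unequal lengths: {lengths}")
        data = np.vstack([np.asarray(signals[label], dtype=float) for label in labels])
        return cls(channels=labels, fs=fs, data=data, **kwargs)


@dataclass
class EventTable:
    """Timestamped tone onsets with identity and session metadata.

    Wraps a DataFrame with columns ``onset`` (s), ``tone``, ``session_day``
    and ``stim_followed``. Onsets are strictly increasing; ``stim_followed``
    may be true only for rewarded tones in conditioning sessions (the reward
    stimulation is delivered 1000 ms after the rewarded tone).
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("onset", "tone", "session_day", "stim_followed")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"event table missing columns: {missing}")
        df = self.df.reset_index(drop=True).copy()
        df["onset"] = df["onset"].astype(float)
        df["stim_followed"] = df["stim_followed"].astype(bool)
        onsets = df["onset"].to_numpy()
        if len(onsets) and np.any(np.diff(onsets) <= 0):
            raise ValidationError("event onsets must be strictly increasing")
        bad_tone = set(df["tone"].unique()) - set(_TONES)
        if bad_tone:
            raise ValidationError(f"unknown tone labels: {sorted(bad_tone)}")
        bad_day = set(df["session_day"].unique()) - set(SESSION_DAYS)
        if bad_day:
            raise ValidationError(f"unknown session_day labels: {sorted(bad_day)}")
        stim_rows = df[df["stim_followed"]]
        if len(stim_rows):
            ok = (stim_rows["tone"] == "rewarded") & stim_rows[
                "session_day"
            ].str.startswith("conditioning")
            if not ok.all():
                raise ValidationError(
                    "stim_followed may be true only for rewarded tones in "
                    "conditioning sessions"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def onsets(self) -> np.ndarray:
        return self.df["onset"].to_numpy()

    def check_within(self, recording: Recording) -> None:
        """Raise unless every onset lies within the recording's span."""
        if len(self) == 0:
            return
        if self.onsets[0] < 0 or self.onsets[-1] > recording.duration_s:
            raise ValidationError(
                "event onsets extend beyond the recording's time span "
                f"([0, {recording.duration_s:.3f}] s)"
            )


@dataclass
class SessionMeta:
    """Stimulus-schedule parameters of one session.

    Conditioning and independent sessions use a mean inter-trial interval of
    12 s (range 10–14 s); extinction sessions use a mean of 4 s. Each tone is
    presented ``n_trials_per_tone`` times (150 in a full 1-h session).
    """

    session_kind: str
    day_index: int = 0
    n_trials_per_tone: int = 150
    iti_mean_s: float = 12.0
    iti_range_s: tuple[float, float] = (10.0, 14.0)

    def __post_init__(self) -> None:
        if self.session_kind not in ("independent", "conditioning", "extinction"):
            raise ValidationError(f"unknown session_kind {self.session_kind!r}")
        lo, hi = self.iti_range_s
        if not (0 < lo <= self.iti_mean_s <= hi):
            raise ValidationError(
                f"iti_mean_s {self.iti_mean_s} outside iti_range_s {self.iti_range_s}"
            )

    @classmethod
    def from_label(
        cls, session_day: str, n_trials_per_tone: int = 150
    ) -> "SessionMeta":
        if session_day not in SESSION_DAYS:
            raise KeyError(f"unknown session_day {session_day!r}")
        if session_day == "independent":
            return cls("independent", 0, n_trials_per_tone, 12.0, (10.0, 14.0))
        kind = "conditioning" if session_day.startswith("conditioning") else "extinction"
        day = int(session_day[-1])
        if kind == "conditioning":
            return cls(kind, day, n_trials_per_tone, 12.0, (10.0, 14.0))
        # Extinction: mean 4 s; the range is symmetric about the mean, in
        # line with the conditioning range of mean +/- 2 s.
        return cls(kind, day, n_trials_per_tone, 4.0, (2.0, 6.0))


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording to ``path`` (.h5 lossless, or .edf 16-bit).

    EDF preserves amplitudes to a quantization step of at most 0.1 uV and
    channel labels / sampling rate exactly; HDF5 is bit-exact.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_h5(recording, path)
    elif path.suffix == ".edf":
        _write_edf(recording, path)
    else:
        raise ValueError(f"unsupported recording container {path.suffix!r}")
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording` (or any EDF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_h5(path)
    if path.suffix == ".edf":
        return _read_edf(path)
    raise ValueError(f"unrecognized recording format {path.suffix!r}")


def _write_h5(recording: Recording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = float(recording.fs)
        f.attrs["start_time"] = float(recording.start_time)
        f.attrs["subject_id"] = recording.subject_id
        f.attrs["session_id"] = recording.session_id
        f.attrs["units"] = "uV"
        f.attrs["channels"] = [c for c in recording.channels]
        f.create_dataset("data", data=recording.data, compression="gzip", shuffle=True)


def _read_h5(path: Path) -> Recording:
    try:
        with h5py.File(path, "r") as f:
            return Recording(
                channels=[
                    c.decode() if isinstance(c, bytes) else str(c)
                    for c in f.attrs["channels"]
                ],
                fs=float(f.attrs["fs"]),
                data=f["data"][()],
                start_time=float(f.attrs.get("start_time", 0.0)),
                subject_id=str(f.attrs.get("subject_id", "unknown")),
                session_id=str(f.attrs.get("session_id", "unknown")),
            )
    except OSError as exc:
        raise IOError(f"cannot parse {path} as an HDF5 recording: {exc}") from exc


def _ascii(value: str, width: int) -> bytes:
    out = value.encode("ascii", "replace")[:width]
    return out.ljust(width)


def _write_edf(recording: Recording, path: Path) -> None:
    """Minimal EDF writer (single data record holding the whole signal)."""
    n_sig = len(recording.channels)
    n_samp = recording.n_samples
    phys_min, phys_max, digital = [], [], []
    for label, row in zip(recording.channels, recording.data):
        lo = float(np.floor(row.min())) - 1.0
        hi = float(np.ceil(row.max())) + 1.0
        if hi - lo > 0.1 * (_EDF_DIG_MAX - _EDF_DIG_MIN):
            raise ValidationError(
                f"channel {label!r} spans {hi - lo:.0f} uV; EDF 16-bit cannot "
                "preserve 0.1 uV resolution over that range — use .h5"
            )
        scale = (hi - lo) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
        dig = np.round((row - lo) / scale + _EDF_DIG_MIN).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)
        digital.append(dig)

    header_bytes = 256 + 256 * n_sig
    record_duration = n_samp / recording.fs
    with open(path, "wb") as f:
        f.write(_ascii("0", 8))
        f.write(_ascii(f"{recording.subject_id} X X X", 80))
        f.write(_ascii(f"Startdate X {recording.session_id} X X", 80))
        f.write(_ascii("01.01.00", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(str(header_bytes), 8))
        f.write(_ascii("", 44))
        f.write(_ascii("1", 8))  # one data record
        f.write(_ascii(f"{record_duration:.6g}", 8))
        f.write(_ascii(str(n_sig), 4))
        for label in recording.channels:
            f.write(_ascii(label, 16))
        for _ in range(n_sig):
            f.write(_ascii("", 80))  # transducer
        for _ in range(n_sig):
            f.write(_ascii("uV", 8))
        for lo in phys_min:
            f.write(_ascii(f"{lo:.6g}", 8))
        for hi in phys_max:
            f.write(_ascii(f"{hi:.6g}", 8))
        for _ in range(n_sig):
            f.write(_ascii(str(_EDF_DIG_MIN), 8))
        for _ in range(n_sig):
            f.write(_ascii(str(_EDF_DIG_MAX), 8))
        for _ in range(n_sig):
            f.write(_ascii("", 80))  # prefiltering
        for _ in range(n_sig):
            f.write(_ascii(str(n_samp), 8))
        for _ in range(n_sig):
            f.write(_ascii("", 32))
        for dig in digital:
            f.write(dig.tobytes())


def _read_edf(path: Path) -> Recording:
    """Read an EDF file directly (validated against MNE's reader in tests)."""
    raw = path.read_bytes()
    if len(raw) < 256:
        raise IOError(f"{path}: truncated EDF header")
    try:
        header_bytes = int(raw[184:192].decode().strip())
        n_records = int(raw[236:244].decode().strip())
        record_duration = float(raw[244:252].decode().strip())
        n_sig = int(raw[252:256].decode().strip())
    except ValueError as exc:
        raise IOError(f"{path}: malformed EDF header: {exc}") from exc
    if len(raw) < header_bytes:
        raise IOError(f"{path}: truncated EDF header")
    patient = raw[8:88].decode("ascii", "replace").strip()
    rec_field = raw[88:168].decode("ascii", "replace").split()
    subject_id = patient.split()[0] if patient else "unknown"
    session_id = rec_field[2] if len(rec_field) > 2 else "unknown"

    # Offsets per EDF layout: label 16, transducer 80, phys dim 8, then the
    # numeric fields (8 each), prefilter 80, samples-per-record 8.
    off_label = 256
    off_dim = off_label + 16 * n_sig + 80 * n_sig
    off_pmin = off_dim + 8 * n_sig
    off_pmax = off_pmin + 8 * n_sig
    off_dmin = off_pmax + 8 * n_sig
    off_dmax = off_dmin + 8 * n_sig
    off_prefilter = off_dmax + 8 * n_sig
    off_nsamp = off_prefilter + 80 * n_sig

    def slot(off: int, i: int, width: int) -> str:
        return raw[off + i * width : off + (i + 1) * width].decode().strip()

    labels = [slot(off_label, i, 16) for i in range(n_sig)]
    phys_min = [float(slot(off_pmin, i, 8)) for i in range(n_sig)]
    phys_max = [float(slot(off_pmax, i, 8)) for i in range(n_sig)]
    dig_min = [int(slot(off_dmin, i, 8)) for i in range(n_sig)]
    dig_max = [int(slot(off_dmax, i, 8)) for i in range(n_sig)]
    nsamp = [int(slot(off_nsamp, i, 8)) for i in range(n_sig)]

    record_len = sum(nsamp)
    expected = header_bytes + 2 * record_len * n_records
    if len(raw) < expected:
        raise IOError(
            f"{path}: truncated EDF data ({len(raw)} bytes, expected {expected})"
        )
    body = np.frombuffer(raw[header_bytes:expected], dtype="<i2")
    chans = [np.empty(nsamp[i] * n_records) for i in range(n_sig)]
    pos = 0
    for rec in range(n_records):
        for i in range(n_sig):
            seg = body[pos : pos + nsamp[i]].astype(float)
            scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
            chans[i][rec * nsamp[i] : (rec + 1) * nsamp[i]] = (
                (seg - dig_min[i]) * scale + phys_min[i]
            )
            pos += nsamp[i]
    fs = nsamp[0] / record_duration
    return Recording(
        channels=labels,
        fs=fs,
        data=np.vstack(chans),
        subject_id=subject_id,
        session_id=session_id,
    )


# ---------------------------------------------------------------------------
# Event-table I/O
# ---------------------------------------------------------------------------

def write_events(events: EventTable, path: str | Path) -> Path:
    """Write an event table as a BIDS-style TSV (onsets at ms precision)."""
    path = Path(path)
    df = events.df.copy()
    df["onset"] = df["onset"].map(lambda x: f"{x:.3f}")
    df["stim_followed"] = df["stim_followed"].map(lambda b: "true" if b else "false")
    df.to_csv(path, sep="\t", index=False, columns=list(EventTable.REQUIRED))
    return path


def read_events(path: str | Path) -> EventTable:
    """Read an event TSV, returning rows sorted by onset regardless of file order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise IOError(f"{path}: empty or unparseable event file") from exc
    missing = [c for c in EventTable.REQUIRED if c not in df.columns]
    if missing:
        raise IOError(f"{path}: missing event columns {missing}")
    if df["stim_followed"].dtype == object:
        df["stim_followed"] = (
            df["stim_followed"].astype(str).str.lower().isin(("true", "1", "yes"))
        )
    df = df.sort_values("onset", kind="stable")
    return EventTable(df)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_yaml_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg or {}


def save_yaml_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
    return path
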