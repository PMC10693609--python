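"""Recording, montage and interval handling.

Covers the acquisition-side conventions of the analysis: signals are
held in microvolts at a known sampling rate, referential contacts are
re-referenced to bipolar channels (anode minus cathode), recordings
acquired at 4000 Hz are decimated to 2000 Hz behind an anti-alias
filter, and only five-minute interictal intervals lying at least three
hours from any seizure are analysed (at most six intervals per night).

Signals travel as EDF files (16-bit, physical units microvolts).  The
writer here emits minimal EDF+-free EDF directly; reading goes through
:mod:`mne`, so a round trip exercises two independent code paths.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Recording",
    "Montage",
    "Interval",
    "IntervalSet",
    "read_recording",
    "write_recording",
    "to_bipolar",
    "downsample",
    "select_intervals",
    "restrict_mesial",
]


@dataclass
class Recording:
    """Multichannel iEEG signal block.

    data : (n_channels, n_samples) array in microvolts
    fs : sampling rate in Hz
    labels : unique channel names
    coords : optional (n_channels, 3) contact coordinates in mm
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (len(self.labels), 3):
                raise ValueError("coords must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


@dataclass
class Montage:
    """Bipolar montage: ordered (anode, cathode) label pairs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate montage pairs")

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.pairs]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"pairs": [list(p) for p in self.pairs]}))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        obj = json.loads(Path(path).read_text())
        return cls([tuple(p) for p in obj["pairs"]])


@dataclass(frozen=True)
class Interval:
    """Half-open analysis window [start_s, start_s + duration_s)."""

    night: int
    start_s: float
    duration_s: float
    sleep_stage: str = "N3"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("interval duration must be positive")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class IntervalSet:
    intervals: list[Interval] = field(default_factory=list)
    seizure_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_night: dict[int, list[Interval]] = {}
        for iv in self.intervals:
            by_night.setdefault(iv.night, []).append(iv)
        for night, ivs in by_night.items():
            ivs = sorted(ivs, key=lambda i: i.start_s)
            for a, b in zip(ivs, ivs[1:]):
                if b.start_s < a.end_s:
                    raise ValueError(f"overlapping intervals in night {night}")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_minutes(self) -> float:
        return sum(iv.duration_s for iv in self.intervals) / 60.0

    def to_json(self, path: str | Path) -> None:
        obj = {
            "intervals": [
                [iv.night, iv.start_s, iv.duration_s, iv.sleep_stage] for iv in self.intervals
            ],
            "seizure_times": list(self.seizure_times),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "IntervalSet":
        obj = json.loads(Path(path).read_text())
        return cls(
            [Interval(int(n), float(s), float(d), str(st)) for n, s, d, st in obj["intervals"]],
            [float(t) for t in obj["seizure_times"]],
        )


# ---------------------------------------------------------------------------
# EDF I/O


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with physical units in microvolts.

    Uses one-second data records, so the recording length must be an
    integer number of seconds at an integer sampling rate.
    """
    if rec.n_channels == 0:
        raise ValueError("cannot write a recording with no channels")
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise ValueError("EDF export requires an integer number of seconds of data")
    n_records = rec.n_samples // fs
    ns = rec.n_channels

    # Per-channel physical scaling to the full 16-bit range.
    dig_min, dig_max = -32767, 32767
    phys_min = np.floor(rec.data.min(axis=1))
    phys_max = np.ceil(rec.data.max(axis=1))
    flat = phys_max <= phys_min
    phys_max[flat] = phys_min[flat] + 1.0

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    fields = [
        [_pad(lbl, 16) for lbl in rec.labels],
        [_pad("iEEG", 80)] * ns,
        [_pad("uV", 8)] * ns,
        [_pad(f"{v:g}"[:8], 8) for v in phys_min],
        [_pad(f"{v:g}"[:8], 8) for v in phys_max],
        [_pad(str(dig_min), 8)] * ns,
        [_pad(str(dig_max), 8)] * ns,
        [_pad("", 80)] * ns,
        [_pad(str(fs), 8)] * ns,
        [_pad("", 32)] * ns,
    ]
    header += b"".join(b"".join(col) for col in fields)

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((rec.data - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def read_recording(path: str | Path) -> Recording:
    """Read an EDF recording into microvolts via mne."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels in EDF file")
    data_uv = raw.get_data() * 1e6  # mne stores volts
    return Recording(data=data_uv, fs=float(raw.info["sfreq"]), labels=labels)


# ---------------------------------------------------------------------------
# Montage / resampling / interval selection


def to_bipolar(rec: Recording, montage: Montage) -> Recording:
    """Re-reference to bipolar channels: each output is anode - cathode."""
    missing = {l for pair in montage.pairs for l in pair} - set(rec.labels)
    if missing:
        raise ValueError(f"montage labels not in recording: {sorted(missing)}")
    idx = {l: i for i, l in enumerate(rec.labels)}
    data = np.stack([rec.data[idx[a]] - rec.data[idx[c]] for a, c in montage.pairs])
    coords = None
    if rec.coords is not None:
        # bipolar contact located midway between the two referential contacts
        coords = np.stack(
            [(rec.coords[idx[a]] + rec.coords[idx[c]]) / 2.0 for a, c in montage.pairs]
        )
    return Recording(data=data, fs=rec.fs, labels=montage.labels, coords=coords)


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Decimate to ``target_fs`` behind a zero-phase anti-alias low-pass.

    The low-pass cuts at 0.8 x the new Nyquist frequency; the decimation
    factor must be an integer (e.g. 4000 Hz -> 2000 Hz).
    """
    from scipy import signal

    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    q = rec.fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"decimation factor {q} is not an integer")
    q = int(round(q))
    if q == 1:
        return Recording(rec.data.copy(), rec.fs, list(rec.labels), rec.coords)
    new_nyq = target_fs / 2.0
    cutoff = 0.8 * new_nyq
    width = 2 * (new_nyq - cutoff) / rec.fs  # normalised transition width
    numtaps, beta = signal.kaiserord(80.0, width)
    numtaps |= 1  # odd length, symmetric
    taps = signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=rec.fs)
    filtered = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    return Recording(filtered[:, ::q], target_fs, list(rec.labels), rec.coords)


def select_intervals(
    ivs: IntervalSet,
    min_gap_to_seizure_s: float = 10800.0,
    max_per_night: int = 6,
    interval_len_s: float = 300.0,
) -> IntervalSet:
    """Keep analysable interictal intervals.

    An interval survives when it lasts exactly ``interval_len_s`` and every
    sample of it lies at least ``min_gap_to_seizure_s`` (three hours by
    default) from every seizure.  At most ``max_per_night`` intervals are
    retained per night, earliest first.
    """
    kept: list[Interval] = []
    per_night: dict[int, int] = {}
    for iv in sorted(ivs.intervals, key=lambda i: (i.night, i.start_s)):
        if abs(iv.duration_s - interval_len_s) > 1e-9:
            continue
        if any(
            not (t <= iv.start_s - min_gap_to_seizure_s or t >= iv.end_s + min_gap_to_seizure_s)
            for t in ivs.seizure_times
        ):
            continue
        if per_night.get(iv.night, 0) >= max_per_night:
            continue
        per_night[iv.night] = per_night.get(iv.night, 0) + 1
        kept.append(iv)
    return IntervalSet(kept, list(ivs.seizure_times))


def restrict_mesial(
    channels: Sequence[str],
    electrode_metadata: Mapping[str, Mapping],
    k: int = 3,
) -> list[str]:
    """Keep only the ``k`` most mesial bipolar channels of each mesial-temporal depth.

    ``electrode_metadata`` maps electrode name to a dict with keys
    ``mesial_temporal`` (bool) and, when flagged, ``order`` — that
    electrode's bipolar channel labels sorted mesial to lateral.
    Channels not belonging to a flagged electrode pass through unchanged.
    """
    keep: set[str] = set(channels)
    for name, meta in electrode_metadata.items():
        if not meta.get("mesial_temporal", False):
            continue
        if "order" not in meta:
            raise ValueError(f"mesial-temporal electrode {name!r} lacks mesial-to-lateral order")
        order = [ch for ch in meta["order"] if ch in keep]
        for ch in order[k:]:
            keep.discard(ch)
    return [ch for ch in channels if ch in keep]
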