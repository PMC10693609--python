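"""Interictal spike markers: peak alignment, reviewer consensus, spike+HFO pairing.

Spikes are marked visually (an isolated triangular wave clearly distinct
from the background) by two reviewers and realigned automatically to the
local broadband peak.  A spike+HFO event is an HFO whose interval
intersects a +/-50 ms window around a spike peak on the same channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_io import Recording
from .events import EventMarker

__all__ = [
    "SpikeMarker",
    "read_spike_markers",
    "align_spike_peak",
    "align_spikes",
    "merge_reviewers",
    "spike_hfo_cooccurrence",
]


@dataclass(frozen=True)
class SpikeMarker:
    """A raw (cursor-placed) spike mark before peak alignment."""

    channel: str
    latency_s: float
    reviewer: str | None = None


def read_spike_markers(path: str | Path) -> list[SpikeMarker]:
    df = pd.read_csv(path)
    reviewers = df["reviewer"] if "reviewer" in df else [None] * len(df)
    return [
        SpikeMarker(str(c), float(t), None if pd.isna(r) else str(r))
        for c, t, r in zip(df["channel"], df["latency_s"], reviewers)
    ]


def align_spike_peak(
    rec: Recording,
    marker: SpikeMarker,
    search_window_ms: float = 50.0,
    spike_half_duration_ms: float = 35.0,
) -> EventMarker:
    """Snap a cursor mark to the spike peak.

    The peak is the maximum absolute broadband amplitude within
    +/-``search_window_ms`` of the mark; onset and offset are placed half a
    spike duration either side of it.  A flat window (no unique maximum
    above the surroundings) keeps the marked latency.  Windows truncated
    by the recording edge are searched over their valid part.
    """
    if marker.channel not in rec.labels:
        raise ValueError(f"marker channel {marker.channel!r} not in recording")
    if not (0.0 <= marker.latency_s <= rec.duration_s):
        raise ValueError(f"marker at {marker.latency_s} s outside recording")
    x = rec.channel(marker.channel)
    half = int(round(search_window_ms / 1000.0 * rec.fs))
    center = int(round(marker.latency_s * rec.fs))
    lo = max(0, center - half)
    hi = min(rec.n_samples, center + half + 1)
    seg = np.abs(x[lo:hi])
    if seg.size == 0 or np.ptp(seg) == 0.0:
        peak_s = marker.latency_s  # degenerate: flat signal, keep the mark
    else:
        peak_s = (lo + int(np.argmax(seg))) / rec.fs
    half_dur = spike_half_duration_ms / 1000.0
    return EventMarker(
        channel=marker.channel,
        kind="spike",
        onset_s=peak_s - half_dur,
        peak_s=peak_s,
        offset_s=peak_s + half_dur,
    )


def align_spikes(
    rec: Recording,
    markers: Iterable[SpikeMarker],
    search_window_ms: float = 50.0,
    spike_half_duration_ms: float = 35.0,
) -> list[EventMarker]:
    return [
        align_spike_peak(rec, m, search_window_ms, spike_half_duration_ms) for m in markers
    ]


def merge_reviewers(
    markers_a: Sequence[EventMarker],
    markers_b: Sequence[EventMarker],
    tol_ms: float = 100.0,
    consensus_accepted: Sequence[EventMarker] = (),
) -> list[EventMarker]:
    """Fuse two reviewers' peak-aligned spike lists into a consensus list.

    Marks from the two reviewers on the same channel whose peaks lie
    within ``tol_ms`` merge into one spike at the mean latency (matched
    greedily by smallest latency difference).  Unmatched marks survive
    only when listed in ``consensus_accepted`` — the marks both reviewers
    agreed to keep when resolving conflicts.
    """
    tol_s = tol_ms / 1000.0
    a = list(markers_a)
    b = list(markers_b)
    candidates = [
        (abs(ma.peak_s - mb.peak_s), i, j)
        for i, ma in enumerate(a)
        for j, mb in enumerate(b)
        if ma.channel == mb.channel and abs(ma.peak_s - mb.peak_s) <= tol_s
    ]
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    consensus: list[EventMarker] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        ma, mb = a[i], b[j]
        peak = (ma.peak_s + mb.peak_s) / 2.0
        half = (ma.offset_s - ma.onset_s) / 2.0
        consensus.append(
            EventMarker(ma.channel, "spike", peak - half, peak, peak + half)
        )
    accepted = set(consensus_accepted)
    for i, ma in enumerate(a):
        if i not in used_a and ma in accepted:
            consensus.append(ma)
    for j, mb in enumerate(b):
        if j not in used_b and mb in accepted:
            consensus.append(mb)
    return sorted(consensus, key=lambda e: (e.channel, e.peak_s))


def spike_hfo_cooccurrence(
    spikes: Sequence[EventMarker],
    hfos: Sequence[EventMarker],
    window_ms: float = 50.0,
) -> list[EventMarker]:
    """Form spike+HFO events: an HFO within +/-``window_ms`` of a spike peak.

    An HFO qualifies when its interval intersects the window around the
    spike peak on the same channel.  Each HFO pairs with at most one
    spike (the one with the nearest peak) and each spike contributes at
    most one event, so the count never exceeds either constituent count.
    The event interval spans both constituents.
    """
    w = window_ms / 1000.0
    candidates: list[tuple[float, int, int]] = []
    for i, sp in enumerate(spikes):
        if sp.kind != "spike":
            raise ValueError("first argument must contain spike markers")
        for j, h in enumerate(hfos):
            if h.channel != sp.channel:
                continue
            if h.onset_s <= sp.peak_s + w and h.offset_s >= sp.peak_s - w:
                candidates.append((abs(h.peak_s - sp.peak_s), i, j))
    candidates.sort()
    used_spikes: set[int] = set()
    used_hfos: set[int] = set()
    out: list[EventMarker] = []
    for _, i, j in candidates:
        if i in used_spikes or j in used_hfos:
            continue
        used_spikes.add(i)
        used_hfos.add(j)
        sp, h = spikes[i], hfos[j]
        out.append(
            EventMarker(
                channel=sp.channel,
                kind="spike+HFO",
                onset_s=min(sp.onset_s, h.onset_s),
                peak_s=sp.peak_s,
                offset_s=max(sp.offset_s, h.offset_s),
            )
        )
    return sorted(out, key=lambda e: (e.channel, e.onset_s))
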