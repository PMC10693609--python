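"""Event markers shared by every stage of the pipeline.

An :class:`EventMarker` records one interictal event on one bipolar
channel: an epileptic spike, a ripple (80-240 Hz oscillation), a fast
ripple (FR, 250-490 Hz), an HFO (a ripple co-occurring with a fast
ripple on the same channel) or a spike+HFO (an HFO within +/-50 ms of a
spike peak).  Times are seconds from recording start; intervals are
half-open conceptually but stored as inclusive onset/offset endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Recognised event kinds.
KINDS = ("spike", "ripple", "FR", "HFO", "spike+HFO")


@dataclass(frozen=True)
class EventMarker:
    """One detected or planted event on a bipolar channel."""

    channel: str
    kind: str
    onset_s: float
    peak_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {KINDS}")
        if not (self.onset_s <= self.peak_s <= self.offset_s):
            raise ValueError(
                f"event times must satisfy onset <= peak <= offset, got "
                f"({self.onset_s}, {self.peak_s}, {self.offset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlaps(self, other: "EventMarker") -> bool:
        """True when the two event intervals intersect (closed intervals)."""
        return self.onset_s <= other.offset_s and other.onset_s <= self.offset_s


def events_to_frame(events: Iterable[EventMarker]) -> pd.DataFrame:
    """Tabulate events with one row per marker (channel, kind, onset/peak/offset)."""
    rows = [
        (e.channel, e.kind, e.onset_s, e.peak_s, e.offset_s) for e in events
    ]
    return pd.DataFrame(rows, columns=["channel", "kind", "onset_s", "peak_s", "offset_s"])


def frame_to_events(df: pd.DataFrame) -> list[EventMarker]:
    return [
        EventMarker(str(r.channel), str(r.kind), float(r.onset_s), float(r.peak_s), float(r.offset_s))
        for r in df.itertuples(index=False)
    ]


def write_events_csv(events: Sequence[EventMarker], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[EventMarker]:
    return frame_to_events(pd.read_csv(path))
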