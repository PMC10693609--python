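"""Per-channel event rates and 95th-percentile biomarker areas.

A biomarker area (Spike, HFO or Spike+HFO area) is the ensemble of
bipolar channels whose pooled event rate exceeds the 95th percentile of
the rate distribution over the whole montage.  Because the threshold is
a percentile of the *rates*, not a fixed channel fraction, the area size
varies with the shape of the distribution tail.  An optional temporal
consistency filter keeps only channels whose rate is high in a minimum
fraction of analysis intervals, guarding the HFO area against transient
artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import IntervalSet
from .events import EventMarker

__all__ = [
    "RateTable",
    "BiomarkerArea",
    "compute_rates",
    "threshold_area",
    "temporal_consistency_filter",
    "compare_area_sizes",
]


@dataclass
class RateTable:
    """Event rates in events/minute per (channel, biomarker, interval).

    ``table`` has columns channel, biomarker, interval, rate, duration_min
    with one row for every montage channel x biomarker x interval (zeros
    included), so spatial percentiles see the whole montage.
    """

    table: pd.DataFrame
    channels: list[str]

    def pooled(self, biomarker: str) -> pd.Series:
        """Pooled rate per channel: total events / total minutes.

        Equals the duration-weighted mean of the interval rates.
        """
        sub = self.table[self.table["biomarker"] == biomarker]
        if sub.empty:
            return pd.Series(0.0, index=self.channels, name=biomarker)
        grouped = sub.groupby("channel", sort=False)
        counts = grouped.apply(
            lambda g: float((g["rate"] * g["duration_min"]).sum()), include_groups=False
        )
        minutes = grouped["duration_min"].sum()
        pooled = (counts / minutes).reindex(self.channels).fillna(0.0)
        pooled.name = biomarker
        return pooled

    def per_interval(self, biomarker: str) -> pd.DataFrame:
        """Channels x intervals matrix of rates for one biomarker."""
        sub = self.table[self.table["biomarker"] == biomarker]
        mat = sub.pivot_table(index="channel", columns="interval", values="rate", fill_value=0.0)
        return mat.reindex(self.channels).fillna(0.0)

    @property
    def biomarkers(self) -> list[str]:
        return sorted(self.table["biomarker"].unique())


@dataclass
class BiomarkerArea:
    """Channels whose pooled rate exceeds the spatial percentile threshold."""

    biomarker: str
    channels: set[str] = field(default_factory=set)
    threshold: float = float("nan")
    defined: bool = True

    def __post_init__(self) -> None:
        if not self.defined and self.channels:
            raise ValueError("an undefined area must have no channels")


def compute_rates(
    events: Sequence[EventMarker],
    intervals: IntervalSet,
    channels: Sequence[str],
) -> RateTable:
    """Count events per channel, biomarker and interval and convert to events/min.

    Events are assigned to the interval containing their peak; an event
    whose peak falls inside no interval is rejected.
    """
    if not intervals.intervals:
        raise ValueError("no analysis intervals")
    channels = list(channels)
    chan_set = set(channels)
    kinds = sorted({e.kind for e in events})
    counts: dict[tuple[str, str, int], int] = {}
    for e in events:
        if e.channel not in chan_set:
            raise ValueError(f"event on channel {e.channel!r} outside the montage")
        for idx, iv in enumerate(intervals.intervals):
            if iv.contains(e.peak_s):
                counts[(e.channel, e.kind, idx)] = counts.get((e.channel, e.kind, idx), 0) + 1
                break
        else:
            raise ValueError(
                f"event at {e.peak_s:.3f} s on {e.channel} lies outside every interval"
            )
    rows = []
    for kind in kinds:
        for ch in channels:
            for idx, iv in enumerate(intervals.intervals):
                minutes = iv.duration_s / 60.0
                n = counts.get((ch, kind, idx), 0)
                rows.append((ch, kind, idx, n / minutes, minutes))
    table = pd.DataFrame(
        rows, columns=["channel", "biomarker", "interval", "rate", "duration_min"]
    )
    return RateTable(table=table, channels=channels)


def _percentile_threshold(rates: np.ndarray, percentile: float) -> float:
    # linear interpolation between order statistics (numpy default)
    return float(np.percentile(rates, percentile, method="linear"))


def threshold_area(
    rt: RateTable,
    biomarker: str,
    percentile: float = 95.0,
) -> BiomarkerArea:
    """Channels strictly exceeding the spatial rate percentile.

    When the biomarker produced no events at all the area cannot be
    defined (as for a patient without co-occurring spikes and HFOs) and
    is returned with ``defined=False`` and no channels.
    """
    if len(rt.channels) < 2:
        raise ValueError("area definition needs at least 2 montage channels")
    pooled = rt.pooled(biomarker)
    if float(pooled.sum()) == 0.0:
        return BiomarkerArea(biomarker=biomarker, channels=set(), defined=False)
    thr = _percentile_threshold(pooled.to_numpy(), percentile)
    members = {ch for ch, r in pooled.items() if r > thr}
    return BiomarkerArea(biomarker=biomarker, channels=members, threshold=thr)


def temporal_consistency_filter(
    rt: RateTable,
    biomarker: str,
    min_fraction: float = 0.5,
    percentile: float = 95.0,
) -> set[str]:
    """Channels whose rate beats the per-interval percentile often enough.

    A channel survives when its rate exceeds the spatial percentile
    threshold of its own interval in at least ``min_fraction`` of the
    intervals.  Intersect the result with :func:`threshold_area` to
    impose temporal consistency on an area (applied to the HFO area by
    default in the pipeline).  With a single interval the filter cannot
    discriminate and returns all channels with a warning.
    """
    mat = rt.per_interval(biomarker)
    n_iv = mat.shape[1]
    if n_iv < 2:
        warnings.warn("temporal consistency filter needs >= 2 intervals; returning all channels")
        return set(rt.channels)
    if min_fraction <= 0:
        return set(rt.channels)
    above = pd.DataFrame(
        {
            iv: mat[iv] > _percentile_threshold(mat[iv].to_numpy(), percentile)
            for iv in mat.columns
        }
    )
    frac = above.mean(axis=1)
    return set(frac.index[frac >= min_fraction])


def compare_area_sizes(
    spike_sizes: Sequence[int],
    hfo_sizes: Sequence[int],
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-patient area sizes.

    Zero differences are dropped; the exact null distribution is used
    for up to 25 informative pairs.  Returns (statistic, p value).
    """
    a = np.asarray(spike_sizes, dtype=float)
    b = np.asarray(hfo_sizes, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired size vectors must have equal length")
    if a.size < 5:
        raise ValueError("need paired counts for at least 5 patients")
    diffs = a - b
    informative = diffs[diffs != 0]
    if informative.size == 0:
        warnings.warn("all paired area sizes tied; p = 1")
        return 0.0, 1.0
    method = "exact" if informative.size <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
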