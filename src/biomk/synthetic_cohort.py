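"""Synthetic iEEG recordings, event ground truth, and patient cohorts.

The clinical analysis operates on bipolar iEEG sampled at 2000 Hz during
interictal slow-wave sleep.  This module fabricates recordings with the
same statistical structure so every downstream stage is testable without
clinical data:

* 1/f (pink) background noise, resembling the iEEG spectrum;
* Poisson-placed triangular biphasic spikes (default 70 ms, 300 uV);
* Gaussian-windowed ripple bursts (120 Hz carrier, 60 ms, 20 uV) and
  fast-ripple bursts (300 Hz, 30 ms, 10 uV);
* configurable co-occurrence: a fraction of ripples carry a superimposed
  fast ripple (forming HFOs), and a fraction of spikes carry a ripple+FR
  pair within +/-50 ms of the spike peak (forming spike+HFO events);
* optional leader/follower propagation: spikes on a designated leader
  channel are echoed on follower channels with a configurable
  probability and a positive, normally distributed latency;
* "hot" channels whose event rates are multiplied, planting a biomarker
  area for the rate-threshold stage to recover.

Derived HFO and spike+HFO ground-truth markers are computed with the
*same* co-occurrence rules the detection modules use, so planted truth
and detector output are directly comparable.  A separate generator
fabricates patient cohorts (areas, resections, ILAE outcomes), and
:func:`table1_fixture` returns the fixed 20-patient reference cohort
used by the outcome-validation stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort_io import Interval, IntervalSet, Recording
from .events import EventMarker

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CohortRow",
    "PatientAreas",
    "simulate_markers",
    "simulate_recording",
    "simulate_cohort",
    "table1_fixture",
    "cohort_to_csv",
    "cohort_from_csv",
]

_EDGE_MARGIN_S = 0.25  # events are planted at least this far from interval edges
_MIN_SPIKE_SPACING_S = 0.3  # planted spikes on one channel are thinned to this spacing


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults mirror the recording conditions assumed downstream."""

    n_channels: int = 8
    fs: float = 2000.0
    duration_s: float = 300.0  # per interval, five minutes as analysed clinically
    n_intervals: int = 1
    background_sd: float = 5.0  # uV, pink-noise standard deviation
    spike_rate: float = 2.0  # events/min per channel
    ripple_rate: float = 2.0
    fr_rate: float = 1.0
    p_ripple_fr_cooccur: float = 0.5
    p_spike_hfo_cooccur: float = 0.3
    leader_channel: int | None = None
    follower_channels: tuple[int, ...] | None = None  # default: every other channel
    follow_prob: float = 0.8
    latency_mean_ms: float = 25.0
    latency_sd_ms: float = 5.0
    hot_channels: tuple[int, ...] = ()
    hot_factor: float = 10.0
    spike_amp_uv: float = 300.0
    spike_duration_s: float = 0.070
    ripple_freq_hz: float = 120.0
    ripple_duration_s: float = 0.060
    ripple_amp_uv: float = 20.0
    fr_freq_hz: float = 300.0
    fr_duration_s: float = 0.030
    fr_amp_uv: float = 10.0
    line_noise_amp_uv: float = 0.0  # optional 50 Hz sinusoid
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_ripple_fr_cooccur", "p_spike_hfo_cooccur", "follow_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("spike_rate", "ripple_rate", "fr_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_channels < 1 or self.duration_s <= 0 or self.n_intervals < 1:
            raise ValueError("need n_channels >= 1, duration_s > 0, n_intervals >= 1")
        fr_possible = self.fr_rate > 0 or (
            self.ripple_rate > 0 and self.p_ripple_fr_cooccur > 0
        ) or (self.spike_rate > 0 and self.p_spike_hfo_cooccur > 0)
        ripple_possible = self.ripple_rate > 0 or (
            self.spike_rate > 0 and self.p_spike_hfo_cooccur > 0
        )
        if fr_possible and self.fs <= 2.0 * self.fr_freq_hz:
            raise ValueError(
                f"fs={self.fs} Hz too low for fast-ripple content at "
                f"{self.fr_freq_hz} Hz; need fs > {2 * self.fr_freq_hz} Hz"
            )
        if ripple_possible and self.fs <= 2.0 * self.ripple_freq_hz:
            raise ValueError(
                f"fs={self.fs} Hz too low for ripple content at {self.ripple_freq_hz} Hz"
            )
        if self.leader_channel is not None and not 0 <= self.leader_channel < self.n_channels:
            raise ValueError("leader_channel out of range")
        if any(not 0 <= c < self.n_channels for c in self.hot_channels):
            raise ValueError("hot_channels out of range")

    @property
    def labels(self) -> list[str]:
        return [f"ch{i:02d}" for i in range(self.n_channels)]

    def intervals(self) -> IntervalSet:
        # at most six five-minute intervals per night, matching the selection rules
        return IntervalSet(
            [
                Interval(night=i // 6, start_s=i * self.duration_s, duration_s=self.duration_s)
                for i in range(self.n_intervals)
            ]
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        obj = json.loads(Path(path).read_text())
        for key in ("follower_channels", "hot_channels"):
            if obj.get(key) is not None:
                obj[key] = tuple(obj[key])
        return cls(**obj)


@dataclass
class GroundTruth:
    """Planted events, planted biomarker areas and the propagation leader."""

    markers: list[EventMarker]
    planted_area: dict[str, set[str]]
    leader_channel: str | None
    intervals: IntervalSet

    def of_kind(self, kind: str) -> list[EventMarker]:
        return [m for m in self.markers if m.kind == kind]


def _thin(times: np.ndarray, min_spacing: float) -> np.ndarray:
    """Drop events closer than ``min_spacing`` to their predecessor."""
    kept: list[float] = []
    for t in np.sort(times):
        if not kept or t - kept[-1] >= min_spacing:
            kept.append(float(t))
    return np.asarray(kept)


def _poisson_times(
    rng: np.random.Generator, rate_per_min: float, start: float, end: float
) -> np.ndarray:
    lam = rate_per_min * (end - start) / 60.0
    n = rng.poisson(lam)
    if n == 0:
        return np.empty(0)
    return np.sort(rng.uniform(start + _EDGE_MARGIN_S, end - _EDGE_MARGIN_S, size=n))


def simulate_markers(cfg: SimConfig) -> GroundTruth:
    """Plant ground-truth event markers without rendering the signal.

    The statistical structure (Poisson placement, co-occurrence coin
    flips, leader/follower echoes) is identical to what
    :func:`simulate_recording` renders; this fast path serves analyses
    that operate on markers only (rates, areas, propagation).
    """
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.labels
    half_spike = cfg.spike_duration_s / 2.0
    apex_frac = 0.4  # apex position within the spike waveform
    half_rip = cfg.ripple_duration_s / 2.0
    half_fr = cfg.fr_duration_s / 2.0
    spikes: list[EventMarker] = []
    ripples: list[EventMarker] = []
    frs: list[EventMarker] = []

    def spike_marker(ch: str, apex: float) -> EventMarker:
        return EventMarker(
            ch, "spike",
            apex - apex_frac * cfg.spike_duration_s,
            apex,
            apex + (1.0 - apex_frac) * cfg.spike_duration_s,
        )

    def burst_markers(ch: str, center: float, with_fr: bool) -> None:
        ripples.append(
            EventMarker(ch, "ripple", center - half_rip, center, center + half_rip)
        )
        if with_fr:
            frs.append(EventMarker(ch, "FR", center - half_fr, center, center + half_fr))

    followers = (
        list(cfg.follower_channels)
        if cfg.follower_channels is not None
        else [i for i in range(cfg.n_channels) if i != cfg.leader_channel]
    )
    for iv in cfg.intervals().intervals:
        start, end = iv.start_s, iv.end_s
        for i, ch in enumerate(labels):
            mult = cfg.hot_factor if i in cfg.hot_channels else 1.0
            # spikes: followers of a planted leader receive echoes only,
            # so every follower spike demonstrably trails a leader spike
            if cfg.leader_channel is None or i == cfg.leader_channel:
                for apex in _thin(
                    _poisson_times(rng, cfg.spike_rate * mult, start, end),
                    _MIN_SPIKE_SPACING_S,
                ):
                    spikes.append(spike_marker(ch, apex))
                    if rng.random() < cfg.p_spike_hfo_cooccur:
                        offset = rng.uniform(-0.020, 0.020)
                        burst_markers(ch, apex + offset, with_fr=True)
            # independent ripples, a fraction carrying a superimposed FR
            for center in _poisson_times(rng, cfg.ripple_rate * mult, start, end):
                burst_markers(ch, center, rng.random() < cfg.p_ripple_fr_cooccur)
            # standalone fast ripples
            for center in _poisson_times(rng, cfg.fr_rate * mult, start, end):
                frs.append(EventMarker(ch, "FR", center - half_fr, center, center + half_fr))
        # leader -> follower echoes
        if cfg.leader_channel is not None:
            min_latency = 1.0 / cfg.fs
            leader_label = labels[cfg.leader_channel]
            leader_apexes = [
                s.peak_s for s in spikes
                if s.channel == leader_label and start <= s.peak_s < end
            ]
            for apex in leader_apexes:
                for f in followers:
                    if rng.random() >= cfg.follow_prob:
                        continue
                    lat = rng.normal(cfg.latency_mean_ms, cfg.latency_sd_ms) / 1000.0
                    while lat < min_latency:  # truncate: follower strictly after leader
                        lat = rng.normal(cfg.latency_mean_ms, cfg.latency_sd_ms) / 1000.0
                    echo = apex + lat
                    if echo < end - _EDGE_MARGIN_S:
                        spikes.append(spike_marker(labels[f], echo))

    # derive HFO and spike+HFO truth with the same rules the detectors use
    from .hfo_detection import cooccur_ripple_fr
    from .spike_events import spike_hfo_cooccurrence

    hfos = cooccur_ripple_fr(ripples, frs)
    spike_hfos = spike_hfo_cooccurrence(sorted(spikes, key=lambda e: e.peak_s), hfos)
    markers = sorted(
        spikes + ripples + frs + hfos + spike_hfos, key=lambda e: (e.peak_s, e.channel)
    )
    hot_labels = {labels[i] for i in cfg.hot_channels}
    planted_area = {b: set(hot_labels) for b in ("spike", "HFO", "spike+HFO")}
    return GroundTruth(
        markers=markers,
        planted_area=planted_area,
        leader_channel=None if cfg.leader_channel is None else labels[cfg.leader_channel],
        intervals=cfg.intervals(),
    )


# ---------------------------------------------------------------------------
# waveform rendering


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude noise normalised to standard deviation ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x * (sd / x.std())


def _spike_waveform(fs: float, duration_s: float, amp: float) -> tuple[np.ndarray, int]:
    """Triangular biphasic transient; returns (waveform, apex sample index).

    Piecewise linear through (0, 0) -> (0.4 d, +A) -> (0.7 d, -A/2) -> (d, 0):
    a sharp positive apex followed by a shallower negative after-wave.
    """
    n = max(int(round(duration_s * fs)), 5)
    apex = int(round(0.4 * (n - 1)))  # breakpoints pinned to samples: apex is exact
    trough = int(round(0.7 * (n - 1)))
    idx = np.arange(n)
    wave = np.interp(idx, [0, apex, trough, n - 1], [0.0, amp, -0.5 * amp, 0.0])
    return wave, apex


def _burst_waveform(fs: float, duration_s: float, freq: float, amp: float) -> np.ndarray:
    """Gaussian-windowed sinusoidal burst centred in its support."""
    n = max(int(round(duration_s * fs)), 5)
    t = (np.arange(n) - (n - 1) / 2.0) / fs
    sigma = duration_s / 6.0
    return amp * np.exp(-(t**2) / (2.0 * sigma**2)) * np.sin(2.0 * np.pi * freq * t)


def _add_at(x: np.ndarray, wave: np.ndarray, center_idx: int, anchor: int) -> None:
    start = center_idx - anchor
    stop = start + wave.size
    lo = max(start, 0)
    hi = min(stop, x.size)
    if lo < hi:
        x[lo:hi] += wave[lo - start : hi - start]


def simulate_recording(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Render a synthetic multichannel recording plus its ground truth.

    Identical configurations (including the seed) yield bit-identical
    output.  With all event rates at zero the recording is pure pink
    noise and the ground-truth marker list is empty.
    """
    truth = simulate_markers(cfg)
    n_samples = int(round(cfg.n_intervals * cfg.duration_s * cfg.fs))
    # noise seed is derived from (not equal to) the planning seed so the
    # marker plan and the background are independent streams
    noise_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6E6F]))
    data = np.empty((cfg.n_channels, n_samples))
    for i in range(cfg.n_channels):
        data[i] = _pink_noise(noise_rng, n_samples, cfg.background_sd)
    if cfg.line_noise_amp_uv > 0:
        t = np.arange(n_samples) / cfg.fs
        data += cfg.line_noise_amp_uv * np.sin(2.0 * np.pi * 50.0 * t)[None, :]

    spike_wave, apex_idx = _spike_waveform(cfg.fs, cfg.spike_duration_s, cfg.spike_amp_uv)
    ripple_wave = _burst_waveform(
        cfg.fs, cfg.ripple_duration_s, cfg.ripple_freq_hz, cfg.ripple_amp_uv
    )
    fr_wave = _burst_waveform(cfg.fs, cfg.fr_duration_s, cfg.fr_freq_hz, cfg.fr_amp_uv)
    label_index = {lbl: i for i, lbl in enumerate(cfg.labels)}
    for m in truth.markers:
        ch = label_index[m.channel]
        center = int(round(m.peak_s * cfg.fs))
        if m.kind == "spike":
            _add_at(data[ch], spike_wave, center, apex_idx)
        elif m.kind == "ripple":
            _add_at(data[ch], ripple_wave, center, (ripple_wave.size - 1) // 2)
        elif m.kind == "FR":
            _add_at(data[ch], fr_wave, center, (fr_wave.size - 1) // 2)
        # HFO / spike+HFO markers are derived labels; their constituents
        # are already rendered above
    rec = Recording(data=data, fs=cfg.fs, labels=cfg.labels)
    return rec, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortRow:
    """One patient of a validation cohort."""

    patient_id: int
    hfo_area_resected: str  # yes / no
    spike_area_resected: str  # yes / no
    spike_hfo_area_resected: str  # yes / no / undefined
    ilae: int  # 1 = seizure freedom, 2-6 = recurrence
    followup_months: int

    def __post_init__(self) -> None:
        if self.ilae not in range(1, 7):
            raise ValueError("ILAE outcome class must be 1..6")
        if self.hfo_area_resected not in ("yes", "no"):
            raise ValueError("hfo_area_resected must be yes/no")
        if self.spike_area_resected not in ("yes", "no"):
            raise ValueError("spike_area_resected must be yes/no")
        if self.spike_hfo_area_resected not in ("yes", "no", "undefined"):
            raise ValueError("spike_hfo_area_resected must be yes/no/undefined")


@dataclass
class PatientAreas:
    """Channel-level truth behind one simulated cohort row."""

    patient_id: int
    hfo_area: set[str]
    spike_area: set[str]
    spike_hfo_area: set[str]  # empty set when the area is undefined
    spike_hfo_defined: bool
    resection: set[str]


def simulate_cohort(
    n_patients: int,
    outcome_rule: Literal["deterministic", "noisy"] = "deterministic",
    epsilon: float = 0.0,
    seed: int | None = None,
    n_channels: int = 20,
    p_resect_hfo_area: float = 0.65,
    p_spike_hfo_undefined: float = 0.05,
) -> tuple[list[CohortRow], list[PatientAreas]]:
    """Fabricate a surgical cohort with channel-level area/resection truth.

    Per patient, a small HFO area is planted, the spike area is a strict
    superset of it (spike areas run larger), and the spike+HFO area
    tracks the HFO area but is occasionally undefined.  The resection
    fully contains the HFO area with probability ``p_resect_hfo_area``.
    Under the deterministic outcome rule the patient is seizure-free
    (ILAE 1) exactly when the HFO area was fully resected, otherwise
    ILAE is drawn uniformly from 2-6; the noisy rule flips the
    seizure-free/recurrent outcome with probability ``epsilon``.  The
    structural draws and the noise draws use separate seed streams, so
    two runs differing only in ``epsilon`` share identical cohorts.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if outcome_rule not in ("deterministic", "noisy"):
        raise ValueError("outcome_rule must be 'deterministic' or 'noisy'")
    ss = np.random.SeedSequence(seed)
    rng_struct, rng_flip = (np.random.default_rng(s) for s in ss.spawn(2))
    labels = [f"ch{i:02d}" for i in range(n_channels)]
    rows: list[CohortRow] = []
    areas: list[PatientAreas] = []
    for pid in range(1, n_patients + 1):
        hfo_area = set(rng_struct.choice(labels, size=rng_struct.integers(1, 4), replace=False))
        extra = [l for l in labels if l not in hfo_area]
        spike_area = hfo_area | set(
            rng_struct.choice(extra, size=rng_struct.integers(1, 5), replace=False)
        )
        undefined = rng_struct.random() < p_spike_hfo_undefined
        spike_hfo_area = set() if undefined else set(hfo_area)
        resect = set(hfo_area)
        spared: set[str] = set()
        if rng_struct.random() >= p_resect_hfo_area:
            # leave at least one HFO-area channel unresected
            spared = {sorted(hfo_area)[int(rng_struct.integers(0, len(hfo_area)))]}
            resect -= spared
        others = [l for l in labels if l not in resect and l not in spared]
        resect |= set(rng_struct.choice(others, size=rng_struct.integers(0, 4), replace=False))
        hfo_in = hfo_area <= resect
        seizure_free = hfo_in
        recurrent_draw = int(rng_struct.integers(2, 7))
        if outcome_rule == "noisy" and rng_flip.random() < epsilon:
            seizure_free = not seizure_free
        flip_draw = int(rng_flip.integers(2, 7))
        if seizure_free:
            ilae = 1
        else:
            ilae = recurrent_draw if not hfo_in else flip_draw
        rows.append(
            CohortRow(
                patient_id=pid,
                hfo_area_resected="yes" if hfo_in else "no",
                spike_area_resected="yes" if spike_area <= resect else "no",
                spike_hfo_area_resected=(
                    "undefined" if undefined else ("yes" if spike_hfo_area <= resect else "no")
                ),
                ilae=ilae,
                followup_months=int(rng_struct.integers(12, 61)),
            )
        )
        areas.append(
            PatientAreas(pid, hfo_area, spike_area, spike_hfo_area, not undefined, resect)
        )
    return rows, areas


#: (hfo, spike, spike+hfo, ilae, follow-up months) per patient 1..20 of the
#: reference cohort; resection flags are yes/no/undefined.
_TABLE1 = [
    ("yes", "yes", "yes", 1, 32),
    ("yes", "no", "yes", 1, 30),
    ("yes", "no", "yes", 1, 28),
    ("yes", "no", "yes", 1, 42),
    ("yes", "yes", "yes", 1, 14),
    ("yes", "yes", "yes", 1, 12),
    ("yes", "no", "no", 3, 53),
    ("yes", "yes", "yes", 3, 28),
    ("yes", "no", "no", 5, 46),
    ("yes", "yes", "yes", 1, 48),
    ("yes", "no", "no", 1, 38),
    ("yes", "yes", "yes", 1, 37),
    ("yes", "yes", "yes", 1, 25),
    ("yes", "no", "yes", 1, 36),
    ("yes", "no", "no", 1, 27),
    ("yes", "yes", "yes", 1, 28),
    ("no", "yes", "yes", 5, 46),
    ("no", "no", "undefined", 5, 38),
    ("no", "no", "no", 6, 18),
    ("no", "no", "no", 5, 21),
]


def table1_fixture() -> list[CohortRow]:
    """The fixed 20-patient reference cohort.

    Patient 18's spike+HFO area is recorded as undefined: no spike+HFO
    events occurred, so that biomarker cannot classify the patient and
    the spike+HFO confusion matrix runs over 19 patients.
    """
    return [
        CohortRow(pid, hfo, spk, sh, ilae, fu)
        for pid, (hfo, spk, sh, ilae, fu) in enumerate(_TABLE1, start=1)
    ]


def cohort_to_csv(rows: Sequence[CohortRow], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(path, index=False)


def cohort_from_csv(path: str | Path) -> list[CohortRow]:
    df = pd.read_csv(path)
    return [
        CohortRow(
            int(r.patient_id),
            str(r.hfo_area_resected),
            str(r.spike_area_resected),
            str(r.spike_hfo_area_resected),
            int(r.ilae),
            int(r.followup_months),
        )
        for r in df.itertuples(index=False)
    ]
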