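"""Generator statistics: determinism, Poisson placement, propagation echoes, cohorts."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from biomk import (
    SimConfig,
    cohort_from_csv,
    cohort_to_csv,
    confusion_matrix,
    simulate_cohort,
    simulate_markers,
    simulate_recording,
    table1_fixture,
)
from biomk.hfo_detection import default_band_specs, filter_band


def test_zero_rates_gives_pure_noise():
    cfg = SimConfig(
        n_channels=2, duration_s=30, spike_rate=0, ripple_rate=0, fr_rate=0,
        p_ripple_fr_cooccur=0, p_spike_hfo_cooccur=0, seed=0,
    )
    rec, truth = simulate_recording(cfg)
    assert truth.markers == []
    # noise is normalised to the configured standard deviation
    assert np.allclose(rec.data.std(axis=1), cfg.background_sd, rtol=1e-6)


def test_identical_seed_identical_output():
    cfg = SimConfig(n_channels=3, duration_s=20, seed=42)
    rec_a, truth_a = simulate_recording(cfg)
    rec_b, truth_b = simulate_recording(cfg)
    assert np.array_equal(rec_a.data, rec_b.data)
    assert truth_a.markers == truth_b.markers


def test_spike_counts_follow_poisson_placement():
    """6 spikes/min for 300 s -> counts inside the Poisson 99% band at lambda=30."""
    lo, hi = stats.poisson.ppf([0.005, 0.995], 30)
    outliers = 0
    for seed in range(12):
        cfg = SimConfig(
            n_channels=1, duration_s=300, spike_rate=6, ripple_rate=0, fr_rate=0,
            p_ripple_fr_cooccur=0, p_spike_hfo_cooccur=0, seed=seed,
        )
        n = len(simulate_markers(cfg).of_kind("spike"))
        outliers += not (lo <= n <= hi)
    assert outliers <= 1


def test_follower_spikes_trail_leader_by_configured_latency():
    cfg = SimConfig(
        n_channels=3, duration_s=120, spike_rate=6, ripple_rate=0, fr_rate=0,
        p_ripple_fr_cooccur=0, p_spike_hfo_cooccur=0,
        leader_channel=0, follow_prob=1.0, latency_mean_ms=25.0, latency_sd_ms=0.1,
        seed=5,
    )
    truth = simulate_markers(cfg)
    leaders = sorted(s.peak_s for s in truth.of_kind("spike") if s.channel == "ch00")
    followers = [s for s in truth.of_kind("spike") if s.channel != "ch00"]
    assert leaders and followers
    for f in followers:
        lat_ms = min((f.peak_s - t) * 1000.0 for t in leaders if t < f.peak_s)
        assert lat_ms == pytest.approx(25.0, abs=1.0)


def test_planted_bursts_exceed_local_background_band_energy(burst_recording):
    """Each planted ripple/FR carries more band energy than nearby background."""
    rec, truth = burst_recording
    ripple_spec, fr_spec = default_band_specs()
    for spec, kind in ((ripple_spec, "ripple"), (fr_spec, "FR")):
        filtered = {
            ch: filter_band(rec.channel(ch), spec, rec.fs) for ch in rec.labels
        }
        for ev in truth.of_kind(kind):
            x = filtered[ev.channel]
            a = int(ev.onset_s * rec.fs)
            b = int(ev.offset_s * rec.fs) + 1
            width = b - a
            ref_a = a - 40 * width
            if ref_a < 0:
                ref_a, b_ref = b + 39 * width, b + 40 * width
            else:
                b_ref = a - 39 * width
            event_rms = np.sqrt(np.mean(x[a:b] ** 2))
            background_rms = np.sqrt(np.mean(x[ref_a:b_ref] ** 2))
            assert event_rms > background_rms


def test_fs_too_low_for_fr_content_rejected():
    with pytest.raises(ValueError, match="fast-ripple"):
        SimConfig(fs=500.0, fr_rate=1.0)
    # without any high-frequency content a low fs is legal
    SimConfig(fs=500.0, spike_rate=2, ripple_rate=0, fr_rate=0,
              p_ripple_fr_cooccur=0, p_spike_hfo_cooccur=0)


@pytest.mark.parametrize(
    "field,value",
    [("p_ripple_fr_cooccur", 1.2), ("follow_prob", -0.1), ("spike_rate", -1.0)],
)
def test_invalid_config_rejected(field, value):
    with pytest.raises(ValueError):
        SimConfig(**{field: value})


def test_config_json_round_trip(tmp_path):
    cfg = SimConfig(n_channels=4, hot_channels=(1, 2), leader_channel=0, seed=9)
    path = tmp_path / "cfg.json"
    cfg.to_json(path)
    assert SimConfig.from_json(path) == cfg


def test_cohort_deterministic_rule_extremes():
    rows, _ = simulate_cohort(15, seed=1, p_resect_hfo_area=1.0, p_spike_hfo_undefined=0.0)
    assert all(r.ilae == 1 for r in rows)
    assert all(r.hfo_area_resected == "yes" for r in rows)
    rows, _ = simulate_cohort(15, seed=1, p_resect_hfo_area=0.0, p_spike_hfo_undefined=0.0)
    assert all(r.ilae >= 2 for r in rows)
    cm = confusion_matrix(rows, "hfo")
    assert cm.fp == 0 and cm.tn == 0


def test_noisy_outcome_flip_fraction():
    """epsilon = 0.2 over 200 patients flips a binomially plausible count."""
    base, _ = simulate_cohort(200, outcome_rule="deterministic", seed=3)
    noisy, _ = simulate_cohort(200, outcome_rule="noisy", epsilon=0.2, seed=3)
    flips = sum((a.ilae == 1) != (b.ilae == 1) for a, b in zip(base, noisy))
    lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.2)
    assert lo <= flips <= hi


def test_cohort_epsilon_validation():
    with pytest.raises(ValueError):
        simulate_cohort(10, outcome_rule="noisy", epsilon=1.5, seed=0)


def test_table1_fixture_marginals():
    rows = table1_fixture()
    assert len(rows) == 20
    assert sum(r.ilae == 1 for r in rows) == 13
    assert sum(r.ilae >= 2 and r.hfo_area_resected == "yes" for r in rows) == 3
    assert sum(r.ilae == 1 and r.spike_area_resected == "yes" for r in rows) == 7
    assert sum(r.ilae == 1 and r.spike_hfo_area_resected == "yes" for r in rows) == 11
    assert sum(r.hfo_area_resected == "yes" for r in rows) == 16
    assert [r.spike_hfo_area_resected for r in rows].count("undefined") == 1
    assert rows[17].spike_hfo_area_resected == "undefined"  # patient 18


def test_cohort_csv_round_trip(tmp_path):
    rows = table1_fixture()
    path = tmp_path / "cohort.csv"
    cohort_to_csv(rows, path)
    assert cohort_from_csv(path) == rows


def test_derived_cooccurrence_markers_consistent():
    """Planted spike+HFO truth satisfies the detectors' own temporal rules."""
    cfg = SimConfig(
        n_channels=2, duration_s=300, spike_rate=6, ripple_rate=0, fr_rate=0,
        p_ripple_fr_cooccur=0, p_spike_hfo_cooccur=1.0, seed=2,
    )
    truth = simulate_markers(cfg)
    spikes = truth.of_kind("spike")
    spike_hfos = truth.of_kind("spike+HFO")
    assert len(spikes) > 0
    assert len(spike_hfos) == len(spikes)  # every spike carries an HFO at p = 1
    for sh in spike_hfos:
        assert dataclasses.asdict(sh)["kind"] == "spike+HFO"
        assert sh.offset_s - sh.onset_s <= 0.25
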