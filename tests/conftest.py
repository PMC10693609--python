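import numpy as np
import pytest

from biomk import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def burst_recording():
    """Recording with planted ripples/FRs (no spikes) and its ground truth."""
    cfg = SimConfig(
        n_channels=2,
        duration_s=120.0,
        spike_rate=0.0,
        ripple_rate=3.0,
        fr_rate=2.0,
        p_ripple_fr_cooccur=0.5,
        p_spike_hfo_cooccur=0.0,
        seed=7,
    )
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def noise_recording():
    """Five minutes of single-channel pure pink noise."""
    cfg = SimConfig(
        n_channels=1,
        duration_s=300.0,
        spike_rate=0.0,
        ripple_rate=0.0,
        fr_rate=0.0,
        p_ripple_fr_cooccur=0.0,
        p_spike_hfo_cooccur=0.0,
        seed=11,
    )
    rec, _ = simulate_recording(cfg)
    return rec


def match_fraction(detected, truths, tol_s=0.020):
    """Fraction of true events matched by a detection within tol_s on the same channel."""
    if not truths:
        return 1.0
    hits = sum(
        any(d.channel == t.channel and abs(d.peak_s - t.peak_s) <= tol_s for d in detected)
        for t in truths
    )
    return hits / len(truths)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
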