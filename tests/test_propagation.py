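"""Leader/receiver pairing, adjacency, modularity clusters, permutation null, PSTH."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from biomk import (
    AdjacencyMatrix,
    EventMarker,
    SimConfig,
    build_adjacency,
    build_propagation_graph,
    detect_clusters,
    pair_events,
    permutation_test_modularity,
    psth,
    render_graph,
    simulate_markers,
)


def _spike(ch, peak):
    return EventMarker(ch, "spike", peak, peak, peak)


def test_pairing_window_and_tie_rules():
    pairs = pair_events([_spike("ch1", 10.000), _spike("ch2", 10.020)])
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.leader_channel, p.receiver_channel) == ("ch1", "ch2")
    assert p.latency_ms == pytest.approx(20.0)
    # beyond the window
    assert pair_events([_spike("ch1", 10.0), _spike("ch2", 10.2)], window_ms=100) == []
    # simultaneous spikes never pair (strict ordering)
    assert pair_events([_spike("ch1", 10.0), _spike("ch2", 10.0)]) == []


def test_receiver_claimed_by_earliest_leader_only():
    spikes = [_spike("a", 10.00), _spike("b", 10.03), _spike("c", 10.05)]
    pairs = pair_events(spikes, window_ms=100)
    to_c = [p for p in pairs if p.receiver_channel == "c"]
    assert len(to_c) == 1 and to_c[0].leader_channel == "a"
    all_pairs = pair_events(spikes, window_ms=100, claim_first=False)
    assert len([p for p in all_pairs if p.receiver_channel == "c"]) == 2


def test_adjacency_direct_count():
    """c leads r after 8 of its 10 spikes -> entry (r, c) = 0.8."""
    spikes = []
    for k in range(10):
        t = 10.0 * k
        spikes.append(_spike("c", t))
        if k < 8:
            spikes.append(_spike("r", t + 0.02))
    pairs = pair_events(spikes)
    adj = build_adjacency(pairs, spikes)
    i_r, i_c = adj.channels.index("r"), adj.channels.index("c")
    assert adj.matrix[i_r, i_c] == pytest.approx(0.8)
    assert adj.out_strength["c"] == pytest.approx(0.8)
    assert adj.in_strength["r"] == pytest.approx(0.8)


def test_no_pairs_gives_zero_matrix():
    spikes = [_spike("a", 0.0), _spike("b", 50.0)]
    adj = build_adjacency([], spikes)
    assert not adj.matrix.any()


def _brute_force_adjacency(spikes, window_s):
    """Independent oracle: all-pairs double loop over spikes."""
    channels = sorted({s.channel for s in spikes})
    idx = {c: i for i, c in enumerate(channels)}
    mat = np.zeros((len(channels), len(channels)))
    for lead in spikes:
        followed = set()
        for other in spikes:
            if other.channel == lead.channel:
                continue
            if lead.peak_s < other.peak_s <= lead.peak_s + window_s:
                followed.add(other.channel)
        for r in followed:
            mat[idx[r], idx[lead.channel]] += 1
    n = np.array([sum(s.channel == c for s in spikes) for c in channels], dtype=float)
    return channels, mat / n[None, :]


def test_adjacency_matches_brute_force_oracle(rng):
    for _ in range(10):
        chans = [f"c{i}" for i in range(rng.integers(2, 6))]
        spikes = [
            _spike(ch, float(t))
            for ch in chans
            for t in rng.uniform(0, 20, rng.integers(1, 50))
        ]
        pairs = pair_events(spikes, window_ms=100, claim_first=False)
        adj = build_adjacency(pairs, spikes, window_ms=100)
        oracle_chans, oracle = _brute_force_adjacency(spikes, 0.100)
        assert adj.channels == oracle_chans
        np.testing.assert_allclose(adj.matrix, oracle, atol=1e-12)


def test_strength_conventions_on_random_matrix(rng):
    n = 5
    m = rng.uniform(0, 1, (n, n))
    np.fill_diagonal(m, 0.0)
    adj = AdjacencyMatrix(m, [f"c{i}" for i in range(n)], 100.0)
    np.testing.assert_allclose(adj.out_strength.to_numpy(), m.sum(axis=0))
    np.testing.assert_allclose(adj.in_strength.to_numpy(), m.sum(axis=1))


def _partitions(items):
    if not items:
        yield []
        return
    head = items[0]
    for part in _partitions(items[1:]):
        yield [[head]] + part
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1 :]


def test_two_block_clusters_match_exhaustive_optimum():
    """Strong within-group, zero between-group weights -> the 2-block partition."""
    chans = [f"c{i}" for i in range(6)]
    m = np.zeros((6, 6))
    for i, j in itertools.combinations(range(3), 2):
        m[i, j] = m[j, i] = 0.8
        m[i + 3, j + 3] = m[j + 3, i + 3] = 0.8
    adj = AdjacencyMatrix(np.clip(m, 0, 1) * (1 - np.eye(6)), chans, 100.0)
    labels, q = detect_clusters(adj)
    groups = {frozenset(ch for ch, g in labels.items() if g == k) for k in set(labels.values())}
    assert groups == {frozenset(chans[:3]), frozenset(chans[3:])}
    assert q > 0.4
    # exhaustive search over all partitions confirms the optimum
    g = nx.Graph()
    g.add_nodes_from(chans)
    for i in range(6):
        for j in range(i + 1, 6):
            w = (m[i, j] + m[j, i]) / 2
            if w > 0:
                g.add_edge(chans[i], chans[j], weight=w)
    best = max(
        nx.community.modularity(g, [set(p) for p in part], weight="weight")
        for part in _partitions(chans)
    )
    assert q == pytest.approx(best, abs=1e-9)


def test_uniform_graph_has_no_community_structure():
    n = 6
    m = np.full((n, n), 0.5)
    np.fill_diagonal(m, 0.0)
    adj = AdjacencyMatrix(m, [f"c{i}" for i in range(n)], 100.0)
    _, q = detect_clusters(adj)
    assert q <= 0.05


def test_single_node_graph():
    adj = AdjacencyMatrix(np.zeros((1, 1)), ["only"], 100.0)
    labels, q = detect_clusters(adj)
    assert labels == {"only": 0}
    assert q == 0.0


def _two_block_spikes(seed_a=10, seed_b=11, spike_rate=20.0):
    common = dict(
        n_channels=4, fs=2000, duration_s=300, n_intervals=1, spike_rate=spike_rate,
        ripple_rate=0, fr_rate=0, p_ripple_fr_cooccur=0, p_spike_hfo_cooccur=0,
        leader_channel=0, follow_prob=0.8,
    )
    ta = simulate_markers(SimConfig(seed=seed_a, **common))
    tb = simulate_markers(SimConfig(seed=seed_b, **common))
    return ta.of_kind("spike") + [
        EventMarker("g" + m.channel, "spike", m.onset_s, m.peak_s, m.offset_s)
        for m in tb.of_kind("spike")
    ]


def test_planted_block_structure_is_significant():
    spikes = _two_block_spikes()
    p, q_obs, q_null = permutation_test_modularity(spikes, n_perm=300, seed=1)
    assert q_obs > 0.3
    assert p <= 0.01
    assert q_null.mean() < 0.1


def test_permutation_p_uniform_under_null(rng):
    """Channel-shuffled spikes give p values centred on 1/2."""
    ps = []
    for seed in range(30):
        local = np.random.default_rng(seed)
        spikes = [
            _spike(f"c{local.integers(0, 5)}", float(t))
            for t in np.sort(local.uniform(0, 120, 150))
        ]
        p, _, _ = permutation_test_modularity(spikes, n_perm=59, seed=seed)
        ps.append(p)
    assert 0.35 <= float(np.mean(ps)) <= 0.65


def test_permutation_requires_positive_n_perm():
    with pytest.raises(ValueError):
        permutation_test_modularity([_spike("a", 0.0), _spike("b", 0.1)], n_perm=0)
    with pytest.warns(UserWarning, match="coarse"):
        permutation_test_modularity(
            [_spike("a", 0.0), _spike("b", 0.02), _spike("a", 1.0)], n_perm=50, seed=0
        )


def test_psth_mass_in_expected_bin():
    spikes = []
    for k in range(20):
        t = 5.0 * k
        spikes.append(_spike("lead", t))
        spikes.append(_spike("recv", t + 0.025))
    edges, hist = psth(spikes, "lead", bin_ms=10, max_latency_ms=200)
    counts = hist["recv"]
    assert counts.sum() == 20
    assert edges[np.argmax(counts)] == 20.0  # all mass in the (20, 30] ms bin
    assert counts[2] == 20


def test_psth_conservation_and_empty_receiver():
    spikes = [_spike("lead", 0.0), _spike("recv", 10.0)]  # latency far out of range
    edges, hist = psth(spikes, "lead")
    assert hist["recv"].sum() == 0
    with pytest.raises(ValueError, match="leader"):
        psth(spikes, "nope")


def test_leader_attains_max_out_strength():
    cfg = SimConfig(
        n_channels=6, fs=2000, duration_s=300, n_intervals=2, spike_rate=20,
        ripple_rate=0, fr_rate=0, p_ripple_fr_cooccur=0, p_spike_hfo_cooccur=0,
        leader_channel=2, follow_prob=0.8, seed=17,
    )
    truth = simulate_markers(cfg)
    g = build_propagation_graph(truth.of_kind("spike"), total_minutes=10.0)
    assert g.adjacency.out_strength.idxmax() == "ch02" == truth.leader_channel


def test_render_thresholds():
    m = np.zeros((3, 3))
    m[1, 0] = 0.8  # c0 -> c1 strong
    m[2, 0] = 0.1  # c0 -> c2 weak: below a quarter of the max
    adj = AdjacencyMatrix(m, ["c0", "c1", "c2"], 100.0)
    import pandas as pd

    from biomk.propagation import PropagationGraph

    graph = PropagationGraph(adj, pd.Series([2.0, 2.0, 2.0], index=adj.channels))
    desc = render_graph(graph)
    assert len(desc["nodes"]) == 3  # equal rates: everyone is at the mean
    weights = {(e["from"], e["to"]) for e in desc["edges"]}
    assert ("c0", "c1") in weights and ("c0", "c2") not in weights


def test_render_empty_graph():
    import pandas as pd

    from biomk.propagation import PropagationGraph

    adj = AdjacencyMatrix(np.zeros((0, 0)), [], 100.0)
    desc = render_graph(PropagationGraph(adj, pd.Series(dtype=float)))
    assert desc == {"nodes": [], "edges": []}
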