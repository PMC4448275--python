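"""Topology module: degree targets, motif scores, construction invariants."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mvsim.config import NetworkConfig
from mvsim.motifs import (
    GENE,
    MIRNA,
    REPRESSION,
    MOTIF_REGISTRY,
    MotifSlot,
    MotifTemplate,
)
from mvsim.topology import (
    DegreeState,
    RegulatoryNetwork,
    add_signalling_nodes,
    build_network,
    gene_subscore,
    instantiate_motif,
    mirna_subscore,
    motif_score,
    proportional_weights,
    sample_degree_targets,
    select_motif,
    signal_target_weights,
)

from conftest import random_tiny_graph

# --- brute-force sub-score oracles (straight re-summation over every bin) ---


def brute_gene_subscore(graph, node, delta, targets):
    nodes = [n for n, d in graph.nodes(data=True) if d["kind"] != "signal"]
    n_total = len(nodes)
    k_max = n_total
    deg = dict(graph.degree())
    p = np.zeros(k_max)
    for n in nodes:
        if 1 <= deg[n] <= k_max:
            p[deg[n] - 1] += 1.0 / n_total
    f = p.copy()
    if 1 <= deg[node] <= k_max:
        f[deg[node] - 1] -= 1.0 / n_total
    if 1 <= deg[node] + delta <= k_max:
        f[deg[node] + delta - 1] += 1.0 / n_total
    s = 0.0
    for k in range(1, k_max + 1):
        dk = targets.d_p[k - 1]
        if dk <= 0:
            continue
        s += np.sign(abs(dk - p[k - 1]) - abs(dk - f[k - 1])) * abs(dk - p[k - 1]) / dk
    return s


def brute_mirna_subscore(graph, node, delta_in, delta_out, targets):
    mirnas = [n for n, d in graph.nodes(data=True) if d["kind"] == MIRNA]
    m = len(mirnas)
    if m == 0:
        return 0.0
    nodes = [n for n, d in graph.nodes(data=True) if d["kind"] != "signal"]
    k_max = len(nodes)

    def part(current_of, delta, target_vec):
        p = np.zeros(k_max)
        for n in mirnas:
            v = current_of(n)
            if 1 <= v <= k_max:
                p[v - 1] += 1.0 / m
        f = p.copy()
        v = current_of(node)
        if 1 <= v <= k_max:
            f[v - 1] -= 1.0 / m
        if 1 <= v + delta <= k_max:
            f[v + delta - 1] += 1.0 / m
        s = 0.0
        for k in range(1, k_max + 1):
            dk = target_vec[k - 1]
            if dk <= 0:
                continue
            s += np.sign(abs(dk - p[k - 1]) - abs(dk - f[k - 1])) * abs(dk - p[k - 1]) / dk
        return s

    return part(graph.in_degree, delta_in, targets.d_p) + part(
        graph.out_degree, delta_out, targets.d_e
    )


# --- degree targets ---------------------------------------------------------


def test_degree_targets_are_normalized_power_and_exponential_laws():
    cfg = NetworkConfig(n_genes=900, n_mirnas=100, alpha=2.2, lambda_=0.5)
    t = sample_degree_targets(cfg)
    assert t.k_max == 1000
    assert t.d_p.sum() == pytest.approx(1.0)
    assert t.d_e.sum() == pytest.approx(1.0)
    assert np.all(t.d_p >= 0) and np.all(t.d_e >= 0)
    # proportionality checks against the raw laws
    k = np.arange(1, 1001)
    ratio = t.d_p * k**2.2
    assert np.allclose(ratio, ratio[0])


def test_degree_targets_small_kmax_matches_direct_summation():
    # brute-force normalization oracle at k_max = 4
    cfg = NetworkConfig(n_genes=4, alpha=2.2)
    t = sample_degree_targets(cfg)
    raw = np.array([1.0, 2.0**-2.2, 3.0**-2.2, 4.0**-2.2])
    z = raw.sum()
    assert np.allclose(t.d_p, raw / z)


def test_degree_targets_exponential_limit_concentrates_on_degree_one():
    cfg = NetworkConfig(n_genes=50, lambda_=50.0)
    t = sample_degree_targets(cfg)
    assert t.d_e[0] > 1 - 1e-8


def test_degree_targets_invalid_parameters_raise():
    with pytest.raises(ValueError):
        NetworkConfig(n_genes=10, alpha=-1.0)
    with pytest.raises(ValueError):
        NetworkConfig(n_genes=10, lambda_=0.0)


# --- sub-scores vs brute force ----------------------------------------------


@pytest.mark.parametrize("seed", range(6))
def test_gene_subscore_matches_bruteforce_on_tiny_networks(seed):
    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(2, 7))
    n_mirnas = int(rng.integers(0, 3))
    g, targets, state = random_tiny_graph(rng, n_genes, n_mirnas)
    for node in [n for n, d in g.nodes(data=True) if d["kind"] == GENE]:
        for delta in (0, 1, 2, 3):
            expected = brute_gene_subscore(g, node, delta, targets)
            got = gene_subscore(g.degree(node), delta, targets, state)
            assert got == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_mirna_subscore_matches_bruteforce_on_tiny_networks(seed):
    rng = np.random.default_rng(100 + seed)
    g, targets, state = random_tiny_graph(rng, int(rng.integers(2, 6)), int(rng.integers(1, 4)))
    for node in [n for n, d in g.nodes(data=True) if d["kind"] == MIRNA]:
        for d_in, d_out in [(0, 0), (1, 0), (0, 1), (1, 1), (2, 1)]:
            expected = brute_mirna_subscore(g, node, d_in, d_out, targets)
            got = mirna_subscore(
                g.in_degree(node), g.out_degree(node), d_in, d_out, targets, state
            )
            assert got == pytest.approx(expected, abs=1e-12)


def test_subscore_positive_when_move_lands_on_target():
    """A move whose hypothetical distribution hits the target at every bin
    scores strictly positive whenever the current distribution misses it."""
    cfg = NetworkConfig(n_genes=4, alpha=2.2)
    targets = sample_degree_targets(cfg)
    # hand-crafted state: all mass on degree 2, target clearly different
    state = DegreeState(
        n_total=4,
        n_mirnas=0,
        p=np.array([targets.d_p[0] - 0.25, targets.d_p[1] + 0.25, targets.d_p[2], targets.d_p[3]]),
        p_in=np.zeros(4),
        p_out=np.zeros(4),
        deg={},
        in_deg={},
        out_deg={},
    )
    # moving a degree-2 node to degree 1 shifts 1/4 mass exactly onto target
    assert gene_subscore(2, -1, targets, state) > 0
    # and the reverse move walks away from the target
    assert gene_subscore(1, 1, targets, state) < 0


def test_subscore_zero_when_already_at_target():
    cfg = NetworkConfig(n_genes=4, alpha=2.2)
    targets = sample_degree_targets(cfg)
    state = DegreeState(
        n_total=4, n_mirnas=0, p=targets.d_p.copy(),
        p_in=np.zeros(4), p_out=np.zeros(4), deg={}, in_deg={}, out_deg={},
    )
    assert gene_subscore(1, 0, targets, state) == 0.0


def test_motif_score_empty_and_single_slot_cases(rng):
    g, targets, state = random_tiny_graph(rng, 5, 1)
    available = sorted(g.nodes)
    auto = MOTIF_REGISTRY["autoregulation"](rng)
    # single-gene-slot motif: score equals the summed lone gene sub-score
    expected = sum(
        gene_subscore(g.degree(n), auto.slot_degree("x"), targets, state)
        for n, d in g.nodes(data=True)
        if d["kind"] == GENE
    )
    assert motif_score(auto, available, g, targets, state) == pytest.approx(expected)


def test_motif_score_matches_termwise_bruteforce(rng):
    g, targets, state = random_tiny_graph(rng, 4, 2)
    available = sorted(g.nodes)
    for name in ("feed_forward_loop", "mirna_feed_forward_loop", "single_input_module"):
        t = MOTIF_REGISTRY[name](rng)
        expected = 0.0
        for slot in t.gene_slots():
            for n, d in g.nodes(data=True):
                if d["kind"] == GENE:
                    expected += brute_gene_subscore(g, n, t.slot_degree(slot.name), targets)
        for slot in t.mirna_slots():
            for n, d in g.nodes(data=True):
                if d["kind"] == MIRNA:
                    expected += brute_mirna_subscore(
                        g, n, t.slot_in_degree(slot.name), t.slot_out_degree(slot.name), targets
                    )
        assert motif_score(t, available, g, targets, state) == pytest.approx(expected)


# --- motif selection ---------------------------------------------------------


def test_select_motif_single_candidate(rng):
    pool = [MOTIF_REGISTRY["autoregulation"](rng)]
    assert select_motif(pool, [-0.5], rng) == 0


def test_select_motif_uniform_for_all_zero_scores(rng):
    pool = [MOTIF_REGISTRY["autoregulation"](rng) for _ in range(3)]
    draws = np.array([select_motif(pool, [0.0, 0.0, 0.0], rng) for _ in range(10_000)])
    counts = np.bincount(draws, minlength=3)
    assert stats.chisquare(counts).pvalue > 1e-3


def test_select_motif_proportional_to_positive_scores(rng):
    pool = [MOTIF_REGISTRY["autoregulation"](rng) for _ in range(2)]
    draws = np.array([select_motif(pool, [3.0, 1.0], rng) for _ in range(10_000)])
    freq0 = np.mean(draws == 0)
    assert freq0 == pytest.approx(0.75, abs=0.02)


def test_proportional_weights_shift_negative_scores():
    w = proportional_weights([-2.0, 1.0])
    assert np.all(w > 0)
    assert w.sum() == pytest.approx(1.0)
    assert w[1] > w[0]


# --- instantiation -----------------------------------------------------------


def _fresh_net(n_genes, n_mirnas=0):
    g = nx.DiGraph()
    for i in range(n_genes):
        g.add_node(f"g{i}", kind=GENE)
    for i in range(n_mirnas):
        g.add_node(f"m{i}", kind=MIRNA)
    cfg = NetworkConfig(n_genes=n_genes, n_mirnas=n_mirnas)
    return RegulatoryNetwork(graph=g, config=cfg), sample_degree_targets(cfg)


def test_instantiate_autoregulation_single_gene(rng):
    from mvsim.config import DynamicsConfig

    net, targets = _fresh_net(1)
    state = DegreeState.from_network(net.graph)
    template = MOTIF_REGISTRY["autoregulation"](rng)
    consumed, xs = instantiate_motif(
        template, net, {"g0"}, targets, state, rng, 0, DynamicsConfig()
    )
    assert consumed == {"g0"} and xs == {"g0"}
    assert net.graph.has_edge("g0", "g0")


def test_instantiate_single_input_module_structure(rng):
    from mvsim.config import DynamicsConfig

    slots = (MotifSlot("x", GENE, True),) + tuple(MotifSlot(f"t{i}", GENE) for i in range(3))
    template = MotifTemplate(
        "single_input_module", slots, tuple(("x", f"t{i}", "activation") for i in range(3))
    )
    net, targets = _fresh_net(4)
    state = DegreeState.from_network(net.graph)
    consumed, xs = instantiate_motif(
        template, net, set(net.graph.nodes), targets, state, rng, 0, DynamicsConfig()
    )
    assert len(consumed) == 4 and len(xs) == 1
    (x,) = xs
    assert net.graph.out_degree(x) == 3
    assert net.graph.number_of_edges() == 3


def test_instantiate_mirna_ffl_has_repressive_mirna_edge(rng):
    from mvsim.config import DynamicsConfig

    template = MOTIF_REGISTRY["mirna_feed_forward_loop"](rng)
    net, targets = _fresh_net(2, 1)
    state = DegreeState.from_network(net.graph)
    consumed, _ = instantiate_motif(
        template, net, set(net.graph.nodes), targets, state, rng, 0, DynamicsConfig()
    )
    assert net.graph.number_of_edges() == 3
    (mirna_edge,) = [
        (u, v, d) for u, v, d in net.graph.edges(data=True)
        if net.graph.nodes[u]["kind"] == MIRNA
    ]
    assert mirna_edge[2]["sign"] == REPRESSION


def test_instantiate_partial_motif_when_nodes_scarce(rng):
    from mvsim.config import DynamicsConfig

    slots = (MotifSlot("x", GENE, True),) + tuple(MotifSlot(f"t{i}", GENE) for i in range(4))
    template = MotifTemplate(
        "single_input_module", slots, tuple(("x", f"t{i}", "activation") for i in range(4))
    )
    net, targets = _fresh_net(2)
    state = DegreeState.from_network(net.graph)
    consumed, xs = instantiate_motif(
        template, net, set(net.graph.nodes), targets, state, rng, 0, DynamicsConfig()
    )
    assert len(consumed) == 2 and len(xs) == 1  # x plus one reachable target


# --- construction ------------------------------------------------------------


def test_build_degenerate_single_gene_terminates():
    net = build_network(NetworkConfig(n_genes=1, seed=0))
    assert net.graph.number_of_nodes() == 1


def test_build_conserves_nodes_and_logs_every_node(small_network):
    cfg = small_network.config
    assert small_network.graph.number_of_nodes() == cfg.n_genes + cfg.n_mirnas + cfg.n_signals
    placed = set()
    for inst in small_network.provenance:
        placed.update(inst["assignment"].values())
    non_signal = {
        n for n, d in small_network.graph.nodes(data=True) if d["kind"] != "signal"
    }
    assert placed == non_signal


def test_build_is_reproducible_under_seed():
    a = build_network(NetworkConfig(n_genes=40, n_mirnas=8, n_signals=2, seed=5))
    b = build_network(NetworkConfig(n_genes=40, n_mirnas=8, n_signals=2, seed=5))
    assert set(a.graph.edges) == set(b.graph.edges)
    assert a.provenance == b.provenance


def test_mirna_source_edges_are_repressive(small_network):
    g = small_network.graph
    for u, v, d in g.edges(data=True):
        if g.nodes[u]["kind"] == MIRNA:
            assert d["sign"] == REPRESSION


def test_hierarchy_levels_recorded(small_network):
    levels = {inst["level"] for inst in small_network.provenance}
    assert 0 in levels and len(levels) >= 2  # recycling actually happened


@given(
    n_genes=st.integers(min_value=1, max_value=40),
    n_mirnas=st.integers(min_value=0, max_value=10),
    n_signals=st.integers(min_value=0, max_value=4),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_construction_invariants_hold_for_random_configs(n_genes, n_mirnas, n_signals, seed):
    cfg = NetworkConfig(n_genes=n_genes, n_mirnas=n_mirnas, n_signals=n_signals, seed=seed)
    net = build_network(cfg)
    g = net.graph
    assert g.number_of_nodes() == n_genes + n_mirnas + n_signals
    for s in net.signals:
        assert g.in_degree(s) == 0
        assert g.out_degree(s) >= 1
    for u, v, d in g.edges(data=True):
        if g.nodes[u]["kind"] == MIRNA:
            assert d["sign"] == REPRESSION
        if u == v:
            assert d["motif"] == "autoregulation"


# --- signalling nodes --------------------------------------------------------


def test_add_zero_signals_is_identity(small_network):
    before = set(small_network.graph.nodes)
    add_signalling_nodes(small_network, 0, np.random.default_rng(0))
    assert set(small_network.graph.nodes) == before


def test_signal_targets_follow_smoothed_out_degree(rng):
    # star: hub with out-degree 9, nine leaves; weights (9+1) : 1 x 9
    g = nx.DiGraph()
    g.add_node("hub", kind=GENE)
    for i in range(9):
        g.add_node(f"l{i}", kind=GENE)
        g.add_edge("hub", f"l{i}", sign="activation")
    nodes, weights = signal_target_weights(g)
    assert weights[nodes.index("hub")] == pytest.approx(10 / 19)
    draws = rng.choice(len(nodes), size=10_000, p=weights)
    hub_freq = np.mean(np.array(nodes)[draws] == "hub")
    assert hub_freq == pytest.approx(10 / 19, abs=0.02)


def test_signal_nodes_have_indegree_zero_on_built_network():
    net = build_network(NetworkConfig(n_genes=80, n_mirnas=10, n_signals=10, seed=2))
    for s in net.signals:
        assert net.graph.in_degree(s) == 0
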