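"""Score-guided motif replication of gene/miRNA regulatory networks.

The generator grows a directed network over a fixed node set (n genes +
m miRNAs) that starts without edges.  At each step a pool of random motif
templates is scored by how much wiring them in would move the current degree
distribution toward user-specified target laws: gene (total) degrees chase a
power law with exponent alpha, miRNA in-degrees chase the same power law
(how many regulators a miRNA has) and miRNA out-degrees chase an exponential
law with rate lambda (how many targets a miRNA represses).  A motif is drawn
with probability proportional to its (shifted) score, concrete nodes are
sampled for its slots by the same sub-scores, and the motif's edges are
added.  Consumed nodes leave the available pool; the node in the master
regulator role ("x") is parked in a separate set H.  When the pool is empty
H is recycled as the next level's pool, which wires modules together
hierarchically and is what produces both hubs and the power-law decay of
the clustering coefficient C(k).

Signalling nodes (exogenous inputs with only outgoing edges) are attached
last, preferring high out-degree targets so a signal can steer the network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .config import DynamicsConfig, NetworkConfig
from .motifs import (
    ACTIVATION,
    GENE,
    MIRNA,
    REPRESSION,
    SIGNAL,
    MotifTemplate,
    sample_template,
)

_EPS = 1e-6  # shift added to proportional-sampling weights


@dataclass(frozen=True)
class DegreeTargets:
    """Target degree-fraction vectors: d_p[k-1] is the desired fraction of
    nodes with degree k under the power law, d_e[k-1] under the exponential
    law for miRNA out-degrees.  Both are normalized over k = 1..k_max."""

    d_p: np.ndarray
    d_e: np.ndarray

    @property
    def k_max(self) -> int:
        return len(self.d_p)


def sample_degree_targets(config: NetworkConfig) -> DegreeTargets:
    """Normalized target fractions over degrees 1..(n_genes + n_mirnas)."""
    if not config.alpha > 0:
        raise ValueError("alpha must be > 0")
    if not config.lambda_ > 0:
        raise ValueError("lambda_ must be > 0")
    k_max = config.n_genes + config.n_mirnas
    k = np.arange(1, k_max + 1, dtype=float)
    d_p = k ** (-config.alpha)
    d_p /= d_p.sum()
    # exponential pmf over k >= 1; computed in log space to dodge underflow of the sum
    log_e = -config.lambda_ * k
    log_e -= log_e.max()
    d_e = np.exp(log_e)
    d_e /= d_e.sum()
    return DegreeTargets(d_p=d_p, d_e=d_e)


@dataclass
class DegreeState:
    """Current degree-fraction snapshot of a growing network.

    p[k-1] is the fraction of all (gene+miRNA) nodes with total degree k;
    p_in / p_out are the analogous fractions over miRNA nodes for in/out
    degree.  Hypothetical fractions after a candidate assignment are derived
    on the fly by moving one node between two degree bins.
    """

    n_total: int
    n_mirnas: int
    p: np.ndarray
    p_in: np.ndarray
    p_out: np.ndarray
    deg: Dict[str, int]
    in_deg: Dict[str, int]
    out_deg: Dict[str, int]

    @classmethod
    def from_network(cls, graph: nx.DiGraph) -> "DegreeState":
        nodes = [n for n, d in graph.nodes(data=True) if d.get("kind") != SIGNAL]
        n_total = len(nodes)
        k_max = n_total
        deg = {n: graph.degree(n) for n in nodes}
        in_deg = {n: graph.in_degree(n) for n in nodes}
        out_deg = {n: graph.out_degree(n) for n in nodes}
        mirnas = [n for n in nodes if graph.nodes[n]["kind"] == MIRNA]
        n_mirnas = len(mirnas)

        def fractions(values: Sequence[int], denom: int) -> np.ndarray:
            counts = np.zeros(k_max, dtype=float)
            for v in values:
                if 1 <= v <= k_max:
                    counts[v - 1] += 1
            return counts / denom if denom else counts

        return cls(
            n_total=n_total,
            n_mirnas=n_mirnas,
            p=fractions([deg[n] for n in nodes], n_total),
            p_in=fractions([in_deg[n] for n in mirnas], n_mirnas),
            p_out=fractions([out_deg[n] for n in mirnas], n_mirnas),
            deg=deg,
            in_deg=in_deg,
            out_deg=out_deg,
        )


def _move_terms(
    k_vals: np.ndarray,
    changes: np.ndarray,
    d: np.ndarray,
    p: np.ndarray,
) -> np.ndarray:
    """Score contribution of degree bins whose hypothetical fraction f
    differs from the current fraction p by `changes`:

        sign(|d_k - p_k| - |d_k - f_k|) * |d_k - p_k| / d_k

    Bins outside 1..k_max or with zero target fraction contribute nothing.
    """
    k_max = min(len(d), len(p))
    k_vals = np.asarray(k_vals)
    valid = (k_vals >= 1) & (k_vals <= k_max)
    idx = np.where(valid, k_vals - 1, 0)
    dk = d[idx]
    pk = p[idx]
    fk = pk + changes
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.sign(np.abs(dk - pk) - np.abs(dk - fk)) * np.abs(dk - pk) / dk
    term = np.where(valid & (dk > 0), term, 0.0)
    return term


def _subscores_1d(
    degrees: np.ndarray,
    delta: int,
    d: np.ndarray,
    p: np.ndarray,
    move: float,
) -> np.ndarray:
    """Vector of sub-scores for moving each candidate from degree bin
    `degrees` to `degrees + delta`, where a move shifts fraction `move`
    between the two bins."""
    degrees = np.asarray(degrees, dtype=int)
    if delta == 0 or move == 0:
        return np.zeros(len(degrees))
    old_terms = _move_terms(degrees, np.full(len(degrees), -move), d, p)
    new_terms = _move_terms(degrees + delta, np.full(len(degrees), +move), d, p)
    return old_terms + new_terms


def gene_subscore(
    degree: int, delta: int, targets: DegreeTargets, state: DegreeState
) -> float:
    """Sub-score of granting a gene of current total degree `degree` the
    connections of a motif slot with `delta` incident template edges.

    Positive when the move shifts the total-degree distribution toward the
    power-law target; summed over every degree bin (only the two bins the
    move touches contribute)."""
    if state.n_total == 0:
        return 0.0
    return float(
        _subscores_1d(np.array([degree]), delta, targets.d_p, state.p, 1.0 / state.n_total)[0]
    )


def gene_subscores(
    degrees: Sequence[int], delta: int, targets: DegreeTargets, state: DegreeState
) -> np.ndarray:
    if state.n_total == 0:
        return np.zeros(len(degrees))
    return _subscores_1d(np.asarray(degrees, dtype=int), delta, targets.d_p, state.p, 1.0 / state.n_total)


def mirna_subscore(
    in_degree: int,
    out_degree: int,
    delta_in: int,
    delta_out: int,
    targets: DegreeTargets,
    state: DegreeState,
) -> float:
    """Sub-score for a miRNA candidate: in-degree chased against the power
    law (number of regulators of the miRNA), out-degree against the
    exponential law (size of its target regulon)."""
    if state.n_mirnas == 0:
        return 0.0
    move = 1.0 / state.n_mirnas
    s_in = _subscores_1d(np.array([in_degree]), delta_in, targets.d_p, state.p_in, move)[0]
    s_out = _subscores_1d(np.array([out_degree]), delta_out, targets.d_e, state.p_out, move)[0]
    return float(s_in + s_out)


def mirna_subscores(
    in_degrees: Sequence[int],
    out_degrees: Sequence[int],
    delta_in: int,
    delta_out: int,
    targets: DegreeTargets,
    state: DegreeState,
) -> np.ndarray:
    if state.n_mirnas == 0:
        return np.zeros(len(in_degrees))
    move = 1.0 / state.n_mirnas
    s_in = _subscores_1d(np.asarray(in_degrees, dtype=int), delta_in, targets.d_p, state.p_in, move)
    s_out = _subscores_1d(np.asarray(out_degrees, dtype=int), delta_out, targets.d_e, state.p_out, move)
    return s_in + s_out


def motif_score(
    template: MotifTemplate,
    available: Sequence[str],
    graph: nx.DiGraph,
    targets: DegreeTargets,
    state: DegreeState,
) -> float:
    """Total motif score: the sum of gene sub-scores over (available gene) x
    (gene slot) pairs plus miRNA sub-scores over (available miRNA) x
    (miRNA slot) pairs."""
    genes = [n for n in available if graph.nodes[n]["kind"] == GENE]
    mirnas = [n for n in available if graph.nodes[n]["kind"] == MIRNA]
    total = 0.0
    if genes:
        gene_degs = np.array([state.deg[n] for n in genes])
        for slot in template.gene_slots():
            total += gene_subscores(gene_degs, template.slot_degree(slot.name), targets, state).sum()
    if mirnas:
        in_degs = np.array([state.in_deg[n] for n in mirnas])
        out_degs = np.array([state.out_deg[n] for n in mirnas])
        for slot in template.mirna_slots():
            total += mirna_subscores(
                in_degs,
                out_degs,
                template.slot_in_degree(slot.name),
                template.slot_out_degree(slot.name),
                targets,
                state,
            ).sum()
    return float(total)


def proportional_weights(scores: Sequence[float]) -> np.ndarray:
    """Non-negative sampling weights proportional to possibly-signed scores.

    Scores are shifted up only when the minimum is negative; a small epsilon
    keeps all-zero pools uniform and every candidate reachable."""
    s = np.asarray(scores, dtype=float)
    w = s - min(s.min(), 0.0) + _EPS
    return w / w.sum()


def select_motif(
    pool: Sequence[MotifTemplate], scores: Sequence[float], rng: np.random.Generator
) -> int:
    """Index of the selected motif, drawn proportionally to shifted scores."""
    if len(pool) == 0:
        raise ValueError("motif pool is empty")
    if len(pool) != len(scores):
        raise ValueError("pool and scores length mismatch")
    return int(rng.choice(len(pool), p=proportional_weights(scores)))


@dataclass
class RegulatoryNetwork:
    """Ground-truth regulatory network: a directed graph whose nodes carry a
    ``kind`` attribute (gene / mirna / signal) and whose edges carry a sign,
    per-edge Hill parameters and motif provenance."""

    graph: nx.DiGraph
    config: NetworkConfig
    provenance: List[dict] = field(default_factory=list)

    def nodes_of_kind(self, kind: str) -> List[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == kind)

    @property
    def genes(self) -> List[str]:
        return self.nodes_of_kind(GENE)

    @property
    def mirnas(self) -> List[str]:
        return self.nodes_of_kind(MIRNA)

    @property
    def signals(self) -> List[str]:
        return self.nodes_of_kind(SIGNAL)


def _sample_hill(rng: np.random.Generator, dyn: DynamicsConfig) -> Tuple[float, float]:
    theta = float(rng.uniform(*dyn.theta_range))
    mu = float(rng.uniform(*dyn.mu_range))
    return theta, mu


def instantiate_motif(
    template: MotifTemplate,
    net: RegulatoryNetwork,
    available: Set[str],
    targets: DegreeTargets,
    state: DegreeState,
    rng: np.random.Generator,
    level: int,
    dyn: DynamicsConfig,
) -> Tuple[Set[str], Set[str]]:
    """Wire one motif instance into the network.

    Slots are filled one at a time (x first) by sampling available nodes of
    the slot's kind proportionally to their shifted sub-scores.  Slots whose
    kind has no remaining candidates are dropped (partial-motif fallback),
    which guarantees at least one node is consumed whenever any slot kind is
    available.  Returns (consumed nodes, nodes that took the x role).
    """
    graph = net.graph
    assignment: Dict[str, str] = {}
    taken: Set[str] = set()
    slots = sorted(template.slots, key=lambda s: not s.is_x)  # x slot first
    for slot in slots:
        candidates = sorted(
            n for n in available if graph.nodes[n]["kind"] == slot.kind and n not in taken
        )
        if not candidates:
            continue
        if slot.kind == GENE:
            degs = np.array([state.deg[n] for n in candidates])
            scores = gene_subscores(degs, template.slot_degree(slot.name), targets, state)
        else:
            in_degs = np.array([state.in_deg[n] for n in candidates])
            out_degs = np.array([state.out_deg[n] for n in candidates])
            scores = mirna_subscores(
                in_degs,
                out_degs,
                template.slot_in_degree(slot.name),
                template.slot_out_degree(slot.name),
                targets,
                state,
            )
        pick = candidates[int(rng.choice(len(candidates), p=proportional_weights(scores)))]
        assignment[slot.name] = pick
        taken.add(pick)

    edges_added = []
    for src_slot, dst_slot, sign in template.edges:
        if src_slot not in assignment or dst_slot not in assignment:
            continue
        u, v = assignment[src_slot], assignment[dst_slot]
        if u == v and template.name != "autoregulation":
            continue  # self-loops only via the autoregulation template
        if graph.has_edge(u, v):
            continue  # duplicate edges silently skipped; first writer wins
        theta, mu = _sample_hill(rng, dyn)
        graph.add_edge(
            u,
            v,
            sign=sign,
            theta=theta,
            mu=mu,
            motif=template.name,
            level=level,
        )
        edges_added.append([u, sign, v])

    consumed = set(assignment.values())
    x_nodes = set()
    x_name = template.x_slot.name
    if x_name in assignment:
        x_nodes.add(assignment[x_name])
    net.provenance.append(
        {
            "instance": len(net.provenance),
            "template": template.name,
            "level": level,
            "assignment": dict(sorted(assignment.items())),
            "edges": edges_added,
        }
    )
    return consumed, x_nodes


def build_network(
    config: NetworkConfig,
    dynamics: Optional[DynamicsConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> RegulatoryNetwork:
    """Grow a hierarchically modular gene+miRNA network and attach signals.

    Iterates motif replication until the available set V_N and the recycled
    regulator set H are both empty.  Each recycling round strictly shrinks
    the node pool (enforced by a stall guard for the pathological case where
    a whole round produced only single-slot motifs), so construction always
    terminates.
    """
    dyn = dynamics or DynamicsConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng

    graph = nx.DiGraph()
    for i in range(config.n_genes):
        graph.add_node(f"g{i:04d}", kind=GENE)
    for i in range(config.n_mirnas):
        graph.add_node(f"m{i:04d}", kind=MIRNA)
    net = RegulatoryNetwork(graph=graph, config=config)
    targets = sample_degree_targets(config)

    pool_nodes = sorted(graph.nodes)
    level = 0
    while pool_nodes:
        round_start = len(pool_nodes)
        remaining: Set[str] = set(pool_nodes)
        recycled: List[str] = []
        while remaining:
            state = DegreeState.from_network(graph)
            kinds_here = {graph.nodes[n]["kind"] for n in remaining}
            pool = []
            for _ in range(config.pool_size):
                t = sample_template(rng, kinds_here)
                if t.slot_kinds() & kinds_here:
                    pool.append(t)
            if not pool:
                raise RuntimeError("no instantiable motif template")  # pragma: no cover
            avail_list = sorted(remaining)
            scores = [motif_score(t, avail_list, graph, targets, state) for t in pool]
            template = pool[select_motif(pool, scores, rng)]
            consumed, x_nodes = instantiate_motif(
                template, net, remaining, targets, state, rng, level, dyn
            )
            if not consumed:  # template had no fillable slot; consume nothing, retry
                continue
            remaining -= consumed
            recycled.extend(sorted(x_nodes))
        if len(recycled) >= round_start:
            # every motif this round was single-slot: recycling cannot shrink
            # the pool any further, so stop (the nodes are already wired).
            break
        pool_nodes = sorted(set(recycled))
        level += 1

    if config.n_signals:
        add_signalling_nodes(net, config.n_signals, rng, dyn)
    return net


def signal_target_weights(graph: nx.DiGraph) -> Tuple[List[str], np.ndarray]:
    """Candidate targets for signalling edges and their sampling weights.

    Weights are out-degree + 1: proportional-to-out-degree targeting biased
    toward hubs, smoothed so leaves stay reachable."""
    nodes = sorted(n for n, d in graph.nodes(data=True) if d["kind"] != SIGNAL)
    if not nodes:
        raise ValueError("cannot attach signalling nodes to an empty network")
    w = np.array([graph.out_degree(n) + 1.0 for n in nodes])
    return nodes, w / w.sum()


def add_signalling_nodes(
    net: RegulatoryNetwork,
    n_signals: int,
    rng: np.random.Generator,
    dynamics: Optional[DynamicsConfig] = None,
) -> RegulatoryNetwork:
    """Attach exogenous signalling nodes: outgoing edges only, targets drawn
    proportionally to (out-degree + 1), 1-3 targets per signal."""
    dyn = dynamics or DynamicsConfig()
    if n_signals == 0:
        return net
    graph = net.graph
    nodes, weights = signal_target_weights(graph)
    for i in range(n_signals):
        sid = f"s{i:03d}"
        graph.add_node(sid, kind=SIGNAL)
        n_targets = int(rng.integers(1, 4))
        n_targets = min(n_targets, len(nodes))
        chosen = rng.choice(len(nodes), size=n_targets, replace=False, p=weights)
        for c in chosen:
            theta, mu = _sample_hill(rng, dyn)
            graph.add_edge(sid, nodes[int(c)], sign=ACTIVATION, theta=theta, mu=mu,
                           motif="signal", level=-1)
    return net
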