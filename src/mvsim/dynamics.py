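"""ODE right-hand sides: Hill regulation, combinator trees, miRNA degradation.

Each gene's concentration x_i obeys

    dx_i/dt = p_i * r_i(regulators) - d_i(miRNAs) * x_i

where r_i in [0,1] is a composition tree of Hill functions joined by the
four regulator-interaction combinators (COOP = min, SYN = capped sum,
INH = complement, COMP = clamped difference), and the degradation rate

    d_i = d_i0 + d_gain * SYN(h(m_1), ..., h(m_q))

rises with the repressing miRNAs (synergistic inhibition).  miRNAs follow
the same production law but degrade at the constant basal rate.  Signalling
nodes are exogenous inputs: their trajectories feed Hill leaves but they are
not state variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np

from .motifs import ACTIVATION, GENE, MIRNA, REPRESSION, SIGNAL

COOP = "COOP"
SYN = "SYN"
INH = "INH"
COMP = "COMP"


@dataclass(frozen=True)
class HillParams:
    """Threshold theta (concentration at half-activation) and steepness mu."""

    theta: float
    mu: float

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be > 0")
        if not self.mu > 0:
            raise ValueError("mu must be > 0")


@dataclass(frozen=True)
class KineticParams:
    """Basal production rate p, basal degradation rate d0, and the gain of
    miRNA-dependent degradation (0 for nodes without miRNA regulators)."""

    production: float
    basal_degradation: float
    mirna_degradation_gain: float = 0.0

    def __post_init__(self) -> None:
        if not self.production > 0:
            raise ValueError("production must be > 0")
        if not self.basal_degradation > 0:
            raise ValueError("basal_degradation must be > 0")
        if self.mirna_degradation_gain < 0:
            raise ValueError("mirna_degradation_gain must be >= 0")


def hill(x, theta: float, mu: float):
    """Hill function h(x; theta, mu) = x^mu / (x^mu + theta^mu).

    Monotone non-decreasing, h(0) = 0, h(theta) = 0.5, h -> 1 as x -> inf.
    Sigmoid for mu > 1.  Raises on negative concentrations.
    """
    if not theta > 0:
        raise ValueError("theta must be > 0")
    if not mu > 0:
        raise ValueError("mu must be > 0")
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentration must be non-negative")
    # h = 1 / (1 + (theta/x)^mu): algebraically identical to the ratio form
    # but exact at x == theta (the ratio is exactly 1) and immune to x^mu
    # overflow for large concentrations
    with np.errstate(divide="ignore"):
        out = np.where(arr > 0, 1.0 / (1.0 + (theta / np.where(arr > 0, arr, 1.0)) ** mu), 0.0)
    return float(out) if np.isscalar(x) else out


def coop(values: Sequence[float]) -> float:
    """Cooperation: all regulators must be active (minimum)."""
    if len(values) == 0:
        raise ValueError("COOP requires at least one input")
    return float(min(values))


def syn(values: Sequence[float]) -> float:
    """Synergy: any regulator suffices (sum capped at 1; empty sum is 0)."""
    return float(min(1.0, sum(values)))


def inh(value: float) -> float:
    """Inhibition: complement of a single regulator's activity."""
    return float(1.0 - value)


def comp(activator: float, repressor: float) -> float:
    """Competition: activator activity net of the repressor, clamped at 0."""
    return float(max(0.0, activator - repressor))


# --- composition trees -----------------------------------------------------


@dataclass(frozen=True)
class HillLeaf:
    source: str
    params: HillParams


@dataclass(frozen=True)
class ConstLeaf:
    value: float = 1.0


@dataclass(frozen=True)
class OpNode:
    op: str
    children: tuple

    def __post_init__(self) -> None:
        if self.op not in (COOP, SYN, INH, COMP):
            raise ValueError(f"unknown combinator {self.op!r}")
        if self.op == INH and len(self.children) != 1:
            raise ValueError("INH takes exactly one child")
        if self.op == COMP and len(self.children) != 2:
            raise ValueError("COMP takes exactly two children")
        if self.op in (COOP, SYN) and len(self.children) < 1:
            raise ValueError(f"{self.op} takes at least one child")


ProductionTree = Union[HillLeaf, ConstLeaf, OpNode]


def evaluate_tree(tree: ProductionTree, concentrations: Mapping[str, float]) -> float:
    """Evaluate a production tree against a node-id -> concentration map.

    Maps [0,1]-valued leaves through [0,1]-preserving combinators, so the
    result is always in [0,1] (ConstLeaf values are fixed at construction
    to lie in [0,1])."""
    if isinstance(tree, ConstLeaf):
        return float(tree.value)
    if isinstance(tree, HillLeaf):
        return float(hill(concentrations[tree.source], tree.params.theta, tree.params.mu))
    vals = [evaluate_tree(c, concentrations) for c in tree.children]
    if tree.op == COOP:
        return coop(vals)
    if tree.op == SYN:
        return syn(vals)
    if tree.op == INH:
        return inh(vals[0])
    return comp(vals[0], vals[1])


def tree_leaves(tree: ProductionTree) -> List[HillLeaf]:
    if isinstance(tree, HillLeaf):
        return [tree]
    if isinstance(tree, ConstLeaf):
        return []
    out: List[HillLeaf] = []
    for c in tree.children:
        out.extend(tree_leaves(c))
    return out


@dataclass
class RegulationModel:
    """Per-node ODE ingredients: a production tree over gene/signal
    regulators, the list of repressing miRNAs (each with its own Hill
    parameters, entering the degradation term only), and kinetic rates."""

    node: str
    production: ProductionTree
    mirna_inputs: Tuple[Tuple[str, HillParams], ...]
    kinetics: KineticParams


def degradation_rate(
    m_values: Sequence[float],
    kinetics: KineticParams,
    mirna_hills: Sequence[HillParams],
) -> float:
    """Degradation rate d0 + gain * SYN(h(m_1), ..., h(m_q)).

    Equals d0 with no (or silent) miRNAs and saturates at d0 + gain when the
    synergistic inhibition caps out."""
    if len(m_values) != len(mirna_hills):
        raise ValueError("m_values and mirna_hills length mismatch")
    d0 = kinetics.basal_degradation
    if not m_values:
        return d0
    hs = [hill(m, p.theta, p.mu) for m, p in zip(m_values, mirna_hills)]
    return d0 + kinetics.mirna_degradation_gain * syn(hs)


def node_derivative(
    model: RegulationModel,
    kind: str,
    x_i: float,
    concentrations: Mapping[str, float],
) -> float:
    """Time derivative of one node's concentration.

    Genes: p * r(regulators) - (d0 + gain*SYN(h(m))) * x.
    miRNAs: same production law, constant basal degradation.
    """
    if x_i < 0:
        raise ValueError("state must be non-negative")
    prod = model.kinetics.production * evaluate_tree(model.production, concentrations)
    if kind == MIRNA:
        return prod - model.kinetics.basal_degradation * x_i
    m_values = [concentrations[src] for src, _ in model.mirna_inputs]
    d = degradation_rate(m_values, model.kinetics, [p for _, p in model.mirna_inputs])
    return prod - d * x_i


# --- random model sampling --------------------------------------------------


def sample_regulation_model(
    node: str,
    kind: str,
    in_edges: Sequence[Tuple[str, str, str, float, float]],
    rng: np.random.Generator,
    dyn_config,
) -> RegulationModel:
    """Draw a regulation model for one node given its in-edges.

    ``in_edges`` holds (source, source_kind, sign, theta, mu) tuples, the
    Hill parameters having been sampled per-edge at network construction.
    miRNA regulators of genes go to the degradation term.  Gene/signal
    activators become Hill leaves; repressors enter either as the second
    argument of a COMP wrapped around an existing subtree (half of the time,
    when a subtree is available) or as INH leaves.  Subtrees are then merged
    pairwise by COOP or SYN chosen uniformly, giving a random binary
    composition in which every in-edge appears exactly once.
    """
    mirna_inputs: List[Tuple[str, HillParams]] = []
    activators: List[Tuple[str, HillParams]] = []
    repressors: List[Tuple[str, HillParams]] = []
    for source, source_kind, sign, theta, mu in in_edges:
        params = HillParams(theta=theta, mu=mu)
        if source_kind == MIRNA and kind == GENE:
            mirna_inputs.append((source, params))
        elif sign == REPRESSION:
            repressors.append((source, params))
        else:
            activators.append((source, params))

    subtrees: List[ProductionTree] = [HillLeaf(s, p) for s, p in activators]
    for source, params in repressors:
        leaf = HillLeaf(source, params)
        if subtrees and rng.random() < 0.5:
            i = int(rng.integers(0, len(subtrees)))
            subtrees[i] = OpNode(COMP, (subtrees[i], leaf))
        else:
            subtrees.append(OpNode(INH, (leaf,)))
    if not subtrees:
        production: ProductionTree = ConstLeaf(1.0)
    else:
        while len(subtrees) > 1:
            i, j = rng.choice(len(subtrees), size=2, replace=False)
            i, j = int(i), int(j)
            op = COOP if rng.random() < 0.5 else SYN
            merged = OpNode(op, (subtrees[i], subtrees[j]))
            subtrees = [t for k, t in enumerate(subtrees) if k not in (i, j)]
            subtrees.append(merged)
        production = subtrees[0]

    d0 = float(rng.uniform(*dyn_config.d0_range))
    p = float(rng.uniform(*dyn_config.p_rel_range)) * d0
    gain = float(rng.uniform(*dyn_config.d_gain_rel_range)) * d0
    if not mirna_inputs:
        gain = 0.0
    return RegulationModel(
        node=node,
        production=production,
        mirna_inputs=tuple(mirna_inputs),
        kinetics=KineticParams(
            production=p, basal_degradation=d0, mirna_degradation_gain=gain
        ),
    )


# --- whole-system model -----------------------------------------------------


@dataclass
class SystemModel:
    """Ordered state vector (genes then miRNAs), one RegulationModel per
    state node, and the list of exogenous signal nodes."""

    nodes: Tuple[str, ...]
    kinds: Tuple[str, ...]
    models: Dict[str, RegulationModel]
    signals: Tuple[str, ...]

    @property
    def n_state(self) -> int:
        return len(self.nodes)

    def gene_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == GENE], dtype=int)

    def mirna_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == MIRNA], dtype=int)


def build_system_model(network, rng: np.random.Generator, dyn_config=None) -> SystemModel:
    """Sample a full dynamical model for a RegulatoryNetwork."""
    from .config import DynamicsConfig

    dyn = dyn_config or DynamicsConfig()
    graph = network.graph
    nodes = tuple(network.genes + network.mirnas)
    kinds = tuple(graph.nodes[n]["kind"] for n in nodes)
    models: Dict[str, RegulationModel] = {}
    for node, kind in zip(nodes, kinds):
        in_edges = [
            (u, graph.nodes[u]["kind"], d["sign"], d["theta"], d["mu"])
            for u, _, d in graph.in_edges(node, data=True)
        ]
        in_edges.sort(key=lambda e: e[0])
        models[node] = sample_regulation_model(node, kind, in_edges, rng, dyn)
    return SystemModel(
        nodes=nodes, kinds=kinds, models=models, signals=tuple(network.signals)
    )


def system_derivative(
    system: SystemModel,
    state: np.ndarray,
    signal_values: Mapping[str, float],
) -> np.ndarray:
    """Reference (unoptimized) right-hand side evaluated node by node."""
    conc = {n: float(max(x, 0.0)) for n, x in zip(system.nodes, state)}
    conc.update({s: float(v) for s, v in signal_values.items()})
    for s in system.signals:
        conc.setdefault(s, 0.0)
    out = np.empty(system.n_state)
    for i, (n, k) in enumerate(zip(system.nodes, system.kinds)):
        out[i] = node_derivative(system.models[n], k, conc[n], conc)
    return out


# --- serialization ----------------------------------------------------------


def _tree_to_dict(tree: ProductionTree) -> dict:
    if isinstance(tree, HillLeaf):
        return {
            "type": "hill",
            "source": tree.source,
            "theta": tree.params.theta,
            "mu": tree.params.mu,
        }
    if isinstance(tree, ConstLeaf):
        return {"type": "const", "value": tree.value}
    return {"type": "op", "op": tree.op, "children": [_tree_to_dict(c) for c in tree.children]}


def _tree_from_dict(d: dict) -> ProductionTree:
    t = d["type"]
    if t == "hill":
        return HillLeaf(d["source"], HillParams(d["theta"], d["mu"]))
    if t == "const":
        return ConstLeaf(d["value"])
    if t == "op":
        return OpNode(d["op"], tuple(_tree_from_dict(c) for c in d["children"]))
    raise ValueError(f"unknown tree node type {t!r}")


def system_to_dict(system: SystemModel) -> dict:
    return {
        "nodes": list(system.nodes),
        "kinds": list(system.kinds),
        "signals": list(system.signals),
        "models": {
            n: {
                "production": _tree_to_dict(m.production),
                "mirna_inputs": [
                    {"source": s, "theta": p.theta, "mu": p.mu}
                    for s, p in m.mirna_inputs
                ],
                "kinetics": {
                    "production": m.kinetics.production,
                    "basal_degradation": m.kinetics.basal_degradation,
                    "mirna_degradation_gain": m.kinetics.mirna_degradation_gain,
                },
            }
            for n, m in system.models.items()
        },
    }


def system_from_dict(d: dict) -> SystemModel:
    models = {}
    for n, md in d["models"].items():
        kin = md["kinetics"]
        models[n] = RegulationModel(
            node=n,
            production=_tree_from_dict(md["production"]),
            mirna_inputs=tuple(
                (mi["source"], HillParams(mi["theta"], mi["mu"]))
                for mi in md["mirna_inputs"]
            ),
            kinetics=KineticParams(
                production=kin["production"],
                basal_degradation=kin["basal_degradation"],
                mirna_degradation_gain=kin["mirna_degradation_gain"],
            ),
        )
    return SystemModel(
        nodes=tuple(d["nodes"]),
        kinds=tuple(d["kinds"]),
        models=models,
        signals=tuple(d["signals"]),
    )
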