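"""Numerical integration and multi-subject dataset generation.

The ODE system is integrated with an adaptive stiff-capable solver (LSODA,
falling back to BDF) over a fixed time grid under per-condition signal
programs.  Steady-state expression is read off at the last simulated time
point.  A dataset is produced subject by subject: jitter the model
parameters (biological variability), integrate, sample the last time point,
and finally apply measurement noise, yielding one matrix per molecular view
(genes, miRNAs) over the same subjects.

For speed the per-node composition trees are flattened once into an
instruction list over a scratch buffer; every right-hand-side evaluation
then does one vectorized Hill evaluation for all regulatory edges followed
by a linear pass over the instructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import ConditionSpec, NoiseConfig, SimulationConfig
from .dynamics import (
    COMP,
    COOP,
    INH,
    SYN,
    ConstLeaf,
    HillLeaf,
    OpNode,
    SystemModel,
)
from .motifs import GENE, MIRNA
from .noise import jitter_parameters, measure

# --- signal programs --------------------------------------------------------


def _const_fn(value: float) -> Callable[[float], float]:
    return lambda t: value


def _periodic_fn(amplitude: float, period: float, waveform: str, offset: float):
    if waveform == "sine":
        return lambda t: offset + 0.5 * amplitude * (1.0 + math.sin(2.0 * math.pi * t / period))
    if waveform == "square":
        return lambda t: offset + (amplitude if math.sin(2.0 * math.pi * t / period) >= 0 else 0.0)
    raise ValueError(f"unknown waveform {waveform!r}")


def _custom_fn(times: Sequence[float], values: Sequence[float]):
    t_arr = np.asarray(times, dtype=float)
    v_arr = np.asarray(values, dtype=float)
    return lambda t: float(np.interp(t, t_arr, v_arr))


@dataclass
class SignalProgram:
    """Resolved per-signal trajectories for one condition.

    ``functions`` maps signal ids to callables of time; ``record`` keeps the
    resolved spec (including values drawn for ``random_constant`` signals)
    as ground-truth annotation.  Signals without an entry are held at 0.
    """

    functions: Dict[str, Callable[[float], float]] = field(default_factory=dict)
    record: Dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_condition(
        cls,
        signal_specs: Mapping[str, Mapping],
        signal_nodes: Sequence[str],
        rng: Optional[np.random.Generator] = None,
    ) -> "SignalProgram":
        default = signal_specs.get("*")
        functions: Dict[str, Callable[[float], float]] = {}
        record: Dict[str, dict] = {}
        for node in signal_nodes:
            spec = signal_specs.get(node, default)
            if spec is None:
                spec = {"type": "zero"}
            spec = dict(spec)
            kind = spec.get("type", "constant")
            if kind == "zero":
                fn = _const_fn(0.0)
                spec = {"type": "constant", "value": 0.0}
            elif kind == "constant":
                value = float(spec["value"])
                if value < 0:
                    raise ValueError("signal values must be >= 0")
                fn = _const_fn(value)
            elif kind == "random_constant":
                if rng is None:
                    raise ValueError("random_constant signal needs a generator")
                lo = float(spec.get("low", 0.0))
                hi = float(spec.get("high", 1.0))
                value = float(rng.uniform(lo, hi))
                fn = _const_fn(value)
                spec = {"type": "constant", "value": value, "sampled_from": [lo, hi]}
            elif kind == "periodic":
                amplitude = float(spec.get("amplitude", 1.0))
                period = float(spec.get("period", 10.0))
                offset = float(spec.get("offset", 0.0))
                waveform = spec.get("waveform", "sine")
                if amplitude < 0 or offset < 0 or period <= 0:
                    raise ValueError("periodic signal needs amplitude,offset >= 0 and period > 0")
                fn = _periodic_fn(amplitude, period, waveform, offset)
            elif kind == "custom":
                fn = _custom_fn(spec["times"], spec["values"])
                if min(spec["values"]) < 0:
                    raise ValueError("signal values must be >= 0")
            else:
                raise ValueError(f"unknown signal spec type {kind!r}")
            functions[node] = fn
            record[node] = spec
        return cls(functions=functions, record=record)

    def values_at(self, t: float, order: Sequence[str]) -> List[float]:
        return [self.functions[s](t) if s in self.functions else 0.0 for s in order]


# --- compiled right-hand side ----------------------------------------------

_OP_LOADH, _OP_CONST, _OP_COOP, _OP_SYN, _OP_INH, _OP_COMP = range(6)


class CompiledSystem:
    """Flattened evaluation plan for a SystemModel's right-hand side."""

    def __init__(self, system: SystemModel):
        self.system = system
        n = system.n_state
        index = {node: i for i, node in enumerate(system.nodes)}
        for j, s in enumerate(system.signals):
            index[s] = n + j
        self.n_signals = len(system.signals)

        edge_src: List[int] = []
        edge_theta: List[float] = []
        edge_mu: List[float] = []

        def add_edge(source: str, theta: float, mu: float) -> int:
            edge_src.append(index[source])
            edge_theta.append(theta)
            edge_mu.append(mu)
            return len(edge_src) - 1

        instructions: List[Tuple[int, int, int, int]] = []
        slot_counter = 0

        def new_slot() -> int:
            nonlocal slot_counter
            slot_counter += 1
            return slot_counter - 1

        def compile_tree(tree) -> int:
            if isinstance(tree, HillLeaf):
                e = add_edge(tree.source, tree.params.theta, tree.params.mu)
                s = new_slot()
                instructions.append((_OP_LOADH, s, e, 0))
                return s
            if isinstance(tree, ConstLeaf):
                s = new_slot()
                instructions.append((_OP_CONST, s, 0, 0))
                return s
            child_slots = [compile_tree(c) for c in tree.children]
            op = {COOP: _OP_COOP, SYN: _OP_SYN, INH: _OP_INH, COMP: _OP_COMP}[tree.op]
            if op == _OP_INH:
                s = new_slot()
                instructions.append((op, s, child_slots[0], 0))
                return s
            if op == _OP_COMP:
                s = new_slot()
                instructions.append((op, s, child_slots[0], child_slots[1]))
                return s
            # n-ary COOP/SYN folded into a binary chain (both are associative
            # under the cap: min(1, a + min(1, b+c)) == min(1, a+b+c))
            acc = child_slots[0]
            for cs in child_slots[1:]:
                s = new_slot()
                instructions.append((op, s, acc, cs))
                acc = s
            return acc

        prod_slots = np.empty(n, dtype=int)
        deg_slots = np.full(n, -1, dtype=int)
        p = np.empty(n)
        d0 = np.empty(n)
        gain = np.zeros(n)
        for i, node in enumerate(system.nodes):
            model = system.models[node]
            prod_slots[i] = compile_tree(model.production)
            p[i] = model.kinetics.production
            d0[i] = model.kinetics.basal_degradation
            if system.kinds[i] == GENE and model.mirna_inputs:
                gain[i] = model.kinetics.mirna_degradation_gain
                acc = None
                for src, params in model.mirna_inputs:
                    e = add_edge(src, params.theta, params.mu)
                    s = new_slot()
                    instructions.append((_OP_LOADH, s, e, 0))
                    if acc is None:
                        acc = s
                    else:
                        s2 = new_slot()
                        instructions.append((_OP_SYN, s2, acc, s))
                        acc = s2
                deg_slots[i] = acc

        self.edge_src = np.asarray(edge_src, dtype=int)
        self.edge_mu = np.asarray(edge_mu)
        self.edge_theta_pow = np.asarray(edge_theta) ** self.edge_mu
        self.instructions = instructions
        self.n_slots = slot_counter
        self.prod_slots = prod_slots
        self.deg_slots = deg_slots
        self.deg_mask = deg_slots >= 0
        self.deg_slots_safe = np.where(self.deg_mask, deg_slots, 0)
        self.p = p
        self.d0 = d0
        self.gain = gain

    def rhs(self, t: float, y: np.ndarray, signal_fns: Sequence[Callable]) -> np.ndarray:
        z = np.maximum(y, 0.0)
        if self.n_signals:
            ext = np.concatenate([z, [fn(t) for fn in signal_fns]])
        else:
            ext = z
        xv = ext[self.edge_src]
        xm = xv ** self.edge_mu
        h = (xm / (xm + self.edge_theta_pow)).tolist()
        buf = [0.0] * self.n_slots
        for op, dst, a, b in self.instructions:
            if op == _OP_LOADH:
                buf[dst] = h[a]
            elif op == _OP_CONST:
                buf[dst] = 1.0
            elif op == _OP_COOP:
                va, vb = buf[a], buf[b]
                buf[dst] = va if va < vb else vb
            elif op == _OP_SYN:
                v = buf[a] + buf[b]
                buf[dst] = 1.0 if v > 1.0 else v
            elif op == _OP_INH:
                buf[dst] = 1.0 - buf[a]
            else:  # COMP
                v = buf[a] - buf[b]
                buf[dst] = v if v > 0.0 else 0.0
        buf_arr = np.asarray(buf)
        prod = buf_arr[self.prod_slots]
        degv = np.where(self.deg_mask, buf_arr[self.deg_slots_safe], 0.0)
        return self.p * prod - (self.d0 + self.gain * degv) * z


# --- integration ------------------------------------------------------------


@dataclass
class Trajectory:
    """Simulated time course: times (T,), values (T, n_state) with non
    negative entries, and the matching node/kind ordering."""

    times: np.ndarray
    values: np.ndarray
    nodes: Tuple[str, ...]
    kinds: Tuple[str, ...]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (time, feature, value) table."""
        records = pd.DataFrame(self.values, columns=list(self.nodes))
        records.insert(0, "time", self.times)
        return records.melt(id_vars="time", var_name="feature", value_name="value")


def integrate(
    system: SystemModel,
    initial_state: np.ndarray,
    signals: Optional[SignalProgram],
    t_grid: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    compiled: Optional[CompiledSystem] = None,
) -> Trajectory:
    """Integrate the system over ``t_grid`` and return the trajectory.

    Tries LSODA first; on failure retries the implicit BDF method, then
    raises with the solver diagnostics.  Small negative excursions from the
    solver are clipped to 0 in the returned values.
    """
    y0 = np.asarray(initial_state, dtype=float)
    if y0.shape != (system.n_state,):
        raise ValueError(f"initial state must have length {system.n_state}")
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)
    comp_sys = compiled or CompiledSystem(system)
    signals = signals or SignalProgram()
    fns = [signals.functions.get(s, _const_fn(0.0)) for s in system.signals]

    last_message = ""
    for method in ("LSODA", "BDF"):
        sol = solve_ivp(
            comp_sys.rhs,
            (t_grid[0], t_grid[-1]),
            y0,
            method=method,
            t_eval=t_grid,
            rtol=rtol,
            atol=atol,
            args=(fns,),
        )
        if sol.success:
            values = np.clip(sol.y.T, 0.0, None)
            return Trajectory(
                times=t_grid, values=values, nodes=system.nodes, kinds=system.kinds
            )
        last_message = sol.message
    raise RuntimeError(f"ODE integration failed (LSODA and BDF): {last_message}")


def steady_state_sample(traj: Trajectory) -> Tuple[pd.Series, pd.Series]:
    """Expression at the last simulated time point, split into the gene view
    and the miRNA view (the steady-state one-shot measurement convention)."""
    last = traj.values[-1]
    genes = pd.Series(
        {n: last[i] for i, (n, k) in enumerate(zip(traj.nodes, traj.kinds)) if k == GENE}
    )
    mirnas = pd.Series(
        {n: last[i] for i, (n, k) in enumerate(zip(traj.nodes, traj.kinds)) if k == MIRNA}
    )
    return genes, mirnas


# --- dataset generation -----------------------------------------------------


@dataclass
class ExpressionDataset:
    """Multi-view expression data plus ground truth.

    ``genes`` / ``mirnas`` are observed (noisy) feature x subject matrices
    sharing subject columns and ``labels``; the ``*_true`` twins hold the
    noiseless steady states; ``signal_programs`` records the resolved signal
    values per condition.
    """

    genes: pd.DataFrame
    mirnas: pd.DataFrame
    genes_true: pd.DataFrame
    mirnas_true: pd.DataFrame
    labels: pd.Series
    signal_programs: Dict[str, dict]


def generate_dataset(
    system: SystemModel,
    conditions: Sequence[ConditionSpec],
    noise_config: Optional[NoiseConfig] = None,
    sim_config: Optional[SimulationConfig] = None,
    rng=0,
) -> ExpressionDataset:
    """Simulate a cohort: per subject, jitter parameters, integrate under the
    condition's signal program, take the last time point, then apply
    measurement noise to the assembled views."""
    noise_config = noise_config or NoiseConfig()
    sim_config = sim_config or SimulationConfig()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    t_grid = np.linspace(0.0, sim_config.t_max, sim_config.n_points)
    y0 = np.full(system.n_state, sim_config.initial_value)
    gene_nodes = [n for n, k in zip(system.nodes, system.kinds) if k == GENE]
    mirna_nodes = [n for n, k in zip(system.nodes, system.kinds) if k == MIRNA]
    gene_idx = system.gene_indices()
    mirna_idx = system.mirna_indices()

    columns: List[str] = []
    labels: List[str] = []
    true_cols: List[np.ndarray] = []
    programs: Dict[str, dict] = {}
    for cond in conditions:
        program = SignalProgram.from_condition(cond.signals, system.signals, rng)
        programs[cond.name] = program.record
        for s in range(cond.n_subjects):
            subject_model = jitter_parameters(system, noise_config, rng)
            traj = integrate(
                subject_model,
                y0,
                program,
                t_grid,
                rtol=sim_config.rtol,
                atol=sim_config.atol,
            )
            true_cols.append(traj.values[-1])
            columns.append(f"{cond.name}_{s:03d}")
            labels.append(cond.name)

    if true_cols:
        true_matrix = np.column_stack(true_cols)
    else:
        true_matrix = np.empty((system.n_state, 0))
    genes_true = pd.DataFrame(true_matrix[gene_idx], index=gene_nodes, columns=columns) \
        if len(gene_idx) else pd.DataFrame(index=gene_nodes, columns=columns, dtype=float)
    mirnas_true = pd.DataFrame(true_matrix[mirna_idx], index=mirna_nodes, columns=columns) \
        if len(mirna_idx) else pd.DataFrame(index=mirna_nodes, columns=columns, dtype=float)
    genes_obs = pd.DataFrame(
        measure(genes_true.to_numpy(), noise_config, rng),
        index=gene_nodes,
        columns=columns,
    )
    mirnas_obs = pd.DataFrame(
        measure(mirnas_true.to_numpy(), noise_config, rng),
        index=mirna_nodes,
        columns=columns,
    )
    return ExpressionDataset(
        genes=genes_obs,
        mirnas=mirnas_obs,
        genes_true=genes_true,
        mirnas_true=mirnas_true,
        labels=pd.Series(labels, index=columns, name="condition"),
        signal_programs=programs,
    )
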