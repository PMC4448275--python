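"""Serialization of networks, models and datasets.

Primary outputs are plain, widely readable formats: GraphML for the typed
network (node ``kind``, edge ``sign`` and Hill parameters), a 3-column
SIF-style TSV edge list, JSON for the dynamical model and provenance, and
TSV matrices for the expression views.  Writes go through a temp-file +
rename so a failed run never leaves a half-written primary output.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd

from . import __version__
from .config import RunConfig, run_config_to_dict
from .dynamics import SystemModel, system_from_dict, system_to_dict
from .simulate import ExpressionDataset
from .topology import RegulatoryNetwork
from .config import NetworkConfig


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_graphml(network: RegulatoryNetwork, path) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    nx.write_graphml(network.graph, tmp)
    os.replace(tmp, path)


def read_graphml(path, config: Optional[NetworkConfig] = None) -> RegulatoryNetwork:
    graph = nx.read_graphml(Path(path))
    graph = nx.DiGraph(graph)
    if config is None:
        kinds = [d.get("kind") for _, d in graph.nodes(data=True)]
        config = NetworkConfig(
            n_genes=max(kinds.count("gene"), 1),
            n_mirnas=kinds.count("mirna"),
            n_signals=kinds.count("signal"),
        )
    return RegulatoryNetwork(graph=graph, config=config)


def write_sif(network: RegulatoryNetwork, path) -> None:
    """3-column TSV edge list: source, sign, target."""
    lines = [
        f"{u}\t{d['sign']}\t{v}"
        for u, v, d in sorted(network.graph.edges(data=True))
    ]
    _atomic_write_text(Path(path), "\n".join(lines) + ("\n" if lines else ""))


def write_provenance(network: RegulatoryNetwork, path, seed: Optional[int] = None,
                     run_config: Optional[RunConfig] = None) -> None:
    """Motif-instance log plus everything needed to regenerate the bundle."""
    payload = {
        "mvsim_version": __version__,
        "network_config": dataclasses.asdict(network.config),
        "seed": seed if seed is not None else network.config.seed,
        "motif_instances": network.provenance,
    }
    if run_config is not None:
        payload["run_config"] = run_config_to_dict(run_config)
    _atomic_write_text(Path(path), json.dumps(payload, indent=1))


def write_system_model(system: SystemModel, path) -> None:
    _atomic_write_text(Path(path), json.dumps(system_to_dict(system), indent=1))


def read_system_model(path) -> SystemModel:
    return system_from_dict(json.loads(Path(path).read_text()))


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    frame.to_csv(tmp, sep="\t", index_label=index_label)
    os.replace(tmp, path)


def write_dataset(dataset: ExpressionDataset, prefix, write_true: bool = True) -> list:
    """Write per-view TSV matrices, labels and signal programs under a prefix.

    Returns the list of files written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(frame: pd.DataFrame, suffix: str, index_label: str = "feature"):
        path = prefix.parent / (prefix.name + suffix)
        _write_tsv(frame, path, index_label)
        written.append(path)

    emit(dataset.genes, "_genes.tsv")
    emit(dataset.mirnas, "_mirnas.tsv")
    if write_true:
        emit(dataset.genes_true, "_genes_true.tsv")
        emit(dataset.mirnas_true, "_mirnas_true.tsv")
    emit(dataset.labels.to_frame(), "_labels.tsv", index_label="subject")
    sig_path = prefix.parent / (prefix.name + "_signals.json")
    _atomic_write_text(sig_path, json.dumps(dataset.signal_programs, indent=1))
    written.append(sig_path)
    return written


def read_candidate_edges(path) -> list:
    """Read a 2-column TSV of candidate (source, target) pairs."""
    frame = pd.read_csv(Path(path), sep="\t", header=None, comment="#")
    if frame.shape[1] < 2:
        raise ValueError("candidate edge file needs at least two columns")
    return [(str(r[0]), str(r[1])) for r in frame.itertuples(index=False)]
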