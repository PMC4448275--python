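"""Catalogue of regulatory motif templates.

Transcriptional regulatory networks are built here by replicating small,
recurrent interaction patterns (motifs): autoregulation, feed-forward and
feedback loops, single-input modules, dense overlapping regulons, and their
miRNA-containing variants.  Each template is a tiny directed pattern of
role-labelled slots; exactly one slot carries the ``x`` (master regulator)
role, whose occupant is recycled into the next hierarchy level during
network construction.

Templates are produced by factory functions registered in ``MOTIF_REGISTRY``
so users can extend the catalogue.  Factories may randomize structural
details (fan-out of a single-input module, regulon density, incoherent
feed-forward signs) through the generator they are handed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Tuple

import numpy as np

GENE = "gene"
MIRNA = "mirna"
SIGNAL = "signal"

ACTIVATION = "activation"
REPRESSION = "repression"


@dataclass(frozen=True)
class MotifSlot:
    """A role-labelled position in a motif template."""

    name: str
    kind: str  # GENE or MIRNA
    is_x: bool = False


@dataclass(frozen=True)
class MotifTemplate:
    """A small directed interaction pattern with signed edges.

    ``edges`` are (source slot name, target slot name, sign) triples.
    Invariants enforced at construction: exactly one ``x`` slot, every edge
    signed, and miRNA-source edges always repressive (miRNAs act by raising
    the degradation rate of their targets, never by activating them).
    """

    name: str
    slots: Tuple[MotifSlot, ...]
    edges: Tuple[Tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        n_x = sum(1 for s in self.slots if s.is_x)
        if n_x != 1:
            raise ValueError(f"template {self.name!r} must have exactly one x slot, found {n_x}")
        by_name = {s.name: s for s in self.slots}
        if len(by_name) != len(self.slots):
            raise ValueError(f"template {self.name!r} has duplicate slot names")
        for src, dst, sign in self.edges:
            if sign not in (ACTIVATION, REPRESSION):
                raise ValueError(f"template {self.name!r}: edge ({src},{dst}) has no valid sign")
            if src not in by_name or dst not in by_name:
                raise ValueError(f"template {self.name!r}: edge references unknown slot")
            if by_name[src].kind == MIRNA and sign != REPRESSION:
                raise ValueError(f"template {self.name!r}: miRNA-source edge must be repressive")

    @property
    def x_slot(self) -> MotifSlot:
        return next(s for s in self.slots if s.is_x)

    def slot_kinds(self) -> set:
        return {s.kind for s in self.slots}

    def gene_slots(self) -> Tuple[MotifSlot, ...]:
        return tuple(s for s in self.slots if s.kind == GENE)

    def mirna_slots(self) -> Tuple[MotifSlot, ...]:
        return tuple(s for s in self.slots if s.kind == MIRNA)

    def slot_degree(self, slot_name: str) -> int:
        """Total number of template edges incident on a slot (self-loops count twice)."""
        d = 0
        for src, dst, _ in self.edges:
            if src == slot_name:
                d += 1
            if dst == slot_name:
                d += 1
        return d

    def slot_in_degree(self, slot_name: str) -> int:
        return sum(1 for _, dst, _ in self.edges if dst == slot_name)

    def slot_out_degree(self, slot_name: str) -> int:
        return sum(1 for src, _, _ in self.edges if src == slot_name)


def _gene(name: str, is_x: bool = False) -> MotifSlot:
    return MotifSlot(name, GENE, is_x)


def _mirna(name: str) -> MotifSlot:
    return MotifSlot(name, MIRNA)


def autoregulation(rng: np.random.Generator) -> MotifTemplate:
    """Self-regulation; negative autoregulation is the common wild-type form."""
    sign = REPRESSION if rng.random() < 0.7 else ACTIVATION
    return MotifTemplate("autoregulation", (_gene("x", True),), (("x", "x", sign),))


def feed_forward_loop(rng: np.random.Generator) -> MotifTemplate:
    # incoherent variant (y represses z) half of the time
    yz = ACTIVATION if rng.random() < 0.5 else REPRESSION
    return MotifTemplate(
        "feed_forward_loop",
        (_gene("x", True), _gene("y"), _gene("z")),
        (("x", "y", ACTIVATION), ("x", "z", ACTIVATION), ("y", "z", yz)),
    )


def feedback_loop(rng: np.random.Generator) -> MotifTemplate:
    """Two- or three-gene cycle with one repressive arm (memory/oscillator motifs)."""
    if rng.random() < 0.5:
        return MotifTemplate(
            "feedback_loop",
            (_gene("x", True), _gene("y")),
            (("x", "y", ACTIVATION), ("y", "x", REPRESSION)),
        )
    return MotifTemplate(
        "feedback_loop",
        (_gene("x", True), _gene("y"), _gene("z")),
        (("x", "y", ACTIVATION), ("y", "z", ACTIVATION), ("z", "x", REPRESSION)),
    )


def single_input_module(rng: np.random.Generator) -> MotifTemplate:
    """One master regulator driving a coordinated battery of 2-5 targets."""
    fan_out = int(rng.integers(2, 6))
    slots = (_gene("x", True),) + tuple(_gene(f"t{i}") for i in range(fan_out))
    edges = tuple(("x", f"t{i}", ACTIVATION) for i in range(fan_out))
    return MotifTemplate("single_input_module", slots, edges)


def dense_overlapping_regulons(rng: np.random.Generator) -> MotifTemplate:
    """A layer of 2-4 regulators densely wired onto 2-4 shared targets."""
    n_reg = int(rng.integers(2, 5))
    n_tgt = int(rng.integers(2, 5))
    regs = ["x"] + [f"r{i}" for i in range(n_reg - 1)]
    tgts = [f"t{i}" for i in range(n_tgt)]
    slots = tuple(_gene(r, r == "x") for r in regs) + tuple(_gene(t) for t in tgts)
    edges = []
    for r in regs:
        for t in tgts:
            if rng.random() < 0.75:
                edges.append((r, t, ACTIVATION))
    # keep the regulon dense: every regulator hits >=1 target and vice versa
    covered_t = {t for _, t, _ in edges}
    for t in tgts:
        if t not in covered_t:
            edges.append((regs[int(rng.integers(0, n_reg))], t, ACTIVATION))
    covered_r = {r for r, _, _ in edges}
    for r in regs:
        if r not in covered_r:
            edges.append((r, tgts[int(rng.integers(0, n_tgt))], ACTIVATION))
    return MotifTemplate("dense_overlapping_regulons", slots, tuple(edges))


def mirna_feed_forward_loop(rng: np.random.Generator) -> MotifTemplate:
    """TF activates both a miRNA and a gene; the miRNA represses the gene."""
    return MotifTemplate(
        "mirna_feed_forward_loop",
        (_gene("x", True), _mirna("m"), _gene("z")),
        (("x", "m", ACTIVATION), ("x", "z", ACTIVATION), ("m", "z", REPRESSION)),
    )


def mirna_feedback_loop(rng: np.random.Generator) -> MotifTemplate:
    """TF activates a miRNA which in turn represses the TF."""
    return MotifTemplate(
        "mirna_feedback_loop",
        (_gene("x", True), _mirna("m")),
        (("x", "m", ACTIVATION), ("m", "x", REPRESSION)),
    )


MOTIF_REGISTRY: Dict[str, Callable[[np.random.Generator], MotifTemplate]] = {
    "autoregulation": autoregulation,
    "feed_forward_loop": feed_forward_loop,
    "feedback_loop": feedback_loop,
    "single_input_module": single_input_module,
    "dense_overlapping_regulons": dense_overlapping_regulons,
    "mirna_feed_forward_loop": mirna_feed_forward_loop,
    "mirna_feedback_loop": mirna_feedback_loop,
}


def sample_template(rng: np.random.Generator, kinds_available: set) -> MotifTemplate:
    """Draw a random template whose slot kinds intersect the available node kinds."""
    names = [
        name
        for name, factory in MOTIF_REGISTRY.items()
        if _factory_kinds(name) & kinds_available
    ]
    if not names:
        raise ValueError("no motif template is compatible with the available node kinds")
    name = names[int(rng.integers(0, len(names)))]
    return MOTIF_REGISTRY[name](rng)


_FACTORY_KINDS = {
    "autoregulation": {GENE},
    "feed_forward_loop": {GENE},
    "feedback_loop": {GENE},
    "single_input_module": {GENE},
    "dense_overlapping_regulons": {GENE},
    "mirna_feed_forward_loop": {GENE, MIRNA},
    "mirna_feedback_loop": {GENE, MIRNA},
}


def _factory_kinds(name: str) -> set:
    return _FACTORY_KINDS.get(name, {GENE})
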