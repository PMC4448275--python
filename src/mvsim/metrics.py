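"""Network validation and ground-truth comparison metrics.

Three families: (i) per-node clustering coefficients and the C(k) curve,
whose power-law decay with exponent near 1 is the signature of hierarchical
modularity; (ii) log-log least-squares fits of degree distributions, the
same line-fit convention used to validate scale-freeness of the generated
networks; (iii) path-length profiles that classify candidate interaction
lists against the ground-truth network (1 = direct edge, >1 = indirect,
Inf = no path).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .config import NetworkConfig
from .motifs import SIGNAL


def _as_graph(network) -> nx.DiGraph:
    if isinstance(network, nx.Graph):
        return network
    return network.graph


def clustering_coefficient(network, node) -> Optional[float]:
    """Directed clustering coefficient C = n / (k (k-1)).

    k counts distinct neighbours (union of predecessors and successors,
    self excluded); n counts directed edges among them, so k(k-1) is the
    number of possible directed pairs and C lies in [0, 1].  Undefined
    (None) for nodes with fewer than two neighbours.
    """
    g = _as_graph(network)
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    nbrs = (set(g.predecessors(node)) | set(g.successors(node))) - {node}
    k = len(nbrs)
    if k < 2:
        return None
    n = sum(1 for u in nbrs for v in g.successors(u) if v in nbrs and v != u)
    return n / (k * (k - 1))


def clustering_curve(network) -> Dict[int, float]:
    """Mean clustering coefficient per total degree, over nodes where C is
    defined.  Signal nodes are excluded (they are exogenous attachments)."""
    g = _as_graph(network)
    acc: Dict[int, List[float]] = {}
    for node, data in g.nodes(data=True):
        if data.get("kind") == SIGNAL:
            continue
        c = clustering_coefficient(g, node)
        if c is None:
            continue
        acc.setdefault(g.degree(node), []).append(c)
    return {k: float(np.mean(v)) for k, v in sorted(acc.items())}


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log OLS line fit: exponent is the slope magnitude."""

    exponent: float
    slope: float
    intercept: float
    r_squared: float
    x: np.ndarray
    y: np.ndarray


def fit_loglog(x: Sequence[float], y: Sequence[float]) -> PowerLawFit:
    """Straight-line fit of log(y) on log(x); non-positive points dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct positive x values for a log-log fit")
    res = stats.linregress(np.log(x), np.log(y))
    return PowerLawFit(
        exponent=abs(res.slope),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        x=x,
        y=y,
    )


def fit_power_law(degrees: Iterable[int]) -> PowerLawFit:
    """Fit a line in log-log space to the degree histogram.

    Degrees are binned at integer values; empty (and zero-degree) bins are
    dropped before the log transform.  Returns the slope magnitude as the
    estimated scale exponent together with R^2.
    """
    degrees = np.asarray(list(degrees), dtype=int)
    if degrees.size == 0:
        raise ValueError("no degree samples")
    ks, counts = np.unique(degrees[degrees > 0], return_counts=True)
    freqs = counts / counts.sum()
    return fit_loglog(ks, freqs)


def pooled_degree_fit(degree_sequences: Sequence[Sequence[int]]) -> PowerLawFit:
    """Log-log line fit over the pooled per-network histogram points.

    Each replicate network contributes its own (degree, frequency) points;
    the line is fitted to all points jointly.  This weights degree bins by
    how many replicates realize them, rather than by pooled counts, so the
    reproducible head of the distribution is not swamped by rare tail bins.
    """
    xs: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    for seq in degree_sequences:
        seq = np.asarray(list(seq), dtype=int)
        seq = seq[seq > 0]
        if seq.size == 0:
            continue
        ks, counts = np.unique(seq, return_counts=True)
        xs.append(ks)
        ys.append(counts / counts.sum())
    if not xs:
        raise ValueError("no positive-degree samples in any network")
    return fit_loglog(np.concatenate(xs), np.concatenate(ys))


def network_degree_sequence(network, include_signals: bool = False) -> List[int]:
    g = _as_graph(network)
    return [
        d
        for n, d in g.degree()
        if include_signals or g.nodes[n].get("kind") != SIGNAL
    ]


def clustering_exponent(network) -> PowerLawFit:
    """Exponent of the C(k) ~ k^-beta decay for one network."""
    curve = clustering_curve(network)
    return fit_loglog(list(curve.keys()), list(curve.values()))


@dataclass
class ScaleInvarianceResult:
    """Per-network C(k) exponents and their regression on network size."""

    sizes: np.ndarray
    exponents: np.ndarray
    slope: float
    conf_int: Tuple[float, float]
    skipped_sizes: List[int]

    @property
    def size_independent(self) -> bool:
        """True when the confidence interval of the size effect covers 0."""
        return self.conf_int[0] <= 0.0 <= self.conf_int[1]


def clustering_scale_invariance(
    sizes: Sequence[int],
    alpha: float = 2.2,
    lambda_: float = 0.5,
    mirna_fraction: float = 0.1,
    seed: int = 0,
    ci_level: float = 0.95,
) -> ScaleInvarianceResult:
    """Generate one network per requested total size and test whether the
    C(k) exponent depends on size.

    Fits each network's clustering-coefficient curve in log-log space, then
    regresses the fitted exponent magnitudes on network size with OLS;
    hierarchical modularity predicts a slope indistinguishable from 0.
    Networks too small to define a C(k) curve are skipped and reported.
    """
    import statsmodels.api as sm

    from .topology import build_network

    rng = np.random.default_rng(seed)
    used_sizes: List[int] = []
    exponents: List[float] = []
    skipped: List[int] = []
    for size in sizes:
        m = int(round(size * mirna_fraction))
        n = max(size - m, 1)
        config = NetworkConfig(n_genes=n, n_mirnas=m, alpha=alpha, lambda_=lambda_)
        net = build_network(config, rng=rng)
        try:
            fit = clustering_exponent(net)
        except ValueError:
            skipped.append(size)
            continue
        used_sizes.append(size)
        exponents.append(fit.exponent)
    if len(set(used_sizes)) < 2:
        raise ValueError("need networks of at least two distinct sizes to regress on size")
    x = sm.add_constant(np.asarray(used_sizes, dtype=float))
    res = sm.OLS(np.asarray(exponents), x).fit()
    ci = res.conf_int(alpha=1 - ci_level)[1]
    return ScaleInvarianceResult(
        sizes=np.asarray(used_sizes),
        exponents=np.asarray(exponents),
        slope=float(res.params[1]),
        conf_int=(float(ci[0]), float(ci[1])),
        skipped_sizes=skipped,
    )


def path_length_profile(network, candidate_edges: Iterable[Tuple[str, str]]) -> Dict:
    """Histogram of directed shortest-path lengths for candidate node pairs.

    Keys are path lengths (1 = the pair is a true direct interaction,
    larger = indirect, math.inf = unreachable or unknown node); values are
    counts.  The counts always sum to the number of candidates.
    """
    g = _as_graph(network)
    profile: Counter = Counter()
    for u, v in candidate_edges:
        if u not in g or v not in g:
            profile[math.inf] += 1
            continue
        if u == v:
            # shortest_path_length returns 0 for a node and itself; a
            # self-candidate is a direct interaction only via a self-loop
            profile[1 if g.has_edge(u, u) else math.inf] += 1
            continue
        try:
            length = nx.shortest_path_length(g, u, v)
        except nx.NetworkXNoPath:
            profile[math.inf] += 1
            continue
        profile[length] += 1
    return dict(profile)
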