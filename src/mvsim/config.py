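"""Configuration objects, presets and YAML/JSON round-tripping.

A full run is described by a :class:`RunConfig`: network size and degree-law
parameters, kinetic sampling ranges, noise levels, simulation grid, and the
per-condition signal programs.  Configs are plain frozen dataclasses so they
serialize losslessly; reloading a saved config and rerunning with the same
seed reproduces a run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Tuple

import yaml

from .noise import NoiseConfig


class ConfigError(ValueError):
    """Raised for schema violations; the message names the offending key."""


@dataclass(frozen=True)
class NetworkConfig:
    """Topology parameters.

    alpha is the power-law scale exponent chased by the gene degree
    distribution (scale-free networks have 2 < alpha < 3); lambda_ is the
    rate of the exponential law chased by miRNA out-degrees; pool_size is
    the number of candidate motifs scored per construction step.
    """

    n_genes: int
    n_mirnas: int = 0
    n_signals: int = 0
    alpha: float = 2.2
    lambda_: float = 0.5
    pool_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_mirnas < 0:
            raise ConfigError("n_mirnas must be >= 0")
        if self.n_signals < 0:
            raise ConfigError("n_signals must be >= 0")
        if not self.alpha > 0:
            raise ConfigError("alpha must be > 0")
        if not self.lambda_ > 0:
            raise ConfigError("lambda_ must be > 0")
        if self.pool_size < 1:
            raise ConfigError("pool_size must be >= 1")


@dataclass(frozen=True)
class DynamicsConfig:
    """Sampling ranges for kinetic parameters.

    Concentrations are dimensionless and live near [0, 1]: Hill thresholds
    theta are drawn from [0.3, 0.8] and steepnesses mu from [2, 10].  Basal
    production is sampled relative to basal degradation (p = U(p_rel)*d0)
    so unregulated steady states p/d0 land near 1, and the miRNA-dependent
    degradation gain relative to d0 keeps repression effective but bounded.
    """

    theta_range: Tuple[float, float] = (0.3, 0.8)
    mu_range: Tuple[float, float] = (2.0, 10.0)
    d0_range: Tuple[float, float] = (0.1, 1.0)
    p_rel_range: Tuple[float, float] = (0.5, 1.5)
    d_gain_rel_range: Tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        for name in ("theta_range", "mu_range", "d0_range", "p_rel_range", "d_gain_rel_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must satisfy 0 < low <= high")


@dataclass(frozen=True)
class SimulationConfig:
    """Time grid and solver settings.

    100 equally spaced points over [0, 50] time units by default; the horizon
    is long relative to 1/d0 so last-time-point sampling sits near steady
    state for non-oscillating nodes.
    """

    t_max: float = 50.0
    n_points: int = 100
    initial_value: float = 0.1
    rtol: float = 1e-6
    atol: float = 1e-8

    def __post_init__(self) -> None:
        if not self.t_max > 0:
            raise ConfigError("t_max must be > 0")
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")
        if self.initial_value < 0:
            raise ConfigError("initial_value must be >= 0")


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: a signal program and a subject count.

    ``signals`` maps signal node ids to program specs (dicts with a ``type``
    key: constant / zero / periodic / random_constant / custom).  The key
    ``"*"`` applies to every signal not listed explicitly.
    """

    name: str
    n_subjects: int
    signals: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    network: NetworkConfig
    dynamics: DynamicsConfig = DynamicsConfig()
    noise: NoiseConfig = NoiseConfig()
    simulation: SimulationConfig = SimulationConfig()
    conditions: Tuple[ConditionSpec, ...] = ()
    seed: int = 0


# Network sizes of the three benchmark profiles.
NETWORK_PRESETS: Dict[str, NetworkConfig] = {
    "grn1": NetworkConfig(n_genes=1000, n_mirnas=100, n_signals=10),
    "grn2": NetworkConfig(n_genes=1000, n_mirnas=300, n_signals=35),
    "grn3": NetworkConfig(n_genes=500, n_mirnas=100, n_signals=20),
}


def preset_run_config(profile: str, seed: int = 0) -> RunConfig:
    """A full run config for a named profile: two conditions of 50 subjects,
    signals all held at 0 in the first and all at 1 in the second."""
    if profile not in NETWORK_PRESETS:
        raise ConfigError(f"unknown profile {profile!r}; choose from {sorted(NETWORK_PRESETS)}")
    net = dataclasses.replace(NETWORK_PRESETS[profile], seed=seed)
    conditions = (
        ConditionSpec("baseline", 50, {"*": {"type": "constant", "value": 0.0}}),
        ConditionSpec("stimulated", 50, {"*": {"type": "constant", "value": 1.0}}),
    )
    return RunConfig(network=net, conditions=conditions, seed=seed)


# ---------------------------------------------------------------------------
# strict (unknown-key-rejecting) dict <-> dataclass conversion


def _build_dataclass(cls, data: Mapping[str, Any], where: str):
    if not isinstance(data, Mapping):
        raise ConfigError(f"{where}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{where}: unknown key {sorted(unknown)[0]!r}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name.endswith("_range") and isinstance(v, (list, tuple)):
            v = tuple(float(x) for x in v)
        kwargs[f.name] = v
    return cls(**kwargs)


def run_config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    if not isinstance(data, Mapping):
        raise ConfigError("config root must be a mapping")
    known = {"network", "dynamics", "noise", "simulation", "conditions", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r}")
    if "network" not in data:
        raise ConfigError("missing required section 'network'")
    network = _build_dataclass(NetworkConfig, data["network"], "network")
    dynamics = _build_dataclass(DynamicsConfig, data.get("dynamics", {}), "dynamics")
    noise = _build_dataclass(NoiseConfig, data.get("noise", {}), "noise")
    simulation = _build_dataclass(SimulationConfig, data.get("simulation", {}), "simulation")
    conditions = []
    for i, c in enumerate(data.get("conditions", [])):
        conditions.append(_build_dataclass(ConditionSpec, c, f"conditions[{i}]"))
    return RunConfig(
        network=network,
        dynamics=dynamics,
        noise=noise,
        simulation=simulation,
        conditions=tuple(conditions),
        seed=int(data.get("seed", 0)),
    )


def run_config_to_dict(config: RunConfig) -> Dict[str, Any]:
    d = dataclasses.asdict(config)
    d["conditions"] = [dataclasses.asdict(c) for c in config.conditions]
    return json.loads(json.dumps(d))  # normalize tuples to lists


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON; JSON is a YAML subset) run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return run_config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(run_config_to_dict(config), sort_keys=False))
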