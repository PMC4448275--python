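"""Biological and technical variability.

Two-level noise model.  Biological variability between subjects is emulated
by jittering every kinetic and Hill parameter with low-variance relative
Gaussian noise before each subject is simulated.  Technical (measurement)
variability follows the classic two-component error model for intensity
data:

    y = c + x * exp(eta) + eps,   eps ~ N(0, sigma_eps), eta ~ N(0, sigma_eta)

where c is a constant mean background level, the additive term dominates at
low expression and the multiplicative (lognormal) term dominates at high
expression.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

_POSITIVITY_FLOOR = 1e-6


@dataclass(frozen=True)
class NoiseConfig:
    """Noise levels.  sigma_bio is the relative std of per-subject parameter
    jitter; c, sigma_eps, sigma_eta parameterize the measurement model."""

    sigma_bio: float = 0.05
    c: float = 0.0
    sigma_eps: float = 0.05
    sigma_eta: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sigma_bio", "sigma_eps", "sigma_eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.c < 0:
            raise ValueError("c must be >= 0")


def _jitter_value(value: float, sigma: float, rng: np.random.Generator) -> float:
    """Multiply by (1 + zeta), zeta ~ N(0, sigma), truncated to stay positive."""
    if sigma == 0:
        return value
    jittered = value * (1.0 + rng.normal(0.0, sigma))
    return max(jittered, _POSITIVITY_FLOOR)


def jitter_parameters(system, config: NoiseConfig, rng: np.random.Generator):
    """Return a copy of a SystemModel with all parameters jittered.

    Every Hill threshold/steepness and every kinetic rate is perturbed
    independently; the input model is left untouched.  With sigma_bio = 0 the
    copy is numerically identical to the original.
    """
    from . import dynamics  # deferred to avoid an import cycle

    sigma = config.sigma_bio
    jittered = copy.deepcopy(system)
    if sigma == 0:
        return jittered

    def jitter_params(params: dynamics.HillParams) -> dynamics.HillParams:
        return dynamics.HillParams(
            theta=_jitter_value(params.theta, sigma, rng),
            mu=_jitter_value(params.mu, sigma, rng),
        )

    def jitter_tree(tree):
        if isinstance(tree, dynamics.HillLeaf):
            return dynamics.HillLeaf(tree.source, jitter_params(tree.params))
        if isinstance(tree, dynamics.ConstLeaf):
            return tree
        return dynamics.OpNode(tree.op, tuple(jitter_tree(c) for c in tree.children))

    for node, model in jittered.models.items():
        jittered.models[node] = dynamics.RegulationModel(
            node=model.node,
            production=jitter_tree(model.production),
            mirna_inputs=tuple(
                (src, jitter_params(p)) for src, p in model.mirna_inputs
            ),
            kinetics=dynamics.KineticParams(
                production=_jitter_value(model.kinetics.production, sigma, rng),
                basal_degradation=_jitter_value(model.kinetics.basal_degradation, sigma, rng),
                mirna_degradation_gain=_jitter_value(
                    model.kinetics.mirna_degradation_gain, sigma, rng
                ),
            ),
        )
    return jittered


def measure(x, config: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply the two-component measurement-error model element-wise.

    Draws are independent per element.  Observed intensities may be negative
    through the additive term; no clipping is applied.
    """
    x = np.asarray(x, dtype=float)
    eta = rng.normal(0.0, config.sigma_eta, size=x.shape)
    eps = rng.normal(0.0, config.sigma_eps, size=x.shape)
    return config.c + x * np.exp(eta) + eps
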