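"""Synthetic mixtures of orthogonal components with angle-controlled weights.

The generator reproduces the statistical structure of the validation model
used throughout this package: each sample is an additive mixture of
``n_true_components`` orthogonal (disjoint-support) source components, and
the per-sample concentration of component *m* in sample *n* is governed by a
mixing angle ``theta[n, m]``:

* disease-labelled sample:  ``x_n = sum_m sin^2(theta[n, m]) * s_m``
* control-labelled sample:  ``x_n = sum_m cos^2(theta[n, m]) * s_m``

so each component is split between the disease rule and the control rule at
an overall concentration of 100% (``sin^2 + cos^2 = 1``). Angles are drawn
uniformly from a role-specific sector: by convention component 0 carries the
disease-specific features, the last component the control-specific features,
and everything in between is neutral (not differentially expressed). The
default sectors [50, 89.99] / [25, 65] / [0.01, 40] degrees overlap
substantially, so neutral features may dominate disease features in many
individual samples -- that overlap is the point of the validation design.

Defaults mirror the validation study: 10 components, K = 15000 features,
100 + 100 samples. Component amplitudes on the support are
Uniform[0.5, 1.5] (the magnitude law is a free choice of the generator;
this keeps all features positive and on a comparable scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ExpressionDataset
from .errors import DimensionError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_components",
    "draw_mixing_angles",
    "synthesize_dataset",
    "simulate_dataset",
]

ROLE_DISEASE = "disease"
ROLE_NEUTRAL = "neutral"
ROLE_CONTROL = "control"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic mixture generator."""

    n_true_components: int = 10
    n_features: int = 15000
    n_disease: int = 100
    n_control: int = 100
    sector_disease: tuple[float, float] = (50.0, 89.99)
    sector_neutral: tuple[float, float] = (25.0, 65.0)
    sector_control: tuple[float, float] = (0.01, 40.0)
    amplitude_low: float = 0.5
    amplitude_high: float = 1.5
    shuffle_supports: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_true_components < 3:
            raise ValueError("need >= 3 components (disease, control, >=1 neutral)")
        if self.n_true_components > self.n_features:
            raise ValueError("more components than features")
        for name in ("sector_disease", "sector_neutral", "sector_control"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi < 90.0):
                raise ValueError(f"{name} must lie strictly inside (0, 90) degrees")
        if not (0 < self.amplitude_low <= self.amplitude_high):
            raise ValueError("need 0 < amplitude_low <= amplitude_high")
        if self.n_disease < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per class")

    def sector_for(self, role: str) -> tuple[float, float]:
        return {
            ROLE_DISEASE: self.sector_disease,
            ROLE_NEUTRAL: self.sector_neutral,
            ROLE_CONTROL: self.sector_control,
        }[role]


@dataclass
class GroundTruth:
    """True components, their roles and (once drawn) the mixing angles."""

    components: np.ndarray          # n_true x K, pairwise-disjoint supports
    roles: list[str]                # per-component role
    angles: np.ndarray | None = None  # N x n_true, degrees

    @property
    def supports(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.components]

    @property
    def disease_index(self) -> int:
        return self.roles.index(ROLE_DISEASE)

    @property
    def control_index(self) -> int:
        return self.roles.index(ROLE_CONTROL)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # stage-keyed streams so each step is reproducible independently of call order
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


def partition_sizes(n_features: int, n_parts: int) -> list[int]:
    """Split ``n_features`` into ``n_parts`` as evenly as possible (larger first)."""
    base, extra = divmod(n_features, n_parts)
    return [base + 1] * extra + [base] * (n_parts - extra)


def generate_components(config: SimulationConfig) -> GroundTruth:
    """Draw orthogonal source components with disjoint feature supports.

    Features are partitioned into ``n_true_components`` contiguous blocks
    (optionally shuffled); within its block a component takes values from
    Uniform[amplitude_low, amplitude_high], zero elsewhere. Component 0 is
    disease-specific, the last component control-specific, the rest neutral.
    """
    rng = _rng(config, 0)
    n, k = config.n_true_components, config.n_features
    order = rng.permutation(k) if config.shuffle_supports else np.arange(k)
    components = np.zeros((n, k))
    start = 0
    for m, size in enumerate(partition_sizes(k, n)):
        idx = order[start:start + size]
        components[m, idx] = rng.uniform(config.amplitude_low, config.amplitude_high,
                                         size=size)
        start += size
    roles = [ROLE_DISEASE] + [ROLE_NEUTRAL] * (n - 2) + [ROLE_CONTROL]
    return GroundTruth(components=components, roles=roles)


def draw_mixing_angles(truth: GroundTruth, config: SimulationConfig) -> np.ndarray:
    """Draw ``theta[n, m]`` uniformly from each component role's sector.

    Angles are independent per sample *and* per component, which is how
    concentration variability across the sample population is simulated.
    Fills ``truth.angles`` and returns it.
    """
    rng = _rng(config, 1)
    n_samples = config.n_disease + config.n_control
    angles = np.empty((n_samples, len(truth.roles)))
    for m, role in enumerate(truth.roles):
        lo, hi = config.sector_for(role)
        angles[:, m] = rng.uniform(lo, hi, size=n_samples)
    truth.angles = angles
    return angles


def synthesize_dataset(truth: GroundTruth,
                       config: SimulationConfig) -> ExpressionDataset:
    """Mix the components into labelled samples with sin^2/cos^2 weights.

    The first ``n_disease`` samples are disease-labelled (weight
    ``sin^2(theta)``), the remaining ``n_control`` control-labelled (weight
    ``cos^2(theta)``); per (sample, component) the two rule weights sum to 1.
    """
    if truth.angles is None:
        raise DimensionError("draw_mixing_angles must run before synthesize_dataset")
    theta = np.radians(truth.angles)
    n_d = config.n_disease
    weights = np.empty_like(theta)
    weights[:n_d] = np.sin(theta[:n_d]) ** 2
    weights[n_d:] = np.cos(theta[n_d:]) ** 2
    values = weights @ truth.components
    labels = np.concatenate([np.ones(n_d, dtype=int),
                             -np.ones(config.n_control, dtype=int)])
    sample_ids = [f"D{i + 1:03d}" for i in range(n_d)] + \
                 [f"C{i + 1:03d}" for i in range(config.n_control)]
    feature_ids = [f"f{j}" for j in range(config.n_features)]
    return ExpressionDataset(values=values, feature_ids=feature_ids,
                             sample_ids=sample_ids, labels=labels)


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Convenience: components -> angles -> mixed dataset, all from one seed."""
    truth = generate_components(config)
    draw_mixing_angles(truth, config)
    return synthesize_dataset(truth, config), truth
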