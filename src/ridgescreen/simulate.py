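"""Simulation of randomized trials with block-correlated Gaussian biomarkers.

The generative model is a linear outcome model

    Y_i = b0 + bT * T_i + sum_j (bX_j * X_ij + bXT_j * X_ij * T_i) + eps_i

with X rows i.i.d. multivariate normal (mean 0, unit marginal variance,
equicorrelated blocks), T ~ Bernoulli(p) independent of X, and Gaussian
noise.  ``analytic_pve`` gives the closed-form proportion of outcome
variance explained by the noiseless signal under this distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .trial import TrialDataset

__all__ = [
    "EffectSpec",
    "CorrelationStructure",
    "SimulationConfig",
    "generate_biomarkers",
    "generate_trial",
    "analytic_pve",
    "default_effects",
    "default_structure",
]


@dataclass(frozen=True)
class EffectSpec:
    """True coefficients of the generative outcome model.

    ``main`` and ``interaction`` are sparse maps from 1-based biomarker
    index to coefficient; absent indices have coefficient zero.
    """

    intercept: float = 0.0
    treatment_effect: float = 0.0
    main: dict[int, float] = field(default_factory=dict)
    interaction: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        for name, mapping in (("main", self.main), ("interaction", self.interaction)):
            for j in mapping:
                if not (isinstance(j, (int, np.integer)) and j >= 1):
                    raise ConfigurationError(f"{name} effect index {j!r} is not a 1-based integer")

    def validate_indices(self, m: int) -> None:
        for j in list(self.main) + list(self.interaction):
            if j > m:
                raise ConfigurationError(f"effect index {j} exceeds number of biomarkers m={m}")


@dataclass(frozen=True)
class CorrelationStructure:
    """Block-equicorrelated biomarker covariance: blocks (1-rho)*I + rho*11'."""

    m: int
    cluster_size: int = 20
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 1 or self.cluster_size < 1:
            raise ConfigurationError("m and cluster_size must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError(f"within-cluster correlation must be in [0, 1), got {self.rho}")
        if self.m % self.cluster_size:
            raise ConfigurationError(
                f"cluster_size {self.cluster_size} does not divide m={self.m}"
            )

    @property
    def n_clusters(self) -> int:
        return self.m // self.cluster_size

    def labels(self) -> np.ndarray:
        """1-based cluster label for each biomarker."""
        return np.repeat(np.arange(1, self.n_clusters + 1), self.cluster_size)


@dataclass(frozen=True)
class SimulationConfig:
    n: int
    effects: EffectSpec
    structure: CorrelationStructure
    allocation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("sample size n must be >= 1")
        if not 0.0 < self.allocation < 1.0:
            raise ConfigurationError("allocation probability must lie in (0, 1)")
        self.effects.validate_indices(self.structure.m)


def generate_biomarkers(
    n: int, structure: CorrelationStructure, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. rows from the block-equicorrelated normal.

    Uses the shared-factor construction X_ij = sqrt(rho)*U_c(j) + sqrt(1-rho)*Z_ij
    (one latent factor per cluster), which realizes the block covariance in
    O(n*m) without forming an m x m Cholesky factor.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n, structure.m))
    if structure.rho == 0.0:
        return z
    u = rng.standard_normal((n, structure.n_clusters))
    shared = np.repeat(u, structure.cluster_size, axis=1)
    return np.sqrt(structure.rho) * shared + np.sqrt(1.0 - structure.rho) * z


def generate_trial(config: SimulationConfig) -> TrialDataset:
    """Simulate one complete trial dataset; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    x = generate_biomarkers(config.n, config.structure, rng)
    t = (rng.random(config.n) < config.allocation).astype(float)
    eff = config.effects
    y = np.full(config.n, eff.intercept, dtype=float)
    y += eff.treatment_effect * t
    for j, beta in eff.main.items():
        y += beta * x[:, j - 1]
    for j, beta in eff.interaction.items():
        y += beta * x[:, j - 1] * t
    y += eff.noise_sd * rng.standard_normal(config.n)
    return TrialDataset(
        outcome=y,
        treatment=t,
        biomarkers=x,
        clusters=config.structure.labels(),
    )


def _effect_covariance(indices: list[int], structure: CorrelationStructure) -> np.ndarray:
    """Covariance submatrix of the biomarkers listed in ``indices`` (1-based)."""
    labels = structure.labels()
    sub = labels[np.asarray(indices, dtype=int) - 1]
    same_cluster = sub[:, None] == sub[None, :]
    sigma = np.where(same_cluster, structure.rho, 0.0)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def analytic_pve(
    spec: EffectSpec, structure: CorrelationStructure, allocation_p: float = 0.5
) -> float:
    """Closed-form proportion of Var(Y) explained by the true mean function.

    With a = main-effect vector, b = interaction vector, p = P(T=1) and
    Sigma the biomarker covariance (X independent of T, E[X] = 0):

        Var(E[Y|X,T]) = bT^2 p(1-p) + a'Sigma a + 2p a'Sigma b + p b'Sigma b

    and PVE = Var(E[Y|X,T]) / (Var(E[Y|X,T]) + noise_sd^2).
    """
    spec.validate_indices(structure.m)
    indices = sorted(set(spec.main) | set(spec.interaction))
    bt = spec.treatment_effect
    p = allocation_p
    signal = bt * bt * p * (1.0 - p)
    if indices:
        sigma = _effect_covariance(indices, structure)
        a = np.array([spec.main.get(j, 0.0) for j in indices])
        b = np.array([spec.interaction.get(j, 0.0) for j in indices])
        signal += a @ sigma @ a + 2.0 * p * (a @ sigma @ b) + p * (b @ sigma @ b)
    return float(signal / (signal + spec.noise_sd**2))


def default_effects(
    interaction_main: float = 0.5,
    interaction_effect: float = 1.0,
    other_main: float = 1.5,
    noise_sd: float = 5.0,
    treatment_effect: float = 0.5,
) -> EffectSpec:
    """Main simulation scenario: one interacting biomarker (first member of
    cluster 1) plus four main-effect-only biomarkers (first members of
    clusters 2-5), under clusters of 20."""
    main = {1: interaction_main, 21: other_main, 41: other_main, 61: other_main, 81: other_main}
    interaction = {1: interaction_effect} if interaction_effect != 0.0 else {}
    return EffectSpec(
        intercept=0.0,
        treatment_effect=treatment_effect,
        main=main,
        interaction=interaction,
        noise_sd=noise_sd,
    )


def default_structure(m: int = 1000, rho: float = 0.6, cluster_size: int = 20) -> CorrelationStructure:
    return CorrelationStructure(m=m, cluster_size=cluster_size, rho=rho)
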