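import numpy as np
import pytest

from ridgescreen import (
    CorrelationStructure,
    EffectSpec,
    SimulationConfig,
    TrialDataset,
    generate_trial,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_trial(rng) -> TrialDataset:
    """n=80, m=12 trial with a genuine interaction at X1."""
    config = SimulationConfig(
        n=80,
        effects=EffectSpec(
            treatment_effect=0.5,
            main={1: 0.5, 5: 1.0},
            interaction={1: 1.0},
            noise_sd=2.0,
        ),
        structure=CorrelationStructure(m=12, cluster_size=4, rho=0.3),
        seed=42,
    )
    return generate_trial(config)


@pytest.fixture
def null_trial(rng) -> TrialDataset:
    """Pure-noise trial: no biomarker has any effect."""
    config = SimulationConfig(
        n=60,
        effects=EffectSpec(treatment_effect=0.0, noise_sd=1.0),
        structure=CorrelationStructure(m=8, cluster_size=4, rho=0.0),
        seed=7,
    )
    return generate_trial(config)


def make_trial(y, t, x, **kwargs) -> TrialDataset:
    return TrialDataset(
        outcome=np.asarray(y, dtype=float),
        treatment=np.asarray(t, dtype=float),
        biomarkers=np.asarray(x, dtype=float),
        **kwargs,
    )
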