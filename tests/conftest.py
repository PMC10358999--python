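import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermoscreen as ts
from thermoscreen.synthetic import EnsembleSpec

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def helix12() -> ts.StructureModel:
    """Ideal 12-residue poly-alanine α helix (φ=−57, ψ=−47)."""
    return ts.make_helix(12)


@pytest.fixture(scope="session")
def helix40() -> ts.StructureModel:
    return ts.make_helix(40)


@pytest.fixture()
def noisy_ensemble(helix12) -> ts.Ensemble:
    """Small Gaussian ensemble: uniform 0.2 Å noise, 30 frames."""
    return ts.make_ensemble(helix12, EnsembleSpec(30, {}, 0.2, seed=11), 300.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
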