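import numpy as np
import pytest

from inducekit import (
    AllostericTF,
    AutoActivationParams,
    MutualRepressionParams,
    preset_params,
)


@pytest.fixture(scope="session")
def tf_default() -> AllostericTF:
    """LacI-like allosteric parameters used by the presets."""
    return AllostericTF(K_A=140e-6, K_I=530e-9, eps=4.5, n_sites=2)


@pytest.fixture(scope="session")
def auto_bistable() -> AutoActivationParams:
    """Strongly cooperative auto-activation switch (omega = 10)."""
    return preset_params("auto_bistable")


@pytest.fixture(scope="session")
def auto_relax() -> AutoActivationParams:
    """Auto-activation set used for relaxation-timescale analysis (omega = 7.5)."""
    return preset_params("auto_relax")


@pytest.fixture(scope="session")
def toggle_symmetric() -> MutualRepressionParams:
    return preset_params("toggle_symmetric")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
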