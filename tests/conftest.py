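import numpy as np
import pytest

from myoquant import PipelineParams, SimulationConfig, generate_image


@pytest.fixture(scope="session")
def default_params() -> PipelineParams:
    return PipelineParams()


@pytest.fixture(scope="session")
def sparse_image():
    """20 well-separated nuclei and two myotubes, seed 3."""
    cfg = SimulationConfig(seed=3, n_nuclei=20, touching_pair_fraction=0.0,
                           n_myotubes=2, target_mdi=0.4)
    return generate_image(cfg)


@pytest.fixture(scope="session")
def default_image():
    """One full default scene (150 nuclei, 6 myotubes, target MDI 0.5)."""
    return generate_image(SimulationConfig(seed=11))


def random_mask(rng: np.random.Generator, shape=(32, 32), p: float | None = None) -> np.ndarray:
    if p is None:
        p = rng.uniform(0.2, 0.8)
    return rng.random(shape) < p
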