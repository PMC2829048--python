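import numpy as np
import pytest

from lgtscreen.pipeline import RunConfig, run_pipeline
from lgtscreen.synthetic_data import GeneratorConfig, generate


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic scenario, seed 1 (shared across the session)."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_run(dataset):
    """One full pipeline run on the seed-1 scenario (placement included)."""
    return run_pipeline(dataset, RunConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
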