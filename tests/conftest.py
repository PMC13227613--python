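import logging

import pytest

from consenslab.cohort import CohortConfig, generate
from consenslab.pipeline import run_pipeline

logging.getLogger("consenslab").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_participants=3, n_days=2)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config, seed=42)


@pytest.fixture(scope="session")
def default_bundle():
    """Full-size default cohort, shared across tests (generation is ~2 s)."""
    return generate(CohortConfig(), seed=0)


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return run_pipeline(default_bundle)


@pytest.fixture(scope="session")
def zero_noise_small():
    cfg = CohortConfig.zero_noise(n_participants=3, n_days=2)
    bundle = generate(cfg, seed=11)
    return bundle, run_pipeline(bundle, thresholds="generator")
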