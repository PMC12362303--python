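import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from navdyn.config import CohortConfig, PipelineConfig
from navdyn.pipeline import run_all

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the pseudo-inverse fallback warning is expected when tests disable motion
logging.getLogger("navdyn.prep").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    """Miniature study: 12 participants, full 24-episode design, 46 regions."""
    return CohortConfig(n_young=6, n_old=6)


@pytest.fixture(scope="session")
def small_result(small_cfg):
    """One full pipeline run shared across tests (seed 11, 200 permutations)."""
    cfg = PipelineConfig(cohort=small_cfg, n_perm=200, seed=11)
    return run_all(cfg)


@pytest.fixture(scope="session")
def segments(small_result):
    return small_result.segments


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
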