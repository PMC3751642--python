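import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acgh_cnv import GenomeSpec, build_probe_map

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return GenomeSpec(
        chromosomes=(
            ("1", 2_000_000),
            ("2", 1_000_000),
            ("Z", 600_000),
            ("W", 120_000),
        )
    )


@pytest.fixture(scope="session")
def small_map(small_genome):
    return build_probe_map(small_genome, spacing_bp=4000, jitter_fraction=0.0, seed=0)


@pytest.fixture(scope="session")
def jittered_map(small_genome):
    return build_probe_map(small_genome, spacing_bp=4000, jitter_fraction=0.2, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
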