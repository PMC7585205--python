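import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_simulation():
    """One shared zero-error simulation reused across test modules."""
    from pegsplice.simulate import (
        SimulationConfig,
        generate_annotation,
        generate_genome,
        simulate_flnc_reads,
    )

    config = SimulationConfig(seed=101, error_rate=0.0)
    genome = generate_genome(config)
    annotation, truth = generate_annotation(config, genome)
    reads = simulate_flnc_reads(config, annotation, genome)
    return config, genome, annotation, truth, reads
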