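import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_triple_proteomes():
    """50-transcript proteome triple with a known mix of planted classes."""
    from resistkit.simulate import generate_ancestral_proteome, plant_mutations

    ancestral = generate_ancestral_proteome(50, (30, 50), seed=11)
    counts = {
        "resistant_specific_sub": 10,
        "resistant_specific_indel": 5,
        "susceptible_specific": 7,
        "reference_specific": 4,
        "triallelic": 3,
    }
    sus, res, ref, truth = plant_mutations(ancestral, counts, seed=12)
    return sus, res, ref, truth
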