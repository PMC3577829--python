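import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from paleomito.io import SequenceRecord
from paleomito.simulate import SimConfig, SourceGenome, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def small_circular_genome() -> SequenceRecord:
    return simulate_genome(5000, 7, circular=True)


@pytest.fixture(scope="session")
def small_linear_genome() -> SequenceRecord:
    return simulate_genome(8000, 9)


@pytest.fixture(scope="session")
def clean_circular_reads(small_circular_genome):
    """Error-free 60x paired reads from the small circular genome."""
    cfg = SimConfig(
        seed=1,
        paired=True,
        seq_error=0.0,
        n_fragments=int(len(small_circular_genome) * 60 / 180),
        sources=[SourceGenome(small_circular_genome, circular=True)],
    )
    return simulate_reads(cfg)
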