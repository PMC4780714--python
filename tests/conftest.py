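import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def focal_genome():
    """Full-scale synthetic plastome with the default (study-like) architecture."""
    from plastomekit.synthetic_data import PlastomeSpec, simulate_plastome
    return simulate_plastome(PlastomeSpec(seed=42))


@pytest.fixture(scope="session")
def focal_structured(focal_genome):
    from plastomekit.structure import detect_inverted_repeat
    genome, truth = focal_genome
    rotated, qmap = detect_inverted_repeat(genome)
    return rotated, qmap, truth


@pytest.fixture(scope="session")
def evolved_set():
    """Seven evolved genomes with the rpl2 intron lost on the (LagA, LagB) stem."""
    from plastomekit.synthetic_data import myrtales7
    root, truth, genomes = myrtales7(seed=13)
    return root, truth, genomes
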