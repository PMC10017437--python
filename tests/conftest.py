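import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from iskit import build_catalog, plant_element, synth_genome
from iskit.transposition_sim import DEFAULT_IS_SPECS


@pytest.fixture(scope="session")
def planted_genome():
    """Synthetic genome with one ISDrpg2-like and one ISDrpg3-like element."""
    g = synth_genome(n_genes=10, seed=101)
    g, t2 = plant_element(g, DEFAULT_IS_SPECS[0], locus=g.features[2].end + 50, seed=1)
    g, t3 = plant_element(g, DEFAULT_IS_SPECS[1], locus=g.features[7].end + 50, seed=1)
    return g, {"IS4-17": t2, "IS4-20": t3}


@pytest.fixture(scope="session")
def planted_catalog(planted_genome):
    genome, _ = planted_genome
    return build_catalog(genome)
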