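import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thermoenv import annotate_protein, proteome_te_frequencies
from thermoenv.simulate import GeneratorConfig, gen_center_table, gen_proteome_set

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_centers():
    return gen_center_table(GeneratorConfig())


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for fast unit tests."""
    return GeneratorConfig(seed=11, n_organisms_per_kingdom=6, n_proteins=8,
                           length_range=(40, 80))


@pytest.fixture(scope="session")
def small_proteome_profiles(small_config):
    """Profiles computed end-to-end (TD -> assignment -> frequencies)."""
    dataset = gen_proteome_set(small_config)
    profiles = []
    for organism in dataset.organisms:
        te_seqs = [annotate_protein(t, dataset.centers) for t in organism.td_tables]
        profiles.append(proteome_te_frequencies(te_seqs, organism.meta))
    return profiles


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
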