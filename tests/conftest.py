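import numpy as np
import pytest
from hypothesis import settings

from proteobin import synthetic

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_community():
    """A 4-population community, small enough for fast unit tests."""
    spec = synthetic.CommunitySpec(
        populations=[
            synthetic.PopulationSpec(
                label=f"Pop{i}", genome_length=400_000,
                gc_target=[0.68, 0.55, 0.45, 0.62][i],
                composition_divergence=0.4,
                mean_coverage=[70.0, 35.0, 25.0, 10.0][i])
            for i in range(4)
        ],
        rng_seed=101,
    )
    contigs, truth = synthetic.simulate_community(spec)
    return spec, contigs, truth


@pytest.fixture(scope="session")
def small_proteome():
    spec = synthetic.ProteomeSimSpec(n_proteins=300, rng_seed=202)
    table, truth = synthetic.simulate_proteome(spec)
    return spec, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
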