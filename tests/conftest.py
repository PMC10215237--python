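import numpy as np
import pytest

from msnetpharm import (
    MultiscaleNetwork,
    SyntheticScenario,
    generate_bundle,
)


@pytest.fixture(scope="session")
def default_bundle():
    """Standard-scenario bundle (200 proteins, 50 functions, 14 compounds)."""
    return generate_bundle(SyntheticScenario(seed=7))


@pytest.fixture(scope="session")
def small_scenario():
    return SyntheticScenario(
        n_proteins=50,
        n_functions=12,
        ppi_edges=120,
        n_disease_proteins=5,
        targets_per_compound=(3, 8),
        n_compounds=6,
        pathway_size_range=(5, 10),
        n_pathways=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    return generate_bundle(small_scenario)


@pytest.fixture
def two_node_network():
    """A single reciprocal protein-protein edge A<->B."""
    return MultiscaleNetwork.from_raw([("A", "B", "pp")])


def make_random_network(seed: int, n_proteins: int = 50, n_functions: int = 12):
    scenario = SyntheticScenario(
        n_proteins=n_proteins,
        n_functions=n_functions,
        ppi_edges=max(n_proteins - 1, int(2.5 * n_proteins)),
        n_disease_proteins=max(2, n_proteins // 10),
        targets_per_compound=(3, min(8, n_proteins)),
        n_compounds=4,
        pathway_size_range=(3, min(10, n_proteins)),
        n_pathways=3,
        seed=seed,
    )
    from msnetpharm.synthetic import generate_multiscale_network

    return generate_multiscale_network(scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
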