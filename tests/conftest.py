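import numpy as np
import pytest

from cascadenet.cascade import TimeClusterAssignment, fit
from cascadenet.synthetic import (
    GeneratorConfig,
    PlantedTruth,
    generate_network,
    simulate_cube,
    simulate_expression,
)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_config):
    return generate_network(default_config)


@pytest.fixture(scope="session")
def default_cube(default_truth, default_config):
    return simulate_cube(default_truth, default_config)


@pytest.fixture(scope="session")
def two_condition_cubes(default_truth, default_config):
    return simulate_expression(default_truth, default_config)


@pytest.fixture(scope="session")
def fitted_model(default_cube, default_truth, default_config):
    clusters = TimeClusterAssignment(
        dict(default_truth.cluster_of), default_config.n_clusters
    )
    return fit(default_cube, clusters, seed=1)


@pytest.fixture()
def chain_model_factory():
    """Fit a noiseless 3-gene chain g1 -> g2 -> g3 with given signs."""

    def make(w12: float, w13: float):
        truth = PlantedTruth(
            (("G001", "G002", float(w12)), ("G002", "G003", float(w13))),
            {"G001": 1, "G002": 2, "G003": 3},
            frozenset(),
        )
        cfg = GeneratorConfig(
            n_genes=3,
            n_subjects=6,
            n_clusters=3,
            edge_density=0.0,
            noise_sd=0.0,
            de_fraction=0.0,
            seed=11,
        )
        cube = simulate_cube(truth, cfg)
        clusters = TimeClusterAssignment(dict(truth.cluster_of), 3)
        model = fit(cube, clusters, cv="loo", seed=0)
        return model, cube, truth

    return make
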