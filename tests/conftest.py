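import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from reexpress import synthetic as syn
from reexpress.matrices import IntensityTable

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> syn.SimConfig:
    """A miniature study: enough genes/samples to exercise every code
    path while keeping fixture generation instant."""
    return syn.SimConfig(n_genes=60, probes_per_gene=(2, 4), n_planted=10,
                         n_samples_cohort=24, subgroup_fraction=0.25,
                         seed=7)


@pytest.fixture(scope="session")
def annotation(small_config):
    return syn.generate_annotation(small_config)


@pytest.fixture(scope="session")
def experiment(small_config, annotation):
    return syn.generate_cell_line_experiment(small_config, annotation)


@pytest.fixture(scope="session")
def cohort_data(small_config, annotation):
    return syn.generate_cohort(small_config, annotation)


@pytest.fixture(scope="session")
def aux(small_config):
    return syn.generate_auxiliary(small_config)


@pytest.fixture()
def tiny_intensities() -> IntensityTable:
    """Hand-sized intensity table with known beta values."""
    probes = ["p1", "p2", "p3"]
    samples = ["a", "b"]
    m = pd.DataFrame([[300.0, 150.0], [100.0, 400.0], [0.0, 250.0]],
                     index=probes, columns=samples)
    u = pd.DataFrame([[100.0, 150.0], [400.0, 100.0], [0.0, 750.0]],
                     index=probes, columns=samples)
    rng = np.random.default_rng(0)
    ctrl = pd.DataFrame(rng.uniform(80, 120, size=(10, 2)),
                        index=[f"n{i}" for i in range(10)], columns=samples)
    return IntensityTable(m, u, ctrl)
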