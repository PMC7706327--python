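import numpy as np
import pytest

from rhizocore import coring, pipeline, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def maize_plot():
    """One deterministic maize plot, reused by read-only tests."""
    config = simulate.SimConfig.for_study("maize", "intermediate")
    return simulate.simulate_plot(config, seed=42)


@pytest.fixture(scope="session")
def bean_plot():
    config = simulate.SimConfig.for_study("bean", "shallow")
    return simulate.simulate_plot(config, seed=43)


@pytest.fixture(scope="session")
def small_species_data():
    """Six-replicate maize dataset with all cores extracted (read-only)."""
    return pipeline.simulate_species(
        "maize", ("shallow", "intermediate", "deep"), 6, seed=99
    )


@pytest.fixture()
def tiny_config():
    """A cheap config for tests that simulate fresh plots."""
    return simulate.SimConfig.for_study(
        "maize", "intermediate", elongation_budget=400.0, branching_frequency=0.1
    )
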