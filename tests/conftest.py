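import pytest

from forestcarbon import WorldConfig, generate_world, render_sources, run_pipeline


@pytest.fixture(scope="session")
def default_world():
    """History-shaped world: gaps, excluded window, discontinued category."""
    return generate_world(WorldConfig(seed=1234))


@pytest.fixture(scope="session")
def default_result(default_world):
    return run_pipeline(render_sources(default_world), with_sensitivity=False)


@pytest.fixture(scope="session")
def complete_world():
    """Same conditions but with complete, noise-free coverage."""
    return generate_world(WorldConfig(seed=99).complete_coverage())


@pytest.fixture(scope="session")
def complete_sources(complete_world):
    return render_sources(complete_world)


@pytest.fixture(scope="session")
def complete_result(complete_sources):
    return run_pipeline(complete_sources, with_sensitivity=True)
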