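import pytest
from hypothesis import HealthCheck, settings

from tfcrosstalk import WorldConfig, generate_world, write_world
from tfcrosstalk.pipeline import analyze, inputs_from_world

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world at a fixed seed (in-memory)."""
    return generate_world(WorldConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_world):
    """Full pipeline result on the default world."""
    return analyze(inputs_from_world(default_world))


@pytest.fixture(scope="session")
def world_dir(default_world, tmp_path_factory):
    """The default world serialized to disk."""
    d = tmp_path_factory.mktemp("world")
    write_world(default_world, d)
    return d
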