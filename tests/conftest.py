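import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from mitocomp import GeneratorConfig, generate_annotation, load_fixture  # noqa: E402
from mitocomp.genetic_code import vertebrate_mitochondrial  # noqa: E402


@pytest.fixture(scope="session")
def code():
    return vertebrate_mitochondrial()


@pytest.fixture(scope="session")
def gf():
    return load_fixture("GF")


@pytest.fixture(scope="session")
def ge():
    return load_fixture("GE")


@pytest.fixture(scope="session")
def gd():
    return load_fixture("GD")


@pytest.fixture(scope="session")
def synthetic_genome():
    """A full synthetic mitogenome on the default (GF-layout) template."""
    annotation, truth = generate_annotation(GeneratorConfig(seed=20240, label="synthA"))
    return annotation, truth
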