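import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from promoterpath.synthetic_data import (  # noqa: E402
    SyntheticSpec,
    make_annotation_fixture,
    make_landscape,
    make_observed_fixture,
)

SRC = "GAC"
DST = "CGG"


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def noiseless_landscape():
    """Landscape at zero replicate noise: activities equal the truth table."""
    return make_landscape(SyntheticSpec(seed=11, replicate_cv=0.0))


@pytest.fixture(scope="session")
def noisy_landscape(spec):
    return make_landscape(spec)


@pytest.fixture(scope="session")
def loci_delta1():
    return make_annotation_fixture("T7_delta1")


@pytest.fixture(scope="session")
def loci_wildtype():
    return make_annotation_fixture("T7_wildtype")


@pytest.fixture(scope="session")
def observed_fixture():
    return make_observed_fixture()
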