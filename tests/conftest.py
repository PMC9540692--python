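import pytest

from qsweep import analyze_community
from qsweep.cahr import CahRReference
from qsweep.synthetic import build_profiles, generate_community, synthetic_reference


@pytest.fixture(scope="session")
def reference():
    return CahRReference(sequence=synthetic_reference())


@pytest.fixture(scope="session")
def profiles():
    return build_profiles()


@pytest.fixture(scope="session")
def community():
    """A small synthetic community shared by pipeline-level tests."""
    return generate_community(n_genomes=12, seed=7)


@pytest.fixture(scope="session")
def pipeline_result(community, profiles, reference):
    return analyze_community(
        community.genomes, community.proteins, profiles, reference
    )
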