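import pytest
from hypothesis import HealthCheck, settings

from bundlekit.alignment import MSA, builtin_alphabets
from bundlekit.fixtures import make_fig1a, make_fig1b, two_motif_groups

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dna():
    return builtin_alphabets()["dna"]


@pytest.fixture(scope="session")
def protein():
    return builtin_alphabets()["protein"]


@pytest.fixture(scope="session")
def fig1a():
    return make_fig1a()


@pytest.fixture(scope="session")
def fig1b():
    return make_fig1b()


@pytest.fixture(scope="session")
def fig1b_groups(fig1b):
    return two_motif_groups(fig1b)


@pytest.fixture
def tiny_dna(dna):
    return MSA(
        ["s1", "s2", "s3", "s4"],
        ["ACGT-", "ACGTA", "TCGAA", "TC-AA"],
        dna,
    )
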