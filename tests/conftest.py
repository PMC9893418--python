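import pytest

from orthostats import (
    Alignment,
    SimConfig,
    simulate_family,
    translate_set,
)


@pytest.fixture(scope="session")
def family():
    """One default-configuration simulated ortholog family with truth."""
    return simulate_family(SimConfig(seed=20518086 % 2**31))


@pytest.fixture(scope="session")
def family_cds(family):
    return family[0]


@pytest.fixture(scope="session")
def family_truth(family):
    return family[1]


@pytest.fixture(scope="session")
def family_proteins(family_cds):
    return translate_set(family_cds)


@pytest.fixture(scope="session")
def protein_alignment(family_proteins):
    return Alignment.from_sequence_set(family_proteins)


@pytest.fixture(scope="session")
def cds_alignment(family_cds):
    return Alignment.from_sequence_set(family_cds)


@pytest.fixture
def toy_alignment():
    """4 rows x 3 columns: conserved, singleton, parsimony-informative."""
    return Alignment(ids=("r1", "r2", "r3", "r4"), rows=("AAA", "AAA", "AAB", "ABB"))
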