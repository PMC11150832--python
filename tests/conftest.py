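import pytest

from ethercdl import RadylChain, SpeciesIndex, build_species, enumerate_species


@pytest.fixture(scope="session")
def default_species():
    """The full default enumeration (saturated C14-C17 chains)."""
    return enumerate_species()


@pytest.fixture(scope="session")
def default_index(default_species):
    return SpeciesIndex(default_species)


@pytest.fixture(scope="session")
def tetraether_cdl():
    """The flagship tetraether cardiolipin: C33 DEG + C31 DEG cores."""
    return build_species(
        "CDL",
        [
            [RadylChain(17, "ether", 1), RadylChain(16, "ether", 2)],
            [RadylChain(17, "ether", 1), RadylChain(14, "ether", 2)],
        ],
    )


@pytest.fixture(scope="session")
def measured_compositions():
    """Measured intact-core percentages per head group (% of class total)."""
    return {
        "PE": {"DAG": 54.0, "AEG": 7.5, "DEG": 25.0},
        "PG": {"DAG": 9.3, "AEG": 17.0, "DEG": 66.2},
    }
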