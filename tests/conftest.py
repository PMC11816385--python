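import itertools

import pytest

from bwsle import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def menthol_lauric(registry):
    return registry.pair("Menthol", "Lauric acid")


@pytest.fixture(scope="session")
def menthol_thymol(registry):
    return registry.pair("Menthol", "Thymol")


@pytest.fixture(scope="session")
def stearic_lauric(registry):
    return registry.pair("Stearic acid", "Lauric acid")


@pytest.fixture(scope="session")
def all_pairs(registry):
    """Every unordered pair of packaged compounds, as ordered BinaryPairs."""
    comps = [registry[n] for n in registry.names]
    from bwsle import BinaryPair
    return [BinaryPair(a, b) for a, b in itertools.combinations(comps, 2)]
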