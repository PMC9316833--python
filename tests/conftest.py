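import pytest
from hypothesis import HealthCheck, settings

from ht6qsar import synthetic

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_molecules():
    return synthetic.make_toy_molecules()


@pytest.fixture(scope="session")
def toy(toy_molecules):
    return {m.mol_id: m for m in toy_molecules}
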