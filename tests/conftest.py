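import pytest

from ncaxis.synth import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """One deterministic synthetic fixture shared by read-only tests."""
    out = tmp_path_factory.mktemp("fixture")
    paths, truth = generate_fixture(FixtureConfig(rng_seed=101), out)
    return paths, truth
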