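import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    from termforge import fixtures as fx
    return fx.generate_worked_example(tmp_path_factory.mktemp("we"))


@pytest.fixture()
def toy_chain_index():
    """Five labelled classes in a subclass chain."""
    from termforge import fixtures as fx
    spec = fx.FixtureSpec(seed=1, n_classes=5, shape="chain",
                          definition_fraction=0.0)
    return fx.index_from_manifest(fx._toy_manifest(spec))
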