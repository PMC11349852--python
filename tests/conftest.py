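import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from luxmeta import FixtureSpec, build_registry, generate_bundle


@pytest.fixture(scope="session")
def registry():
    return build_registry("1.0")


@pytest.fixture()
def clean_bundle(registry):
    """A small valid-by-construction bundle (2 participants, 2 devices)."""
    return generate_bundle(FixtureSpec(seed=11, n_participants=2, n_devices=2), registry)


@pytest.fixture()
def fixture_tree(tmp_path, registry):
    """A bundle written to disk together with its light CSVs."""
    from luxmeta import write_fixture_tree

    spec = FixtureSpec(seed=5, n_participants=2, n_devices=1,
                       days=1.0, sampling_interval_s=60.0)
    bundle = write_fixture_tree(spec, tmp_path, registry)
    return tmp_path, bundle, spec
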