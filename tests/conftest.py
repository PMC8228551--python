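import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def packaged_reports():
    from mirnet_pd.fixtures import load_packaged_de_reports

    return load_packaged_de_reports()


@pytest.fixture(scope="session")
def packaged_sets(packaged_reports):
    from mirnet_pd.curation import consolidate_de_sets

    return consolidate_de_sets(packaged_reports)


@pytest.fixture(scope="session")
def packaged_studies():
    from mirnet_pd.fixtures import load_packaged_studies

    return load_packaged_studies()


@pytest.fixture(scope="session")
def packaged_targets():
    from mirnet_pd.fixtures import load_packaged_target_sets

    return load_packaged_target_sets()
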