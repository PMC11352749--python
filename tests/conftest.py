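import numpy as np
import pytest

from fcgan import FixtureConfig, extract_features, make_dataset, make_feature_fixture


@pytest.fixture(scope="session")
def small_fixture_config():
    """Small planted-signal cohort used by fast unit tests."""
    return FixtureConfig(
        regions=10,
        sites=(("A", 20, 20), ("B", 10, 10)),
        timepoints=(40, 60),
        planted_edges=((0, 1), (2, 3), (4, 5), (6, 7)),
        effect=0.4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_features(small_fixture_config):
    """Feature table planted directly at the feature level (fast path)."""
    return make_feature_fixture(small_fixture_config)


@pytest.fixture(scope="session")
def small_timeseries(small_fixture_config):
    return make_dataset(small_fixture_config)


@pytest.fixture(scope="session")
def planted_features():
    """The reference planted cohort: 16 regions, Δr=0.4, 200 subjects/class,
    multi-site, features computed from simulated time series."""
    cfg = FixtureConfig(seed=101)
    series, pheno = make_dataset(cfg)
    return extract_features(series, pheno)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
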