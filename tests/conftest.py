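import pytest

from pharmpred import (
    FixtureSpec,
    build_target_datasets,
    make_assay_table,
    make_atc_toyset,
    make_separable_library,
)


@pytest.fixture(scope="session")
def separable_library():
    """5 scaffold-classes x 10 decorated members, deterministic."""
    return make_separable_library(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def atc_toyset():
    return make_atc_toyset(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def assay_fixture():
    return make_assay_table(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def target_datasets(assay_fixture):
    activities, _ = assay_fixture
    return build_target_datasets(activities)


@pytest.fixture(scope="session")
def separable_target(target_datasets):
    datasets, _ = target_datasets
    return next(d for d in datasets if d.target_id == "T_SEP")
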