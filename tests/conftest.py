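import pytest

from grapepan.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized 17-accession cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_families=300, seed=11))


@pytest.fixture(scope="session")
def default_bundle_dir(default_cohort, tmp_path_factory):
    from grapepan.simulate import write_bundle

    d = tmp_path_factory.mktemp("bundle")
    write_bundle(default_cohort, d)
    return d
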