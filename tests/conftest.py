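import pytest

from s3ql import default_core, generate_fixture, load_core_model


@pytest.fixture(scope="session")
def core():
    return default_core()


@pytest.fixture(scope="session")
def skos_core():
    return load_core_model("skos")


@pytest.fixture()
def gi():
    """GI clinical-trials scenario: one deployment, two users, Fig-style
    permission assignments."""
    return generate_fixture("gi_trials", seed=0)


@pytest.fixture()
def mlst():
    """Three deployments behind one root registry, for federation tests."""
    return generate_fixture("mlst_mini", seed=0)
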