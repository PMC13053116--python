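import pytest

from genoprev.pipeline import RunConfig, run_pipeline
from genoprev.simulate import generate_gbe1_fixture


@pytest.fixture(scope="session")
def fixture_tables():
    """The deterministic GBE1 fixture bundle, generated once per session."""
    return generate_gbe1_fixture()


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A full --fixture --mode both pipeline run (reports + written files)."""
    out = tmp_path_factory.mktemp("fixture_run")
    return run_pipeline(RunConfig(out_dir=out, fixture=True, mode="both"))


@pytest.fixture(scope="session")
def conservative_report(fixture_bundle):
    return fixture_bundle["modes"]["conservative"]["report"]


@pytest.fixture(scope="session")
def relaxed_report(fixture_bundle):
    return fixture_bundle["modes"]["relaxed"]["report"]
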